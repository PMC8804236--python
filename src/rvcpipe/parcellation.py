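"""Parcellation specification: ROI inventory, tissue classes, and weights.

A parcellation divides the standard-space brain into regions of interest
(ROIs), each assigned to one of four tissue classes: gray matter (GM),
white matter (WM), cerebrospinal fluid (CSF), and ventricular ("deep")
cerebrospinal fluid (dCSF).  dCSF is carried as its own aggregation set
even though anatomically it is part of CSF; the whole-brain summary uses
GM/WM/CSF only.

Two kinds of weights live here:

* ``c_i`` — within-tissue ROI weights, the fraction of the tissue's total
  voxel count contributed by ROI *i*.  They sum to 1 within each tissue
  and turn ROI-level relative volume changes into a tissue-level change.
* ``w_X`` — fixed tissue weights for the whole-brain summary, the
  fraction of the ICBM152 template brain occupied by each tissue mask
  (GM 0.4262, WM 0.3912, CSF 0.1826).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

TISSUES = ("GM", "WM", "CSF", "dCSF")

#: Fraction of the ICBM152 (MNI-152 nonlinear 6th generation) template brain
#: covered by each binarized tissue mask.  Taken as constants.
DEFAULT_TISSUE_WEIGHTS: Mapping[str, float] = {
    "GM": 0.4262,
    "WM": 0.3912,
    "CSF": 0.1826,
}


@dataclass(frozen=True)
class Roi:
    roi_id: int
    tissue: str
    voxel_count: int


@dataclass
class ParcellationSpec:
    """ROI inventory with tissue classes, voxel counts, and weights.

    Parameters
    ----------
    rois
        Sequence of :class:`Roi` (or ``(roi_id, tissue, voxel_count)``
        tuples).  ROI ids must be unique positive integers and tissues
        one of ``GM``, ``WM``, ``CSF``, ``dCSF``.
    voxel_volume
        Volume of one voxel in mm³ (default 1.0, i.e. 1 mm isotropic).
    tissue_weights
        Whole-brain weights ``w_X`` for GM/WM/CSF.  Defaults to the
        ICBM152 mask fractions.
    """

    rois: Sequence[Roi]
    voxel_volume: float = 1.0
    tissue_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_WEIGHTS)
    )

    def __post_init__(self) -> None:
        rois = [r if isinstance(r, Roi) else Roi(*r) for r in self.rois]
        if not rois:
            raise ValueError("parcellation must contain at least one ROI")
        seen: set[int] = set()
        for r in rois:
            if r.roi_id in seen:
                raise ValueError(f"duplicate roi_id in parcellation: {r.roi_id}")
            seen.add(r.roi_id)
            if r.tissue not in TISSUES:
                raise ValueError(
                    f"unknown tissue label {r.tissue!r} for ROI {r.roi_id}; "
                    f"expected one of {TISSUES}"
                )
            if r.voxel_count <= 0:
                raise ValueError(f"ROI {r.roi_id} has non-positive voxel count")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")
        for x, w in self.tissue_weights.items():
            if x not in TISSUES:
                raise ValueError(f"tissue weight for unknown tissue {x!r}")
            if w <= 0:
                raise ValueError(f"non-positive tissue weight for {x}")
        object.__setattr__(self, "rois", tuple(rois))
        # cache the frame and the within-tissue weights
        df = pd.DataFrame(
            {
                "roi_id": [r.roi_id for r in rois],
                "tissue": [r.tissue for r in rois],
                "voxel_count": [r.voxel_count for r in rois],
            }
        )
        df["c_i"] = df["voxel_count"] / df.groupby("tissue")["voxel_count"].transform("sum")
        self._frame = df

    @property
    def frame(self) -> pd.DataFrame:
        """ROI table with columns roi_id, tissue, voxel_count, c_i."""
        return self._frame.copy()

    @property
    def tissues(self) -> tuple[str, ...]:
        present = self._frame["tissue"].unique().tolist()
        return tuple(t for t in TISSUES if t in present)

    @property
    def roi_ids(self) -> tuple[int, ...]:
        return tuple(self._frame["roi_id"])

    def roi_weights(self, tissue: str) -> pd.Series:
        """Within-tissue weights ``c_i`` indexed by roi_id; sum to 1."""
        sub = self._frame[self._frame["tissue"] == tissue]
        if sub.empty:
            raise ValueError(f"tissue {tissue!r} has no ROIs in this parcellation")
        return sub.set_index("roi_id")["c_i"]

    def rois_of(self, tissue: str) -> tuple[int, ...]:
        return tuple(self.roi_weights(tissue).index)

    # ------------------------------------------------------------------ I/O

    def to_dict(self) -> dict:
        return {
            "voxel_volume": self.voxel_volume,
            "tissue_weights": dict(self.tissue_weights),
            "rois": [
                {"roi_id": r.roi_id, "tissue": r.tissue, "voxel_count": r.voxel_count}
                for r in self.rois
            ],
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_parcellation(path: str | Path) -> ParcellationSpec:
    """Load a parcellation spec from YAML or JSON.

    The file holds ``rois`` (list of mappings with roi_id, tissue,
    voxel_count) and optionally ``voxel_volume`` and ``tissue_weights``;
    omitted tissue weights fall back to the ICBM152 defaults.
    """
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict) or "rois" not in payload:
        raise ValueError(f"parcellation file {path} lacks a 'rois' entry")
    rois = [
        Roi(int(r["roi_id"]), str(r["tissue"]), int(r["voxel_count"]))
        for r in payload["rois"]
    ]
    return ParcellationSpec(
        rois=rois,
        voxel_volume=float(payload.get("voxel_volume", 1.0)),
        tissue_weights=payload.get("tissue_weights", dict(DEFAULT_TISSUE_WEIGHTS)),
    )
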