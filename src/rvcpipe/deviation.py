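"""Control-referenced 95%-CI deviation maps.

For each tissue, the control (NCA) cohort's tissue-level change at
Retest defines a 95% reference interval.  Each collision-sport (CSA)
ROI is then flagged, per follow-up session, when its mean ROI-level
change across athletes lies strictly outside that interval: below the
lower bound (negative map) or above the upper bound (positive map).

The default reference is the population-style 95% interval of NCA
rTVC (mean +/- 1.96 s); the t-based CI of the NCA *mean*
(mean +/- t_{0.975,n-1} * s / sqrt(n)) is available via
``method="mean_ci"``.  The population interval is the default because
the mean-level CI shrinks as 1/sqrt(n) — the same rate at which cohort
means fluctuate — so under a null cohort entire tissues flip in and out
of the maps from seed to seed, whereas the population interval yields
stable, sparse maps (and an empty WM map) consistent with a
test-retest reference range.  Note the deliberate scale mismatch of the
procedure either way: ROI-level CSA means are compared against a
tissue-level control interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats as sps

from .parcellation import ParcellationSpec


@dataclass(frozen=True)
class ReferenceInterval:
    """95% reference interval of control rTVC for one tissue."""

    tissue: str
    lower: float
    upper: float
    n: int
    method: str  # "population" (mean +/- 1.96 s) or "mean_ci" (CI of the mean)

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("reference interval has lower > upper")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def build_reference(
    nca_rtvc: pd.DataFrame,
    tissue: str,
    session: str = "Retest",
    method: str = "population",
    conf_level: float = 0.95,
) -> ReferenceInterval:
    """Reference interval from NCA tissue-level change at Retest."""
    vals = nca_rtvc.loc[
        (nca_rtvc["tissue"] == tissue) & (nca_rtvc["session"] == session), "rtvc"
    ].to_numpy(dtype=float)
    n = len(vals)
    if n < 3:
        raise ValueError(f"reference interval for {tissue} needs n >= 3 controls, got {n}")
    mean = float(vals.mean())
    s = float(vals.std(ddof=1))
    if method == "mean_ci":
        half = float(sps.t.ppf(0.5 + conf_level / 2.0, n - 1)) * s / np.sqrt(n)
    elif method == "population":
        half = float(sps.norm.ppf(0.5 + conf_level / 2.0)) * s
    else:
        raise ValueError(f"unknown reference method {method!r}")
    return ReferenceInterval(tissue=tissue, lower=mean - half, upper=mean + half,
                             n=n, method=method)


@dataclass
class DeviationEntry:
    """Flagged ROIs for one (tissue, session)."""

    tissue: str
    session: str
    reference: ReferenceInterval
    positive_rois: tuple[int, ...]
    negative_rois: tuple[int, ...]
    roi_means: pd.DataFrame  # roi_id, mean_rrvc, n_athletes

    def __post_init__(self) -> None:
        overlap = set(self.positive_rois) & set(self.negative_rois)
        if overlap:
            raise ValueError(f"ROIs flagged both positive and negative: {sorted(overlap)}")


@dataclass
class DeviationMaps:
    entries: dict[tuple[str, str], DeviationEntry] = field(default_factory=dict)

    def add(self, entry: DeviationEntry) -> None:
        self.entries[(entry.tissue, entry.session)] = entry

    def flag_counts(self) -> pd.DataFrame:
        rows = [
            {
                "tissue": t, "session": s,
                "n_positive": len(e.positive_rois),
                "n_negative": len(e.negative_rois),
            }
            for (t, s), e in self.entries.items()
        ]
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (t, s), e in self.entries.items():
            for roi in e.positive_rois:
                rows.append({"tissue": t, "session": s, "roi_id": roi, "direction": "positive"})
            for roi in e.negative_rois:
                rows.append({"tissue": t, "session": s, "roi_id": roi, "direction": "negative"})
        return pd.DataFrame(rows, columns=["tissue", "session", "roi_id", "direction"])


def flag_rois(
    csa_rrvc: pd.DataFrame,
    session: str,
    reference: ReferenceInterval,
    parcellation: ParcellationSpec,
) -> DeviationEntry:
    """Flag tissue ROIs whose mean CSA rRVC leaves the reference interval.

    Strict inequalities at the bounds: a mean exactly on a bound is
    "within reference".  ROIs with no contributing athlete at the
    session are skipped with a warning.
    """
    tissue_rois = parcellation.rois_of(reference.tissue)
    sub = csa_rrvc[
        (csa_rrvc["session"] == session) & csa_rrvc["roi_id"].isin(tissue_rois)
    ]
    means = sub.groupby("roi_id")["rrvc"].agg(["mean", "count"])
    absent = sorted(set(tissue_rois) - set(means.index))
    if absent:
        warnings.warn(
            f"{reference.tissue} ROIs with no athletes at {session} skipped: {absent}"
        )
    positive = tuple(int(r) for r in means.index[means["mean"] > reference.upper])
    negative = tuple(int(r) for r in means.index[means["mean"] < reference.lower])
    roi_means = means.reset_index().rename(
        columns={"mean": "mean_rrvc", "count": "n_athletes"}
    )
    return DeviationEntry(
        tissue=reference.tissue,
        session=session,
        reference=reference,
        positive_rois=positive,
        negative_rois=negative,
        roi_means=roi_means,
    )


def build_deviation_maps(
    csa_rrvc: pd.DataFrame,
    nca_rtvc: pd.DataFrame,
    parcellation: ParcellationSpec,
    sessions: tuple[str, ...] = ("In1", "In2", "Post1", "Post2", "Post3"),
    tissues: tuple[str, ...] | None = None,
    method: str = "population",
) -> DeviationMaps:
    """Full deviation-map pass: one entry per (tissue, CSA session)."""
    maps = DeviationMaps()
    for tissue in tissues or parcellation.tissues:
        ref = build_reference(nca_rtvc, tissue, method=method)
        for session in sessions:
            if not (csa_rrvc["session"] == session).any():
                continue
            maps.add(flag_rois(csa_rrvc, session, ref, parcellation))
    return maps


def write_maps(
    maps: DeviationMaps,
    template: str | Path | nib.spatialimages.SpatialImage,
    parcellation: ParcellationSpec,
    outdir: str | Path,
) -> pd.DataFrame:
    """Serialize maps as NIfTI label images plus a tidy flag table.

    For each (tissue, session) and direction, an image containing only
    the flagged ROI labels is written — but only when the map is
    non-empty (an all-clear tissue, typically WM, produces no image).
    The flag table CSV is always written, empty or not.  Template labels
    must be a subset of the parcellation.
    """
    img = template if isinstance(template, nib.spatialimages.SpatialImage) else nib.load(
        str(template)
    )
    data = np.asanyarray(img.dataobj).astype(np.int32)
    labels = set(np.unique(data).tolist()) - {0}
    unknown = labels - set(parcellation.roi_ids)
    if unknown:
        raise ValueError(f"template labels not in parcellation: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flags = maps.to_frame()
    flags.to_csv(outdir / "deviation_flags.csv", index=False)
    for (tissue, session), entry in maps.entries.items():
        for direction, rois in (
            ("positive", entry.positive_rois),
            ("negative", entry.negative_rois),
        ):
            if not rois:
                continue
            mask = np.where(np.isin(data, list(rois)), data, 0).astype(np.int32)
            out_img = nib.Nifti1Image(mask, img.affine, dtype=np.int32)
            nib.save(out_img, outdir / f"{tissue}_{session}_{direction}.nii.gz")
    return flags


def read_map_labels(path: str | Path) -> set[int]:
    """Flagged ROI ids present in a written map image."""
    data = np.asanyarray(nib.load(str(path)).dataobj)
    return set(int(v) for v in np.unique(data) if v != 0)
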