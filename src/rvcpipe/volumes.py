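"""ROI volume tables: schema, CSV round-trip, and NIfTI label-image extraction.

The central container is a long-format :class:`pandas.DataFrame` with one
row per (athlete, session, ROI) and columns ``athlete_id``, ``group``
(CSA or NCA), ``sex``, ``sport``, ``session``, ``roi_id``, and
``volume_mm3``.  Volumes are strictly positive and the
(athlete, session, roi) key is unique.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .parcellation import ParcellationSpec

#: Documented column order of a volume table.
VOLUME_COLUMNS = (
    "athlete_id",
    "group",
    "sex",
    "sport",
    "session",
    "roi_id",
    "volume_mm3",
)

KEY_COLUMNS = ("athlete_id", "session", "roi_id")

CSA_SESSIONS = ("Pre", "In1", "In2", "Post1", "Post2", "Post3")
NCA_SESSIONS = ("Test", "Retest")
BASELINE_BY_GROUP = {"CSA": "Pre", "NCA": "Test"}


def validate_volume_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, key uniqueness, and positivity of a volume table."""
    missing = [c for c in VOLUME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"volume table missing columns: {missing}")
    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        first = df.loc[dup, list(KEY_COLUMNS)].iloc[0]
        raise ValueError(
            "duplicate (athlete, session, roi) record: "
            f"({first['athlete_id']}, {first['session']}, {first['roi_id']})"
        )
    if (df["volume_mm3"] <= 0).any():
        bad = df.loc[df["volume_mm3"] <= 0].iloc[0]
        raise ValueError(
            f"non-positive volume for athlete {bad['athlete_id']}, "
            f"session {bad['session']}, ROI {bad['roi_id']}"
        )
    return df


def read_volume_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a volume table CSV."""
    df = pd.read_csv(path)
    df["roi_id"] = df["roi_id"].astype(int)
    return validate_volume_table(df)


def write_volume_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a validated volume table to CSV (documented column order)."""
    validate_volume_table(df)
    df.loc[:, list(VOLUME_COLUMNS)].to_csv(path, index=False)


def extract_roi_volumes(
    label_image: str | Path | nib.spatialimages.SpatialImage,
    parcellation: ParcellationSpec,
) -> pd.DataFrame:
    """Quantify ROI volumes (mm³) from an integer-labeled NIfTI image.

    Each ROI's volume is its voxel count in the image times the voxel
    volume from the image header.  Labels are interpreted in voxel space;
    no resampling is applied.  Background is label 0.

    Returns a frame with columns ``roi_id``, ``tissue``, ``volume_mm3``.
    ROIs of the parcellation absent from the image get volume 0 with a
    warning; labels present in the image but unknown to the parcellation
    raise an error listing the orphans.
    """
    img = label_image if isinstance(label_image, nib.spatialimages.SpatialImage) else nib.load(
        str(label_image)
    )
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any((z is None) or not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError("label image header lacks valid voxel dimensions")
    voxel_mm3 = float(np.prod(zooms))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError("label image contains non-integer values")
        data = rounded.astype(np.int64)
    labels, counts = np.unique(data, return_counts=True)
    count_of = dict(zip(labels.tolist(), counts.tolist()))
    count_of.pop(0, None)
    known = set(parcellation.roi_ids)
    orphans = sorted(set(count_of) - known)
    if orphans:
        raise ValueError(f"labels present in image but not in parcellation: {orphans}")
    records = []
    parc = parcellation.frame
    for roi_id, tissue in zip(parc["roi_id"], parc["tissue"]):
        n = count_of.get(roi_id, 0)
        if n == 0:
            warnings.warn(f"ROI {roi_id} absent from label image; volume set to 0")
        records.append({"roi_id": roi_id, "tissue": tissue, "volume_mm3": n * voxel_mm3})
    return pd.DataFrame.from_records(records)
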