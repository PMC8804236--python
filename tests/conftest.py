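import numpy as np
import pandas as pd
import pytest

from rvcpipe import ParcellationSpec, Roi


@pytest.fixture
def small_parcellation() -> ParcellationSpec:
    """Two GM ROIs (300/700 voxels), one WM, one CSF, two dCSF ROIs."""
    return ParcellationSpec(
        rois=[
            Roi(1, "GM", 300),
            Roi(2, "GM", 700),
            Roi(3, "WM", 500),
            Roi(4, "CSF", 200),
            Roi(5, "dCSF", 60),
            Roi(6, "dCSF", 40),
        ]
    )


def make_volume_table(records) -> pd.DataFrame:
    """records: (athlete_id, group, session, roi_id, volume)."""
    rows = [
        {
            "athlete_id": a,
            "group": g,
            "sex": "M",
            "sport": "football" if g == "CSA" else "non-collision",
            "session": s,
            "roi_id": roi,
            "volume_mm3": float(v),
        }
        for a, g, s, roi, v in records
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
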