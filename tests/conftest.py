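import numpy as np
import pandas as pd
import pytest

from mctarget import Cohort, make_published_fixtures


def long_rows(pid, site, markers_h, block=None, sample="S1"):
    """One row per marker for a single sample, canonical long format."""
    block = block or f"{site}_T1"
    return [
        {
            "patient_id": pid,
            "site_label": site,
            "block_id": block,
            "sample_id": sample,
            "marker": m,
            "h_score": h,
            "pct_level0": np.nan,
            "pct_level1": np.nan,
            "pct_level2": np.nan,
        }
        for m, h in markers_h.items()
    ]


def cohort_from_scores(sample_scores):
    """Build a Cohort from [(pid, site, block, sample, {marker: h}), ...]."""
    rows = []
    for pid, site, block, sample, markers_h in sample_scores:
        rows.extend(long_rows(pid, site, markers_h, block=block, sample=sample))
    return Cohort(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def published_fixtures():
    return make_published_fixtures()
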