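import numpy as np
import pandas as pd
import pytest

from hypermut.catalogue import synthetic_catalogue
from hypermut.cohort import SimulationConfig, simulate_cohort, simulate_counts


@pytest.fixture(scope="session")
def catalogue():
    return synthetic_catalogue()


@pytest.fixture(scope="session")
def small_cohort():
    """200-trio cohort with full DNM records (shared, read-only)."""
    return simulate_cohort(SimulationConfig(n_trios=200, seed=11))


@pytest.fixture(scope="session")
def big_counts():
    """5000-trio counts-only table (shared, read-only)."""
    return simulate_counts(SimulationConfig(n_trios=5000, seed=3))


@pytest.fixture
def base_call():
    """A clean autosomal DNM record passing every filter rule."""
    return dict(trio_id="t1", child_id="c1", chrom="1", pos=1000, ref="C",
                alt="T", gt_child="0/1", gt_father="0/0", gt_mother="0/0",
                rd_child=30, rd_father=30, rd_mother=30,
                altreads_father=0, altreads_mother=0, altreads_child=15,
                vaf_child=0.5, vartype="SNV")


def make_calls(base, *overrides):
    rows = [dict(base)]
    for i, ov in enumerate(overrides, start=1):
        row = dict(base)
        row.update({"pos": base["pos"] + 1000 * i})
        row.update(ov)
        rows.append(row)
    return pd.DataFrame(rows)
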