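import numpy as np
import pandas as pd
import pytest

from snpnet import synthdata
from snpnet.geno_core import CohortDataset, SupersetFrequencyTable, parse_dataset


def make_dataset(rows, groups=None):
    """Build a CohortDataset from (sample_id, group, call, call, ...) tuples."""
    n_markers = len(rows[0]) - 2
    columns = ["sample_id", "group"] + [f"M{i + 1}" for i in range(n_markers)]
    return parse_dataset(pd.DataFrame(rows, columns=columns), groups=groups)


def make_freq(rows, groups):
    """Build a SupersetFrequencyTable from {superset: (count per group)}."""
    counts = pd.DataFrame.from_dict(
        {sup: list(c) for sup, c in rows.items()}, orient="index", columns=list(groups)
    ).sort_index()
    counts.index.name = "superset"
    return SupersetFrequencyTable(counts=counts, totals=counts.sum(axis=0))


def random_dataset(rng, n_individuals, n_markers, n_groups=2):
    codes = rng.integers(0, 3, size=(n_individuals, n_markers)).astype(np.uint8)
    groups = tuple(f"g{i}" for i in range(n_groups))
    group_codes = rng.integers(0, n_groups, size=n_individuals).astype(np.intp)
    # ensure every declared group is populated
    group_codes[:n_groups] = np.arange(n_groups)
    return CohortDataset(
        marker_names=tuple(f"M{j + 1}" for j in range(n_markers)),
        groups=groups,
        sample_ids=tuple(f"s{i}" for i in range(n_individuals)),
        group_codes=group_codes,
        codes=codes,
    )


@pytest.fixture(scope="session")
def acs_cohort():
    """The two-group study-sized synthetic cohort (91 cases / 86 controls)."""
    return synthdata.generate_cohort(synthdata.acs_like(seed=11))


@pytest.fixture(scope="session")
def oral_cohort():
    """The three-group synthetic cohort (369/219/298)."""
    return synthdata.generate_cohort(synthdata.oral_like(seed=11))
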