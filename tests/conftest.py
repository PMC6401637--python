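import numpy as np
import pandas as pd
import pytest

from fosnet import (
    GroupDesign,
    RegionActivityTable,
    SyntheticNetworkSpec,
    generate_activity,
)


@pytest.fixture
def small_table():
    """4 regions x 8 subjects, two groups of 4, hand-set counts."""
    rng = np.random.default_rng(42)
    counts = rng.uniform(10, 90, size=(4, 8))
    regions = ["A", "B", "C", "D"]
    subjects = [f"s{i}" for i in range(8)]
    table = RegionActivityTable(regions=regions, subject_ids=subjects, counts=counts)
    design = GroupDesign(
        pd.DataFrame(
            {
                "subject_id": subjects,
                "genotype": ["WT"] * 4 + ["KO"] * 4,
                "condition": ["conspecific"] * 8,
            }
        )
    )
    return table, design


@pytest.fixture
def default_run():
    """One full-design synthetic draw (6 groups x 7 subjects, 21 regions)."""
    spec = SyntheticNetworkSpec(seed=7)
    return generate_activity(spec)
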