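import numpy as np
import pytest

from micquant.calibration import CalibratedProfile
from micquant.decontamination import TriplicateSet
from micquant.io_tables import load_reference_accuracy_table


@pytest.fixture(scope="session")
def reference_table():
    """Packaged validation-series measurements (16 taxon/level rows x 2 methods)."""
    return load_reference_accuracy_table()


@pytest.fixture(scope="session")
def reference_replicates(reference_table):
    """(taxon, level, method) -> the three replicate copy values."""
    return {
        (r.taxon, float(r.input_copies), r.method): (r.rep1, r.rep2, r.rep3)
        for r in reference_table.itertuples()
    }


def make_triplicate(group_id, per_otu_copies, factor=1.0):
    """Build a TriplicateSet from {otu: (c1, c2, c3)} copy values."""
    profiles = []
    for i in range(3):
        copies = {otu: float(vals[i]) for otu, vals in per_otu_copies.items() if vals[i] > 0}
        profiles.append(CalibratedProfile(f"{group_id}_r{i + 1}", copies, factor))
    return TriplicateSet(group_id, tuple(profiles))


@pytest.fixture
def make_trip():
    return make_triplicate
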