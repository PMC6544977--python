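import pytest

import hsmkit as hk
from hsmkit.model import ThresholdKey


@pytest.fixture(scope="session")
def toy():
    return hk.toy_two_gene_model()


@pytest.fixture(scope="session")
def phage():
    return hk.phage_lambda_model()


@pytest.fixture(scope="session")
def toy_orderings(toy):
    """The six joint toy orderings in canonical (table) order."""
    s1 = hk.enumerate_orderings(toy, hk.OrderingConstraints(), "s1")
    assert len(s1) == 1
    s2 = hk.enumerate_orderings(toy, hk.OrderingConstraints(), "s2")
    return [o.merge(s1[0]) for o in s2]


@pytest.fixture(scope="session")
def phage_sweep(phage):
    """Full 500-ordering sweep of the phage model (built once per session)."""
    return hk.sweep_orderings(
        phage,
        [hk.phage_constraint_set("free_interleave"), hk.phage_constraint_set("or2_ol2_equal")],
    )


def cro_wild_type(ordering) -> bool:
    """Wild-type condition: both Cro thresholds for bOR2 strictly below the
    corresponding Cro thresholds for bOL2."""
    r = ordering.rank_map("Cro")
    return (
        r[ThresholdKey("Cro", "bOR2", "assoc")] < r[ThresholdKey("Cro", "bOL2", "assoc")]
        and r[ThresholdKey("Cro", "bOR2", "dissoc")] < r[ThresholdKey("Cro", "bOL2", "dissoc")]
    )
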