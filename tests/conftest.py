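import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirscreen.netbuild import (
    PREDICTED,
    VALIDATED_HIGH,
    VALIDATED_LOW,
    DiseaseNetwork,
    EvidenceEdge,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

PREDICTED_SOURCES = ("HOCTAR", "ExprTargetDB", "starBase")


@pytest.fixture
def predicted_sources():
    return PREDICTED_SOURCES


@pytest.fixture
def toy_disease_network():
    """{(A,g1),(A,g2),(A,g3),(B,g3)}: single-line of A = {g1,g2}, of B = {}."""
    edges = [("A", "g1"), ("A", "g2"), ("A", "g3"), ("B", "g3")]
    return DiseaseNetwork(
        edges=edges,
        de_mirnas={"A", "B"},
        de_genes={"g1", "g2", "g3"},
        gene_is_tf={"g1": True, "g2": False, "g3": False},
    )


def make_edge(mirna, gene, evidence=VALIDATED_LOW, source="miRTarBase", tf=False):
    return EvidenceEdge(mirna, gene, evidence, source, tf)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
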