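"""Evidence-filtered miRNA→mRNA reference network and disease subnetwork.

The reference network is assembled from an edge list in which every record
carries an evidence type and a source database label. A (miRNA, gene) pair
is retained when it is validated by at least one low-throughput experiment,
or when it is predicted by at least two of the three computational
prediction databases. Pairs supported only by high-throughput validation
are conservatively dropped. The disease-specific network is the subgraph
induced by mapping the DE-miRNA and DE-mRNA sets onto the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

VALIDATED_LOW = "validated_low_throughput"
VALIDATED_HIGH = "validated_high_throughput"
PREDICTED = "predicted"
EVIDENCE_TYPES = frozenset({VALIDATED_LOW, VALIDATED_HIGH, PREDICTED})


@dataclass(frozen=True)
class EvidenceEdge:
    """One interaction record from one source database."""

    mirna_id: str
    gene_id: str
    evidence_type: str
    source: str
    gene_is_tf: bool = False


@dataclass
class ReferenceNetwork:
    """Deduplicated bipartite miRNA→gene network after evidence filtering."""

    edges: list[tuple[str, str]]
    gene_is_tf: dict[str, bool]
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.edges}

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.edges}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for m, t in self.edges:
            g.add_node(m, bipartite="mirna")
            g.add_node(t, bipartite="gene", is_tf=self.gene_is_tf.get(t, False))
            g.add_edge(m, t, evidence=self.evidence.get((m, t), ""))
        return g


@dataclass
class DiseaseNetwork:
    """Subnetwork of the reference induced by DE feature sets.

    Nodes exist only through retained edges; ``gene_is_tf`` covers every gene
    that appears as a target.
    """

    edges: list[tuple[str, str]]
    de_mirnas: set[str]
    de_genes: set[str]
    gene_is_tf: dict[str, bool]

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.edges}

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.edges}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for m, t in self.edges:
            g.add_node(m, bipartite="mirna")
            g.add_node(t, bipartite="gene", is_tf=self.gene_is_tf.get(t, False))
            g.add_edge(m, t)
        return g


def build_reference_network(edges: list[EvidenceEdge],
                            predicted_sources: tuple[str, ...] | list[str],
                            min_predicted_sources: int = 2) -> ReferenceNetwork:
    """Apply the evidence-retention rule and deduplicate.

    A pair is retained iff it has ≥1 ``validated_low_throughput`` record, or
    records from ≥ ``min_predicted_sources`` distinct predicted sources (the
    2-of-3 rule). Pairs with only high-throughput validation are dropped.
    """
    predicted_sources = tuple(predicted_sources)
    if len(predicted_sources) != 3:
        raise ValueError(f"expected exactly 3 prediction databases, got {len(predicted_sources)}")

    by_pair: dict[tuple[str, str], dict] = {}
    seen_records: set[tuple[str, str, str]] = set()
    for e in edges:
        if e.evidence_type not in EVIDENCE_TYPES:
            raise ValueError(f"unknown evidence type {e.evidence_type!r}")
        if e.evidence_type == PREDICTED and e.source not in predicted_sources:
            raise ValueError(f"predicted edge with unknown prediction source {e.source!r}")
        rec = (e.mirna_id, e.gene_id, e.source)
        if rec in seen_records:
            continue
        seen_records.add(rec)
        slot = by_pair.setdefault((e.mirna_id, e.gene_id), {
            "validated_low": False, "pred_sources": set(), "is_tf": False,
        })
        if e.evidence_type == VALIDATED_LOW:
            slot["validated_low"] = True
        elif e.evidence_type == PREDICTED:
            slot["pred_sources"].add(e.source)
        slot["is_tf"] = slot["is_tf"] or e.gene_is_tf

    retained: list[tuple[str, str]] = []
    gene_is_tf: dict[str, bool] = {}
    evidence: dict[tuple[str, str], str] = {}
    for pair in sorted(by_pair):
        slot = by_pair[pair]
        tags = []
        if slot["validated_low"]:
            tags.append(VALIDATED_LOW)
        if len(slot["pred_sources"]) >= min_predicted_sources:
            tags.append(f"{PREDICTED}:{len(slot['pred_sources'])}of{len(predicted_sources)}")
        if tags:
            retained.append(pair)
            evidence[pair] = "+".join(tags)
            g = pair[1]
            gene_is_tf[g] = gene_is_tf.get(g, False) or slot["is_tf"]
    return ReferenceNetwork(edges=retained, gene_is_tf=gene_is_tf, evidence=evidence)


def extract_disease_network(ref: ReferenceNetwork,
                            de_mirnas: set[str],
                            de_genes: set[str],
                            mode: str = "strict") -> DiseaseNetwork:
    """Map DE sets onto the reference.

    ``strict`` keeps edge (m, g) iff both endpoints are DE; ``either`` keeps
    it if at least one endpoint is DE. DE ids absent from the reference are
    ignored with a logged warning.
    """
    if mode not in ("strict", "either"):
        raise ValueError(f"mode must be 'strict' or 'either', got {mode!r}")
    de_mirnas = set(de_mirnas)
    de_genes = set(de_genes)
    absent = (de_mirnas - ref.mirnas) | (de_genes - ref.genes)
    if absent:
        logger.warning("%d DE ids absent from the reference network are ignored", len(absent))

    if mode == "strict":
        edges = [(m, g) for m, g in ref.edges if m in de_mirnas and g in de_genes]
    else:
        edges = [(m, g) for m, g in ref.edges if m in de_mirnas or g in de_genes]
    genes = {g for _, g in edges}
    return DiseaseNetwork(
        edges=edges,
        de_mirnas=de_mirnas & ref.mirnas,
        de_genes=de_genes & ref.genes,
        gene_is_tf={g: ref.gene_is_tf.get(g, False) for g in genes},
    )


def network_summary(net: ReferenceNetwork | DiseaseNetwork) -> tuple[int, int, int]:
    """(n_mirnas, n_genes, n_edges) over distinct nodes and edges."""
    return len(net.mirnas), len(net.genes), len(set(net.edges))


# ---------------------------------------------------------------------------
# TSV dialect (shared with mirscreen.synthetic writers)

EDGE_COLUMNS = ["mirna_id", "gene_id", "evidence_type", "source", "gene_is_tf"]


def read_edges_tsv(path: str | Path) -> list[EvidenceEdge]:
    df = pd.read_csv(path, sep="\t")
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"edge TSV missing columns {sorted(missing)} "
                         "(edge direction must be miRNA→gene; swapped columns are rejected)")
    return [
        EvidenceEdge(str(r.mirna_id), str(r.gene_id), str(r.evidence_type),
                     str(r.source), bool(int(r.gene_is_tf)))
        for r in df.itertuples(index=False)
    ]


def write_network_tsv(net: ReferenceNetwork | DiseaseNetwork, path: str | Path) -> None:
    """Write retained (mirna, gene) pairs with the gene TF flag."""
    rows = [{"mirna_id": m, "gene_id": g, "gene_is_tf": int(net.gene_is_tf.get(g, False))}
            for m, g in net.edges]
    pd.DataFrame(rows, columns=["mirna_id", "gene_id", "gene_is_tf"]).to_csv(
        path, sep="\t", index=False)


def read_network_tsv(path: str | Path) -> DiseaseNetwork:
    df = pd.read_csv(path, sep="\t")
    edges = [(str(m), str(g)) for m, g in zip(df["mirna_id"], df["gene_id"])]
    tf = {str(g): bool(int(t)) for g, t in zip(df["gene_id"], df["gene_is_tf"])}
    return DiseaseNetwork(edges=edges, de_mirnas={m for m, _ in edges},
                          de_genes={g for _, g in edges}, gene_is_tf=tf)
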