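"""Network-vulnerability screen for candidate biomarker miRNAs.

A miRNA whose regulatory activity in the disease network is unusually
*unique* — many of its targets are regulated by no other miRNA, and those
exclusive targets are enriched for transcription factors — is a vulnerable
point of the network and a biomarker candidate. Two statistics capture
this per miRNA:

* NSR (negative/single-line regulation ratio): the fraction of a miRNA's
  targets with in-degree 1, i.e. regulated by that miRNA alone;
* TSP (TF single-line percentage): the fraction of those single-line
  targets annotated as transcription factors.

Both are referred to a degree-preserving null obtained by rewiring the
bipartite network with double-edge swaps (miRNA out-degrees and gene
in-degrees are conserved exactly), giving one-sided upper-tail permutation
p-values with the +1/(N+1) small-sample correction. The NSR p-value
compares single-line target counts (same denominator as the observed
ratio); the TSP p-value compares the *count* of TF-annotated single-line
targets rather than the fraction — with few single-line targets the
fraction saturates at 1 under the null and carries almost no evidence,
whereas the count accumulates it. Candidates must clear
both p-value thresholds; ranking is by ascending p_nsr, then ascending
p_tsp, then descending NSR, then id — a deterministic total order.

Because double-edge swaps conserve every gene's in-degree, the *set* of
single-line genes is identical in every rewired replicate; only which
miRNA each one attaches to varies. Each replicate therefore costs O(|E|)
beyond the swaps themselves.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .netbuild import DiseaseNetwork, ReferenceNetwork

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 1000
#: swap attempts per rewired replicate, as a multiple of the edge count
SWAPS_PER_EDGE = 10


@dataclass
class VulnerabilityScore:
    mirna_id: str
    n_targets: int
    n_single_line: int
    nsr: float
    tsp: float
    tsp_defined: bool
    p_nsr: float
    p_tsp: float
    rank: int = 0
    is_candidate: bool = False


def single_line_targets(net: DiseaseNetwork | ReferenceNetwork, mirna_id: str) -> set[str]:
    """Targets of ``mirna_id`` regulated by no other miRNA (in-degree 1)."""
    if mirna_id not in net.mirnas:
        raise KeyError(f"{mirna_id!r} not in network")
    indeg: dict[str, int] = {}
    for _, g in net.edges:
        indeg[g] = indeg.get(g, 0) + 1
    return {g for m, g in net.edges if m == mirna_id and indeg[g] == 1}


def _observed_stats(m_idx: list[int], g_idx: list[int], deg: np.ndarray,
                    tf: np.ndarray, n_mirnas: int, n_genes: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-miRNA single-line target count and TF count among them."""
    indeg = np.zeros(n_genes, dtype=np.int64)
    for g in g_idx:
        indeg[g] += 1
    singles = np.zeros(n_mirnas, dtype=np.int64)
    tf_singles = np.zeros(n_mirnas, dtype=np.int64)
    for m, g in zip(m_idx, g_idx):
        if indeg[g] == 1:
            singles[m] += 1
            if tf[g]:
                tf_singles[m] += 1
    return singles, tf_singles


def vulnerability_scores(net: DiseaseNetwork | ReferenceNetwork,
                         n_permutations: int = DEFAULT_N_PERMUTATIONS,
                         seed: int = 0) -> list[VulnerabilityScore]:
    """Score every miRNA in the network against the rewiring null.

    ``p_nsr``/``p_tsp`` are upper-tail permutation p-values with the
    ``(1 + #{null >= observed}) / (n_permutations + 1)`` correction, so they
    lie in (0, 1]. The null statistic for ``p_nsr`` is the single-line
    target count, for ``p_tsp`` the TF-annotated single-line target count.
    A miRNA with no single-line targets has TSP undefined and ``p_tsp = 1``
    (no evidence of uniqueness).
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive (null undefined otherwise)")
    edges = sorted(set(net.edges))
    if not edges:
        raise ValueError("cannot score an empty network")

    mirnas = sorted({m for m, _ in edges})
    genes = sorted({g for _, g in edges})
    m_index = {m: i for i, m in enumerate(mirnas)}
    g_index = {g: i for i, g in enumerate(genes)}
    n_m, n_g = len(mirnas), len(genes)
    m_idx = [m_index[m] for m, _ in edges]
    g_idx = [g_index[g] for _, g in edges]
    n_edges = len(edges)

    tf = np.array([bool(net.gene_is_tf.get(g, False)) for g in genes])
    if not tf.any():
        logger.warning("no gene in the network carries a TF annotation; TSP is identically 0")

    deg = np.zeros(n_m, dtype=np.int64)
    for m in m_idx:
        deg[m] += 1

    obs_singles, obs_tf = _observed_stats(m_idx, g_idx, deg, tf, n_m, n_g)
    obs_tsp = np.where(obs_singles > 0, obs_tf / np.maximum(obs_singles, 1), 0.0)

    ge_nsr = np.zeros(n_m, dtype=np.int64)
    ge_tsp = np.zeros(n_m, dtype=np.int64)
    rng = np.random.default_rng(seed)
    n_attempts = SWAPS_PER_EDGE * n_edges
    tf_list = tf.tolist()

    for _ in range(n_permutations):
        g_cur = list(g_idx)
        adj = {m * n_g + g for m, g in zip(m_idx, g_cur)}
        pairs = rng.integers(0, n_edges, size=(n_attempts, 2)).tolist()
        for a, b in pairs:
            ga = g_cur[a]
            gb = g_cur[b]
            if ga == gb:
                continue
            ma = m_idx[a]
            mb = m_idx[b]
            k1 = ma * n_g + gb
            k2 = mb * n_g + ga
            if k1 in adj or k2 in adj:
                continue
            adj.remove(ma * n_g + ga)
            adj.remove(mb * n_g + gb)
            adj.add(k1)
            adj.add(k2)
            g_cur[a] = gb
            g_cur[b] = ga

        # in-degrees are conserved, so recompute singles from the new wiring
        indeg = [0] * n_g
        for g in g_cur:
            indeg[g] += 1
        null_singles = [0] * n_m
        null_tf = [0] * n_m
        for m, g in zip(m_idx, g_cur):
            if indeg[g] == 1:
                null_singles[m] += 1
                if tf_list[g]:
                    null_tf[m] += 1
        for m in range(n_m):
            if null_singles[m] >= obs_singles[m]:
                ge_nsr[m] += 1
            if null_tf[m] >= obs_tf[m]:
                ge_tsp[m] += 1

    p_nsr = (1 + ge_nsr) / (n_permutations + 1)
    p_tsp = (1 + ge_tsp) / (n_permutations + 1)

    scores = []
    for i, m in enumerate(mirnas):
        defined = obs_singles[i] > 0
        scores.append(VulnerabilityScore(
            mirna_id=m,
            n_targets=int(deg[i]),
            n_single_line=int(obs_singles[i]),
            nsr=float(obs_singles[i] / deg[i]),
            tsp=float(obs_tsp[i]) if defined else 0.0,
            tsp_defined=bool(defined),
            p_nsr=float(p_nsr[i]),
            p_tsp=float(p_tsp[i]) if defined else 1.0,
        ))
    scores.sort(key=lambda s: (s.p_nsr, s.p_tsp, -s.nsr, s.mirna_id))
    for rank, s in enumerate(scores, start=1):
        s.rank = rank
    return scores


def screen_candidates(scores: list[VulnerabilityScore],
                      alpha_nsr: float = 0.05,
                      alpha_tsp: float = 0.05) -> list[VulnerabilityScore]:
    """Candidates clear both permutation thresholds, returned in rank order."""
    out = []
    for s in sorted(scores, key=lambda s: s.rank):
        s.is_candidate = s.p_nsr < alpha_nsr and s.p_tsp < alpha_tsp
        if s.is_candidate:
            out.append(s)
    return out


def scores_frame(scores: list[VulnerabilityScore]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in sorted(scores, key=lambda s: s.rank)])


def write_scores_tsv(scores: list[VulnerabilityScore], path: str | Path) -> None:
    scores_frame(scores).to_csv(path, sep="\t", index=False)


def write_candidates_json(scores: list[VulnerabilityScore], path: str | Path) -> None:
    payload = [asdict(s) for s in scores if s.is_candidate]
    Path(path).write_text(json.dumps(payload, indent=2))
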