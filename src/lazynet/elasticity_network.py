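"""Ensemble Jacobian elasticities and seed-based subgraph expansion.

An elasticity is the local directed sensitivity of one gene's one-step
prediction to another gene's baseline level.  The signed matrix S is
oriented source-row -> target-column: ``S[g, i] = d(predicted x_i)/d(x_g)``
at a common baseline, so row g lists genes downstream of g and column g
lists genes upstream of g.  (The opposite convention is equally common;
this one is fixed here and used consistently by the expansion and all
downstream statistics.)

Seed expansion grows a directed subgraph breadth-first from anchor genes,
keeping per-hop the top-N neighbors whose |elasticity| clears both an
absolute floor and a percentile of the frontier gene's own ranked
candidate list.  Benchmark recall/enrichment then measure how much of a
curated regulator set the expanded graph recovers versus uniform chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_model import (
    EnsembleModel,
    ExpressionState,
    ShapeError,
    ValidationError,
)

__all__ = [
    "ElasticityMatrix",
    "ExpansionConfig",
    "Subgraph",
    "RecallReport",
    "compute_elasticity_matrix",
    "expand_seed",
    "merge_subgraphs",
    "benchmark_recall",
    "mean_per_seed_recall",
    "elasticity_rank_pvalues",
    "apply_bh_filter",
    "write_subgraph_tsv",
    "read_subgraph_tsv",
]


@dataclass
class ElasticityMatrix:
    """Signed source -> target sensitivity matrix at a baseline state."""

    signed: np.ndarray
    gene_ids: tuple
    baseline: ExpressionState | None = None

    def __post_init__(self):
        self.signed = np.asarray(self.signed, dtype=float)
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        d = len(self.gene_ids)
        if self.signed.shape != (d, d):
            raise ShapeError("signed matrix must be square over the panel")
        if not np.all(np.isfinite(self.signed)):
            bad = np.argwhere(~np.isfinite(self.signed))
            pairs = [
                (self.gene_ids[i], self.gene_ids[j]) for i, j in bad[:5]
            ]
            raise ValidationError(f"non-finite elasticities at {pairs}")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def abs(self) -> np.ndarray:
        return np.abs(self.signed)

    def index(self, gene: str) -> int:
        if gene not in self._index:
            raise ValidationError(f"gene {gene!r} not in elasticity panel")
        return self._index[gene]


def compute_elasticity_matrix(
    ensemble: EnsembleModel,
    baseline: ExpressionState,
    include_identity: bool = False,
    panel=None,
) -> ElasticityMatrix:
    """Member-averaged Jacobian of the one-step prediction at a baseline.

    With ``include_identity=False`` (default) the residual path's identity
    contribution is excluded, i.e. S reflects only dt * dF/dx; the identity
    merely shifts the diagonal and never affects off-diagonal edges.
    ``panel`` optionally restricts rows/columns to a gene subset (e.g.
    protein-coding genes).
    """
    if baseline.dimension != ensemble.dimension:
        raise ShapeError("baseline dimension != ensemble dimension")
    d = baseline.dimension
    acc = np.zeros((d, d))
    for member in ensemble.members:
        acc += member.dt * member.jacobian_rate(baseline.values)
    jac = acc / len(ensemble.members)  # rows = targets, cols = sources
    if include_identity:
        jac = jac + np.eye(d)
    signed = jac.T  # source-row -> target-column
    gene_ids = (
        ensemble.gene_ids if ensemble.gene_ids is not None else baseline.gene_ids
    )
    em = ElasticityMatrix(signed, gene_ids, baseline)
    if panel is not None:
        idx = np.array([em.index(g) for g in panel])
        em = ElasticityMatrix(
            signed[np.ix_(idx, idx)], tuple(panel), baseline
        )
    return em


@dataclass
class ExpansionConfig:
    """Seed-expansion knobs mirroring the --top/--depth/--pct CLI flags."""

    top: int = 32
    depth: int = 4
    pct: float | None = 99.0
    floor: float = 0.001
    bh_q: float = 1.0

    def __post_init__(self):
        if self.top < 1 or self.depth < 1:
            raise ValidationError("top and depth must be >= 1")
        if not self.floor > 0:
            raise ValidationError("floor must be positive")
        if self.pct is not None and not 0 < self.pct < 100:
            raise ValidationError("pct must be in (0, 100) or None")


@dataclass
class Subgraph:
    """Directed scored edge set: nodes + {(source, target): attrs}."""

    nodes: set = field(default_factory=set)
    edges: dict = field(default_factory=dict)  # (src, tgt) -> attrs dict
    seeds: set = field(default_factory=set)

    def __post_init__(self):
        self.nodes = set(self.nodes)
        for (s, t), attrs in self.edges.items():
            if s == t:
                raise ValidationError(f"self-loop on {s!r}")
            if s not in self.nodes or t not in self.nodes:
                raise ValidationError(f"edge endpoint outside node set: {(s, t)}")
            attrs.setdefault("sign", 1)
            attrs.setdefault("hop", 0)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def undirected_pairs(self) -> set:
        return {frozenset(e) for e in self.edges}

    def add_edge(self, src, tgt, score, sign, hop):
        self.nodes.add(src)
        self.nodes.add(tgt)
        key = (src, tgt)
        old = self.edges.get(key)
        if old is None or score > old["score"]:
            self.edges[key] = {"score": score, "sign": sign, "hop": hop}
        elif old is not None:
            old["hop"] = min(old["hop"], hop)


def _candidates(A: np.ndarray, S: np.ndarray, g: int, gene_ids):
    """Directed candidates at a frontier gene: its row (downstream edges
    g -> j) and its column (upstream edges j -> g), self excluded."""
    d = A.shape[0]
    cands = []
    for j in range(d):
        if j == g:
            continue
        cands.append((gene_ids[j], "down", A[g, j], int(np.sign(S[g, j]) or 1)))
        cands.append((gene_ids[j], "up", A[j, g], int(np.sign(S[j, g]) or 1)))
    return cands


def expand_seed(
    elasticity: ElasticityMatrix, seed_gene: str, config: ExpansionConfig
) -> Subgraph:
    """Breadth-first subgraph expansion from one anchor gene.

    At each frontier gene the union of its row (downstream) and column
    (upstream) |elasticity| entries forms the candidate list; candidates
    must clear the absolute floor AND exceed the ``pct`` percentile of that
    gene's own full ranked candidate list.  The top ``config.top`` surviving
    neighbors (ranked by best score, ties broken by gene id) are admitted
    with every passing directed edge; already-visited genes contribute
    edges but are not re-expanded.
    """
    A, S = elasticity.abs, elasticity.signed
    gene_ids = elasticity.gene_ids
    elasticity.index(seed_gene)  # raises if absent
    graph = Subgraph(nodes={seed_gene}, seeds={seed_gene})
    visited = {seed_gene}
    frontier = [seed_gene]
    for hop in range(1, config.depth + 1):
        next_frontier = []
        for gene in sorted(frontier):
            g = elasticity.index(gene)
            cands = _candidates(A, S, g, gene_ids)
            scores = np.array([c[2] for c in cands])
            cutoff = (
                float(np.percentile(scores, config.pct))
                if config.pct is not None
                else -np.inf
            )
            passing = [
                c for c in cands if c[2] >= config.floor and c[2] > cutoff
            ]
            best: dict = {}
            for name, direction, score, sign in passing:
                cur = best.setdefault(name, {"score": -np.inf, "dirs": []})
                cur["score"] = max(cur["score"], score)
                cur["dirs"].append((direction, score, sign))
            ranked = sorted(best.items(), key=lambda kv: (-kv[1]["score"], kv[0]))
            for name, info in ranked[: config.top]:
                for direction, score, sign in info["dirs"]:
                    if direction == "down":
                        graph.add_edge(gene, name, score, sign, hop)
                    else:
                        graph.add_edge(name, gene, score, sign, hop)
                if name not in visited:
                    visited.add(name)
                    next_frontier.append(name)
        frontier = next_frontier
        if not frontier:
            break
    return graph


def merge_subgraphs(graphs) -> Subgraph:
    """Node/edge union; duplicate edges keep the max score and min hop."""
    merged = Subgraph()
    for g in graphs:
        merged.nodes |= g.nodes
        merged.seeds |= g.seeds
        for (s, t), attrs in g.edges.items():
            merged.add_edge(s, t, attrs["score"], attrs["sign"], attrs["hop"])
    return merged


@dataclass
class RecallReport:
    """Benchmark recovery: hits, recall and fold enrichment over chance."""

    hits: int
    recall: float
    enrichment: float
    expected: float
    n_nodes: int
    n_benchmark: int
    per_seed_recall: dict = field(default_factory=dict)


def benchmark_recall(
    graph,
    benchmark,
    background_size: int,
    seeds=None,
    count_seeds: bool = True,
    per_seed_recall: dict | None = None,
) -> RecallReport:
    """Recall and enrichment of a benchmark gene set in a subgraph.

    hits = |nodes ∩ benchmark| (seed genes that are benchmark members are
    counted by default; set ``count_seeds=False`` to exclude them);
    expected = |benchmark| * |nodes| / background_size under uniform random
    gene selection; enrichment = hits / expected.
    """
    benchmark = set(benchmark)
    if not benchmark:
        raise ValidationError("benchmark set is empty")
    nodes = set(graph.nodes) if isinstance(graph, Subgraph) else set(graph)
    if background_size < len(nodes):
        raise ValidationError(
            f"background ({background_size}) smaller than node set ({len(nodes)})"
        )
    hit_set = nodes & benchmark
    if not count_seeds and seeds:
        hit_set -= set(seeds)
    hits = len(hit_set)
    expected = len(benchmark) * len(nodes) / background_size
    return RecallReport(
        hits=hits,
        recall=hits / len(benchmark),
        enrichment=hits / expected if expected > 0 else 0.0,
        expected=expected,
        n_nodes=len(nodes),
        n_benchmark=len(benchmark),
        per_seed_recall=dict(per_seed_recall or {}),
    )


def mean_per_seed_recall(
    elasticity: ElasticityMatrix,
    benchmark,
    config: ExpansionConfig,
    background_size: int | None = None,
) -> tuple:
    """Average recall when each benchmark gene seeds its own expansion."""
    benchmark = sorted(set(benchmark))
    per_seed = {}
    for gene in benchmark:
        if gene not in elasticity.gene_ids:
            continue
        graph = expand_seed(elasticity, gene, config)
        hits = len(graph.nodes & set(benchmark))
        per_seed[gene] = hits / len(benchmark)
    mean = float(np.mean(list(per_seed.values()))) if per_seed else 0.0
    return mean, per_seed


# ---------------------------------------------------------------------------
# Rank-null p-values and Benjamini-Hochberg machinery (q = 1 is a no-op
# passthrough matching "effectively no FDR filtering", but smaller q works)


def elasticity_rank_pvalues(graph: Subgraph, elasticity: ElasticityMatrix):
    """Per-edge p = fraction of off-diagonal |elasticity| >= edge score."""
    A = elasticity.abs
    off = A[~np.eye(A.shape[0], dtype=bool)]
    off_sorted = np.sort(off)
    n = off_sorted.size
    pvals = {}
    for key, attrs in graph.edges.items():
        ge = n - np.searchsorted(off_sorted, attrs["score"], side="left")
        pvals[key] = ge / n
    return pvals


def apply_bh_filter(
    graph: Subgraph, elasticity: ElasticityMatrix, q: float = 1.0
) -> Subgraph:
    """Benjamini-Hochberg filter on rank-null edge p-values."""
    if q >= 1.0 or not graph.edges:
        return graph
    pvals = elasticity_rank_pvalues(graph, elasticity)
    keys = sorted(pvals)
    reject = multipletests([pvals[k] for k in keys], alpha=q, method="fdr_bh")[0]
    kept = {k: graph.edges[k] for k, r in zip(keys, reject) if r}
    nodes = set(graph.seeds)
    for s, t in kept:
        nodes.add(s)
        nodes.add(t)
    return Subgraph(nodes=nodes, edges=kept, seeds=set(graph.seeds))


# ---------------------------------------------------------------------------
# TSV IO


def write_subgraph_tsv(graph: Subgraph, path):
    rows = [
        {
            "source": s,
            "target": t,
            "score": attrs["score"],
            "sign": attrs["sign"],
            "hop": attrs["hop"],
        }
        for (s, t), attrs in sorted(graph.edges.items())
    ]
    pd.DataFrame(
        rows, columns=["source", "target", "score", "sign", "hop"]
    ).to_csv(path, sep="\t", index=False)


def read_subgraph_tsv(path) -> Subgraph:
    df = pd.read_csv(path, sep="\t")
    graph = Subgraph()
    for row in df.itertuples(index=False):
        graph.add_edge(
            str(row.source),
            str(row.target),
            float(row.score),
            int(getattr(row, "sign", 1)),
            int(getattr(row, "hop", 0)),
        )
    return graph
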