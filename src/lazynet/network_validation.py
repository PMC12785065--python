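"""Concordance statistics for an inferred regulatory subgraph.

Two families of checks against external evidence:

* co-expression enrichment against a matched null — for every directed
  edge, random gene pairs are drawn from strata that jointly bin genes by
  mean expression/detection and by in-/out-degree in the elasticity graph,
  so abundance and hub effects cannot masquerade as signal; observed vs
  expected tail fractions of the reference correlation r at thresholds tau
  give fold enrichments (unsigned, sign-matched and opposite-sign views);

* reference-graph overlap — hypergeometric edge overlap over the universe
  of unordered gene pairs, size-matched random-gene-set density nulls,
  degree-preserving Maslov-Sneppen rewiring, and a 75th-percentile
  dichotomization of model vs reference edge scores into both-high /
  reference-only / model-only classes.

Directed model edges are collapsed to unordered pairs wherever the
reference is undirected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_model import ValidationError
from .elasticity_network import Subgraph

__all__ = [
    "AnnotatedEdge",
    "MatchedNullConfig",
    "OverlapResult",
    "annotate_edges",
    "matched_null_enrichment",
    "overlap_hypergeometric",
    "density_random_gene_sets",
    "maslov_sneppen_rewire",
    "quartile_classify",
    "reference_table_to_dict",
]


@dataclass(frozen=True)
class AnnotatedEdge:
    """A directed model edge with its reference correlation, when known."""

    source: str
    target: str
    score: float
    sign: int = 1
    reference_r: float | None = None

    def __post_init__(self):
        if self.reference_r is not None and not -1 <= self.reference_r <= 1:
            raise ValidationError("reference_r must lie in [-1, 1]")


@dataclass
class MatchedNullConfig:
    """Stratified-null sampling parameters for co-expression enrichment."""

    n_pairs_per_edge: int = 400
    expression_bins: int = 5
    degree_bins: int = 5
    tau_grid: tuple = (0.20, 0.40)
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs_per_edge < 1:
            raise ValidationError("n_pairs_per_edge must be >= 1")
        if self.expression_bins < 1 or self.degree_bins < 1:
            raise ValidationError("bin counts must be >= 1")


def reference_table_to_dict(table) -> dict:
    """(geneA, geneB, r) rows -> {frozenset(pair): r} (last write wins)."""
    if isinstance(table, dict):
        return {frozenset(k): float(v) for k, v in table.items()}
    df = pd.DataFrame(table)
    a, b, r = df.columns[:3]
    return {
        frozenset((str(x), str(y))): float(v)
        for x, y, v in zip(df[a], df[b], df[r])
        if str(x) != str(y)
    }


def annotate_edges(graph: Subgraph, reference: dict) -> list:
    """Attach reference r to each directed edge of a subgraph."""
    ref = reference_table_to_dict(reference)
    out = []
    for (s, t), attrs in sorted(graph.edges.items()):
        out.append(
            AnnotatedEdge(
                s, t, attrs["score"], attrs["sign"],
                ref.get(frozenset((s, t))),
            )
        )
    return out


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin index per value; degenerate distributions collapse bins."""
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")


def matched_null_enrichment(
    edges,
    reference_r,
    config: MatchedNullConfig,
    gene_expression: dict | None = None,
):
    """Observed vs matched-null tail fractions of the reference correlation.

    For each annotated edge, ``n_pairs_per_edge`` null pairs (i', j') are
    drawn with i' from the joint (expression-bin, out-degree-bin) stratum
    of the source and j' from the (expression-bin, in-degree-bin) stratum
    of the target; empty strata widen to the nearest non-empty bins with a
    warning.  Edges without a reference value are excluded from both the
    numerator and the null sampling.  Returns, per tau, fold enrichments
    for the unsigned, positive-tail, negative-tail, sign-matched and
    opposite-sign views, plus bookkeeping counts.  Deterministic per seed.
    """
    ref = reference_table_to_dict(reference_r)
    edges = list(edges)
    known = [e for e in edges if e.reference_r is not None]
    n_missing = len(edges) - len(known)
    if not known:
        raise ValidationError("no edge carries a reference correlation")

    # degree profile of the model graph (over all edges, known or not)
    out_deg: dict = {}
    in_deg: dict = {}
    for e in edges:
        out_deg[e.source] = out_deg.get(e.source, 0) + 1
        in_deg[e.target] = in_deg.get(e.target, 0) + 1

    # null-pair universe: genes occurring in the reference table
    universe = sorted({g for pair in ref for g in pair})
    if len(universe) < 2:
        raise ValidationError("reference universe too small to sample pairs")
    if gene_expression is None:
        gene_expression = {g: 0.0 for g in universe}
    expr = np.array([float(gene_expression.get(g, 0.0)) for g in universe])
    odeg = np.array([out_deg.get(g, 0) for g in universe], dtype=float)
    ideg = np.array([in_deg.get(g, 0) for g in universe], dtype=float)

    ebin = _quantile_bins(expr, config.expression_bins)
    obin = _quantile_bins(odeg, config.degree_bins)
    ibin = _quantile_bins(ideg, config.degree_bins)

    src_strata: dict = {}
    tgt_strata: dict = {}
    for idx, g in enumerate(universe):
        src_strata.setdefault((ebin[idx], obin[idx]), []).append(idx)
        tgt_strata.setdefault((ebin[idx], ibin[idx]), []).append(idx)

    def stratum_of(gene, strata, ebins, dbins, degs):
        if gene in universe_index:
            i = universe_index[gene]
            key = (ebins[i], dbins[i])
        else:
            # gene absent from reference: nearest stratum by raw values
            gx = float(gene_expression.get(gene, 0.0))
            key = (
                int(np.searchsorted(
                    np.quantile(expr, np.linspace(0, 1, config.expression_bins + 1)[1:-1]),
                    gx, side="right")),
                0,
            )
        if key in strata:
            return strata[key]
        # widen to the nearest non-empty stratum (L1 distance in bin space)
        best = min(
            strata,
            key=lambda k: abs(k[0] - key[0]) + abs(k[1] - key[1]),
        )
        warnings.warn(
            f"empty stratum {key} widened to {best}", stacklevel=3
        )
        return strata[best]

    universe_index = {g: i for i, g in enumerate(universe)}
    rng = np.random.default_rng(config.seed)

    null_r = []
    for e in known:
        src_pool = stratum_of(e.source, src_strata, ebin, obin, odeg)
        tgt_pool = stratum_of(e.target, tgt_strata, ebin, ibin, ideg)
        got = 0
        attempts = 0
        max_attempts = 20 * config.n_pairs_per_edge
        while got < config.n_pairs_per_edge and attempts < max_attempts:
            attempts += 1
            i = universe[src_pool[rng.integers(len(src_pool))]]
            j = universe[tgt_pool[rng.integers(len(tgt_pool))]]
            if i == j:
                continue
            r = ref.get(frozenset((i, j)))
            if r is None:
                continue
            null_r.append(r)
            got += 1
    null_r = np.array(null_r)
    if null_r.size == 0:
        raise ValidationError("could not sample any null pair with a reference r")

    obs_r = np.array([e.reference_r for e in known])
    signs = np.array([e.sign for e in known])

    results = {}
    for tau in config.tau_grid:
        per_tau = {}
        views = {
            "unsigned": (np.abs(obs_r), np.abs(null_r), lambda v, t: v >= t),
            "positive": (obs_r, null_r, lambda v, t: v >= t),
            "negative": (-obs_r, -null_r, lambda v, t: v >= t),
            "sign_matched": (signs * obs_r, null_r, lambda v, t: v >= t),
            "opposite_sign": (-signs * obs_r, null_r, lambda v, t: v >= t),
        }
        for name, (ov, nv, pred) in views.items():
            observed = float(np.mean(pred(ov, tau)))
            expected = float(np.mean(pred(nv, tau)))
            if expected > 0:
                fold = observed / expected
            else:  # empty tails on both sides carry no evidence
                fold = np.nan if observed == 0 else np.inf
            per_tau[name] = {
                "observed": observed,
                "expected": expected,
                "fold": fold,
            }
        results[tau] = per_tau
    results["n_edges"] = len(known)
    results["n_missing_reference"] = n_missing
    results["n_null_pairs"] = int(null_r.size)
    return results


# ---------------------------------------------------------------------------
# Reference-graph overlap, density null, rewiring, quartile classes


@dataclass
class OverlapResult:
    n_edges: int
    n_reference: int
    n_overlap: int
    population_pairs: int
    p_hypergeometric: float
    jaccard: float


def _to_pairs(edges) -> set:
    """Any edge collection -> deduplicated unordered symbol pairs."""
    if isinstance(edges, Subgraph):
        return edges.undirected_pairs()
    pairs = set()
    for e in edges:
        if isinstance(e, AnnotatedEdge):
            a, b = e.source, e.target
        elif isinstance(e, (frozenset, set)):
            a, b = sorted(e)
        else:
            a, b = e[0], e[1]
        if a != b:
            pairs.add(frozenset((str(a), str(b))))
    return pairs


def overlap_hypergeometric(edges, reference_edges, gene_universe) -> OverlapResult:
    """One-tailed hypergeometric test of edge overlap.

    The population is every unordered pair over ``gene_universe``; success
    states are the reference pairs, draws are the (deduplicated, unordered,
    universe-restricted) model pairs; p is the upper tail at the observed
    overlap.
    """
    universe = {str(g) for g in gene_universe}
    if len(universe) < 2:
        raise ValidationError("gene universe must contain at least 2 genes")
    in_universe = lambda p: all(g in universe for g in p)  # noqa: E731
    model = {p for p in _to_pairs(edges) if in_universe(p)}
    reference = {p for p in _to_pairs(reference_edges) if in_universe(p)}
    population = len(universe) * (len(universe) - 1) // 2
    if len(model) > population:
        raise ValidationError("more draws than population pairs")
    overlap = len(model & reference)
    p = float(hypergeom.sf(overlap - 1, population, len(reference), len(model)))
    union = len(model | reference)
    return OverlapResult(
        n_edges=len(model),
        n_reference=len(reference),
        n_overlap=overlap,
        population_pairs=population,
        p_hypergeometric=min(p, 1.0),
        jaccard=overlap / union if union else 0.0,
    )


def density_random_gene_sets(
    node_set,
    reference_graph,
    background_genes,
    n_draws: int = 1000,
    seed: int = 0,
):
    """Reference-edge density of a node set vs size-matched random sets.

    observed density = reference edges with both endpoints in the node set
    divided by C(n, 2); the null re-draws equally sized gene sets uniformly
    from the background; empirical one-sided p uses the add-one correction
    (1 + #{null >= observed}) / (1 + n_draws).
    """
    nodes = {str(g) for g in node_set}
    if len(nodes) < 2:
        raise ValidationError("node set must contain at least 2 genes")
    background = sorted({str(g) for g in background_genes})
    if len(nodes) > len(background):
        raise ValidationError("node set larger than background")
    ref_pairs = _to_pairs(reference_graph)

    def density(genes: set) -> float:
        n = len(genes)
        inside = sum(1 for p in ref_pairs if all(g in genes for g in p))
        return inside / (n * (n - 1) / 2)

    observed = density(nodes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_draws)
    bg = np.array(background)
    for i in range(n_draws):
        draw = set(bg[rng.choice(len(bg), size=len(nodes), replace=False)])
        null[i] = density(draw)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_draws)
    return observed, float(null.mean()), float(null.std()), float(p)


def maslov_sneppen_rewire(graph, n_iterations: int = 1000, seed: int = 0):
    """Degree-preserving randomization by repeated double-edge swaps.

    Accepts a networkx Graph or any unordered-pair collection; returns the
    same kind.  The degree sequence is preserved exactly and no self-loops
    or parallel edges are introduced.  Graphs too small to admit a legal
    swap are returned unchanged with a warning.
    """
    as_pairs = not isinstance(graph, nx.Graph)
    G = nx.Graph(sorted(tuple(sorted(p)) for p in _to_pairs(graph))) if as_pairs else graph.copy()
    if G.number_of_edges() < 2 or G.number_of_nodes() < 4:
        warnings.warn("graph too small to rewire; returned unchanged", stacklevel=2)
        return _to_pairs(graph) if as_pairs else G
    try:
        nx.double_edge_swap(
            G,
            nswap=n_iterations,
            max_tries=max(100 * n_iterations, 1000),
            seed=seed,
        )
    except nx.NetworkXError as err:
        warnings.warn(f"rewiring stopped early: {err}", stacklevel=2)
    if as_pairs:
        return {frozenset(e) for e in G.edges()}
    return G


def quartile_classify(model_scores, reference_scores):
    """2x2 dichotomy of paired edge scores at their 75th percentiles.

    Returns one class per edge: 'both-high', 'reference-only', 'model-only'
    or 'neither'.  Thresholds are the 75th percentile of each score over
    the classified edges themselves.
    """
    model_scores = np.asarray(model_scores, dtype=float)
    reference_scores = np.asarray(reference_scores, dtype=float)
    if model_scores.shape != reference_scores.shape or model_scores.ndim != 1:
        raise ValidationError("need matching 1-d score vectors")
    if model_scores.size < 4:
        raise ValidationError("quartile classification needs >= 4 edges")
    mt = np.quantile(model_scores, 0.75)
    rt = np.quantile(reference_scores, 0.75)
    classes = []
    for m, r in zip(model_scores, reference_scores):
        mh, rh = m > mt, r > rt
        if mh and rh:
            classes.append("both-high")
        elif rh:
            classes.append("reference-only")
        elif mh:
            classes.append("model-only")
        else:
            classes.append("neither")
    return classes
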