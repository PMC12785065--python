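"""Ground-truth generators for every pipeline stage.

A sparse monomial ODE system plays the role of the unknown regulatory
rate law; from it the generators derive (i) two-snapshot state pairs,
(ii) a full guide screen — control / singlet / multiplet cells with a
negative-binomial count readout and per-cell library-size variation — and
(iii) external-evidence fixtures (a co-expression table, a reference edge
list and a protein intensity matrix) with signal planted on the true
interaction pairs so the validation statistics have a known answer.

Everything is bit-reproducible per seed.  The count readout is negative
binomial with configurable dispersion, matching the sparse overdispersed
regime of real droplet screens.  The control baseline is made an exact
fixed point of the rate law by balancing per-gene first-order degradation
or constant production (homeostasis of unperturbed cells), which avoids
nonlinear root-finding entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    ExpressionState,
    Monomial,
    MonomialSystem,
    ValidationError,
    embed_monomial_system,
)
from .perturb_data import CountMatrix, GuideTable, SnapshotPair
from .proteomics_validation import ProteinMatrix

__all__ = [
    "ScreenSimConfig",
    "sample_monomial_system",
    "simulate_snapshot_pairs",
    "simulate_guide_screen",
    "make_reference_tables",
]


@dataclass
class ScreenSimConfig:
    """Conditions of a simulated two-snapshot guide screen.

    Defaults describe a compact, well-powered screen on a focused panel:
    a 20-gene dynamic panel with a 30-term rate law among 80 stable
    housekeeping genes (which carry most of the library, as in
    transcriptome-wide data), 500 control cells, 2000 singlets and 200
    multiplets, 5% multiplicative biological noise, ~10k-count libraries
    with 30% cell-to-cell size variation, an overdispersed
    negative-binomial readout, 75% knockdown for interference and a 3x
    boost for activation, with planted effects (coefficients 0.2-1.0 at
    dt=0.5) in the 10-50% response range typical of strong Perturb-seq
    hits.
    """

    n_genes: int = 20
    n_terms: int = 30
    sparsity: float = 0.15
    exponent_choices: tuple = (-2, -1, 1, 2)
    coefficient_range: tuple = (0.2, 1.0)
    n_housekeeping_genes: int = 80
    n_control_cells: int = 500
    n_singlet_cells: int = 2000
    n_multiplet_cells: int = 200
    guides_per_target: int = 2
    noise_sd: float = 0.05
    library_size_mean: float = 10000.0
    library_size_cv: float = 0.3
    nb_dispersion: float = 10.0
    dt: float = 0.5
    ko_floor_factor: float = 0.25
    oe_boost_factor: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_genes", "n_terms", "n_control_cells", "n_singlet_cells",
            "n_multiplet_cells",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not self.dt > 0:
            raise ValidationError("dt must be positive")


def _gene_names(d: int) -> list:
    width = max(2, len(str(d - 1)))
    return [f"G{i:0{width}d}" for i in range(d)]


def sample_monomial_system(
    d: int,
    K: int,
    sparsity: float = 0.15,
    seed: int = 0,
    exponent_choices=(-2, -1, 1, 2),
    coefficient_range=(0.05, 0.5),
) -> MonomialSystem:
    """Random sparse monomial rate law with K signed terms.

    Each term targets one output gene, involves at most ceil(sparsity * d)
    input genes with nonzero integer exponents drawn from
    ``exponent_choices``, carries a log-uniform positive coefficient, and a
    random production/decay sign.  The interaction ground truth is
    available as ``system.support()``.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    if not 0 < sparsity <= 1:
        raise ValidationError("sparsity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    max_nz = max(1, int(np.ceil(sparsity * d)))
    lo, hi = np.log(coefficient_range[0]), np.log(coefficient_range[1])
    terms: list = [[] for _ in range(d)]
    for _ in range(K):
        target = int(rng.integers(d))
        n_nz = int(rng.integers(1, max_nz + 1))
        genes = rng.choice(d, size=n_nz, replace=False)
        exponents = np.zeros(d)
        exponents[genes] = rng.choice(exponent_choices, size=n_nz)
        coef = float(np.exp(rng.uniform(lo, hi)))
        sign = int(rng.choice([-1, 1]))
        terms[target].append((sign, Monomial(coef, exponents)))
    return MonomialSystem(dimension=d, terms=terms)


def _default_state_distribution(rng: np.random.Generator, d: int) -> np.ndarray:
    return rng.lognormal(mean=0.0, sigma=0.5, size=d)


def simulate_snapshot_pairs(
    system: MonomialSystem,
    n_pairs: int,
    state_distribution=None,
    dt: float = 0.1,
    noise_sd: float = 0.05,
    seed: int = 0,
    explode_cap: float = 1e3,
) -> list:
    """Noisy one-step snapshot pairs from a known rate law.

    time-0 states are drawn from ``state_distribution`` (default lognormal
    around 1), the post state is one exact Euler step of the embedded
    model, and multiplicative log-normal noise of scale ``noise_sd`` is
    applied.  Pairs whose post state exceeds ``explode_cap`` are resampled
    (count reported via the returned list's ``.resampled`` attribute is
    avoided; a ValidationError is raised if resampling cannot succeed).
    """
    model = embed_monomial_system(system, dt=dt)
    rng = np.random.default_rng(seed)
    draw = state_distribution or _default_state_distribution
    gene_ids = _gene_names(system.dimension)
    pairs = []
    resampled = 0
    while len(pairs) < n_pairs:
        x0 = np.asarray(draw(rng, system.dimension), dtype=float)
        post = model.step_values(x0)
        if np.max(np.abs(post)) > explode_cap:
            resampled += 1
            if resampled > 100 * max(n_pairs, 1):
                raise ValidationError(
                    "dynamics explode for almost every sampled state"
                )
            continue
        if noise_sd > 0:
            post = post * np.exp(rng.normal(0.0, noise_sd, size=len(post)))
        pairs.append(
            SnapshotPair(
                ExpressionState(x0, gene_ids),
                ExpressionState(np.maximum(post, model.block.eps_floor), gene_ids),
                group_key=("pair", str(len(pairs))),
            )
        )
    return pairs


def balance_to_steady_state(
    system: MonomialSystem, baseline: np.ndarray
) -> MonomialSystem:
    """Make ``baseline`` an exact fixed point of the rate law.

    Unperturbed cells are homeostatic, so the control state should satisfy
    F(baseline) = 0.  Each gene's residual rate is absorbed by first-order
    self-degradation (a positive residual) or a constant production term
    (a negative residual) — both standard ingredients of gene-regulatory
    rate laws, and neither adds an off-diagonal interaction, so the
    planted cross-gene support is unchanged.
    """
    baseline = np.asarray(baseline, dtype=float)
    residual = system.rate(baseline)
    terms = [list(t) for t in system.terms]
    d = system.dimension
    for i in range(d):
        if residual[i] > 0:
            decay = np.zeros(d)
            decay[i] = 1.0
            terms[i].append((-1, Monomial(residual[i] / baseline[i], decay)))
        elif residual[i] < 0:
            terms[i].append((1, Monomial(-residual[i], np.zeros(d))))
    balanced = MonomialSystem(dimension=d, terms=terms)
    assert np.allclose(balanced.rate(baseline), 0.0, atol=1e-9)
    return balanced


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_guide_screen(config: ScreenSimConfig, system=None):
    """Full two-snapshot guide screen: counts, guide calls, ground truth.

    The dynamic panel obeys the sampled monomial system, balanced so that
    the control baseline is an exact steady state (homeostasis); a larger
    complement of stable housekeeping genes carries most of the library so
    that single-gene edits perturb the per-cell total only mildly, as in a
    transcriptome-wide screen.  Each singlet edits one dynamic gene (floor
    for interference, boost for activation, alternating by target index)
    and takes one Euler step; multiplets edit two.  Counts are a
    negative-binomial readout of the positive expression with per-cell
    log-normal library sizes.  Returns (CountMatrix, GuideTable, truth)
    where truth carries the system, its support matrix, the baseline and
    the per-target modality.
    """
    rng = np.random.default_rng(config.seed)
    if system is None:
        system = sample_monomial_system(
            config.n_genes,
            config.n_terms,
            config.sparsity,
            seed=int(rng.integers(2**31 - 1)),
            exponent_choices=config.exponent_choices,
            coefficient_range=config.coefficient_range,
        )
    d = system.dimension
    genes = _gene_names(d)
    baseline = rng.lognormal(0.0, 0.2, size=d)
    system = balance_to_steady_state(system, baseline)
    n_hk = config.n_housekeeping_genes
    hk_genes = [f"HK{j:03d}" for j in range(n_hk)]
    hk_level = rng.lognormal(1.0, 0.5, size=n_hk)
    modality = {
        g: ("interference" if i % 2 == 0 else "activation")
        for i, g in enumerate(genes)
    }

    expr_cols, barcodes, guide_rows = [], [], []

    def add_cell(expr, n_guides, target, guide_id, mod):
        bc = f"CELL{len(barcodes):06d}"
        barcodes.append(bc)
        expr_cols.append(expr)
        guide_rows.append(
            {
                "barcode": bc,
                "n_guides": n_guides,
                "target_gene": target,
                "modality": mod if target else "non-targeting",
                "guide_id": guide_id,
            }
        )

    def cell_noise(expr):
        full = np.concatenate([expr, hk_level])
        return full * np.exp(rng.normal(0.0, config.noise_sd, size=d + n_hk))

    def perturbed_state(targets):
        x0 = baseline.copy()
        for g in targets:
            gi = genes.index(g)
            if modality[g] == "interference":
                x0[gi] = baseline[gi] * config.ko_floor_factor
            else:
                x0[gi] = baseline[gi] * config.oe_boost_factor
        post = x0 + config.dt * system.rate(x0)
        return np.clip(post, 1e-4, 1e4)

    for _ in range(config.n_control_cells):
        add_cell(cell_noise(baseline), 0, None, None, None)

    for c in range(config.n_singlet_cells):
        g = genes[c % d]
        guide = f"{g}_g{(c // d) % config.guides_per_target + 1}"
        add_cell(cell_noise(perturbed_state([g])), 1, g, guide, modality[g])

    for c in range(config.n_multiplet_cells):
        pick = rng.choice(d, size=2, replace=False)
        ts = [genes[i] for i in pick]
        add_cell(
            cell_noise(perturbed_state(ts)),
            2,
            ts[0],
            f"{ts[0]}_g1+{ts[1]}_g1",
            modality[ts[0]],
        )

    expr = np.column_stack(expr_cols)  # genes x cells, positive
    libs = config.library_size_mean * np.exp(
        rng.normal(0.0, config.library_size_cv, size=expr.shape[1])
    )
    frac = expr / expr.sum(axis=0, keepdims=True)
    counts = _nb_counts(rng, frac * libs, config.nb_dispersion)

    matrix = CountMatrix(counts, genes + hk_genes, barcodes)
    guides = GuideTable(pd.DataFrame(guide_rows))
    truth = {
        "system": system,
        "support": system.support(),
        "baseline": baseline,
        "gene_ids": genes,
        "housekeeping": hk_genes,
        "hk_level": hk_level,
        "modality": modality,
    }
    return matrix, guides, truth


def make_reference_tables(
    system: MonomialSystem,
    signal_r: float = 0.5,
    n_decoy_pairs: int | None = None,
    seed: int = 0,
    true_edge_fraction: float = 0.5,
    n_channels: int = 9,
    r_noise: float = 0.05,
):
    """External-evidence fixtures with signal planted on true interactions.

    Returns ``(coexpression, reference_edges, protein_matrix)``:

    * coexpression — DataFrame (geneA, geneB, r) covering every unordered
      gene pair; true-interaction pairs get r near ``signal_r``, decoys
      near 0 (all clipped to [-0.99, 0.99]);
    * reference_edges — DataFrame (geneA, geneB, score) containing a
      ``true_edge_fraction`` sample of the true pairs plus an equal number
      of random decoys;
    * protein_matrix — ProteinMatrix over ``n_channels`` channels in which
      profiles of true-edge partners share correlation ~= ``signal_r``.
    """
    rng = np.random.default_rng(seed)
    d = system.dimension
    genes = _gene_names(d)
    support = system.support()
    true_pairs = sorted(
        {
            frozenset((genes[i], genes[j]))
            for i in range(d)
            for j in range(d)
            if i != j and support[i, j]
        },
        key=lambda p: tuple(sorted(p)),
    )
    true_set = set(true_pairs)

    rows = []
    for i in range(d):
        for j in range(i + 1, d):
            pair = frozenset((genes[i], genes[j]))
            if pair in true_set:
                r = signal_r + rng.normal(0.0, r_noise)
            else:
                r = rng.normal(0.0, r_noise)
            rows.append(
                {
                    "geneA": genes[i],
                    "geneB": genes[j],
                    "r": float(np.clip(r, -0.99, 0.99)),
                }
            )
    coexpression = pd.DataFrame(rows)

    n_true = max(1, int(round(true_edge_fraction * len(true_pairs))))
    chosen_idx = rng.choice(len(true_pairs), size=min(n_true, len(true_pairs)),
                            replace=False)
    chosen = [true_pairs[i] for i in sorted(chosen_idx)]
    if n_decoy_pairs is None:
        n_decoy_pairs = len(chosen)
    decoys = set()
    while len(decoys) < n_decoy_pairs:
        i, j = rng.choice(d, size=2, replace=False)
        pair = frozenset((genes[i], genes[j]))
        if pair not in true_set:
            decoys.add(pair)
    ref_rows = [
        {"geneA": a, "geneB": b, "score": float(rng.uniform(0.5, 1.0))}
        for a, b in (tuple(sorted(p)) for p in list(chosen) + sorted(
            decoys, key=lambda p: tuple(sorted(p))))
    ]
    reference_edges = pd.DataFrame(ref_rows)

    # protein profiles: independent gaussians, then true-edge partners get
    # a shared component so their channel-wise correlation ~= signal_r
    profiles = {g: rng.normal(0.0, 1.0, size=n_channels) for g in genes}
    rho = float(np.clip(signal_r, -0.99, 0.99))
    for pair in true_pairs:
        a, b = sorted(pair)
        profiles[b] = rho * profiles[a] + np.sqrt(max(1 - rho**2, 1e-6)) * (
            rng.normal(0.0, 1.0, size=n_channels)
        )
    values = np.vstack([2.0 ** (20.0 + profiles[g]) for g in genes])
    protein_matrix = ProteinMatrix(
        values, genes, [f"channel_{k + 1}" for k in range(n_channels)]
    )
    return coexpression, reference_edges, protein_matrix
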