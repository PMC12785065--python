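"""Log-linear-exp (LLE) residual block and one-step Euler dynamics.

The rate law of a gene-regulatory ODE is represented as a signed sum of
monomials ``c * x1**a1 * ... * xd**ad``.  A single LLE block computes the
positive monomial rates

    m(x) = exp(W2 @ log(max(W1 @ x + b1, eps)) + b2)

and a signed output-combination matrix ``C`` maps the M monomial rates onto
the d genes, so the full rate law is ``F(x) = C @ m(x)``.  One explicit Euler
step ``x + dt * F(x)`` links a baseline ("time-0") expression state to its
post-perturbation snapshot, which is exactly the two-snapshot design of
CRISPR activation/interference screens.

Working in log space means a single hidden row encodes an entire monomial
exactly: its exponent vector sits in the corresponding row of ``W2`` (with
``W1`` the identity) and its log-coefficient in ``b2``.  A K-term rate law
therefore needs only K(d+1) trainable scalars plus signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "ExpressionState",
    "Monomial",
    "MonomialSystem",
    "LLEBlock",
    "EulerStepModel",
    "EnsembleModel",
    "lle_forward",
    "euler_step",
    "embed_monomial_system",
    "ensemble_predict",
    "save_model",
    "load_model",
    "save_ensemble",
    "load_ensemble",
]

DEFAULT_EPS_FLOOR = 1e-8


class ShapeError(ValueError):
    """Dimension mismatch between states, parameters or ensemble members."""


class ValidationError(ValueError):
    """Invariant violation (non-positive state, non-finite parameter, ...)."""


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ShapeError(f"{name} must be a 1-d vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ExpressionState:
    """Strictly positive expression vector over an ordered gene panel."""

    values: np.ndarray
    gene_ids: tuple

    def __init__(self, values, gene_ids):
        values = _as_vector(values, "values")
        gene_ids = tuple(str(g) for g in gene_ids)
        if len(values) != len(gene_ids):
            raise ShapeError(
                f"{len(values)} values for {len(gene_ids)} gene ids"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ValidationError("gene_ids must be unique")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite")
        if np.any(values <= 0):
            raise ValidationError("expression values must be strictly positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)

    @property
    def dimension(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Monomial:
    """A single power-law term ``coefficient * prod_j x_j**exponents[j]``."""

    coefficient: float
    exponents: np.ndarray

    def __init__(self, coefficient, exponents):
        coefficient = float(coefficient)
        exponents = _as_vector(exponents, "exponents")
        if not coefficient > 0:
            raise ValidationError("monomial coefficient must be positive")
        if not np.all(np.isfinite(exponents)):
            raise ValidationError("monomial exponents must be finite")
        object.__setattr__(self, "coefficient", coefficient)
        object.__setattr__(self, "exponents", exponents)

    def evaluate(self, x: np.ndarray) -> float:
        return float(self.coefficient * np.prod(x ** self.exponents))


@dataclass
class MonomialSystem:
    """Ground-truth rate law: per gene, a signed list of monomials.

    ``terms[i]`` is a list of ``(sign, Monomial)`` with sign +1 for
    production and -1 for decay; an empty list means a constant (zero) rate
    for that gene.
    """

    dimension: int
    terms: list

    def __post_init__(self):
        if len(self.terms) != self.dimension:
            raise ShapeError("need one (possibly empty) term list per gene")
        for gene_terms in self.terms:
            for sign, mono in gene_terms:
                if sign not in (-1, 1):
                    raise ValidationError("term sign must be +1 or -1")
                if len(mono.exponents) != self.dimension:
                    raise ShapeError("exponent vector length != dimension")

    @property
    def n_terms(self) -> int:
        return sum(len(t) for t in self.terms)

    def rate(self, x) -> np.ndarray:
        """Direct evaluation of F(x); the oracle the LLE embedding must match."""
        x = np.asarray(x, dtype=float)
        out = np.zeros(self.dimension)
        for i, gene_terms in enumerate(self.terms):
            for sign, mono in gene_terms:
                out[i] += sign * mono.evaluate(x)
        return out

    def jacobian(self, x) -> np.ndarray:
        """Closed-form dF_i/dx_j of the monomial rate law (rows = outputs)."""
        x = np.asarray(x, dtype=float)
        jac = np.zeros((self.dimension, self.dimension))
        for i, gene_terms in enumerate(self.terms):
            for sign, mono in gene_terms:
                val = sign * mono.evaluate(x)
                nz = np.nonzero(mono.exponents)[0]
                for j in nz:
                    jac[i, j] += val * mono.exponents[j] / x[j]
        return jac

    def support(self) -> np.ndarray:
        """Boolean interaction support, oriented source-row -> target-column."""
        sup = np.zeros((self.dimension, self.dimension), dtype=bool)
        for i, gene_terms in enumerate(self.terms):
            for _sign, mono in gene_terms:
                sup[np.nonzero(mono.exponents)[0], i] = True
        return sup


@dataclass
class LLEBlock:
    """Parameters of one log -> linear -> exp transformation.

    Hidden pre-activations ``W1 @ x + b1`` are clamped at ``eps_floor``
    before the log so that gradients stay finite when a pre-activation
    drifts non-positive during training.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    eps_floor: float = DEFAULT_EPS_FLOOR

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        H, d = self.W1.shape
        M, H2 = self.W2.shape
        if H2 != H or self.b1.shape != (H,) or self.b2.shape != (M,):
            raise ShapeError(
                f"inconsistent block shapes: W1 {self.W1.shape}, b1 "
                f"{self.b1.shape}, W2 {self.W2.shape}, b2 {self.b2.shape}"
            )
        if not self.eps_floor > 0:
            raise ValidationError("eps_floor must be positive")
        for name in ("W1", "b1", "W2", "b2"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite values in {name}")

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.W2.shape[0]


def lle_forward(x, block: LLEBlock) -> np.ndarray:
    """Positive monomial rates ``exp(W2 log(max(W1 x + b1, eps)) + b2)``.

    ``x`` may be an :class:`ExpressionState` or a positive vector / matrix of
    row vectors; the output has one entry per row of ``W2``.
    """
    if isinstance(x, ExpressionState):
        x = x.values
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    xx = np.atleast_2d(x)
    if xx.shape[1] != block.n_inputs:
        raise ShapeError(
            f"input dimension {xx.shape[1]} != block input {block.n_inputs}"
        )
    if np.any(xx <= 0) or not np.all(np.isfinite(xx)):
        raise ValidationError("LLE input must be strictly positive and finite")
    h = xx @ block.W1.T + block.b1
    logh = np.log(np.maximum(h, block.eps_floor))
    out = np.exp(logh @ block.W2.T + block.b2)
    return out[0] if squeeze else out


@dataclass
class EulerStepModel:
    """One explicit Euler step of the LLE rate law.

    ``out_weights`` (d x M) is the signed combination mapping the block's
    positive monomial rates onto per-gene rates; ``None`` means the block's
    outputs are used directly (requires M == d), i.e. a purely productive
    rate law.  ``dt`` is fixed to 1 during training: with only two snapshots
    the product of step size and elasticity is what is learnable, so the
    step folds into the coefficients.
    """

    block: LLEBlock
    dt: float = 1.0
    out_weights: np.ndarray | None = None
    gene_ids: tuple | None = None
    seed: int | None = None

    def __post_init__(self):
        if not self.dt > 0:
            raise ValidationError("dt must be positive")
        if self.out_weights is not None:
            self.out_weights = np.asarray(self.out_weights, dtype=float)
            if self.out_weights.shape != (self.dimension, self.block.n_outputs):
                raise ShapeError(
                    f"out_weights shape {self.out_weights.shape} != "
                    f"({self.dimension}, {self.block.n_outputs})"
                )
            if not np.all(np.isfinite(self.out_weights)):
                raise ValidationError("non-finite out_weights")
        elif self.block.n_outputs != self.block.n_inputs:
            raise ShapeError(
                "without out_weights the block must map d inputs to d outputs"
            )
        if self.gene_ids is not None:
            self.gene_ids = tuple(str(g) for g in self.gene_ids)
            if len(self.gene_ids) != self.dimension:
                raise ShapeError("gene_ids length != model dimension")

    @property
    def dimension(self) -> int:
        return self.block.n_inputs

    def rate(self, x, sign_weights=None) -> np.ndarray:
        """Signed rate F(x) = C @ m(x); batched over rows when x is 2-d."""
        m = lle_forward(x, self.block)
        if self.out_weights is not None:
            f = m @ self.out_weights.T
        else:
            f = m
        if sign_weights is not None:
            f = f * np.asarray(sign_weights, dtype=float)
        return f

    def jacobian_rate(self, x) -> np.ndarray:
        """Analytic dF_i/dx_j at a single state (rows = output genes).

        Entries where the log-argument clamp is active have zero gradient,
        matching the piecewise forward pass exactly.
        """
        if isinstance(x, ExpressionState):
            x = x.values
        x = _as_vector(x, "x")
        blk = self.block
        h = blk.W1 @ x + blk.b1
        hc = np.maximum(h, blk.eps_floor)
        active = (h > blk.eps_floor).astype(float)
        m = np.exp(blk.W2 @ np.log(hc) + blk.b2)
        # dm_k/dx_j = m_k * sum_h W2[k,h] * active_h / hc_h * W1[h,j]
        inner = blk.W2 @ ((active / hc)[:, None] * blk.W1)
        dm = m[:, None] * inner
        if self.out_weights is not None:
            return self.out_weights @ dm
        return dm

    def step_values(self, x, sign_weights=None) -> np.ndarray:
        """x + dt*F(x), clamped at eps_floor to preserve positivity."""
        if isinstance(x, ExpressionState):
            x = x.values
        x = np.asarray(x, dtype=float)
        return np.maximum(
            x + self.dt * self.rate(x, sign_weights), self.block.eps_floor
        )

    def n_trainable(self, train_w1: bool = False) -> int:
        n = self.block.W2.size + self.block.b2.size
        if self.out_weights is not None:
            n += self.out_weights.size
        if train_w1:
            n += self.block.W1.size + self.block.b1.size
        return n


def euler_step(state, model: EulerStepModel, sign_weights=None):
    """One Euler update of an expression state.

    Returns an :class:`ExpressionState` when given one (positivity enforced
    by the eps_floor clamp), otherwise a plain array.
    """
    if isinstance(state, ExpressionState):
        if state.dimension != model.dimension:
            raise ShapeError("state dimension != model dimension")
        vals = model.step_values(state.values, sign_weights)
        gene_ids = model.gene_ids if model.gene_ids is not None else state.gene_ids
        return ExpressionState(vals, gene_ids)
    return model.step_values(state, sign_weights)


def embed_monomial_system(
    system: MonomialSystem, dt: float = 1.0, eps_floor: float = 1e-30
) -> EulerStepModel:
    """Exact LLE embedding of a monomial rate law.

    ``W1`` is the identity (so the hidden layer is the state itself), each
    monomial contributes one row of ``W2`` holding its exponent vector with
    its log-coefficient in ``b2``, and the signed assignment of monomials to
    genes goes into ``out_weights``.  On positive states the forward pass
    then reproduces direct evaluation to floating-point rounding.

    The tiny default ``eps_floor`` keeps the clamp inert on the positive
    domain so the representation is exact rather than approximate.
    """
    d = system.dimension
    rows, biases = [], []
    col_gene, col_sign = [], []
    for i, gene_terms in enumerate(system.terms):
        for sign, mono in gene_terms:
            rows.append(mono.exponents)
            biases.append(np.log(mono.coefficient))
            col_gene.append(i)
            col_sign.append(sign)
    if not rows:  # a system with no terms anywhere: F == 0
        rows = [np.zeros(d)]
        biases = [0.0]
        col_gene = [0]
        col_sign = [0]
    M = len(rows)
    out = np.zeros((d, M))
    for k, (i, s) in enumerate(zip(col_gene, col_sign)):
        out[i, k] = s
    block = LLEBlock(
        W1=np.eye(d),
        b1=np.zeros(d),
        W2=np.vstack(rows),
        b2=np.array(biases),
        eps_floor=eps_floor,
    )
    return EulerStepModel(block=block, dt=dt, out_weights=out)


@dataclass
class EnsembleModel:
    """Replica models averaged arithmetically at inference time."""

    members: list = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise ValidationError("ensemble must have at least one member")
        d = self.members[0].dimension
        gid = self.members[0].gene_ids
        for mem in self.members[1:]:
            if mem.dimension != d:
                raise ShapeError("ensemble members disagree on dimension")
            if mem.gene_ids != gid:
                raise ShapeError("ensemble members disagree on gene panel")

    @property
    def dimension(self) -> int:
        return self.members[0].dimension

    @property
    def gene_ids(self):
        return self.members[0].gene_ids

    def step_values(self, x) -> np.ndarray:
        preds = [m.step_values(x) for m in self.members]
        return np.mean(preds, axis=0)


def ensemble_predict(state, ensemble: EnsembleModel):
    """Arithmetic mean of the member one-step predictions."""
    if isinstance(state, ExpressionState):
        if state.dimension != ensemble.dimension:
            raise ShapeError("state dimension != ensemble dimension")
        vals = ensemble.step_values(state.values)
        gene_ids = (
            ensemble.gene_ids if ensemble.gene_ids is not None else state.gene_ids
        )
        return ExpressionState(vals, gene_ids)
    return ensemble.step_values(state)


# ---------------------------------------------------------------------------
# Checkpoint IO (single-file HDF5 container)


def _write_model_group(grp, model: EulerStepModel):
    grp.create_dataset("W1", data=model.block.W1)
    grp.create_dataset("b1", data=model.block.b1)
    grp.create_dataset("W2", data=model.block.W2)
    grp.create_dataset("b2", data=model.block.b2)
    if model.out_weights is not None:
        grp.create_dataset("out_weights", data=model.out_weights)
    grp.attrs["eps_floor"] = model.block.eps_floor
    grp.attrs["dt"] = model.dt
    if model.seed is not None:
        grp.attrs["seed"] = int(model.seed)
    if model.gene_ids is not None:
        grp.create_dataset(
            "gene_ids",
            data=np.array(model.gene_ids, dtype=h5py.string_dtype()),
        )


def _read_model_group(grp) -> EulerStepModel:
    block = LLEBlock(
        W1=grp["W1"][...],
        b1=grp["b1"][...],
        W2=grp["W2"][...],
        b2=grp["b2"][...],
        eps_floor=float(grp.attrs["eps_floor"]),
    )
    gene_ids = None
    if "gene_ids" in grp:
        gene_ids = tuple(g.decode() for g in grp["gene_ids"][...])
    return EulerStepModel(
        block=block,
        dt=float(grp.attrs["dt"]),
        out_weights=grp["out_weights"][...] if "out_weights" in grp else None,
        gene_ids=gene_ids,
        seed=int(grp.attrs["seed"]) if "seed" in grp.attrs else None,
    )


def save_model(model: EulerStepModel, path):
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "euler_step_model"
        _write_model_group(f, model)


def load_model(path) -> EulerStepModel:
    with h5py.File(path, "r") as f:
        return _read_model_group(f)


def save_ensemble(ensemble: EnsembleModel, path):
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "ensemble_model"
        for i, mem in enumerate(ensemble.members):
            _write_model_group(f.create_group(f"member_{i:03d}"), mem)


def load_ensemble(path) -> EnsembleModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") == "euler_step_model":
            return EnsembleModel(members=[_read_model_group(f)])
        names = sorted(k for k in f.keys() if k.startswith("member_"))
        return EnsembleModel(members=[_read_model_group(f[k]) for k in names])
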