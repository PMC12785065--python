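"""From raw counts + guide calls to snapshot-pair training data.

The pipeline mirrors the minimal two-snapshot Perturb-seq preparation:
QC filter, library-size normalization with a pseudocount and natural log,
highly-variable-gene panel selection, leakage-free time-0 construction
(an averaged control baseline with a single edit at the targeted gene),
and group-aware train/validation/test splits keyed on
(target gene x guide x batch) so no guide or batch straddles partitions.

Matrices are gene x cell throughout (10x convention for Matrix Market
triplets).  Baseline cells (0/unknown guides) only ever inform the time-0
average; singlets train, multiplets test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core_model import ExpressionState, ShapeError, ValidationError

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "GuideTable",
    "PerturbationSpec",
    "SnapshotPair",
    "normalize_counts",
    "qc_filter",
    "select_hvg",
    "build_time0",
    "group_split",
    "guide_split",
    "build_snapshot_pairs",
    "read_mtx_dir",
    "read_dense_tsv",
    "read_guide_table",
    "save_pairs",
    "load_pairs",
]

#: positive floor applied when turning normalized (log-scale, >= 0) values
#: into strictly positive model states
STATE_FLOOR = 1e-8

MODALITY_INTERFERENCE = "interference"
MODALITY_ACTIVATION = "activation"
MODALITY_NON_TARGETING = "non-targeting"

_MODALITY_ALIASES = {
    "interference": MODALITY_INTERFERENCE,
    "crispri": MODALITY_INTERFERENCE,
    "ko": MODALITY_INTERFERENCE,
    "knockout": MODALITY_INTERFERENCE,
    "knockdown": MODALITY_INTERFERENCE,
    "activation": MODALITY_ACTIVATION,
    "crispra": MODALITY_ACTIVATION,
    "oe": MODALITY_ACTIVATION,
    "overexpression": MODALITY_ACTIVATION,
    "non-targeting": MODALITY_NON_TARGETING,
    "nontargeting": MODALITY_NON_TARGETING,
    "ntc": MODALITY_NON_TARGETING,
    "control": MODALITY_NON_TARGETING,
}


def canonical_modality(value: str) -> str:
    key = str(value).strip().lower()
    if key not in _MODALITY_ALIASES:
        raise ValidationError(f"unknown guide modality {value!r}")
    return _MODALITY_ALIASES[key]


def _check_unique(names, what):
    names = [str(n) for n in names]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate {what}")
    return names


@dataclass
class CountMatrix:
    """Gene x cell raw count matrix with identifiers and optional batches."""

    counts: np.ndarray | sp.spmatrix
    gene_ids: list
    barcodes: list
    batch: np.ndarray | None = None

    def __post_init__(self):
        if sp.issparse(self.counts):
            self.counts = self.counts.tocsr()
        else:
            self.counts = np.asarray(self.counts)
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        self.barcodes = _check_unique(self.barcodes, "barcodes")
        g, c = self.counts.shape
        if g != len(self.gene_ids) or c != len(self.barcodes):
            raise ShapeError(
                f"counts {self.counts.shape} vs {len(self.gene_ids)} genes, "
                f"{len(self.barcodes)} barcodes"
            )
        if self.batch is not None:
            self.batch = np.asarray(self.batch)
            if len(self.batch) != c:
                raise ShapeError("one batch label per cell required")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def subset(self, gene_idx=None, cell_idx=None) -> "CountMatrix":
        counts = self.counts
        gene_ids, barcodes, batch = self.gene_ids, self.barcodes, self.batch
        if gene_idx is not None:
            gene_idx = np.asarray(gene_idx)
            counts = counts[gene_idx, :]
            gene_ids = [gene_ids[i] for i in gene_idx]
        if cell_idx is not None:
            cell_idx = np.asarray(cell_idx)
            counts = counts[:, cell_idx]
            barcodes = [barcodes[i] for i in cell_idx]
            if batch is not None:
                batch = batch[cell_idx]
        return CountMatrix(counts, gene_ids, barcodes, batch)


@dataclass
class ExpressionMatrix:
    """Gene x cell normalized expression values (log scale, >= 0)."""

    values: np.ndarray
    gene_ids: list
    barcodes: list
    batch: np.ndarray | None = None
    target_library: float | None = None
    pseudocount: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        self.barcodes = _check_unique(self.barcodes, "barcodes")
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ShapeError("values shape does not match identifiers")
        if self.batch is not None:
            self.batch = np.asarray(self.batch)
            if len(self.batch) != len(self.barcodes):
                raise ShapeError("one batch label per cell required")

    def subset_cells(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[:, idx],
            self.gene_ids,
            [self.barcodes[i] for i in idx],
            None if self.batch is None else self.batch[idx],
            self.target_library,
            self.pseudocount,
        )

    def subset_genes(self, panel) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in panel if g not in index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        idx = np.array([index[g] for g in panel])
        return ExpressionMatrix(
            self.values[idx, :],
            list(panel),
            self.barcodes,
            self.batch,
            self.target_library,
            self.pseudocount,
        )


@dataclass
class GuideTable:
    """Per-barcode guide-call summary.

    Columns: barcode, n_guides (int >= 0), target_gene (empty/None iff
    n_guides == 0), modality (interference / activation / non-targeting),
    optional guide_id.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        required = {"barcode", "n_guides", "target_gene", "modality"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"guide table missing columns {sorted(missing)}")
        df["barcode"] = df["barcode"].astype(str)
        if df["barcode"].duplicated().any():
            raise ValidationError("duplicate barcodes in guide table")
        df["n_guides"] = df["n_guides"].astype(int)
        if (df["n_guides"] < 0).any():
            raise ValidationError("n_guides must be non-negative")
        df["target_gene"] = df["target_gene"].where(
            df["target_gene"].notna(), None
        )
        df.loc[df["target_gene"].astype(str).isin(["", "nan", "None"]),
               "target_gene"] = None
        has_target = df["target_gene"].notna()
        if ((df["n_guides"] >= 1) & ~has_target).any():
            raise ValidationError("guided barcode without a target gene")
        if ((df["n_guides"] == 0) & has_target).any():
            raise ValidationError("baseline barcode with a target gene")
        df.loc[has_target, "modality"] = [
            canonical_modality(m) for m in df.loc[has_target, "modality"]
        ]
        if "guide_id" not in df.columns:
            df["guide_id"] = df["target_gene"].fillna("") + "_g1"
        self.table = df.set_index("barcode", drop=False)

    def lookup(self, barcode: str):
        if barcode in self.table.index:
            return self.table.loc[barcode]
        return None


@dataclass(frozen=True)
class PerturbationSpec:
    """How a targeted gene's coordinate is edited in the time-0 vector."""

    target_gene: str
    mode: str  # "floor" (CRISPRi/KO) or "observed_post" (CRISPRa/OE)
    floor_value: float = STATE_FLOOR

    def __post_init__(self):
        if self.mode not in ("floor", "observed_post"):
            raise ValidationError(f"unknown perturbation mode {self.mode!r}")
        if not self.floor_value > 0:
            raise ValidationError("floor_value must be positive")


@dataclass(frozen=True)
class SnapshotPair:
    """(time-0 state, post state, group key) — the unit of training data."""

    time0: ExpressionState
    post: ExpressionState
    group_key: tuple

    def __post_init__(self):
        if self.time0.gene_ids != self.post.gene_ids:
            raise ShapeError("time0 and post must share the gene panel")
        if not self.group_key:
            raise ValidationError("group_key must be non-empty")


# ---------------------------------------------------------------------------
# Preprocessing operations


def normalize_counts(
    raw: CountMatrix,
    pseudocount: float = 1.0,
    target_library: float | None = None,
) -> ExpressionMatrix:
    """Library-size normalization followed by z = log(x + pseudocount).

    Each cell's counts are rescaled to a common library size (default: the
    median of per-cell totals) before the log.  Zero-total cells cannot be
    rescaled and are dropped with a warning.
    """
    if not pseudocount > 0:
        raise ValidationError("pseudocount must be positive")
    dense = raw.dense()
    totals = dense.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-total cell(s)", stacklevel=2
        )
        dense = dense[:, keep]
        totals = totals[keep]
    if dense.shape[1] == 0:
        raise ValidationError("no cells left after dropping zero-total cells")
    if target_library is None:
        target_library = float(np.median(totals))
    scaled = dense * (target_library / totals)
    values = np.log(scaled + pseudocount)
    keep_idx = np.nonzero(keep)[0]
    return ExpressionMatrix(
        values,
        raw.gene_ids,
        [raw.barcodes[i] for i in keep_idx],
        None if raw.batch is None else raw.batch[keep_idx],
        target_library=target_library,
        pseudocount=pseudocount,
    )


def qc_filter(
    raw: CountMatrix,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 200,
) -> CountMatrix:
    """Keep genes detected in >= min cells, then cells with >= min genes.

    Both thresholds are inclusive and the two passes run exactly once, in
    gene-then-cell order.
    """
    counts = raw.counts
    detected = counts > 0
    if sp.issparse(detected):
        gene_ok = np.asarray(detected.sum(axis=1)).ravel() >= min_cells_per_gene
    else:
        gene_ok = detected.sum(axis=1) >= min_cells_per_gene
    out = raw.subset(gene_idx=np.nonzero(gene_ok)[0])
    detected = out.counts > 0
    if sp.issparse(detected):
        cell_ok = np.asarray(detected.sum(axis=0)).ravel() >= min_genes_per_cell
    else:
        cell_ok = detected.sum(axis=0) >= min_genes_per_cell
    out = out.subset(cell_idx=np.nonzero(cell_ok)[0])
    if out.n_genes == 0 or out.n_cells == 0:
        raise ValidationError("QC filter removed every gene or cell")
    return out


def select_hvg(normalized: ExpressionMatrix, fraction: float = 0.25) -> list:
    """Top-fraction highly variable genes by variance of the log values.

    Ties at the cutoff (and everywhere) break lexicographically on gene id
    so the panel is deterministic.  Returns ceil(fraction * G) gene ids,
    most variable first.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    disp = normalized.values.var(axis=1)
    order = sorted(
        range(len(disp)), key=lambda i: (-disp[i], normalized.gene_ids[i])
    )
    k = int(np.ceil(fraction * len(disp)))
    return [normalized.gene_ids[i] for i in order[:k]]


def build_time0(
    controls: ExpressionMatrix,
    spec: PerturbationSpec,
    post_cells: ExpressionMatrix | None = None,
    stratum=None,
) -> ExpressionState:
    """Averaged control baseline with a single edit at the targeted gene.

    The baseline is the per-gene mean over control cells (restricted to
    ``stratum`` when batch labels exist; falls back to the global mean with
    a warning when the stratum is empty).  Exactly one coordinate is then
    modified: the floor value for interference/KO, or the mean observed
    post level of the target across ``post_cells`` for activation/OE.  No
    other coordinate is touched and no individual test cell's non-target
    values are ever read.
    """
    if controls.values.shape[1] == 0:
        raise ValidationError("no control cells")
    if spec.target_gene not in controls.gene_ids:
        raise ValidationError(f"target gene {spec.target_gene!r} not in panel")
    values = controls.values
    if stratum is not None and controls.batch is not None:
        mask = controls.batch == stratum
        if mask.any():
            values = values[:, mask]
        else:
            warnings.warn(
                f"no control cells in stratum {stratum!r}; using global mean",
                stacklevel=2,
            )
    baseline = values.mean(axis=1)
    g = controls.gene_ids.index(spec.target_gene)
    if spec.mode == "floor":
        baseline[g] = spec.floor_value
    else:
        if post_cells is None or post_cells.values.shape[1] == 0:
            raise ValidationError("observed_post mode needs post cells")
        gi = post_cells.gene_ids.index(spec.target_gene)
        baseline[g] = float(post_cells.values[gi, :].mean())
    baseline = np.maximum(baseline, STATE_FLOOR)
    return ExpressionState(baseline, controls.gene_ids)


def group_split(pairs, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Assign whole (target x guide x batch) groups to train/val/test.

    Group counts match the ratios up to rounding; deterministic per seed;
    no group ever straddles partitions.
    """
    if not np.isclose(sum(ratios), 1.0):
        raise ValidationError("ratios must sum to 1")
    groups: dict = {}
    for p in pairs:
        groups.setdefault(p.group_key, []).append(p)
    keys = sorted(groups)
    if len(keys) < 3:
        raise ValidationError("need at least 3 groups to split three ways")
    rng = np.random.default_rng(seed)
    order = [keys[i] for i in rng.permutation(len(keys))]
    n = len(order)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    n_train = min(n_train, n - 2)
    n_val = max(1, min(n_val, n - n_train - 1))
    parts = (
        order[:n_train],
        order[n_train : n_train + n_val],
        order[n_train + n_val :],
    )
    return tuple([p for k in part for p in groups[k]] for part in parts)


def guide_split(matrix: CountMatrix, guides: GuideTable):
    """Partition barcodes into baseline (0/unknown), singlet and multiplet."""
    baseline, singlet, multiplet = [], [], []
    unknown = 0
    for bc in matrix.barcodes:
        row = guides.lookup(bc)
        if row is None:
            unknown += 1
            baseline.append(bc)
        elif row["n_guides"] == 0:
            baseline.append(bc)
        elif row["n_guides"] == 1:
            singlet.append(bc)
        else:
            multiplet.append(bc)
    if unknown:
        warnings.warn(
            f"{unknown} barcode(s) missing from guide table treated as baseline",
            stacklevel=2,
        )
    return baseline, singlet, multiplet


def _spec_for(row, floor_value: float) -> PerturbationSpec:
    mode = (
        "observed_post"
        if row["modality"] == MODALITY_ACTIVATION
        else "floor"
    )
    return PerturbationSpec(row["target_gene"], mode, floor_value)


def build_snapshot_pairs(
    normalized: ExpressionMatrix,
    guides: GuideTable,
    cells=None,
    floor_value: float | None = None,
    scale: str = "linear",
) -> list:
    """One snapshot pair per guided cell.

    time-0 is the control-derived single-edit baseline for the cell's
    target; post is the cell's own profile (floored to stay strictly
    positive); the group key is (target, guide_id, batch).  ``cells``
    restricts which barcodes become pairs (e.g. singlets only); control
    baselines always come from the 0-guide cells.

    ``scale`` selects the working scale the model sees: ``"linear"``
    (default) exponentiates the normalized log values back to
    library-size-scaled counts + pseudocount — the model's own LOG layer
    then recovers the log representation — while ``"log"`` feeds the
    normalized log values directly.  The default KO floor is the
    pseudocount on the linear scale (a fully silenced gene) and a small
    positive value on the log scale.
    """
    if scale not in ("linear", "log"):
        raise ValidationError(f"unknown working scale {scale!r}")
    if scale == "linear":
        working = ExpressionMatrix(
            np.exp(normalized.values),
            normalized.gene_ids,
            normalized.barcodes,
            normalized.batch,
            normalized.target_library,
            normalized.pseudocount,
        )
        if floor_value is None:
            floor_value = (
                normalized.pseudocount if normalized.pseudocount else 1.0
            )
    else:
        working = normalized
        if floor_value is None:
            floor_value = STATE_FLOOR
    normalized = working
    col = {bc: i for i, bc in enumerate(normalized.barcodes)}
    is_control = np.array(
        [
            (row := guides.lookup(bc)) is None or row["n_guides"] == 0
            for bc in normalized.barcodes
        ]
    )
    if not is_control.any():
        raise ValidationError("no control cells to average into time-0")
    controls = normalized.subset_cells(np.nonzero(is_control)[0])

    if cells is None:
        cells = [
            bc
            for bc in normalized.barcodes
            if (row := guides.lookup(bc)) is not None and row["n_guides"] >= 1
        ]

    # group guided cells by target so observed_post means are per target
    by_target: dict = {}
    for bc in cells:
        if bc not in col:
            continue
        row = guides.lookup(bc)
        if row is None or row["n_guides"] == 0:
            continue
        by_target.setdefault(row["target_gene"], []).append(bc)

    pairs = []
    for target, bcs in sorted(by_target.items()):
        if target not in normalized.gene_ids:
            warnings.warn(
                f"target {target!r} absent from gene panel; skipping "
                f"{len(bcs)} cell(s)",
                stacklevel=2,
            )
            continue
        idx = np.array([col[bc] for bc in bcs])
        post_cells = normalized.subset_cells(idx)
        for bc in bcs:
            row = guides.lookup(bc)
            spec = _spec_for(row, floor_value)
            stratum = None
            if normalized.batch is not None:
                stratum = normalized.batch[col[bc]]
            time0 = build_time0(controls, spec, post_cells, stratum=stratum)
            post_vals = np.maximum(normalized.values[:, col[bc]], STATE_FLOOR)
            post = ExpressionState(post_vals, normalized.gene_ids)
            group_key = (
                target,
                row["guide_id"],
                "" if stratum is None else str(stratum),
            )
            pairs.append(SnapshotPair(time0, post, group_key))
    return pairs


def control_baseline(
    normalized: ExpressionMatrix, guides: GuideTable, scale: str = "linear"
) -> ExpressionState:
    """Mean control-cell expression on the model's working scale.

    This is the common baseline at which ensemble elasticities are
    evaluated for network inference.
    """
    is_control = np.array(
        [
            (row := guides.lookup(bc)) is None or row["n_guides"] == 0
            for bc in normalized.barcodes
        ]
    )
    if not is_control.any():
        raise ValidationError("no control cells")
    vals = normalized.values[:, is_control]
    if scale == "linear":
        vals = np.exp(vals)
    mean = np.maximum(vals.mean(axis=1), STATE_FLOOR)
    return ExpressionState(mean, normalized.gene_ids)


# ---------------------------------------------------------------------------
# Readers and pair container IO


def read_mtx_dir(directory) -> CountMatrix:
    """10x-style Matrix Market triplet: matrix.mtx + features.tsv + barcodes.tsv."""
    from pathlib import Path

    directory = Path(directory)
    counts = scipy.io.mmread(directory / "matrix.mtx").tocsr()
    features = pd.read_csv(
        directory / "features.tsv", sep="\t", header=None
    )
    barcodes = pd.read_csv(
        directory / "barcodes.tsv", sep="\t", header=None
    )
    return CountMatrix(
        counts,
        features.iloc[:, 0].astype(str).tolist(),
        barcodes.iloc[:, 0].astype(str).tolist(),
    )


def read_dense_tsv(path) -> CountMatrix:
    """Dense TSV with gene ids in the first column, barcodes as header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        df.to_numpy(), df.index.astype(str).tolist(), list(df.columns)
    )


def read_guide_table(path) -> GuideTable:
    return GuideTable(pd.read_csv(path, sep="\t"))


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def save_pairs(pairs, path, baseline: ExpressionState | None = None):
    """Write snapshot pairs (and optionally the control baseline) to HDF5."""
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("no pairs to save")
    gene_ids = pairs[0].time0.gene_ids
    X = np.stack([p.time0.values for p in pairs])
    Y = np.stack([p.post.values for p in pairs])
    keys = np.array(
        ["\t".join(map(str, p.group_key)) for p in pairs],
        dtype=h5py.string_dtype(),
    )
    with h5py.File(path, "w") as f:
        f.create_dataset("time0", data=X)
        f.create_dataset("post", data=Y)
        f.create_dataset("group_key", data=keys)
        f.create_dataset(
            "gene_ids", data=np.array(gene_ids, dtype=h5py.string_dtype())
        )
        if baseline is not None:
            if baseline.gene_ids != gene_ids:
                raise ShapeError("baseline panel differs from pair panel")
            f.create_dataset("baseline", data=baseline.values)


def load_pairs(path, with_baseline: bool = False):
    with h5py.File(path, "r") as f:
        X = f["time0"][...]
        Y = f["post"][...]
        keys = [k.decode() for k in f["group_key"][...]]
        gene_ids = tuple(g.decode() for g in f["gene_ids"][...])
        baseline = None
        if "baseline" in f:
            baseline = ExpressionState(f["baseline"][...], gene_ids)
    pairs = [
        SnapshotPair(
            ExpressionState(x, gene_ids),
            ExpressionState(y, gene_ids),
            tuple(k.split("\t")),
        )
        for x, y, k in zip(X, Y, keys)
    ]
    if with_baseline:
        return pairs, baseline
    return pairs
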