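"""Masking benchmark: fit a dropout logistic, hide real values, score recovery.

The benchmark emulates measurement dropout on data whose values are known:
a logistic curve relating a gene's zero fraction to its positive-mean
expression is fitted to the data itself, then for each gene a handful of
nonzero entries are hidden (set to zero) with probabilities from that
curve, and an imputer is scored on how well it restores them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import ExpressionMatrix, ValidationError


@dataclass
class DropoutLogistic:
    """Logistic dropout-probability curve p(x) = 1 / (1 + exp(-k (x - x0))).

    ``x`` is log1p expression; ``mid`` (x0) is where p = 0.5 and ``shape``
    (k) its slope — negative for the usual "high expression drops out
    less" behaviour.
    """

    mid: float
    shape: float

    def probability(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return 1.0 / (1.0 + np.exp(-self.shape * (x - self.mid)))


@dataclass
class MaskSet:
    """Entries hidden by :func:`mask`: (cell_id, gene_id, original value)."""

    entries: list[tuple[str, str, float]]
    n_per_gene: int = 10

    def __post_init__(self) -> None:
        coords = [(c, g) for c, g, _ in self.entries]
        if len(set(coords)) != len(coords):
            raise ValidationError("duplicate (cell, gene) pairs in mask set")
        if any(v <= 0 for _, _, v in self.entries):
            raise ValidationError("masked original values must be positive")

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["cell_id", "gene_id", "value"])


@dataclass
class AccuracyReport:
    """Recovery metrics on masked entries, all in log1p space."""

    overall_mse: float
    overall_pearson: float
    per_gene_mse: pd.Series
    per_cell_mse: pd.Series
    n_masked: int = 0
    extras: dict = field(default_factory=dict)


def _gene_fit_points(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (log1p positive-mean, zero-fraction) points for the fit.

    Only genes with both zeros and positive values constrain the curve.
    """
    V = matrix.values
    n_cells = matrix.n_cells
    xs, ys = [], []
    for j in range(matrix.n_genes):
        col = V[:, j]
        pos = col[col > 0]
        n_zero = n_cells - pos.size
        if pos.size == 0 or n_zero == 0:
            continue
        xs.append(np.log1p(pos.mean()))
        ys.append(n_zero / n_cells)
    return np.array(xs), np.array(ys)


def fit_dropout_logistic(matrix: ExpressionMatrix) -> DropoutLogistic:
    """Least-squares logistic fit of zero fraction vs log1p positive mean."""
    if matrix.space != "raw":
        raise ValidationError("dropout fit operates on raw counts")
    x, y = _gene_fit_points(matrix)
    if x.size < 3:
        raise ValidationError(
            "need at least 3 genes with both zero and positive values to fit"
        )

    def logistic(x, mid, shape):
        return 1.0 / (1.0 + np.exp(-shape * (x - mid)))

    p0 = (float(np.median(x)), -1.0)
    try:
        popt, _ = optimize.curve_fit(
            logistic, x, y, p0=p0, maxfev=10000, xtol=1e-8, ftol=1e-8
        )
    except RuntimeError as exc:
        raise ValidationError(f"dropout logistic fit failed: {exc}") from exc
    return DropoutLogistic(mid=float(popt[0]), shape=float(popt[1]))


def mask(
    matrix: ExpressionMatrix,
    model: DropoutLogistic,
    n_per_gene: int = 10,
    seed: int = 0,
) -> tuple[ExpressionMatrix, MaskSet]:
    """Hide up to ``n_per_gene`` nonzero entries per gene.

    Within each gene the cells to hide are drawn without replacement with
    probability proportional to the fitted dropout probability of the
    entry's own log1p value, so low values — the ones dropout would
    plausibly have claimed — are hidden preferentially. The input matrix
    is not modified.
    """
    if n_per_gene < 1:
        raise ValidationError("n_per_gene must be >= 1")
    if matrix.space != "raw":
        raise ValidationError("masking operates on raw counts")
    rng = np.random.default_rng(seed)
    masked = matrix.values.copy()
    entries: list[tuple[str, str, float]] = []
    for j, gene in enumerate(matrix.gene_ids):
        col = matrix.values[:, j]
        nz = np.flatnonzero(col > 0)
        if nz.size == 0:
            continue
        p = model.probability(np.log1p(col[nz]))
        total = p.sum()
        q = p / total if total > 0 else np.full(nz.size, 1.0 / nz.size)
        take = min(n_per_gene, nz.size)
        picked = rng.choice(nz, size=take, replace=False, p=q)
        for i in picked:
            entries.append((matrix.cell_ids[i], gene, float(col[i])))
            masked[i, j] = 0.0
    out = ExpressionMatrix(
        masked, cell_ids=list(matrix.cell_ids), gene_ids=list(matrix.gene_ids), space="raw"
    )
    return out, MaskSet(entries=entries, n_per_gene=n_per_gene)


def score(
    original: ExpressionMatrix,
    imputed: ExpressionMatrix,
    maskset: MaskSet,
) -> AccuracyReport:
    """Score recovery of masked entries, on log1p-transformed values.

    Overall MSE and Pearson correlation are over all masked entries;
    per-gene / per-cell MSE group the squared residuals by gene or cell.
    """
    if original.shape != imputed.shape:
        raise ValidationError("original and imputed shapes differ")
    if len(maskset) == 0:
        raise ValidationError("mask set is empty")
    cell_pos = {c: i for i, c in enumerate(original.cell_ids)}
    gene_pos = {g: j for j, g in enumerate(original.gene_ids)}
    rows = np.array([cell_pos[c] for c, _, _ in maskset.entries])
    cols = np.array([gene_pos[g] for _, g, _ in maskset.entries])
    truth = np.log1p(np.array([v for _, _, v in maskset.entries]))
    pred = np.log1p(imputed.values[rows, cols])
    sq = (truth - pred) ** 2
    if truth.size >= 2 and np.std(truth) > 0 and np.std(pred) > 0:
        pearson = float(stats.pearsonr(truth, pred).statistic)
    else:
        pearson = float("nan")
    frame = pd.DataFrame(
        {
            "cell": [c for c, _, _ in maskset.entries],
            "gene": [g for _, g, _ in maskset.entries],
            "sq": sq,
        }
    )
    return AccuracyReport(
        overall_mse=float(sq.mean()),
        overall_pearson=pearson,
        per_gene_mse=frame.groupby("gene")["sq"].mean(),
        per_cell_mse=frame.groupby("cell")["sq"].mean(),
        n_masked=int(truth.size),
    )


# -- reference baselines ------------------------------------------------------

def baseline_zero(masked: ExpressionMatrix) -> ExpressionMatrix:
    """The do-nothing imputer: masked entries stay zero."""
    return masked.copy()


def baseline_gene_mean(masked: ExpressionMatrix) -> ExpressionMatrix:
    """Fill every zero with its gene's mean over positive entries."""
    out = masked.values.copy()
    for j in range(masked.n_genes):
        col = out[:, j]
        pos = col[col > 0]
        if pos.size:
            col[col == 0] = pos.mean()
    return ExpressionMatrix(
        out, cell_ids=list(masked.cell_ids), gene_ids=list(masked.gene_ids), space="raw"
    )
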