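"""Gene selection, log transform, target partitioning, predictor selection.

These four steps define each sub-network's inputs and outputs: genes worth
imputing are picked by their variance-over-mean ratio, shuffled into
balanced target subsets, and each subset is paired with the non-target
genes most correlated with its targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError


@dataclass
class GeneSelection:
    """Genes retained for imputation, with their dispersion statistic."""

    imputable_genes: list[str]
    vmr: pd.Series  # per-gene variance-over-mean ratio (NaN for zero-mean genes)
    threshold: float


@dataclass
class SubnetPlan:
    """One sub-network's target genes, predictor genes and layer sizes."""

    targets: list[str]
    predictors: list[str]
    hidden_size: int = 256
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError("plan needs at least one target gene")
        if not self.predictors:
            raise ValidationError("plan needs at least one predictor gene")
        if set(self.targets) & set(self.predictors):
            raise ValidationError("targets and predictors must be disjoint")


def gene_vmr(matrix: ExpressionMatrix, ddof: int = 0) -> pd.Series:
    """Per-gene variance-over-mean ratio on raw counts.

    Population variance (ddof=0) by default; zero-mean genes get NaN.
    """
    values = matrix.values
    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        vmr = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), np.nan)
    return pd.Series(vmr, index=list(matrix.gene_ids), name="vmr")


def select_genes(
    matrix: ExpressionMatrix, threshold: float = 0.5, ddof: int = 0
) -> GeneSelection:
    """Keep genes whose variance/mean ratio strictly exceeds ``threshold``.

    Zero-mean genes have an undefined ratio and are never selected.
    Order of the selected genes follows the matrix's column order.
    """
    if matrix.n_genes == 0 or matrix.n_cells == 0:
        raise ValidationError("cannot select genes from an empty matrix")
    if matrix.space != "raw":
        raise ValidationError("gene selection operates on raw counts")
    vmr = gene_vmr(matrix, ddof=ddof)
    keep = vmr[vmr > threshold].index.tolist()  # NaN compares False
    return GeneSelection(imputable_genes=keep, vmr=vmr, threshold=threshold)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise log(1 + x); marks the result as log-space."""
    if matrix.space != "raw":
        raise ValidationError("matrix is already log-transformed")
    return ExpressionMatrix(
        np.log1p(matrix.values),
        cell_ids=list(matrix.cell_ids),
        gene_ids=list(matrix.gene_ids),
        space="log",
    )


def inverse_log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise exp(x) - 1, restoring raw space."""
    if matrix.space != "log":
        raise ValidationError("matrix is not in log space")
    return ExpressionMatrix(
        np.expm1(matrix.values),
        cell_ids=list(matrix.cell_ids),
        gene_ids=list(matrix.gene_ids),
        space="raw",
    )


def partition_targets(genes: list[str], subset_size: int, seed: int) -> list[list[str]]:
    """Shuffle genes by ``seed`` and split into balanced subsets.

    The number of subsets is ceil(len(genes) / subset_size) and subset sizes
    differ by at most one, so no sub-network gets a degenerate tail.
    """
    if subset_size < 1:
        raise ValidationError("subset_size must be >= 1")
    if not genes:
        raise ValidationError("no genes to partition")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    shuffled = [genes[i] for i in order]
    n_groups = -(-len(genes) // subset_size)
    return [list(chunk) for chunk in np.array_split(np.array(shuffled, dtype=object), n_groups)]


def select_predictors(
    log_matrix: ExpressionMatrix, targets: list[str], k: int = 5
) -> list[str]:
    """Top-k most correlated non-target genes per target, pooled.

    Correlation is absolute Pearson on log-space values across cells;
    zero-variance genes are never candidates. The pooled set is
    deduplicated and ordered by the matrix's gene column order.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    gene_index = {g: j for j, g in enumerate(log_matrix.gene_ids)}
    missing = [t for t in targets if t not in gene_index]
    if missing:
        raise ValidationError(f"targets absent from matrix: {missing[:5]}")
    target_idx = np.array([gene_index[t] for t in targets])
    n_genes = log_matrix.n_genes
    is_target = np.zeros(n_genes, dtype=bool)
    is_target[target_idx] = True
    if is_target.all():
        raise ValidationError("no non-target genes available as predictors")

    X = log_matrix.values
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    # exact constancy check; std of an identical-valued column can be ~1e-16
    constant = np.ptp(X, axis=0) == 0
    std = np.where(constant, 0.0, std)
    usable = ~constant & ~is_target
    if not usable.any():
        raise ValidationError("all candidate predictor genes are constant")

    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (X - mean) / np.where(std > 0, std, 1.0)
    Z[:, std == 0] = 0.0
    # |corr| block: targets x all genes, computed once.
    corr = np.abs(Z[:, target_idx].T @ Z) / X.shape[0]
    corr[:, ~usable] = -np.inf  # exclude targets and constant genes

    chosen: set[int] = set()
    k_eff = min(k, int(usable.sum()))
    for row in corr:
        # stable top-k with ties broken by column order
        top = np.argsort(-row, kind="stable")[:k_eff]
        chosen.update(int(j) for j in top if np.isfinite(row[j]))
    return [log_matrix.gene_ids[j] for j in sorted(chosen)]
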