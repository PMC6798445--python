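"""Downstream evaluation: clustering agreement, DE recovery, FISH-style
distribution comparison.

Clustering agreement (adjusted Rand, adjusted mutual information,
Fowlkes-Mallows, silhouette) quantifies how well a clustering of imputed
data matches reference cell-type labels. DE recovery scores a one-vs-rest
t-test pipeline against simulator ground truth as a ROC AUC. The
FISH-style operations (housekeeping-factor normalisation, Gini
coefficients, efficiency-factor rescaling, Kolmogorov-Smirnov distances)
compare expression distributions between a reference assay and an
imputed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ValidationError
from .simulate import SimTruth, truth_de_labels


# -- clustering agreement -----------------------------------------------------

def _aligned_labels(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    a = pd.Series(a)
    b = pd.Series(b)
    if set(a.index) != set(b.index):
        raise ValidationError("label sets cover different cells")
    b = b.reindex(a.index)
    return a.to_numpy(), b.to_numpy()


def adjusted_rand(a: pd.Series, b: pd.Series) -> float:
    """Chance-adjusted Rand index between two partitions of the same cells."""
    x, y = _aligned_labels(a, b)
    return float(skm.adjusted_rand_score(x, y))


def adjusted_mutual_information(a: pd.Series, b: pd.Series) -> float:
    """Mutual information adjusted for chance; 1 for identical partitions."""
    x, y = _aligned_labels(a, b)
    return float(skm.adjusted_mutual_info_score(x, y))


def fowlkes_mallows(a: pd.Series, b: pd.Series) -> float:
    """Geometric mean of pairwise precision and recall: sqrt(TP/(TP+FP) * TP/(TP+FN))."""
    x, y = _aligned_labels(a, b)
    return float(skm.fowlkes_mallows_score(x, y))


def silhouette(embedding: np.ndarray | pd.DataFrame, labels: pd.Series) -> float:
    """Mean silhouette coefficient over cells, Euclidean distances.

    ``embedding`` is any cells x d coordinate matrix (e.g. UMAP
    components computed elsewhere); rows must align with ``labels``.
    """
    if isinstance(embedding, pd.DataFrame):
        lab = pd.Series(labels).reindex(embedding.index)
        if lab.isna().any():
            raise ValidationError("labels missing for some embedded cells")
        X = embedding.to_numpy(dtype=np.float64)
        y = lab.to_numpy()
    else:
        X = np.asarray(embedding, dtype=np.float64)
        y = np.asarray(pd.Series(labels))
        if X.shape[0] != y.size:
            raise ValidationError("embedding rows and labels differ in length")
    if len(set(y)) < 2:
        raise ValidationError("silhouette needs at least two clusters")
    return float(skm.silhouette_score(X, y, metric="euclidean"))


# -- differential-expression recovery ----------------------------------------

def de_calling_table(
    matrix: ExpressionMatrix,
    groups: pd.Series,
    top_n: int = 500,
) -> pd.DataFrame:
    """Per-group one-vs-rest Welch t-tests with BH adjustment, top-n per group.

    For each group every gene is tested in-group vs all other cells on
    log1p values, p-values are Benjamini-Hochberg adjusted within the
    group, and the ``top_n`` smallest-adjusted-p genes are kept as one
    record each. Returns a frame with columns ``group``, ``gene``,
    ``padj`` and ``calling_prob`` (= 1 - padj).
    """
    groups = pd.Series(groups)
    if set(groups.index) - set(matrix.cell_ids):
        raise ValidationError("group labels cover cells absent from the matrix")
    groups = groups.reindex(matrix.cell_ids)
    if groups.isna().any():
        raise ValidationError("every cell needs a group label")
    if groups.nunique() < 2:
        raise ValidationError("need at least two groups")
    L = np.log1p(matrix.values)
    records = []
    for g in sorted(groups.unique()):
        in_mask = (groups == g).to_numpy()
        if in_mask.sum() < 2 or (~in_mask).sum() < 2:
            raise ValidationError(f"group {g!r} needs >= 2 cells on both sides")
        res = stats.ttest_ind(L[in_mask], L[~in_mask], axis=0, equal_var=False)
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        padj = multipletests(pvals, method="fdr_bh")[1]
        order = np.argsort(padj, kind="stable")[: min(top_n, padj.size)]
        for j in order:
            records.append((g, matrix.gene_ids[j], float(padj[j]), 1.0 - float(padj[j])))
    return pd.DataFrame(records, columns=["group", "gene", "padj", "calling_prob"])


def de_auc(
    matrix: ExpressionMatrix,
    groups: pd.Series,
    truth: SimTruth | pd.Series,
    top_n: int = 500,
) -> float:
    """ROC AUC of DE calling against ground truth, over all genes.

    The per-group top-n extractions define the *called* gene set: a
    pooled gene's calling probability is its maximum 1 - adjusted p
    across the groups that extracted it, and a gene never extracted is
    simply not called (probability 0). The ROC compares these
    probabilities with the per-gene truth (DE factor differing from 1 in
    at least one group), so the score rewards pulling weakly expressed
    true DE genes into the called set — which is exactly what imputation
    is supposed to enable — and penalises calling genes that are DE
    nowhere.
    """
    table = de_calling_table(matrix, groups, top_n=top_n)
    is_de = truth_de_labels(truth) if isinstance(truth, SimTruth) else pd.Series(truth)
    missing = set(matrix.gene_ids) - set(is_de.index)
    if missing:
        raise ValidationError("truth labels missing for some genes")
    per_gene = table.groupby("gene")["calling_prob"].max()
    scores = pd.Series(0.0, index=list(matrix.gene_ids))
    scores[per_gene.index] = per_gene
    y = is_de.reindex(scores.index).astype(bool).to_numpy()
    if y.all() or not y.any():
        raise ValidationError("truth labels are all one class; AUC undefined")
    return float(skm.roc_auc_score(y, scores.to_numpy()))


# -- FISH-style distribution comparison --------------------------------------

def gapdh_normalize(
    matrix: ExpressionMatrix,
    housekeeping_gene: str,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
) -> ExpressionMatrix:
    """Housekeeping-factor normalisation with outlier trimming.

    Cells strictly below the ``lower_pct`` or strictly above the
    ``upper_pct`` percentile of the housekeeping gene are removed; each
    remaining cell's row is multiplied by
    mean(retained housekeeping) / cell's housekeeping value.
    """
    if housekeeping_gene not in matrix.gene_ids:
        raise ValidationError(f"housekeeping gene {housekeeping_gene!r} absent")
    j = matrix.gene_ids.index(housekeeping_gene)
    hk = matrix.values[:, j]
    lo = np.percentile(hk, lower_pct)
    hi = np.percentile(hk, upper_pct)
    keep = (hk >= lo) & (hk <= hi)
    if not keep.any():
        raise ValidationError("no cells retained after outlier trimming")
    hk_kept = hk[keep]
    if np.any(hk_kept <= 0):
        raise ValidationError("housekeeping gene must be positive in retained cells")
    factor = hk_kept.mean() / hk_kept
    out = matrix.values[keep] * factor[:, None]
    return ExpressionMatrix(
        out,
        cell_ids=[c for c, k in zip(matrix.cell_ids, keep) if k],
        gene_ids=list(matrix.gene_ids),
        space=matrix.space,
    )


def gini(values: np.ndarray) -> float:
    """Gini coefficient sum_ij |x_i - x_j| / (2 n^2 mean) of a nonnegative vector."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValidationError("empty vector")
    if np.any(x < 0):
        raise ValidationError("values must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValidationError("Gini undefined for an all-zero vector")
    xs = np.sort(x)
    n = xs.size
    ranks = np.arange(1, n + 1)
    return float((2.0 * np.sum(ranks * xs)) / (n * total) - (n + 1.0) / n)


@dataclass
class FishComparison:
    """Per-gene distribution-comparison results against a reference assay."""

    efficiency_factors: pd.Series
    ks_statistic: pd.Series
    gini_reference: pd.Series
    gini_method: pd.Series
    mse: pd.Series  # only for genes with paired vectors
    corr: pd.Series  # only for genes with paired vectors
    skipped: list[str] = field(default_factory=list)


def distribution_compare(
    reference: dict[str, np.ndarray],
    method: dict[str, np.ndarray],
    strict_formula: bool = False,
) -> FishComparison:
    """Compare per-gene expression distributions to a reference assay.

    For each shared gene the method values are rescaled by an efficiency
    factor mean(reference)/mean(method) so means match, then the
    two-sample K-S statistic and both Gini coefficients are computed.
    Where the vectors are paired (equal length, same cells) a per-gene
    MSE and Pearson correlation are reported too; ``strict_formula``
    switches those to the summed squared error and a
    covariance/(variance*variance) ratio instead of the conventional
    mean/Pearson forms.
    """
    genes = [g for g in reference if g in method]
    eff, ks, g_ref, g_met, mses, corrs, skipped = {}, {}, {}, {}, {}, {}, []
    for g in genes:
        ref = np.asarray(reference[g], dtype=np.float64).ravel()
        met = np.asarray(method[g], dtype=np.float64).ravel()
        if ref.size == 0 or met.size == 0:
            raise ValidationError(f"empty vector for gene {g!r}")
        m = met.mean()
        if m == 0:
            skipped.append(g)
            continue
        factor = ref.mean() / m
        met_scaled = met * factor
        eff[g] = factor
        ks[g] = float(stats.ks_2samp(ref, met_scaled).statistic)
        if ref.sum() > 0:
            g_ref[g] = gini(ref)
        if met_scaled.sum() > 0:
            g_met[g] = gini(met_scaled)
        if ref.size == met.size:
            diff2 = (ref - met_scaled) ** 2
            mses[g] = float(diff2.sum() if strict_formula else diff2.mean())
            if np.std(ref) > 0 and np.std(met_scaled) > 0:
                if strict_formula:
                    corrs[g] = float(
                        np.cov(ref, met_scaled, ddof=0)[0, 1]
                        / (np.var(ref) * np.var(met_scaled))
                    )
                else:
                    corrs[g] = float(stats.pearsonr(ref, met_scaled).statistic)
    return FishComparison(
        efficiency_factors=pd.Series(eff, dtype=float),
        ks_statistic=pd.Series(ks, dtype=float),
        gini_reference=pd.Series(g_ref, dtype=float),
        gini_method=pd.Series(g_met, dtype=float),
        mse=pd.Series(mses, dtype=float),
        corr=pd.Series(corrs, dtype=float),
        skipped=skipped,
    )


def gini_agreement(comparison: FishComparison) -> tuple[float, float]:
    """(Pearson correlation, MSE) between reference and method Gini pairs."""
    shared = comparison.gini_reference.index.intersection(comparison.gini_method.index)
    if len(shared) < 2:
        raise ValidationError("need at least two genes with Gini on both sides")
    a = comparison.gini_reference[shared].to_numpy()
    b = comparison.gini_method[shared].to_numpy()
    corr = float(stats.pearsonr(a, b).statistic) if np.std(a) > 0 and np.std(b) > 0 else float("nan")
    return corr, float(np.mean((a - b) ** 2))
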