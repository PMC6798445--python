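"""Group-structured scRNA-seq count simulator with logistic dropout.

A deliberately compact generative model in the Splatter family: gamma gene
means, per-group log-normal differential-expression factors, log-normal
library sizes, Poisson counts, and an entry-wise logistic dropout whose
argument is the log1p expected count. It records complete ground truth
(group labels, DE factors, pre-dropout counts, dropout mask) so imputation
and the downstream metrics can be evaluated against known answers.

It is not a drop-in Splatter replacement — there is no biological
coefficient of variation trend, no batch effects and no trajectories —
but it reproduces the structure those evaluations need: distinct cell
groups, per-group DE genes, and expression-dependent zero inflation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

#: Default cell-group proportions: five groups at 10/10/20/20/40 %.
DEFAULT_PROPORTIONS = (0.10, 0.10, 0.20, 0.20, 0.40)


@dataclass
class SimParams:
    """Simulation parameters.

    Dropout follows p(drop) = 1 / (1 + exp(-shape * (log1p(mu) - mid)))
    per entry with expected count mu; ``dropout_shape=-inf`` disables
    dropout entirely. DE factors are log-normal multipliers applied to a
    ``de_prob`` fraction of genes per group (half up-, half
    down-regulated on average); 1 means not differentially expressed.
    """

    n_genes: int = 4000
    n_cells: int = 2000
    group_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    de_prob: float = 0.1
    de_factor_loc: float = 0.1
    de_factor_scale: float = 0.4
    mean_shape: float = 8.0
    mean_rate: float = 0.5
    libsize_location: float = 10.3
    libsize_scale: float = 0.2
    dropout_mid: float = 1.0
    dropout_shape: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.group_proportions, dtype=np.float64)
        if props.ndim != 1 or props.size < 1:
            raise ValidationError("group_proportions must be a 1-D vector")
        if np.any(props <= 0):
            raise ValidationError("group proportions must be positive")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValidationError("group proportions must sum to 1")
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValidationError("n_genes and n_cells must be >= 1")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValidationError("de_prob must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    group_labels: pd.Series  # cell_id -> group name
    de_factors: pd.DataFrame  # groups x genes multipliers (1 = not DE)
    expected: np.ndarray  # cells x genes Poisson rates
    pre_dropout: np.ndarray  # cells x genes counts before dropout
    dropout_mask: np.ndarray  # cells x genes booleans, True = zeroed
    post_dropout: np.ndarray  # cells x genes observed counts


def simulate(params: SimParams | None = None, **overrides) -> tuple[ExpressionMatrix, SimTruth]:
    """Draw one dataset; fixed seed gives bit-identical output.

    Keyword overrides are applied on top of ``params`` (or the defaults).
    """
    if params is None:
        params = SimParams(**overrides)
    elif overrides:
        raise ValidationError("pass either a SimParams or keyword overrides, not both")
    rng = np.random.default_rng(params.seed)
    G, C = params.n_genes, params.n_cells
    props = np.asarray(params.group_proportions, dtype=np.float64)
    K = props.size
    group_names = [f"group{k + 1}" for k in range(K)]

    base_mean = rng.gamma(shape=params.mean_shape, scale=1.0 / params.mean_rate, size=G)

    # Per-group DE factors: log-normal, inverted with probability 1/2.
    factors = np.ones((K, G))
    for k in range(K):
        is_de = rng.random(G) < params.de_prob
        f = np.exp(rng.normal(params.de_factor_loc, params.de_factor_scale, size=G))
        down = rng.random(G) < 0.5
        f = np.where(down, 1.0 / f, f)
        factors[k, is_de] = f[is_de]

    group_of_cell = rng.choice(K, size=C, p=props)
    lib = np.exp(rng.normal(params.libsize_location, params.libsize_scale, size=C))

    # Expected counts: group mean profile normalised to proportions x library size.
    group_mean = base_mean[None, :] * factors  # K x G
    group_prop = group_mean / group_mean.sum(axis=1, keepdims=True)
    expected = group_prop[group_of_cell, :] * lib[:, None]  # C x G

    pre = rng.poisson(expected).astype(np.float64)

    if np.isneginf(params.dropout_shape):
        drop_prob = np.zeros_like(expected)
    else:
        x = np.log1p(expected)
        drop_prob = 1.0 / (1.0 + np.exp(-params.dropout_shape * (x - params.dropout_mid)))
    mask = rng.random((C, G)) < drop_prob
    post = np.where(mask, 0.0, pre)

    cell_ids = [f"cell{i}" for i in range(C)]
    gene_ids = [f"gene{j}" for j in range(G)]
    matrix = ExpressionMatrix(post, cell_ids=cell_ids, gene_ids=gene_ids, space="raw")
    truth = SimTruth(
        group_labels=pd.Series(
            [group_names[k] for k in group_of_cell], index=cell_ids, name="group"
        ),
        de_factors=pd.DataFrame(factors, index=group_names, columns=gene_ids),
        expected=expected,
        pre_dropout=pre,
        dropout_mask=mask,
        post_dropout=post,
    )
    return matrix, truth


def truth_de_labels(truth: SimTruth) -> pd.Series:
    """Boolean per gene: differentially expressed in at least one group."""
    return (truth.de_factors != 1.0).any(axis=0).rename("is_de")
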