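"""Divide-and-conquer dropout imputation as a scikit-learn transformer.

:class:`DropoutImputer` selects imputable genes by their variance-over-mean
ratio, shuffles them into balanced target subsets, trains one small dense
network per subset (predictors = most-correlated non-target genes), and at
transform time fills *only* the zero entries of imputable genes with the
networks' predictions, leaving every other entry bit-identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix, ValidationError
from .nn import SubNetwork, fit_subnetwork
from .preprocessing import (
    SubnetPlan,
    log_transform,
    partition_targets,
    select_genes,
    select_predictors,
)


def _as_dataframe(X) -> tuple[pd.DataFrame, bool]:
    """Coerce input to a cells x genes DataFrame; report if it was one."""
    if isinstance(X, ExpressionMatrix):
        return X.to_df(), False
    if isinstance(X, pd.DataFrame):
        return X, True
    arr = np.asarray(X, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D cells x genes matrix")
    return (
        pd.DataFrame(arr, columns=[f"gene{j}" for j in range(arr.shape[1])]),
        False,
    )


class DropoutImputer(BaseEstimator, TransformerMixin):
    """Impute scRNA-seq dropout zeros with per-subset dense networks.

    Parameters
    ----------
    vmr_threshold : float, default 0.5
        Genes with raw-count variance/mean strictly above this are imputed;
        the rest pass through untouched.
    subset_size : int, default 512
        Maximum number of target genes per sub-network.
    n_predictors : int, default 5
        Top-|Pearson| correlated non-target genes kept per target gene.
    hidden_size : int, default 256
        Hidden-layer width of each sub-network.
    dropout_rate : float, default 0.2
        Training-time hidden-unit dropout (regularisation; unrelated to
        the measurement dropout being imputed).
    learning_rate : float, default 1e-4
        Adam step size.
    batch_size : int, default 64
    max_epochs : int, default 500
    patience : int, default 5
        Early stopping: halt a sub-network when its held-out loss has not
        improved for this many consecutive epochs; best weights restored.
    test_fraction : float, default 0.05
        Fraction of cells held out to monitor overfitting. Held-out cells
        are still imputed.
    train_cell_fraction : float, default 1.0
        Optional training on a random subset of cells; prediction always
        covers every cell.
    architecture : {"relu", "linear", "none_hidden"}, default "relu"
    seed : int, default 0
        Master seed; per-subnetwork seeds are derived from it so adding
        subsets does not reshuffle earlier ones.

    Attributes
    ----------
    gene_selection_ : GeneSelection
        The variance-over-mean filter result.
    plans_ : list of SubnetPlan
        Target/predictor assignment of every sub-network.
    networks_ : list of SubNetwork
        The fitted networks, parallel to ``plans_``.
    training_log_ : list of dict
        Per-plan per-epoch train/test losses.
    feature_names_in_ : ndarray of str
        Gene identifiers seen at fit time.
    """

    def __init__(
        self,
        vmr_threshold: float = 0.5,
        subset_size: int = 512,
        n_predictors: int = 5,
        hidden_size: int = 256,
        dropout_rate: float = 0.2,
        learning_rate: float = 1e-4,
        batch_size: int = 64,
        max_epochs: int = 500,
        patience: int = 5,
        test_fraction: float = 0.05,
        train_cell_fraction: float = 1.0,
        architecture: str = "relu",
        seed: int = 0,
    ) -> None:
        self.vmr_threshold = vmr_threshold
        self.subset_size = subset_size
        self.n_predictors = n_predictors
        self.hidden_size = hidden_size
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.test_fraction = test_fraction
        self.train_cell_fraction = train_cell_fraction
        self.architecture = architecture
        self.seed = seed

    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "DropoutImputer":
        """Select genes, build plans, and train every sub-network."""
        if not 0.0 < self.test_fraction < 1.0:
            raise ValidationError("test_fraction must be in (0, 1)")
        if not 0.0 < self.train_cell_fraction <= 1.0:
            raise ValidationError("train_cell_fraction must be in (0, 1]")
        df, _ = _as_dataframe(X)
        matrix = ExpressionMatrix.from_df(df, space="raw")
        n_cells = matrix.n_cells

        # Seed tree: one branch per concern, then one per plan.
        ss = np.random.SeedSequence(self.seed)
        s_cells, s_split, s_partition, s_plans = ss.spawn(4)

        selection = select_genes(matrix, threshold=self.vmr_threshold)
        if not selection.imputable_genes:
            raise ValidationError("no gene passes the variance-over-mean filter")
        log_mat = log_transform(matrix)

        # A single subset covering the whole matrix would leave no predictor
        # candidates; force at least two subsets in that degenerate case.
        effective_subset = self.subset_size
        if (
            len(selection.imputable_genes) == matrix.n_genes
            and len(selection.imputable_genes) <= self.subset_size
        ):
            if matrix.n_genes < 2:
                raise ValidationError("cannot impute a single-gene matrix")
            effective_subset = -(-matrix.n_genes // 2)
        target_groups = partition_targets(
            selection.imputable_genes,
            effective_subset,
            seed=int(s_partition.generate_state(1)[0] % (2**31)),
        )

        # Optional cell subsampling, then train/test split.
        if self.train_cell_fraction < 1.0:
            rng_cells = np.random.default_rng(s_cells)
            n_use = max(2, int(round(self.train_cell_fraction * n_cells)))
            used = np.sort(rng_cells.choice(n_cells, size=n_use, replace=False))
        else:
            used = np.arange(n_cells)
        n_test = int(round(self.test_fraction * used.size))
        if n_test < 1 or used.size - n_test < 1:
            raise ValidationError(
                f"{used.size} training cells cannot support a "
                f"{self.test_fraction:.0%} held-out split"
            )
        rng_split = np.random.default_rng(s_split)
        perm = rng_split.permutation(used)
        test_cells, train_cells = perm[:n_test], perm[n_test:]

        gene_pos = {g: j for j, g in enumerate(log_mat.gene_ids)}
        L = log_mat.values
        self.plans_ = []
        self.networks_ = []
        self.training_log_ = []
        plan_seeds = s_plans.spawn(len(target_groups))
        for targets, plan_ss in zip(target_groups, plan_seeds):
            predictors = select_predictors(log_mat, targets, k=self.n_predictors)
            plan = SubnetPlan(
                targets=targets,
                predictors=predictors,
                hidden_size=self.hidden_size,
                dropout_rate=self.dropout_rate,
            )
            p_idx = np.array([gene_pos[g] for g in predictors])
            t_idx = np.array([gene_pos[g] for g in targets])
            net = SubNetwork(
                n_in=len(predictors),
                n_out=len(targets),
                hidden_size=self.hidden_size,
                dropout_rate=self.dropout_rate,
                architecture=self.architecture,
                learning_rate=self.learning_rate,
                seed=int(plan_ss.generate_state(1)[0] % (2**31)),
            )
            log = fit_subnetwork(
                net,
                L[np.ix_(train_cells, p_idx)],
                L[np.ix_(train_cells, t_idx)],
                L[np.ix_(test_cells, p_idx)],
                L[np.ix_(test_cells, t_idx)],
                batch_size=self.batch_size,
                max_epochs=self.max_epochs,
                patience=self.patience,
            )
            self.plans_.append(plan)
            self.networks_.append(net)
            self.training_log_.append(log)

        self.gene_selection_ = selection
        self.feature_names_in_ = np.array(list(matrix.gene_ids))
        self.n_features_in_ = matrix.n_genes
        return self

    # ------------------------------------------------------------------
    def _check_genes(self, df: pd.DataFrame) -> None:
        if not hasattr(self, "plans_"):
            raise ValidationError("imputer is not fitted")
        if list(df.columns) != list(self.feature_names_in_):
            raise ValidationError("gene set/order differs from the fitted matrix")

    def predict_full(self, X) -> pd.DataFrame:
        """Raw-space network predictions for every imputable-gene entry.

        Diagnostic view: unlike :meth:`transform` this returns predictions
        for all entries (non-imputable genes keep their input values).
        """
        df, _ = _as_dataframe(X)
        self._check_genes(df)
        L = np.log1p(df.to_numpy(dtype=np.float64))
        out = df.to_numpy(dtype=np.float64).copy()
        gene_pos = {g: j for j, g in enumerate(df.columns)}
        for plan, net in zip(self.plans_, self.networks_):
            p_idx = np.array([gene_pos[g] for g in plan.predictors])
            t_idx = np.array([gene_pos[g] for g in plan.targets])
            pred_log = net.predict(L[:, p_idx].astype(np.float32))
            out[:, t_idx] = np.clip(np.expm1(pred_log.astype(np.float64)), 0.0, None)
        return pd.DataFrame(out, index=df.index, columns=df.columns)

    def transform(self, X):
        """Fill zero entries of imputable genes; preserve everything else.

        Returns the same container type as the input (DataFrame in,
        DataFrame out; array in, array out).
        """
        df, was_df = _as_dataframe(X)
        self._check_genes(df)
        raw = df.to_numpy(dtype=np.float64)
        if np.any(raw < 0):
            raise ValidationError("negative values in matrix to impute")
        out = raw.copy()
        L = np.log1p(raw)
        gene_pos = {g: j for j, g in enumerate(df.columns)}
        for plan, net in zip(self.plans_, self.networks_):
            p_idx = np.array([gene_pos[g] for g in plan.predictors])
            t_idx = np.array([gene_pos[g] for g in plan.targets])
            pred_log = net.predict(L[:, p_idx].astype(np.float32))
            pred_raw = np.clip(np.expm1(pred_log.astype(np.float64)), 0.0, None)
            block = out[:, t_idx]
            zeros = block == 0.0
            block[zeros] = pred_raw[zeros]
            out[:, t_idx] = block
        if isinstance(X, ExpressionMatrix):
            return ExpressionMatrix(
                out, cell_ids=list(X.cell_ids), gene_ids=list(X.gene_ids), space="raw"
            )
        if was_df:
            return pd.DataFrame(out, index=df.index, columns=df.columns)
        return out

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X)


# -- thin functional wrappers over the estimator -----------------------------

def fit(matrix: ExpressionMatrix, **config) -> DropoutImputer:
    """Train a :class:`DropoutImputer` on an :class:`ExpressionMatrix`."""
    return DropoutImputer(**config).fit(matrix)


def impute(matrix: ExpressionMatrix, model: DropoutImputer) -> ExpressionMatrix:
    """Apply a fitted imputer; fills only zeros of imputable genes."""
    return model.transform(matrix)
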