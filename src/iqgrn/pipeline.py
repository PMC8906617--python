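"""End-to-end inference pipeline as a scikit-learn style estimator.

``GrnInference.fit`` runs impute -> binarize -> density -> hierarchy ->
candidate network -> rule selection on an :class:`ExpressionDataset` (or a
raw matrix plus pseudo-time) and exposes every intermediate as a fitted
attribute.  It composes with sklearn's ``get_params``/``set_params`` and
``clone`` so parameter sweeps can reuse standard tooling.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionDataset
from .preprocess import binarize, expression_density, impute
from .network import build_candidate_network, hierarchy_from_density
from .infer import select_rules

__all__ = ["GrnInference", "infer_grn"]


class GrnInference(BaseEstimator):
    """Infer an executable Boolean GRN from expression plus pseudo-time.

    Parameters
    ----------
    impute_enabled : bool, default True
        Apply graph-diffusion dropout imputation before binarization.
    impute_k : int, default 15
        Neighbourhood size of the imputation cell graph.
    impute_t : int, default 3
        Diffusion steps; 0 disables smoothing even when enabled.
    binarize_method : {"kmeans", "mean"}, default "kmeans"
        Per-gene on/off thresholding rule.
    density_window : int or "auto", default "auto"
        Moving-average window (cells); auto = max(3, n_cells / n_genes).
    sign_threshold : float, default 0.05
        Minimum |Pearson r| to assign an interaction sign (permissive).
    mi_grid : int, default 20
        Histogram resolution of the conditional-resampled MI estimator.
    allow_autoregulation : bool, default True
        Offer a self-activation candidate to genes with < 2 activators.
    agreement_cutoff : float, default 80.0
        Minimum teacher-forced agreement (percent) for a rule to compete.
    lag : int, default 1
        Prediction lag (cells) of the agreement score.
    relaxed : bool, default False
        Also try the opposite combinator within each regulator group.

    Attributes
    ----------
    imputed_ : ExpressionDataset
    binarized_ : BinarizedDataset
    density_ : DensityProfile
    hierarchy_ : GeneHierarchy
    candidate_network_ : CandidateNetwork
    model_ : GrnModel
    """

    def __init__(self, impute_enabled: bool = True, impute_k: int = 15,
                 impute_t: int = 3, binarize_method: str = "kmeans",
                 density_window="auto", sign_threshold: float = 0.05,
                 mi_grid: int = 20, allow_autoregulation: bool = True,
                 agreement_cutoff: float = 80.0, lag: int = 1,
                 relaxed: bool = False):
        self.impute_enabled = impute_enabled
        self.impute_k = impute_k
        self.impute_t = impute_t
        self.binarize_method = binarize_method
        self.density_window = density_window
        self.sign_threshold = sign_threshold
        self.mi_grid = mi_grid
        self.allow_autoregulation = allow_autoregulation
        self.agreement_cutoff = agreement_cutoff
        self.lag = lag
        self.relaxed = relaxed

    def _as_dataset(self, X, pseudotime) -> ExpressionDataset:
        if isinstance(X, ExpressionDataset):
            return X
        X = np.asarray(X, dtype=float)
        if pseudotime is None:
            raise ValueError("pseudotime is required when X is a raw matrix")
        return ExpressionDataset(
            cell_ids=[f"c{i}" for i in range(X.shape[0])],
            gene_ids=[f"g{j}" for j in range(X.shape[1])],
            values=X, pseudotime=np.asarray(pseudotime, dtype=float))

    def fit(self, X, y=None, pseudotime=None):
        data = self._as_dataset(X, pseudotime)
        if self.impute_enabled and self.impute_t > 0:
            k = min(self.impute_k, data.n_cells - 1)
            data = impute(data, k_neighbors=k, diffusion_t=self.impute_t)
        self.imputed_ = data
        self.binarized_ = binarize(data, method=self.binarize_method)
        self.density_ = expression_density(self.binarized_, self.density_window)
        self.hierarchy_ = hierarchy_from_density(self.density_)
        self.candidate_network_ = build_candidate_network(
            data, self.hierarchy_, sign_threshold=self.sign_threshold,
            grid=self.mi_grid, allow_autoregulation=self.allow_autoregulation)
        self.model_ = select_rules(
            self.candidate_network_, self.binarized_,
            agreement_cutoff=self.agreement_cutoff, lag=self.lag,
            relaxed=self.relaxed, provenance={"params": self.get_params()})
        return self

    def predict(self, X=None):
        """Return the inferred executable model (the estimator's output)."""
        check_is_fitted(self, "model_")
        return self.model_


def infer_grn(data: ExpressionDataset, **params):
    """Functional wrapper: fit a :class:`GrnInference` and return the model."""
    est = GrnInference(**params).fit(data)
    return est.model_, est
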