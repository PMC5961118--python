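"""Categorical phenotype prediction by non-negative constrained projection.

The model is deconvolution-style: on the selected marker regions S, each
region's expression is regressed on the disjoint 0/1 level indicators with
no intercept and coefficients constrained non-negative, so the fitted
coefficient matrix beta (|S| x L) holds the per-level mean expression
profile of every region. A new sample's expression vector e over S is then
projected onto the profiles,

    gamma = argmin_{gamma >= 0} || e - beta gamma ||^2 ,

and the sample is assigned the level with the uniquely largest membership
weight gamma_l. When the maximum is tied (within a relative tolerance) or
all weights are zero, the sample is labelled "unassigned": abstention is
preferred over an arbitrary coin flip. gamma is reported raw (not
normalized to sum to 1), together with the projection residual norm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .matrix import ExpressionMatrix
from .phenotypes import PhenotypeTable
from .regions import Region
from .selection import (
    OneVsRestDesign,
    SelectedRegionSet,
    fit_moderated_models,
    select_top_regions,
)

logger = logging.getLogger(__name__)

#: Abstention label emitted when membership weights do not single out a level.
UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# numerical cores (arrays only)
# ---------------------------------------------------------------------------

def fit_nonneg_means(E: np.ndarray, indicators: np.ndarray) -> np.ndarray:
    """Constrained least-squares fit of Eq-style mean profiles.

    Solves, per region r, ``min_{b >= 0} || E_r - D b ||`` where D is the
    n x L indicator design (no intercept). With disjoint 0/1 indicators the
    unconstrained optimum is the per-level mean, so the solution equals the
    clipped per-level means; the constrained formulation is used regardless
    so the contract survives covariate extensions.
    """
    E = np.asarray(E, dtype=float)
    D = np.asarray(indicators, dtype=float)
    coef = np.empty((E.shape[0], D.shape[1]))
    for r in range(E.shape[0]):
        coef[r], _ = nnls(D, E[r])
    return coef


def project_memberships(coef: np.ndarray, E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative projection of each sample (column of E) onto the profiles.

    Returns (gamma, residual) with gamma of shape (n_samples, L) and the
    Euclidean residual norms.
    """
    coef = np.asarray(coef, dtype=float)
    E = np.asarray(E, dtype=float)
    n = E.shape[1]
    gamma = np.empty((n, coef.shape[1]))
    resid = np.empty(n)
    for j in range(n):
        gamma[j], resid[j] = nnls(coef, E[:, j])
    return gamma, resid


def labels_from_memberships(
    gamma: np.ndarray, levels: list[str], tie_tol: float = 1e-8
) -> np.ndarray:
    """Assign each sample the level of its unique maximum weight.

    A sample is "unassigned" when the maximum weight is zero or when two or
    more weights lie within ``tie_tol * max`` of the maximum (floating-point
    maxima are never exactly tied, so the tolerance makes the rule
    operational).
    """
    gamma = np.asarray(gamma, dtype=float)
    out = np.empty(gamma.shape[0], dtype=object)
    for j, row in enumerate(gamma):
        mx = row.max()
        if mx <= 0:
            out[j] = UNASSIGNED
            continue
        near = np.sum(row >= mx - tie_tol * mx)
        out[j] = UNASSIGNED if near > 1 else levels[int(np.argmax(row))]
    return out


# ---------------------------------------------------------------------------
# model object and ExpressionMatrix-level operations
# ---------------------------------------------------------------------------

@dataclass
class CategoricalModel:
    """Fitted constrained mean-expression model on a region set S."""

    phenotype: str
    levels: list[str]
    regions: list[Region]
    coef: np.ndarray                      # |S| x L, entries >= 0
    tie_tol: float = 1e-8
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (len(self.regions), len(self.levels)):
            raise ValueError(
                f"coefficient matrix shape {self.coef.shape} does not match "
                f"{len(self.regions)} regions x {len(self.levels)} levels"
            )
        if np.any(self.coef < 0):
            raise ValueError("coefficients must be non-negative")
        dead = [lev for j, lev in enumerate(self.levels) if not np.any(self.coef[:, j] > 0)]
        if dead:
            warnings.warn(
                f"levels with all-zero mean profiles can never be assigned: {dead}",
                UserWarning,
                stacklevel=2,
            )

    @property
    def zero_regions(self) -> list[Region]:
        """Regions whose mean profile is zero in every level (flagged, kept)."""
        mask = ~np.any(self.coef > 0, axis=1)
        return [r for r, z in zip(self.regions, mask) if z]


@dataclass
class MembershipResult:
    """Per-sample membership weights, residuals and assigned labels."""

    samples: list[str]
    levels: list[str]
    gamma: np.ndarray       # (n_samples, L)
    residual: np.ndarray    # (n_samples,)
    labels: np.ndarray      # object array; level or "unassigned"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.gamma, index=self.samples,
            columns=[f"gamma_{lev}" for lev in self.levels],
        )
        df.insert(0, "predicted", self.labels)
        df["residual"] = self.residual
        df.index.name = "sample"
        return df


def build_predictor(
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    column: str,
    selection: SelectedRegionSet,
    tie_tol: float = 1e-8,
    provenance: dict | None = None,
) -> CategoricalModel:
    """Fit the non-negative mean-expression model on the selected regions."""
    regions = selection.union
    try:
        sub = m.subset_regions(regions)
    except KeyError as exc:
        raise ValueError(f"selected region absent from matrix: {exc}") from exc
    usable = pheno.usable_mask(column)
    values = pheno.values(column)
    levels = pheno.levels(column)
    train_cols = np.flatnonzero(usable)
    for lev in levels:
        n_lev = int(np.sum(values[train_cols] == lev))
        if n_lev < 2:
            raise ValueError(
                f"level {lev!r} has {n_lev} usable training samples (need >= 2)"
            )
    D = np.column_stack([(values[train_cols] == lev).astype(float) for lev in levels])
    E = sub.values[:, train_cols]
    coef = fit_nonneg_means(E, D)
    zero_rows = int(np.sum(~np.any(coef > 0, axis=1)))
    if zero_rows:
        logger.warning("%d selected regions have all-zero mean profiles", zero_rows)
    prov = dict(provenance or {})
    prov.setdefault("n_regions_requested", selection.n_requested)
    prov.setdefault("n_training_samples", len(train_cols))
    prov.setdefault("log2_transformed", bool(m.transformed))
    return CategoricalModel(
        phenotype=column,
        levels=levels,
        regions=regions,
        coef=coef,
        tie_tol=tie_tol,
        provenance=prov,
    )


def extract_data(
    m_new: ExpressionMatrix, model, mode: str = "strict"
) -> ExpressionMatrix:
    """Restrict a new matrix to the model's regions, in model order.

    No re-selection of regions is performed: prediction always uses the
    exact regions the model was built on, which limits overfitting.
    In ``strict`` mode any missing region is an error; ``lenient`` mode
    zero-fills missing rows, warns, and records the count in ``meta``.
    """
    regions = list(model.regions)
    idx = m_new.region_index()
    missing = [r for r in regions if r not in idx]
    if missing and mode == "strict":
        ids = ", ".join(r.id for r in missing[:10])
        raise ValueError(
            f"{len(missing)} model regions missing from new matrix: {ids}"
        )
    if not missing:
        return m_new.subset_regions(regions)
    if mode != "lenient":
        raise ValueError(f"unknown extract mode {mode!r}")
    logger.warning(
        "zero-filling %d model regions absent from the new matrix", len(missing)
    )
    values = np.zeros((len(regions), len(m_new.samples)))
    for i, r in enumerate(regions):
        if r in idx:
            values[i] = m_new.values[idx[r]]
    out = ExpressionMatrix(regions, m_new.samples, values, m_new.transformed)
    out.meta["zero_filled_regions"] = len(missing)
    return out


def project_samples(e: ExpressionMatrix, model: CategoricalModel) -> MembershipResult:
    """Project samples of ``e`` (rows aligned to S) onto the model profiles."""
    if list(e.regions) != list(model.regions):
        raise ValueError(
            "expression rows are not aligned to the model regions; "
            "run extract_data first"
        )
    gamma, resid = project_memberships(model.coef, e.values)
    labels = labels_from_memberships(gamma, model.levels, model.tie_tol)
    return MembershipResult(
        samples=list(e.samples),
        levels=list(model.levels),
        gamma=gamma,
        residual=resid,
        labels=labels,
    )


def assign_labels(result: MembershipResult, tie_tol: float) -> MembershipResult:
    """Re-assign labels under a different tie tolerance (total function)."""
    labels = labels_from_memberships(result.gamma, result.levels, tie_tol)
    return MembershipResult(
        samples=result.samples,
        levels=result.levels,
        gamma=result.gamma,
        residual=result.residual,
        labels=labels,
    )


def predict_pheno(
    m_new: ExpressionMatrix, model: CategoricalModel, mode: str = "strict"
) -> MembershipResult:
    """extract_data -> project_samples -> label assignment on a new dataset.

    A prediction is made for every sample, whether or not a reported value
    exists for it.
    """
    return project_samples(extract_data(m_new, model, mode=mode), model)


@dataclass
class ResubstitutionReport:
    """Predictions on the training data plus the resubstitution error."""

    predicted: pd.Series
    reported: pd.Series
    resubstitution_error: float     # percent
    n_predicted: int                # usable-denominator size

    @property
    def accuracy(self) -> float:
        return 100.0 - self.resubstitution_error


def test_predictor(
    m_train: ExpressionMatrix,
    pheno: PhenotypeTable,
    model: CategoricalModel,
) -> ResubstitutionReport:
    """Resubstitution check: predict the data the model was fit on.

    RE = (1 - correct / predicted) x 100 over samples with a usable
    reported value belonging to the model's levels; unassigned predictions
    count as incorrect.
    """
    result = predict_pheno(m_train, model)
    reported = pd.Series(
        pheno.canonical[model.phenotype].to_numpy(), index=pheno.samples, dtype=object
    )
    predicted = pd.Series(result.labels, index=result.samples, dtype=object)
    usable = pheno.usable_mask(model.phenotype)
    in_model = np.array(
        [v in set(model.levels) for v in reported.to_numpy()], dtype=bool
    )
    denom_mask = usable & in_model
    n_denom = int(denom_mask.sum())
    if n_denom == 0:
        raise ValueError(
            "no samples with usable reported values: resubstitution error undefined"
        )
    correct = int(
        np.sum(predicted.to_numpy()[denom_mask] == reported.to_numpy()[denom_mask])
    )
    re = (1.0 - correct / n_denom) * 100.0
    return ResubstitutionReport(
        predicted=predicted,
        reported=reported,
        resubstitution_error=re,
        n_predicted=n_denom,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class CategoricalPhenotypePredictor(BaseEstimator, ClassifierMixin):
    """Marker-selection + constrained-projection classifier.

    Selects ``n_regions`` discriminating features per class with one-vs-rest
    moderated t-statistics, fits the non-negative per-class mean profile
    matrix on their deduplicated union, and classifies new samples by
    non-negative least-squares projection onto the profiles. Samples whose
    maximum membership weight is tied (within ``tie_tol``, relative) or zero
    receive the abstention label ``"unassigned"``.

    Follows the scikit-learn API: ``X`` is (n_samples, n_features) — the
    transpose of the regions x samples matrices used elsewhere in this
    package.

    Parameters
    ----------
    n_regions : int, default 20
        Markers selected per class before deduplication.
    tie_tol : float, default 1e-8
        Relative tolerance of the unassigned tie rule.

    Attributes
    ----------
    classes_ : ndarray of class labels (sorted).
    feature_indices_ : ndarray of selected feature columns (deduplicated).
    coef_ : ndarray of shape (len(feature_indices_), n_classes)
        Non-negative per-class mean profiles.
    selection_ : SelectedRegionSet over synthetic per-column regions.
    """

    def __init__(self, n_regions: int = 20, tie_tol: float = 1e-8):
        self.n_regions = n_regions
        self.tie_tol = tie_tol

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent numbers of samples")
        usable = np.array(
            [v is not None and v == v and str(v) != "" for v in y], dtype=bool
        )
        classes = np.unique(y[usable].astype(str))
        if classes.size < 2:
            raise ValueError("need at least 2 classes with usable labels")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]

        regions = [Region("feature", i, i + 1) for i in range(X.shape[1])]
        samples = [f"s{i}" for i in range(X.shape[0])]
        em = ExpressionMatrix(regions, samples, X.T, transformed=True)
        usable_samples = [s for s, u in zip(samples, usable) if u]
        y_usable = y[usable].astype(str)

        fits = {}
        for cls in classes:
            design = OneVsRestDesign(
                level=str(cls),
                samples=usable_samples,
                indicator=(y_usable == cls).astype(float),
            )
            fits[str(cls)] = fit_moderated_models(em, design)
        self.selection_ = select_top_regions(fits, self.n_regions)
        self.feature_indices_ = np.array(
            [r.start for r in self.selection_.union], dtype=int
        )
        D = np.column_stack([(y_usable == cls).astype(float) for cls in classes])
        E = X[np.flatnonzero(usable)][:, self.feature_indices_].T
        self.coef_ = fit_nonneg_means(E, D)
        return self

    def predict_membership(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Membership weights gamma and projection residuals for ``X``."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return project_memberships(self.coef_, X[:, self.feature_indices_].T)

    def predict(self, X) -> np.ndarray:
        gamma, _ = self.predict_membership(X)
        return labels_from_memberships(gamma, list(self.classes_), self.tie_tol)

    def score(self, X, y, sample_weight=None) -> float:
        """Fraction of usable labels predicted exactly (abstention counts wrong)."""
        y = np.asarray(y, dtype=object)
        usable = np.array(
            [v is not None and v == v and str(v) != "" for v in y], dtype=bool
        )
        if not usable.any():
            raise ValueError("no usable labels to score against")
        pred = self.predict(X)
        return float(np.mean(pred[usable] == y[usable].astype(str)))
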