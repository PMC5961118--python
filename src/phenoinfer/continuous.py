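"""Continuous phenotype prediction via per-region natural spline expansions.

Region selection mirrors the categorical path but swaps the 0/1 indicator
for a natural cubic spline basis of the phenotype: expression at each
region is regressed on the spline terms, variances are moderated, and
regions are ranked by the moderated F-statistic over the spline
coefficients (a joint, two-sided notion of association that captures
nonlinear trends).

The predictor itself inverts the direction: the phenotype is regressed,
in one joint least-squares fit, on the concatenated spline expansions of
the selected regions' expression,

    E[P | {E_r}] = sum_{r in S, l} beta_rl s_l(E_r),

with per-region knots derived from that region's *training* expression
(and frozen thereafter — re-deriving knots on new data would silently
change the model). The cardinal bases of different regions each span
constants, so the joint design is rank deficient by construction; collinear
columns are pruned by pivoted QR and recorded. Accuracy is summarized by
RMSE and the squared Pearson correlation R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .matrix import ExpressionMatrix
from .moderation import (
    moderated_f_pvalues,
    prior_from_moments,
    log_variance_moments,
    squeeze_variances,
)
from .regions import Region
from .selection import SelectedRegionSet
from .splines import SplineBasis, make_spline_basis

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# array-level cores
# ---------------------------------------------------------------------------

def continuous_association_stats(
    E: np.ndarray, y: np.ndarray, n_basis: int = 5
) -> pd.DataFrame:
    """Moderated F of each region's expression on the spline basis of y.

    ``E`` is regions x samples. Returns a frame with columns F, p, s2 and
    the residual df used, in region order.
    """
    E = np.asarray(E, dtype=float)
    y = np.asarray(y, dtype=float)
    basis = make_spline_basis(y, n_basis)
    B = basis.evaluate(y)
    # the cardinal columns sum to 1, so drop one and add an explicit intercept
    X = np.column_stack([np.ones_like(y), B[:, 1:]])
    n, p_cols = X.shape
    if n < p_cols + 1:
        raise ValueError(
            f"need at least {p_cols + 1} samples for residual df >= 1, got {n}"
        )
    k = p_cols - 1  # spline df tested jointly
    Q, _ = np.linalg.qr(X)
    fitted = (E @ Q) @ Q.T
    resid = E - fitted
    rss1 = np.einsum("ij,ij->i", resid, resid)
    centered = E - E.mean(axis=1, keepdims=True)
    rss0 = np.einsum("ij,ij->i", centered, centered)
    df = float(n - p_cols)
    s2 = np.maximum(rss1 / df, 0.0)
    zero_var = np.var(E, axis=1) == 0.0
    s2 = np.where(zero_var, 0.0, s2)
    prior = prior_from_moments(log_variance_moments(s2, df))
    s2_post, _ = squeeze_variances(s2, df, prior=prior)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.maximum(rss0 - rss1, 0.0) / k / s2_post
    F = np.where(zero_var | ~np.isfinite(F), 0.0, F)
    p = moderated_f_pvalues(F, k, df, prior.df)
    p = np.where(zero_var, 1.0, p)
    return pd.DataFrame({"F": F, "p": p, "s2": s2, "df": df, "zero_variance": zero_var})


def _rank_by_f(stats: pd.DataFrame) -> list[int]:
    p = stats["p"].to_numpy()
    F = stats["F"].to_numpy()
    return sorted(range(len(p)), key=lambda i: (p[i], -F[i], i))


def joint_spline_fit(
    E_sel: np.ndarray, y: np.ndarray, n_basis: int = 5
) -> tuple[list[SplineBasis], np.ndarray, list[int], np.ndarray]:
    """One joint least-squares fit of y on all per-region spline expansions.

    Returns (bases, coef, pruned_columns, fitted). ``coef`` is laid out as
    ``n_regions x n_basis`` flattened row-major, zero-padded where a
    region's basis was reduced or a column was pruned as collinear.
    """
    E_sel = np.asarray(E_sel, dtype=float)
    y = np.asarray(y, dtype=float)
    n_regions, n = E_sel.shape
    if n_regions * n_basis > n:
        raise ValueError(
            f"{n_regions} regions x {n_basis} basis functions = "
            f"{n_regions * n_basis} coefficients exceed {n} samples; "
            "select fewer regions"
        )
    bases = [make_spline_basis(E_sel[r], n_basis) for r in range(n_regions)]
    cols = []
    col_map = []  # flat (padded) column index of each real design column
    for r, basis in enumerate(bases):
        block = basis.evaluate(E_sel[r])
        for j in range(basis.n_basis):
            cols.append(block[:, j])
            col_map.append(r * n_basis + j)
    A = np.column_stack(cols)

    Q, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(A.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    dropped = sorted(set(range(A.shape[1])) - set(keep.tolist()))
    if dropped:
        logger.info("pruned %d collinear spline columns", len(dropped))
    coef_kept, *_ = np.linalg.lstsq(A[:, keep], y, rcond=None)
    coef = np.zeros(n_regions * n_basis)
    for c, value in zip(keep, coef_kept):
        coef[col_map[c]] = value
    fitted = A[:, keep] @ coef_kept
    pruned = [col_map[c] for c in dropped]
    return bases, coef, pruned, fitted


def evaluate_spline_design(
    bases: list[SplineBasis], E_sel: np.ndarray, n_basis: int
) -> tuple[np.ndarray, np.ndarray]:
    """Padded design matrix of shape (n_samples, n_regions * n_basis).

    Also returns a per-sample flag marking values beyond any region's
    boundary knots (linear-tail extrapolation).
    """
    E_sel = np.asarray(E_sel, dtype=float)
    n_regions, n = E_sel.shape
    A = np.zeros((n, n_regions * n_basis))
    extrapolated = np.zeros(n, dtype=bool)
    for r, basis in enumerate(bases):
        block = basis.evaluate(E_sel[r])
        A[:, r * n_basis : r * n_basis + basis.n_basis] = block
        extrapolated |= ~basis.in_range(E_sel[r])
    return A, extrapolated


def squared_correlation(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """R^2 as the squared Pearson correlation of observed vs predicted."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2 or np.std(y_true) == 0 or np.std(y_pred) == 0:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# model object and ExpressionMatrix-level operations
# ---------------------------------------------------------------------------

@dataclass
class ContinuousModel:
    """Joint spline regression of a continuous phenotype on region set S."""

    phenotype: str
    regions: list[Region]
    n_basis: int
    knots: list[np.ndarray]
    coef: np.ndarray                 # flat, n_regions * n_basis, zero-padded
    pruned_columns: list[int] = field(default_factory=list)
    training_rmse: float | None = None
    training_r2: float | None = None
    provenance: dict = field(default_factory=dict)

    def bases(self) -> list[SplineBasis]:
        return [SplineBasis(k) for k in self.knots]


@dataclass
class ContinuousPrediction:
    """Predicted values with extrapolation flags and optional accuracy."""

    samples: list[str]
    predicted: np.ndarray
    extrapolated: np.ndarray
    reported: np.ndarray | None = None
    rmse: float | None = None
    r2: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"predicted": self.predicted, "extrapolated": self.extrapolated},
            index=self.samples,
        )
        if self.reported is not None:
            df["reported"] = self.reported
        df.index.name = "sample"
        return df


def select_regions_continuous(
    m: ExpressionMatrix, y: np.ndarray, n: int, n_basis: int = 5, phenotype: str = ""
) -> SelectedRegionSet:
    """Rank regions by moderated F against the spline basis of y; take top n."""
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 20:
        raise ValueError(f"need >= 20 usable phenotype values, got {int(ok.sum())}")
    stats = continuous_association_stats(m.values[:, ok], y[ok], n_basis)
    order = _rank_by_f(stats)
    usable = [i for i in order if not stats["zero_variance"].iloc[i]]
    top = usable[: min(n, len(usable))]
    regions = [m.regions[i] for i in top]
    rows = [
        {
            "region_id": m.regions[i].id,
            "chrom": m.regions[i].chrom,
            "start": m.regions[i].start,
            "end": m.regions[i].end,
            "level": "spline",
            "F": stats["F"].iloc[i],
            "p": stats["p"].iloc[i],
            "rank": rank + 1,
        }
        for rank, i in enumerate(top)
    ]
    return SelectedRegionSet(
        phenotype=phenotype,
        levels=["spline"],
        n_requested=n,
        per_level={"spline": regions},
        stats=pd.DataFrame(rows),
    )


def build_continuous_predictor(
    m: ExpressionMatrix,
    y: np.ndarray,
    selection: SelectedRegionSet,
    n_basis: int = 5,
    phenotype: str = "",
    provenance: dict | None = None,
) -> ContinuousModel:
    """Fit the joint spline regression on the selected regions."""
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    regions = selection.union
    sub = m.subset_regions(regions)
    E = sub.values[:, ok]
    bases, coef, pruned, fitted = joint_spline_fit(E, y[ok], n_basis)
    rmse = float(np.sqrt(np.mean((y[ok] - fitted) ** 2)))
    r2 = squared_correlation(y[ok], fitted)
    prov = dict(provenance or {})
    prov.setdefault("n_training_samples", int(ok.sum()))
    prov.setdefault("basis", "cardinal-natural-spline")
    prov.setdefault("knots_per_region", n_basis)
    return ContinuousModel(
        phenotype=phenotype or selection.phenotype,
        regions=regions,
        n_basis=n_basis,
        knots=[b.knots for b in bases],
        coef=coef,
        pruned_columns=pruned,
        training_rmse=rmse,
        training_r2=r2,
        provenance=prov,
    )


def predict_continuous(
    m_new: ExpressionMatrix,
    model: ContinuousModel,
    y_reported: np.ndarray | None = None,
    mode: str = "strict",
) -> ContinuousPrediction:
    """Evaluate the model on new samples using the frozen training knots."""
    from .categorical import extract_data

    sub = extract_data(m_new, model, mode=mode)
    A, extrapolated = evaluate_spline_design(model.bases(), sub.values, model.n_basis)
    predicted = A @ model.coef
    reported = None
    rmse = r2 = None
    if y_reported is not None:
        reported = np.asarray(y_reported, dtype=float)
        ok = np.isfinite(reported)
        if ok.any():
            rmse = float(np.sqrt(np.mean((reported[ok] - predicted[ok]) ** 2)))
            r2 = squared_correlation(reported[ok], predicted[ok])
    return ContinuousPrediction(
        samples=list(sub.samples),
        predicted=predicted,
        extrapolated=extrapolated,
        reported=reported,
        rmse=rmse,
        r2=r2,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class ContinuousPhenotypePredictor(BaseEstimator, RegressorMixin):
    """Spline-on-expression regressor with moderated-F feature selection.

    Selects ``n_regions`` features whose expression tracks the target's
    spline basis, then fits the target on the concatenated per-feature
    natural-spline expansions (knots from training expression, frozen).

    Parameters
    ----------
    n_regions : int, default 100
        Features selected by moderated F. Must satisfy
        ``n_regions * n_basis <= n_samples``.
    n_basis : int, default 5
        Knots (= cardinal basis functions) per feature.

    Attributes
    ----------
    feature_indices_ : selected feature columns, in rank order.
    bases_ : per-feature SplineBasis.
    coef_ : flat coefficient vector (zero-padded over pruned columns).
    pruned_columns_ : flat design columns removed as collinear.
    training_rmse_, training_r2_ : training-set summary.
    """

    def __init__(self, n_regions: int = 100, n_basis: int = 5):
        self.n_regions = n_regions
        self.n_basis = n_basis

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 20:
            raise ValueError(f"need >= 20 finite targets, got {int(ok.sum())}")
        self.n_features_in_ = X.shape[1]
        E = X[ok].T
        stats = continuous_association_stats(E, y[ok], self.n_basis)
        order = _rank_by_f(stats)
        usable = [i for i in order if not stats["zero_variance"].iloc[i]]
        self.feature_indices_ = np.asarray(usable[: self.n_regions], dtype=int)
        self.selection_stats_ = stats
        bases, coef, pruned, fitted = joint_spline_fit(
            E[self.feature_indices_], y[ok], self.n_basis
        )
        self.bases_ = bases
        self.coef_ = coef
        self.pruned_columns_ = pruned
        self.training_rmse_ = float(np.sqrt(np.mean((y[ok] - fitted) ** 2)))
        self.training_r2_ = squared_correlation(y[ok], fitted)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        A, self.extrapolated_ = evaluate_spline_design(
            self.bases_, X[:, self.feature_indices_].T, self.n_basis
        )
        return A @ self.coef_
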