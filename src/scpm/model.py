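"""Seed connectome-based predictive modeling (sCPM).

The model predicts a per-participant subjective outcome (e.g. stressor-induced
change in rated stress) from seed-based functional connectivity features.
Within each cross-validation fold, clusters whose connectivity correlates with
the outcome across training participants (Spearman, two-sided p below a
threshold) are split by correlation sign into a *positive* and a *negative*
network.  Each network is summarized by its mean connectivity ("network
strength") and a univariate ordinary-least-squares line relates strength to
outcome; the fitted lines predict the held-out participants.  Predictive power
is the Spearman correlation r_s between predicted and observed outcomes, and
its significance is assessed nonparametrically against models refit on
shuffled outcomes.

`SCPMRegressor` exposes one fold's worth of this as a scikit-learn estimator;
`cross_validate` / `permutation_pvalue` build the full leave-one-out or k-fold
analysis on top of it.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold, LeaveOneOut
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

SEEDS = ("full", "aHPC", "pHPC")
WINDOWS = ("all", "early")
REFERENCES = ("S-B", "(S-B)-(N-B)")


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def _rank_corr(rank_x: np.ndarray, rank_y: np.ndarray) -> np.ndarray:
    """Pearson correlation of rank matrices via exact integer sums.

    ``rank_x`` is (n, C) column ranks, ``rank_y`` (P, n) row ranks (average
    ties, so multiples of 1/2).  Doubling makes every intermediate sum an
    exactly representable integer, which keeps results bit-identical across
    differently-shaped calls (single outcome vs permutation batches) — the
    largest-drop fallback compares successive gaps and must not depend on
    floating-point summation order.
    """
    A = 2.0 * np.asarray(rank_x, dtype=float)
    B = 2.0 * np.asarray(rank_y, dtype=float)
    n = A.shape[0]
    sxy = B @ A                                   # (P, C), exact
    sa = A.sum(axis=0)
    sb = B.sum(axis=1)
    va = n * (A ** 2).sum(axis=0) - sa ** 2       # (C,)
    vb = n * (B ** 2).sum(axis=1) - sb ** 2       # (P,)
    num = n * sxy - sb[:, None] * sa[None, :]
    den = np.sqrt(vb[:, None] * va[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    return np.clip(r, -1.0, 1.0)


def spearman_rp(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise Spearman correlation of ``X`` (n, p) with ``y`` (n,).

    Returns ``(r, p)`` arrays of length p.  p-values use the t approximation
    (as :func:`scipy.stats.spearmanr` does for n > 2).  Constant columns
    yield NaN in both outputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    rx = stats.rankdata(X, axis=0)
    ry = stats.rankdata(y)
    r = _rank_corr(rx, ry[None, :])[0]
    p = _t_pvalue(r, n)
    return r, p


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a correlation via the t distribution with n-2 df."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(np.isnan(r), np.nan, p)


def predictive_power(predicted, observed) -> float:
    """Spearman r_s between model-predicted and observed outcomes.

    Ties receive average ranks.  Raises if either vector is constant
    (the correlation is undefined there).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValueError("predicted/observed must be equal-length vectors of size >= 3")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ValueError("predictive power undefined for a constant vector")
    r = _rank_corr(stats.rankdata(predicted)[:, None],
                   stats.rankdata(observed)[None, :])
    return float(r[0, 0])


def partial_spearman(x, y, covariates=None) -> tuple[float, float]:
    """Partial Spearman correlation of ``x`` and ``y`` given ``covariates``.

    All variables are rank-transformed (average ties); ``x`` and ``y`` ranks
    are residualized on an intercept plus the covariate ranks by OLS, and the
    Pearson correlation of the residuals is returned with a t-based two-sided
    p-value at ``n - 2 - k`` degrees of freedom.  With no covariates this is
    the plain Spearman r_s.  Collinear covariate columns are dropped with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        covariates = np.empty((n, 0))
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    k = Z.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} observations for {k} covariates")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    D = np.column_stack([np.ones(n)] + [stats.rankdata(Z[:, j]) for j in range(k)])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        warnings.warn("collinear covariates dropped in partial_spearman")
        # keep a maximal independent subset of columns (intercept always kept)
        keep = [0]
        for j in range(1, D.shape[1]):
            if np.linalg.matrix_rank(D[:, keep + [j]]) > len(keep):
                keep.append(j)
        D = D[:, keep]
        k = D.shape[1] - 1
    ex = rx - D @ np.linalg.lstsq(D, rx, rcond=None)[0]
    ey = ry - D @ np.linalg.lstsq(D, ry, rcond=None)[0]
    # a variable lying in the covariate span leaves only rounding noise
    for e, orig in ((ex, rx), (ey, ry)):
        if (e ** 2).sum() <= 1e-20 * ((orig - orig.mean()) ** 2).sum():
            return 0.0, 1.0
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    if denom == 0:
        return 0.0, 1.0
    r = float(np.clip(ex @ ey / denom, -1, 1))
    df = n - 2 - k
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / max(1.0 - r ** 2, np.finfo(float).tiny))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def largest_drop_select(correlations) -> np.ndarray:
    """Fallback selection: keep the clusters above the largest gap in |r_s|.

    Correlations are ranked by absolute value, strongest first; the gap
    between each pair of successive coefficients is computed and all clusters
    above the largest gap are kept.  When every gap ties (e.g. all |r_s|
    equal) only the single strongest cluster is kept.  Returns selected
    column indices.  NaN correlations (constant columns) are never selected.
    """
    r = np.asarray(correlations, dtype=float)
    valid = np.flatnonzero(np.isfinite(r))
    if valid.size == 0:
        raise ValueError("no defined correlations to select from")
    if valid.size == 1:
        return valid
    order = valid[np.argsort(-np.abs(r[valid]), kind="stable")]
    mags = np.abs(r[order])
    gaps = mags[:-1] - mags[1:]
    n_keep = int(np.argmax(gaps)) + 1
    return np.sort(order[:n_keep])


def spearman_select(X, y, p_thresh: float = 0.05, fallback: bool = True
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Select positive/negative network columns by Spearman correlation.

    Columns with two-sided p < ``p_thresh`` join the positive network when
    r_s > 0 and the negative network when r_s < 0.  If *neither* network
    receives a column (as happens under shuffled outcomes) and ``fallback``
    is set, :func:`largest_drop_select` is applied instead and its selection
    partitioned by sign.  Constant columns are skipped with a log message.
    Returns ``(pos_ids, neg_ids)`` as sorted index arrays.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 training rows")
    r, p = spearman_rp(X, y)
    n_const = int(np.isnan(r).sum())
    if n_const:
        logger.info("spearman_select: skipped %d constant column(s)", n_const)
    with np.errstate(invalid="ignore"):
        hit = p < p_thresh
    pos = np.flatnonzero(hit & (r > 0))
    neg = np.flatnonzero(hit & (r < 0))
    if pos.size == 0 and neg.size == 0 and fallback:
        sel = largest_drop_select(r)
        pos = sel[r[sel] > 0]
        neg = sel[r[sel] < 0]
    return pos, neg


def network_strength(row, ids) -> float:
    """Mean feature value over the clusters of one network for one row."""
    ids = np.asarray(ids, dtype=int)
    if ids.size == 0:
        raise ValueError("network is empty: model non-predictive for this network")
    return float(np.mean(np.asarray(row, dtype=float)[ids]))


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class SCPMRegressor(BaseEstimator, RegressorMixin):
    """One seed-CPM model: select networks on the training set, fit linear
    network-strength models, predict new participants.

    Parameters
    ----------
    p_thresh : float
        Two-sided Spearman selection threshold.
    network : {"positive", "negative", "combined"}
        Which prediction :meth:`predict` returns.  "combined" fits a single
        OLS on both network strengths (when both exist).
    fallback : bool
        Use the largest-drop rule when no cluster passes ``p_thresh``.

    Attributes
    ----------
    pos_ids_, neg_ids_ : ndarray of int
        Selected cluster column indices per network.
    coef_ : dict
        Per-network ``(intercept, slope)`` (or intercept + two slopes for
        "combined").  A network with no clusters maps to ``None`` and its
        prediction falls back to the training-outcome mean.
    """

    def __init__(self, p_thresh: float = 0.05, network: str = "positive",
                 fallback: bool = True):
        self.p_thresh = p_thresh
        self.network = network
        self.fallback = fallback

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D and aligned with y")
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in inputs")
        if not 0 < self.p_thresh <= 1:
            raise ValueError("p_thresh must be in (0, 1]")
        if self.network not in ("positive", "negative", "combined"):
            raise ValueError(f"unknown network {self.network!r}")
        self.pos_ids_, self.neg_ids_ = spearman_select(
            X, y, self.p_thresh, fallback=self.fallback)
        self.y_mean_ = float(y.mean())
        self.n_features_in_ = X.shape[1]
        self.coef_ = {
            "positive": _fit_line(X, y, self.pos_ids_),
            "negative": _fit_line(X, y, self.neg_ids_),
        }
        if self.pos_ids_.size and self.neg_ids_.size:
            S = np.column_stack([X[:, self.pos_ids_].mean(axis=1),
                                 X[:, self.neg_ids_].mean(axis=1)])
            D = np.column_stack([np.ones(len(y)), S])
            self.coef_["combined"] = tuple(np.linalg.lstsq(D, y, rcond=None)[0])
        else:
            self.coef_["combined"] = None
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return self._predict_network(X, self.network)

    def _predict_network(self, X, network: str) -> np.ndarray:
        coefs = self.coef_[network]
        if coefs is None:
            # empty network: non-predictive, fall back to the training mean
            return np.full(X.shape[0], self.y_mean_)
        if network == "combined":
            b0, b1, b2 = coefs
            return (b0 + b1 * X[:, self.pos_ids_].mean(axis=1)
                    + b2 * X[:, self.neg_ids_].mean(axis=1))
        b0, b1 = coefs
        ids = self.pos_ids_ if network == "positive" else self.neg_ids_
        return b0 + b1 * X[:, ids].mean(axis=1)


def _fit_line(X, y, ids):
    """OLS of y on the mean of the selected columns; None if none selected."""
    if len(ids) == 0:
        return None
    s = X[:, ids].mean(axis=1)
    sc = s - s.mean()
    denom = (sc ** 2).sum()
    slope = 0.0 if denom == 0 else float(sc @ (y - y.mean()) / denom)
    return float(y.mean() - slope * s.mean()), slope


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """Selection and per-network model of one cross-validation fold."""
    test_index: np.ndarray
    pos_ids: np.ndarray
    neg_ids: np.ndarray
    coef: dict
    predicted: dict  # network -> array over test rows


@dataclass
class SCPMResult:
    """Cross-validated sCPM predictions and (optional) permutation inference."""
    folds: list[FoldResult]
    predicted: dict           # network -> (n,) predicted vector
    observed: np.ndarray
    r_s: dict                 # network -> Spearman predictive power
    everyfold_pos: np.ndarray
    everyfold_neg: np.ndarray
    scheme: str
    seed: int | None = None
    null: dict = field(default_factory=dict)     # network -> (n_perm,) null r_s
    p_value: dict = field(default_factory=dict)  # network -> permutation p
    participant_ids: list | None = None

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "observed": self.observed.tolist(),
            "predicted": {k: v.tolist() for k, v in self.predicted.items()},
            "r_s": self.r_s,
            "p_value": self.p_value,
            "everyfold_pos": self.everyfold_pos.tolist(),
            "everyfold_neg": self.everyfold_neg.tolist(),
            "folds": [
                {"test_index": f.test_index.tolist(),
                 "pos_ids": f.pos_ids.tolist(), "neg_ids": f.neg_ids.tolist()}
                for f in self.folds
            ],
            "participant_ids": self.participant_ids,
        }


def _make_folds(n: int, scheme: str, n_splits: int, seed):
    if scheme == "loo":
        return list(LeaveOneOut().split(np.arange(n))), "loo"
    if scheme == "kfold":
        kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return list(kf.split(np.arange(n))), f"kfold{n_splits}"
    raise ValueError(f"unknown CV scheme {scheme!r}")


def _safe_spearman(pred: np.ndarray, obs: np.ndarray) -> float:
    """r_s with the convention that a constant predicted vector scores 0."""
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return 0.0
    return float(stats.spearmanr(pred, obs).statistic)


def cross_validate(features, outcome, scheme: str = "loo", n_splits: int = 10,
                   p_thresh: float = 0.05, seed: int | None = None,
                   fallback: bool = True) -> SCPMResult:
    """Full cross-validated sCPM analysis.

    ``features`` may be a DataFrame (rows = participants, columns = clusters)
    or an (n, p) array; ``outcome`` a Series or vector aligned to it.  Folds
    are leave-one-out or shuffled k-fold (seeded).  Within each fold, networks
    are selected and fit on training rows only and the held-out rows are
    predicted; ``everyfold_pos``/``everyfold_neg`` are the cluster indices
    selected in every fold.
    """
    pids = None
    if isinstance(features, pd.DataFrame):
        if isinstance(outcome, pd.Series):
            if not features.index.equals(outcome.index):
                raise ValueError("feature and outcome participant ids misaligned")
        pids = list(features.index)
        columns = list(features.columns)
    else:
        columns = None
    X = np.asarray(features, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    folds, scheme_name = _make_folds(n, scheme, n_splits, seed)

    fold_results = []
    predicted = {k: np.empty(n) for k in ("positive", "negative", "combined")}
    for train, test in folds:
        if train.size == 0:
            raise ValueError("fold with empty training set")
        est = SCPMRegressor(p_thresh=p_thresh, fallback=fallback).fit(X[train], y[train])
        preds = {net: est._predict_network(X[test], net)
                 for net in ("positive", "negative", "combined")}
        for net in preds:
            predicted[net][test] = preds[net]
        fold_results.append(FoldResult(test_index=test, pos_ids=est.pos_ids_,
                                       neg_ids=est.neg_ids_, coef=est.coef_,
                                       predicted=preds))
    everyfold_pos = _intersect_all([f.pos_ids for f in fold_results], X.shape[1])
    everyfold_neg = _intersect_all([f.neg_ids for f in fold_results], X.shape[1])
    r_s = {net: _safe_spearman(predicted[net], y) for net in predicted}
    return SCPMResult(folds=fold_results, predicted=predicted, observed=y,
                      r_s=r_s, everyfold_pos=everyfold_pos,
                      everyfold_neg=everyfold_neg, scheme=scheme_name,
                      seed=seed, participant_ids=pids)


def _intersect_all(id_lists, n_cols: int) -> np.ndarray:
    mask = np.ones(n_cols, dtype=bool)
    for ids in id_lists:
        m = np.zeros(n_cols, dtype=bool)
        m[ids] = True
        mask &= m
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# vectorized batch engine (used for permutation nulls)
# ---------------------------------------------------------------------------

def _batch_cv(X: np.ndarray, Y: np.ndarray, folds, p_thresh: float = 0.05):
    """Run the fold loop for many outcome vectors at once.

    ``Y`` is (P, n): each row is one outcome vector (e.g. one permutation).
    Returns ``(pred, sel_pos, sel_neg)`` where ``pred`` maps network name to a
    (P, n) prediction matrix and ``sel_*`` are (P, n_folds, n_clusters)
    boolean selection masks.  Selection, fitting, and prediction are exactly
    the per-fold procedure of :func:`cross_validate`, vectorized across the P
    outcome rows (ranked-matrix products for the Spearman screen, closed-form
    univariate OLS for the network lines).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    P, n = Y.shape
    C = X.shape[1]
    nf = len(folds)
    pred = {k: np.empty((P, n)) for k in ("positive", "negative")}
    sel_pos = np.zeros((P, nf, C), dtype=bool)
    sel_neg = np.zeros((P, nf, C), dtype=bool)

    for fi, (train, test) in enumerate(folds):
        Xtr = X[train]
        ntr = train.size
        rx = stats.rankdata(Xtr, axis=0)
        Ytr = Y[:, train]
        ry = stats.rankdata(Ytr, axis=1)
        R = _rank_corr(rx, ry)                   # (P, C)
        pv = _t_pvalue(R, ntr)
        with np.errstate(invalid="ignore"):
            hit = pv < p_thresh
        pos = hit & (R > 0)
        neg = hit & (R < 0)
        need_fb = ~(pos.any(axis=1) | neg.any(axis=1))
        for i in np.flatnonzero(need_fb):
            sel = largest_drop_select(R[i])
            pos[i, sel[R[i, sel] > 0]] = True
            neg[i, sel[R[i, sel] < 0]] = True
        sel_pos[:, fi, :] = pos
        sel_neg[:, fi, :] = neg

        ymean = Ytr.mean(axis=1)                 # (P,)
        Yc = Ytr - ymean[:, None]
        for mask, net in ((pos, "positive"), (neg, "negative")):
            cnt = mask.sum(axis=1).astype(float)            # (P,)
            empty = cnt == 0
            cnt_safe = np.where(empty, 1.0, cnt)
            Str = (Xtr @ mask.T) / cnt_safe                 # (ntr, P)
            Ste = (X[test] @ mask.T) / cnt_safe             # (nte, P)
            Sc = Str - Str.mean(axis=0)
            var = (Sc ** 2).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                slope = np.where(var == 0, 0.0, (Sc * Yc.T).sum(axis=0)
                                 / np.where(var == 0, 1.0, var))
            intercept = ymean - slope * Str.mean(axis=0)
            out = intercept[None, :] + slope[None, :] * Ste  # (nte, P)
            out[:, empty] = ymean[empty][None, :]
            pred[net][:, test] = out.T
    return pred, sel_pos, sel_neg


def permutation_pvalue(features, outcome, n_perm: int = 1000,
                       seed: int | None = 0, scheme: str = "loo",
                       n_splits: int = 10, p_thresh: float = 0.05
                       ) -> SCPMResult:
    """Cross-validated sCPM with a shuffled-outcome permutation null.

    The outcome vector is shuffled across participants ``n_perm`` times; the
    complete cross-validation pipeline (selection inside folds, network fits,
    held-out prediction) is re-run per shuffle and the null predictive powers
    r_s stored.  Per network, ``p = (1 + #{null >= observed}) / (1 + n_perm)``
    (add-one estimator, one-sided: a predictive model yields a positive
    predicted-vs-observed correlation for either network).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    result = cross_validate(features, outcome, scheme=scheme, n_splits=n_splits,
                            p_thresh=p_thresh, seed=seed)
    X = np.asarray(features, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    folds, _ = _make_folds(n, scheme, n_splits, seed)
    rng = np.random.default_rng(seed)
    Y = np.stack([y[rng.permutation(n)] for _ in range(n_perm)])
    pred, _, _ = _batch_cv(X, Y, folds, p_thresh=p_thresh)
    for net in ("positive", "negative"):
        null = _rowwise_spearman(pred[net], Y)
        obs = result.r_s[net]
        result.null[net] = null
        result.p_value[net] = float((1 + np.sum(null >= obs)) / (1 + n_perm))
    return result


def _rowwise_spearman(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Spearman r per row pair; constant rows score 0."""
    ra = stats.rankdata(A, axis=1)
    rb = stats.rankdata(B, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    sa = np.sqrt((ra ** 2).sum(axis=1))
    sb = np.sqrt((rb ** 2).sum(axis=1))
    denom = sa * sb
    out = np.zeros(A.shape[0])
    ok = denom > 0
    out[ok] = (ra[ok] * rb[ok]).sum(axis=1) / denom[ok]
    return np.clip(out, -1.0, 1.0)


# ---------------------------------------------------------------------------
# model families and corrections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One member of the sCPM model family for a given outcome."""
    seed: str       # "full" | "aHPC" | "pHPC"
    window: str     # "all" | "early"
    reference: str  # "S-B" | "(S-B)-(N-B)"
    outcome: str


def enumerate_model_specs(outcome: str, seeds=SEEDS, windows=WINDOWS,
                          references=REFERENCES) -> list[ModelSpec]:
    """The factorial family of models trained per subjective outcome:
    3 seeds x 2 windows x 2 reference schemes = 12, in deterministic order."""
    return [ModelSpec(s, w, r, outcome)
            for s, w, r in itertools.product(seeds, windows, references)]


def bonferroni_alpha(family_size: int, fwer: float = 0.05) -> float:
    """Per-model alpha under Bonferroni correction, reported at 4 decimals."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return round(fwer / family_size, 4)


def classify_network_response(mean_changes, network_sign: str,
                              consistency: float = 0.75) -> str:
    """Classify how stressor exposure modulated a predictive network.

    ``mean_changes`` holds the group-mean stressor-vs-neutral connectivity
    change per network cluster.  For a positive network (higher connectivity
    predicts more stress) decreases are *attenuating* and increases
    *amplifying*; for a negative network the mapping is mirrored.  If fewer
    than ``consistency`` of the clusters agree in direction the response is
    *random*.
    """
    changes = np.atleast_1d(np.asarray(mean_changes, dtype=float))
    if network_sign not in ("positive", "negative"):
        raise ValueError("network_sign must be 'positive' or 'negative'")
    if changes.size == 0:
        raise ValueError("no clusters to classify")
    sign = 1.0 if network_sign == "positive" else -1.0
    amplifying = sign * changes > 0
    attenuating = sign * changes < 0
    frac_att = attenuating.mean()
    frac_amp = amplifying.mean()
    if frac_att >= consistency:
        return "attenuating"
    if frac_amp >= consistency:
        return "amplifying"
    return "random"
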