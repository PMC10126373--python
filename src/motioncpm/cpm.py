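"""Connectome-based predictive modeling (CPM) of head motion.

The four CPM steps: (1) *feature selection* — Pearson-correlate every edge
with the motion scores across subjects and keep edges whose two-sided
parametric p falls below ``selection_p``, split by correlation sign into a
positive and a negative mask; (2) *feature summarization* — sum each
subject's selected edge z-values into positive (X) and negative (Y)
network strengths; (3) *model building* — ordinary least squares of the
score on the strengths, Ψ = a + bX + cY (restricted variants fix c = 0 or
b = 0); (4) *assessment* — predict held-out subjects and correlate
observed with predicted scores (Pearson R, Spearman ρ).

Cross-validation is leave-one-out with selection and fitting nested inside
every fold, or twofold (train on one sample, predict the other).
Significance comes from rerunning the complete nested LOO on randomly
permuted scores and locating the observed R in that null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import RunConfig
from .exceptions import (DegenerateDataError, DimensionError, FitError,
                         InvalidResultError, ValidationError)

logger = logging.getLogger(__name__)


@dataclass
class FeatureMasks:
    """Boolean positive/negative edge masks from feature selection."""

    positive: np.ndarray
    negative: np.ndarray
    selection_p: float
    n_subjects: int

    def __post_init__(self) -> None:
        self.positive = np.asarray(self.positive, dtype=bool)
        self.negative = np.asarray(self.negative, dtype=bool)
        if self.positive.shape != self.negative.shape:
            raise DimensionError("mask shapes differ")
        if (self.positive & self.negative).any():
            raise ValidationError("positive and negative masks overlap")

    @property
    def n_edges(self) -> int:
        return self.positive.shape[0]


@dataclass
class CPMModel:
    """Fitted prediction model Ψ = a + bX + cY with its edge masks."""

    variant: str
    a: float
    b: float
    c: float
    masks: FeatureMasks | None = None
    score_name: str = ""
    session_id: str = ""
    n_train: int = 0
    n_nodes: int = 0

    def __post_init__(self) -> None:
        if self.variant == "positive_only" and self.c != 0.0:
            raise ValidationError("positive_only model must have c = 0")
        if self.variant == "negative_only" and self.b != 0.0:
            raise ValidationError("negative_only model must have b = 0")


@dataclass
class PredictionResult:
    """Observed vs predicted scores and their agreement statistics."""

    observed: np.ndarray
    predicted: np.ndarray
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    n: int
    valid: bool = True
    n_degenerate_folds: int = 0


@dataclass
class NullDistribution:
    """Prediction accuracies under random score permutations."""

    accuracies: np.ndarray
    sd: float
    mean: float
    n_skipped: int = 0
    flagged: bool = False

    def empirical_p(self, observed_r: float) -> float:
        """(1 + #{null ≥ observed}) / (n + 1); never exactly zero."""
        acc = self.accuracies
        return float((1 + np.sum(acc >= observed_r)) / (acc.size + 1))


# ---------------------------------------------------------------------------
# feature selection


def edge_correlations(edges: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r of every edge column with the scores (NaN for constant edges)."""
    edges = np.asarray(edges, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    xc = edges - edges.mean(axis=0)
    yc = scores - scores.mean()
    num = yc @ xc
    denx = np.sqrt((xc ** 2).sum(axis=0))
    deny = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / (denx * deny)
    r[denx == 0] = np.nan
    return r


def selection_r_threshold(n: int, selection_p: float) -> float:
    """|r| above which the two-sided parametric p is below ``selection_p``.

    Uses the t-transform of r with n−2 degrees of freedom, so thresholding
    |r| is exactly equivalent to thresholding the parametric p-value.
    """
    tcrit = stats.t.ppf(1.0 - selection_p / 2.0, n - 2)
    return float(tcrit / np.sqrt(tcrit ** 2 + n - 2))


def select_features(edges: np.ndarray, scores: np.ndarray,
                    selection_p: float = 0.01) -> FeatureMasks:
    """Select edges significantly correlated with the motion scores.

    Positive mask: parametric two-sided p < ``selection_p`` and r > 0;
    negative mask: p < ``selection_p`` and r < 0.  Constant edge columns
    (r undefined) are excluded from both masks and counted in a log
    message.
    """
    edges = np.asarray(edges, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if edges.ndim != 2 or edges.shape[0] != scores.shape[0]:
        raise DimensionError("edges must be (n_subjects, n_edges) aligned "
                             "with scores")
    n = scores.shape[0]
    if n < 4:
        raise ValidationError("feature selection needs at least 4 subjects")
    if np.ptp(scores) == 0:
        raise DegenerateDataError("scores are constant; selection undefined")
    r = edge_correlations(edges, scores)
    n_constant = int(np.isnan(r).sum())
    if n_constant:
        logger.info("select_features: %d constant edge columns excluded",
                    n_constant)
    rcrit = selection_r_threshold(n, selection_p)
    with np.errstate(invalid="ignore"):
        positive = r > rcrit
        negative = r < -rcrit
    return FeatureMasks(positive=positive, negative=negative,
                        selection_p=selection_p, n_subjects=n)


# ---------------------------------------------------------------------------
# strengths and model


def network_strengths(edge_vector: np.ndarray,
                      masks: FeatureMasks) -> tuple[float, float]:
    """Positive and negative network strengths (X, Y) for one subject."""
    edge_vector = np.asarray(edge_vector, dtype=float)
    if edge_vector.shape[0] != masks.n_edges:
        raise DimensionError("edge vector length does not match masks")
    return (float(edge_vector[masks.positive].sum()),
            float(edge_vector[masks.negative].sum()))


def strengths_matrix(edges: np.ndarray, masks: FeatureMasks) -> np.ndarray:
    """(n_subjects, 2) array of [X, Y] strengths for a cohort edge matrix."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape[1] != masks.n_edges:
        raise DimensionError("edge matrix width does not match masks")
    return np.column_stack([edges[:, masks.positive].sum(axis=1),
                            edges[:, masks.negative].sum(axis=1)])


def fit_model(X: np.ndarray, Y: np.ndarray, scores: np.ndarray,
              variant: str = "bilinear",
              masks: FeatureMasks | None = None) -> CPMModel:
    """Ordinary least squares of the score on the network strengths."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if X.shape[0] != n or Y.shape[0] != n:
        raise DimensionError("strengths and scores lengths differ")
    if n < 3:
        raise ValidationError("model fit needs at least 3 subjects")
    ones = np.ones(n)
    if variant == "bilinear":
        xc, yc = X - X.mean(), Y - Y.mean()
        nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
        if nx > 0 and ny > 0 and abs(xc @ yc) >= nx * ny * (1 - 1e-12):
            raise FitError("X and Y strengths are exactly collinear; use a "
                           "positive_only or negative_only variant")
        design = np.column_stack([ones, X, Y])
        beta, *_ = np.linalg.lstsq(design, scores, rcond=None)
        a, b, c = beta
    elif variant == "positive_only":
        beta, *_ = np.linalg.lstsq(np.column_stack([ones, X]), scores,
                                   rcond=None)
        a, b, c = beta[0], beta[1], 0.0
    elif variant == "negative_only":
        beta, *_ = np.linalg.lstsq(np.column_stack([ones, Y]), scores,
                                   rcond=None)
        a, b, c = beta[0], 0.0, beta[1]
    else:
        raise ValidationError(f"unknown model variant {variant!r}")
    return CPMModel(variant=variant, a=float(a), b=float(b), c=float(c),
                    masks=masks, n_train=n)


def predict(model: CPMModel, X: float | np.ndarray,
            Y: float | np.ndarray) -> float | np.ndarray:
    """Ψ̂ = a + bX + cY."""
    return model.a + model.b * np.asarray(X, dtype=float) \
        + model.c * np.asarray(Y, dtype=float)


# ---------------------------------------------------------------------------
# accuracy and significance statistics


def accuracy(observed: np.ndarray, predicted: np.ndarray) -> PredictionResult:
    """Pearson R (with two-sided parametric p) and Spearman ρ between
    observed and predicted scores."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n = observed.shape[0]
    if predicted.shape[0] != n:
        raise DimensionError("observed and predicted lengths differ")
    if n < 3:
        raise ValidationError("accuracy needs at least 3 subjects")
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        raise InvalidResultError("accuracy undefined for constant input")
    pr = stats.pearsonr(observed, predicted)
    rho = stats.spearmanr(observed, predicted).statistic
    return PredictionResult(observed=observed, predicted=predicted,
                            pearson_r=float(pr.statistic),
                            pearson_p=float(pr.pvalue),
                            spearman_rho=float(rho), n=n)


def critical_r(n: int, alpha: float = 0.05, m_comparisons: int = 1) -> float:
    """Two-sided Bonferroni-corrected critical Pearson correlation.

    The critical |r| at corrected level alpha/m via the t distribution with
    n−2 degrees of freedom: r* = t*/sqrt(t*² + n − 2).  For n = 207,
    alpha = 0.05 and 16 comparisons this is 0.204.
    """
    if n < 4:
        raise ValidationError("critical_r needs n >= 4")
    if m_comparisons < 1:
        raise ValidationError("m_comparisons must be >= 1")
    tcrit = stats.t.ppf(1.0 - alpha / (2.0 * m_comparisons), n - 2)
    return float(tcrit / np.sqrt(tcrit ** 2 + n - 2))


def williams_test(r12: float, r13: float, r23: float,
                  n: int) -> tuple[float, float]:
    """Williams's t for two dependent correlations sharing variable 1.

    Tests H0: ρ12 = ρ13 given the correlation r23 between the two
    non-shared variables; t has n−3 degrees of freedom.
    """
    for r in (r12, r13, r23):
        if not abs(r) < 1:
            raise ValidationError("correlations must satisfy |r| < 1")
    if n < 5:
        raise ValidationError("williams_test needs n >= 5")
    det = 1 - r12 ** 2 - r13 ** 2 - r23 ** 2 + 2 * r12 * r13 * r23
    if det <= 0:
        raise ValidationError("correlation matrix is not positive definite")
    rbar = (r12 + r13) / 2.0
    denom = 2 * (n - 1) / (n - 3) * det + rbar ** 2 * (1 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1 + r23) / denom)
    p = 2.0 * stats.t.sf(abs(t), n - 3)
    return float(t), float(p)


def steiger_test(r12: float, r34: float, r13: float, r14: float,
                 r23: float, r24: float, n: int) -> tuple[float, float]:
    """Steiger's z for two dependent correlations with no shared variable.

    Tests H0: ρ12 = ρ34 using the difference of Fisher z transforms with
    the Pearson–Filon covariance of dependent correlations (Dunn–Clark
    form).  With all cross-correlations zero this reduces to the
    independent-samples Fisher z-difference statistic.
    """
    for r in (r12, r34, r13, r14, r23, r24):
        if not abs(r) < 1:
            raise ValidationError("correlations must satisfy |r| < 1")
    if n < 5:
        raise ValidationError("steiger_test needs n >= 5")
    R = np.array([[1, r12, r13, r14],
                  [r12, 1, r23, r24],
                  [r13, r23, 1, r34],
                  [r14, r24, r34, 1]], dtype=float)
    if np.linalg.eigvalsh(R).min() <= 0:
        raise ValidationError("4x4 correlation matrix is not positive definite")
    psi = (0.5 * r12 * r34 * (r13 ** 2 + r14 ** 2 + r23 ** 2 + r24 ** 2)
           + r13 * r24 + r14 * r23
           - (r12 * r13 * r14 + r12 * r23 * r24
              + r34 * r13 * r23 + r34 * r14 * r24))
    s = psi / ((1 - r12 ** 2) * (1 - r34 ** 2))
    z = (np.arctanh(r12) - np.arctanh(r34)) * np.sqrt((n - 3) / (2 - 2 * s))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# cross-validation


def _fold_predict(edges: np.ndarray, scores: np.ndarray, train: np.ndarray,
                  masks: FeatureMasks, variant: str,
                  holdout: np.ndarray) -> tuple[np.ndarray, bool]:
    """Fit on the training rows and predict the holdout rows.

    Returns (predictions, degenerate).  A fold is degenerate when the
    required masks select no edges (or the resulting strengths are
    constant); it then predicts the training-mean score.
    """
    S = strengths_matrix(edges, masks)
    X, Y = S[:, 0], S[:, 1]
    if variant == "bilinear":
        usable = (np.ptp(X[train]) > 0) or (np.ptp(Y[train]) > 0)
    elif variant == "positive_only":
        usable = np.ptp(X[train]) > 0
    else:
        usable = np.ptp(Y[train]) > 0
    if not usable:
        return np.full(holdout.shape[0], scores[train].mean()), True
    if variant == "bilinear" and (np.ptp(X[train]) == 0 or np.ptp(Y[train]) == 0):
        # one strength column constant: fall back to the informative one
        variant = "positive_only" if np.ptp(X[train]) > 0 else "negative_only"
    model = fit_model(X[train], Y[train], scores[train], variant=variant)
    return np.asarray(predict(model, X[holdout], Y[holdout])), False


def loo_cv(edges: np.ndarray, scores: np.ndarray, cfg: RunConfig,
           leak_selection: bool = False) -> PredictionResult:
    """Leave-one-out CPM with selection and fitting nested per fold.

    At each of n iterations one subject is held out; feature selection and
    model fitting use only the n−1 retained subjects, and the held-out
    subject's score is predicted from its own network strengths under that
    fold's masks.  Accuracy is computed on the assembled predictions.

    ``leak_selection=True`` selects features once on all n subjects
    (deliberately un-nested; for leakage diagnostics only).

    Folds whose masks select no edges predict the fold-mean score and are
    counted in ``n_degenerate_folds``; if every fold is degenerate the
    result is flagged invalid (``valid=False``, NaN accuracy).
    """
    edges = np.asarray(edges, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n, n_edges = edges.shape
    if scores.shape[0] != n:
        raise DimensionError("scores length does not match edge rows")
    if n < 5:
        raise ValidationError("leave-one-out CPM needs at least 5 subjects")
    if np.ptp(scores) == 0:
        raise InvalidResultError("scores are constant; accuracy undefined")
    variant = cfg.model_variant

    # per-edge sufficient statistics for O(n_edges) leave-one-out selection
    Sx = edges.sum(axis=0)
    Sxx = (edges ** 2).sum(axis=0)
    Sy = scores.sum()
    Syy = (scores ** 2).sum()
    Sxy = scores @ edges
    rcrit = selection_r_threshold(n - 1, cfg.selection_p)
    if leak_selection:
        pooled_masks = select_features(edges, scores, cfg.selection_p)

    predicted = np.empty(n)
    n_degenerate = 0
    m = n - 1
    for k in range(n):
        if leak_selection:
            masks = pooled_masks
        else:
            sx = Sx - edges[k]
            sxx = Sxx - edges[k] ** 2
            sy = Sy - scores[k]
            syy = Syy - scores[k] ** 2
            sxy = Sxy - scores[k] * edges[k]
            cov = sxy - sx * sy / m
            varx = sxx - sx ** 2 / m
            vary = syy - sy ** 2 / m
            with np.errstate(invalid="ignore", divide="ignore"):
                r = cov / np.sqrt(varx * vary)
            r[varx <= 0] = np.nan
            with np.errstate(invalid="ignore"):
                masks = FeatureMasks(positive=r > rcrit, negative=r < -rcrit,
                                     selection_p=cfg.selection_p, n_subjects=m)
        train = np.concatenate([np.arange(k), np.arange(k + 1, n)])
        pred, degenerate = _fold_predict(edges, scores, train, masks, variant,
                                         np.array([k]))
        predicted[k] = pred[0]
        if degenerate:
            n_degenerate += 1
    if n_degenerate:
        logger.info("loo_cv: %d/%d folds degenerate (no selected edges)",
                    n_degenerate, n)
    if n_degenerate == n or np.ptp(predicted) == 0:
        # fold-mean-only predictions carry no connectome information
        return PredictionResult(observed=scores, predicted=predicted,
                                pearson_r=float("nan"),
                                pearson_p=float("nan"),
                                spearman_rho=float("nan"), n=n, valid=False,
                                n_degenerate_folds=n_degenerate)
    result = accuracy(scores, predicted)
    result.n_degenerate_folds = n_degenerate
    return result


def twofold_cv(train_edges: np.ndarray, train_scores: np.ndarray,
               test_edges: np.ndarray, test_scores: np.ndarray,
               cfg: RunConfig) -> tuple[PredictionResult, CPMModel]:
    """Train CPM on one sample, predict the other unchanged.

    Masks and coefficients come from the full training sample and are
    applied to every test subject.  Returns the test-sample prediction
    result and the trained model.
    """
    train_edges = np.asarray(train_edges, dtype=float)
    test_edges = np.asarray(test_edges, dtype=float)
    if train_edges.shape[1] != test_edges.shape[1]:
        raise DimensionError(
            f"edge counts differ: train {train_edges.shape[1]} vs "
            f"test {test_edges.shape[1]}")
    masks = select_features(train_edges, train_scores, cfg.selection_p)
    S_train = strengths_matrix(train_edges, masks)
    n_train = train_edges.shape[0]
    pred, degenerate = _fold_predict(
        np.vstack([train_edges, test_edges]),
        np.concatenate([train_scores, test_scores]),
        np.arange(n_train), masks, cfg.model_variant,
        np.arange(n_train, n_train + test_edges.shape[0]))
    model = CPMModel(variant=cfg.model_variant, a=float("nan"), b=0.0, c=0.0,
                     masks=masks, n_train=n_train)
    if not degenerate:
        X, Y = S_train[:, 0], S_train[:, 1]
        variant = cfg.model_variant
        if variant == "bilinear" and (np.ptp(X) == 0 or np.ptp(Y) == 0):
            variant = "positive_only" if np.ptp(X) > 0 else "negative_only"
        model = fit_model(X, Y, train_scores, variant=variant, masks=masks)
    if degenerate or np.ptp(pred) == 0:
        return (PredictionResult(observed=np.asarray(test_scores, dtype=float),
                                 predicted=pred, pearson_r=float("nan"),
                                 pearson_p=float("nan"),
                                 spearman_rho=float("nan"),
                                 n=test_edges.shape[0], valid=False,
                                 n_degenerate_folds=1), model)
    result = accuracy(test_scores, pred)
    return result, model


def permutation_null(edges: np.ndarray, scores: np.ndarray, cfg: RunConfig,
                     observed_r: float | None = None,
                     n_permutations: int | None = None) -> NullDistribution:
    """Null distribution of LOO-CPM accuracy under score permutation.

    Each permutation shuffles the scores (seeded by ``cfg.rng_seed``) and
    reruns the complete nested leave-one-out CPM, recording the Pearson R
    between permuted-observed and predicted scores.  Permutations whose
    fold structure is entirely degenerate are skipped and counted; the
    distribution is flagged when more than 5 % are skipped.
    """
    n_perm = n_permutations if n_permutations is not None else cfg.n_permutations
    if n_perm < 100:
        raise ValidationError("permutation_null needs at least 100 permutations")
    rng = np.random.default_rng(cfg.rng_seed)
    scores = np.asarray(scores, dtype=float)
    accs: list[float] = []
    n_skipped = 0
    for _ in range(n_perm):
        perm_scores = rng.permutation(scores)
        try:
            res = loo_cv(edges, perm_scores, cfg)
        except InvalidResultError:
            n_skipped += 1
            continue
        if not res.valid:
            n_skipped += 1
            continue
        accs.append(res.pearson_r)
    if n_skipped:
        logger.info("permutation_null: %d/%d permutations skipped",
                    n_skipped, n_perm)
    acc = np.asarray(accs)
    if acc.size == 0:
        raise InvalidResultError("all permutations degenerate")
    null = NullDistribution(accuracies=acc, sd=float(acc.std(ddof=1)),
                            mean=float(acc.mean()), n_skipped=n_skipped,
                            flagged=n_skipped > 0.05 * n_perm)
    if observed_r is not None:
        null.observed_p = null.empirical_p(observed_r)
    return null
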