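"""Logistic-regression risk classifier with the full pruning chain.

The modelling chain mirrors common practice for a binary logistic model fed
with many correlated signal features:

1. multicollinearity pruning — of every feature pair with |Pearson r| above
   a threshold (0.7 by default) the later feature in catalogue order is
   dropped;
2. outlier removal — a preliminary logistic fit flags observations with
   Cook's distance > 4/n or hat-matrix (centre) leverage > 2(k+1)/n, removed
   once, not iteratively;
3. iterative model refinement — maximum-likelihood logistic regression,
   dropping features whose Wald p-value exceeds alpha or whose odds ratio is
   within ``or_epsilon`` of 1, refitting until stable;
4. evaluation — resubstitution (apparent) confusion matrix, accuracy,
   sensitivity and specificity, with the NO_RISK class on the sensitivity
   row.  An events-per-variable ratio (smallest class size / number of
   predictors) above 10 is checked as a reliability guard.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

LABELS = ("NO_RISK", "RISK")  # RISK is the positive (coded 1) class


def _round1(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class EvalMetrics:
    confusion: np.ndarray  # rows = actual (NO_RISK, RISK), cols = predicted
    accuracy: float        # percent, one decimal
    sensitivity: float     # percent correct among actual NO_RISK
    specificity: float     # percent correct among actual RISK
    n_correct: int
    n_total: int


@dataclass
class FitRound:
    features: list[str]
    dropped: list[str]
    reasons: dict[str, str]


@dataclass
class ModelReport:
    features_after_correlation: list[str]
    removed_outliers: list[int]
    removed_per_class: dict[str, int]
    final_features: list[str]
    coefficients: dict[str, float]
    odds_ratios: dict[str, float]
    p_values: dict[str, float]
    events_per_variable: float
    metrics: EvalMetrics
    rounds: list[FitRound] = field(default_factory=list)
    separation_flag: bool = False
    protocol: str = "apparent (resubstitution)"

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "features_after_correlation": self.features_after_correlation,
            "removed_outliers": self.removed_outliers,
            "removed_per_class": self.removed_per_class,
            "final_features": self.final_features,
            "coefficients": self.coefficients,
            "odds_ratios": self.odds_ratios,
            "p_values": self.p_values,
            "events_per_variable": self.events_per_variable,
            "separation_flag": self.separation_flag,
            "confusion_matrix": self.metrics.confusion.tolist(),
            "accuracy_pct": self.metrics.accuracy,
            "sensitivity_pct": self.metrics.sensitivity,
            "specificity_pct": self.metrics.specificity,
            "n_correct": self.metrics.n_correct,
            "n_total": self.metrics.n_total,
            "rounds": [
                {"features": r.features, "dropped": r.dropped, "reasons": r.reasons}
                for r in self.rounds
            ],
        }


def prune_correlated(
    table: pd.DataFrame,
    features: list[str],
    r_threshold: float = 0.7,
) -> list[str]:
    """Greedy multicollinearity pruning in catalogue order.

    Scans features in the given order; a feature correlated above the
    threshold (absolute Pearson r) with any already-kept feature is dropped.
    Constant columns have undefined correlation and are dropped with a
    warning.  Deterministic.
    """
    if len(table) < 2:
        raise ValueError("at least 2 rows required for correlation pruning")
    X = table[features].to_numpy(dtype=float)
    sd = X.std(axis=0)
    kept: list[int] = []
    for j, name in enumerate(features):
        if sd[j] == 0:
            logger.warning("dropping constant feature %s (undefined correlation)", name)
            continue
        ok = True
        for i in kept:
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if abs(r) > r_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return [features[j] for j in kept]


def _encode_labels(labels: pd.Series | np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    unknown = set(np.unique(labels)) - set(LABELS)
    if unknown:
        raise ValueError(f"unseen labels: {sorted(unknown)}")
    return (labels == "RISK").astype(float)


class _LogitFit:
    """Logistic fit on internally standardised predictors.

    Standardisation is an affine reparametrisation: fitted probabilities and
    Wald p-values are unchanged, and coefficients are reported back on the
    original scale (beta_j = beta_std_j / sd_j), so odds ratios keep their
    per-original-unit meaning.
    """

    def __init__(self, X: pd.DataFrame, y: np.ndarray):
        self.columns = [c for c in X.columns if c != "const"]
        Z = X.copy()
        self._mu = X[self.columns].mean()
        self._sd = X[self.columns].std(ddof=0).replace(0.0, 1.0)
        Z[self.columns] = (X[self.columns] - self._mu) / self._sd
        self._Z = Z
        model = sm.Logit(y, Z)
        self.separated = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(disp=0, maxiter=500, method="lbfgs")
                res = sm.Logit(y, Z).fit(disp=0, maxiter=100, method="newton",
                                         start_params=res.params)
            if not res.mle_retvals.get("converged", True):
                raise PerfectSeparationError("logistic fit did not converge")
            if np.abs(res.params).max() > 1e3:
                raise PerfectSeparationError("diverging coefficients")
        except (PerfectSeparationError, np.linalg.LinAlgError):
            logger.warning("perfect separation / non-convergence: reporting a "
                           "weakly L2-regularised fit")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit_regularized(alpha=1e-6, L1_wt=0.0, disp=0,
                                            maxiter=1000)
            self.separated = True
        self._res = res

    @property
    def params(self) -> pd.Series:
        """Coefficients on the original predictor scale (plus intercept)."""
        std = pd.Series(np.asarray(self._res.params), index=self._Z.columns)
        out = std.copy()
        for c in self.columns:
            out[c] = std[c] / self._sd[c]
        if "const" in out.index:
            out["const"] = std["const"] - float(
                sum(std[c] * self._mu[c] / self._sd[c] for c in self.columns)
            )
        return out

    @property
    def pvalues(self) -> pd.Series:
        try:
            return pd.Series(np.asarray(self._res.pvalues), index=self._Z.columns)
        except (AttributeError, ValueError, np.linalg.LinAlgError):
            return pd.Series(np.nan, index=self._Z.columns)

    def predict_proba(self) -> np.ndarray:
        return np.asarray(self._res.predict(self._Z))


def _logit_fit(X: pd.DataFrame, y: np.ndarray) -> tuple[_LogitFit, bool]:
    fit = _LogitFit(X, y)
    return fit, fit.separated


def remove_outliers(
    table: pd.DataFrame,
    features: list[str],
    labels: pd.Series | np.ndarray,
    cooks_threshold: float = 1.0,
    leverage_factor: float = 3.0,
) -> tuple[pd.DataFrame, list[int]]:
    """Single-pass influence-based outlier removal from a logistic fit.

    Removes rows with Cook's distance above ``cooks_threshold`` (the classic
    D > 1 rule) or hat-matrix leverage above ``leverage_factor * (k + 1) / n``
    (three times the mean leverage; k predictors, +1 for the intercept).
    Milder cutoffs such as 4/n for Cook's distance or twice the mean leverage
    flag of the order of 10% of perfectly clean Gaussian data and are left to
    the caller; the defaults operate at the few-per-mille scale expected of
    genuine outliers.  Guards against fitting with fewer than 5 rows per
    predictor.
    """
    y = _encode_labels(labels)
    n, k = len(table), len(features)
    if n < 5 * k:
        raise ValueError(f"refusing outlier fit: {n} rows for {k} predictors (< 5x)")
    X = sm.add_constant(table[features].astype(float), has_constant="add")
    # standardise for numerical stability; hat leverage and Cook's distance
    # are invariant under affine reparametrisation of the design
    sd = X.std(ddof=0).replace(0.0, 1.0)
    mu = X.mean()
    for c in X.columns:
        if c != "const":
            X[c] = (X[c] - mu[c]) / sd[c]
    glm = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            res = glm.fit()
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        counts = pd.Series(y).value_counts().to_dict()
        raise RuntimeError(
            f"preliminary logistic fit failed ({exc}); class counts {counts} — "
            "check for separation or collinearity"
        ) from exc
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        infl = res.get_influence(observed=False)
        cooks = infl.cooks_distance[0]
        hat = infl.hat_matrix_diag
    mask = (cooks > cooks_threshold) | (hat > leverage_factor * (k + 1) / n)
    removed = list(table.index[mask])
    return table.loc[~mask], removed


def fit_classifier(
    table: pd.DataFrame,
    features: list[str],
    labels_column: str = "label",
    alpha: float = 0.05,
    or_epsilon: float = 0.01,
    max_rounds: int = 10,
) -> ModelReport:
    """Iteratively refined logistic regression with resubstitution metrics.

    Starting from ``features``, each round drops predictors with Wald
    p > ``alpha`` or |odds ratio - 1| <= ``or_epsilon`` and refits, until the
    feature set is stable or ``max_rounds`` is reached.  Metrics are apparent
    (resubstitution), as recorded in the report's ``protocol`` field.
    """
    y = _encode_labels(table[labels_column])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    current = list(features)
    rounds: list[FitRound] = []
    separated = False
    res = None
    for _ in range(max_rounds):
        X = sm.add_constant(table[current].astype(float), has_constant="add")
        res, sep = _logit_fit(X, y)
        separated = separated or sep
        if sep:
            # p-values are unreliable under separation; stop pruning
            rounds.append(FitRound(list(current), [], {}))
            break
        params = res.params.drop("const", errors="ignore")
        pvals = res.pvalues.drop("const", errors="ignore")
        with np.errstate(over="ignore"):
            odds = np.exp(params)
        reasons = {}
        for name in current:
            if pvals[name] > alpha:
                reasons[name] = f"p={pvals[name]:.3g} > {alpha}"
            elif abs(odds[name] - 1.0) <= or_epsilon:
                reasons[name] = f"|OR-1|={abs(odds[name]-1):.3g} <= {or_epsilon}"
        dropped = list(reasons)
        rounds.append(FitRound(list(current), dropped, reasons))
        if not dropped:
            break
        current = [f for f in current if f not in reasons]
        if not current:
            break

    if current:
        X = sm.add_constant(table[current].astype(float), has_constant="add")
        res, sep = _logit_fit(X, y)
        separated = separated or sep
        prob = res.predict_proba()
        params = res.params.drop("const", errors="ignore")
        pvals = res.pvalues.drop("const", errors="ignore")
        coeffs = params.to_dict()
        with np.errstate(over="ignore"):
            odds_ratios = np.exp(params).to_dict()
        p_values = pvals.to_dict()
    else:
        # empty model: intercept only, majority-rate prediction
        rate = y.mean()
        prob = np.full(len(y), rate)
        coeffs, odds_ratios, p_values = {}, {}, {}

    predictions = np.where(prob >= 0.5, "RISK", "NO_RISK")
    metrics = evaluate(predictions, table[labels_column])
    class_sizes = table[labels_column].value_counts()
    epv = float(class_sizes.min() / max(len(current), 1))
    return ModelReport(
        features_after_correlation=list(features),
        removed_outliers=[],
        removed_per_class={},
        final_features=current,
        coefficients=coeffs,
        odds_ratios=odds_ratios,
        p_values=p_values,
        events_per_variable=epv,
        metrics=metrics,
        rounds=rounds,
        separation_flag=separated,
    )


def evaluate(predictions, labels) -> EvalMetrics:
    """Confusion matrix and percentage metrics (one decimal, half-up).

    Rows of the confusion matrix are the actual classes in the order
    (NO_RISK, RISK); sensitivity is the percentage of actual NO_RISK
    instances classified correctly, specificity the same for RISK.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    for arr, what in ((predictions, "prediction"), (labels, "label")):
        unknown = set(np.unique(arr)) - set(LABELS)
        if unknown:
            raise ValueError(f"unseen {what} values: {sorted(unknown)}")
    cm = np.zeros((2, 2), dtype=int)
    for i, actual in enumerate(LABELS):
        for j, pred in enumerate(LABELS):
            cm[i, j] = int(np.sum((labels == actual) & (predictions == pred)))
    return evaluate_confusion(cm)


def evaluate_confusion(cm: np.ndarray) -> EvalMetrics:
    """Metrics from a (actual x predicted) confusion matrix with rows
    (NO_RISK, RISK)."""
    cm = np.asarray(cm, dtype=int)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("confusion matrix must be 2x2 with non-negative counts")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    correct = int(cm[0, 0] + cm[1, 1])
    row0, row1 = cm[0].sum(), cm[1].sum()
    return EvalMetrics(
        confusion=cm,
        accuracy=_round1(100.0 * correct / total),
        sensitivity=_round1(100.0 * cm[0, 0] / row0) if row0 else float("nan"),
        specificity=_round1(100.0 * cm[1, 1] / row1) if row1 else float("nan"),
        n_correct=correct,
        n_total=total,
    )
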