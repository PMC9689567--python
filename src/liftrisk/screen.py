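"""Per-feature two-class statistical screening.

Each feature is compared between the NO_RISK and RISK trials of the same
subjects.  Pairing is within subject: the i-th lift of the NO_RISK trial is
paired with the i-th lift of the RISK trial (an alternative per-subject-mean
pairing is available).  Normality of each class's paired values is assessed
with a Shapiro-Wilk test at the 95% confidence level; when both classes pass,
a two-tailed paired t-test is used, otherwise the Wilcoxon signed-rank test.
No multiple-testing correction is applied by default; Benjamini-Hochberg is
available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import feature_columns

logger = logging.getLogger(__name__)

_MIN_PAIRS = 8


@dataclass
class ScreenResult:
    feature: str
    mean_no_risk: float
    sd_no_risk: float
    mean_risk: float
    sd_risk: float
    normality_p_no_risk: float
    normality_p_risk: float
    test_used: str  # paired_t | wilcoxon
    p_value: float
    significant: bool

    def summary(self) -> dict:
        return {
            "feature": self.feature,
            "NO_RISK": f"{self.mean_no_risk:.2f} ± {self.sd_no_risk:.2f}",
            "RISK": f"{self.mean_risk:.2f} ± {self.sd_risk:.2f}",
            "test": self.test_used,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def paired_values(
    table: pd.DataFrame,
    feature: str,
    pairing: str = "lift",
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (NO_RISK, RISK) value arrays for one feature.

    ``pairing='lift'`` matches rows on (subject, lift_index) across the two
    trial labels; ``pairing='subject'`` pairs per-subject means.  Rows without
    a partner are dropped (count logged).
    """
    sub = table[["subject", "lift_index", "label", feature]]
    a = sub[sub["label"] == "NO_RISK"]
    b = sub[sub["label"] == "RISK"]
    if a.empty or b.empty:
        raise ValueError("both classes must be present for screening")
    if pairing == "subject":
        ga = a.groupby("subject")[feature].mean()
        gb = b.groupby("subject")[feature].mean()
        common = ga.index.intersection(gb.index)
        return ga.loc[common].to_numpy(), gb.loc[common].to_numpy()
    if pairing != "lift":
        raise ValueError(f"unknown pairing {pairing!r}")
    merged = a.merge(b, on=["subject", "lift_index"], suffixes=("_0", "_1"))
    dropped = len(a) + len(b) - 2 * len(merged)
    if dropped:
        logger.info("screening %s: dropped %d unpaired rows", feature, dropped)
    return merged[f"{feature}_0"].to_numpy(), merged[f"{feature}_1"].to_numpy()


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # a constant sample is treated as non-normal
    return float(stats.shapiro(x).pvalue)


def paired_test(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    normality_on: str = "values",
) -> tuple[str, float, float, float]:
    """Normality-gated paired test; returns (test_used, p, shapiro_p_x, shapiro_p_y).

    ``normality_on='values'`` gates on each class's values;
    ``'differences'`` gates on the paired differences instead.
    """
    diffs = y - x
    px, py = _shapiro_p(x), _shapiro_p(y)
    if not np.any(diffs):
        # identical classes: no evidence of any difference
        test = "paired_t" if min(px, py) > alpha else "wilcoxon"
        return test, 1.0, px, py
    if normality_on == "differences":
        normal = _shapiro_p(diffs) > alpha
    elif normality_on == "values":
        normal = px > alpha and py > alpha
    else:
        raise ValueError(f"unknown normality_on {normality_on!r}")
    if normal:
        return "paired_t", float(stats.ttest_rel(x, y).pvalue), px, py
    res = stats.wilcoxon(x, y, zero_method="wilcox")
    return "wilcoxon", float(res.pvalue), px, py


def screen_features(
    table: pd.DataFrame,
    alpha: float = 0.05,
    pairing: str = "lift",
    features: list[str] | None = None,
    fdr: bool = False,
    normality_on: str = "values",
) -> list[ScreenResult]:
    """Screen every feature column for a class difference.

    Returns one :class:`ScreenResult` per feature; ``significant`` is
    ``p < alpha`` (Benjamini-Hochberg adjusted when ``fdr=True``).
    """
    if features is None:
        features = [c for c in feature_columns() if c in table.columns]
    results: list[ScreenResult] = []
    for feat in features:
        x, y = paired_values(table, feat, pairing=pairing)
        if len(x) < _MIN_PAIRS:
            raise ValueError(
                f"only {len(x)} pairs for {feat}; at least {_MIN_PAIRS} required"
            )
        test, p, px, py = paired_test(x, y, alpha=alpha, normality_on=normality_on)
        results.append(ScreenResult(
            feature=feat,
            mean_no_risk=float(x.mean()), sd_no_risk=float(x.std(ddof=1)),
            mean_risk=float(y.mean()), sd_risk=float(y.std(ddof=1)),
            normality_p_no_risk=px, normality_p_risk=py,
            test_used=test, p_value=p, significant=bool(p < alpha),
        ))
    if fdr:
        from statsmodels.stats.multitest import multipletests
        reject, _, _, _ = multipletests([r.p_value for r in results],
                                        alpha=alpha, method="fdr_bh")
        for r, rej in zip(results, reject):
            r.significant = bool(rej)
    return results


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Tabular layout: feature, class means +/- SD, test and p-value."""
    return pd.DataFrame([{
        "feature": r.feature,
        "no_risk_mean": r.mean_no_risk, "no_risk_sd": r.sd_no_risk,
        "risk_mean": r.mean_risk, "risk_sd": r.sd_risk,
        "normality_p_no_risk": r.normality_p_no_risk,
        "normality_p_risk": r.normality_p_risk,
        "test_used": r.test_used, "p_value": r.p_value,
        "significant": r.significant,
    } for r in results])
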