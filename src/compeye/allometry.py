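"""Allometric scaling statistics.

Traits scale as a power law Y = a X^b; on log-log axes this is the line
log Y = log a + b log X, fitted by ordinary least squares.  The exponent
b classifies the scaling: b = 0 constant, 0 < b < 1 hypoallometric,
b = 1 isometric, b > 1 hyperallometric, b < 0 inverse.  84% confidence
bands around the mean response (computed in log space, then
exponentiated) are the conventional display for comparing regression
means between groups at alpha = 0.05.  Group means are compared by
one-way ANOVA with Sidak-Holm corrected pairwise t tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "LandmarkRecord",
    "AllometricRegression",
    "trait_lengths",
    "fit_allometry",
    "sidak_holm",
    "compare_groups",
]

LANDMARKS = tuple("abcdefgh")


@dataclass
class LandmarkRecord:
    """Eight 2D landmarks (a-h, micrometers) on a lateral photograph.

    a-b span the eye; c-d the head segment; d-e the thorax segment;
    e-f the abdomen segment; g-h the conventional thorax.
    """

    specimen_id: str
    genotype: str
    points: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [k for k in LANDMARKS if k not in self.points]
        if missing:
            raise ValidationError(f"missing landmarks: {missing}")
        for k in LANDMARKS:
            p = np.asarray(self.points[k], dtype=float)
            if p.shape != (2,) or not np.all(np.isfinite(p)):
                raise ValidationError(f"landmark {k} is not a finite 2D point")
            self.points[k] = p


def _seg(rec: LandmarkRecord, p: str, q: str) -> float:
    return float(np.linalg.norm(rec.points[p] - rec.points[q]))


def trait_lengths(rec: LandmarkRecord) -> dict:
    """Trait lengths (micrometers) from one landmark record.

    Body length is the sum of the head (c-d), thorax (d-e), and abdomen
    (e-f) segments, robust to idiosyncratic bending.  A zero-length
    segment (duplicated landmark) flags the row invalid.
    """
    row = {
        "specimen_id": rec.specimen_id,
        "genotype": rec.genotype,
        "eye_length": _seg(rec, "a", "b"),
        "head_length": _seg(rec, "c", "d"),
        "thorax_length": _seg(rec, "g", "h"),
        "thorax_segment": _seg(rec, "d", "e"),
        "abdomen_length": _seg(rec, "e", "f"),
    }
    row["body_length"] = (row["head_length"] + row["thorax_segment"]
                          + row["abdomen_length"])
    row["valid"] = all(
        row[k] > 0 for k in ("eye_length", "head_length", "thorax_length",
                             "thorax_segment", "abdomen_length")
    )
    return row


class AllometricRegression(BaseEstimator, RegressorMixin):
    """Power-law fit Y = a X^b via OLS on log-transformed traits.

    Parameters
    ----------
    alpha_class : float, default 0.05
        The exponent is classified from its (1 - alpha_class) CI.
    band_level : float, default 0.84
        Level of the mean-response confidence band used for display.

    Fitted attributes
    -----------------
    slope_ (b), intercept_ (log a), se_b_, r_squared_, p_value_ (of b),
    ci_b_ (classification CI for b), classification_.
    """

    def __init__(self, alpha_class: float = 0.05, band_level: float = 0.84):
        self.alpha_class = alpha_class
        self.band_level = band_level

    def fit(self, X, y) -> "AllometricRegression":
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(x) != len(y):
            raise ValidationError("X and y lengths differ")
        if len(x) < 3:
            raise InsufficientDataError("allometric fit needs n >= 3")
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValidationError("power-law traits must be positive")

        design = np.column_stack([np.ones(len(x)), np.log(x)])
        res = sm.OLS(np.log(y), design).fit()
        self.result_ = res
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.se_b_ = float(res.bse[1])
        self.r_squared_ = float(res.rsquared)
        self.p_value_ = float(res.pvalues[1])
        lo, hi = res.conf_int(alpha=self.alpha_class)[1]
        self.ci_b_ = (float(lo), float(hi))
        self.classification_ = self._classify(self.slope_, self.ci_b_)
        return self

    @staticmethod
    def _classify(b: float, ci: tuple[float, float]) -> str:
        lo, hi = ci
        if hi < 0:
            return "inverse"
        if lo <= 0 <= hi:
            return "constant"
        if lo <= 1 <= hi:
            return "isometric"
        if hi < 1:
            return "hypoallometric"
        return "hyperallometric"

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        return np.exp(self.intercept_ + self.slope_ * np.log(x))

    def confidence_band(self, X, level: float | None = None) -> pd.DataFrame:
        """Mean-response confidence band, exponentiated from log space."""
        level = self.band_level if level is None else level
        x = np.asarray(X, dtype=float).ravel()
        design = np.column_stack([np.ones(len(x)), np.log(x)])
        pred = self.result_.get_prediction(design)
        frame = pred.summary_frame(alpha=1.0 - level)
        return pd.DataFrame({
            "x": x,
            "mean": np.exp(frame["mean"].to_numpy()),
            "lower": np.exp(frame["mean_ci_lower"].to_numpy()),
            "upper": np.exp(frame["mean_ci_upper"].to_numpy()),
        })

    def summary(self) -> dict:
        return {
            "log_a": self.intercept_,
            "a": float(np.exp(self.intercept_)),
            "b": self.slope_,
            "se_b": self.se_b_,
            "ci_b": list(self.ci_b_),
            "r_squared": self.r_squared_,
            "p_value": self.p_value_,
            "classification": self.classification_,
        }


def fit_allometry(X, y, **kwargs) -> AllometricRegression:
    """Functional wrapper over :class:`AllometricRegression`."""
    return AllometricRegression(**kwargs).fit(X, y)


def sidak_holm(pvalues) -> np.ndarray:
    """Sidak-Holm step-down adjustment.

    At step k of the m ordered raw p-values, the adjusted value is
    1 - (1 - p_(k))^(m - k + 1), enforced monotone nondecreasing.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("pvalues must be a non-empty 1D sequence")
    return multipletests(p, method="holm-sidak")[1]


def compare_groups(values_by_group: dict, welch: bool = False) -> dict:
    """One-way ANOVA plus Sidak-Holm-adjusted pairwise t tests.

    Parameters
    ----------
    values_by_group : mapping of group label -> 1D array of measurements
        (each group needs n >= 2).
    welch : use Welch's t instead of the pooled-variance Student's t.

    Returns a dict with ``anova_f``, ``anova_p`` and a ``pairwise``
    DataFrame (group_a, group_b, t, p_raw, p_adjusted, significant).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise InsufficientDataError(f"group {name!r} has n < 2")

    f_stat, p_anova = stats.f_oneway(*groups.values())
    names = list(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, p = stats.ttest_ind(groups[names[i]], groups[names[j]],
                                   equal_var=not welch)
            rows.append({"group_a": names[i], "group_b": names[j],
                         "t": float(t), "p_raw": float(p)})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = sidak_holm(table["p_raw"].to_numpy())
    table["significant"] = table["p_adjusted"] < 0.05
    return {"anova_f": float(f_stat), "anova_p": float(p_anova),
            "pairwise": table}
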