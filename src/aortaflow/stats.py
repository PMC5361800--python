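"""Morphometric normalization and the comparison/agreement battery.

Implements body-surface-area normalization, diameter Z-scores against a
configurable normative model, normality-gated paired and two-group
comparisons (Kolmogorov–Smirnov gate at α = 0.05 selecting t-test vs
rank-based test), Pearson correlation, Cohen's kappa, and Bland–Altman
limits of agreement.  No multiple-testing correction is applied; each test
is reported at its own p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["NormativeModel", "TestResult", "BlandAltman", "compute_bsa",
           "zscore", "is_dilated", "compare_paired", "compare_groups",
           "pearson", "cohens_kappa", "bland_altman", "ks_normal"]

ALPHA_NORMALITY = 0.05


@dataclass
class NormativeModel:
    """Normative diameter model: mean and SD as polynomials of a predictor.

    ``mean_coeffs`` / ``sd_coeffs`` are polynomial coefficients in
    ascending order (mm, mm per predictor unit, ...); ``predictor`` is one
    of BSA (m²), height (cm) or age (years); ``valid_range`` bounds the
    predictor values the model was fitted on.
    """

    site: str
    predictor: str
    mean_coeffs: tuple
    sd_coeffs: tuple
    valid_range: tuple
    source: str = "synthetic example model"

    def mean(self, x: float) -> float:
        return float(np.polynomial.polynomial.polyval(x, self.mean_coeffs))

    def sd(self, x: float) -> float:
        s = float(np.polynomial.polynomial.polyval(x, self.sd_coeffs))
        if s <= 0:
            raise ValueError(f"normative SD non-positive at {self.predictor}={x}")
        return s


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: int
    normal: bool | None = None
    warning: str | None = None


@dataclass
class BlandAltman:
    bias: float
    lower: float
    upper: float
    sd_diff: float
    grand_mean: float

    @property
    def percent_of_mean(self) -> dict:
        gm = abs(self.grand_mean)
        if gm == 0:
            return {"bias": float("nan"), "lower": float("nan"),
                    "upper": float("nan")}
        return {k: 100.0 * abs(v) / gm
                for k, v in (("bias", self.bias), ("lower", self.lower),
                             ("upper", self.upper))}


def compute_bsa(height_cm: float, weight_kg: float,
                formula: str = "mosteller") -> float:
    """Body surface area, m².  Mosteller √(h·w/3600) default; DuBois optional."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    if formula == "dubois":
        return float(0.007184 * height_cm ** 0.725 * weight_kg ** 0.425)
    raise ValueError(f"unknown BSA formula {formula!r}")


def zscore(diameter_mm: float, predictor_value: float,
           model: NormativeModel) -> float:
    """Diameter Z-score: (observed − normative mean) / normative SD."""
    lo, hi = model.valid_range
    if not lo <= predictor_value <= hi:
        raise ValueError(
            f"{model.predictor}={predictor_value} outside the model's valid "
            f"range [{lo}, {hi}]")
    return float((diameter_mm - model.mean(predictor_value))
                 / model.sd(predictor_value))


def is_dilated(z: float, threshold: float = 2.0) -> bool:
    """Dilation rule: Z-score above 2 flags an enlarged vessel."""
    return z > threshold


def ks_normal(x: np.ndarray, alpha: float = ALPHA_NORMALITY) -> bool:
    """Kolmogorov–Smirnov normality gate on standardized data."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return True
    _, p = sps.kstest((x - x.mean()) / sd, "norm")
    return p >= alpha


def compare_paired(x1, x2) -> TestResult:
    """Paired comparison with a KS normality gate on the differences.

    Normal differences → two-sided paired t-test; otherwise Wilcoxon
    signed-rank.  All-zero differences yield p = 1 with a warning.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("paired samples must have equal length")
    n = len(x1)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    d = x2 - x1
    if np.allclose(d, 0):
        return TestResult("paired t-test", 0.0, 1.0, n, normal=True,
                          warning="all differences zero")
    if d.std(ddof=1) == 0:
        return TestResult("paired t-test", float("inf"), 0.0, n, normal=True,
                          warning="zero variance of non-zero differences")
    if ks_normal(d):
        t, p = sps.ttest_rel(x2, x1)
        return TestResult("paired t-test", float(t), float(p), n, normal=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = sps.wilcoxon(x2, x1)
    return TestResult("Wilcoxon signed-rank", float(w), float(p), n,
                      normal=False)


def compare_groups(x, y, equal_var: bool = True) -> TestResult:
    """Two-group comparison with a KS normality gate on each group.

    Both groups normal → two-sided two-sample t-test (pooled variance by
    default, Welch via ``equal_var=False``); otherwise Mann–Whitney U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need n >= 3 per group")
    n = len(x) + len(y)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if np.allclose(x.mean(), y.mean()):
            return TestResult("two-sample t-test", 0.0, 1.0, n, normal=True,
                              warning="identical constant groups")
        return TestResult("two-sample t-test", float("inf"), 0.0, n,
                          normal=True, warning="constant groups")
    if ks_normal(x) and ks_normal(y):
        t, p = sps.ttest_ind(x, y, equal_var=equal_var)
        name = "two-sample t-test" if equal_var else "Welch t-test"
        return TestResult(name, float(t), float(p), n, normal=True)
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult("Mann-Whitney U", float(u), float(p), n, normal=False)


def pearson(x, y) -> TestResult:
    """Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult("Pearson r", float(r), float(p), len(x))


def cohens_kappa(r1, r2) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e).

    ``r1``/``r2`` are equal-length categorical rating vectors; expected
    agreement comes from the product of the raters' marginal frequencies.
    Raises when both raters use a single shared category (κ undefined).
    """
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("ratings must be equal-length vectors")
    cats = np.union1d(r1, r2)
    if len(cats) < 2:
        raise ValueError("kappa undefined: a single shared category")
    n = len(r1)
    p_o = np.mean(r1 == r2)
    m1 = np.array([np.mean(r1 == c) for c in cats])
    m2 = np.array([np.mean(r2 == c) for c in cats])
    p_e = float(np.sum(m1 * m2))
    if p_e == 1.0:
        raise ValueError("kappa undefined: expected agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


def bland_altman(x1, x2) -> BlandAltman:
    """Limits of agreement between two paired measurements.

    bias = mean(x2 − x1); limits = bias ± 1.96·SD(differences);
    ``percent_of_mean`` expresses each relative to the grand mean of all
    measurements (the convention used for interobserver WSS agreement).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or len(x1) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    d = x2 - x1
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, lower=bias - 1.96 * sd,
                       upper=bias + 1.96 * sd, sd_diff=sd,
                       grand_mean=float(np.concatenate([x1, x2]).mean()))
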