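"""Allometric size correction of morphometric characters.

Body measurements of fish scale with total length (TL), so raw characters
mostly reflect size. The correction used here regresses ``log(character)`` on
``log(TL)`` within groups, estimates a common within-group slope ``b_c`` by
ANCOVA, and removes the length component:

    adjusted = ln(value) - b_c * (ln(length) - ln(ref_length))

i.e. every specimen is rescaled to the size-free shape it would have at the
reference length (by default the grand mean TL). Characters whose log-log
regression on TL is not significant bypass the correction (slope 0, pure log
transform).

The :class:`SizeAdjuster` estimator wraps this as a scikit-learn transformer;
the module-level functions are thin wrappers / building blocks around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._exceptions import DegenerateDesignError, InsufficientDataError

__all__ = [
    "CharacterRegression",
    "AncovaResult",
    "SizeAdjuster",
    "regress_on_length",
    "ancova_common_slope",
    "adjust_for_size",
    "flag_outliers_regression",
    "flag_outliers_boxplot",
]


@dataclass(frozen=True)
class CharacterRegression:
    """OLS fit of log(value) on log(length) for one character."""

    character: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class AncovaResult:
    """Slope-heterogeneity test and common within-group slope."""

    character: str
    f_interaction: float
    df: tuple[int, int]
    p_value: float
    common_slope: float


def _as_log_pair(values, lengths):
    values = np.asarray(values, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if values.shape != lengths.shape:
        raise ValueError("values and lengths must have the same shape")
    if np.any(lengths <= 0) or np.any(values <= 0):
        raise DegenerateDesignError("values and lengths must be positive")
    return np.log(values), np.log(lengths)


def regress_on_length(values, lengths, character: str = "") -> CharacterRegression:
    """OLS of log(value) on log(length) with a two-sided slope test."""
    y, x = _as_log_pair(values, lengths)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise InsufficientDataError("need at least 3 finite pairs")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("length vector is constant")
    if np.ptp(y) == 0:
        # constant character: no length relationship by definition
        return CharacterRegression(
            character=character, slope=0.0, intercept=float(y[0]),
            r_squared=0.0, p_value=1.0, n=int(x.size),
        )
    res = stats.linregress(x, y)
    return CharacterRegression(
        character=character,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def ancova_common_slope(values, lengths, groups, character: str = "") -> AncovaResult:
    """Slope-heterogeneity F (separate vs common slopes) and pooled slope.

    Both nested models carry separate intercepts per group; the interaction F
    compares the residual sums of squares of the common-slope model against
    the separate-slopes model.
    """
    y, x = _as_log_pair(values, lengths)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise InsufficientDataError("need at least 2 groups")
    sxx = sxy = syy = 0.0
    rss_sep = 0.0
    n = 0
    for g in levels:
        m = groups == g
        if m.sum() < 3:
            raise InsufficientDataError(f"group {g!r} has fewer than 3 specimens")
        xg, yg = x[m], y[m]
        xg_c, yg_c = xg - xg.mean(), yg - yg.mean()
        sxx_g = float(xg_c @ xg_c)
        if sxx_g == 0:
            raise DegenerateDesignError(f"length constant within group {g!r}")
        sxy_g = float(xg_c @ yg_c)
        syy_g = float(yg_c @ yg_c)
        sxx += sxx_g
        sxy += sxy_g
        syy += syy_g
        rss_sep += syy_g - sxy_g**2 / sxx_g
        n += int(m.sum())
    k = len(levels)
    common = sxy / sxx
    rss_common = syy - sxy**2 / sxx
    df1, df2 = k - 1, n - 2 * k
    num = max(rss_common - rss_sep, 0.0) / df1
    den = rss_sep / df2
    if den == 0.0:
        f = 0.0 if num <= 1e-12 else np.inf
    else:
        f = num / den
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return AncovaResult(character, float(f), (df1, df2), p, float(common))


def adjust_for_size(values, lengths, slope: float, ref_length: float):
    """Size-free log-scale values: ln(v) - slope * (ln(l) - ln(ref))."""
    y, x = _as_log_pair(values, lengths)
    if ref_length <= 0:
        raise DegenerateDesignError("ref_length must be positive")
    return y - slope * (x - np.log(ref_length))


def flag_outliers_regression(residuals: pd.DataFrame, threshold: float = 3.0):
    """Flag specimens with any |standardized residual| above *threshold*.

    Returns ``(flags, details)``: a boolean Series per specimen and a frame of
    (specimen, character, z) for each offence. Characters with zero residual
    variance are skipped with a warning.
    """
    residuals = pd.DataFrame(residuals)
    if not np.isfinite(residuals.to_numpy()).all():
        raise ValueError("residual matrix must be finite")
    flags = pd.Series(False, index=residuals.index)
    offences = []
    for char in residuals.columns:
        col = residuals[char]
        sd = col.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            warnings.warn(
                f"character {char!r} has zero residual variance; skipped",
                stacklevel=2,
            )
            continue
        z = (col - col.mean()) / sd
        hit = z.abs() > threshold
        flags |= hit
        for idx in residuals.index[hit]:
            offences.append(
                {"specimen": idx, "character": char, "z": float(z.loc[idx])}
            )
    details = pd.DataFrame(offences, columns=["specimen", "character", "z"])
    return flags, details


def flag_outliers_boxplot(counts: pd.DataFrame, k: float = 3.0):
    """Flag counts outside [Q1 - k*IQR, Q3 + k*IQR] per character.

    ``k = 3`` corresponds to the SPSS "extreme value" convention, ``k = 1.5``
    to ordinary boxplot outliers. Characters with zero IQR (near-constant
    discrete counts) are skipped: collapsed fences would flag every value
    away from the median, which is not an outlier statement.
    """
    counts = pd.DataFrame(counts)
    flags = pd.Series(False, index=counts.index)
    offences = []
    for char in counts.columns:
        col = counts[char].astype(float)
        q1, q3 = col.quantile(0.25), col.quantile(0.75)
        iqr = q3 - q1
        if iqr == 0:
            continue
        lo, hi = q1 - k * iqr, q3 + k * iqr
        hit = (col < lo) | (col > hi)
        flags |= hit
        for idx in counts.index[hit]:
            offences.append(
                {"specimen": idx, "character": char, "value": col.loc[idx]}
            )
    details = pd.DataFrame(offences, columns=["specimen", "character", "value"])
    return flags, details


class SizeAdjuster(BaseEstimator, TransformerMixin):
    """Remove allometric length effects from morphometric characters.

    Fit on a table whose ``length_col`` column holds total length; all other
    (numeric) columns are characters. When group labels are passed as ``y``,
    per-character common within-group slopes are estimated by ANCOVA;
    otherwise the pooled OLS slope is used. Characters whose log-log slope is
    not significant at ``alpha`` are only log-transformed (slope 0).

    Parameters
    ----------
    length_col : column name (DataFrame input) or index (array input).
    ref_length : reference length; defaults to the grand mean of the fit data.
    alpha : significance gate for the slope of log(char) on log(TL).

    Attributes
    ----------
    slopes_ : Series of slopes actually applied per character.
    regressions_ : DataFrame of per-character log-log OLS fits.
    ancova_ : DataFrame of slope-heterogeneity tests (when groups given).
    ref_length_ : reference length used by :meth:`transform`.
    """

    def __init__(self, length_col="TL_mm", ref_length: float | None = None,
                 alpha: float = 0.05):
        self.length_col = length_col
        self.ref_length = ref_length
        self.alpha = alpha

    def _split(self, X):
        X = pd.DataFrame(X)
        if self.length_col not in X.columns:
            raise KeyError(f"length column {self.length_col!r} not in input")
        lengths = X[self.length_col].to_numpy(dtype=float)
        chars = X.drop(columns=[self.length_col])
        return chars, lengths

    def fit(self, X, y=None):
        chars, lengths = self._split(X)
        self.feature_names_in_ = np.asarray(chars.columns, dtype=object)
        self.ref_length_ = (
            float(np.mean(lengths)) if self.ref_length is None
            else float(self.ref_length)
        )
        regs, ancovas, slopes = [], [], {}
        for char in chars.columns:
            reg = regress_on_length(chars[char], lengths, character=str(char))
            regs.append(reg)
            if reg.p_value >= self.alpha:
                slopes[char] = 0.0  # uncorrelated with length: log only
                continue
            if y is not None:
                anc = ancova_common_slope(
                    chars[char], lengths, y, character=str(char)
                )
                ancovas.append(anc)
                slopes[char] = anc.common_slope
            else:
                slopes[char] = reg.slope
        self.regressions_ = pd.DataFrame([vars(r) for r in regs]).set_index(
            "character"
        )
        self.ancova_ = (
            pd.DataFrame([vars(a) for a in ancovas]).set_index("character")
            if ancovas
            else pd.DataFrame(
                columns=["f_interaction", "df", "p_value", "common_slope"]
            )
        )
        self.slopes_ = pd.Series(slopes, name="slope")
        return self

    def transform(self, X):
        chars, lengths = self._split(X)
        out = {}
        for char in self.feature_names_in_:
            out[char] = adjust_for_size(
                chars[char], lengths, self.slopes_[char], self.ref_length_
            )
        return pd.DataFrame(out, index=chars.index)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(
            [f"adj_{c}" for c in self.feature_names_in_], dtype=object
        )
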