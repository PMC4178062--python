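"""Two-way multivariate screening of group and sex effects.

``manova_two_way`` runs a two-way crossed MANOVA (Pillai's trace and Wilks'
lambda with their standard F approximations) on a sum-to-zero coded design,
so with balanced cells the effect tests coincide with the usual Type-III
convention. ``per_variable_F`` gives the univariate follow-up per response,
and ``select_nondimorphic`` drops sexually dimorphic characters at a raw
alpha (no multiplicity correction — the screen is deliberately liberal, as is
conventional for dimorphism filtering before discriminant analysis).

``permanova_two_way`` is a permutational MANOVA on Euclidean distances of
z-scored variables: the sum of squares is partitioned sequentially over the
crossed design (orthogonal, hence exactly additive, and identical to Type III
under balance), the pseudo-F is MS_term / MS_residual, and the p-value comes
from free permutation of observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.manova import MANOVA as _SM_MANOVA

from ._exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    RankDeficiencyError,
)

__all__ = [
    "ManovaResult",
    "PermanovaResult",
    "manova_two_way",
    "per_variable_F",
    "select_nondimorphic",
    "permanova_two_way",
]


@dataclass(frozen=True)
class ManovaResult:
    """One effect of a (two-way) MANOVA."""

    effect: str
    pillai: float
    wilks: float
    f_pillai: float
    df_pillai: tuple[float, float]
    p_pillai: float
    f_wilks: float
    df_wilks: tuple[float, float]
    p_wilks: float
    partial_eta_squared: float  # Pillai V / s
    observed_power: float  # noncentral-F at alpha, SPSS convention


@dataclass(frozen=True)
class PermanovaResult:
    """One term of the PERMANOVA partition."""

    term: str
    df: int
    ss: float
    ms: float
    pseudo_f: float
    p_perm: float
    unique_perms: int
    n_perm: int
    seed: int | None


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def _sum_coded(labels):
    """Sum-to-zero (deviation) coding; returns (matrix n x (k-1), levels)."""
    labels = np.asarray(labels)
    levels = list(pd.unique(labels))
    k = len(levels)
    index = {lab: i for i, lab in enumerate(levels)}
    Z = np.zeros((labels.shape[0], max(k - 1, 0)))
    for row, lab in enumerate(labels):
        i = index[lab]
        if i < k - 1:
            Z[row, i] = 1.0
        else:
            Z[row, :] = -1.0
    return Z, levels


def _two_way_design(factor_a, factor_b):
    """Intercept + sum-coded A, B and interaction columns."""
    Za, levels_a = _sum_coded(factor_a)
    n = Za.shape[0]
    blocks = [np.ones((n, 1)), Za]
    spans = {"A": (1, 1 + Za.shape[1])}
    if factor_b is not None:
        Zb, levels_b = _sum_coded(factor_b)
        start = 1 + Za.shape[1]
        blocks.append(Zb)
        spans["B"] = (start, start + Zb.shape[1])
        inter = np.einsum("ni,nj->nij", Za, Zb).reshape(n, -1)
        start += Zb.shape[1]
        blocks.append(inter)
        spans["A:B"] = (start, start + inter.shape[1])
    else:
        levels_b = None
    return np.hstack(blocks), spans, levels_a, levels_b


def _check_cells(factor_a, factor_b):
    if factor_b is None:
        counts = pd.Series(factor_a).value_counts()
        if counts.min() < 1 or len(counts) < 2:
            raise InsufficientDataError("factor A needs >= 2 non-empty levels")
        return len(counts)
    tab = pd.crosstab(pd.Series(factor_a), pd.Series(factor_b))
    if (tab.to_numpy() == 0).any():
        raise InsufficientDataError("every cell of the A x B design must be non-empty")
    return tab.size


def _collinear_columns(X):
    """Indices of columns with near-zero pivots in a pivoted QR of centered X."""
    Xc = X - X.mean(axis=0)
    from scipy.linalg import qr

    _, R, piv = qr(Xc, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(Xc.shape) * np.finfo(float).eps if d.size else 0.0
    return sorted(int(piv[i]) for i in range(len(d)) if d[i] <= tol)


def manova_two_way(X, factor_a, factor_b=None, *, alpha: float = 0.05,
                   effect_names=("group", "sex")) -> dict[str, ManovaResult]:
    """Two-way crossed MANOVA; returns one result per effect (A, B, A x B).

    With ``factor_b=None`` a one-way MANOVA of factor A is run. Pillai's
    trace and Wilks' lambda are reported with their standard approximate F
    tests; the partial effect size is Pillai's V/s and observed power comes
    from the noncentral F implied by the sample F (lambda = F * df1).
    """
    X = pd.DataFrame(X)
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("responses must be finite")
    n, p = values.shape
    n_cells = _check_cells(factor_a, factor_b)
    if n <= p + n_cells:
        raise InsufficientDataError(
            f"n = {n} too small for p = {p} responses and {n_cells} cells"
        )
    if np.linalg.matrix_rank(values - values.mean(axis=0)) < p:
        cols = _collinear_columns(values)
        names = [str(X.columns[i]) for i in cols]
        raise RankDeficiencyError(f"collinear response columns: {names}")
    exog, spans, _, _ = _two_way_design(factor_a, factor_b)
    name_a, name_b = effect_names
    labels = {"A": name_a, "B": name_b, "A:B": f"{name_a}:{name_b}"}
    if p == 1:
        return _manova_univariate(values[:, 0], exog, spans, labels, alpha)
    mod = _SM_MANOVA(values, exog)
    hypotheses = []
    for key, (lo, hi) in spans.items():
        L = np.zeros((hi - lo, exog.shape[1]))
        L[np.arange(hi - lo), np.arange(lo, hi)] = 1.0
        hypotheses.append((labels[key], L))
    res = mod.mv_test(hypotheses=hypotheses)
    out: dict[str, ManovaResult] = {}
    for key, (lo, hi) in spans.items():
        name = labels[key]
        st = res.results[name]["stat"]
        pillai = st.loc["Pillai's trace"]
        wilks = st.loc["Wilks' lambda"]
        q = hi - lo
        s = min(p, q)
        f_p, df1_p, df2_p = (
            float(pillai["F Value"]),
            float(pillai["Num DF"]),
            float(pillai["Den DF"]),
        )
        crit = stats.f.isf(alpha, df1_p, df2_p)
        power = float(stats.ncf.sf(crit, df1_p, df2_p, f_p * df1_p))
        out[name] = ManovaResult(
            effect=name,
            pillai=float(pillai["Value"]),
            wilks=float(wilks["Value"]),
            f_pillai=f_p,
            df_pillai=(df1_p, df2_p),
            p_pillai=float(pillai["Pr > F"]),
            f_wilks=float(wilks["F Value"]),
            df_wilks=(float(wilks["Num DF"]), float(wilks["Den DF"])),
            p_wilks=float(wilks["Pr > F"]),
            partial_eta_squared=float(pillai["Value"]) / s,
            observed_power=power,
        )
    return out


def _manova_univariate(y, exog, spans, labels, alpha):
    """Single response: every multivariate statistic collapses to ANOVA F."""
    out = {}
    n, k_full = exog.shape
    rss_full = _rss(exog, y)
    scale = float(((y - y.mean()) ** 2).sum())
    df2 = n - k_full
    for key, (lo, hi) in spans.items():
        keep = [j for j in range(k_full) if not (lo <= j < hi)]
        rss_red = _rss(exog[:, keep], y)
        q = hi - lo
        ss_h = max(rss_red - rss_full, 0.0)
        denom = ss_h + rss_full
        v = ss_h / denom if denom > scale * 1e-14 else 0.0
        f = _safe_f(ss_h / q, rss_full / df2 if df2 else 0.0, scale)
        p_val = float(stats.f.sf(f, q, df2)) if np.isfinite(f) else 0.0
        crit = stats.f.isf(alpha, q, df2)
        power = float(stats.ncf.sf(crit, q, df2, f * q)) if np.isfinite(f) \
            else 1.0
        out[labels[key]] = ManovaResult(
            effect=labels[key], pillai=v, wilks=1.0 - v, f_pillai=f,
            df_pillai=(float(q), float(df2)), p_pillai=p_val, f_wilks=f,
            df_wilks=(float(q), float(df2)), p_wilks=p_val,
            partial_eta_squared=v, observed_power=power,
        )
    return out


def _safe_f(num, den, scale):
    """F ratio with a relative-tolerance guard for zero-residual fits."""
    if den <= scale * 1e-14:
        return 0.0 if num <= scale * 1e-14 else np.inf
    return num / den


def per_variable_F(X, factor, other=None) -> pd.DataFrame:
    """Univariate two-way model F for *factor*, one row per response column.

    *other* is the second crossed factor (plus interaction) adjusted for; with
    ``other=None`` this is a one-way ANOVA per column. Returns a frame with
    columns F, df1, df2, p indexed by variable.
    """
    X = pd.DataFrame(X)
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("responses must be finite")
    # full design: factor of interest is "A" here
    exog, spans, _, _ = _two_way_design(factor, other)
    lo, hi = spans["A"]
    keep = [j for j in range(exog.shape[1]) if not (lo <= j < hi)]
    reduced = exog[:, keep]
    n, k_full = exog.shape
    q = hi - lo
    rows = []
    for j, col in enumerate(X.columns):
        y = values[:, j]
        rss_full = _rss(exog, y)
        rss_red = _rss(reduced, y)
        df2 = n - k_full
        scale = float(((y - y.mean()) ** 2).sum())
        f = _safe_f(max(rss_red - rss_full, 0.0) / q, rss_full / df2, scale)
        p = float(stats.f.sf(f, q, df2)) if np.isfinite(f) else 0.0
        rows.append({"variable": str(col), "F": float(f), "df1": q,
                     "df2": df2, "p": p})
    return pd.DataFrame(rows).set_index("variable")


def _rss(design, y):
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def select_nondimorphic(per_variable: pd.DataFrame, alpha: float = 0.05):
    """Retain variables with p >= alpha for the sex effect.

    Accepts the frame from :func:`per_variable_F` (or anything with a ``p``
    column); returns ``(retained, removed)`` lists of variable names.
    """
    if len(per_variable) == 0:
        raise ValueError("per-variable results are empty")
    p = per_variable["p"]
    retained = [str(v) for v in per_variable.index[p >= alpha]]
    removed = [str(v) for v in per_variable.index[p < alpha]]
    return retained, removed


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _projector(design):
    q, _ = np.linalg.qr(design)
    return q @ q.T


def permanova_two_way(X, factor_a, factor_b=None, *, n_perm: int = 9999,
                      seed: int | None = None, standardize: bool = True,
                      effect_names=("group", "sex")) -> dict[str, PermanovaResult]:
    """Permutational MANOVA (Euclidean distances on z-scored variables).

    Sequential orthogonal SS partition over the crossed design; pseudo-F is
    MS_term / MS_residual; p = (# permuted F >= observed + 1) / (n_perm + 1)
    under free permutation of observations. Also reports residual and total
    rows (ss only) and the number of unique permutations encountered.
    """
    if n_perm < 99:
        raise ValueError("n_perm < 99 gives unstable permutation p-values")
    X = pd.DataFrame(X)
    values = X.to_numpy(dtype=float)
    if standardize:
        sd = values.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            dropped = [str(c) for c, z in zip(X.columns, zero) if z]
            warnings.warn(
                f"dropping zero-variance columns: {dropped}", stacklevel=2
            )
            values = values[:, ~zero]
            sd = sd[~zero]
        if values.shape[1] == 0:
            raise DegenerateInputError("no variable carries any variation")
        values = (values - values.mean(axis=0)) / sd
    n = values.shape[0]
    centered = values - values.mean(axis=0)
    total_ss = float((centered**2).sum())
    if total_ss <= 0:
        raise DegenerateInputError("all pairwise distances are zero")

    name_a, name_b = effect_names
    Za, levels_a = _sum_coded(factor_a)
    ones = np.ones((n, 1))
    designs = [("intercept", ones)]
    terms = []
    cum = ones
    for label, block, df in _term_blocks(Za, factor_a, factor_b, name_a, name_b):
        prev = _projector(cum)
        cum = np.hstack([cum, block])
        proj = _projector(cum) - prev
        terms.append((label, proj, df))
    p_full = _projector(cum)
    resid_proj = np.eye(n) - p_full
    df_resid = n - int(round(np.trace(p_full)))
    if df_resid <= 0:
        raise InsufficientDataError("no residual degrees of freedom")

    def term_ss(Y):
        return [float(np.sum((proj @ Y) * Y)) for _, proj, _ in terms]

    obs_ss = term_ss(values)
    resid_ss = float(np.sum((resid_proj @ values) * values))
    ms_resid = resid_ss / df_resid
    obs_f = [
        (ss / df) / ms_resid for ss, (_, _, df) in zip(obs_ss, terms)
    ]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    seen = set()
    for _ in range(n_perm):
        perm = rng.permutation(n)
        seen.add(perm.tobytes())
        Yp = values[perm]
        ss_p = term_ss(Yp)
        resid_p = float(np.sum((resid_proj @ Yp) * Yp))
        ms_r = resid_p / df_resid
        for i, (_, _, df) in enumerate(terms):
            f_p = (ss_p[i] / df) / ms_r
            if f_p >= obs_f[i] - 1e-12:
                exceed[i] += 1
    unique = len(seen)

    out: dict[str, PermanovaResult] = {}
    for i, (label, _, df) in enumerate(terms):
        out[label] = PermanovaResult(
            term=label,
            df=df,
            ss=obs_ss[i],
            ms=obs_ss[i] / df,
            pseudo_f=obs_f[i],
            p_perm=float((exceed[i] + 1) / (n_perm + 1)),
            unique_perms=unique,
            n_perm=n_perm,
            seed=seed,
        )
    out["Residual"] = PermanovaResult(
        "Residual", df_resid, resid_ss, ms_resid, np.nan, np.nan, unique,
        n_perm, seed,
    )
    out["Total"] = PermanovaResult(
        "Total", n - 1, total_ss, np.nan, np.nan, np.nan, unique, n_perm, seed,
    )
    return out


def _term_blocks(Za, factor_a, factor_b, name_a, name_b):
    yield name_a, Za, Za.shape[1]
    if factor_b is not None:
        Zb, _ = _sum_coded(factor_b)
        yield name_b, Zb, Zb.shape[1]
        inter = np.einsum("ni,nj->nij", Za, Zb).reshape(Za.shape[0], -1)
        yield f"{name_a}:{name_b}", inter, inter.shape[1]
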