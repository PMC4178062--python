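"""Stepwise multiple discriminant analysis with Mahalanobis-D2 selection.

The classifier is a canonical (Fisher) discriminant analysis preceded by
SPSS-style stepwise variable selection: at each step the candidate that
maximizes the MINIMUM pairwise Mahalanobis D2 between groups enters, provided
its partial F-to-enter (from the Wilks'-lambda ratio of the nested variable
sets) clears the threshold; included variables whose partial F falls below
the removal threshold leave again. Discriminant functions come from the
generalized eigenproblem ``B v = lambda W v`` (between/within scatter) and are
scaled to unit pooled within-group score variance. Classification is nearest
group centroid in discriminant space with equal priors; ties break towards
the lowest group index (deterministic by contract).

:class:`StepwiseDiscriminantAnalysis` is the scikit-learn estimator; the
module-level functions are thin wrappers over it (or small self-contained
statistics such as Press's Q).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, ClassifierMixin

from ._exceptions import InsufficientDataError, SingularMatrixError

__all__ = [
    "StepRecord",
    "StepTrace",
    "ClassificationTable",
    "PressQ",
    "StepwiseDiscriminantAnalysis",
    "stratified_subsample",
    "scatter_matrices",
    "mahalanobis_d2",
    "stepwise_select",
    "fit_discriminant",
    "loocv_confusion",
    "press_q",
    "potency_index",
    "score_size_independence",
]

F_ENTER_DEFAULT = 3.84  # SPSS stepwise defaults
F_REMOVE_DEFAULT = 2.71


@dataclass(frozen=True)
class StepRecord:
    variable: object
    action: str  # "enter" | "remove"
    f_statistic: float
    min_d2: float


@dataclass
class StepTrace:
    steps: list[StepRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(s) for s in self.steps],
            columns=["variable", "action", "f_statistic", "min_d2"],
        )


@dataclass(frozen=True)
class PressQ:
    """Press's Q statistic: (N - n K)^2 / (N (K - 1)), chi-square on 1 df."""

    q: float
    df: int
    p_value: float


@dataclass
class ClassificationTable:
    """K x K confusion counts (rows = true group, columns = predicted)."""

    counts: pd.DataFrame
    n_classes: int
    n_total: int
    n_correct: int
    percent_correct: pd.Series
    overall_percent: float

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ClassificationTable":
        counts = pd.DataFrame(counts)
        mat = counts.to_numpy()
        row_sums = mat.sum(axis=1)
        diag = np.diag(mat)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(row_sums > 0, 100.0 * diag / row_sums, np.nan)
        return cls(
            counts=counts,
            n_classes=counts.shape[0],
            n_total=int(mat.sum()),
            n_correct=int(diag.sum()),
            percent_correct=pd.Series(pct, index=counts.index),
            overall_percent=100.0 * diag.sum() / mat.sum(),
        )


# ---------------------------------------------------------------------------
# plumbing statistics
# ---------------------------------------------------------------------------

def stratified_subsample(table: pd.DataFrame, *, group_col: str = "group",
                         strata_cols=("river", "sex"),
                         targets: dict | None = None,
                         seed: int | None = None) -> pd.DataFrame:
    """Reduce groups to target sizes with proportional stratified allocation.

    For each group with a target below its size, stratum quotas follow
    largest-remainder rounding of the proportional shares; specimens are then
    drawn without replacement within strata. Groups without a target (or with
    target >= size) are kept whole. Deterministic given *seed*.
    """
    targets = targets or {}
    rng = np.random.default_rng(seed)
    pieces = []
    for g, gdf in table.groupby(group_col, sort=False):
        target = targets.get(g)
        if target is None or target >= len(gdf):
            pieces.append(gdf)
            continue
        if target <= 0:
            raise ValueError(f"target for group {g!r} must be positive")
        strata = gdf.groupby(list(strata_cols), sort=True)
        keys = list(strata.groups)
        sizes = np.array([len(strata.get_group(k)) for k in keys])
        quotas = _largest_remainder(target * sizes / sizes.sum())
        # cap at stratum size and push the excess to the largest remainders
        over = quotas - sizes
        if (over > 0).any():
            import warnings

            warnings.warn(
                f"group {g!r}: stratum quota exceeded stratum size; "
                "reallocating", stacklevel=2,
            )
            excess = int(over[over > 0].sum())
            quotas = np.minimum(quotas, sizes)
            room = sizes - quotas
            order = np.argsort(-room, kind="stable")
            for idx in order:
                take = min(excess, room[idx])
                quotas[idx] += take
                excess -= take
                if excess == 0:
                    break
        for k, q in zip(keys, quotas):
            sdf = strata.get_group(k)
            if q >= len(sdf):
                pieces.append(sdf)
            elif q > 0:
                pick = rng.choice(len(sdf), size=int(q), replace=False)
                pieces.append(sdf.iloc[np.sort(pick)])
    return pd.concat(pieces).sort_index()


def _largest_remainder(shares: np.ndarray) -> np.ndarray:
    base = np.floor(shares).astype(int)
    rem = shares - base
    short = int(round(shares.sum())) - int(base.sum())
    order = np.argsort(-rem, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base


def scatter_matrices(X, y):
    """Pooled within-group (W) and between-group (B) scatter; W + B = total.

    Raises :class:`SingularMatrixError` when W is rank-deficient (collinear
    variables are named by index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes = pd.unique(y)
    k = len(classes)
    if any((y == c).sum() < 2 for c in classes):
        raise InsufficientDataError("every group needs at least 2 specimens")
    if n - k < p:
        raise InsufficientDataError(
            f"n - K = {n - k} < p = {p}: within scatter would be singular"
        )
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for c in classes:
        block = X[y == c]
        mu = block.mean(axis=0)
        d = block - mu
        W += d.T @ d
        offset = (mu - grand)[:, None]
        B += len(block) * (offset @ offset.T)
    if k > 1 and np.linalg.matrix_rank(W) < p:
        from .screening import _collinear_columns

        raise SingularMatrixError(
            f"within-group scatter is singular; collinear variables "
            f"(column indices): {_collinear_columns(X)}"
        )
    return W, B


def mahalanobis_d2(mean_i, mean_j, pooled_cov) -> float:
    """D2 = (m_i - m_j)' S^-1 (m_i - m_j) with S positive definite."""
    d = np.asarray(mean_i, float) - np.asarray(mean_j, float)
    S = np.asarray(pooled_cov, float)
    try:
        c = linalg.cho_factor(S)
    except linalg.LinAlgError as err:
        raise SingularMatrixError(
            "pooled covariance is not positive definite"
        ) from err
    return float(d @ linalg.cho_solve(c, d))


# ---------------------------------------------------------------------------
# stepwise machinery (shared by the estimator)
# ---------------------------------------------------------------------------

class _StepwiseState:
    """Group means and scatter blocks for fast subset statistics."""

    def __init__(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes = np.array(sorted(pd.unique(y).tolist()))
        self.n, self.p = X.shape
        self.k = len(self.classes)
        grand = X.mean(axis=0)
        self.means = np.array(
            [X[y == c].mean(axis=0) for c in self.classes]
        )
        self.W = np.zeros((self.p, self.p))
        for c in self.classes:
            d = X[y == c] - X[y == c].mean(axis=0)
            self.W += d.T @ d
        dall = X - grand
        self.T = dall.T @ dall

    def wilks(self, subset) -> float:
        if not subset:
            return 1.0
        idx = np.ix_(subset, subset)
        sw, ldw = np.linalg.slogdet(self.W[idx])
        st, ldt = np.linalg.slogdet(self.T[idx])
        if sw <= 0 or st <= 0:
            return np.nan
        return float(np.exp(ldw - ldt))

    def min_d2(self, subset) -> float:
        idx = np.ix_(subset, subset)
        S = self.W[idx] / (self.n - self.k)
        try:
            c = linalg.cho_factor(S)
        except linalg.LinAlgError:
            return np.nan
        best = np.inf
        for i in range(self.k):
            for j in range(i + 1, self.k):
                d = self.means[i, subset] - self.means[j, subset]
                best = min(best, float(d @ linalg.cho_solve(c, d)))
        return best

    def partial_f(self, lam_small, lam_big, n_in_small) -> float:
        """F for adding one variable to a set of size n_in_small."""
        ratio = lam_big / lam_small
        df1 = self.k - 1
        df2 = self.n - self.k - n_in_small
        if df2 <= 0 or not np.isfinite(ratio) or ratio <= 0:
            return np.nan
        return (df2 / df1) * (1.0 - ratio) / ratio


def _run_stepwise(state: _StepwiseState, f_enter, f_remove, max_steps):
    selected: list[int] = []
    trace = StepTrace()
    max_steps = max_steps or 2 * state.p
    seen_states = set()
    for _ in range(max_steps):
        key = tuple(sorted(selected))
        if key in seen_states:
            break
        seen_states.add(key)
        lam_cur = state.wilks(selected)
        # --- entry: best min-D2 among candidates clearing F-to-enter
        best_var, best_d2, best_f = None, -np.inf, np.nan
        for v in range(state.p):
            if v in selected:
                continue
            lam_new = state.wilks(selected + [v])
            if not np.isfinite(lam_new):
                continue
            f_in = state.partial_f(lam_cur, lam_new, len(selected))
            if not np.isfinite(f_in) or f_in < f_enter:
                continue
            d2 = state.min_d2(selected + [v])
            if np.isfinite(d2) and d2 > best_d2:
                best_var, best_d2, best_f = v, d2, f_in
        changed = False
        if best_var is not None:
            selected.append(best_var)
            trace.steps.append(
                StepRecord(best_var, "enter", best_f, best_d2)
            )
            changed = True
        # --- removal: drop variables whose partial F fell below threshold
        while len(selected) > 1:
            lam_full = state.wilks(selected)
            worst_var, worst_f = None, np.inf
            for v in selected:
                rest = [u for u in selected if u != v]
                lam_rest = state.wilks(rest)
                f_out = state.partial_f(lam_rest, lam_full, len(rest))
                if np.isfinite(f_out) and f_out < worst_f:
                    worst_var, worst_f = v, f_out
            if worst_var is None or worst_f >= f_remove:
                break
            selected.remove(worst_var)
            trace.steps.append(
                StepRecord(
                    worst_var, "remove", worst_f,
                    state.min_d2(selected) if selected else np.nan,
                )
            )
            changed = True
        if not changed:
            break
    return trace, selected


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class StepwiseDiscriminantAnalysis(BaseEstimator, ClassifierMixin):
    """Canonical discriminant analysis with optional stepwise selection.

    Parameters
    ----------
    select : run stepwise Mahalanobis-D2 selection (default). With
        ``select=False`` the variable set is fixed: either ``variables`` or
        all columns.
    variables : explicit variable set (names for DataFrame input, indices
        otherwise) used when ``select=False``.
    f_enter, f_remove : partial-F thresholds of the stepwise procedure
        (defaults 3.84 / 2.71, the SPSS convention). ``f_enter`` must exceed
        ``f_remove``.
    max_steps : cap on stepwise iterations (default ``2 p``).

    Attributes (after fit)
    ----------------------
    classes_, selected_, step_trace_, eigenvalues_,
    explained_variance_ratio_, scalings_ (variables x functions, unit pooled
    within-group score variance), centroids_, loadings_ (pooled within-group
    variable-score correlations), potency_index_, wilks_lambda_, chi2_,
    chi2_df_, chi2_p_.
    """

    def __init__(self, select: bool = True, variables=None,
                 f_enter: float = F_ENTER_DEFAULT,
                 f_remove: float = F_REMOVE_DEFAULT,
                 max_steps: int | None = None):
        self.select = select
        self.variables = variables
        self.f_enter = f_enter
        self.f_remove = f_remove
        self.max_steps = max_steps

    # -- helpers ---------------------------------------------------------
    def _resolve_columns(self, X):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            return X.to_numpy(dtype=float)
        self.feature_names_in_ = None
        return np.asarray(X, dtype=float)

    def _variable_indices(self, values):
        if self.variables is None:
            return list(range(values.shape[1]))
        if self.feature_names_in_ is not None:
            names = list(self.feature_names_in_)
            missing = [v for v in self.variables if v not in names]
            if missing:
                raise KeyError(f"variables not in input: {missing}")
            return [names.index(v) for v in self.variables]
        return [int(v) for v in self.variables]

    def fit(self, X, y):
        values = self._resolve_columns(X)
        y = np.asarray(y)
        if values.ndim != 2 or values.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        if not np.isfinite(values).all():
            raise ValueError("X must be finite")
        if self.select and not self.f_enter > self.f_remove:
            raise ValueError("f_enter must exceed f_remove")
        self.classes_ = np.array(sorted(pd.unique(y).tolist()))
        if len(self.classes_) < 2:
            raise InsufficientDataError("need at least 2 groups")
        state = _StepwiseState(values, y)
        if self.select:
            self.step_trace_, sel = _run_stepwise(
                state, self.f_enter, self.f_remove, self.max_steps
            )
            if self.feature_names_in_ is not None:
                self.step_trace_ = StepTrace([
                    StepRecord(self.feature_names_in_[r.variable], r.action,
                               r.f_statistic, r.min_d2)
                    for r in self.step_trace_.steps
                ])
        else:
            sel = self._variable_indices(values)
            if not sel:
                raise ValueError("variables must be non-empty")
            self.step_trace_ = StepTrace()
        self.selected_idx_ = list(sel)
        self.selected_ = self._selected_names()
        if not sel:
            # legal outcome of the stepwise run; no discriminant functions
            self.eigenvalues_ = np.array([])
            self.explained_variance_ratio_ = np.array([])
            return self
        self._fit_canonical(values, y, sel)
        return self

    def _selected_names(self):
        if self.feature_names_in_ is not None:
            return [self.feature_names_in_[i] for i in self.selected_idx_]
        return list(self.selected_idx_)

    def _fit_canonical(self, values, y, sel):
        Xs = values[:, sel]
        n, p = Xs.shape
        k = len(self.classes_)
        W, B = scatter_matrices(Xs, y)
        m = min(p, k - 1)
        try:
            evals, evecs = linalg.eigh(B, W)
        except linalg.LinAlgError as err:
            raise SingularMatrixError(
                "within-group scatter singular on selected variables"
            ) from err
        order = np.argsort(evals)[::-1][:m]
        lam = np.clip(evals[order], 0.0, None)
        V = evecs[:, order]
        # eigh normalizes v' W v = 1; rescale to unit pooled within variance
        coef = V * np.sqrt(n - k)
        S_w = W / (n - k)
        grand = Xs.mean(axis=0)
        scores = (Xs - grand) @ coef
        centroids = np.array(
            [scores[y == c].mean(axis=0) for c in self.classes_]
        )
        sd_vars = np.sqrt(np.diag(S_w))
        loadings = (S_w @ coef) / sd_vars[:, None]
        # sign convention: largest-|loading| of each function positive
        for f in range(m):
            j = int(np.argmax(np.abs(loadings[:, f])))
            if loadings[j, f] < 0:
                coef[:, f] *= -1
                loadings[:, f] *= -1
                centroids[:, f] *= -1
                scores[:, f] *= -1
        shares = lam / lam.sum() if lam.sum() > 0 else np.full(m, np.nan)
        self.eigenvalues_ = lam
        self.explained_variance_ratio_ = shares
        self.scalings_ = coef
        self.intercept_means_ = grand
        self.centroids_ = centroids
        self.loadings_ = loadings
        self.potency_index_ = potency_index(loadings, shares)
        self.wilks_lambda_ = float(np.prod(1.0 / (1.0 + lam)))
        self.chi2_df_ = p * (k - 1)
        factor = n - 1 - (p + k) / 2.0
        self.chi2_ = float(-factor * np.log(self.wilks_lambda_))
        self.chi2_p_ = float(stats.chi2.sf(self.chi2_, self.chi2_df_))
        return self

    # -- inference -------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "selected_idx_"):
            raise AttributeError("estimator is not fitted")
        if not self.selected_idx_:
            raise ValueError(
                "no discriminating variables were selected; "
                "cannot transform or predict"
            )

    def _subset(self, X):
        if isinstance(X, pd.DataFrame):
            if self.feature_names_in_ is not None:
                missing = [
                    v for v in self.selected_ if v not in X.columns
                ]
                if missing:
                    raise KeyError(f"missing variables: {missing}")
                return X[self.selected_].to_numpy(dtype=float)
            return X.to_numpy(dtype=float)[:, self.selected_idx_]
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] == len(self.selected_idx_):
            return X  # already restricted to the selected variables
        return X[:, self.selected_idx_]

    def transform(self, X):
        """Discriminant scores (n x n_functions)."""
        self._check_fitted()
        Xs = self._subset(X)
        return (Xs - self.intercept_means_) @ self.scalings_

    def predict(self, X):
        """Nearest-centroid assignment; ties to the lowest group index."""
        scores = self.transform(X)
        d2 = (
            (scores[:, None, :] - self.centroids_[None, :, :]) ** 2
        ).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]


# ---------------------------------------------------------------------------
# thin wrappers
# ---------------------------------------------------------------------------

def stepwise_select(X, y, f_enter: float = F_ENTER_DEFAULT,
                    f_remove: float = F_REMOVE_DEFAULT,
                    max_steps: int | None = None):
    """Stepwise Mahalanobis-D2 selection; returns (StepTrace, selected)."""
    est = StepwiseDiscriminantAnalysis(
        select=True, f_enter=f_enter, f_remove=f_remove, max_steps=max_steps
    ).fit(X, y)
    return est.step_trace_, est.selected_


def fit_discriminant(X, y, selected=None) -> StepwiseDiscriminantAnalysis:
    """Fit the canonical discriminant model on a fixed variable set."""
    return StepwiseDiscriminantAnalysis(select=False, variables=selected).fit(
        X, y
    )


def loocv_confusion(X, y, selected=None) -> ClassificationTable:
    """Leave-one-out cross-validated confusion table (fixed variable set).

    Each specimen is classified by a model refit on the remaining n - 1;
    raises when a fold would leave a group with fewer than 2 members.
    """
    values = (
        X[selected].to_numpy(dtype=float)
        if isinstance(X, pd.DataFrame) and selected is not None
        else np.asarray(X, dtype=float)
    )
    if isinstance(X, pd.DataFrame) and selected is None:
        values = X.to_numpy(dtype=float)
    y = np.asarray(y)
    classes = np.array(sorted(pd.unique(y).tolist()))
    counts = {c: (y == c).sum() for c in classes}
    if min(counts.values()) < 3:
        raise InsufficientDataError(
            "LOOCV needs every group to keep >= 2 members in each fold"
        )
    n = values.shape[0]
    mat = pd.DataFrame(0, index=classes, columns=classes)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        est = StepwiseDiscriminantAnalysis(select=False).fit(
            values[mask], y[mask]
        )
        pred = est.predict(values[i])[0]
        mat.loc[y[i], pred] += 1
        mask[i] = True
    return ClassificationTable.from_counts(mat)


def press_q(table: ClassificationTable) -> PressQ:
    """Press's Q for a confusion table: (N - n K)^2 / (N (K - 1))."""
    N, n, k = table.n_total, table.n_correct, table.n_classes
    if N <= 0 or k < 2:
        raise ValueError("need N > 0 and K >= 2")
    q = (N - n * k) ** 2 / (N * (k - 1))
    return PressQ(q=float(q), df=1, p_value=float(stats.chi2.sf(q, 1)))


def potency_index(loadings, shares) -> np.ndarray:
    """PI_j = sum_f loading_jf^2 * share_f (overall discriminatory weight)."""
    loadings = np.asarray(loadings, dtype=float)
    shares = np.asarray(shares, dtype=float)
    return (loadings**2) @ shares


def score_size_independence(scores, lengths) -> pd.DataFrame:
    """Per-function OLS of discriminant scores on total length (r2, p)."""
    scores = np.asarray(scores, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    rows = []
    for f in range(scores.shape[1]):
        y = scores[:, f]
        if np.ptp(y) == 0 or np.ptp(lengths) == 0:
            rows.append({"function": f + 1, "r_squared": 0.0,
                         "df": len(y) - 2, "p": 1.0})
            continue
        res = stats.linregress(lengths, y)
        rows.append({
            "function": f + 1,
            "r_squared": float(res.rvalue**2),
            "df": len(y) - 2,
            "p": float(res.pvalue),
        })
    return pd.DataFrame(rows).set_index("function")
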