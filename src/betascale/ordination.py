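"""Canonical redundancy analysis (RDA) with permutation inference.

RDA here is multivariate least squares of a column-centered response table
Y (typically Hellinger-transformed abundances) on standardized predictors,
with explained variance measured against the total variance of Y:

    R^2 = SS(fitted) / SS_total,
    F   = (SS_fit / m) / (SS_res / (n - m - 1)),

and the Ezekiel adjustment R^2_adj = 1 - (1 - R^2)(n - 1)/(n - m - 1).
Significance comes from permutation: rows of Y are permuted directly, or —
when a conditioning matrix W is given — the residuals of Y on W are permuted
(reduced-model residual permutation). Forward selection follows the
double-stopping rule: a global test of all candidates gates the procedure,
each entering variable must pass a partial permutation test at alpha, and
the cumulative adjusted R^2 may not exceed the global model's.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .io import ValidationError

_RANK_TOL = 1e-9


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel-adjusted R^2; equals R^2 when m = 0; may be negative."""
    if m == 0:
        return float(r2)
    if n <= m + 1:
        raise ValidationError(f"adjusted R^2 undefined for n={n}, m={m}")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - m - 1))


def _as_matrix(A, what: str) -> np.ndarray:
    if A is None:
        return None
    M = A.to_numpy(dtype=float) if hasattr(A, "to_numpy") else np.asarray(A, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.ndim != 2:
        raise ValidationError(f"{what} must be a 2-d matrix")
    return M


def _column_names(A, m: int, prefix: str) -> list[str]:
    if hasattr(A, "columns"):
        return [str(c) for c in A.columns]
    return [f"{prefix}{j}" for j in range(m)]


def _orthonormal_basis(X: np.ndarray, names: list[str]) -> np.ndarray:
    """QR basis of the column space; raises naming collinear columns."""
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0))
    Q, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > _RANK_TOL * max(diag[0], 1e-300)).sum()) if len(diag) else 0
    if rank < X.shape[1]:
        dropped = [names[j] for j in piv[rank:]]
        raise ValidationError(
            f"predictor matrix is rank-deficient; collinear column(s): {dropped}"
        )
    return Q[:, :rank]


@dataclass
class PermutationTest:
    """Result of a permutation F-test."""

    statistic: float
    pvalue: float
    n_perm: int
    degenerate: bool = False


class RDA:
    """Redundancy analysis of Y on X, optionally partialling out W.

    Parameters
    ----------
    Y : (n, p) array or DataFrame
        Response table; columns are centered internally.
    X : (n, m) array or DataFrame
        Predictors; standardized to z-scores internally (``standardize``).
    condition : optional (n, q) matrix W
        Covariables to partial out of both Y and X (partial RDA); R^2 is
        then the semipartial fraction of the *total* variance of Y.
    """

    def __init__(self, Y, X, condition=None, standardize: bool = True):
        Ym = _as_matrix(Y, "Y")
        Xm = _as_matrix(X, "X")
        Wm = _as_matrix(condition, "condition") if condition is not None else None
        n = Ym.shape[0]
        if Xm.shape[0] != n or (Wm is not None and Wm.shape[0] != n):
            raise ValidationError("Y, X and condition must have matching row counts")
        self.nobs = n
        self.x_names = _column_names(X, Xm.shape[1], "x")

        self._Yc = Ym - Ym.mean(axis=0)
        self.ss_total = float((self._Yc**2).sum())
        if self.ss_total <= 0:
            raise ValidationError("Y has zero total variance")

        Xc = Xm - Xm.mean(axis=0)
        if standardize:
            sd = Xc.std(axis=0, ddof=1)
            const = sd <= 0
            if const.any():
                raise ValidationError(
                    f"constant predictor column(s): {[self.x_names[j] for j in np.flatnonzero(const)]}"
                )
            Xc = Xc / sd

        if Wm is not None and Wm.shape[1] > 0:
            Wc = Wm - Wm.mean(axis=0)
            self._Qw = _orthonormal_basis(Wc, _column_names(condition, Wm.shape[1], "w"))
        else:
            self._Qw = None
        self.n_condition = 0 if self._Qw is None else self._Qw.shape[1]

        if self._Qw is not None:
            self._Yr = self._Yc - self._Qw @ (self._Qw.T @ self._Yc)
            Xc = Xc - self._Qw @ (self._Qw.T @ Xc)
        else:
            self._Yr = self._Yc
        self._Q = _orthonormal_basis(Xc, self.x_names)
        self.n_predictors = self._Q.shape[1]
        if n <= self.n_predictors + self.n_condition + 1:
            raise ValidationError(
                f"too few observations (n={n}) for m={self.n_predictors} predictors"
                + (f" and q={self.n_condition} covariables" if self.n_condition else "")
            )

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "RDAResults":
        proj = self._Q @ (self._Q.T @ self._Yr)
        ss_fit = float((proj**2).sum())
        ss_resid = float((self._Yr**2).sum()) - ss_fit
        return RDAResults(self, ss_fit, max(ss_resid, 0.0), proj)

    # -- permutation inference --------------------------------------------

    def permutation_test(self, n_perm: int = 999, seed=None) -> PermutationTest:
        """Permutation F-test of X (given the condition, if any).

        Without a condition the rows of centered Y are permuted; with one,
        the residuals of Y on the condition are permuted. p uses the
        add-one estimator (1 + #{F* >= F}) / (1 + n_perm).
        """
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        res = self.fit()
        if res.ss_resid <= 1e-12 * self.ss_total:
            return PermutationTest(np.inf, 1.0 / (1.0 + n_perm), n_perm, degenerate=True)
        f_obs = res.fvalue
        rng = np.random.default_rng(seed)
        m, df_resid = self.n_predictors, res.df_resid
        Yr = self._Yr
        ss_full = float((Yr**2).sum())
        count = 0
        for _ in range(n_perm):
            Yp = Yr[rng.permutation(self.nobs)]
            ss_fit_p = float(((self._Q.T @ Yp) ** 2).sum())
            f_p = (ss_fit_p / m) / ((ss_full - ss_fit_p) / df_resid)
            if f_p >= f_obs:
                count += 1
        return PermutationTest(f_obs, (1.0 + count) / (1.0 + n_perm), n_perm)


@dataclass
class RDAResults:
    """Explained variance, F statistic and residuals of a fitted RDA."""

    model: RDA
    ss_fit: float
    ss_resid: float
    fitted: np.ndarray = field(repr=False)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_model(self) -> int:
        return self.model.n_predictors

    @property
    def df_resid(self) -> int:
        return self.nobs - self.model.n_predictors - self.model.n_condition - 1

    @property
    def rsquared(self) -> float:
        return self.ss_fit / self.model.ss_total

    @property
    def rsquared_adj(self) -> float:
        if self.model.n_condition:
            raise ValidationError(
                "adjusted R^2 of a partial RDA is not defined here; "
                "use plain fits and difference their adjusted R^2"
            )
        return adjusted_r2(self.rsquared, self.nobs, self.df_model)

    @property
    def fvalue(self) -> float:
        return (self.ss_fit / self.df_model) / (self.ss_resid / self.df_resid)

    @property
    def resid(self) -> np.ndarray:
        return self.model._Yr - self.fitted

    def permutation_test(self, n_perm: int = 999, seed=None) -> PermutationTest:
        return self.model.permutation_test(n_perm=n_perm, seed=seed)

    def summary(self) -> str:
        lines = [
            "Redundancy analysis",
            "-" * 44,
            f"observations        {self.nobs:>10d}",
            f"predictors          {self.df_model:>10d}",
            f"covariables         {self.model.n_condition:>10d}",
            f"SS total            {self.model.ss_total:>10.5f}",
            f"SS fitted           {self.ss_fit:>10.5f}",
            f"R^2                 {self.rsquared:>10.5f}",
        ]
        if not self.model.n_condition:
            lines.append(f"R^2 adjusted        {self.rsquared_adj:>10.5f}")
        lines.append(f"F                   {self.fvalue:>10.4f}")
        return "\n".join(lines)


def rda_r2(Y, X, condition=None) -> RDAResults:
    """Convenience wrapper: fit an RDA and return its results object."""
    return RDA(Y, X, condition=condition).fit()


def permutation_test(Y, X, condition=None, n_perm: int = 999, seed=None) -> PermutationTest:
    """Permutation F-test of X on Y (given ``condition``), see :meth:`RDA.permutation_test`."""
    return RDA(Y, X, condition=condition).permutation_test(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

@dataclass
class ForwardSelectionResult:
    """Outcome of permutation-based forward selection."""

    selected: list[str]
    indices: list[int]
    steps: pd.DataFrame
    global_pvalue: float
    global_r2_adj: float
    r2_adj: float

    @property
    def n_selected(self) -> int:
        return len(self.indices)


def forward_select(
    Y,
    candidates,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed=None,
    use_ceiling: bool = True,
) -> ForwardSelectionResult:
    """Forward selection of predictors by permutation, double-stopping rule.

    Procedure: (0) a global permutation test of the full candidate set; if
    p > alpha nothing is selected, otherwise the full model's adjusted R^2
    becomes a ceiling; (1) repeatedly add the candidate with the largest
    additional explained variance, testing it by residual permutation at
    level ``alpha``; (2) stop when the best candidate fails its test or when
    adding it would push the cumulative adjusted R^2 past the ceiling
    (``use_ceiling=False`` disables the ceiling rule). Ties are broken by
    candidate input order.
    """
    Ym = _as_matrix(Y, "Y")
    Xm = _as_matrix(candidates, "candidates")
    if Xm.shape[1] == 0:
        raise ValidationError("at least one candidate is required")
    if Xm.shape[0] != Ym.shape[0]:
        raise ValidationError("Y and candidates must have matching row counts")
    names = _column_names(candidates, Xm.shape[1], "cand")
    n = Ym.shape[0]
    rng = np.random.default_rng(seed)

    Yc = Ym - Ym.mean(axis=0)
    ss_tot = float((Yc**2).sum())
    if ss_tot <= 0:
        raise ValidationError("Y has zero total variance")
    Xc = Xm - Xm.mean(axis=0)
    norms0 = np.linalg.norm(Xc, axis=0)
    live = norms0 > 1e-12
    empty_steps = pd.DataFrame(
        columns=["variable", "partial_r2", "cum_r2", "cum_r2_adj", "F", "pvalue"]
    )

    # ---- global gate ----
    rank_all = np.linalg.matrix_rank(Xc[:, live]) if live.any() else 0
    if rank_all >= 1 and n - rank_all - 1 >= 1:
        Qall, _, _ = scipy.linalg.qr(Xc[:, live], mode="economic", pivoting=True)
        Qall = Qall[:, :rank_all]
        ss_fit_all = float(((Qall.T @ Yc) ** 2).sum())
        df_resid_all = n - rank_all - 1
        resid_all = ss_tot - ss_fit_all
        if resid_all <= 1e-12 * ss_tot:
            global_p = 1.0 / (1.0 + n_perm)
        else:
            f_obs = (ss_fit_all / rank_all) / (resid_all / df_resid_all)
            count = 0
            for _ in range(n_perm):
                Yp = Yc[rng.permutation(n)]
                ssf = float(((Qall.T @ Yp) ** 2).sum())
                fp = (ssf / rank_all) / ((ss_tot - ssf) / df_resid_all)
                if fp >= f_obs:
                    count += 1
            global_p = (1.0 + count) / (1.0 + n_perm)
        global_adj = adjusted_r2(ss_fit_all / ss_tot, n, rank_all)
        if global_p > alpha:
            return ForwardSelectionResult([], [], empty_steps, global_p, global_adj, 0.0)
        ceiling = global_adj if use_ceiling else np.inf
    else:
        # saturated candidate set: the global test is not estimable
        global_p, global_adj, ceiling = np.nan, np.nan, np.inf

    # ---- stepwise additions ----
    selected: list[int] = []
    rows = []
    B = np.empty((n, 0))
    Xr = Xc.copy()
    Yres = Yc.copy()
    ss_res = ss_tot
    while True:
        k = len(selected)
        df_resid = n - k - 2
        if df_resid < 1:
            break
        norms = np.linalg.norm(Xr, axis=0)
        active = live & (norms > 1e-8 * np.maximum(norms0, 1e-300))
        active[selected] = False
        if not active.any():
            break
        U = Xr.T @ Yres
        extra = np.where(active, (U**2).sum(axis=1) / np.where(norms > 0, norms, 1.0) ** 2, -np.inf)
        best = int(np.argmax(extra))
        extra_best = float(extra[best])
        if extra_best <= 0:
            break
        q = Xr[:, best] / norms[best]
        resid_after = ss_res - extra_best
        if resid_after <= 1e-12 * ss_tot:
            p = 1.0 / (1.0 + n_perm)
            f_obs = np.inf
        else:
            f_obs = extra_best / (resid_after / df_resid)
            count = 0
            for _ in range(n_perm):
                qp = q[rng.permutation(n)]
                e = float(((qp @ Yres) ** 2).sum())
                fp = e / ((ss_res - e) / df_resid)
                if fp >= f_obs:
                    count += 1
            p = (1.0 + count) / (1.0 + n_perm)
        if p > alpha:
            break
        cum_r2 = (ss_tot - resid_after) / ss_tot
        cum_adj = adjusted_r2(cum_r2, n, k + 1)
        if cum_adj > ceiling + 1e-12:
            break  # ceiling breached: reject the triggering candidate
        selected.append(best)
        rows.append(
            {
                "variable": names[best],
                "partial_r2": extra_best / ss_tot,
                "cum_r2": cum_r2,
                "cum_r2_adj": cum_adj,
                "F": f_obs,
                "pvalue": p,
            }
        )
        B = np.column_stack([B, q])
        Yres = Yres - np.outer(q, q @ Yres)
        Xr = Xr - np.outer(q, q @ Xr)
        ss_res = resid_after

    steps = pd.DataFrame(rows) if rows else empty_steps
    final_adj = float(steps["cum_r2_adj"].iloc[-1]) if len(steps) else 0.0
    return ForwardSelectionResult(
        [names[j] for j in selected], selected, steps, global_p, global_adj, final_adj
    )
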