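"""Penalized-regression-spline additive models (scikit-learn style).

The estimator fits a Gaussian additive model

    y = b0 + sum_j f_j(x_j) + X_lin beta + eps

where each smooth f_j is a cubic B-spline expansion with a second-order
difference penalty on its coefficients (P-splines).  The amount of
smoothing is selected automatically by minimising the generalised
cross-validation score over a log-spaced grid of penalty weights, so a
user never chooses a bandwidth.  With no smooth terms the model is
exactly ordinary least squares.

Identifiability: each smooth is constrained to sum to zero over the
observed data (the constraint is absorbed by reparameterising the basis
into its null space), so smooths never compete with the intercept.
Factor-by smooths get one constrained basis per factor level, sharing a
single smoothing weight, which yields separate mean curves per level.

Inference notes: the covariance of the penalized estimate uses the
frequentist sandwich ``sigma^2 A^-1 X'X A^-1`` with ``A = X'X + lam*S``;
p-values for penalized smooth blocks use a rank-truncated Wald statistic
against an F reference with the model's residual effective degrees of
freedom, and are approximate.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "LinearTerm",
    "FactorTerm",
    "SmoothTerm",
    "SmoothByFactorTerm",
    "LinearByFactorTerm",
    "TermList",
    "Design",
    "GAMRegressor",
    "build_design",
    "fit_penalized",
    "RankDeficientError",
    "DEFAULT_LAM_GRID",
]

DEFAULT_N_SPLINES = 10
DEFAULT_LAM_GRID = np.logspace(-3.0, 8.0, 34)


class GAMError(ValueError):
    pass


class RankDeficientError(GAMError):
    """Unpenalized design is rank deficient; names the collinear columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(self.columns)
        )


# ---------------------------------------------------------------------------
# model terms
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LinearTerm:
    name: str
    role: str = "covariate"


@dataclasses.dataclass(frozen=True)
class FactorTerm:
    name: str
    role: str = "covariate"


@dataclasses.dataclass(frozen=True)
class SmoothTerm:
    name: str
    n_splines: int = DEFAULT_N_SPLINES
    role: str = "independent"


@dataclasses.dataclass(frozen=True)
class SmoothByFactorTerm:
    """Deviation smooths of `name` for each non-reference level of `by`.

    Used together with a main :class:`SmoothTerm` and a main
    :class:`FactorTerm`, this parameterises a smooth-by-factor
    interaction identifiably: the reference level follows the main
    smooth, other levels add a penalized deviation curve.
    """

    name: str
    by: str
    n_splines: int = DEFAULT_N_SPLINES
    role: str = "interaction"


@dataclasses.dataclass(frozen=True)
class LinearByFactorTerm:
    """Slope deviations of `name` for each non-reference level of `by`."""

    name: str
    by: str
    role: str = "interaction"


Term = LinearTerm | FactorTerm | SmoothTerm | SmoothByFactorTerm | LinearByFactorTerm
TermList = tuple


def term_label(term: Term) -> str:
    if isinstance(term, SmoothTerm):
        return f"s({term.name})"
    if isinstance(term, SmoothByFactorTerm):
        return f"s({term.name}):{term.by}"
    if isinstance(term, LinearByFactorTerm):
        return f"{term.name}:{term.by}"
    return term.name


def term_variables(terms: Iterable[Term]) -> list[str]:
    """Data columns referenced by a term list, in first-use order."""
    seen: list[str] = []
    for t in terms:
        extra = (t.by,) if isinstance(t, (SmoothByFactorTerm, LinearByFactorTerm)) else ()
        for name in (t.name,) + extra:
            if name not in seen:
                seen.append(name)
    return seen


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _bspline_knots(x: np.ndarray, n_splines: int, degree: int = 3) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        hi = lo + 1.0
    n_interior = n_splines - degree - 1
    if n_interior < 0:
        raise GAMError(f"n_splines must be >= {degree + 1}")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )


def _basis_matrix(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    lo, hi = knots[degree], knots[-degree - 1]
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, knots, degree).toarray()


def _second_diff_penalty(k: int) -> np.ndarray:
    d = np.diff(np.eye(k), n=2, axis=0)
    return d.T @ d


@dataclasses.dataclass
class _BlockInfo:
    term: Term
    label: str
    sl: slice
    penalized: bool
    # transform payload
    kind: str
    knots: np.ndarray | None = None
    constraint_basis: np.ndarray | None = None  # Q, or per-level list
    levels: list | None = None
    per_level_q: list | None = None


@dataclasses.dataclass
class Design:
    """Materialised model design: matrix, penalty, and a transform recipe."""

    X: np.ndarray
    S: np.ndarray
    blocks: list[_BlockInfo]
    column_names: list[str]
    has_smooth: bool
    terms: tuple

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        """Design matrix for new rows using the stored bases and codings."""
        n = len(data)
        out = np.empty((n, self.n_coef))
        for b in self.blocks:
            if b.kind == "intercept":
                out[:, b.sl] = 1.0
            elif b.kind == "linear":
                out[:, b.sl] = np.asarray(data[b.term.name], float)[:, None]
            elif b.kind == "factor":
                vals = data[b.term.name].astype(str).to_numpy()
                cols = np.zeros((n, len(b.levels) - 1))
                for j, lev in enumerate(b.levels[1:]):
                    cols[:, j] = vals == lev
                out[:, b.sl] = cols
            elif b.kind == "smooth":
                basis = _basis_matrix(np.asarray(data[b.term.name], float), b.knots)
                out[:, b.sl] = basis @ b.constraint_basis
            elif b.kind == "smooth_by":
                xvals = np.asarray(data[b.term.name], float)
                gvals = data[b.term.by].astype(str).to_numpy()
                basis = _basis_matrix(xvals, b.knots)
                cols = []
                for lev, q in zip(b.levels[1:], b.per_level_q):
                    ind = (gvals == lev).astype(float)[:, None]
                    cols.append((basis * ind) @ q)
                out[:, b.sl] = np.hstack(cols)
            elif b.kind == "linear_by":
                xvals = np.asarray(data[b.term.name], float)
                gvals = data[b.term.by].astype(str).to_numpy()
                cols = [
                    xvals * (gvals == lev) for lev in b.levels[1:]
                ]
                out[:, b.sl] = np.column_stack(cols)
            else:  # pragma: no cover
                raise GAMError(f"unknown block kind {b.kind}")
        return out

    def block_for(self, role: str) -> list[_BlockInfo]:
        return [b for b in self.blocks if getattr(b.term, "role", None) == role]


def _null_space_of_sum(c: np.ndarray) -> np.ndarray:
    q = sla.null_space(c[None, :])
    if q.shape[1] != c.size - 1:  # constraint degenerate (c == 0)
        q = np.eye(c.size)[:, : c.size - 1]
    return q


def build_design(data: pd.DataFrame, terms: Sequence[Term]) -> Design:
    """Build the penalized design for a term list over complete-case data."""
    n = len(data)
    if n == 0:
        raise GAMError("no rows remain after removing sessions with missing values")
    cols: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["(Intercept)"]
    blocks: list[_BlockInfo] = [
        _BlockInfo(LinearTerm("(Intercept)", role="intercept"), "(Intercept)",
                   slice(0, 1), False, "intercept")
    ]
    pen_blocks: list[tuple[slice, np.ndarray]] = []
    pos = 1
    has_smooth = False
    for term in terms:
        if isinstance(term, LinearTerm):
            v = np.asarray(data[term.name], float)[:, None]
            cols.append(v)
            sl = slice(pos, pos + 1)
            blocks.append(_BlockInfo(term, term.name, sl, False, "linear"))
            names.append(term.name)
            pos += 1
        elif isinstance(term, FactorTerm):
            vals = data[term.name].astype(str).to_numpy()
            levels = sorted(set(vals))
            if len(levels) < 2:
                raise GAMError(
                    f"factor {term.name!r} has a single level in the analysis rows"
                )
            dummies = np.column_stack(
                [(vals == lev).astype(float) for lev in levels[1:]]
            )
            cols.append(dummies)
            sl = slice(pos, pos + dummies.shape[1])
            blocks.append(
                _BlockInfo(term, term.name, sl, False, "factor", levels=levels)
            )
            names.extend(f"{term.name}[{lev}]" for lev in levels[1:])
            pos += dummies.shape[1]
        elif isinstance(term, SmoothTerm):
            x = np.asarray(data[term.name], float)
            knots = _bspline_knots(x, term.n_splines)
            basis = _basis_matrix(x, knots)
            q = _null_space_of_sum(basis.sum(axis=0))
            z = basis @ q
            cols.append(z)
            sl = slice(pos, pos + z.shape[1])
            s_block = q.T @ _second_diff_penalty(term.n_splines) @ q
            pen_blocks.append((sl, s_block))
            blocks.append(
                _BlockInfo(term, term_label(term), sl, True, "smooth",
                           knots=knots, constraint_basis=q)
            )
            names.extend(f"s({term.name}).{j}" for j in range(z.shape[1]))
            pos += z.shape[1]
            has_smooth = True
        elif isinstance(term, SmoothByFactorTerm):
            x = np.asarray(data[term.name], float)
            gvals = data[term.by].astype(str).to_numpy()
            levels = sorted(set(gvals))
            if len(levels) < 2:
                raise GAMError(
                    f"interaction factor {term.by!r} has a single level"
                )
            knots = _bspline_knots(x, term.n_splines)
            basis = _basis_matrix(x, knots)
            pieces, qs = [], []
            d2 = _second_diff_penalty(term.n_splines)
            s_parts = []
            for lev in levels[1:]:
                ind = (gvals == lev).astype(float)[:, None]
                csum = (basis * ind).sum(axis=0)
                q = _null_space_of_sum(csum)
                qs.append(q)
                pieces.append((basis * ind) @ q)
                s_parts.append(q.T @ d2 @ q)
            z = np.hstack(pieces)
            sl = slice(pos, pos + z.shape[1])
            cols.append(z)
            pen_blocks.append((sl, sla.block_diag(*s_parts)))
            blocks.append(
                _BlockInfo(term, term_label(term), sl, True, "smooth_by",
                           knots=knots, levels=levels, per_level_q=qs)
            )
            for lev, q in zip(levels[1:], qs):
                names.extend(
                    f"s({term.name}):{term.by}[{lev}].{j}" for j in range(q.shape[1])
                )
            pos += z.shape[1]
            has_smooth = True
        elif isinstance(term, LinearByFactorTerm):
            x = np.asarray(data[term.name], float)
            gvals = data[term.by].astype(str).to_numpy()
            levels = sorted(set(gvals))
            if len(levels) < 2:
                raise GAMError(
                    f"interaction factor {term.by!r} has a single level"
                )
            z = np.column_stack([x * (gvals == lev) for lev in levels[1:]])
            sl = slice(pos, pos + z.shape[1])
            cols.append(z)
            blocks.append(
                _BlockInfo(term, term_label(term), sl, False, "linear_by",
                           levels=levels)
            )
            names.extend(f"{term.name}:{term.by}[{lev}]" for lev in levels[1:])
            pos += z.shape[1]
        else:
            raise GAMError(f"unknown term type {type(term).__name__}")
    X = np.hstack(cols)
    S = np.zeros((pos, pos))
    for sl, s_block in pen_blocks:
        S[sl, sl] = s_block
    return Design(X, S, blocks, names, has_smooth, tuple(terms))


# ---------------------------------------------------------------------------
# penalized fitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FitInternals:
    beta: np.ndarray
    lam: float
    edf: float
    rss: float
    gcv: float
    sigma2: float
    cov: np.ndarray          # frequentist covariance of beta
    edf_per_coef: np.ndarray
    fitted: np.ndarray


def check_rank(design: Design, tol: float = 1e-8) -> None:
    """QR-with-pivoting rank check; raises naming collinear columns.

    Columns are scaled to unit norm first so the check is about linear
    dependence, not about measures living on different scales.
    """
    X = design.X
    norms = np.linalg.norm(X, axis=0)
    if (norms == 0).any():
        bad = [design.column_names[j] for j in np.nonzero(norms == 0)[0]]
        raise RankDeficientError(bad)
    _, r, piv = sla.qr(X / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag[0] == 0:
        raise RankDeficientError(design.column_names)
    rank = int(np.sum(diag > tol * diag[0]))
    if rank < X.shape[1]:
        bad = [design.column_names[j] for j in piv[rank:]]
        raise RankDeficientError(bad)


def fit_penalized(
    design: Design,
    y: np.ndarray,
    lam_grid: np.ndarray | None = None,
) -> FitInternals:
    """Penalized least squares with GCV selection of the penalty weight.

    A single weight multiplies the whole smooth penalty (all smooth
    blocks share it); unpenalized models skip the grid and reduce to OLS.
    """
    y = np.asarray(y, float).ravel()
    X, S = design.X, design.S
    n, p = X.shape
    if n <= p:
        raise GAMError(f"need more rows ({n}) than coefficients ({p})")
    check_rank(design)
    xtx = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)
    grid = (
        np.asarray(lam_grid if lam_grid is not None else DEFAULT_LAM_GRID, float)
        if design.has_smooth
        else np.array([0.0])
    )
    best = None
    for lam in grid:
        a = xtx + lam * S
        try:
            cf = sla.cho_factor(a)
        except sla.LinAlgError:
            continue
        beta = sla.cho_solve(cf, xty)
        ainv_xtx = sla.cho_solve(cf, xtx)
        edf = float(np.trace(ainv_xtx))
        rss = max(yty - 2 * beta @ xty + beta @ xtx @ beta, 0.0)
        denom = max(n - edf, 1e-10)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, edf, rss, ainv_xtx, cf)
    if best is None:
        raise GAMError("penalized normal equations not positive definite")
    gcv, lam, beta, edf, rss, ainv_xtx, cf = best
    sigma2 = rss / max(n - edf, 1e-10)
    ainv = sla.cho_solve(cf, np.eye(p))
    cov = sigma2 * (ainv @ xtx @ ainv)
    return FitInternals(
        beta=beta,
        lam=float(lam),
        edf=edf,
        rss=rss,
        gcv=gcv,
        sigma2=sigma2,
        cov=cov,
        edf_per_coef=np.diag(ainv_xtx).copy(),
        fitted=X @ beta,
    )


def block_pvalue(
    fit: FitInternals, sl: slice, penalized: bool, n: int
) -> tuple[float, float, float]:
    """Approximate Wald test for one term block.

    Returns (p, F statistic, block edf).  Penalized blocks use a
    rank-truncated inverse of the block covariance with rank equal to the
    rounded block edf (an approximate test; see module docstring).
    """
    beta = fit.beta[sl]
    vb = fit.cov[sl, sl]
    edf_b = float(np.sum(fit.edf_per_coef[sl]))
    ncol = beta.size
    df_resid = max(n - fit.edf, 1e-10)
    if not penalized:
        r = ncol
        try:
            stat = float(beta @ sla.solve(vb, beta, assume_a="pos"))
        except sla.LinAlgError:
            stat = float(beta @ np.linalg.pinv(vb) @ beta)
    else:
        r = int(np.clip(np.round(edf_b), 1, ncol))
        w, v = np.linalg.eigh(vb)
        order = np.argsort(w)[::-1][:r]
        w_r, v_r = w[order], v[:, order]
        w_r = np.where(w_r > 0, w_r, np.inf)
        proj = v_r.T @ beta
        stat = float(np.sum(proj**2 / w_r))
    fstat = stat / r
    p = float(stats.f.sf(fstat, r, df_resid))
    return max(min(p, 1.0), np.finfo(float).tiny), fstat, edf_b


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class GAMRegressor(RegressorMixin, BaseEstimator):
    """Additive model with penalized spline smooths, GCV-tuned.

    Parameters
    ----------
    terms : tuple of term objects
        Ordered model terms (:class:`LinearTerm`, :class:`FactorTerm`,
        :class:`SmoothTerm`, :class:`SmoothByFactorTerm`).  The response
        is passed separately to :meth:`fit`.
    lam_grid : array-like or None
        Candidate penalty weights; ``None`` uses a log-spaced default.

    Attributes (after fit)
    ----------------------
    coef_, lam_, edf_, sigma2_ : penalized-fit quantities
    r2_, deviance_explained_, adjusted_r2_, aic_, bic_ : fit summaries
    term_summaries_ : list of per-term dicts (label, role, p, F, edf)
    design_ : the materialised :class:`Design` (used for prediction)
    """

    def __init__(self, terms: tuple = (), lam_grid=None):
        self.terms = terms
        self.lam_grid = lam_grid

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        y = np.asarray(y, float).ravel()
        if len(y) != len(X):
            raise GAMError("X and y length mismatch")
        needed = term_variables(self.terms)
        missing = [c for c in needed if c not in X.columns]
        if missing:
            raise GAMError(f"missing predictor column(s): {', '.join(missing)}")
        sub = X[needed] if needed else X.iloc[:, :0]
        if len(needed) and sub.isna().any().any():
            raise GAMError(
                "predictors contain missing values; apply complete_cases first"
            )
        if np.isnan(y).any():
            raise GAMError("response contains missing values; apply complete_cases first")
        design = build_design(X, self.terms)
        internals = fit_penalized(design, y, self.lam_grid)
        n = design.n_obs
        tss = float(np.sum((y - y.mean()) ** 2))
        rss = internals.rss
        self.design_ = design
        self.fit_ = internals
        self.coef_ = internals.beta
        self.lam_ = internals.lam
        self.edf_ = internals.edf
        self.sigma2_ = internals.sigma2
        self.n_used_ = n
        self.fitted_values_ = internals.fitted
        self.residuals_ = y - internals.fitted
        self.y_ = y
        if tss > 0:
            self.r2_ = 1.0 - rss / tss
        else:
            self.r2_ = 0.0
        # Gaussian identity-link: deviance explained coincides with R^2;
        # both are reported under their own names.
        self.deviance_explained_ = self.r2_
        denom = tss / max(n - 1, 1)
        self.adjusted_r2_ = (
            1.0 - (rss / max(n - internals.edf, 1e-10)) / denom if denom > 0 else 0.0
        )
        sigma2_mle = max(rss / n, np.finfo(float).tiny)
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_mle) + 1.0)
        k = internals.edf + 1.0  # + scale parameter
        self.loglik_ = loglik
        self.aic_ = -2.0 * loglik + 2.0 * k
        self.bic_ = -2.0 * loglik + np.log(n) * k
        self.term_summaries_ = []
        for b in design.blocks:
            if b.kind == "intercept":
                continue
            p, fstat, edf_b = block_pvalue(internals, b.sl, b.penalized, n)
            self.term_summaries_.append(
                {
                    "term": b.label,
                    "role": getattr(b.term, "role", "covariate"),
                    "p_value": p,
                    "f_stat": fstat,
                    "edf": edf_b,
                    "penalized": b.penalized,
                }
            )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return self.design_.transform(X) @ self.coef_

    def predict_se(self, X: pd.DataFrame) -> np.ndarray:
        """Pointwise standard errors of the mean prediction."""
        self._check_fitted()
        xm = self.design_.transform(X)
        var = np.einsum("ij,jk,ik->i", xm, self.fit_.cov, xm)
        return np.sqrt(np.maximum(var, 0.0))

    def contribution(self, roles: Sequence[str], X: pd.DataFrame | None = None) -> np.ndarray:
        """Summed fitted contribution of all terms with the given roles."""
        self._check_fitted()
        xm = self.design_.X if X is None else self.design_.transform(X)
        out = np.zeros(xm.shape[0])
        for b in self.design_.blocks:
            if getattr(b.term, "role", None) in roles:
                out += xm[:, b.sl] @ self.coef_[b.sl]
        return out

    def pvalue_for_role(self, role: str) -> float | None:
        """Smallest p among blocks holding the given role (usually unique)."""
        self._check_fitted()
        ps = [t["p_value"] for t in self.term_summaries_ if t["role"] == role]
        return min(ps) if ps else None

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise GAMError("estimator is not fitted")
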