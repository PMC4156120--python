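"""Additive metamodel with penalized-spline smooths.

Fits ``y_i = f0 + sum_k f_k(x_ki) + eps_i`` where each ``f_k`` is a cubic
penalized regression spline subject to a sum-to-zero (centering) constraint
over the data.  Smoothness of each term is selected automatically by
generalized cross-validation (GCV); the wiggliness penalty is the exact
integrated squared second derivative, whose null space is exactly the
linear functions, so an infinitely penalized term degenerates to a
straight line (one equivalent degree of freedom after centering).

The equivalent degrees of freedom (e.d.f.) of a term is the trace of the
corresponding block of the influence matrix: 1 for a straight line, 2 for
a parabola, climbing toward ``basis_dim - 1`` as the fit becomes rougher.
Approximate per-term F statistics test each smooth against the null
(zero) function.

In the interpolation regime -- a response that some low-degree polynomial
reproduces to machine precision -- prediction-error criteria cannot
identify the smoothing parameter (every candidate fit has numerically
zero residual).  The fit then collapses each smooth to its minimal-degree
exact polynomial representation, which recovers the classical e.d.f.
semantics exactly (line -> 1, parabola -> 2).  See docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import f as _f_dist

__all__ = [
    "GamFit",
    "ResponseCurve",
    "fit_gam",
    "term_edf",
    "term_ftest",
    "adjusted_r2",
    "response_curve",
    "summary_table",
    "significance_stars",
]

_DEGREE = 3
_EXACT_FIT_TOL = 1e-10  # RSS/TSS below this counts as a numerically exact fit


def _uniform_knots(basis_dim: int) -> np.ndarray:
    """Clamped uniform cubic knot vector on [0, 1] for `basis_dim` functions."""
    n_inner = basis_dim - _DEGREE + 1
    inner = np.linspace(0.0, 1.0, n_inner)
    return np.concatenate([np.zeros(_DEGREE), inner, np.ones(_DEGREE)])


def _bspline_design(knots: np.ndarray, x: np.ndarray) -> np.ndarray:
    xc = np.clip(x, 0.0, 1.0)
    return BSpline.design_matrix(xc, knots, _DEGREE).toarray()


def _curvature_penalty(knots: np.ndarray) -> np.ndarray:
    """Exact integral of products of second derivatives of the basis.

    Second derivatives of cubic B-splines are piecewise linear, so their
    pairwise products are piecewise quadratic and two-point Gauss-Legendre
    quadrature per knot span is exact.
    """
    k = len(knots) - _DEGREE - 1
    spans = np.unique(knots)
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    pts, wts = [], []
    for a, b in zip(spans[:-1], spans[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        pts.extend(mid + half * gauss)
        wts.extend([half, half])
    pts = np.asarray(pts)
    wts = np.asarray(wts)
    d2 = np.empty((len(pts), k))
    eye = np.eye(k)
    for j in range(k):
        d2[:, j] = BSpline(knots, eye[j], _DEGREE).derivative(2)(pts)
    return d2.T @ (wts[:, None] * d2)


@dataclass
class _Term:
    """One smooth term: basis construction plus its centering transform."""

    name: str
    lo: float
    hi: float
    kind: str = "spline"  # 'spline' | 'poly'
    basis_dim: int = 10
    degree: int = 0  # polynomial degree when kind == 'poly' (0 => dropped)
    knots: np.ndarray | None = None
    Z: np.ndarray | None = None  # constraint null-space basis (spline)
    col_means: np.ndarray | None = None  # centering offsets (poly)
    penalty: np.ndarray | None = None
    lam: float = 1.0

    def _norm(self, x: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        if span <= 0:
            return np.zeros_like(x, dtype=float)
        return (np.asarray(x, dtype=float) - self.lo) / span

    def build(self, x: np.ndarray) -> np.ndarray:
        """Centered model columns for this term, evaluated at raw inputs x."""
        u = self._norm(x)
        if self.kind == "poly":
            if self.degree == 0:
                return np.empty((len(u), 0))
            cols = np.column_stack([u**d for d in range(1, self.degree + 1)])
            return cols - self.col_means
        B = _bspline_design(self.knots, u)
        return B @ self.Z

    @property
    def n_cols(self) -> int:
        if self.kind == "poly":
            return self.degree
        return self.basis_dim - 1


@dataclass
class ResponseCurve:
    """Centered smooth-term effect on an even grid with a +/-2 SE band."""

    name: str
    grid: np.ndarray
    effect: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


@dataclass
class GamFit:
    """Fitted additive model; see :func:`fit_gam`."""

    names: list[str]
    terms: list[_Term]
    blocks: list[slice]
    beta: np.ndarray
    intercept: float
    edf: np.ndarray  # per-term
    edf_total: float  # including intercept
    rss: float
    tss: float
    sigma2: float
    n: int
    cov_bayes: np.ndarray  # sigma2 * A^{-1}
    cov_freq: np.ndarray  # sigma2 * A^{-1} X'X A^{-1}
    fitted: np.ndarray
    residuals: np.ndarray
    X: np.ndarray = None
    y: np.ndarray = None
    dropped: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(X.shape[0], self.intercept)
        for k, term in enumerate(self.terms):
            cols = term.build(X[:, k])
            if cols.shape[1]:
                out += cols @ self.beta[self.blocks[k]]
        return out

    def term_values(self, k: int, x: np.ndarray) -> np.ndarray:
        cols = self.terms[k].build(np.asarray(x, dtype=float))
        if cols.shape[1] == 0:
            return np.zeros(len(np.atleast_1d(x)))
        return cols @ self.beta[self.blocks[k]]


def _assemble(terms: list[_Term], X: np.ndarray):
    n = X.shape[0]
    cols = [np.ones((n, 1))]
    blocks = []
    start = 1
    for k, term in enumerate(terms):
        C = term.build(X[:, k])
        cols.append(C)
        blocks.append(slice(start, start + C.shape[1]))
        start += C.shape[1]
    return np.hstack(cols), blocks


def _penalized_fit(M, MtM, Mty, y, terms, blocks, lambdas):
    p = MtM.shape[0]
    A = MtM.copy()
    for term, blk, lam in zip(terms, blocks, lambdas):
        if term.kind == "spline" and lam > 0:
            A[blk, blk] += lam * term.penalty
    # small ridge for numerical rank safety; negligible vs data scale
    A[np.diag_indices(p)] += 1e-12 * (1.0 + np.diag(MtM))
    try:
        Ainv = np.linalg.solve(A, np.eye(p))
    except np.linalg.LinAlgError:
        Ainv = np.linalg.pinv(A, rcond=1e-12)
    beta = Ainv @ Mty
    fitted = M @ beta
    rss = float(np.sum((y - fitted) ** 2))
    infl_diag = np.einsum("ij,ji->i", Ainv, MtM)
    edf_total = float(np.sum(infl_diag))
    edf_terms = np.array([float(np.sum(infl_diag[blk])) for blk in blocks])
    return beta, fitted, rss, edf_total, edf_terms, Ainv


def _gcv(n, rss, edf_total):
    denom = max(n - edf_total, 1e-8)
    return n * rss / denom**2


def fit_gam(
    X,
    y,
    names: list[str] | None = None,
    basis_dim: int = 10,
    lambdas=None,
    loglam_grid: np.ndarray | None = None,
) -> GamFit:
    """Fit the additive metamodel with automatic smoothness selection.

    Parameters
    ----------
    X : (n, K) array
        Input design; one column per additive term.  No interactions are
        considered.
    y : (n,) array
        Response (STAR values in the pipeline use-case).
    names : optional list of term names.
    basis_dim : spline basis dimension per term (before centering).
    lambdas : optional fixed smoothing parameter(s); scalar or length-K.
        ``lambdas=0`` gives the unpenalized regression-spline fit.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.ndim(y) == 1 and len(y) > 1:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    n, K = X.shape
    if n != len(y):
        raise ValueError("X and y have incompatible lengths")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite values are not allowed")
    if names is None:
        names = [f"x{k}" for k in range(K)]
    if n < 10 * K:
        warnings.warn(
            f"only {n} observations for {K} smooth terms; fit may be unstable",
            stacklevel=2,
        )

    knots = _uniform_knots(basis_dim)
    S_raw = _curvature_penalty(knots)
    dropped: list[str] = []
    terms: list[_Term] = []
    for k in range(K):
        lo, hi = float(X[:, k].min()), float(X[:, k].max())
        if hi - lo <= 1e-12 * max(1.0, abs(hi)):
            warnings.warn(
                f"input '{names[k]}' is constant; term dropped", stacklevel=2
            )
            dropped.append(names[k])
            terms.append(_Term(names[k], lo, hi, kind="poly", degree=0))
            continue
        term = _Term(names[k], lo, hi, basis_dim=basis_dim)
        term.knots = knots
        B = _bspline_design(knots, term._norm(X[:, k]))
        cmean = B.mean(axis=0)
        q, _ = np.linalg.qr(cmean[:, None], mode="complete")
        term.Z = q[:, 1:]
        term.penalty = term.Z.T @ S_raw @ term.Z
        terms.append(term)

    M, blocks = _assemble(terms, X)
    MtM = M.T @ M
    Mty = M.T @ y
    tss = float(np.sum((y - y.mean()) ** 2))
    active = [k for k in range(K) if terms[k].n_cols > 0]

    if lambdas is not None:
        lam_vec = np.broadcast_to(np.asarray(lambdas, dtype=float), (K,)).copy()
    else:
        # GCV smoothness selection by coordinate descent on a log grid
        if loglam_grid is None:
            loglam_grid = np.linspace(-7.0, 13.0, 26)
        lam_vec = np.full(K, 1.0)
        _, _, rss0, edf0, _, _ = _penalized_fit(M, MtM, Mty, y, terms, blocks, lam_vec)
        best = _gcv(n, rss0, edf0)
        for _sweep in range(4):
            changed = False
            for k in active:
                for ll in loglam_grid:
                    trial = lam_vec.copy()
                    trial[k] = 10.0**ll
                    _, _, rss, edf_t, _, _ = _penalized_fit(
                        M, MtM, Mty, y, terms, blocks, trial
                    )
                    g = _gcv(n, rss, edf_t)
                    if g < best - 1e-14 * (1 + abs(best)):
                        best, lam_vec = g, trial
                        changed = True
            if not changed:
                break

    beta, fitted, rss, edf_total, edf_terms, Ainv = _penalized_fit(
        M, MtM, Mty, y, terms, blocks, lam_vec
    )

    # Interpolation regime: smoothing parameter unidentifiable; collapse each
    # term to its minimal-degree exact polynomial representation.  The
    # absolute floor handles constant responses whose TSS is itself only
    # rounding noise.
    exact_thresh = _EXACT_FIT_TOL * max(
        tss, 1e-12 * n * float(np.mean(y**2)), 1e-300
    )
    if lambdas is None and rss <= exact_thresh:
        max_deg = min(6, basis_dim - 2)
        for k in active:
            original = terms[k]
            chosen = None
            for deg in range(0, max_deg + 1):
                cand = _Term(
                    original.name, original.lo, original.hi, kind="poly", degree=deg
                )
                u = cand._norm(X[:, k])
                if deg > 0:
                    cols = np.column_stack([u**d for d in range(1, deg + 1)])
                    cand.col_means = cols.mean(axis=0)
                terms[k] = cand
                M, blocks = _assemble(terms, X)
                MtM, Mty = M.T @ M, M.T @ y
                lam_trial = lam_vec.copy()
                _, _, rss_c, _, _, _ = _penalized_fit(
                    M, MtM, Mty, y, terms, blocks, lam_trial
                )
                if rss_c <= exact_thresh:
                    chosen = cand
                    break
            terms[k] = chosen if chosen is not None else original
        M, blocks = _assemble(terms, X)
        MtM, Mty = M.T @ M, M.T @ y
        beta, fitted, rss, edf_total, edf_terms, Ainv = _penalized_fit(
            M, MtM, Mty, y, terms, blocks, lam_vec
        )

    for term, lam in zip(terms, lam_vec):
        term.lam = float(lam)

    resid_df = n - edf_total
    sigma2 = rss / resid_df if resid_df > 0 else np.nan
    cov_bayes = sigma2 * Ainv if np.isfinite(sigma2) else np.full_like(Ainv, np.nan)
    cov_freq = (
        sigma2 * (Ainv @ MtM @ Ainv) if np.isfinite(sigma2) else np.full_like(Ainv, np.nan)
    )
    return GamFit(
        names=list(names),
        terms=terms,
        blocks=blocks,
        beta=beta,
        intercept=float(beta[0]),
        edf=edf_terms,
        edf_total=edf_total,
        rss=rss,
        tss=tss,
        sigma2=float(sigma2) if np.isfinite(sigma2) else np.nan,
        n=n,
        cov_bayes=cov_bayes,
        cov_freq=cov_freq,
        fitted=fitted,
        residuals=y - fitted,
        X=X,
        y=y,
        dropped=dropped,
    )


def term_edf(fit: GamFit, k: int) -> float:
    """Trace-based equivalent degrees of freedom of term k."""
    return float(fit.edf[k])


def term_ftest(fit: GamFit, k: int) -> tuple[float, float]:
    """F test of term k against the null (zero) function.

    The p-value comes from the classical nested F test of the term's
    unpenalized basis against an intercept-only model, applied to the
    term's partial residual (response minus all other fitted terms).
    For a single-term model this is exactly F-distributed under the
    Gaussian null; for additive designs it is near-exact.  A larger F
    means a stronger effect, matching the ordering semantics of the
    reported sensitivity tables.
    """
    resid_df = fit.n - fit.edf_total
    if resid_df <= 0:
        raise ValueError("saturated fit: residual degrees of freedom <= 0")
    term = fit.terms[k]
    if term.n_cols == 0:
        return 0.0, 1.0
    partial = fit.residuals + fit.term_values(k, fit.X[:, k])
    C = term.build(fit.X[:, k])
    M1 = np.column_stack([np.ones(fit.n), C])
    q = int(np.linalg.matrix_rank(M1)) - 1
    if q < 1 or fit.n - 1 - q < 1:
        return 0.0, 1.0
    rss0 = float(np.sum((partial - partial.mean()) ** 2))
    coef, _, _, _ = np.linalg.lstsq(M1, partial, rcond=None)
    rss1 = float(np.sum((partial - M1 @ coef) ** 2))
    if rss1 <= _EXACT_FIT_TOL * max(rss0, 1e-300):
        # numerically exact fit of a non-null term
        return (np.inf, 0.0) if rss0 > 0 else (0.0, 1.0)
    F = ((rss0 - rss1) / q) / (rss1 / (fit.n - 1 - q))
    p = float(_f_dist.sf(F, q, fit.n - 1 - q))
    return float(F), p


def adjusted_r2(fit: GamFit) -> float:
    """1 - (RSS/(n - edf_total)) / (TSS/(n - 1))."""
    if fit.n <= fit.edf_total:
        raise ValueError("no residual degrees of freedom")
    if fit.tss <= 1e-12 * fit.n * float(np.mean(fit.y**2)) or fit.tss <= 0:
        return 0.0  # response constant to numerical precision
    return 1.0 - (fit.rss / (fit.n - fit.edf_total)) / (fit.tss / (fit.n - 1))


def response_curve(fit: GamFit, k: int, n_grid: int = 100) -> ResponseCurve:
    """Centered effect of input k on an even grid with a +/-2 SE band."""
    term = fit.terms[k]
    grid = np.linspace(term.lo, term.hi, n_grid)
    cols = term.build(grid)
    if cols.shape[1] == 0:
        zero = np.zeros(n_grid)
        return ResponseCurve(fit.names[k], grid, zero, zero, zero)
    eff = cols @ fit.beta[fit.blocks[k]]
    Vb = fit.cov_bayes[fit.blocks[k], fit.blocks[k]]
    if np.all(np.isfinite(Vb)):
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", cols, Vb, cols), 0.0))
    else:
        se = np.zeros(n_grid)
    return ResponseCurve(fit.names[k], grid, eff, eff - 2 * se, eff + 2 * se)


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def summary_table(fit: GamFit) -> pd.DataFrame:
    """Per-term e.d.f., F, p and stars, plus the model adjusted R^2."""
    rows = []
    r2 = adjusted_r2(fit)
    for k, name in enumerate(fit.names):
        F, p = term_ftest(fit, k)
        rows.append(
            {
                "input": name,
                "edf": term_edf(fit, k),
                "F": F,
                "p": p,
                "signif": significance_stars(p),
                "adj_r2": r2,
            }
        )
    return pd.DataFrame(rows)
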