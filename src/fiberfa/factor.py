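"""Exploratory factor analysis of the myosin gene panel.

The model assumes each cell's standardized panel expression z is driven
by two correlated latent programs (fast- and slow-twitch authenticity):

    z = Lambda f + e,   Cov(f) = Phi,   Cov(e) = diag(u^2)

so the panel correlation matrix decomposes as
R = Lambda Phi Lambda' + diag(u^2).  The number of factors is chosen by
Horn's parallel analysis, loadings are extracted by minimum residual
(minres) and rotated obliquely with quartimin, and per-cell factor
scores are regression (Thurstone) estimates.  Everything is implemented
directly on top of numpy/scipy so each step can be checked against
simple independent oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

logger = logging.getLogger(__name__)

__all__ = [
    "kmo", "kmo_from_corr", "parallel_analysis", "extract_factors",
    "rotate_quartimin", "score_factors", "map_factors_to_fiber_types",
    "FiberFactorModel", "FiberFactorResults",
    "ConvergenceError", "MappingError",
]


class ConvergenceError(RuntimeError):
    pass


class MappingError(RuntimeError):
    """Fast and slow seed genes load on the same factor."""


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns]
    arr = np.asarray(data, dtype=float)
    return arr, [f"v{i}" for i in range(arr.shape[1])]

def zscore(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"variable at column {bad} is constant")
    return (X - X.mean(axis=0)) / sd


def correlation(X: np.ndarray) -> np.ndarray:
    Z = zscore(X)
    n = Z.shape[0]
    return Z.T @ Z / (n - 1)


# ---------------------------------------------------------------------------
# Sampling adequacy

def kmo_from_corr(R: np.ndarray, ridge: float = 0.0
                  ) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin adequacy from a correlation matrix.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are
    the anti-image partial correlations obtained from the inverse of R;
    per-variable MSA uses the same ratio restricted to one row.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if p < 2:
        raise ValueError("KMO needs at least 2 variables")
    Rw = R + ridge * np.eye(p) if ridge else R
    try:
        Rinv = scipy.linalg.inv(Rw)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; pass ridge > 0") from err
    d = 1.0 / np.sqrt(np.diag(Rinv))
    Q = -Rinv * np.outer(d, d)  # anti-image partial correlations
    np.fill_diagonal(Q, 0.0)
    R_off = R - np.diag(np.diag(R))
    r2 = R_off ** 2
    q2 = Q ** 2
    denom = r2.sum(axis=1) + q2.sum(axis=1)
    msa = np.divide(r2.sum(axis=1), denom, out=np.zeros_like(denom),
                    where=denom > 0)
    overall = r2.sum() / (r2.sum() + q2.sum())
    return float(overall), msa


def kmo(data, ridge: float = 0.0) -> tuple[float, pd.Series]:
    """KMO/MSA from a cells x variables data matrix (variables z-scored)."""
    X, names = _as_matrix(data)
    overall, msa = kmo_from_corr(correlation(X), ridge=ridge)
    return overall, pd.Series(msa, index=names, name="MSA")


# ---------------------------------------------------------------------------
# Parallel analysis

def parallel_analysis(data, n_reps: int = 100, quantile: float = 0.95,
                      seed: int = 0) -> tuple[int, pd.DataFrame]:
    """Horn's parallel analysis for the number of factors to retain.

    Observed correlation-matrix eigenvalues are compared rank by rank
    with the ``quantile`` of eigenvalues from ``n_reps`` standard-normal
    datasets of the same shape; factors are retained while the observed
    eigenvalue exceeds its null quantile, stopping at the first failure.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X, _ = _as_matrix(data)
    n, p = X.shape
    if n < 3:
        raise ValueError("parallel analysis needs at least 3 observations")
    obs = np.sort(scipy.linalg.eigvalsh(correlation(X)))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_reps, p))
    for r in range(n_reps):
        Znull = rng.standard_normal((n, p))
        null[r] = np.sort(scipy.linalg.eigvalsh(np.corrcoef(Znull.T)))[::-1]
    thresh = np.quantile(null, quantile, axis=0)
    exceed = obs > thresh
    m = int(np.argmin(exceed)) if not exceed.all() else p
    table = pd.DataFrame({
        "k": np.arange(1, p + 1),
        "lambda_obs": obs,
        "lambda_null_q": thresh,
        "retained": np.arange(p) < m,
    })
    return m, table


# ---------------------------------------------------------------------------
# Extraction

def _loadings_from_psi(R: np.ndarray, psi: np.ndarray, m: int) -> np.ndarray:
    Rr = R - np.diag(psi)
    vals, vecs = scipy.linalg.eigh(Rr)
    vals, vecs = vals[::-1][:m], vecs[:, ::-1][:, :m]
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _offdiag_residual(R: np.ndarray, L: np.ndarray) -> float:
    resid = R - L @ L.T
    np.fill_diagonal(resid, 0.0)
    return float((resid ** 2).sum() / 2.0)


def extract_factors(data, m: int, method: str = "minres",
                    max_iter: int = 1000
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unrotated loadings, communalities and uniquenesses.

    ``data`` may be a cells x variables matrix/DataFrame or a
    correlation matrix (square, unit diagonal).  minres minimizes the
    off-diagonal residual of R - Lambda Lambda' over the uniquenesses;
    ``method="paf"`` runs classic principal-axis iteration instead.
    """
    X, _ = _as_matrix(data)
    if X.shape[0] == X.shape[1] and np.allclose(np.diag(X), 1.0) and np.allclose(X, X.T):
        R = X.copy()
    else:
        R = correlation(X)
    p = R.shape[0]
    if not (1 <= m < p):
        raise ValueError(f"need 1 <= m < {p} variables, got m={m}")

    smc = 1.0 - 1.0 / np.diag(scipy.linalg.inv(R + 1e-10 * np.eye(p)))
    start = np.clip(1.0 - smc, 1e-4, 1.0)

    if method == "minres":
        res = scipy.optimize.minimize(
            lambda psi: _offdiag_residual(R, _loadings_from_psi(R, psi, m)),
            x0=start, method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * p,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10},
        )
        if not res.success and res.status != 1:
            raise ConvergenceError(
                f"minres failed after {res.nit} iterations: {res.message} "
                f"(residual {res.fun:.3e})")
        psi = res.x
    elif method == "paf":
        h2 = smc.copy()
        for _ in range(max_iter):
            L = _loadings_from_psi(R, 1.0 - h2, m)
            h2_new = np.clip((L ** 2).sum(axis=1), 0.0, 1.0)
            if np.max(np.abs(h2_new - h2)) < 1e-8:
                h2 = h2_new
                break
            h2 = h2_new
        else:
            raise ConvergenceError(
                f"principal-axis iteration did not converge in {max_iter} steps")
        psi = 1.0 - h2
    else:
        raise ValueError(f"unknown extraction method {method!r}")

    L = _loadings_from_psi(R, psi, m)
    h2 = np.clip((L ** 2).sum(axis=1), 0.0, 1.0)
    return L, h2, 1.0 - h2


# ---------------------------------------------------------------------------
# Quartimin rotation (oblimin gamma = 0) by oblique gradient projection

def _quartimin_criterion(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Q = sum_i sum_{k != l} L2_ik L2_il and its gradient dQ/dL."""
    L2 = L ** 2
    m = L.shape[1]
    N = np.ones((m, m)) - np.eye(m)
    inner = L2 @ N
    return float((L2 * inner).sum()), 4.0 * L * inner


def _gpa_oblique(A: np.ndarray, T0: np.ndarray, max_iter: int = 1000,
                 tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, float]:
    T = T0.copy()
    Ti = scipy.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin_criterion(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = np.sqrt((Gp ** 2).sum())
        if s < tol:
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            Tt = X / np.sqrt((X ** 2).sum(axis=0))
            try:
                Ti = scipy.linalg.inv(Tt)
            except scipy.linalg.LinAlgError:
                al /= 2.0
                continue
            L = A @ Ti.T
            ft, Gq = _quartimin_criterion(L)
            if ft < f - 0.5 * s ** 2 * al:
                break
            al /= 2.0
        else:
            break
        T = Tt
        f = ft
        G = -(L.T @ Gq @ Ti).T
    else:
        raise ConvergenceError(
            f"quartimin rotation did not converge (criterion {f:.6e})")
    return L, T, f


def rotate_quartimin(L_unrotated: np.ndarray, n_restarts: int = 10,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Oblique quartimin rotation; returns (rotated loadings, Phi).

    The quartimin criterion (sum over variables of cross-products of
    squared loadings) is minimized by gradient projection over oblique
    rotation matrices T with unit-norm columns; Phi = T'T.  Random
    restarts guard against local minima; the model fit
    Lambda Phi Lambda' equals the unrotated Lambda Lambda'.
    """
    A = np.asarray(L_unrotated, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("quartimin rotation needs at least 2 factors")
    m = A.shape[1]
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            T0 = np.eye(m)
        else:
            T0 = rng.standard_normal((m, m))
            T0 /= np.sqrt((T0 ** 2).sum(axis=0))
            if abs(scipy.linalg.det(T0)) < 1e-6:
                continue
        try:
            L, T, f = _gpa_oblique(A, T0)
        except ConvergenceError:
            continue
        if best is None or f < best[2] - 1e-12:
            best = (L, T, f)
    if best is None:
        raise ConvergenceError("quartimin rotation failed from every start")
    L, T, _ = best
    Phi = T.T @ T
    return L, Phi


def quartimin_value(L: np.ndarray) -> float:
    return _quartimin_criterion(np.asarray(L, dtype=float))[0]


# ---------------------------------------------------------------------------
# Factor scores

def score_factors(data, loadings: np.ndarray, phi: np.ndarray | None = None,
                  method: str = "regression") -> np.ndarray:
    """Per-observation factor scores from standardized data.

    Regression (Thurstone) scores are F = Z R^{-1} (Lambda Phi);
    Bartlett scores weight by inverse uniquenesses instead.
    """
    X, _ = _as_matrix(data)
    Z = zscore(X)
    L = np.asarray(loadings, dtype=float)
    m = L.shape[1]
    Phi = np.eye(m) if phi is None else np.asarray(phi, dtype=float)
    R = correlation(X)
    if method == "regression":
        W = scipy.linalg.solve(R, L @ Phi, assume_a="sym")
    elif method == "bartlett":
        S = L @ Phi  # structure matrix
        u2 = np.clip(1.0 - (L * S).sum(axis=1), 1e-6, None)
        Uinv = np.diag(1.0 / u2)
        W = Uinv @ L @ scipy.linalg.inv(L.T @ Uinv @ L)
    else:
        raise ValueError(f"unknown score method {method!r}")
    return Z @ W


def map_factors_to_fiber_types(loadings: pd.DataFrame, seeds_fast: list[str],
                               seeds_slow: list[str]) -> dict[str, int]:
    """Label factor columns by which seed group loads on them.

    The factor with the greatest mean loading over the fast seeds is
    "fast", likewise "slow"; it is an error when one factor wins both
    (the two programs collapsed onto a single dimension).
    """
    for g in list(seeds_fast) + list(seeds_slow):
        if g not in loadings.index:
            raise KeyError(f"seed gene {g!r} missing from loadings")
    fast_mean = loadings.loc[list(seeds_fast)].mean(axis=0).to_numpy()
    slow_mean = loadings.loc[list(seeds_slow)].mean(axis=0).to_numpy()
    if np.allclose(fast_mean, 0) or np.allclose(slow_mean, 0):
        raise MappingError("a seed group has all-zero loadings")
    fast_ix = int(np.argmax(fast_mean))
    slow_ix = int(np.argmax(slow_mean))
    if fast_ix == slow_ix:
        raise MappingError(
            f"fast and slow seeds both load most on factor {fast_ix}")
    return {"fast": fast_ix, "slow": slow_ix}


# ---------------------------------------------------------------------------
# Model / Results front end

class FiberFactorModel:
    """EFA model of fast/slow fiber identity over a myosin gene panel.

    Parameters
    ----------
    expr
        cells x genes expression DataFrame (log2(RPM + 1) recommended)
        or an :class:`~fiberfa.preprocess.ExprMatrix`.
    panel
        Gene columns entering the analysis (z-scored internally).
    seeds_fast, seeds_slow
        Marker genes anchoring the factor-to-fiber-type mapping.
    """

    def __init__(self, expr, panel: list[str],
                 seeds_fast: list[str] = ("Myh1", "Myh2", "Myh4"),
                 seeds_slow: list[str] = ("Myh7",)):
        from .preprocess import ExprMatrix
        if isinstance(expr, ExprMatrix):
            frame = expr.to_frame()
        else:
            frame = pd.DataFrame(expr)
        missing = [g for g in panel if g not in frame.columns]
        if missing:
            raise KeyError(f"panel genes not in expression matrix: {missing}")
        self.data = frame[list(panel)]
        self.panel = list(panel)
        self.seeds_fast = [g for g in seeds_fast if g in panel]
        self.seeds_slow = [g for g in seeds_slow if g in panel]
        if not self.seeds_fast or not self.seeds_slow:
            raise ValueError("both seed groups must intersect the panel")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, panel=None, **kw):
        return cls(frame, panel=list(panel or frame.columns), **kw)

    def fit(self, n_factors: int | str = "auto", method: str = "minres",
            rotation: str = "quartimin", score_method: str = "regression",
            pa_reps: int = 100, pa_quantile: float = 0.95,
            seed: int = 0) -> "FiberFactorResults":
        X = self.data.to_numpy(dtype=float)
        overall_kmo, msa = kmo(self.data)
        eigen_table = None
        if n_factors == "auto":
            m, eigen_table = parallel_analysis(X, n_reps=pa_reps,
                                               quantile=pa_quantile, seed=seed)
            if m < 1:
                logger.warning("parallel analysis retained 0 factors; "
                               "falling back to m=1")
                m = 1
        else:
            m = int(n_factors)

        L, h2, u2 = extract_factors(X, m=m, method=method)
        if m >= 2 and rotation == "quartimin":
            L_rot, Phi = rotate_quartimin(L, seed=seed)
        elif rotation in ("none", None) or m < 2:
            L_rot, Phi = L, np.eye(m)
        else:
            raise ValueError(f"unknown rotation {rotation!r}")

        # canonical orientation: dominant loading of each factor positive
        dom = np.take_along_axis(L_rot, np.abs(L_rot).argmax(axis=0)[None, :],
                                 axis=0)[0]
        flip = np.where(dom < 0, -1.0, 1.0)
        L_rot = L_rot * flip
        Phi = Phi * np.outer(flip, flip)
        load_df = pd.DataFrame(L_rot, index=self.panel,
                               columns=[f"factor{k + 1}" for k in range(m)])
        if m >= 2:
            mapping = map_factors_to_fiber_types(load_df, self.seeds_fast,
                                                 self.seeds_slow)
            order = [mapping["fast"], mapping["slow"]] + [
                k for k in range(m) if k not in mapping.values()]
            names = ["fast", "slow"] + [f"extra{j}" for j in
                                        range(1, m - 1)]
        else:
            mapping = {}
            order = [0]
            names = ["factor1"]
        L_rot = L_rot[:, order]
        Phi = Phi[np.ix_(order, order)]
        # orient each factor so its seed/marker loadings are positive
        signs = np.ones(m)
        for j, name in enumerate(names):
            seeds = {"fast": self.seeds_fast, "slow": self.seeds_slow}.get(name)
            ref = (L_rot[[self.panel.index(g) for g in seeds], j].mean()
                   if seeds else L_rot[:, j].sum())
            if ref < 0:
                signs[j] = -1.0
        L_rot = L_rot * signs
        Phi = Phi * np.outer(signs, signs)

        F = score_factors(X, L_rot, Phi, method=score_method)
        load_df = pd.DataFrame(L_rot, index=self.panel, columns=names)
        return FiberFactorResults(
            model=self,
            loadings=load_df,
            phi=pd.DataFrame(Phi, index=names, columns=names),
            communalities=pd.Series(h2, index=self.panel, name="h2"),
            uniquenesses=pd.Series(u2, index=self.panel, name="u2"),
            kmo=overall_kmo,
            msa=msa,
            eigen_table=eigen_table,
            n_factors=m,
            factor_names=names,
            scores=pd.DataFrame(F, index=self.data.index,
                                columns=[f"F_{n}" for n in names]),
            settings={"method": method, "rotation": rotation,
                      "score_method": score_method, "n_factors": n_factors,
                      "pa_reps": pa_reps, "pa_quantile": pa_quantile,
                      "seed": seed},
        )


@dataclass
class FiberFactorResults:
    """Fitted loadings, adequacy diagnostics and per-cell factor scores."""

    model: FiberFactorModel
    loadings: pd.DataFrame
    phi: pd.DataFrame
    communalities: pd.Series
    uniquenesses: pd.Series
    kmo: float
    msa: pd.Series
    eigen_table: pd.DataFrame | None
    n_factors: int
    factor_names: list[str]
    scores: pd.DataFrame
    settings: dict = field(default_factory=dict)

    def loading_table(self) -> pd.DataFrame:
        tab = self.loadings.copy()
        tab["h2"] = self.communalities
        tab["u2"] = self.uniquenesses
        tab["MSA"] = self.msa.to_numpy()
        return tab.reset_index(names="gene")

    def summary(self) -> str:
        lines = ["Fiber-type factor analysis",
                 "=" * 60,
                 f"cells: {len(self.scores)}   panel genes: "
                 f"{len(self.model.panel)}   factors: {self.n_factors}",
                 f"overall KMO: {self.kmo:.3f}",
                 "",
                 "Pattern loadings (oblique), communalities, uniquenesses:",
                 self.loading_table().to_string(index=False,
                                                float_format="%.3f"),
                 "",
                 "Factor correlations (Phi):",
                 self.phi.to_string(float_format="%.3f")]
        if self.eigen_table is not None:
            lines += ["", "Parallel analysis (observed vs null quantile):",
                      self.eigen_table.to_string(index=False,
                                                 float_format="%.3f")]
        return "\n".join(lines)

    def plot_score_histograms(self, bins: int = 60, ax=None):
        """Histograms of the factor scores (threshold-picking aid)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for col in self.scores.columns:
            ax.hist(self.scores[col], bins=bins, alpha=0.5, label=col)
        ax.set_xlabel("factor score")
        ax.set_ylabel("cells")
        ax.legend()
        return ax
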