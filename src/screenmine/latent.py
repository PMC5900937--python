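"""Latent structure of binary screening indicators.

The observed 0/1 indicators are modelled as dichotomized bivariate-normal
variables: item j is present when a latent standard-normal variate exceeds a
threshold fixed by its marginal prevalence. Under that model the association
between two items on the latent scale is the *tetrachoric* correlation,
estimated here by profile maximum likelihood: thresholds are fixed at the
inverse-normal quantiles of the margins and the 2x2 cell probabilities are
maximized over the single correlation parameter.

The tetrachoric matrix feeds an exploratory factor analysis — iterated
principal-axis extraction followed by oblique (oblimin/quartimin) rotation —
and internal consistency of the resulting item groups is summarized with
Cronbach α.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .transactions import TransactionMatrix

__all__ = [
    "TetrachoricResult",
    "TetrachoricMatrix",
    "FactorSolution",
    "AlphaReport",
    "bivariate_normal_cdf",
    "tetrachoric_pair",
    "tetrachoric_matrix",
    "principal_axis_factor",
    "oblimin_rotate",
    "assign_items",
    "cronbach_alpha",
    "tucker_congruence",
    "match_factors",
]

_RHO_BOUND = 0.999


def bivariate_normal_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Evaluated in closed form through Owen's T function, which is accurate
    over the whole correlation range including |rho| near 1.
    """
    if abs(rho) >= 1.0:
        if rho >= 1.0:
            return float(stats.norm.cdf(min(h, k)))
        return float(max(stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0, 0.0))
    if rho == 0.0:
        return float(stats.norm.cdf(h) * stats.norm.cdf(k))
    if h == 0.0 and k == 0.0:
        return 0.25 + math.asin(rho) / (2.0 * math.pi)
    # Owen (1956); zero arguments are nudged off the removable singularity.
    eps = 1e-14
    hh = h if h != 0.0 else eps
    kk = k if k != 0.0 else eps
    s = math.sqrt(1.0 - rho * rho)
    a_h = (kk - rho * hh) / (hh * s)
    a_k = (hh - rho * kk) / (kk * s)
    delta = 0.0 if hh * kk > 0 else 0.5
    value = (
        0.5 * (stats.norm.cdf(hh) + stats.norm.cdf(kk))
        - float(special.owens_t(hh, a_h))
        - float(special.owens_t(kk, a_k))
        - delta
    )
    return float(min(max(value, 0.0), 1.0))


@dataclass(frozen=True)
class TetrachoricResult:
    rho: float
    converged: bool
    continuity_corrected: bool


def _cell_probabilities(t1: float, t2: float, rho: float) -> np.ndarray:
    """2x2 probabilities (p11, p10, p01, p00) with 1 = above threshold."""
    c1 = stats.norm.cdf(t1)
    c2 = stats.norm.cdf(t2)
    p00 = bivariate_normal_cdf(t1, t2, rho)
    p11 = 1.0 - c1 - c2 + p00
    p10 = (1.0 - c1) - p11
    p01 = (1.0 - c2) - p11
    return np.clip(np.array([p11, p10, p01, p00]), 1e-300, 1.0)


def tetrachoric_pair(table: np.ndarray) -> TetrachoricResult:
    """Profile-ML tetrachoric correlation from a 2x2 count table.

    ``table[i, j]`` counts patients with first item = i, second item = j
    (i, j in {1, 0} order: row/col 0 is "present"). Any zero cell triggers a
    0.5 continuity correction to every cell, flagged in the result.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("table must be a nonnegative 2x2 count matrix")
    if table.sum() == 0:
        raise ValueError("table has no observations")
    corrected = False
    if np.any(table == 0):
        table = table + 0.5
        corrected = True
    n11, n10 = table[0]
    n01, n00 = table[1]
    n = table.sum()
    p1 = (n11 + n10) / n
    p2 = (n11 + n01) / n
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("a margin is degenerate even after continuity correction")
    t1 = stats.norm.isf(p1)
    t2 = stats.norm.isf(p2)
    counts = np.array([n11, n10, n01, n00])

    def nll(rho: float) -> float:
        return -float(counts @ np.log(_cell_probabilities(t1, t2, rho)))

    res = optimize.minimize_scalar(
        nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(np.clip(res.x, -_RHO_BOUND, _RHO_BOUND))
    return TetrachoricResult(rho=rho, converged=bool(res.success),
                             continuity_corrected=corrected)


@dataclass(frozen=True)
class TetrachoricMatrix:
    items: tuple[str, ...]
    values: np.ndarray
    converged: np.ndarray  # boolean per pair
    continuity_corrected: np.ndarray  # boolean per pair
    smoothed: bool  # True when PSD eigenvalue clipping was applied

    def pair(self, a: str, b: str) -> float:
        i, j = self.items.index(a), self.items.index(b)
        return float(self.values[i, j])


def _nearest_psd(r: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and rescale back to unit diagonal."""
    w, v = np.linalg.eigh(r)
    w = np.maximum(w, floor)
    r2 = (v * w) @ v.T
    d = np.sqrt(np.diag(r2))
    r2 = r2 / np.outer(d, d)
    np.fill_diagonal(r2, 1.0)
    return r2


def tetrachoric_matrix(T: TransactionMatrix) -> TetrachoricMatrix:
    """Pairwise tetrachoric estimates, symmetrized and PSD-smoothed if needed."""
    m = T.m
    cols = [T.column(i).astype(bool) for i in T.items]
    for item, col in zip(T.items, cols):
        if col.all() or not col.any():
            raise ValueError(f"constant column: {item!r}")
    values = np.eye(m)
    converged = np.ones((m, m), dtype=bool)
    corrected = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            a, b = cols[i], cols[j]
            table = np.array(
                [
                    [(a & b).sum(), (a & ~b).sum()],
                    [(~a & b).sum(), (~a & ~b).sum()],
                ]
            )
            res = tetrachoric_pair(table)
            values[i, j] = values[j, i] = res.rho
            converged[i, j] = converged[j, i] = res.converged
            corrected[i, j] = corrected[j, i] = res.continuity_corrected
    smoothed = False
    if np.linalg.eigvalsh(values)[0] < 1e-6:
        values = _nearest_psd(values)
        smoothed = True
    return TetrachoricMatrix(tuple(T.items), values, converged, corrected, smoothed)


@dataclass(frozen=True)
class FactorSolution:
    items: tuple[str, ...]
    unrotated: np.ndarray  # m x k
    rotated: np.ndarray | None  # pattern loadings, m x k
    factor_correlations: np.ndarray | None  # k x k
    communalities: np.ndarray
    uniquenesses: np.ndarray
    iterations: int
    converged: bool
    heywood: bool
    residual_norm: float

    @property
    def loadings(self) -> np.ndarray:
        return self.unrotated if self.rotated is None else self.rotated

    def reproduced(self) -> np.ndarray:
        """Model-implied correlation matrix (common part, unit diagonal)."""
        if self.rotated is None or self.factor_correlations is None:
            rep = self.unrotated @ self.unrotated.T
        else:
            rep = self.rotated @ self.factor_correlations @ self.rotated.T
        rep = rep.copy()
        np.fill_diagonal(rep, 1.0)
        return rep


def _initial_communalities(r: np.ndarray) -> np.ndarray:
    """Squared multiple correlations; fall back to max |row correlation|."""
    try:
        inv = np.linalg.inv(r)
        smc = 1.0 - 1.0 / np.diag(inv)
        if np.all((smc > 0) & (smc < 1)):
            return smc
    except np.linalg.LinAlgError:
        pass
    off = np.abs(r - np.eye(r.shape[0]))
    return off.max(axis=1)


def principal_axis_factor(
    R: TetrachoricMatrix | np.ndarray,
    n_factors: int,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FactorSolution:
    """Iterated principal-axis extraction of ``n_factors`` common factors.

    The correlation matrix diagonal is replaced by communality estimates,
    the reduced matrix eigendecomposed, and communalities recomputed from
    the leading components until they stabilize. Communalities driven to or
    beyond 1 (Heywood cases) are clamped at 0.999 and flagged.
    """
    if isinstance(R, TetrachoricMatrix):
        items = R.items
        r = np.asarray(R.values, dtype=float)
    else:
        r = np.asarray(R, dtype=float)
        items = tuple(f"item{i + 1}" for i in range(r.shape[0]))
    m = r.shape[0]
    if not 1 <= n_factors < m:
        raise ValueError("n_factors must satisfy 1 <= n_factors < m")

    comm = np.clip(_initial_communalities(r), 1e-4, 0.999)
    heywood = False
    loadings = np.zeros((m, n_factors))
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        reduced = r.copy()
        np.fill_diagonal(reduced, comm)
        w, v = np.linalg.eigh(reduced)
        idx = np.argsort(w)[::-1][:n_factors]
        w_top = np.maximum(w[idx], 0.0)
        loadings = v[:, idx] * np.sqrt(w_top)
        new_comm = (loadings ** 2).sum(axis=1)
        if np.any(new_comm >= 1.0):
            heywood = True
            new_comm = np.minimum(new_comm, 0.999)
        if np.max(np.abs(new_comm - comm)) < tol:
            comm = new_comm
            converged = True
            break
        comm = new_comm
    # Deterministic sign: each factor's loading sum nonnegative.
    signs = np.where(loadings.sum(axis=0) < 0, -1.0, 1.0)
    loadings = loadings * signs
    residual = r - loadings @ loadings.T
    np.fill_diagonal(residual, 0.0)
    return FactorSolution(
        items=items,
        unrotated=loadings,
        rotated=None,
        factor_correlations=None,
        communalities=comm,
        uniquenesses=1.0 - comm,
        iterations=iterations,
        converged=converged,
        heywood=heywood,
        residual_norm=float(np.linalg.norm(residual)),
    )


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin criterion value and gradient wrt the pattern loadings."""
    L2 = L ** 2
    k = L.shape[1]
    N = np.ones((k, k)) - np.eye(k)
    f = float(np.sum(L2 * (L2 @ N))) / 4.0
    grad = L * (L2 @ N)
    return f, grad


def _gpa_oblique(
    A: np.ndarray,
    T0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Gradient-projection oblique rotation minimizing the quartimin criterion."""
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.diag(T.T @ G))
        s = float(np.linalg.norm(Gp))
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            v = 1.0 / np.sqrt(np.diag(X.T @ X))
            Tt = X * v
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    Phi = T.T @ T
    return L, Phi, f, converged


def oblimin_rotate(solution: FactorSolution, n_restarts: int = 5,
                   seed: int = 0) -> FactorSolution:
    """Oblique quartimin rotation of a principal-axis solution.

    Runs gradient projection from the identity start plus ``n_restarts``
    seeded random orthonormal starts and keeps the lowest criterion value.
    The reproduced correlation matrix is invariant under the rotation.
    """
    A = solution.unrotated
    k = A.shape[1]
    if k == 1:
        return solution
    starts = [np.eye(k)]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        q, _ = np.linalg.qr(rng.standard_normal((k, k)))
        starts.append(q)
    best = None
    for T0 in starts:
        L, Phi, f, converged = _gpa_oblique(A, T0)
        if best is None or f < best[2] - 1e-12:
            best = (L, Phi, f, converged)
    L, Phi, _, converged = best
    # Deterministic presentation: positive loading sums, factors ordered by
    # explained sum of squared loadings.
    signs = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    order = np.argsort(-(L ** 2).sum(axis=0), kind="stable")
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    return FactorSolution(
        items=solution.items,
        unrotated=solution.unrotated,
        rotated=L,
        factor_correlations=Phi,
        communalities=solution.communalities,
        uniquenesses=solution.uniquenesses,
        iterations=solution.iterations,
        converged=solution.converged and converged,
        heywood=solution.heywood,
        residual_norm=solution.residual_norm,
    )


@dataclass(frozen=True)
class ItemAssignment:
    factor: int | None  # 0-based factor index; None when unassignable
    loading: float
    tied: bool


def assign_items(solution: FactorSolution) -> dict[str, ItemAssignment]:
    """Assign each item to the factor with the largest |rotated loading|.

    Exact ties break toward the lower factor index (flagged); an all-zero
    loading row is flagged unassignable.
    """
    L = solution.loadings
    out: dict[str, ItemAssignment] = {}
    for i, item in enumerate(solution.items):
        row = np.abs(L[i])
        if np.all(row == 0.0):
            out[item] = ItemAssignment(factor=None, loading=0.0, tied=False)
            continue
        j = int(np.argmax(row))
        tied = int(np.sum(row == row[j])) > 1
        out[item] = ItemAssignment(factor=j, loading=float(L[i, j]), tied=tied)
    return out


@dataclass(frozen=True)
class AlphaReport:
    items: tuple[str, ...]
    k: int
    item_variances: np.ndarray
    total_variance: float
    alpha: float


def cronbach_alpha(T: TransactionMatrix, items: tuple[str, ...] | list[str]) -> AlphaReport:
    """Cronbach α = k/(k−1) · (1 − Σs_i²/s_T²) over 0/1 indicator columns.

    Population (divide-by-n) variances are used for both the item variances
    and the total-score variance, so the n-scaling cancels.
    """
    items = tuple(items)
    if len(items) < 2:
        raise ValueError("Cronbach alpha requires at least 2 items")
    cols = np.column_stack([T.column(i) for i in items]).astype(float)
    item_var = cols.var(axis=0)  # population convention
    total_var = cols.sum(axis=1).var()
    if total_var == 0:
        raise ValueError("total-score variance is zero")
    k = len(items)
    alpha = k / (k - 1) * (1.0 - item_var.sum() / total_var)
    return AlphaReport(items=items, k=k, item_variances=item_var,
                       total_variance=float(total_var), alpha=float(alpha))


def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(x @ y / math.sqrt((x @ x) * (y @ y)))


def match_factors(recovered: np.ndarray, target: np.ndarray) -> tuple[list[int], list[float]]:
    """Greedy matching of recovered factor columns to target columns.

    Returns, per target column, the index of the matched recovered column and
    the absolute Tucker congruence of the match.
    """
    k = target.shape[1]
    available = list(range(recovered.shape[1]))
    assignment: list[int] = []
    congruences: list[float] = []
    for j in range(k):
        scores = [abs(tucker_congruence(recovered[:, c], target[:, j])) for c in available]
        best = int(np.argmax(scores))
        assignment.append(available.pop(best))
        congruences.append(scores[best])
    return assignment, congruences
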