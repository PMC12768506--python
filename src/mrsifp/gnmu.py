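"""Global non-negative matrix underapproximation (G-NMU).

Factorizes a non-negative spectral matrix ``X`` (m spectral points x n
voxels) into non-negative ``W`` (m x r source spectra) and ``H`` (r x n
contributions) under the element-wise underapproximation constraint

    W @ H <= X.

Unlike plain NMF, the constraint forbids overestimating signal anywhere,
which yields sparse, additive, part-based sources — appropriate for
magnitude MR spectra where a source should never explain more signal than
was observed.

Solver
------
The constrained problem is attacked by Lagrangian relaxation, the standard
approach in the underapproximation literature: multipliers ``Lam >= 0`` on
the violated constraints are maintained, (W, H) are updated by HALS
(hierarchical alternating least squares, a projected block coordinate
descent) on the shifted data ``X - Lam``, and the multipliers follow a
diminishing-step subgradient update ``Lam <- max(0, Lam - rho/t (X - WH))``.
Rank one is a special case with an exact feasible alternating scheme: for a
fixed spectrum ``w`` the optimal contribution of each voxel has a closed
form (an unconstrained least-squares coefficient clipped to the largest
feasible value), and symmetrically for ``w`` given ``h``; each half-step is
an exact constrained minimizer, so the objective is monotone and every
iterate is feasible.

After the iterations, a final feasibility projection rescales each voxel's
contribution vector by the largest factor <= 1 keeping ``W h <= x``, so the
defining invariant holds exactly, not just approximately. The iterate with
the lowest post-projection objective is retained, making the reported
objective sequence non-increasing by construction.

A recursive mode (rank-one fit, subtract, repeat — classical NMU deflation,
valid because a feasible rank-one fit leaves a non-negative residual) is
available for comparison; the global mode, which fits all r sources
jointly, is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .basis import MetaboliteBasis

logger = logging.getLogger(__name__)

__all__ = [
    "SourceSet",
    "gnmu_decompose",
    "project_contributions",
    "source_composition",
    "feasibility_violation",
]


@dataclass
class SourceSet:
    """Result of a G-NMU decomposition.

    ``W`` columns are scaled to unit maximum (magnitudes carried by ``H``)
    and sources are ordered by total contribution, descending.
    """

    W: np.ndarray  # m x r, non-negative, unit-max columns
    H: np.ndarray  # r x n, non-negative
    r: int
    residual: float  # ||X - WH||_F at the returned iterate
    iterations_run: int
    objective_history: np.ndarray = field(repr=False, default=None)
    ppm_axis: np.ndarray | None = field(repr=False, default=None)


def feasibility_violation(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """max(WH - X): positive values are underapproximation violations."""
    return float((W @ H - X).max())


def _project_feasible(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Largest per-column scaling s_j <= 1 of H such that W H <= X exactly."""
    V = W @ H
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(V > 0, X / np.where(V > 0, V, 1.0), np.inf)
    scale = np.minimum(ratio.min(axis=0), 1.0)
    scale = np.where(np.isfinite(scale), scale, 1.0)
    return H * scale[None, :]


def _nndsvd(X: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization (zeros filled with the data mean)."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    m, n = X.shape
    W = np.zeros((m, r))
    H = np.zeros((r, n))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for k in range(1, min(r, len(S))):
        u, v = U[:, k], Vt[k]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_p = np.linalg.norm(up) * np.linalg.norm(vp)
        n_n = np.linalg.norm(un) * np.linalg.norm(vn)
        if n_p >= n_n:
            norm_u, norm_v = np.linalg.norm(up), np.linalg.norm(vp)
            if norm_u * norm_v > 0:
                W[:, k] = np.sqrt(S[k] * n_p) * up / norm_u
                H[k] = np.sqrt(S[k] * n_p) * vp / norm_v
        else:
            norm_u, norm_v = np.linalg.norm(un), np.linalg.norm(vn)
            if norm_u * norm_v > 0:
                W[:, k] = np.sqrt(S[k] * n_n) * un / norm_u
                H[k] = np.sqrt(S[k] * n_n) * vn / norm_v
    avg = X.mean()
    W[W <= 0] = avg / max(r, 1)
    H[H <= 0] = avg / max(r, 1)
    return W, H


def _rank_one_underapprox(
    X: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact feasible alternating minimization for rank-one NMU.

    Each half-step solves min ||x_j - h_j w||^2 s.t. 0 <= h_j w <= x_j in
    closed form (clip the LS coefficient to the feasibility bound), so
    iterates are always feasible and the objective never increases. The
    scheme is a local method; it is restarted from several deterministic
    initial spectra (leading singular vector, the largest data columns, a
    flat spectrum) and the best fit is kept.
    """
    U, _, _ = np.linalg.svd(X, full_matrices=False)
    m = X.shape[0]
    starts = [np.abs(U[:, 0]), np.ones(m)]
    col_order = np.argsort(-np.linalg.norm(X, axis=0), kind="stable")
    starts += [X[:, j].copy() for j in col_order[:8]]
    if m <= 10:
        # zeros in X wall off whole support patterns; for small problems
        # enumerate every binary support as an extra start
        starts += [
            np.array([(b >> i) & 1 for i in range(m)], dtype=float)
            for b in range(1, 2**m)
        ]
        starts += list(np.random.default_rng(0).uniform(0, 1, (16, m)))
    candidates = []
    for w0 in starts:
        w, h = _rank_one_from(X, w0, max_iter, tol)
        candidates.append((float(np.linalg.norm(X - np.outer(w, h))), w, h))
    candidates.sort(key=lambda t: t[0])
    best_obj, w, h = candidates[0]
    best = (w, h)
    if best_obj > float(np.linalg.norm(X)):
        best_obj, best = float(np.linalg.norm(X)), (np.zeros(m), np.zeros(X.shape[1]))
    if m <= 64:
        # the alternation's fixed points sit against feasibility walls; a
        # derivative-free polish of the reduced objective w -> min_h obj
        # escapes them at negligible cost for small problems. For the very
        # smallest problems the landscape has many narrow basins, so the
        # polish is additionally seeded from a coarse grid over spectra.
        from scipy.optimize import minimize

        polish_starts = [c[:2] for c in candidates[:5]]
        if m <= 6:
            polish_starts += _coarse_grid_seeds(X, levels=6, top=5)
        for _, w0 in polish_starts:
            res = minimize(
                lambda wv: _rank_one_reduced_obj(X, wv), w0, method="Powell",
                options={"xtol": 1e-6, "ftol": 1e-12, "maxiter": 2000},
            )
            if res.fun < best_obj:
                w = np.clip(res.x, 0.0, None)
                best_obj, best = res.fun, (w, _h_given_w(X, w))
    return best


def _coarse_grid_seeds(X: np.ndarray, levels: int, top: int) -> list[tuple[float, np.ndarray]]:
    """Best spectra from a coarse grid over [0,1]^m (one component pinned at 1),
    scored by the reduced rank-one objective with closed-form contributions."""
    m = X.shape[0]
    grid = np.linspace(0.0, 1.0, levels + 1)
    blocks = []
    for pin in range(m):
        rest = np.array(np.meshgrid(*[grid] * (m - 1))).reshape(m - 1, -1).T
        blocks.append(np.insert(rest, pin, 1.0, axis=1))
    W = np.unique(np.vstack(blocks), axis=0)
    wsq = (W**2).sum(axis=1)
    cross = W @ X
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(W[:, :, None] > 0,
                         X[None, :, :] / np.where(W[:, :, None] > 0, W[:, :, None], 1.0),
                         np.inf)
    h = np.clip(cross / wsq[:, None], 0.0, ratio.min(axis=1))
    obj2 = (X**2).sum() - (2 * h * cross - h**2 * wsq[:, None]).sum(axis=1)
    order = np.argsort(obj2, kind="stable")[:top]
    return [(float(np.sqrt(max(obj2[k], 0.0))), W[k]) for k in order]


def _h_given_w(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Closed-form optimal feasible contributions for a fixed spectrum."""
    wsq = float(w @ w)
    if wsq == 0:
        return np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        bound = np.where(w[:, None] > 0,
                         X / np.where(w[:, None] > 0, w[:, None], 1.0), np.inf)
    return np.clip((w @ X) / wsq, 0.0, bound.min(axis=0))


def _rank_one_reduced_obj(X: np.ndarray, wv: np.ndarray) -> float:
    w = np.clip(wv, 0.0, None)
    return float(np.linalg.norm(X - np.outer(w, _h_given_w(X, w))))


def _rank_one_from(X, w, max_iter, tol):
    if w.max() > 0:
        w = w / w.max()
    h = np.zeros(X.shape[1])
    prev = np.inf
    for it in range(max_iter):
        # h given w: per-column closed form
        wsq = float(w @ w)
        if wsq == 0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            bound = np.where(w[:, None] > 0, X / np.where(w[:, None] > 0, w[:, None], 1.0), np.inf)
        ub = bound.min(axis=0)
        h = np.clip((w @ X) / wsq, 0.0, ub)
        # w given h: per-row closed form
        hsq = float(h @ h)
        if hsq == 0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            bound = np.where(h[None, :] > 0, X / np.where(h[None, :] > 0, h[None, :], 1.0), np.inf)
        ub_w = bound.min(axis=1)
        w = np.clip((X @ h) / hsq, 0.0, ub_w)
        obj = float(np.linalg.norm(X - np.outer(w, h)))
        if prev - obj <= tol * max(prev, 1.0):
            break
        prev = obj
    return w, h


def _hals_sweep(R: np.ndarray, W: np.ndarray, H: np.ndarray) -> None:
    """One HALS sweep of H then W on min ||R - WH||_F, in place.

    R may contain negative entries (it is X - Lam); the projected updates
    remain valid coordinate-descent steps.
    """
    WtW = W.T @ W
    WtR = W.T @ R
    r = W.shape[1]
    for k in range(r):
        denom = WtW[k, k]
        if denom <= 1e-12:
            continue
        H[k] = np.maximum(0.0, H[k] + (WtR[k] - WtW[k] @ H) / denom)
    HHt = H @ H.T
    RHt = R @ H.T
    for k in range(r):
        denom = HHt[k, k]
        if denom <= 1e-12:
            continue
        W[:, k] = np.maximum(0.0, W[:, k] + (RHt[:, k] - W @ HHt[:, k]) / denom)


def gnmu_decompose(
    X: np.ndarray,
    r: int = 7,
    max_iter: int = 300,
    tol: float = 1e-8,
    seed: int = 0,
    mode: str = "global",
    init: str = "nndsvd",
    rho: float = 1.0,
    inner_iter: int = 2,
    ppm_axis: np.ndarray | None = None,
) -> SourceSet:
    """Decompose ``X >= 0`` into r non-negative sources with ``WH <= X``.

    Parameters
    ----------
    X:
        Non-negative matrix, m spectral points x n voxels.
    r:
        Number of sources; must satisfy 1 <= r <= min(m, n). Default 7,
        the rank at which glioma MRSI spectra resolve into interpretable
        neuronal/glial/oncometabolic sources.
    max_iter, tol:
        Outer iteration budget and relative objective-improvement stopping
        tolerance.
    seed:
        Seed for the random initialization (``init="random"``); the default
        SVD-based initialization is deterministic regardless.
    mode:
        ``"global"`` fits all sources jointly (default); ``"recursive"``
        deflates rank-one fits.
    rho:
        Base step of the diminishing multiplier update (global mode).
    inner_iter:
        HALS sweeps per outer iteration (global mode).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    m, n = X.shape
    if not 1 <= r <= min(m, n):
        raise ValueError(f"rank r={r} must lie in [1, min(m, n)={min(m, n)}]")

    if mode == "recursive":
        W, H, history, iters = _decompose_recursive(X, r, max_iter, tol)
    elif mode == "global":
        if r == 1:
            w, h = _rank_one_underapprox(X, max_iter, tol)
            W, H = w[:, None], h[None, :]
            history = np.array([float(np.linalg.norm(X - W @ H))])
            iters = max_iter
        else:
            W, H, history, iters = _decompose_global(
                X, r, max_iter, tol, seed, init, rho, inner_iter
            )
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'global' or 'recursive'")

    H = _project_feasible(X, W, H)
    # unit-max source spectra; magnitudes carried by H
    peak = W.max(axis=0)
    pos = peak > 0
    W[:, pos] /= peak[pos]
    H[pos] *= peak[pos, None]
    order = np.argsort(-H.sum(axis=1), kind="stable")
    W, H = W[:, order], H[order]
    residual = float(np.linalg.norm(X - W @ H))
    return SourceSet(
        W=W, H=H, r=r, residual=residual, iterations_run=iters,
        objective_history=np.asarray(history), ppm_axis=ppm_axis,
    )


def _decompose_global(X, r, max_iter, tol, seed, init, rho, inner_iter):
    m, n = X.shape
    if init == "nndsvd":
        W, H = _nndsvd(X, r)
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(X.mean() / r) if X.mean() > 0 else 1.0
        W = rng.uniform(0, 1, (m, r)) * scale
        H = rng.uniform(0, 1, (r, n)) * scale
    else:
        raise ValueError(f"unknown init {init!r}")

    # Phase 1: unconstrained HALS warm-up. Activating the multipliers from a
    # poor iterate lets early, large constraint violations dominate Lam and
    # the diminishing steps never recover; warming up to a good fit first
    # keeps the Lagrangian phase a refinement of the overshoot, not a restart.
    warmup = max(10, max_iter // 3)
    Lam = np.zeros_like(X)
    best_obj = np.inf
    best = (W.copy(), H.copy())
    history = []
    it = 0
    for it in range(1, max_iter + 1):
        R = X if it <= warmup else X - Lam
        for _ in range(inner_iter):
            _hals_sweep(R, W, H)
        if it > warmup:
            # Phase 2: diminishing-step subgradient ascent on the multipliers
            V = W @ H
            Lam = np.maximum(0.0, Lam - (rho / (it - warmup)) * (X - V))
        Hf = _project_feasible(X, W, H)
        obj = float(np.linalg.norm(X - W @ Hf))
        if obj < best_obj:
            best_obj, best = obj, (W.copy(), Hf)
        history.append(min(obj, best_obj))
    return best[0], best[1], np.minimum.accumulate(history), it


def _decompose_recursive(X, r, max_iter, tol):
    m, n = X.shape
    residual = X.copy()
    W = np.zeros((m, r))
    H = np.zeros((r, n))
    history = []
    for k in range(r):
        w, h = _rank_one_underapprox(residual, max_iter, tol)
        W[:, k], H[k] = w, h
        residual = np.maximum(residual - np.outer(w, h), 0.0)
        history.append(float(np.linalg.norm(X - W @ H)))
    return W, H, np.array(history), max_iter * r


def project_contributions(W: np.ndarray, X_new: np.ndarray) -> np.ndarray:
    """Non-negative least-squares contributions of fixed sources to new spectra.

    Solves ``h_j = argmin_{h>=0} ||x_j - W h||_2`` per voxel (column) and
    returns the r x n_new contribution matrix. Used both to re-quantify
    source contributions across tumor voxels and to project the tumor-derived
    sources onto healthy tissue.
    """
    W = np.asarray(W, dtype=float)
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[:, None]
    if X_new.shape[0] != W.shape[0]:
        raise ValueError(
            f"spectral-grid mismatch: W has {W.shape[0]} points, "
            f"spectra have {X_new.shape[0]}"
        )
    H = np.empty((W.shape[1], X_new.shape[1]))
    for j in range(X_new.shape[1]):
        H[:, j], _ = nnls(W, X_new[:, j])
    return H


def source_composition(W: np.ndarray, basis: MetaboliteBasis) -> np.ndarray:
    """Attribute each source spectrum to metabolites by NNLS unmixing.

    Each column of ``W`` is fit against all basis spectra with non-negative
    least squares; a metabolite's share is its fitted coefficient times the
    integral of its basis spectrum, normalized to sum to 100 per source.
    Returns an r x n_metabolites percentage matrix.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[0] != basis.n_points:
        raise ValueError(
            f"spectral-grid mismatch: W has {W.shape[0]} points, "
            f"basis has {basis.n_points}"
        )
    B = basis.spectra
    integrals = basis.integrals()
    frac = np.zeros((W.shape[1], B.shape[1]))
    for k in range(W.shape[1]):
        coef, _ = nnls(B, W[:, k])
        weight = coef * integrals
        total = weight.sum()
        if total > 0:
            frac[k] = 100.0 * weight / total
    return frac
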