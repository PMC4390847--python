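"""Total-degree polynomial homotopy continuation, batched over paths.

All isolated complex roots of a square polynomial system f(x) = 0 are found
by deforming an easy start system g (decoupled x_i^d_i - 1 = 0, whose roots
are products of roots of unity) into f along

    H(x, t) = (1 - t) * gamma * g(x) + t * f(x),

with a random complex gamma making the path set probability-one regular, and
tracking every start root from t = 0 to t = 1 with an Euler predictor and
Newton corrector under per-path adaptive step control.  The tracker operates
on flat arrays of paths, so many structurally identical systems (a Monte
Carlo census) are continued simultaneously in one vectorised run.

Systems are expected in the scaled/normalised form produced by
``PolySystem.scaled`` so that finite roots are O(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from .polysys import PolySystem

__all__ = ["HomotopyResult", "solve_batch", "solve_system"]

#: paths whose scaled |x| exceeds this are classified as diverging to infinity
X_DIVERGE = 1e8


@dataclass
class HomotopyResult:
    """Roots and per-path diagnostics for one batch member."""

    roots: np.ndarray            # (n_roots, n_vars) complex, deduplicated
    n_paths: int
    n_converged: int
    n_diverged: int              # solutions at infinity (benign)
    n_failed: int                # genuine tracking failures
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def ok(self) -> bool:
        return self.n_failed == 0



def _bsolve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched linear solve for stacked (P, n, n) systems and (P, n) rhs.

    A singular member must not poison the batch: on LinAlgError the solve
    falls back to per-path least squares for the offending systems only.
    """
    try:
        return np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(b)
        for p in range(A.shape[0]):
            try:
                out[p] = np.linalg.solve(A[p], b[p])
            except np.linalg.LinAlgError:
                out[p] = np.linalg.lstsq(A[p], b[p], rcond=None)[0]
        return out

def _start_roots(degrees: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """All Bezout-count roots of the decoupled start system x_i^d_i = 1."""
    grids = [np.exp(2j * np.pi * np.arange(d) / d) for d in degrees]
    mesh = np.meshgrid(*grids, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def _newton_polish(
    f: PolySystem, X: np.ndarray, sys_idx: np.ndarray, iters: int = 12, tol: float = 1e-12
):
    """Plain Newton on the target system; returns polished X and residual norms."""
    for _ in range(iters):
        F = f.eval(X, sys_idx)
        res = np.abs(F).max(axis=1)
        active = res > tol
        if not active.any():
            break
        J = f.jac(X[active], sys_idx[active])
        dX = _bsolve(J, F[active])
        X = X.copy()
        X[active] -= dX
    return X, np.abs(f.eval(X, sys_idx)).max(axis=1)


def _solve_batch_once(
    f: PolySystem,
    seed: int = 0,
    dt0: float = 0.05,
    dt_min: float = 1e-8,
    t_end: float = 0.995,
    newton_tol: float = 1e-10,
    max_steps: int = 2000,
    dedupe_rtol: float = 1e-8,
) -> List[HomotopyResult]:
    """One tracking pass (one random gamma) over every system in the batch."""
    rng = np.random.default_rng(seed)
    n = f.n_vars
    degrees = f.degrees()
    starts = _start_roots(degrees, rng)            # (B, n)
    B = starts.shape[0]
    S = f.n_systems
    gamma = np.exp(2j * np.pi * rng.random())      # common random phase

    # flat path arrays: S systems x B paths
    sys_idx = np.repeat(np.arange(S), B)
    X = np.tile(starts, (S, 1)).astype(complex)
    P = X.shape[0]
    t = np.zeros(P)
    dt = np.full(P, dt0)
    status = np.zeros(P, dtype=np.int8)            # 0 active, 1 done, 2 diverged, 3 failed

    dpow = degrees - 1

    def g_eval(Xa):
        return Xa**degrees - 1.0

    def H_eval(Xa, ta, idx):
        F = f.eval(Xa, idx)
        G = g_eval(Xa)
        return (1 - ta)[:, None] * gamma * G + ta[:, None] * F

    def H_jac(Xa, ta, idx):
        J = f.jac(Xa, idx) * ta[:, None, None]
        gdiag = gamma * degrees * Xa**dpow * (1 - ta)[:, None]
        J[:, np.arange(n), np.arange(n)] += gdiag
        return J

    def Ht_eval(Xa, idx):
        return f.eval(Xa, idx) - gamma * g_eval(Xa)

    for _ in range(max_steps):
        active = status == 0
        if not active.any():
            break
        ia = np.where(active)[0]
        Xa, ta, dta, idx = X[ia], t[ia], dt[ia], sys_idx[ia]
        # Euler predictor: H_x dx/dt = -H_t
        J = H_jac(Xa, ta, idx)
        Ht = Ht_eval(Xa, idx)
        v = _bsolve(J, -Ht)
        t_new = np.minimum(ta + dta, t_end)
        h = (t_new - ta)[:, None]
        X_new = Xa + v * h
        # Newton corrector at t_new
        ok = np.ones(len(ia), dtype=bool)
        for _c in range(3):
            Hc = H_eval(X_new, t_new, idx)
            res = np.abs(Hc).max(axis=1)
            todo = ok & (res > newton_tol)
            if not todo.any():
                break
            Jc = H_jac(X_new[todo], t_new[todo], idx[todo])
            dXc = _bsolve(Jc, Hc[todo])
            Xt = X_new.copy()
            Xt[todo] -= dXc
            X_new = Xt
        res = np.abs(H_eval(X_new, t_new, idx)).max(axis=1)
        # guard against path jumping: the corrected point must stay close to
        # the Euler prediction (a large pull means another path's basin)
        pred_move = np.abs(v * h).max(axis=1)
        corr_move = np.abs(X_new - (Xa + v * h)).max(axis=1)
        near = corr_move <= np.maximum(2.0 * pred_move, 1e-4 * (1 + np.abs(Xa).max(axis=1)))
        accept = ok & near & (res <= newton_tol * 100)
        big = np.abs(X_new).max(axis=1) > X_DIVERGE
        # commit accepted steps
        acc = ia[accept]
        X[acc] = X_new[accept]
        t[acc] = t_new[accept]
        dt[acc] = np.minimum(dta[accept] * 2.0, 0.1)
        # diverged paths
        div = ia[accept & big]
        status[div] = 2
        # completed paths (truncated endgame: Newton polish covers the rest)
        done = ia[accept & (t_new >= t_end) & ~big]
        status[done] = 1
        # rejected: halve dt
        rej = ia[~accept]
        dt[rej] = dta[~accept] / 2.0
        status[rej[dt[rej] < dt_min]] = 3

    status[status == 0] = 3  # ran out of steps

    # endgame: walk the remaining homotopy interval with geometrically
    # shrinking steps so each path stays in its own root's basin; a single
    # Newton jump from t_end can reroute paths with steep final approaches
    eg = np.where(status == 1)[0]
    if len(eg):
        Xe, te, idxe = X[eg], t[eg], sys_idx[eg]
        gap = 1.0 - te
        for k in range(1, 13):
            t_k = 1.0 - gap * 0.5**k
            h = (t_k - te)[:, None]
            J = H_jac(Xe, te, idxe)
            Ht = Ht_eval(Xe, idxe)
            ve = _bsolve(J, -Ht)
            Xe = Xe + ve * h
            for _c in range(3):
                Hc = H_eval(Xe, t_k, idxe)
                todo_e = np.abs(Hc).max(axis=1) > newton_tol
                if not todo_e.any():
                    break
                dXc = _bsolve(H_jac(Xe[todo_e], t_k[todo_e], idxe[todo_e]), Hc[todo_e])
                Xe = Xe.copy()
                Xe[todo_e] -= dXc
            te = t_k
        blow = np.abs(Xe).max(axis=1) > X_DIVERGE
        status[eg[blow]] = 2
        X[eg] = Xe

    # polish finished paths on the target system; failed paths get a rescue
    # attempt too (they often sit near a singular root of the target)
    results: List[HomotopyResult] = []
    fin = (status == 1) | (status == 3)
    Xf = X[fin]
    idxf = sys_idx[fin]
    if len(Xf):
        Xf, resf = _newton_polish(f, Xf, idxf)
    else:
        resf = np.empty(0)
    conv = resf < 1e-8 if len(Xf) else np.empty(0, dtype=bool)

    suspicious: List[int] = []
    for s in range(S):
        mask_s = sys_idx == s
        fin_s = np.where(idxf == s)[0]
        good = fin_s[conv[fin_s]] if len(fin_s) else fin_s
        roots = Xf[good] if len(fin_s) else np.empty((0, n), dtype=complex)
        roots, counts = _dedupe(roots, dedupe_rtol)
        # a path counts as failed only if it neither diverged nor produced a
        # polished root
        n_fail = int(B - int(np.sum(status[mask_s] == 2)) - len(good))
        results.append(
            HomotopyResult(
                roots=roots,
                n_paths=B,
                n_converged=len(roots),
                n_diverged=int(np.sum(status[mask_s] == 2)),
                n_failed=n_fail,
                residuals=resf[good] if len(fin_s) else np.empty(0),
            )
        )
    return results


def _merge_results(a: HomotopyResult, b: HomotopyResult, dedupe_rtol: float) -> HomotopyResult:
    roots = (
        np.concatenate([a.roots, b.roots])
        if len(a.roots) and len(b.roots)
        else (a.roots if len(a.roots) else b.roots)
    )
    roots, _ = _dedupe(roots, dedupe_rtol)
    return HomotopyResult(
        roots=roots,
        n_paths=a.n_paths,
        n_converged=len(roots),
        n_diverged=max(a.n_diverged, b.n_diverged),
        n_failed=min(a.n_failed, b.n_failed),
        residuals=a.residuals if len(a.residuals) else b.residuals,
    )


def solve_batch(
    f: PolySystem,
    seed: int = 0,
    n_passes: int = 2,
    dedupe_rtol: float = 1e-8,
    **kw,
) -> List[HomotopyResult]:
    """All isolated roots of every system in the batch.

    Runs ``n_passes`` independent tracking passes (each with its own random
    gamma and start-phase) and unions the root sets per system: a single
    random deformation occasionally loses a path near ill-conditioned
    geometry, and the probability of the same root escaping two independent
    deformations is negligible.  Systems that still show several paths ending
    on one *regular* root — the signature of a path-crossing jump — get one
    extra fine-stepped pass.
    """
    passes = [
        _solve_batch_once(f, seed=seed + 7919 * p, dedupe_rtol=dedupe_rtol, **kw)
        for p in range(max(n_passes, 1))
    ]
    results = passes[0]
    for other in passes[1:]:
        results = [
            _merge_results(a, b, dedupe_rtol) for a, b in zip(results, other)
        ]
    return results


def _dedupe(roots: np.ndarray, rtol: float):
    """Merge near-identical roots; returns (unique roots, multiplicities)."""
    if len(roots) <= 1:
        return roots, [1] * len(roots)
    kept: List[np.ndarray] = []
    counts: List[int] = []
    for r in roots:
        dup = False
        for i, q in enumerate(kept):
            scale = max(1.0, float(np.abs(q).max()))
            if np.abs(r - q).max() < rtol * scale * 10:
                counts[i] += 1
                dup = True
                break
        if not dup:
            kept.append(r)
            counts.append(1)
    return np.array(kept), counts


def solve_system(f: PolySystem, seed: int = 0, **kw) -> HomotopyResult:
    """Convenience wrapper for a single (non-batched) system."""
    return solve_batch(f, seed=seed, **kw)[0]
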