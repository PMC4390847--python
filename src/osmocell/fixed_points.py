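"""Fixed points, bifurcation curves and spherical crossings.

The full variable-volume vesicle model is not polynomial (the surface term
carries a 2/3 power of the state), so its steady states are located by a
surface-sweep construction:

1. impose a constant membrane surface ``S_mu0``; the steady-state conditions
   become a square polynomial system solved completely by total-degree
   homotopy continuation;
2. convert each valid root to its implied volume and plot it at height
   ``S_mu0`` in morphology space;
3. sweep ``S_mu0``, linking roots into branches — the bifurcation curve.

Steady states of the full model are exactly the points where a branch crosses
the spherical line Phi = 1, i.e. where the imposed surface equals the sphere
surface for the implied volume.  Stability at step 1 ignores the dilution
term and surface variation, so it is reported as quasi-stability; crossings
can be confirmed by integrating the full model (see :mod:`osmocell.dynamics`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .homotopy import solve_batch, solve_system
from .network import ReactionNetwork, Reaction
from .polysys import PolySystem, steady_state_system, steady_state_system_batch, union_systems
from .reactor import (
    VesicleEnvironment,
    MembraneSpec,
    VesicleReactor,
    diameter_from_omega,
    sphere_omega_from_diameter,
    sphere_surface_from_diameter,
    surface_from_volume,
    reduced_surface,
)

__all__ = [
    "FixedPoint",
    "sweep_surface_many",
    "BifurcationCurve",
    "Branch",
    "steady_state_system",
    "solve_all_fixed_points",
    "filter_valid",
    "real_roots",
    "quasi_stability",
    "sweep_surface",
    "spherical_crossings",
    "classify_bistability",
    "schlogl_reservoir_fixed_points",
    "wilhelm_reservoir_fixed_points",
    "CouplingCurve",
    "coupling_response_curve",
    "cyclic_condition_crossings",
    "multistart_roots",
    "default_surface_grid",
]

#: relative tolerance below which an imaginary part is considered noise
IMAG_TOL = 1e-8
#: relative distance below which two roots are merged
DEDUPE_RTOL = 1e-8
#: eigenvalue tolerance factor (times spectral radius) for marginality
STAB_TOL = 1e-9
#: fixed points larger than this equivalent-sphere diameter are discarded
OMEGA_MAX_DIAMETER_NM = 2000.0


@dataclass
class FixedPoint:
    """A steady state of the fixed-surface vesicle system.

    ``S_mu0`` is the imposed surface; ``omega`` the volume implied by the
    isotonic condition; ``phi`` their reduced surface.  ``stability`` is the
    quasi-stability label from the fixed-surface Jacobian.
    """

    s: Dict[str, float]
    S_mu0: float
    omega: float
    phi: float
    stability: str = "unclassified"
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    residual: float = float("nan")

    @property
    def s_vec(self) -> np.ndarray:
        return np.array(list(self.s.values()))

    @property
    def diameter_nm(self) -> float:
        return diameter_from_omega(self.omega)

    @property
    def total_concentration(self) -> float:
        return float(sum(self.s.values()))


@dataclass
class Branch:
    """An ordered run of linked fixed points across the surface grid."""

    points: List[FixedPoint] = field(default_factory=list)

    @property
    def surfaces(self) -> np.ndarray:
        return np.array([p.S_mu0 for p in self.points])

    @property
    def omegas(self) -> np.ndarray:
        return np.array([p.omega for p in self.points])


@dataclass
class BifurcationCurve:
    """Branches of fixed points swept over the imposed surface."""

    surface_grid: np.ndarray
    branches: List[Branch]
    reactor: Optional[VesicleReactor] = None
    diagnostics: Dict = field(default_factory=dict)

    def n_points_at(self, S_mu0: float, rtol: float = 1e-9) -> int:
        n = 0
        for br in self.branches:
            n += int(np.any(np.isclose(br.surfaces, S_mu0, rtol=rtol)))
        return n


# ---------------------------------------------------------------------------
# root solving and filtering

def real_roots(roots: np.ndarray, imag_tol: float = IMAG_TOL) -> np.ndarray:
    """Keep roots whose every component is numerically real; drop imag parts."""
    if len(roots) == 0:
        return np.empty((0, roots.shape[1] if roots.ndim == 2 else 0))
    ok = np.all(np.abs(roots.imag) < imag_tol * (1.0 + np.abs(roots.real)), axis=1)
    return roots[ok].real


def filter_valid(
    roots: np.ndarray,
    C_eps: float,
    B_T: float,
    omega_max: Optional[float] = None,
    neg_tol: float = 1e-10,
) -> np.ndarray:
    """Apply the physical validity filters to real candidate roots.

    Keeps roots with all concentrations >= 0 (tiny negative path-tracking
    noise is clamped), total concentration strictly below C_eps (positive
    volume), and implied volume below the size cap (default: sphere of
    2000 nm diameter).
    """
    if omega_max is None:
        omega_max = sphere_omega_from_diameter(OMEGA_MAX_DIAMETER_NM)
    if len(roots) == 0:
        return roots
    roots = np.array(roots, dtype=float)
    keep = np.all(roots >= -neg_tol * C_eps, axis=1)
    roots = np.clip(roots[keep], 0.0, None)
    if len(roots) == 0:
        return roots
    tot = roots.sum(axis=1)
    keep = tot < C_eps * (1.0 - 1e-12)
    roots = roots[keep]
    if len(roots) == 0:
        return roots
    omega = B_T / (C_eps - roots.sum(axis=1))
    return roots[omega < omega_max]


def quasi_stability(
    reactor: VesicleReactor,
    s: Dict[str, float] | np.ndarray,
    S_mu0: float,
    system: Optional[PolySystem] = None,
) -> Tuple[str, np.ndarray]:
    """Stability label from the fixed-surface Jacobian (no dilution term).

    Returns ``(label, eigenvalues)`` with label 'stable' when all eigenvalue
    real parts are negative, 'unstable' when any is positive, and 'marginal'
    within a tolerance band scaled by the spectral radius.
    """
    if system is None:
        system = steady_state_system(reactor, S_mu0)
    v = (
        reactor.network.concentrations_to_array(s)
        if isinstance(s, dict)
        else np.asarray(s, dtype=float)
    )
    J = system.jac(v.astype(complex)[None, :], np.zeros(1, dtype=np.int64))[0].real
    eig = np.linalg.eigvals(J)
    rad = float(np.abs(eig).max()) if len(eig) else 0.0
    tol = STAB_TOL * max(rad, 1e-300)
    re = eig.real
    if np.all(re < -tol):
        label = "stable"
    elif np.any(re > tol):
        label = "unstable"
    else:
        label = "marginal"
    return label, eig


def _make_fixed_point(
    reactor: VesicleReactor,
    v: np.ndarray,
    S_mu0: float,
    system: Optional[PolySystem] = None,
    classify: bool = True,
) -> FixedPoint:
    omega = reactor.B_T / (reactor.C_eps - float(v.sum()))
    phi = reduced_surface(omega, S_mu0)
    residual = float("nan")
    if system is not None:
        residual = float(
            np.abs(system.eval(v.astype(complex)[None, :], np.zeros(1, dtype=np.int64))).max()
        )
    fp = FixedPoint(
        s=reactor.network.array_to_concentrations(v),
        S_mu0=S_mu0,
        omega=omega,
        phi=phi,
        residual=residual,
    )
    if classify:
        fp.stability, fp.eigenvalues = quasi_stability(reactor, v, S_mu0, system)
    return fp


def solve_all_fixed_points(
    reactor: VesicleReactor,
    S_mu0: float,
    seed: int = 0,
    classify: bool = True,
    omega_max: Optional[float] = None,
) -> List[FixedPoint]:
    """All valid fixed points of the fixed-surface system at one surface.

    Solves the complete complex root set by total-degree homotopy
    continuation, filters to real, non-negative, positive-volume roots below
    the size cap, classifies quasi-stability and returns the fixed points
    sorted by increasing volume.
    """
    system = steady_state_system(reactor, S_mu0)
    scale = reactor.C_eps
    res = solve_system(system.scaled(scale), seed=seed)
    roots = real_roots(res.roots) * scale
    roots = _merge_duplicates(roots, scale)
    valid = filter_valid(roots, reactor.C_eps, reactor.B_T, omega_max=omega_max)
    fps = [
        _make_fixed_point(reactor, v, S_mu0, system, classify=classify) for v in valid
    ]
    fps.sort(key=lambda fp: fp.omega)
    return fps


def _merge_duplicates(roots: np.ndarray, scale: float) -> np.ndarray:
    if len(roots) <= 1:
        return roots
    kept: List[np.ndarray] = []
    for r in roots:
        if not any(np.abs(r - q).max() < DEDUPE_RTOL * scale * 10 for q in kept):
            kept.append(r)
    return np.array(kept)


# ---------------------------------------------------------------------------
# dense multi-start Newton oracle

def multistart_roots(
    system: PolySystem,
    box_hi: float,
    n_starts: int = 1000,
    seed: int = 0,
    tol: float = 1e-12,
    max_iter: int = 80,
) -> np.ndarray:
    """Real roots by damped Newton from many random starts (cross-check).

    Starts are uniform in [-0.1, 1.1] * box_hi per coordinate, deliberately
    overshooting the physical box so boundary roots are found.  Returns the
    deduplicated real converged points.  Independent of the homotopy tracker.
    """
    rng = np.random.default_rng(seed)
    n = system.n_vars
    scale = box_hi
    ps = system.scaled(scale)
    X = rng.uniform(-0.1, 1.1, size=(n_starts, n)).astype(complex)
    idx = np.zeros(n_starts, dtype=np.int64)
    for _ in range(max_iter):
        F = ps.eval(X, idx)
        res = np.abs(F).max(axis=1)
        act = res > tol
        if not act.any():
            break
        J = ps.jac(X[act], idx[act])
        try:
            dX = np.linalg.solve(J, F[act][..., None])[..., 0]
        except np.linalg.LinAlgError:
            dX = np.zeros_like(X[act])
            for p in range(int(act.sum())):
                try:
                    dX[p] = np.linalg.solve(J[p], F[act][p])
                except np.linalg.LinAlgError:
                    pass
        # damped update: cap the step to keep iterates finite
        step = np.abs(dX).max(axis=1, keepdims=True)
        damp = np.minimum(1.0, 10.0 / np.maximum(step, 1e-300))
        Xn = X.copy()
        Xn[act] = X[act] - dX * damp
        X = Xn
    F = ps.eval(X, idx)
    conv = np.abs(F).max(axis=1) < 1e-9
    roots = real_roots(X[conv], imag_tol=1e-7) * scale
    return _merge_duplicates(roots, scale)


# ---------------------------------------------------------------------------
# surface sweep and branch linking

def default_surface_grid(
    d_min_nm: float = 50.0, d_max_nm: float = 2000.0, n: int = 200
) -> np.ndarray:
    """Log-spaced surfaces spanning spheres of the given diameters."""
    s_lo = sphere_surface_from_diameter(d_min_nm)
    s_hi = sphere_surface_from_diameter(d_max_nm)
    return np.logspace(math.log10(s_lo), math.log10(s_hi), n)


#: cap on the per-step branch-linking distance in normalised concentrations
BRANCH_LINK_CAP = 0.2


def _link_key(fp: FixedPoint, C_eps: float) -> np.ndarray:
    # concentrations determine the state completely (the volume is an exact
    # function of them), and unlike log Omega they stay well scaled as the
    # solute total approaches C_eps on large-vesicle branches
    return fp.s_vec / C_eps


def sweep_surface_many(
    reactors: Sequence[VesicleReactor],
    surfaces: np.ndarray,
    seed: int = 0,
    classify: bool = True,
    link_cap: float = BRANCH_LINK_CAP,
    omega_max: Optional[float] = None,
) -> List[BifurcationCurve]:
    """Sweep several same-topology reactors over one surface grid at once.

    All (reactor, surface) systems are continued in a single batched homotopy
    run; used heavily by the parameter search, where many perturbed
    candidates are screened per iteration.
    """
    surfaces = np.asarray(surfaces, dtype=float)
    if np.any(np.diff(surfaces) <= 0) or np.any(surfaces <= 0):
        raise ValueError("surface grid must be positive and strictly increasing")
    systems = [
        steady_state_system(r, S) for r in reactors for S in surfaces
    ]
    batch = union_systems(systems)
    scales = np.repeat([r.C_eps for r in reactors], len(surfaces))
    results = solve_batch(batch.scaled(scales), seed=seed)

    curves: List[BifurcationCurve] = []
    nS = len(surfaces)
    for ri, reactor in enumerate(reactors):
        C_eps = reactor.C_eps
        per_surface: List[List[FixedPoint]] = []
        n_failed = 0
        for si, S_mu0 in enumerate(surfaces):
            res = results[ri * nS + si]
            n_failed += res.n_failed
            roots = _merge_duplicates(real_roots(res.roots) * C_eps, C_eps)
            valid = filter_valid(roots, C_eps, reactor.B_T, omega_max=omega_max)
            system = systems[ri * nS + si] if classify else None
            fps = [
                _make_fixed_point(reactor, v, S_mu0, system, classify=classify)
                for v in valid
            ]
            fps.sort(key=lambda fp: fp.omega)
            per_surface.append(fps)
        curves.append(
            _link_branches(reactor, surfaces, per_surface, link_cap, n_failed)
        )
    return curves


def sweep_surface(
    reactor: VesicleReactor,
    surfaces: Optional[np.ndarray] = None,
    seed: int = 0,
    classify: bool = True,
    link_cap: float = BRANCH_LINK_CAP,
    omega_max: Optional[float] = None,
) -> BifurcationCurve:
    """Build the bifurcation curve by sweeping the imposed surface.

    All surface values are solved in one batched homotopy run (the systems
    share their monomial structure), then roots are linked across adjacent
    grid values by nearest neighbour in (log10 Omega, s/C_eps) with a
    distance cap; unmatched roots open or close branches.
    """
    if surfaces is None:
        surfaces = default_surface_grid()
    return sweep_surface_many(
        [reactor], surfaces, seed=seed, classify=classify,
        link_cap=link_cap, omega_max=omega_max,
    )[0]


def _link_branches(
    reactor: VesicleReactor,
    surfaces: np.ndarray,
    per_surface: List[List[FixedPoint]],
    link_cap: float,
    n_failed: int,
) -> BifurcationCurve:
    C_eps = reactor.C_eps
    branches: List[Branch] = []
    open_branches: List[Branch] = []
    ambiguous = 0
    for fps in per_surface:
        prev_keys = [_link_key(br.points[-1], C_eps) for br in open_branches]
        new_keys = [_link_key(fp, C_eps) for fp in fps]
        pairs = []
        for i, pk in enumerate(prev_keys):
            for j, nk in enumerate(new_keys):
                d = float(np.linalg.norm(pk - nk))
                if d <= link_cap:
                    pairs.append((d, i, j))
        pairs.sort()
        used_prev, used_new = set(), set()
        matches = {}
        losers = set()
        for d, i, j in pairs:
            if i in used_prev or j in used_new:
                if i not in used_prev and j in used_new:
                    losers.add(i)
                continue
            used_prev.add(i)
            used_new.add(j)
            matches[i] = j
        # a transition is ambiguous only if a branch lost its sole candidate
        # to a competitor and therefore closes despite a nearby continuation
        ambiguous += sum(1 for i in losers if i not in used_prev)
        still_open: List[Branch] = []
        for i, br in enumerate(open_branches):
            if i in matches:
                br.points.append(fps[matches[i]])
                still_open.append(br)
            else:
                branches.append(br)
        for j, fp in enumerate(fps):
            if j not in used_new:
                still_open.append(Branch(points=[fp]))
        open_branches = still_open
    branches.extend(open_branches)
    branches.sort(key=lambda br: br.points[0].S_mu0)

    if ambiguous:
        warnings.warn(
            f"branch linking was ambiguous at {ambiguous} grid transitions; "
            "consider a finer surface grid",
            RuntimeWarning,
        )
    return BifurcationCurve(
        surface_grid=surfaces,
        branches=branches,
        reactor=reactor,
        diagnostics={"n_path_failures": n_failed, "n_ambiguous_links": ambiguous},
    )


# ---------------------------------------------------------------------------
# spherical (Phi = 1) crossings

def _newton_refine(
    system: PolySystem, v0: np.ndarray, scale: float, iters: int = 40, tol: float = 1e-13
) -> Optional[np.ndarray]:
    ps = system.scaled(scale)
    x = (v0 / scale).astype(complex)[None, :]
    idx = np.zeros(1, dtype=np.int64)
    for _ in range(iters):
        F = ps.eval(x, idx)
        if np.abs(F).max() < tol:
            break
        try:
            dx = np.linalg.solve(ps.jac(x, idx)[0], F[0])
        except np.linalg.LinAlgError:
            return None
        x = x - dx[None, :]
    if np.abs(ps.eval(x, idx)).max() > 1e-9:
        return None
    v = x[0].real * scale
    return v


def spherical_crossings(
    curve: BifurcationCurve,
    reactor: Optional[VesicleReactor] = None,
    phi_tol: float = 1e-6,
    max_bisect: int = 200,
) -> List[FixedPoint]:
    """Full-model steady states: branch crossings of the Phi = 1 line.

    Along each branch the sign of ``S_mu0 - sphere_surface(Omega*)`` is
    monitored; each sign change is refined by bisection on the imposed
    surface, re-solving the fixed-surface system locally by Newton from the
    bracketing root, until |Phi - 1| < ``phi_tol``.  Crossings at the grid
    edge are reported in the curve diagnostics instead.
    """
    reactor = reactor or curve.reactor
    if reactor is None:
        raise ValueError("a reactor is required to refine crossings")
    C_eps = reactor.C_eps
    crossings: List[FixedPoint] = []
    unresolved = []
    for br in curve.branches:
        pts = br.points
        fvals = [p.S_mu0 - surface_from_volume(p.omega) for p in pts]
        if len(pts) >= 1:
            # crossing exactly at an endpoint inside the grid still shows as a
            # sign change with a neighbour; a tangency at the edge does not.
            if len(pts) == 1 and abs(pts[0].phi - 1.0) < phi_tol:
                crossings.append(pts[0])
                continue
        for k in range(len(pts) - 1):
            if fvals[k] == 0.0:
                crossings.append(pts[k])
                continue
            if fvals[k] * fvals[k + 1] < 0:
                fp = _refine_crossing(
                    reactor, pts[k], pts[k + 1], phi_tol, max_bisect
                )
                if fp is not None:
                    crossings.append(fp)
                else:
                    unresolved.append((pts[k].S_mu0, pts[k + 1].S_mu0))
        if fvals and fvals[-1] == 0.0:
            crossings.append(pts[-1])
    if unresolved:
        curve.diagnostics.setdefault("unresolved_crossings", []).extend(unresolved)
        warnings.warn(
            f"{len(unresolved)} Phi=1 crossings could not be refined", RuntimeWarning
        )
    crossings.sort(key=lambda fp: fp.omega)
    return crossings


def _refine_crossing(
    reactor: VesicleReactor,
    lo: FixedPoint,
    hi: FixedPoint,
    phi_tol: float,
    max_bisect: int,
) -> Optional[FixedPoint]:
    C_eps = reactor.C_eps
    S_a, S_b = lo.S_mu0, hi.S_mu0
    v_a, v_b = lo.s_vec, hi.s_vec
    f_a = S_a - surface_from_volume(lo.omega)
    best = None
    for _ in range(max_bisect):
        if S_b - S_a <= 1e-14 * S_a:
            # interval exhausted (fold grazing the spherical line); accept the
            # best point seen if it is nearly spherical
            if best is not None and abs(best[2] - 1.0) < math.sqrt(phi_tol):
                v_m, S_m, _ = best
                return _make_fixed_point(
                    reactor, v_m, S_m, steady_state_system(reactor, S_m), classify=True
                )
            return None
        S_m = math.sqrt(S_a * S_b)  # geometric mid on the log-spaced axis
        system = steady_state_system(reactor, S_m)
        w = (math.log(S_m) - math.log(S_a)) / (math.log(S_b) - math.log(S_a))
        v0 = v_a * (1 - w) + v_b * w
        v_m = _newton_refine(system, v0, C_eps)
        if v_m is None:
            return None
        valid = filter_valid(v_m[None, :], C_eps, reactor.B_T, omega_max=np.inf)
        if len(valid) == 0:
            return None
        v_m = valid[0]
        omega_m = reactor.B_T / (C_eps - v_m.sum())
        f_m = S_m - surface_from_volume(omega_m)
        phi_m = reduced_surface(omega_m, S_m)
        if best is None or abs(phi_m - 1.0) < abs(best[2] - 1.0):
            best = (v_m, S_m, phi_m)
        if abs(phi_m - 1.0) < phi_tol:
            return _make_fixed_point(reactor, v_m, S_m, system, classify=True)
        if f_a * f_m < 0:
            S_b, v_b = S_m, v_m
        else:
            S_a, v_a, f_a = S_m, v_m, f_m
    return None


def classify_bistability(crossings: Sequence[FixedPoint]) -> str:
    """'bistable' iff exactly three crossings ordered stable/unstable/stable
    by increasing volume; 'monostable' for a single stable crossing; else
    'other'."""
    labels = [fp.stability for fp in sorted(crossings, key=lambda f: f.omega)]
    if labels == ["stable"]:
        return "monostable"
    if labels == ["stable", "unstable", "stable"]:
        return "bistable"
    return "other"


# ---------------------------------------------------------------------------
# closed-form bulk (reservoir) fixed points of the two reference switches

def schlogl_reservoir_fixed_points(
    x: float,
    z: float,
    k1: float = 5.25e4,
    k1r: float = 2.85e3,
    k2: float = 9.15e-2,
    k2r: float = 7.15e-3,
) -> np.ndarray:
    """Real positive steady states of the Schlögl switch under reservoirs.

    The intermediate Y obeys the cubic
    ``-k1r y^3 + k1 x y^2 - k2 y + k2r z = 0`` (X + 2Y <-> 3Y, Y <-> Z with
    X, Z clamped).  Roots come from the companion matrix; up to three.

    Note the default reverse trimolecular constant 2.85e3 M^-2 s^-1: only
    this value makes the classic bistable regime's three steady states
    consistent with the cubic's Vieta relations (root sum = k1*x/k1r, root
    product = k2r*z/k1r).
    """
    roots = np.roots([-k1r, k1 * x, -k2, k2r * z])
    real = roots[np.abs(roots.imag) < 1e-9 * (1 + np.abs(roots.real))].real
    return np.sort(real[real > 0])


def wilhelm_reservoir_fixed_points(
    x: float = 1.17e-3,
    k1: float = 5.86e2,
    k2: float = 9.26e2,
    k3: float = 5.75e2,
    k4: float = 9.98e-2,
) -> List[Tuple[float, float]]:
    """(y*, z*) steady states of the Wilhelm switch under reservoirs.

    Dynamics dy/dt = 2 k1 x z - k2 y^2 - k3 y z - k4 y,
    dz/dt = k2 y^2 - k1 x z reduce via z* = k2 y*^2/(k1 x) to the quadratic
    (k3 k2/(k1 x)) y^2 - k2 y + k4 = 0; (0, 0) is always a steady state.
    """
    pairs: List[Tuple[float, float]] = [(0.0, 0.0)]
    A = k3 * k2 / (k1 * x)
    disc = k2 * k2 - 4 * A * k4
    if disc >= 0:
        for y in ((k2 - math.sqrt(disc)) / (2 * A), (k2 + math.sqrt(disc)) / (2 * A)):
            if y > 0:
                pairs.append((y, k2 * y * y / (k1 * x)))
    pairs.sort(key=lambda p: p[0])
    return pairs


# ---------------------------------------------------------------------------
# osmotic coupling response curves

@dataclass
class CouplingCurve:
    """Steady-state particle number of one reaction set vs foreign buffer.

    For each value of ``B_extra`` (particles contributed by the other,
    chemically disjoint set), ``B_own`` lists the total particle number this
    set holds at each of its steady states with effective trapped buffer
    ``B_T + B_extra``.  Grid values with no valid steady state appear with an
    empty list (recorded gaps).
    """

    B_extra: np.ndarray
    B_own: List[List[float]]
    states: List[List[np.ndarray]]
    sub_reactor: VesicleReactor
    S_mu0: float

    def single_valued(self) -> Tuple[np.ndarray, np.ndarray]:
        """Return (B_extra, B_own) keeping only grid points with one state."""
        xs, ys = [], []
        for x, owns in zip(self.B_extra, self.B_own):
            if len(owns) == 1:
                xs.append(x)
                ys.append(owns[0])
        return np.array(xs), np.array(ys)

    def ranked_branches(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        """Approximate branches linking same-rank roots across the grid.

        Sub-networks are often multi-valued (a small-volume and a
        large-volume steady state); sorting the held particle numbers at
        each grid value and connecting equal ranks recovers the branch
        structure whenever branches do not cross.
        """
        out: List[Tuple[np.ndarray, np.ndarray]] = []
        max_rank = max((len(o) for o in self.B_own), default=0)
        for rank in range(max_rank):
            xs, ys = [], []
            for x, owns in zip(self.B_extra, self.B_own):
                if len(owns) > rank:
                    xs.append(x)
                    ys.append(sorted(owns)[rank])
            if len(xs) >= 1:
                out.append((np.array(xs), np.array(ys)))
        return out


def coupling_response_curve(
    sub_reactor: VesicleReactor,
    B_extra_grid: np.ndarray,
    S_mu0: float,
    C_eps: Optional[float] = None,
    seed: int = 0,
) -> CouplingCurve:
    """Response of one chemically-independent set to foreign buffer load.

    From the viewpoint of one reaction set, every molecule of the other set
    is inert trapped buffer, so its steady states solve the set's own
    fixed-surface system with ``B_T`` replaced by ``B_T + B_extra`` (and the
    full external total ``C_eps`` of the shared medium).  ``B_own`` is then
    ``Omega* x (sum of the set's concentrations)``.
    """
    B_extra_grid = np.asarray(B_extra_grid, dtype=float)
    env = sub_reactor.environment
    if C_eps is not None:
        extra_b = C_eps - env.C_eps
        if extra_b < -1e-15:
            raise ValueError("joint C_eps must be at least the sub-reactor's")
        env = VesicleEnvironment(b_eps=env.b_eps + extra_b, s_eps=dict(env.s_eps))
    C = env.C_eps
    B_own: List[List[float]] = []
    states: List[List[np.ndarray]] = []
    for B_extra in B_extra_grid:
        eff = VesicleReactor(
            network=sub_reactor.network,
            environment=env,
            membrane=sub_reactor.membrane,
            B_T=sub_reactor.B_T + B_extra,
        )
        fps = solve_all_fixed_points(eff, S_mu0, seed=seed, classify=False,
                                     omega_max=np.inf)
        owns = []
        sts = []
        for fp in fps:
            omega = eff.B_T / (C - fp.total_concentration)
            owns.append(omega * fp.total_concentration)
            sts.append(fp.s_vec)
        B_own.append(owns)
        states.append(sts)
    return CouplingCurve(B_extra_grid, B_own, states, sub_reactor, S_mu0)


def cyclic_condition_crossings(
    curve1: CouplingCurve,
    curve2: CouplingCurve,
    joint_reactor: Optional[VesicleReactor] = None,
    tol: float = 1e-8,
) -> List[Dict]:
    """Joint steady states from the mutual-buffer consistency condition.

    ``curve1`` gives B1 = f1(B2) and ``curve2`` gives B2 = f2(B1).  Their
    intersections in the (B1, B2) plane satisfy the cyclic condition: each
    set's steady state supplies exactly the buffer the other set assumed.
    Intersections are located by segment-pair crossing of the sampled curves
    and, when a ``joint_reactor`` is given, refined by Newton on the joint
    fixed-surface system and verified by its residual.
    """
    hits = []
    # curve 1 samples B1 = f1(B2): points (B1, B2) = (y, x) per branch;
    # curve 2 samples B2 = f2(B1): points (B1, B2) = (x, y)
    for x1, y1 in curve1.ranked_branches():
        p1 = np.stack([y1, x1], axis=1)
        for x2, y2 in curve2.ranked_branches():
            p2 = np.stack([x2, y2], axis=1)
            for a0, a1 in zip(p1[:-1], p1[1:]):
                for b0, b1 in zip(p2[:-1], p2[1:]):
                    pt = _segment_intersection(a0, a1, b0, b1)
                    if pt is not None:
                        hits.append(pt)
    out: List[Dict] = []
    for B1, B2 in hits:
        rec = {"B1": float(B1), "B2": float(B2), "verified": False}
        if joint_reactor is not None:
            rec.update(
                _verify_cyclic_point(curve1, curve2, joint_reactor, B1, B2, tol)
            )
        out.append(rec)
    out.sort(key=lambda r: (r["B1"], r["B2"]))
    return out


def _segment_intersection(a0, a1, b0, b1):
    d1 = a1 - a0
    d2 = b1 - b0
    den = d1[0] * d2[1] - d1[1] * d2[0]
    if den == 0:
        return None
    t = ((b0[0] - a0[0]) * d2[1] - (b0[1] - a0[1]) * d2[0]) / den
    u = ((b0[0] - a0[0]) * d1[1] - (b0[1] - a0[1]) * d1[0]) / den
    if -1e-12 <= t <= 1 + 1e-12 and -1e-12 <= u <= 1 + 1e-12:
        return a0 + t * d1
    return None


def _verify_cyclic_point(curve1, curve2, joint_reactor, B1, B2, tol):
    """Polish an intersection on the joint system and check its residual."""
    sub1, sub2 = curve1.sub_reactor, curve2.sub_reactor
    S_mu0 = curve1.S_mu0
    # starting concentrations: re-solve each sub-system at the crossing
    c1 = coupling_response_curve(sub1, np.array([B2]), S_mu0,
                                 C_eps=joint_reactor.C_eps)
    c2 = coupling_response_curve(sub2, np.array([B1]), S_mu0,
                                 C_eps=joint_reactor.C_eps)
    if not c1.states[0] or not c2.states[0]:
        return {"verified": False}
    # pick the state whose B_own is closest to the crossing estimate
    i1 = int(np.argmin([abs(b - B1) for b in c1.B_own[0]]))
    i2 = int(np.argmin([abs(b - B2) for b in c2.B_own[0]]))
    net = joint_reactor.network
    v0 = np.zeros(net.n_species)
    for sp, val in zip(sub1.network.species, c1.states[0][i1]):
        v0[net.index(sp)] = val
    for sp, val in zip(sub2.network.species, c2.states[0][i2]):
        v0[net.index(sp)] = val
    system = steady_state_system(joint_reactor, S_mu0)
    v = _newton_refine(system, v0, joint_reactor.C_eps)
    if v is None:
        return {"verified": False}
    res = float(
        np.abs(system.eval(v.astype(complex)[None, :], np.zeros(1, dtype=np.int64))).max()
    )
    fp = _make_fixed_point(joint_reactor, v, S_mu0, system, classify=True)
    return {
        "verified": res < max(tol, 1e-6 * np.abs(system.coeffs).max()),
        "residual": res,
        "fixed_point": fp,
    }
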