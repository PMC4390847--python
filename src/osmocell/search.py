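"""Monte-Carlo parameter-space search for vesicle bistability.

The pipeline mirrors a two-phase strategy:

* Phase 1 — "wide area" uniform sampling of rate constants, permeability
  multipliers, external concentrations and buffer load, solving the complete
  fixed-point set of every draw at one imposed surface (a 400-nm sphere) and
  taking a census of valid-fixed-point counts.  Draws with three fixed
  points are bistability candidates; a local "hot spot" resampling (every
  parameter perturbed uniformly +/-20%) amplifies them.

* Phase 2 — steering.  A candidate's bifurcation curve is moved through
  morphology space by the exact transformation
  {Omega, S_mu} -> {Omega*b*c, S_mu*b/a} obtained by scaling D_i by a*c and
  B_T by b*c (the polynomial system depends on these only through
  K_i = S_mu*D_i/B_T, so fixed-point concentrations are untouched).  The
  scaling is chosen so the curve crosses the spherical Phi = 1 line three
  times inside the viable vesicle size range, then verified by re-sweeping
  and by full-model integration at the stable crossings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fixed_points import (
    sweep_surface_many,
    BifurcationCurve,
    FixedPoint,
    classify_bistability,
    default_surface_grid,
    filter_valid,
    real_roots,
    solve_all_fixed_points,
    spherical_crossings,
    sweep_surface,
)
from .homotopy import solve_batch
from .network import Reaction, ReactionNetwork
from .polysys import steady_state_system_batch
from .reactor import (
    diameter_from_omega,
    sphere_omega_from_diameter,
    MembraneSpec,
    VesicleEnvironment,
    VesicleReactor,
    sphere_surface_from_diameter,
    surface_from_volume,
)

__all__ = [
    "SamplingRanges",
    "ScalingTransform",
    "CensusResult",
    "sample_wide",
    "sample_hotspot",
    "census",
    "transform_curve",
    "rescale_concentrations",
    "find_bistable_regimes",
    "schlogl_network",
    "wilhelm_network",
    "preset_ranges",
    "SCHLOGL_BULK",
    "WILHELM_BULK",
]

# classic bulk bistable regimes (concentrations M, first order s^-1,
# second order M^-1 s^-1, third order M^-2 s^-1)
SCHLOGL_BULK = {
    "x": 6.47e-4, "z": 6.32e-4,
    "k1": 5.25e4, "k1r": 2.85e3, "k2": 9.15e-2, "k2r": 7.15e-3,
}
WILHELM_BULK = {
    "x": 1.17e-3,
    "k1": 5.86e2, "k2": 9.26e2, "k3": 5.75e2, "k4": 9.98e-2,
}


def schlogl_network(k1r: float = SCHLOGL_BULK["k1r"]) -> ReactionNetwork:
    """Schlögl switch X + 2Y <-> 3Y, Y <-> Z with the bulk rate constants.

    The reverse trimolecular constant defaults to the Vieta-consistent
    2.85e3 M^-2 s^-1 and is exposed as a parameter.
    """
    b = SCHLOGL_BULK
    return ReactionNetwork(
        ["X", "Y", "Z"],
        [
            Reaction({"X": 1, "Y": 2}, {"Y": 3}, b["k1"], k1r),
            Reaction({"Y": 1}, {"Z": 1}, b["k2"], b["k2r"]),
        ],
    )


def wilhelm_network() -> ReactionNetwork:
    """Wilhelm switch (four irreversible reactions) with bulk rate constants."""
    b = WILHELM_BULK
    return ReactionNetwork(
        ["X", "Y", "Z", "W"],
        [
            Reaction({"X": 1, "Z": 1}, {"Y": 2}, b["k1"]),
            Reaction({"Y": 2}, {"Y": 1, "Z": 1}, b["k2"]),
            Reaction({"Y": 1, "Z": 1}, {"Z": 1, "W": 1}, b["k3"]),
            Reaction({"Y": 1}, {"W": 1}, b["k4"]),
        ],
    )


@dataclass
class SamplingRanges:
    """Uniform sampling ranges for the vesicle reactor parameter space.

    Defaults are the wide-area search ranges; the encapsulated Schlögl /
    Wilhelm census presets override concentrations to the low (mM) regime
    and pin reservoir externals and rate constants (see :func:`preset_ranges`).
    """

    k_range: Tuple[float, float] = (0.0, 10.0)
    kr_max_factor: float = 0.1          # reverse rate in (0, k * factor)
    D_mult_range: Tuple[float, float] = (0.2, 50.0)
    s_eps_range: Tuple[float, float] = (0.0, 0.2)
    b_eps_center: float = 0.2
    b_eps_frac: float = 0.4             # b_eps uniform in center*(1 +/- frac)
    B_T_range: Optional[Tuple[float, float]] = None  # overrides center/frac
    B_T_center: float = 63064.0
    B_T_frac: float = 0.4
    pinned_s_eps: Dict[str, float] = field(default_factory=dict)
    pin_rates: bool = False             # keep the template network's constants

    def __post_init__(self):
        for lo, hi in (self.k_range, self.D_mult_range, self.s_eps_range):
            if not (0 <= lo < hi):
                raise ValueError("ranges must satisfy 0 <= lo < hi")
        if self.B_T_range is not None and not (0 < self.B_T_range[0] < self.B_T_range[1]):
            raise ValueError("B_T range must be positive and increasing")


def preset_ranges(name: str) -> Tuple[ReactionNetwork, SamplingRanges]:
    """Named census presets for the encapsulated bulk switches.

    'schlogl_cs1' / 'wilhelm_cs1': permeability multipliers in (1/5, 50),
    non-reservoir externals in (0, 0.002) M, external buffer 0.002 M +/- 40%,
    trapped buffer count in (2, 2000), rate constants pinned to the bulk
    regimes, reservoir externals pinned (x and z for Schlögl, x for Wilhelm;
    the Wilhelm waste w diffuses with a sampled external concentration).
    """
    common = dict(
        s_eps_range=(0.0, 0.002),
        b_eps_center=0.002,
        b_eps_frac=0.4,
        B_T_range=(2.0, 2000.0),
        pin_rates=True,
    )
    if name == "schlogl_cs1":
        net = schlogl_network()
        ranges = SamplingRanges(
            pinned_s_eps={"X": SCHLOGL_BULK["x"], "Z": SCHLOGL_BULK["z"]}, **common
        )
        return net, ranges
    if name == "wilhelm_cs1":
        net = wilhelm_network()
        ranges = SamplingRanges(pinned_s_eps={"X": WILHELM_BULK["x"]}, **common)
        return net, ranges
    raise KeyError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# sampling

def _build_reactor(
    network: ReactionNetwork,
    rates: Sequence[Tuple[float, float]],
    D_mult: Dict[str, float],
    s_eps: Dict[str, float],
    b_eps: float,
    B_T: float,
) -> VesicleReactor:
    reactions = [
        replace(rx, k=k, kr=kr) for rx, (k, kr) in zip(network.reactions, rates)
    ]
    net = ReactionNetwork(list(network.species), reactions)
    return VesicleReactor(
        network=net,
        environment=VesicleEnvironment(b_eps=b_eps, s_eps=s_eps),
        membrane=MembraneSpec(D_mult=D_mult),
        B_T=B_T,
    )


def sample_wide(
    network: ReactionNetwork,
    ranges: SamplingRanges,
    n: int,
    seed: int,
) -> List[VesicleReactor]:
    """Draw ``n`` reactors uniformly from the wide-area sampling ranges."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    out: List[VesicleReactor] = []
    for _ in range(n):
        rates = []
        for rx in network.reactions:
            if ranges.pin_rates:
                rates.append((rx.k, rx.kr))
            else:
                k = rng.uniform(*ranges.k_range)
                kr = rng.uniform(0.0, k * ranges.kr_max_factor) if rx.reversible else 0.0
                rates.append((k, kr))
        D_mult = {sp: rng.uniform(*ranges.D_mult_range) for sp in network.species}
        s_eps = {}
        for sp in network.species:
            if sp in ranges.pinned_s_eps:
                s_eps[sp] = ranges.pinned_s_eps[sp]
            else:
                s_eps[sp] = rng.uniform(*ranges.s_eps_range)
        b_eps = ranges.b_eps_center * rng.uniform(
            1 - ranges.b_eps_frac, 1 + ranges.b_eps_frac
        )
        if ranges.B_T_range is not None:
            B_T = rng.uniform(*ranges.B_T_range)
        else:
            B_T = ranges.B_T_center * rng.uniform(
                1 - ranges.B_T_frac, 1 + ranges.B_T_frac
            )
        out.append(_build_reactor(network, rates, D_mult, s_eps, b_eps, B_T))
    return out


def sample_hotspot(
    basis: VesicleReactor,
    n: int,
    fraction: float = 0.2,
    seed: int = 0,
    pinned_s_eps: Sequence[str] = (),
    pin_rates: bool = False,
) -> List[VesicleReactor]:
    """Local resampling around a basis reactor: every free parameter uniform
    in basis * (1 +/- fraction)."""
    rng = np.random.default_rng(seed)

    def perturb(v: float) -> float:
        return v * rng.uniform(1 - fraction, 1 + fraction)

    out: List[VesicleReactor] = []
    for _ in range(n):
        rates = []
        for rx in basis.network.reactions:
            if pin_rates:
                rates.append((rx.k, rx.kr))
            else:
                rates.append((perturb(rx.k), perturb(rx.kr) if rx.kr > 0 else 0.0))
        D_mult = {
            sp: perturb(basis.membrane.D_mult.get(sp, 0.0))
            for sp in basis.network.species
        }
        s_eps = {}
        for sp in basis.network.species:
            v = basis.environment.s_eps.get(sp, 0.0)
            s_eps[sp] = v if sp in pinned_s_eps else perturb(v)
        out.append(
            _build_reactor(
                basis.network,
                rates,
                D_mult,
                s_eps,
                perturb(basis.environment.b_eps),
                perturb(basis.B_T),
            )
        )
    return out


# ---------------------------------------------------------------------------
# census

@dataclass
class CensusResult:
    """Valid-fixed-point census over a batch of sampled parameter sets."""

    counts: List[int]                  # per-set valid fixed point count
    n: int
    seed: int
    S_mu0: float
    n_solver_failures: int             # sets excluded from the fractions
    diagnostics: Dict = field(default_factory=dict)

    def fraction(self, k: int) -> float:
        """Fraction of (non-failed) sets with exactly k valid fixed points."""
        good = [c for c in self.counts if c >= 0]
        if not good:
            return float("nan")
        return sum(1 for c in good if c == k) / len(good)

    def summary(self) -> Dict[str, float]:
        good = [c for c in self.counts if c >= 0]
        out = {f"{k}": self.fraction(k) for k in range(4)}
        out["4+"] = sum(1 for c in good if c >= 4) / max(len(good), 1)
        return out


def census(
    reactors: Sequence[VesicleReactor],
    S_mu0: float,
    seed: int = 0,
    chunk: int = 250,
) -> CensusResult:
    """Count valid fixed points of every sampled reactor at one surface.

    All draws are continued in chunks of batched homotopy runs (the systems
    share their monomial structure).  A set whose homotopy run loses paths
    without rescue is recorded as a solver failure (count -1) and excluded
    from the census fractions.
    """
    counts: List[int] = []
    n_fail_sets = 0
    path_failures = 0
    for lo in range(0, len(reactors), chunk):
        part = reactors[lo : lo + chunk]
        batch = steady_state_system_batch(part, S_mu0)
        # scale each draw's variables by its own total external concentration
        scales = np.array([r.C_eps for r in part])
        results = solve_batch(batch.scaled(scales), seed=seed + lo)
        for r, res, scale in zip(part, results, scales):
            path_failures += res.n_failed
            if res.n_failed > 0 and res.n_converged == 0:
                counts.append(-1)
                n_fail_sets += 1
                continue
            roots = real_roots(res.roots) * scale
            valid = filter_valid(roots, r.C_eps, r.B_T)
            counts.append(len(valid))
    return CensusResult(
        counts=counts,
        n=len(reactors),
        seed=seed,
        S_mu0=S_mu0,
        n_solver_failures=n_fail_sets,
        diagnostics={"n_path_failures": path_failures},
    )


# ---------------------------------------------------------------------------
# structured transformations

@dataclass(frozen=True)
class ScalingTransform:
    """Morphology-space steering scalars (a, b, c), all > 0.

    Scaling every D_i by a*c and B_T by b*c leaves each K_i = S_mu*D_i/B_T
    invariant when the surface is rescaled by b/a and the volume by b*c, so
    fixed-point concentrations are unchanged while their morphology moves to
    {Omega*b*c, S_mu*b/a}.
    """

    a: float = 1.0
    b: float = 1.0
    c: float = 1.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("a, b, c must be > 0")

    def map_morphology(self, omega: float, S_mu: float) -> Tuple[float, float]:
        return omega * self.b * self.c, S_mu * self.b / self.a


def transform_curve(
    reactor: VesicleReactor, a: float, b: float, c: float
) -> Tuple[VesicleReactor, ScalingTransform]:
    """Apply the (a, b, c) steering transformation to a reactor.

    Returns the transformed reactor (D_i scaled by a*c, B_T by b*c) and the
    transform object whose ``map_morphology`` predicts where every fixed
    point of the original reactor lands in morphology space.
    """
    tr = ScalingTransform(a, b, c)
    membrane = MembraneSpec(
        D_mult={sp: m * a * c for sp, m in reactor.membrane.D_mult.items()},
        D_ref=reactor.membrane.D_ref,
        thickness=reactor.membrane.thickness,
    )
    new = VesicleReactor(
        network=reactor.network,
        environment=reactor.environment,
        membrane=membrane,
        B_T=reactor.B_T * b * c,
        phi_burst=reactor.phi_burst,
    )
    return new, tr


def rescale_concentrations(reactor: VesicleReactor, n_factor: float) -> VesicleReactor:
    """Rescale the concentration regime by 1/n_factor (e.g. molar -> 10 mM).

    External concentrations and B_T divide by n; a rate constant of order m
    multiplies by n^(m-1) (reverse constants by their own order), leaving
    fixed-point concentrations divided by n at identical {Omega, S_mu} and an
    unchanged time scale.
    """
    if n_factor <= 0:
        raise ValueError("n_factor must be > 0")
    n = n_factor
    reactions = [
        replace(
            rx,
            k=rx.k * n ** (rx.order - 1),
            kr=rx.kr * n ** (rx.reverse_order - 1) if rx.kr > 0 else 0.0,
        )
        for rx in reactor.network.reactions
    ]
    net = ReactionNetwork(list(reactor.network.species), reactions)
    env = VesicleEnvironment(
        b_eps=reactor.environment.b_eps / n,
        s_eps={sp: v / n for sp, v in reactor.environment.s_eps.items()},
    )
    return VesicleReactor(
        network=net,
        environment=env,
        membrane=reactor.membrane,
        B_T=reactor.B_T / n,
        phi_burst=reactor.phi_burst,
    )


# ---------------------------------------------------------------------------
# phase 2 steering: place three crossings on the Phi = 1 line

def _branch_f_series(curve: BifurcationCurve) -> List[np.ndarray]:
    """Per-branch series of f = log10 S_mu0 - log10 sphere_surface(Omega*).

    A fixed point is spherical iff f = 0; the (a,b,c) transformation shifts
    every f by the same amount, log10(b/a) - (2/3) log10(b*c).
    """
    out = []
    for br in curve.branches:
        f = np.array(
            [math.log10(p.S_mu0) - math.log10(surface_from_volume(p.omega)) for p in br.points]
        )
        out.append(f)
    return out


def _crossing_pattern(
    curve: BifurcationCurve, f_series: List[np.ndarray], w: float
) -> List[Tuple[float, str]]:
    """Crossings of the shifted curve with the spherical line.

    Returns (log10 Omega at the crossing, quasi-stability of the nearer
    bracketing point) for every sign change of f + w along every branch,
    sorted by volume.
    """
    out = []
    for br, f in zip(curve.branches, f_series):
        g = f + w
        for k in range(len(g) - 1):
            if g[k] * g[k + 1] < 0:
                lo, hi = br.points[k], br.points[k + 1]
                frac = abs(g[k]) / (abs(g[k]) + abs(g[k + 1]))
                logom = (1 - frac) * math.log10(lo.omega) + frac * math.log10(hi.omega)
                stab = lo.stability if abs(g[k]) < abs(g[k + 1]) else hi.stability
                out.append((logom, stab))
    out.sort()
    return out


def _steering_windows(
    curve: BifurcationCurve, f_series: List[np.ndarray]
) -> List[Tuple[float, float, float]]:
    """All shifts giving a stable/unstable/stable crossing pattern.

    Returns (w, spread, width) per qualifying window: ``spread`` is the
    log10-volume distance between the outer crossings (how far apart the two
    stable vesicle sizes are) and ``width`` the window's robustness in w.
    """
    crit = sorted({-v for f in f_series for v in f})
    if not crit:
        return []
    out = []
    edges = [crit[0] - 1e-3] + crit + [crit[-1] + 1e-3]
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo < 1e-12:
            continue
        w = 0.5 * (lo + hi)
        pattern = _crossing_pattern(curve, f_series, w)
        if [p[1] for p in pattern] == ["stable", "unstable", "stable"]:
            spread = pattern[-1][0] - pattern[0][0]
            out.append((w, spread, hi - lo))
    return out


#: target log10-volume spread of the crossing triple; 3.8 corresponds to a
#: ~18-fold diameter ratio, the small-SUV to mid-GUV span of the viability
#: window (the climb keeps shrinking the spread toward this)
_MAX_SPREAD = 3.8

#: largest spread still accepted for verification after the climb budget;
#: 5.9 is a ~90-fold diameter ratio
_ACCEPT_SPREAD = 5.9

#: quasi-stability violation (relative to the spectral radius) below which a
#: window is considered on-target by the hill climb; verification itself
#: admits any window with three well-separated crossings, because the
#: fixed-surface labels are predictors only and full-model integration is the
#: deciding stability check
_VIOL_CAP = 0.08

#: minimum log10-volume separation between adjacent crossings: smaller means
#: a fold grazing the spherical line (a tangency), not three distinct states
_MIN_SEPARATION = 0.15

#: minimum log10-volume spread of the whole triple: two "stable sizes" less
#: than a decade of volume apart are fold-local structure (and are where
#: coarse sweeps produce phantom crossings), not two distinct vesicle states
_MIN_SPREAD = 1.0


def _window_margin(
    curve: BifurcationCurve, f_series: List[np.ndarray], w: float
) -> Optional[Tuple[float, float]]:
    """Stability violation and spread of the three crossings at shift w.

    Crossings inherit a leading eigenvalue (real part, normalised by the
    local spectral radius) interpolated between the bracketing sweep points.
    The violation sums how far each crossing is from the required sign
    (outer two stable, middle unstable); 0 means the pattern is exactly
    stable/unstable/stable.  Returns None unless exactly three crossings.
    """
    xs = []
    for br, f in zip(curve.branches, f_series):
        g = f + w
        for k in range(len(g) - 1):
            if g[k] * g[k + 1] < 0:
                frac = abs(g[k]) / (abs(g[k]) + abs(g[k + 1]))
                p, q = br.points[k], br.points[k + 1]
                lam_p = p.eigenvalues.real.max() / max(np.abs(p.eigenvalues).max(), 1e-300)
                lam_q = q.eigenvalues.real.max() / max(np.abs(q.eigenvalues).max(), 1e-300)
                lam = (1 - frac) * lam_p + frac * lam_q
                logom = (1 - frac) * math.log10(p.omega) + frac * math.log10(q.omega)
                xs.append((logom, lam))
    if len(xs) != 3:
        return None
    xs.sort()
    viol = max(0.0, xs[0][1]) + max(0.0, -xs[1][1]) + max(0.0, xs[2][1])
    spread = xs[2][0] - xs[0][0]
    sep = min(xs[1][0] - xs[0][0], xs[2][0] - xs[1][0])
    return viol, spread, sep


def _steer_objective(
    curve: BifurcationCurve, f_series: List[np.ndarray]
) -> Tuple[float, Optional[float]]:
    """Staged scalar objective for the steering hill climb (0 = verify).

    Curves with no three-crossing shift window score 10 + segment-overlap
    gap (driving the stable/unstable/stable segments toward a common
    window); curves with a window score the smallest stability violation
    (continuous in the parameters, unlike the binary labels) plus any excess
    crossing spread beyond the viable size window.  The shift of the best
    window is returned alongside.
    """
    crit = sorted({-v for f in f_series for v in f})
    best: Tuple[float, Optional[float]] = (math.inf, None)
    if crit:
        edges = [crit[0] - 1e-3] + crit + [crit[-1] + 1e-3]
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi - lo < 1e-12:
                continue
            w = 0.5 * (lo + hi)
            ms = _window_margin(curve, f_series, w)
            if ms is None:
                continue
            viol, spread, sep = ms
            score = (
                max(0.0, viol - _VIOL_CAP)
                + max(0.0, spread - _ACCEPT_SPREAD)
                + max(0.0, _MIN_SPREAD - spread)
                + max(0.0, _MIN_SEPARATION - sep)
            )
            if score < best[0] or (score == best[0] == 0.0 and best[1] is None):
                best = (score, w)
    if best[1] is not None:
        return best
    gap = _overlap_gap(_stability_segments(curve, f_series))
    return 10.0 + min(max(gap, 0.0), 100.0), None


def _steering_shift(
    curve: BifurcationCurve, f_series: List[np.ndarray]
) -> Optional[float]:
    """Shift w for the most compact stable/unstable/stable crossing triple."""
    wins = _steering_windows(curve, f_series)
    if not wins:
        return None
    return min(wins, key=lambda t: t[1])[0]


def _stability_segments(
    curve: BifurcationCurve, f_series: List[np.ndarray]
) -> List[Tuple[str, float, float, float, float]]:
    """Constant-stability runs of each branch.

    Each segment is (label, f_min, f_max, log10 Omega at start, at end) where
    f = log10 S_mu0 - log10 sphere_surface(Omega*); the (a,b,c) transformation
    shifts every f rigidly, so these intervals decide which segments can be
    made to cross the spherical line together.
    """
    segs = []
    for br, f in zip(curve.branches, f_series):
        labs = [p.stability for p in br.points]
        start = 0
        for k in range(1, len(labs) + 1):
            if k == len(labs) or labs[k] != labs[start]:
                segs.append(
                    (
                        labs[start],
                        float(f[start:k].min()),
                        float(f[start:k].max()),
                        math.log10(br.points[start].omega),
                        math.log10(br.points[k - 1].omega),
                    )
                )
                start = k
    return segs


def _overlap_gap(segs: List[Tuple[str, float, float, float, float]]) -> float:
    """Infeasibility of a stable/unstable/stable triple under a rigid shift.

    Negative values mean some shift w puts a crossing on a small-volume
    stable segment, a mid-volume unstable segment and a large-volume stable
    segment simultaneously; positive values measure how far (in log10 units)
    the segment f-intervals are from overlapping.  Drives the hill climb.
    """
    stables = [s for s in segs if s[0] == "stable"]
    unstabs = [s for s in segs if s[0] == "unstable"]
    best = math.inf
    for s1 in stables:
        for s2 in stables:
            if s1 is s2:
                continue
            om1 = 0.5 * (s1[3] + s1[4])
            om2 = 0.5 * (s2[3] + s2[4])
            if om1 >= om2:
                continue
            for u in unstabs:
                # the unstable segment only needs to reach into the volume
                # range between the stable pair (segments can span decades)
                if max(u[3], u[4]) < min(s1[3], s1[4]) or min(u[3], u[4]) > max(
                    s2[3], s2[4]
                ):
                    continue
                lo = max(s1[1], s2[1], u[1])
                hi = min(s1[2], s2[2], u[2])
                best = min(best, lo - hi)
    return best


@dataclass
class BistableRegime:
    """A verified emergent-bistability record from the search pipeline.

    ``quasi_pattern`` records whether the three crossings carry the
    stable/unstable/stable labels already at the fixed-surface (quasi) level;
    ``confirmed_by_integration`` whether the outer crossings were confirmed
    as attractors of the full variable-volume dynamics, which is the
    decisive stability notion.
    """

    reactor: VesicleReactor
    transform: ScalingTransform
    crossings: List[FixedPoint]
    classification: str
    basis: Optional[VesicleReactor] = None
    confirmed_by_integration: bool = False
    quasi_pattern: bool = False


def find_bistable_regimes(
    network: ReactionNetwork,
    ranges: SamplingRanges,
    budget: int = 4000,
    seed: int = 0,
    S_mu0: Optional[float] = None,
    max_climbs: int = 4,
    hotspot_n: int = 250,
    n_sweep: int = 120,
    target_diameter_nm: float = 320.0,
    confirm: bool = True,
    max_verified: int = 1,
) -> List[BistableRegime]:
    """Full two-phase pipeline: wide sampling -> screening -> steering -> verify.

    Phase 1 censuses ``budget`` wide-area draws at a 400-nm surface and keeps
    draws with three or more valid fixed points.  Phase 2 screens every
    candidate's bifurcation curve for how close its stable/unstable/stable
    segments are to a common spherical crossing window (the steering
    objective), hill-climbs the ``max_climbs`` most promising candidates to
    close it, applies the exact (a,b,c) steering, and verifies the resulting
    three crossings by quasi-stability pattern and (with ``confirm``)
    full-model integration.

    Returns verified regimes (at most ``max_verified``); an empty list means
    the seeded budget produced no steerable candidate.
    """
    if budget <= 0:
        raise ValueError("budget must be > 0")
    if S_mu0 is None:
        S_mu0 = sphere_surface_from_diameter(400.0)
    draws = sample_wide(network, ranges, budget, seed)
    cens = census(draws, S_mu0, seed=seed)
    bases = [r for r, c in zip(draws, cens.counts) if c >= 3]
    if not bases:
        return []

    # hot-spot amplification: local +/-20% resampling around each wide-area
    # basis multiplies the candidate pool with diverse curve geometries
    rng = np.random.default_rng(seed + 211)
    candidates: List[VesicleReactor] = list(bases)
    for basis in bases[:3]:
        hot = sample_hotspot(
            basis, hotspot_n, fraction=0.2, seed=int(rng.integers(2**31)),
            pinned_s_eps=tuple(ranges.pinned_s_eps), pin_rates=ranges.pin_rates,
        )
        hc = census(hot, S_mu0, seed=seed + 101)
        candidates.extend(r for r, c in zip(hot, hc.counts) if c >= 3)

    # screening: batched wide sweeps over all candidates, ranked by objective
    wide = default_surface_grid(*_STEER_GRID)
    scored = []
    for lo in range(0, len(candidates), 40):
        part = candidates[lo : lo + 40]
        curves = sweep_surface_many(part, wide, seed=seed, classify=True,
                                    omega_max=np.inf)
        for r, c in zip(part, curves):
            obj, _ = _steer_objective(c, _branch_f_series(c))
            scored.append((obj, r, c))
    scored.sort(key=lambda t: t[0])

    regimes: List[BistableRegime] = []
    grid = default_surface_grid(n=n_sweep)
    for rank, (obj, cand, curve) in enumerate(scored[:max_climbs]):
        if obj > 100.0:
            continue
        regime = _steer_candidate(
            cand, grid, seed + 31 * rank, target_diameter_nm, confirm,
            start_curve=curve,
        )
        if regime is not None:
            regimes.append(regime)
            if len(regimes) >= max_verified:
                break
    return regimes


def _knob_moves(
    r: VesicleReactor, factors: Tuple[float, float] = (0.6, 1.7)
) -> List[VesicleReactor]:
    """Coordinate line-search proposals: each free parameter scaled alone.

    Complements the isotropic hot-spot proposals in the steering climb;
    single-parameter moves travel much further per evaluation when the
    objective is dominated by one knob (often a permeability ratio).
    """
    out: List[VesicleReactor] = []
    rates0 = [(rx.k, rx.kr) for rx in r.network.reactions]
    for f in factors:
        for j in range(len(rates0)):
            rates = list(rates0)
            rates[j] = (rates[j][0] * f, rates[j][1] * f)
            out.append(
                _build_reactor(r.network, rates, dict(r.membrane.D_mult),
                               dict(r.environment.s_eps), r.environment.b_eps, r.B_T)
            )
        for sp in r.network.species:
            D = dict(r.membrane.D_mult)
            D[sp] = D.get(sp, 0.0) * f
            out.append(
                _build_reactor(r.network, rates0, D, dict(r.environment.s_eps),
                               r.environment.b_eps, r.B_T)
            )
            if r.environment.s_eps.get(sp, 0.0) > 0:
                se = dict(r.environment.s_eps)
                se[sp] = se[sp] * f
                out.append(
                    _build_reactor(r.network, rates0, dict(r.membrane.D_mult), se,
                                   r.environment.b_eps, r.B_T)
                )
        out.append(
            _build_reactor(r.network, rates0, dict(r.membrane.D_mult),
                           dict(r.environment.s_eps), r.environment.b_eps * f, r.B_T)
        )
        out.append(
            _build_reactor(r.network, rates0, dict(r.membrane.D_mult),
                           dict(r.environment.s_eps), r.environment.b_eps, r.B_T * f)
        )
    return out


#: surface grid for steering sweeps: far beyond the viability window, since
#: the transformation can translate any region into it afterwards
_STEER_GRID = (2.0, 2e5, 96)


def _steer_candidate(
    cand: VesicleReactor,
    grid: np.ndarray,
    seed: int,
    target_diameter_nm: float,
    confirm: bool,
    climb_iters: int = 70,
    climb_proposals: int = 8,
    gap_goal: float = -0.05,
    start_curve: Optional[BifurcationCurve] = None,
    start_gap: Optional[float] = None,
) -> Optional[BistableRegime]:
    """Steer one three-fixed-point candidate into verified bistability.

    The rigid (a,b,c) transformation alone often cannot make both stable
    branch segments cross the spherical line, so a short seeded hill climb
    perturbs the free parameters (hot-spot style, +/-15%) to shrink the
    segment-overlap gap first; the shift and recentering are then exact.
    """
    wide = default_surface_grid(*_STEER_GRID)
    rng = np.random.default_rng(seed + 9173)
    cur = cand
    if start_curve is None:
        start_curve = sweep_surface(cur, wide, seed=seed, classify=True,
                                    omega_max=np.inf)
    curve = start_curve
    # candidates sometimes already admit a verifiable window: try before
    # spending the climb budget
    regime = _try_verify(cur, grid, seed, target_diameter_nm, confirm, cand)
    if regime is not None:
        return regime
    obj, w = _steer_objective(curve, _branch_f_series(curve))
    stale = 0
    for _ in range(climb_iters):
        if obj <= 0.0 or stale >= 16:
            break
        # proposal size tracks the objective: coarse while reshaping the
        # curve, fine while polishing a stability margin
        frac = float(min(0.15, max(0.03, obj))) if obj < 10 else 0.15
        props = _knob_moves(cur) + sample_hotspot(
            cur, climb_proposals, fraction=frac, seed=int(rng.integers(2**31))
        )
        prop_curves = sweep_surface_many(
            props, wide, seed=seed, classify=True, omega_max=np.inf
        )
        improved = False
        for p, c2 in zip(props, prop_curves):
            o2, w2 = _steer_objective(c2, _branch_f_series(c2))
            if o2 < obj:
                obj, cur, curve, w = o2, p, c2, w2
                improved = True
        stale = 0 if improved else stale + 1
    if cur is cand:
        return None
    return _try_verify(cur, grid, seed, target_diameter_nm, confirm, cand)


def _try_verify(
    cur: VesicleReactor,
    grid: np.ndarray,
    seed: int,
    target_diameter_nm: float,
    confirm: bool,
    basis: VesicleReactor,
) -> Optional[BistableRegime]:
    """Fine re-sweep of a candidate, then verify its best steering windows.

    Windows only need three well-separated crossings; the quasi-violation
    orders the attempts but full-model integration decides stability.
    """
    fine = sweep_surface(
        cur, default_surface_grid(_STEER_GRID[0], _STEER_GRID[1], 320),
        seed=seed, classify=True, omega_max=np.inf,
    )
    f_series = _branch_f_series(fine)
    for viol, spread, wmid in _verification_windows(fine, f_series)[:8]:
        regime = _verify_window(
            cur, fine, f_series, wmid, grid, seed, target_diameter_nm, confirm, basis
        )
        if regime is not None:
            return regime
    return None


def _verification_windows(
    curve: BifurcationCurve, f_series: List[np.ndarray]
) -> List[Tuple[float, float, float]]:
    """(violation, spread, shift) for every admissible steering window."""
    crit = sorted({-v for f in f_series for v in f})
    if not crit:
        return []
    out = []
    edges = [crit[0] - 1e-3] + crit + [crit[-1] + 1e-3]
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo < 1e-12:
            continue
        wmid = 0.5 * (lo + hi)
        ms = _window_margin(curve, f_series, wmid)
        if ms is None:
            continue
        viol, spread, sep = ms
        if _MIN_SPREAD <= spread <= _ACCEPT_SPREAD and sep >= _MIN_SEPARATION:
            out.append((viol, spread, wmid))
    out.sort()
    return out


def _verify_window(
    cur: VesicleReactor,
    curve: BifurcationCurve,
    f_series: List[np.ndarray],
    w: float,
    grid: np.ndarray,
    seed: int,
    target_diameter_nm: float,
    confirm: bool,
    basis: VesicleReactor,
) -> Optional[BistableRegime]:
    """Apply one steering shift and verify the crossing triple end to end."""
    # realise the shift with b = c = 1, a = 10^-w  (f shifts by -log10 a)
    a = 10.0 ** (-w)
    # recenter along the Phi=1 line: put the crossings' geometric-mean
    # diameter at the target (b scales every Omega, hence diameters by b^1/3)
    pattern = _crossing_pattern(curve, f_series, w)
    logom_mean = float(np.mean([p[0] for p in pattern]))
    d_mean = diameter_from_omega(10.0 ** logom_mean)
    b = (target_diameter_nm / d_mean) ** 3
    # moving along the Phi=1 line (slope 2/3 in log morphology space) needs
    # a coordinated surface factor: scale a by b^(1/3) so the crossing
    # pattern is preserved while every crossing diameter scales by b^(1/3)
    final, tr = transform_curve(cur, a * b ** (1.0 / 3.0), b, 1.0)
    # verification grid: cover the predicted crossing diameters with margin
    d_lo = diameter_from_omega(10.0 ** pattern[0][0]) * b ** (1 / 3) / 3.0
    d_hi = diameter_from_omega(10.0 ** pattern[-1][0]) * b ** (1 / 3) * 3.0
    vgrid = default_surface_grid(d_lo, d_hi, len(grid))
    curve3 = sweep_surface(final, vgrid, seed=seed, classify=True,
                           omega_max=sphere_omega_from_diameter(d_hi * 2))
    crossings = spherical_crossings(curve3, final)
    if len(crossings) != 3:
        return None
    # the three crossings must be genuinely distinct vesicle states, not a
    # fold grazing the spherical line (tangency) counted twice
    logoms = [math.log10(fp.omega) for fp in crossings]
    if min(np.diff(logoms)) < 0.15:
        return None
    quasi_ok = classify_bistability(crossings) == "bistable"
    # the fixed-surface labels are only predictors; the decisive test is
    # whether the outer crossings attract the full variable-volume dynamics
    confirmed = False
    if confirm:
        confirmed = _confirm_crossing(final, crossings[0]) and _confirm_crossing(
            final, crossings[2]
        )
        if not confirmed:
            return None
    elif not quasi_ok:
        return None
    return BistableRegime(
        reactor=final,
        transform=tr,
        crossings=crossings,
        classification="bistable",
        basis=basis,
        confirmed_by_integration=confirmed,
        quasi_pattern=quasi_ok,
    )


def _confirm_crossing(
    reactor: VesicleReactor,
    fp: FixedPoint,
    perturbation: float = 0.02,
    rel_tol: float = 0.01,
) -> bool:
    """Integrate the full model from small perturbations of a stable crossing.

    The quasi-stability label ignores the dilution term and surface
    variation, so a stable crossing is confirmed only if the full dynamics
    return from (i) +/-2% volume changes at fixed composition and (ii) a
    compositional jitter at fixed solute total.  Per-species concentration
    kicks are deliberately avoided: at large-vesicle states the solute total
    sits just below C_eps, so they translate into enormous volume excursions
    that can jump the saddle and say nothing about local stability.
    """
    from .dynamics import integrate  # deferred: avoid import cycle

    C = reactor.C_eps
    sv = fp.s_vec
    tot = float(sv.sum())
    jitter = np.array([1 + 0.25 * perturbation * (1 if i % 2 == 0 else -1)
                       for i in range(len(sv))])
    comp = sv * jitter
    comp *= tot / comp.sum()
    starts = [
        sv * (C - (C - tot) * (1 - perturbation)) / tot,
        sv * (C - (C - tot) * (1 + perturbation)) / tot,
        comp,
    ]
    rates = np.abs(fp.eigenvalues.real)
    slow = 1.0 / max(rates.min(), 1e-12) if len(rates) else 1e4
    ref = np.maximum(np.abs(sv), 1e-30)
    for v in starts:
        if v.sum() >= C:
            return False
        s0 = reactor.network.array_to_concentrations(v)
        try:
            traj = integrate(reactor, s0, (0.0, 20.0 * slow), n_samples=150)
        except Exception:
            return False
        if not np.all(np.abs(traj.s[-1] - sv) / ref < rel_tol):
            return False
    return True
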