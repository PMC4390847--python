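"""Time integration of the vesicle reactor, with syringe injections.

Two equivalent formulations are provided:

* concentration space — the variable-volume ODEs with the dilution term;
* molecule-number space — d n_i/dt = Omega r_i + S_mu D_i (s_eps_i - s_i),
  with the volume recovered exactly from Omega = (B_T + sum_j n_j) / C_eps.

The number-space form needs no dilution term (numbers are extensive), which
makes it both an independent oracle for the concentration form and the
natural home for injection events, which add molecules at a fixed rate.
Integration uses a stiff-capable adaptive method: steady-state branches may
sit at volumes orders of magnitude apart, with relaxation times from seconds
to days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .network import mak_rates_vec
from .reactor import (
    OsmoticBlowupError,
    VesicleReactor,
    _full_rhs_vec,
    diameter_from_omega,
    surface_from_volume,
)

__all__ = [
    "InjectionEvent",
    "Trajectory",
    "integrate",
    "number_space_rhs",
    "detect_steady_state",
]

#: default integrator tolerances (relative; absolute is in M or molecules)
RTOL = 1e-8
ATOL = 1e-12


@dataclass(frozen=True)
class InjectionEvent:
    """A simulated-syringe injection: molecules of one species at a fixed rate."""

    species: str
    rate: float          # molecules per second
    start: float         # s
    duration: float      # s

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("injection rate must be >= 0")
        if self.duration <= 0:
            raise ValueError("injection duration must be > 0")

    @property
    def end(self) -> float:
        return self.start + self.duration

    def active(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass
class Trajectory:
    """Time series of a vesicle reactor run.

    Concentrations in M, molecule numbers n_i = s_i * Omega, the scaled
    volume, surface area, reduced surface (identically 1 under spherical
    kinetics) and equivalent spherical diameter.
    """

    t: np.ndarray
    species: List[str]
    s: np.ndarray            # (n_times, n_species) M
    n: np.ndarray            # (n_times, n_species) molecules
    omega: np.ndarray
    S_mu: np.ndarray
    diameter_nm: np.ndarray
    events: List[InjectionEvent] = field(default_factory=list)

    def concentrations(self, i: int = -1) -> Dict[str, float]:
        return {sp: float(c) for sp, c in zip(self.species, self.s[i])}

    def isotonic_residual(self, B_T: float, C_eps: float) -> np.ndarray:
        """|B_T/Omega + sum(s) - C_eps| at every sample."""
        return np.abs(B_T / self.omega + self.s.sum(axis=1) - C_eps)

    def to_frame(self):
        """Wide-form pandas DataFrame of the full time series."""
        import pandas as pd

        data = {"t": self.t, "omega": self.omega, "S_mu": self.S_mu,
                "diameter_nm": self.diameter_nm}
        for j, sp in enumerate(self.species):
            data[f"s_{sp}"] = self.s[:, j]
            data[f"n_{sp}"] = self.n[:, j]
        return pd.DataFrame(data)


def number_space_rhs(
    reactor: VesicleReactor,
    n: Mapping[str, float] | np.ndarray,
    injection_rates: Optional[np.ndarray] = None,
) -> Dict[str, float] | np.ndarray:
    """Molecule-number derivatives dn_i/dt at a number state.

    Omega follows exactly from inverting the isotonic volume relation:
    Omega = (B_T + sum_j n_j) / C_eps.  Injections add their rate directly.
    Accepts and returns either a map or an array in species order.
    """
    net = reactor.network
    as_map = isinstance(n, Mapping)
    v = (
        np.array([float(n[sp]) for sp in net.species])
        if as_map
        else np.asarray(n, dtype=float)
    )
    omega = (reactor.B_T + v.sum()) / reactor.C_eps
    s = v / omega
    S_mu = surface_from_volume(omega)
    dn = omega * mak_rates_vec(net, s) + S_mu * reactor.D_vec() * (
        reactor.s_eps_vec() - s
    )
    if injection_rates is not None:
        dn = dn + injection_rates
    return net.array_to_concentrations(dn) if as_map else dn


def _injection_breakpoints(
    injections: Sequence[InjectionEvent], t0: float, t1: float
) -> List[float]:
    pts = {t0, t1}
    for ev in injections:
        for tp in (ev.start, ev.end):
            if t0 < tp < t1:
                pts.add(tp)
    return sorted(pts)


def integrate(
    reactor: VesicleReactor,
    s0: Mapping[str, float],
    t_span: Tuple[float, float],
    injections: Sequence[InjectionEvent] = (),
    rtol: float = RTOL,
    atol: float = ATOL,
    n_samples: int = 400,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the full variable-volume model from initial concentrations.

    The system is propagated in molecule-number space (exact volume
    inversion, injections additive) and converted to concentrations for
    output; injection start/end times are integration breakpoints so events
    are resolved sharply.  Raises :class:`OsmoticBlowupError` if the initial
    state is osmotically inadmissible.
    """
    net = reactor.network
    v0 = net.concentrations_to_array(s0)
    if v0.sum() >= reactor.C_eps:
        raise OsmoticBlowupError("initial solute total reaches C_eps")
    idx = {sp: i for i, sp in enumerate(net.species)}
    for ev in injections:
        if ev.species not in idx:
            raise ValueError(f"injection for undeclared species {ev.species!r}")

    omega0 = reactor.volume(v0)
    n0 = v0 * omega0
    t0, t1 = t_span
    breaks = _injection_breakpoints(injections, t0, t1)
    t_eval = np.linspace(t0, t1, n_samples)
    # absolute tolerance in molecules: concentration atol times typical volume
    atol_n = atol * omega0

    ts: List[np.ndarray] = []
    ns: List[np.ndarray] = []
    n_cur = n0
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)
        rates = np.zeros(net.n_species)
        for ev in injections:
            if ev.active(mid):
                rates[idx[ev.species]] += ev.rate

        def rhs(t, n):
            return number_space_rhs(reactor, np.maximum(n, 0.0), rates)

        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        if len(seg_eval) == 0 or seg_eval[0] > a:
            seg_eval = np.concatenate([[a], seg_eval])
        if seg_eval[-1] < b:
            seg_eval = np.concatenate([seg_eval, [b]])
        sol = solve_ivp(
            rhs, (a, b), n_cur, method=method, rtol=rtol, atol=atol_n,
            t_eval=seg_eval, dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{a:g}, {b:g}]: {sol.message}")
        ts.append(sol.t)
        ns.append(sol.y.T)
        n_cur = sol.y[:, -1]

    t_all = np.concatenate(ts)
    n_all = np.concatenate(ns)
    # guard against integrator undershoot
    low = n_all < 0
    if np.any(n_all < -atol_n * 1e3):
        raise RuntimeError("negative molecule numbers beyond tolerance")
    n_all[low] = 0.0
    omega = (reactor.B_T + n_all.sum(axis=1)) / reactor.C_eps
    s_all = n_all / omega[:, None]
    S_mu = np.array([surface_from_volume(w) for w in omega])
    return Trajectory(
        t=t_all,
        species=list(net.species),
        s=s_all,
        n=n_all,
        omega=omega,
        S_mu=S_mu,
        diameter_nm=np.array([diameter_from_omega(w) for w in omega]),
        events=list(injections),
    )


def detect_steady_state(
    traj: Trajectory, window: float, tol: float = 1e-6
) -> Tuple[bool, Dict[str, float]]:
    """Convergence check on the tail of a trajectory.

    Converged when the maximum relative concentration change of every species
    over the trailing ``window`` (in time units) is below ``tol``.  Returns
    the flag and the terminal concentration state.
    """
    if traj.t[-1] - traj.t[0] <= window:
        raise ValueError("trajectory shorter than the requested window")
    mask = traj.t >= traj.t[-1] - window
    tail = traj.s[mask]
    ref = np.maximum(np.abs(tail[-1]), 1e-300)
    rel = np.abs(tail - tail[-1]).max(axis=0) / ref
    return bool(np.all(rel < tol)), traj.concentrations(-1)
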