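"""Reactor formulations: reservoir, CSTR, and the semi-permeable vesicle.

The vesicle reactor couples a mass-action network to a compartment whose
aqueous volume is slaved to osmotic balance.  Water crosses the bilayer much
faster than any solute, so the total internal concentration (reacting solutes
plus ``B_T`` trapped impermeable buffer molecules) always equals the total
external concentration ``C_eps``.  That isotonic condition makes the scaled
volume an algebraic function of the internal state,

    Omega = B_T / (C_eps - sum_j s_j),

and the membrane surface follows the volume as a sphere.  Concentration ODEs
then pick up a membrane diffusion term and a dilution term from the changing
solvent volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .constants import BILAYER_THICKNESS, D_RIBOSE, N_A, PHI_BURST
from .network import ReactionNetwork, mak_rates_vec

__all__ = [
    "OsmoticBlowupError",
    "VesicleEnvironment",
    "MembraneSpec",
    "VesicleReactor",
    "CSTRSpec",
    "MorphologyPoint",
    "volume_from_concentrations",
    "surface_from_volume",
    "reduced_surface",
    "sphere_omega_from_diameter",
    "sphere_surface_from_diameter",
    "diameter_from_omega",
    "diameter_from_surface",
    "diffusion_constant",
    "rhs_cstr",
    "rhs_reservoir",
    "rhs_vesicle_highbuffer",
    "rhs_vesicle_full",
    "residence_time_equivalent",
]


class OsmoticBlowupError(ValueError):
    """Total internal solute concentration reached C_eps: volume is undefined.

    Physically the vesicle takes up water without bound; the model has no
    solution there, so the condition is an error rather than a clamp.
    """


# ---------------------------------------------------------------------------
# geometry

def volume_from_concentrations(B_T: float, C_eps: float, s: Mapping[str, float] | Sequence[float]) -> float:
    """Scaled vesicle volume Omega from the isotonic condition.

    ``s`` may be a concentration map or a plain sequence of concentrations.
    Raises :class:`OsmoticBlowupError` when the solute total reaches C_eps.
    """
    total = float(sum(s.values())) if isinstance(s, Mapping) else float(np.sum(s))
    if total >= C_eps:
        raise OsmoticBlowupError(
            f"total internal solute concentration {total:g} M >= C_eps {C_eps:g} M"
        )
    return B_T / (C_eps - total)


def surface_from_volume(omega: float) -> float:
    """Surface area (dm^2) of a sphere with scaled volume Omega.

    Exact sphere geometry: S = (36 pi V^2)^(1/3) with V = Omega/N_A in dm^3,
    so that the reduced surface of the pair (Omega, S) is exactly 1.
    """
    if omega <= 0:
        raise ValueError(f"Omega must be > 0, got {omega}")
    V = omega / N_A
    return (36.0 * math.pi * V * V) ** (1.0 / 3.0)


def reduced_surface(omega: float, S_mu: float) -> float:
    """Dimensionless reduced surface Phi = S / (sphere surface for Omega).

    Phi = 1 is spherical, Phi < 1 osmotically tense (burst near
    :data:`~osmocell.constants.PHI_BURST`), Phi > 1 deflated/filamentous.
    """
    if omega <= 0 or S_mu <= 0:
        raise ValueError("Omega and S_mu must be > 0")
    return S_mu / surface_from_volume(omega)


def sphere_omega_from_diameter(d_nm: float) -> float:
    """Scaled volume of a sphere of the given diameter in nm."""
    d_dm = d_nm * 1e-8  # 1 nm = 1e-8 dm
    return N_A * math.pi * d_dm**3 / 6.0


def sphere_surface_from_diameter(d_nm: float) -> float:
    """Surface area (dm^2) of a sphere of the given diameter in nm."""
    d_dm = d_nm * 1e-8
    return math.pi * d_dm**2


def diameter_from_omega(omega: float) -> float:
    """Equivalent-sphere diameter (nm) for a scaled volume."""
    V = omega / N_A
    return (6.0 * V / math.pi) ** (1.0 / 3.0) * 1e8


def diameter_from_surface(S_mu: float) -> float:
    """Equivalent-sphere diameter (nm) for a surface area in dm^2."""
    return math.sqrt(S_mu / math.pi) * 1e8


# ---------------------------------------------------------------------------
# domain types

@dataclass
class VesicleEnvironment:
    """External medium: buffer plus per-species solute concentrations (M)."""

    b_eps: float
    s_eps: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.b_eps < 0:
            raise ValueError("external buffer concentration must be >= 0")
        for sp, c in self.s_eps.items():
            if c < 0:
                raise ValueError(f"external concentration of {sp!r} must be >= 0")

    @property
    def C_eps(self) -> float:
        """Total external concentration, b_eps + sum of solutes."""
        return self.b_eps + sum(self.s_eps.values())


@dataclass
class MembraneSpec:
    """Bilayer permeability model: per-species multipliers of a reference.

    ``D_mult[sp]`` scales the ribose-through-oleic-acid reference permeability;
    0 means impermeable, and species absent from the map default to 0.
    """

    D_mult: Dict[str, float] = field(default_factory=dict)
    D_ref: float = D_RIBOSE
    thickness: float = BILAYER_THICKNESS

    def __post_init__(self):
        for sp, m in self.D_mult.items():
            if m < 0:
                raise ValueError(f"permeability multiplier of {sp!r} must be >= 0")
        if self.D_ref <= 0 or self.thickness <= 0:
            raise ValueError("reference permeability and thickness must be > 0")

    def diffusion_constant(self, species: str) -> float:
        """Effective membrane diffusion constant D_i = D_mult * D_ref / thickness."""
        return self.D_mult.get(species, 0.0) * self.D_ref / self.thickness


def diffusion_constant(D_mult: float, membrane: Optional[MembraneSpec] = None) -> float:
    """Effective diffusion constant for a bare multiplier (module-level form)."""
    if D_mult < 0:
        raise ValueError("permeability multiplier must be >= 0")
    if membrane is None:
        return D_mult * D_RIBOSE / BILAYER_THICKNESS
    return D_mult * membrane.D_ref / membrane.thickness


@dataclass
class VesicleReactor:
    """A reaction network inside a semi-permeable, variable-volume vesicle."""

    network: ReactionNetwork
    environment: VesicleEnvironment
    membrane: MembraneSpec
    B_T: float
    phi_burst: float = PHI_BURST

    def __post_init__(self):
        if not self.B_T > 0:
            raise ValueError("trapped buffer count B_T must be > 0")
        for sp in self.environment.s_eps:
            if sp not in self.network.species:
                raise ValueError(f"external concentration for undeclared species {sp!r}")
        for sp in self.membrane.D_mult:
            if sp not in self.network.species:
                raise ValueError(f"permeability for undeclared species {sp!r}")

    @property
    def C_eps(self) -> float:
        return self.environment.C_eps

    def s_eps_vec(self) -> np.ndarray:
        return np.array(
            [self.environment.s_eps.get(sp, 0.0) for sp in self.network.species]
        )

    def D_vec(self) -> np.ndarray:
        return np.array(
            [self.membrane.diffusion_constant(sp) for sp in self.network.species]
        )

    def volume(self, s: Mapping[str, float] | Sequence[float]) -> float:
        return volume_from_concentrations(self.B_T, self.C_eps, s)

    def morphology(self, s: Mapping[str, float] | Sequence[float], S_mu: Optional[float] = None) -> "MorphologyPoint":
        omega = self.volume(s)
        if S_mu is None:
            S_mu = surface_from_volume(omega)
        return MorphologyPoint.from_omega_surface(omega, S_mu)


@dataclass
class CSTRSpec:
    """Continuous-flow stirred tank reactor: feed concentrations and theta.

    Only the mean residence time theta = Omega_CSTR / Q_f enters the dynamics.
    """

    s_feed: Dict[str, float]
    theta: float

    def __post_init__(self):
        if not self.theta > 0:
            raise ValueError("mean residence time theta must be > 0")


@dataclass
class MorphologyPoint:
    """One point of vesicle morphology space: volume/surface plus derived axes."""

    omega: float
    S_mu: float
    phi: float
    d_omega_nm: float
    d_surface_nm: float

    @classmethod
    def from_omega_surface(cls, omega: float, S_mu: float) -> "MorphologyPoint":
        return cls(
            omega=omega,
            S_mu=S_mu,
            phi=reduced_surface(omega, S_mu),
            d_omega_nm=diameter_from_omega(omega),
            d_surface_nm=diameter_from_surface(S_mu),
        )

    def region(self, phi_burst: float = PHI_BURST) -> str:
        """Classify the morphology: 'burst' (Phi below the burst threshold),
        'tense' (Phi < 1), 'spherical', or 'deflated'."""
        if self.phi < phi_burst:
            return "burst"
        if self.phi < 1.0 - 1e-12:
            return "tense"
        if self.phi <= 1.0 + 1e-12:
            return "spherical"
        return "deflated"


# ---------------------------------------------------------------------------
# right-hand sides (dict API; array forms used internally by the integrators)

def rhs_cstr(network: ReactionNetwork, cstr: CSTRSpec, s: Mapping[str, float]) -> Dict[str, float]:
    """ds_i/dt = r_i(s) + (1/theta) (s_feed_i - s_i)."""
    v = network.concentrations_to_array(s)
    feed = np.array([cstr.s_feed.get(sp, 0.0) for sp in network.species])
    dv = mak_rates_vec(network, v) + (feed - v) / cstr.theta
    return network.array_to_concentrations(dv)


def rhs_reservoir(network: ReactionNetwork, pinned: Mapping[str, float], s: Mapping[str, float]) -> Dict[str, float]:
    """Reservoir conditions: pinned species held constant, intermediates react.

    ``pinned`` maps reservoir species to their clamped concentrations; their
    time derivative is 0.  ``s`` must supply the intermediate concentrations
    (pinned entries in ``s`` are ignored in favour of the clamp).
    """
    full = dict(s)
    full.update(pinned)
    v = network.concentrations_to_array(full)
    dv = mak_rates_vec(network, v)
    out = network.array_to_concentrations(dv)
    for sp in pinned:
        out[sp] = 0.0
    return out


def rhs_vesicle_highbuffer(
    reactor: VesicleReactor, omega0: float, S_mu0: float, s: Mapping[str, float]
) -> Dict[str, float]:
    """High-buffer vesicle: constant volume/surface, Fickian membrane exchange.

    ds_i/dt = r_i(s) + (1/Omega0) S_mu0 D_i (s_eps_i - s_i).
    """
    if omega0 <= 0 or S_mu0 <= 0:
        raise ValueError("Omega0 and S_mu0 must be > 0")
    net = reactor.network
    v = net.concentrations_to_array(s)
    dv = mak_rates_vec(net, v) + (S_mu0 / omega0) * reactor.D_vec() * (reactor.s_eps_vec() - v)
    return net.array_to_concentrations(dv)


def _full_rhs_vec(reactor: VesicleReactor, v: np.ndarray):
    """Array core of the full variable-volume model.

    Returns (ds/dt, Omega, S_mu, dilution-term vector).  With the isotonic
    volume substituted, the exchange term becomes
    g_i = r_i + (S_mu D_i / B_T)(C_eps - sum s)(s_eps_i - s_i)
    and the dilution term is -(s_i/C_eps) * sum_j g_j, which is the standard
    -(s_i/Omega) dOmega/dt correction after eliminating Omega.
    """
    C_eps = reactor.C_eps
    total = float(np.sum(v))
    if total >= C_eps:
        raise OsmoticBlowupError(
            f"total internal solute concentration {total:g} M >= C_eps {C_eps:g} M"
        )
    omega = reactor.B_T / (C_eps - total)
    S_mu = surface_from_volume(omega)
    g = mak_rates_vec(reactor.network, v) + (S_mu / reactor.B_T) * reactor.D_vec() * (
        C_eps - total
    ) * (reactor.s_eps_vec() - v)
    dilution = -(v / C_eps) * float(np.sum(g))
    return g + dilution, omega, S_mu, dilution


def rhs_vesicle_full(reactor: VesicleReactor, s: Mapping[str, float]):
    """Full variable-volume vesicle ODE right-hand side plus diagnostics.

    Returns ``(ds_dt, diagnostics)`` where diagnostics carries the implied
    volume Omega, surface S_mu and the per-species dilution term.
    """
    net = reactor.network
    v = net.concentrations_to_array(s)
    dv, omega, S_mu, dilution = _full_rhs_vec(reactor, v)
    return net.array_to_concentrations(dv), {
        "omega": omega,
        "S_mu": S_mu,
        "dilution": net.array_to_concentrations(dilution),
    }


def residence_time_equivalent(reactor: VesicleReactor, S_mu0: float, D: float) -> float:
    """CSTR residence time matching a high-buffer vesicle with a common D.

    theta = B_T / (S_mu0 * D * b_eps).  With all species sharing this D and
    s_eps = s_feed, the high-buffer vesicle rhs equals the CSTR rhs exactly.
    """
    if S_mu0 <= 0 or D <= 0:
        raise ValueError("S_mu0 and D must be > 0")
    b_eps = reactor.environment.b_eps
    if b_eps <= 0:
        raise ValueError("b_eps must be > 0 for the CSTR equivalence")
    return reactor.B_T / (S_mu0 * D * b_eps)
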