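"""Configuration loading, result serialisation and packaged fixtures.

Run configurations are YAML (JSON-compatible) documents with a ``network``
section (species + reaction strings), a ``reactor`` section (B_T, external
buffer and solute concentrations, permeability multipliers, optional
overrides of the membrane reference constants) and optional task sections
(injections, grids, tolerances).  Tabular results are written as CSV,
summaries as JSON; outputs are canonically sorted so reruns diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import BILAYER_THICKNESS, D_RIBOSE, PHI_BURST
from .dynamics import InjectionEvent, Trajectory
from .fixed_points import BifurcationCurve, FixedPoint
from .network import ReactionNetwork, parse_network
from .reactor import MembraneSpec, VesicleEnvironment, VesicleReactor
from .search import CensusResult, preset_ranges

__all__ = [
    "load_config",
    "reactor_from_config",
    "reactor_to_config",
    "write_results",
    "fixed_points_frame",
    "curve_frame",
    "trajectory_frame",
    "generate_fixtures",
]


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


def load_config(path) -> Dict:
    """Load and validate a YAML/JSON run configuration.

    Fills defaults (membrane constants, burst threshold, tolerances) and
    raises :class:`ConfigError` with a field-level message on violations.
    """
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config: {exc}")
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    if "preset" in cfg:
        return cfg
    for section in ("network", "reactor"):
        if section not in cfg:
            raise ConfigError(f"missing required section {section!r}")
    net = cfg["network"]
    net.setdefault("reactions", [])
    if not net["reactions"] and not net.get("species"):
        raise ConfigError("network needs reactions and/or an explicit species list")
    rx = cfg["reactor"]
    if "B_T" not in rx:
        raise ConfigError("reactor.B_T is required")
    if not rx["B_T"] > 0:
        raise ConfigError("reactor.B_T must be > 0")
    if "b_eps" not in rx:
        raise ConfigError("reactor.b_eps is required")
    rx.setdefault("s_eps", {})
    rx.setdefault("D_mult", {})
    rx.setdefault("D_ref", D_RIBOSE)
    rx.setdefault("bilayer_thickness", BILAYER_THICKNESS)
    rx.setdefault("phi_burst", PHI_BURST)
    cfg.setdefault("seed", 0)
    cfg.setdefault("tolerances", {"rtol": 1e-8, "atol": 1e-12})
    return cfg


def reactor_from_config(cfg: Dict) -> VesicleReactor:
    """Instantiate a :class:`VesicleReactor` from a validated config dict."""
    if "preset" in cfg:
        name = cfg["preset"]
        net, _ = preset_ranges(name)
        raise ConfigError(
            f"preset {name!r} defines sampling ranges, not a single reactor; "
            "use the census/search tasks"
        )
    netcfg = cfg["network"]
    reactions = netcfg.get("reactions", [])
    if isinstance(reactions, list):
        reactions = "; ".join(reactions)
    if reactions.strip():
        network = parse_network(reactions, species=netcfg.get("species"))
    else:
        network = ReactionNetwork(list(netcfg["species"]), [])
    rx = cfg["reactor"]
    env = VesicleEnvironment(
        b_eps=float(rx["b_eps"]),
        s_eps={sp: float(v) for sp, v in rx.get("s_eps", {}).items()},
    )
    mem = MembraneSpec(
        D_mult={sp: float(v) for sp, v in rx.get("D_mult", {}).items()},
        D_ref=float(rx.get("D_ref", D_RIBOSE)),
        thickness=float(rx.get("bilayer_thickness", BILAYER_THICKNESS)),
    )
    return VesicleReactor(
        network=network,
        environment=env,
        membrane=mem,
        B_T=float(rx["B_T"]),
        phi_burst=float(rx.get("phi_burst", PHI_BURST)),
    )


def reactor_to_config(reactor: VesicleReactor) -> Dict:
    """Serialise a reactor back to the config schema (round-trippable)."""
    return {
        "network": {
            "species": list(reactor.network.species),
            "reactions": [str(r) for r in reactor.network.reactions],
        },
        "reactor": {
            "B_T": reactor.B_T,
            "b_eps": reactor.environment.b_eps,
            "s_eps": dict(reactor.environment.s_eps),
            "D_mult": dict(reactor.membrane.D_mult),
            "D_ref": reactor.membrane.D_ref,
            "bilayer_thickness": reactor.membrane.thickness,
            "phi_burst": reactor.phi_burst,
        },
    }


def config_hash(cfg: Dict) -> str:
    """Stable short hash of a config for provenance records."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# tabular exports

def fixed_points_frame(fps: Sequence[FixedPoint]) -> pd.DataFrame:
    """Fixed points as a DataFrame, sorted by volume (canonical order)."""
    rows = []
    for fp in sorted(fps, key=lambda f: f.omega):
        row = {
            "S_mu0": fp.S_mu0,
            "omega": fp.omega,
            "phi": fp.phi,
            "d_omega_nm": fp.diameter_nm,
            "stability": fp.stability,
            "residual": fp.residual,
        }
        for sp, v in fp.s.items():
            row[f"s_{sp}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def curve_frame(curve: BifurcationCurve) -> pd.DataFrame:
    """Bifurcation curve as (branch id, surface, concentrations, morphology)."""
    rows = []
    for bid, br in enumerate(curve.branches):
        for fp in br.points:
            row = {
                "branch": bid,
                "S_mu0": fp.S_mu0,
                "omega": fp.omega,
                "phi": fp.phi,
                "d_omega_nm": fp.diameter_nm,
                "stability": fp.stability,
            }
            for sp, v in fp.s.items():
                row[f"s_{sp}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    return traj.to_frame()


def write_results(result, path, fmt: Optional[str] = None) -> Path:
    """Write a result object to disk (CSV for tables, JSON for summaries).

    Accepts DataFrames, trajectories, curves, fixed-point lists, census
    results and plain dicts; the format is inferred from the object unless
    given.  Returns the path written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False)
        return path
    if isinstance(result, Trajectory):
        trajectory_frame(result).to_csv(path, index=False)
        return path
    if isinstance(result, BifurcationCurve):
        curve_frame(result).to_csv(path, index=False)
        return path
    if isinstance(result, (list, tuple)) and all(
        isinstance(x, FixedPoint) for x in result
    ):
        fixed_points_frame(result).to_csv(path, index=False)
        return path
    if isinstance(result, CensusResult):
        payload = {
            "n": result.n,
            "seed": result.seed,
            "S_mu0": result.S_mu0,
            "n_solver_failures": result.n_solver_failures,
            "fractions": result.summary(),
            "counts": result.counts,
        }
        path.write_text(json.dumps(payload, indent=2, default=float))
        return path
    if isinstance(result, dict):
        path.write_text(json.dumps(result, indent=2, sort_keys=True, default=float))
        return path
    raise TypeError(f"cannot serialise {type(result).__name__}")


# ---------------------------------------------------------------------------
# packaged fixtures

def generate_fixtures(seed: int = 0) -> Dict[str, Dict]:
    """Reference configurations generated programmatically.

    Returns named configs for: the bulk Schlögl and Wilhelm switches
    encapsulated at their reservoir-matched externals, a reaction-free
    single-solute reactor (unique diffusive steady state), and the census
    presets by name.  Deterministic given the seed.
    """
    schlogl = {
        "network": {
            "species": ["X", "Y", "Z"],
            "reactions": [
                "X + 2 Y <-> 3 Y (k=52500, kr=2850)",
                "Y <-> Z (k=0.0915, kr=0.00715)",
            ],
        },
        "reactor": {
            "B_T": 63064.0,
            "b_eps": 0.2,
            "s_eps": {"X": 6.47e-4, "Y": 0.0, "Z": 6.32e-4},
            "D_mult": {"X": 50.0, "Y": 0.0, "Z": 50.0},
        },
        "seed": seed,
    }
    wilhelm = {
        "network": {
            "species": ["X", "Y", "Z", "W"],
            "reactions": [
                "X + Z -> 2 Y (k=586)",
                "2 Y -> Y + Z (k=926)",
                "Y + Z -> Z + W (k=575)",
                "Y -> W (k=0.0998)",
            ],
        },
        "reactor": {
            "B_T": 63064.0,
            "b_eps": 0.2,
            "s_eps": {"X": 1.17e-3, "Y": 0.0, "Z": 0.0, "W": 0.0},
            "D_mult": {"X": 50.0, "Y": 0.0, "Z": 0.0, "W": 50.0},
        },
        "seed": seed,
    }
    inert = {
        "network": {"species": ["A"], "reactions": []},
        "reactor": {
            "B_T": 63064.0,
            "b_eps": 0.2,
            "s_eps": {"A": 0.05},
            "D_mult": {"A": 1.0},
        },
        "seed": seed,
    }
    return {
        "schlogl_bulk": schlogl,
        "wilhelm_bulk": wilhelm,
        "reaction_free": inert,
        "census_presets": {"schlogl": "schlogl_cs1", "wilhelm": "wilhelm_cs1"},
    }
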