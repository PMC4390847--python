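"""Sparse multivariate polynomial systems for steady-state analysis.

At a fixed membrane surface the vesicle steady-state conditions are
polynomials in the internal concentrations,

    r_i(s) + (S_mu0 D_i / B_T) (C_eps - sum_j s_j) (s_eps_i - s_i) = 0,

one equation per species.  This module represents such square systems in a
vectorised monomial form (coefficients, exponent matrix, equation index) that
supports batched evaluation and Jacobians over many points at once — the
workhorse layout for the homotopy path tracker and for Monte-Carlo censuses
where thousands of structurally identical systems differ only in their
coefficients.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .network import ReactionNetwork
from .reactor import VesicleReactor

__all__ = ["PolySystem", "steady_state_system", "steady_state_system_batch", "union_systems"]


class PolySystem:
    """A square system of n polynomial equations in n variables.

    Parameters
    ----------
    n_vars
        Number of variables (= number of equations).
    coeffs
        Monomial coefficients, shape (m,) for a single system or (S, m) for a
        batch of S systems sharing the monomial structure.
    expts
        Integer exponent matrix, shape (m, n_vars).
    eq_idx
        Equation index of each monomial, shape (m,).
    """

    def __init__(self, n_vars: int, coeffs: np.ndarray, expts: np.ndarray, eq_idx: np.ndarray):
        coeffs = np.atleast_2d(np.asarray(coeffs, dtype=complex))
        self.n_vars = int(n_vars)
        self.coeffs = coeffs                      # (S, m)
        self.expts = np.asarray(expts, dtype=np.int64)   # (m, n)
        self.eq_idx = np.asarray(eq_idx, dtype=np.int64) # (m,)
        m = self.expts.shape[0]
        if self.coeffs.shape[1] != m or self.eq_idx.shape[0] != m:
            raise ValueError("inconsistent monomial arrays")
        # incidence matrix scattering monomials into equations
        self._inc = np.zeros((m, self.n_vars), dtype=float)
        self._inc[np.arange(m), self.eq_idx] = 1.0
        # pre-computed derivative data per variable
        self._dexp: List[np.ndarray] = []
        self._dfac: List[np.ndarray] = []
        for j in range(self.n_vars):
            e = self.expts.copy()
            fac = e[:, j].astype(float)
            e[:, j] = np.maximum(e[:, j] - 1, 0)
            self._dexp.append(e)
            self._dfac.append(fac)

    # -- basic properties ---------------------------------------------------

    @property
    def n_systems(self) -> int:
        return self.coeffs.shape[0]

    def degrees(self) -> np.ndarray:
        """Total degree of each equation (max over its monomials)."""
        tot = self.expts.sum(axis=1)
        deg = np.zeros(self.n_vars, dtype=np.int64)
        np.maximum.at(deg, self.eq_idx, tot)
        return deg

    def bezout_count(self) -> int:
        return int(np.prod(self.degrees()))

    # -- evaluation ---------------------------------------------------------

    def _monomials(self, X: np.ndarray, expts: np.ndarray) -> np.ndarray:
        # X: (P, n) -> (P, m); integer powers only
        P = X.shape[0]
        T = np.ones((P, expts.shape[0]), dtype=X.dtype)
        for j in range(self.n_vars):
            col = expts[:, j]
            if not col.any():
                continue
            maxp = int(col.max())
            pw = X[:, j : j + 1]
            powers = [None, pw]
            for p in range(2, maxp + 1):
                powers.append(powers[-1] * pw)
            for p in range(1, maxp + 1):
                mask = col == p
                if mask.any():
                    T[:, mask] *= powers[p]
        return T

    def eval(self, X: np.ndarray, sys_idx: np.ndarray | None = None) -> np.ndarray:
        """Evaluate all equations at points X (P, n_vars) -> (P, n_vars).

        ``sys_idx`` (P,) selects which coefficient row each point uses; for a
        single system it may be omitted.
        """
        X = np.atleast_2d(X)
        c = self._coeff_rows(X.shape[0], sys_idx)
        T = self._monomials(X, self.expts)
        return (c * T) @ self._inc

    def jac(self, X: np.ndarray, sys_idx: np.ndarray | None = None) -> np.ndarray:
        """Jacobian at points X -> (P, n_eq, n_vars)."""
        X = np.atleast_2d(X)
        P = X.shape[0]
        c = self._coeff_rows(P, sys_idx)
        J = np.empty((P, self.n_vars, self.n_vars), dtype=complex)
        for j in range(self.n_vars):
            T = self._monomials(X, self._dexp[j])
            J[:, :, j] = (c * self._dfac[j] * T) @ self._inc
        return J

    def _coeff_rows(self, P: int, sys_idx: np.ndarray | None) -> np.ndarray:
        if sys_idx is None:
            if self.n_systems != 1:
                raise ValueError("sys_idx required for a batched system")
            return self.coeffs[np.zeros(P, dtype=np.int64)]
        return self.coeffs[np.asarray(sys_idx, dtype=np.int64)]

    # -- conditioning -------------------------------------------------------

    def scaled(self, var_scale) -> "PolySystem":
        """Substitute s = var_scale * u and renormalise each equation.

        Returns a system in the dimensionless variable u whose equations each
        have maximum |coefficient| 1 — the form handed to the path tracker.
        Roots map back as s = var_scale * u.  ``var_scale`` may be a scalar
        or a per-system array of shape (S,).
        """
        tot = self.expts.sum(axis=1)
        var_scale = np.asarray(var_scale, dtype=float)
        if var_scale.ndim == 0:
            c = self.coeffs * (var_scale ** tot)
        else:
            c = self.coeffs * (var_scale[:, None] ** tot[None, :])
        # per-equation max |c| normalisation (per batched system)
        norm = np.zeros((self.n_systems, self.n_vars))
        for i in range(self.n_vars):
            mask = self.eq_idx == i
            if mask.any():
                norm[:, i] = np.abs(c[:, mask]).max(axis=1)
        norm[norm == 0] = 1.0
        c = c / norm[:, self.eq_idx]
        return PolySystem(self.n_vars, c, self.expts, self.eq_idx)

    def select(self, i: int) -> "PolySystem":
        """Extract one system from a batch."""
        return PolySystem(self.n_vars, self.coeffs[i : i + 1], self.expts, self.eq_idx)


# ---------------------------------------------------------------------------
# construction from a vesicle reactor


def _accumulate(terms: Dict[Tuple[int, Tuple[int, ...]], float], eq: int, expt: Sequence[int], coeff: float):
    key = (eq, tuple(int(e) for e in expt))
    terms[key] = terms.get(key, 0.0) + coeff


def _mak_terms(network: ReactionNetwork, terms: Dict, idx: Mapping[str, int]):
    n = network.n_species
    for rx in network.reactions:
        fe = np.zeros(n, dtype=int)
        for sp, nu in rx.reactants.items():
            fe[idx[sp]] += nu
        re = np.zeros(n, dtype=int)
        for sp, nu in rx.products.items():
            re[idx[sp]] += nu
        for sp in set(rx.reactants) | set(rx.products):
            dnu = rx.net_change(sp)
            if dnu == 0:
                continue
            _accumulate(terms, idx[sp], fe, dnu * rx.k)
            if rx.kr > 0:
                _accumulate(terms, idx[sp], re, -dnu * rx.kr)


def steady_state_system(reactor: VesicleReactor, S_mu0: float) -> PolySystem:
    """Fixed-surface steady-state polynomial system for a vesicle reactor.

    Equation i:  r_i(s) + K_i (C_eps - sum_j s_j)(s_eps_i - s_i) = 0,
    with K_i = S_mu0 * D_i / B_T.  The dilution term is absent because the
    volume is stationary at any steady state.
    """
    if S_mu0 <= 0:
        raise ValueError("S_mu0 must be > 0")
    net = reactor.network
    n = net.n_species
    idx = {sp: i for i, sp in enumerate(net.species)}
    terms: Dict[Tuple[int, Tuple[int, ...]], float] = {}
    _mak_terms(net, terms, idx)

    K = S_mu0 * reactor.D_vec() / reactor.B_T
    s_eps = reactor.s_eps_vec()
    C_eps = reactor.C_eps
    zero = np.zeros(n, dtype=int)
    for i in range(n):
        if K[i] == 0.0:
            continue
        # K_i (C_eps - sum_j s_j)(s_eps_i - s_i)
        _accumulate(terms, i, zero, K[i] * C_eps * s_eps[i])
        ei = zero.copy(); ei[i] = 1
        _accumulate(terms, i, ei, -K[i] * C_eps)
        for j in range(n):
            ej = zero.copy(); ej[j] = 1
            _accumulate(terms, i, ej, -K[i] * s_eps[i])
            eij = ej.copy(); eij[i] += 1
            _accumulate(terms, i, eij, K[i])

    keys = sorted(terms)
    eq_idx = np.array([k[0] for k in keys], dtype=np.int64)
    expts = np.array([k[1] for k in keys], dtype=np.int64)
    coeffs = np.array([terms[k] for k in keys], dtype=complex)
    return PolySystem(n, coeffs, expts, eq_idx)


def union_systems(systems: Sequence[PolySystem]) -> PolySystem:
    """Stack single systems into one batch over the union monomial structure.

    Monomials absent from a member are retained with coefficient 0 so every
    system shares the exponent matrix (required for batched path tracking).
    """
    keymaps = []
    allkeys = set()
    for ps in systems:
        km = {
            (int(e), tuple(ex)): c
            for e, ex, c in zip(ps.eq_idx, ps.expts, ps.coeffs[0])
        }
        keymaps.append(km)
        allkeys.update(km)
    keys = sorted(allkeys)
    eq_idx = np.array([k[0] for k in keys], dtype=np.int64)
    expts = np.array([k[1] for k in keys], dtype=np.int64)
    coeffs = np.array(
        [[km.get(k, 0.0) for k in keys] for km in keymaps], dtype=complex
    )
    return PolySystem(systems[0].n_vars, coeffs, expts, eq_idx)


def steady_state_system_batch(reactors: Sequence[VesicleReactor], S_mu0: float) -> PolySystem:
    """Batch of steady-state systems sharing one monomial structure.

    All reactors must share the same network topology; they may differ in rate
    constants, permeabilities, external concentrations and B_T.
    """
    return union_systems([steady_state_system(r, S_mu0) for r in reactors])
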