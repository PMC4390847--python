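"""Fixed points: closed forms, homotopy solving, sweeps and crossings."""

import numpy as np
import pytest

from osmocell.fixed_points import (
    classify_bistability,
    coupling_response_curve,
    cyclic_condition_crossings,
    default_surface_grid,
    filter_valid,
    multistart_roots,
    quasi_stability,
    real_roots,
    schlogl_reservoir_fixed_points,
    solve_all_fixed_points,
    spherical_crossings,
    sweep_surface,
    wilhelm_reservoir_fixed_points,
    FixedPoint,
)
from osmocell.network import ReactionNetwork, parse_network
from osmocell.polysys import steady_state_system
from osmocell.reactor import (
    MembraneSpec,
    VesicleEnvironment,
    VesicleReactor,
    sphere_omega_from_diameter,
    sphere_surface_from_diameter,
    surface_from_volume,
)
from osmocell.search import SCHLOGL_BULK, WILHELM_BULK, sample_wide, SamplingRanges


class TestReservoirClosedForms:
    def test_schlogl_printed_roots(self):
        b = SCHLOGL_BULK
        roots = schlogl_reservoir_fixed_points(
            b["x"], b["z"], b["k1"], b["k1r"], b["k2"], b["k2r"]
        )
        assert len(roots) == 3
        for got, want in zip(roots, (5.03e-5, 4.01e-3, 7.86e-3)):
            assert got == pytest.approx(want, rel=5e-3)

    def test_schlogl_vieta_relations(self):
        b = SCHLOGL_BULK
        roots = schlogl_reservoir_fixed_points(
            b["x"], b["z"], b["k1"], b["k1r"], b["k2"], b["k2r"]
        )
        assert roots.sum() == pytest.approx(b["k1"] * b["x"] / b["k1r"], rel=1e-10)
        assert np.prod(roots) == pytest.approx(
            b["k2r"] * b["z"] / b["k1r"], rel=1e-10
        )

    def test_schlogl_strong_drain_limit(self):
        # with no back-supply of Y and a strong sink, only a root near 0
        roots = schlogl_reservoir_fixed_points(1e-4, 0.0, k2=50.0, k2r=0.0)
        assert len(roots) == 0 or np.all(roots < 1e-6)

    def test_wilhelm_printed_pairs(self):
        pairs = wilhelm_reservoir_fixed_points()
        assert pairs[0] == (0.0, 0.0)
        (yu, zu), (y2, z2) = pairs[1], pairs[2]
        assert yu == pytest.approx(1.20e-4, rel=5e-3)
        assert zu == pytest.approx(1.94e-5, rel=5e-3)
        assert y2 == pytest.approx(1.07e-3, rel=5e-3)
        assert z2 == pytest.approx(1.55e-3, rel=5e-3)

    def test_wilhelm_small_k4_limit(self):
        b = WILHELM_BULK
        pairs = wilhelm_reservoir_fixed_points(k4=1e-9)
        ys = [p[0] for p in pairs]
        # nontrivial roots approach k4/k2 -> 0 and k1*x/k3
        assert min(y for y in ys if y > 0) < 1e-10
        assert max(ys) == pytest.approx(b["k1"] * b["x"] / b["k3"], rel=1e-3)

    def test_wilhelm_negative_discriminant(self):
        pairs = wilhelm_reservoir_fixed_points(k4=1e3)
        assert pairs == [(0.0, 0.0)]


class TestHomotopyAgainstClosedForms:
    def test_schlogl_cubic_as_one_variable_system(self):
        """The homotopy solver reproduces the printed cubic roots."""
        from osmocell.polysys import PolySystem
        from osmocell.homotopy import solve_system

        b = SCHLOGL_BULK
        ps = PolySystem(
            1,
            np.array([-b["k1r"], b["k1"] * b["x"], -b["k2"], b["k2r"] * b["z"]]),
            np.array([[3], [2], [1], [0]]),
            np.zeros(4, dtype=np.int64),
        )
        res = solve_system(ps.scaled(1e-2), seed=1)
        roots = np.sort(real_roots(res.roots).ravel()) * 1e-2
        expected = schlogl_reservoir_fixed_points(
            b["x"], b["z"], b["k1"], b["k1r"], b["k2"], b["k2r"]
        )
        assert np.allclose(roots, expected, rtol=1e-8)

    def test_wilhelm_embedded_reservoir(self):
        """Homotopy on the 2-D Wilhelm reservoir system finds all printed
        pairs (plus none extra)."""
        from osmocell.polysys import PolySystem
        from osmocell.homotopy import solve_system

        b = WILHELM_BULK
        # dy/dt = 2k1xz - k2y^2 - k3yz - k4y; dz/dt = k2y^2 - k1xz
        coeffs = np.array(
            [2 * b["k1"] * b["x"], -b["k2"], -b["k3"], -b["k4"],
             b["k2"], -b["k1"] * b["x"]]
        )
        expts = np.array([[0, 1], [2, 0], [1, 1], [1, 0], [2, 0], [0, 1]])
        eq = np.array([0, 0, 0, 0, 1, 1])
        ps = PolySystem(2, coeffs, expts, eq)
        res = solve_system(ps.scaled(2e-3), seed=2)
        roots = real_roots(res.roots) * 2e-3
        roots = roots[np.all(roots > -1e-12, axis=1)]
        ys = np.sort(roots[:, 0])
        assert len(ys) == 3
        assert ys[0] == pytest.approx(0.0, abs=1e-10)
        assert ys[1] == pytest.approx(1.20e-4, rel=5e-3)
        assert ys[2] == pytest.approx(1.07e-3, rel=5e-3)


class TestSolveAllFixedPoints:
    def test_linear_single_species(self, inert_single_reactor):
        S = sphere_surface_from_diameter(400.0)
        fps = solve_all_fixed_points(inert_single_reactor, S, seed=0)
        assert len(fps) == 1
        assert fps[0].s["A"] == pytest.approx(0.05, rel=1e-9)

    def test_matches_multistart_oracle(self, schlogl_vesicle, surface_400nm):
        system = steady_state_system(schlogl_vesicle, surface_400nm)
        oracle = multistart_roots(system, schlogl_vesicle.C_eps, n_starts=800, seed=9)
        oracle_valid = filter_valid(
            oracle, schlogl_vesicle.C_eps, schlogl_vesicle.B_T
        )
        fps = solve_all_fixed_points(schlogl_vesicle, surface_400nm, seed=0)
        assert len(fps) == len(oracle_valid)
        got = np.sort([fp.s_vec[0] for fp in fps])
        want = np.sort(oracle_valid[:, 0])
        assert np.allclose(got, want, rtol=1e-6)

    def test_residuals_are_tiny(self, schlogl_vesicle, surface_400nm):
        for fp in solve_all_fixed_points(schlogl_vesicle, surface_400nm, seed=0):
            assert fp.residual < 1e-10 * schlogl_vesicle.C_eps


class TestFilterValid:
    def test_complex_pair_removed(self):
        roots = np.array([[0.1 + 1e-3j, 0.2], [0.1 - 1e-3j, 0.2]])
        assert len(real_roots(roots)) == 0

    def test_negative_volume_removed(self):
        roots = np.array([[0.15, 0.1]])  # total 0.25 > C_eps
        assert len(filter_valid(roots, C_eps=0.2, B_T=100.0)) == 0

    def test_oversize_removed(self):
        C, B = 0.2, 1e10
        roots = np.array([[0.05, 0.05]])
        omega = B / (C - 0.1)
        assert omega > sphere_omega_from_diameter(2500.0)
        assert len(filter_valid(roots, C, B)) == 0
        assert len(filter_valid(roots, C, B, omega_max=np.inf)) == 1


class TestQuasiStability:
    def test_schlogl_reservoir_labels(self):
        """The three printed steady states are stable / unstable / stable."""
        b = SCHLOGL_BULK
        net = parse_network(
            "X + 2Y <-> 3Y (k=5.25e4, kr=2.85e3); Y <-> Z (k=9.15e-2, kr=7.15e-3)"
        )
        # reservoir conditions: high permeability pins X, Z at externals;
        # Y impermeable so its dynamics are pure chemistry (permeabilities
        # moderate enough that the stability tolerance stays meaningful)
        env = VesicleEnvironment(b_eps=1.0, s_eps={"X": b["x"], "Y": 0.0, "Z": b["z"]})
        mem = MembraneSpec(D_mult={"X": 1e3, "Y": 0.0, "Z": 1e3})
        r = VesicleReactor(network=net, environment=env, membrane=mem, B_T=63064.0)
        S = sphere_surface_from_diameter(400.0)
        labels = []
        for y in (5.03e-5, 4.01e-3, 7.86e-3):
            lab, _ = quasi_stability(r, {"X": b["x"], "Y": y, "Z": b["z"]}, S)
            labels.append(lab)
        assert labels == ["stable", "unstable", "stable"]

    def test_pure_decay_is_stable(self):
        net = parse_network("X -> Y (k=3.0)")
        env = VesicleEnvironment(b_eps=0.2, s_eps={"X": 0.01, "Y": 0.0})
        mem = MembraneSpec(D_mult={"X": 1.0, "Y": 1.0})
        r = VesicleReactor(network=net, environment=env, membrane=mem, B_T=1000.0)
        S = sphere_surface_from_diameter(200.0)
        fps = solve_all_fixed_points(r, S, seed=0)
        assert len(fps) >= 1
        assert all(fp.stability == "stable" for fp in fps)


class TestSweepAndCrossings:
    def test_reaction_free_single_branch_one_crossing(self, inert_single_reactor):
        r = inert_single_reactor
        grid = default_surface_grid(100, 1500, 60)
        curve = sweep_surface(r, grid, seed=0)
        assert len(curve.branches) == 1
        for fp in curve.branches[0].points:
            assert fp.s["A"] == pytest.approx(0.05, rel=1e-8)
        crossings = spherical_crossings(curve, r)
        assert len(crossings) == 1
        # unique steady state: internal buffer concentration equals external
        omega_expected = r.B_T / r.environment.b_eps
        assert crossings[0].omega == pytest.approx(omega_expected, rel=1e-6)
        assert abs(crossings[0].phi - 1.0) < 1e-6

    def test_single_value_grid_degenerates(self, schlogl_vesicle, surface_400nm):
        fps = solve_all_fixed_points(schlogl_vesicle, surface_400nm, seed=0)
        curve = sweep_surface(schlogl_vesicle, np.array([surface_400nm]), seed=0)
        assert sum(len(b.points) for b in curve.branches) == len(fps)

    def test_classification_rules(self):
        def fp(omega, stability):
            return FixedPoint(
                s={}, S_mu0=1.0, omega=omega, phi=1.0, stability=stability
            )

        assert classify_bistability([fp(1, "stable")]) == "monostable"
        assert (
            classify_bistability(
                [fp(1, "stable"), fp(2, "unstable"), fp(3, "stable")]
            )
            == "bistable"
        )
        assert classify_bistability([fp(1, "stable"), fp(2, "stable")]) == "other"
        assert classify_bistability([]) == "other"


class TestImpossibilityProperties:
    def test_single_unimolecular_never_bistable(self):
        """X -> Y alone can never be bistable in the vesicle reactor.

        Fold pairs (one stable, one unstable fixed point at the same imposed
        surface) do occur; what can never occur is a stable/unstable/stable
        triple — the signature of bistability.
        """
        net = parse_network("X -> Y (k=1)")
        draws = sample_wide(net, SamplingRanges(), 60, seed=21)
        S = sphere_surface_from_diameter(400.0)
        for r in draws:
            fps = solve_all_fixed_points(r, S, seed=5)
            assert len(fps) <= 2
            assert classify_bistability(fps) != "bistable"

    def test_inert_species_do_not_change_counts(self, schlogl_vesicle, surface_400nm):
        """Adding an inert diffusing solute leaves the fixed-point count
        unchanged and equilibrates to its own external concentration."""
        base = solve_all_fixed_points(schlogl_vesicle, surface_400nm, seed=0)
        r = schlogl_vesicle
        net2 = ReactionNetwork(r.network.species + ["I"], list(r.network.reactions))
        env2 = VesicleEnvironment(
            b_eps=r.environment.b_eps, s_eps={**r.environment.s_eps, "I": 0.0005}
        )
        mem2 = MembraneSpec(D_mult={**r.membrane.D_mult, "I": 3.0})
        r2 = VesicleReactor(network=net2, environment=env2, membrane=mem2, B_T=r.B_T)
        fps2 = solve_all_fixed_points(r2, surface_400nm, seed=0)
        assert len(fps2) == len(base)
        for fp in fps2:
            assert fp.s["I"] == pytest.approx(0.0005, rel=1e-6)


class TestOsmoticCoupling:
    def _uni_reactor(self, sp_in, sp_out, k, d_in, d_out, s_in, s_out, b_eps, B_T):
        net = parse_network(f"{sp_in} -> {sp_out} (k={k})")
        env = VesicleEnvironment(b_eps=b_eps, s_eps={sp_in: s_in, sp_out: s_out})
        mem = MembraneSpec(D_mult={sp_in: d_in, sp_out: d_out})
        return VesicleReactor(network=net, environment=env, membrane=mem, B_T=B_T)

    def test_identical_reactions_give_mirror_curves(self):
        """Two identical unimolecular reactions: response curves reflect in
        the B1 = B2 diagonal."""
        S = sphere_surface_from_diameter(300.0)
        r1 = self._uni_reactor("X", "Y", 0.8, 4.0, 0.6, 0.03, 0.01, 0.1, 20000)
        r2 = self._uni_reactor("P", "Q", 0.8, 4.0, 0.6, 0.03, 0.01, 0.1, 20000)
        C_joint = 0.1 + 2 * (0.03 + 0.01)
        grid = np.linspace(0, 30000, 12)
        c1 = coupling_response_curve(r1, grid, S, C_eps=C_joint)
        c2 = coupling_response_curve(r2, grid, S, C_eps=C_joint)
        b1 = c1.ranked_branches()
        b2 = c2.ranked_branches()
        assert len(b1) == len(b2) >= 1
        for (x1, y1), (x2, y2) in zip(b1, b2):
            assert len(x1) >= 3
            assert np.allclose(x1, x2)
            assert np.allclose(y1, y2, rtol=1e-9)  # mirror symmetry

    def test_inert_limit_is_chemistry_free(self):
        """With a vanishing rate constant and matched in/out externals the
        held particle number is just Omega* times the external total."""
        S = sphere_surface_from_diameter(300.0)
        r = self._uni_reactor("X", "Y", 1e-12, 2.0, 2.0, 0.02, 0.02, 0.1, 20000)
        curve = coupling_response_curve(r, np.array([0.0, 5000.0]), S)
        for B_extra, owns in zip(curve.B_extra, curve.B_own):
            assert len(owns) == 1
            B_eff = 20000 + B_extra
            omega = B_eff / (r.C_eps - 0.04)
            assert owns[0] == pytest.approx(omega * 0.04, rel=1e-6)

    def test_curve_is_continuous(self):
        S = sphere_surface_from_diameter(300.0)
        r = self._uni_reactor("X", "Y", 0.2, 4.0, 0.6, 0.03, 0.01, 0.1, 20000)
        grid = np.linspace(0, 40000, 25)
        curve = coupling_response_curve(r, grid, S)
        branches = curve.ranked_branches()
        assert branches
        for x, y in branches:
            assert len(x) == len(grid)
            steps = np.abs(np.diff(y))
            assert steps.max() < 0.2 * (np.ptp(y) + 1)

    def test_cyclic_condition_matches_joint_solve(self):
        """Intersections of the two response curves are joint fixed points.

        The symmetric case (identical reactions, identical constants) must
        produce an intersection on the B1 = B2 diagonal.
        """
        S = sphere_surface_from_diameter(300.0)
        net = parse_network("X -> Y (k=0.05); P -> Q (k=0.05)")
        env = VesicleEnvironment(
            b_eps=0.1, s_eps={"X": 0.03, "Y": 0.01, "P": 0.03, "Q": 0.01}
        )
        mem = MembraneSpec(D_mult={"X": 4.0, "Y": 0.6, "P": 4.0, "Q": 0.6})
        joint = VesicleReactor(network=net, environment=env, membrane=mem, B_T=20000.0)
        sub1 = self._sub(joint, ["X", "Y"])
        sub2 = self._sub(joint, ["P", "Q"])
        grid = np.linspace(0.0, 80000.0, 60)
        c1 = coupling_response_curve(sub1, grid, S, C_eps=joint.C_eps)
        c2 = coupling_response_curve(sub2, grid, S, C_eps=joint.C_eps)
        hits = cyclic_condition_crossings(c1, c2, joint_reactor=joint)
        verified = [h for h in hits if h.get("verified")]
        assert len(verified) >= 1
        fps = solve_all_fixed_points(joint, S, seed=0, omega_max=np.inf)
        for h in verified:
            # symmetric configuration: intersection sits on the diagonal
            assert h["B1"] == pytest.approx(h["B2"], rel=1e-6)
            fp = h["fixed_point"]
            assert any(
                np.allclose(fp.s_vec, other.s_vec, rtol=1e-6) for other in fps
            )

    def test_non_overlapping_ranges_no_crossings(self):
        S = sphere_surface_from_diameter(300.0)
        r = self._uni_reactor("X", "Y", 0.05, 4.0, 0.6, 0.03, 0.01, 0.1, 20000)
        c1 = coupling_response_curve(r, np.array([0.0, 100.0]), S)
        c2 = coupling_response_curve(r, np.array([1e7, 2e7]), S)
        assert cyclic_condition_crossings(c1, c2) == []

    @staticmethod
    def _sub(joint, species):
        net = ReactionNetwork(
            species,
            [
                rx
                for rx in joint.network.reactions
                if set(rx.reactants) | set(rx.products) <= set(species)
            ],
        )
        env = VesicleEnvironment(
            b_eps=joint.environment.b_eps,
            s_eps={sp: joint.environment.s_eps.get(sp, 0.0) for sp in species},
        )
        mem = MembraneSpec(
            D_mult={sp: joint.membrane.D_mult.get(sp, 0.0) for sp in species}
        )
        return VesicleReactor(network=net, environment=env, membrane=mem, B_T=joint.B_T)
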