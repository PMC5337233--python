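import numpy as np
import pytest

from isolabel import (
    EMUKey,
    FluxAssignment,
    FractionVector,
    MoietySpec,
    brute_force_isotopomer_solve,
    build_cascade,
    decompose_network,
    parse_network,
)
from isolabel.cascade_solver import (
    MissingInputError,
    SingularCascadeError,
    StationarityError,
    emu_isotopomer_from_joint,
    emu_mass_from_joint,
    infer_moiety_specs,
    simulate,
    solve_steady_state,
    steady_state_residual,
)
from isolabel.fixtures import FixtureConfig, generate_fixture


def iso(spec, values):
    return FractionVector("isotopomer", np.asarray(values, dtype=float), spec)


CONDENSATION = "A[ab] + B[c] -> C[a] + D[bc] @ v"


class TestBuildAndSolveSmall:
    def test_pass_through_preserves_any_input(self):
        spec = MoietySpec.homonuclear("A", 2, 1)
        a = iso(spec, [0.4, 0.3, 0.2, 0.1])
        for v in (0.5, 7.0):
            sol = simulate("A[ab] -> B[ab] @ v", FluxAssignment({"v": v}), {"A": a})
            assert np.allclose(
                sol[EMUKey("B", (1, 2))].values, emu_mass_from_joint(a, (1, 2)).values
            )

    def test_mixing_is_flux_weighted_average(self):
        spec = MoietySpec.homonuclear("A", 1, 1)
        net = "A[a] -> C[a] @ v1\nB[b] -> C[b] @ v2\nC[c] -> Out[c] @ v3"
        a = iso(spec, [0.2, 0.8])
        b = iso(MoietySpec.homonuclear("B", 1, 1), [0.9, 0.1])
        fluxes = FluxAssignment({"v1": 2.0, "v2": 3.0, "v3": 5.0})
        sol = simulate(net, fluxes, {"A": a, "B": b})
        expected = (2.0 * np.array([0.2, 0.8]) + 3.0 * np.array([0.9, 0.1])) / 5.0
        assert np.allclose(sol[EMUKey("C", (1,))].values, expected)

    def test_condensation_convolves_reagent_marginals(self):
        specA = MoietySpec.homonuclear("A", 2, 1)
        specB = MoietySpec.homonuclear("B", 1, 1)
        a = iso(specA, [0, 1.0, 0, 0])  # atom 2 fully labeled
        b = iso(specB, [1.0, 0])  # unlabeled
        sol = simulate(CONDENSATION, FluxAssignment({"v": 1.3}), {"A": a, "B": b})
        assert np.allclose(sol[EMUKey("D", (1, 2))].values, [0.0, 1.0, 0.0])

    def test_empty_identity_system_gives_empty_cascade(self):
        system = decompose_network([])
        cascade = build_cascade(system, FluxAssignment({}), {}, specs={})
        assert cascade.sizes == []
        assert solve_steady_state(cascade).values == {}

    def test_scale_invariance_of_fluxes(self):
        fix = generate_fixture(FixtureConfig(seed=5))
        sol1 = simulate(fix.reactions, fix.fluxes, fix.inputs, specs=fix.specs)
        sol2 = simulate(fix.reactions, fix.fluxes.scaled(17.0), fix.inputs, specs=fix.specs)
        for key in sol1.values:
            assert np.allclose(sol1[key].values, sol2[key].values, atol=1e-10)

    def test_solution_vectors_are_distributions(self):
        fix = generate_fixture(FixtureConfig(seed=9))
        sol = simulate(fix.reactions, fix.fluxes, fix.inputs, specs=fix.specs)
        for key, fv in sol.items():
            assert fv.values.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(fv.values >= -1e-9)

    def test_within_size_cycle_solved_linearly(self):
        net = "A[a] -> B[a] @ v1\nB[a] <-> C[a] @ v2\nB[a] -> Out[a] @ v3"
        fluxes = FluxAssignment({"v1": 1.0, "v2.fwd": 2.0, "v2.rev": 2.0, "v3": 1.0})
        a = iso(MoietySpec.homonuclear("A", 1, 1), [0.3, 0.7])
        sol = simulate(net, fluxes, {"A": a})
        assert np.allclose(sol[EMUKey("C", (1,))].values, [0.3, 0.7], atol=1e-10)


class TestErrors:
    def test_stationarity_violation_names_the_metabolite(self):
        net = "A[a] -> B[a] @ v1\nB[a] -> C[a] @ v2"
        a = iso(MoietySpec.homonuclear("A", 1, 1), [0.5, 0.5])
        with pytest.raises(StationarityError, match="'B'"):
            simulate(net, FluxAssignment({"v1": 1.0, "v2": 2.0}), {"A": a})

    def test_missing_source_spec_raises(self):
        net = "A[a] -> B[a] @ v"
        with pytest.raises(MissingInputError, match="infer"):
            simulate(net, FluxAssignment({"v": 1.0}), {})

    def test_zero_throughput_cycle_is_singular(self):
        net = "A[a] -> B[a] @ v0\nB[a] -> C[a] @ v1\nC[a] -> B[a] @ v2\nB[a] -> Out[a] @ v3"
        # v0 = 0: the B<->C loop has no external supply
        fluxes = FluxAssignment({"v0": 0.0, "v1": 2.0, "v2": 2.0, "v3": 0.0})
        a = iso(MoietySpec.homonuclear("A", 1, 1), [0.5, 0.5])
        with pytest.raises((SingularCascadeError, ValueError)):
            simulate(net, fluxes, {"A": a})

    def test_unlabeled_source_defaults_with_warning(self, caplog):
        net = "A[a] + B[b] -> C[ab] @ v\nC[ab] -> D[ab] @ v"
        a = iso(MoietySpec.homonuclear("A", 1, 1), [0.0, 1.0])
        specs = infer_moiety_specs(
            parse_network(net), {"A": a.spec, "B": MoietySpec.homonuclear("B", 1, 1)}
        )
        with caplog.at_level("WARNING", logger="isolabel"):
            sol = simulate(net, FluxAssignment({"v": 1.0}), {"A": a}, specs=specs)
        assert "unlabeled" in caplog.text
        assert np.allclose(sol[EMUKey("D", (1, 2))].values, [0, 1, 0])


class TestVertexPartition:
    def test_condensation_size_two_has_convolution_source(self):
        reactions = parse_network(CONDENSATION + "\nD[bc] -> E[bc] @ v")
        system = decompose_network(reactions)
        a = iso(MoietySpec.homonuclear("A", 2, 1), [0.25] * 4)
        b = iso(MoietySpec.homonuclear("B", 1, 1), [0.5, 0.5])
        cascade = build_cascade(system, FluxAssignment({"v": 1.0}), {"A": a, "B": b},
                                reactions=reactions)
        part = cascade.vertex_partition(2)
        assert EMUKey("D", (1, 2)) in part["intermediates"]
        assert EMUKey("E", (1, 2)) in part["sinks"]
        conv = [v for v in part["sources"] if not isinstance(v, EMUKey)]
        assert len(conv) == 1 and len(conv[0].rhs_factors) == 2
        blocks = cascade.adjacency_blocks(2)
        assert blocks["A21"].sum() == pytest.approx(1.0)  # conv -> D
        assert blocks["A32"].sum() == pytest.approx(1.0)  # D -> E

    def test_residual_vanishes_at_steady_state(self):
        fix = generate_fixture(FixtureConfig(seed=3))
        system = decompose_network(fix.reactions)
        cascade = build_cascade(system, fix.fluxes, fix.inputs, specs=fix.specs)
        sol = solve_steady_state(cascade)
        for res in steady_state_residual(cascade, sol).values():
            assert np.max(np.abs(res)) < 1e-9


class TestBruteForceOracle:
    def test_pass_through_reproduces_input(self):
        spec = MoietySpec.homonuclear("A", 2, 1)
        a = iso(spec, [0.4, 0.3, 0.2, 0.1])
        out = brute_force_isotopomer_solve(
            parse_network("A[ab] -> B[ab] @ v"), FluxAssignment({"v": 1.0}), {"A": a}
        )
        assert np.allclose(out["B"].values, a.values)

    def test_condensation_joint_is_outer_product_of_marginals(self):
        specA = MoietySpec.homonuclear("A", 2, 1)
        specB = MoietySpec.homonuclear("B", 1, 1)
        rng = np.random.default_rng(2)
        a = iso(specA, rng.dirichlet(np.ones(4)))
        b = iso(specB, rng.dirichlet(np.ones(2)))
        out = brute_force_isotopomer_solve(
            parse_network(CONDENSATION), FluxAssignment({"v": 1.0}), {"A": a, "B": b}
        )
        a2 = emu_isotopomer_from_joint(a, (2,)).values
        b1 = emu_isotopomer_from_joint(b, (1,)).values
        assert np.allclose(out["D"].values, np.outer(a2, b1).reshape(-1), atol=1e-11)

    @pytest.mark.parametrize("seed", range(25))
    def test_cascade_agrees_with_oracle_on_fixtures(self, seed):
        """IM-projected isotopomer balance equals the EMU cascade solution."""
        fix = generate_fixture(FixtureConfig(seed=seed))
        sol = simulate(fix.reactions, fix.fluxes, fix.inputs, specs=fix.specs)
        oracle = brute_force_isotopomer_solve(
            fix.reactions, fix.fluxes, fix.inputs, specs=fix.specs
        )
        checked = 0
        for key, fv in sol.items():
            met = key.metabolite_id
            if met in oracle:
                ref = emu_mass_from_joint(oracle[met], key.atom_set).values
                assert np.allclose(fv.values, ref, atol=1e-8)
                checked += 1
        assert checked > 0

    @pytest.mark.parametrize("seed", [1, 4, 13])
    def test_boolean_interpretation_matches_oracle_marginals(self, seed):
        fix = generate_fixture(FixtureConfig(seed=seed))
        sol = simulate(
            fix.reactions, fix.fluxes, fix.inputs, specs=fix.specs,
            interpretation="boolean",
        )
        oracle = brute_force_isotopomer_solve(
            fix.reactions, fix.fluxes, fix.inputs, specs=fix.specs
        )
        for key, fv in sol.items():
            met = key.metabolite_id
            if met in oracle:
                ref = emu_isotopomer_from_joint(oracle[met], key.atom_set).values
                assert np.allclose(fv.values, ref, atol=1e-8)

    def test_heteronuclear_fixture_agrees(self):
        fix = generate_fixture(
            FixtureConfig(seed=2, elements={"C": 1, "N": 1})
        )
        sol = simulate(fix.reactions, fix.fluxes, fix.inputs, specs=fix.specs)
        oracle = brute_force_isotopomer_solve(
            fix.reactions, fix.fluxes, fix.inputs, specs=fix.specs
        )
        for key, fv in sol.items():
            met = key.metabolite_id
            if met in oracle:
                ref = emu_mass_from_joint(oracle[met], key.atom_set).values
                assert np.allclose(fv.values, ref, atol=1e-8)

    def test_highest_shift_equals_all_labeled_cumomer_fraction(self):
        fix = generate_fixture(FixtureConfig(seed=7))
        sol = simulate(fix.reactions, fix.fluxes, fix.inputs, specs=fix.specs)
        oracle = brute_force_isotopomer_solve(
            fix.reactions, fix.fluxes, fix.inputs, specs=fix.specs
        )
        for key, fv in sol.items():
            met = key.metabolite_id
            if met not in oracle:
                continue
            emu_iso = emu_isotopomer_from_joint(oracle[met], key.atom_set)
            assert sol.cumomer_fraction(key) == pytest.approx(
                float(emu_iso.values[-1]), abs=1e-9
            )
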