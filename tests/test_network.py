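import json

import numpy as np
import pytest

from hypofeed.network import (
    ConvergenceError,
    NetworkSpec,
    ParameterVector,
    canonical_network,
    compute_net_input,
    gated_net_input_ntsca,
    make_initial_state,
    propagate_output_stage,
    run_to_fixed_point,
    unit_response,
)


class TestCanonicalStructure:
    def test_units_and_parameters(self, spec):
        assert len(spec.units) == 12
        assert len(spec.rule_units) == 8
        assert set(spec.rule_units) == {"AgRP", "POMC", "NGABA", "OXT", "MCH", "OX", "LHGal", "NT"}
        non_hyp = [u.id for u in spec.units if not u.hypothalamic]
        assert set(non_hyp) == {"NTSCA", "NTSGLP1", "VTA", "NAc"}
        assert spec.n_params == 51
        assert len(spec.substances) == 5

    def test_output_stage_ends_with_fi(self, spec):
        assert spec.output_stage_order[-1] == "FI"

    def test_ligand_flow_is_acyclic(self, spec):
        # validate() raises on cycles; also check the edge list explicitly
        import networkx as nx

        g = nx.DiGraph(spec.ligand_flow_edges())
        assert nx.is_directed_acyclic_graph(g)

    def test_json_round_trip(self, spec, tmp_path):
        path = tmp_path / "net.json"
        spec.save(path)
        again = NetworkSpec.load(path)
        assert again.param_names == spec.param_names
        assert again.to_json() == spec.to_json()

    def test_bad_wiring_rejected(self, spec):
        doc = spec.to_json()
        doc["receptors"][0]["ligands"] = [{"kind": "substance", "name": "nonesuch"}]
        with pytest.raises(ValueError, match="undeclared substance"):
            NetworkSpec.from_json(doc)


class TestParameterVector:
    def test_key_set_must_match(self, spec):
        with pytest.raises(ValueError, match="parameter keys"):
            ParameterVector(spec, {"POMC.LepRB": 1.0})

    def test_negative_strength_rejected(self, spec):
        vals = np.zeros(spec.n_params)
        vals[0] = -0.1
        with pytest.raises(ValueError, match="nonnegative"):
            ParameterVector(spec, vals)

    def test_dict_round_trip(self, spec, random_params):
        again = ParameterVector(spec, random_params.to_dict())
        assert np.allclose(again.values, random_params.values)
        assert again.distance() == pytest.approx(np.linalg.norm(random_params.values))


class TestInitialState:
    def test_defaults(self, spec):
        s = make_initial_state(spec)
        assert all(v == 1.0 for v in s.substances.values())
        assert all(v == 0.0 for v in s.drugs.values())
        assert all(s.resp[e] == 0.0 for e in spec.elements)
        assert all(s.live[e] == 1 for e in spec.elements)
        assert s.overrides == {}

    def test_leptin_deficient(self, spec):
        s = make_initial_state(spec, {"leptin": 0.0})
        assert s.substances["leptin"] == 0.0
        assert s.substances["ghrelin"] == 1.0

    def test_negative_level_rejected(self, spec):
        with pytest.raises(ValueError, match="negative"):
            make_initial_state(spec, {"leptin": -1.0})
        with pytest.raises(ValueError, match="unknown"):
            make_initial_state(spec, {"insulin": 1.0})


class TestNetInput:
    def _pomc_setup(self, spec):
        vals = {n: 0.0 for n in spec.param_names}
        vals.update({"POMC.LepRB": 1.0, "POMC.Y1R": 0.5, "POMC.GABAR": 0.5,
                     "POMC.5HT2CR": 1.0, "POMC.bias": 0.0})
        params = ParameterVector(spec, vals)
        state = make_initial_state(spec, {"leptin": 2.0})
        state.resp["AgRP"] = 1.0  # delivers NPY 1 and GABA 1
        state.resp["NGABA"] = 0.0
        return params, state

    def test_pomc_net_arithmetic(self, spec):
        params, state = self._pomc_setup(spec)
        # 1*2 - 0.5*1 - 0.5*(1+0) + 1*(1+0) + 0
        assert compute_net_input("POMC", state, params, spec) == pytest.approx(2.0)

    def test_risperidone_halves_5ht2cr(self, spec):
        params, state = self._pomc_setup(spec)
        state.drugs["risperidone"] = 1.0
        assert compute_net_input("POMC", state, params, spec) == pytest.approx(1.5)
        state.drugs["risperidone"] = 10.0  # effective strength clamps at zero
        assert compute_net_input("POMC", state, params, spec) == pytest.approx(1.0)

    def test_unknown_unit_rejected(self, spec, random_params):
        with pytest.raises(KeyError):
            compute_net_input("VMH", make_initial_state(spec), random_params, spec)

    def test_matches_term_by_term_oracle(self, spec, rng):
        """Net input equals an independent per-receptor re-summation."""
        for _ in range(20):
            n_str = len(spec.receptors)
            vals = np.concatenate([rng.uniform(0, 3, n_str), rng.uniform(-2, 2, 13)])
            params = ParameterVector(spec, vals)
            state = make_initial_state(
                spec, {s: float(rng.uniform(0, 2)) for s in spec.substances},
                {d: float(rng.uniform(0, 1)) for d in spec.drugs},
            )
            for u in spec.unit_ids:
                state.resp[u] = float(rng.uniform(0, 3))
            unit = str(rng.choice([u for u in spec.unit_ids if u != "NTSCA"]))
            expected = params[f"{unit}.bias"]
            for rec in spec.receptors_by_unit[unit]:
                lig = 0.0
                for l in rec.ligands:
                    lig += (state.substances[l.name] if l.kind == "substance"
                            else state.drugs[l.name] if l.kind == "drug"
                            else state.resp[l.name])
                for l in rec.inverse_agonists:
                    lig -= state.resp[l.name]
                s = params[f"{unit}.{rec.name}"]
                if rec.hook == "risperidone_halving":
                    s = max(0.0, s - state.drugs["risperidone"] / 2)
                expected += rec.sign * s * lig
            got = compute_net_input(unit, state, params, spec)
            assert got == pytest.approx(expected)


class TestNtscaGate:
    def _setup(self, spec, leprb, ghsr, cckr=1.0, cck=1.0, bias=0.0):
        vals = {n: 0.0 for n in spec.param_names}
        vals.update({"NTSCA.LepRB": leprb, "NTSCA.GHSR": ghsr,
                     "NTSCA.CCKR": cckr, "NTSCA.bias": bias})
        params = ParameterVector(spec, vals)
        state = make_initial_state(spec, {"cck": cck})
        return params, state

    def test_open_gate_includes_cck_term(self, spec):
        params, state = self._setup(spec, leprb=0.5, ghsr=0.0)  # modulator sum +0.5
        assert gated_net_input_ntsca(state, params, spec) == pytest.approx(1.5)

    def test_negative_modulator_excludes_cck(self, spec):
        params, state = self._setup(spec, leprb=0.0, ghsr=0.2)  # modulator sum -0.2
        assert gated_net_input_ntsca(state, params, spec) == pytest.approx(-0.2)

    def test_zero_cck_keeps_gate_shut(self, spec):
        params, state = self._setup(spec, leprb=0.5, ghsr=0.0, cck=0.0)
        assert gated_net_input_ntsca(state, params, spec) == pytest.approx(0.5)


class TestUnitResponse:
    @pytest.mark.parametrize(
        "net,live,stim,expected",
        [(-3.2, 1, 0.0, 0.0), (2.5, 0, 10.0, 0.0), (2.5, 1, 0.0, 2.5), (-1.0, 1, 3.0, 2.0)],
    )
    def test_examples(self, net, live, stim, expected):
        assert unit_response(net, live, stim) == pytest.approx(expected)


class TestFixedPoint:
    def test_zero_network_stays_silent(self, spec):
        params = ParameterVector.zeros(spec)
        term = run_to_fixed_point(make_initial_state(spec), params, spec)
        assert all(term.resp[e] == 0.0 for e in spec.elements)

    def test_output_stage_idempotent(self, spec, random_params):
        term = run_to_fixed_point(make_initial_state(spec), random_params, spec)
        again = propagate_output_stage(term, random_params, spec)
        for e in spec.elements:
            assert again.resp[e] == pytest.approx(float(term.resp[e]), abs=1e-12)

    def test_nonnegative_responses(self, spec, rng):
        for _ in range(10):
            n_str = len(spec.receptors)
            vals = np.concatenate([rng.uniform(0, 5, n_str), rng.uniform(-5, 5, 13)])
            term = run_to_fixed_point(make_initial_state(spec), ParameterVector(spec, vals), spec)
            assert all(float(term.resp[e]) >= 0.0 for e in spec.elements)

    def test_excitatory_strength_monotonicity(self, spec, rng):
        """Raising a purely excitatory receptor's strength never lowers
        its owner's terminal response."""
        n_str = len(spec.receptors)
        base_vals = np.concatenate([rng.uniform(0, 2, n_str), rng.uniform(-1, 1, 13)])
        i = spec.strength_index("POMC", "LepRB")  # excitatory, substance-driven
        lo_vals, hi_vals = base_vals.copy(), base_vals.copy()
        lo_vals[i], hi_vals[i] = 0.5, 2.5
        lo = run_to_fixed_point(make_initial_state(spec), ParameterVector(spec, lo_vals), spec)
        hi = run_to_fixed_point(make_initial_state(spec), ParameterVector(spec, hi_vals), spec)
        assert float(hi.resp["POMC"]) >= float(lo.resp["POMC"]) - 1e-12

    def test_converges_within_sweep_bound(self, spec, random_params):
        run_to_fixed_point(make_initial_state(spec), random_params, spec)  # must not raise
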