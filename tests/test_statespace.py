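import numpy as np
import pytest

from hypofeed.network import ParameterVector, make_initial_state, run_to_fixed_point
from hypofeed.statespace import (
    StateSpaceError,
    applicable_rules,
    elaborate,
    enumerate_reachable,
    parse_predicate,
    search,
    state_key,
    step,
    terminal_and_baseline,
)
from hypofeed.toys import brute_force_enumerate, make_random_toy, make_toy_chain


class TestToyChain:
    def test_two_unit_chain_terminal(self):
        spec, params = make_toy_chain(2, weights=1.0)
        term = run_to_fixed_point(make_initial_state(spec), params, spec)
        assert float(term.resp["U1"]) == pytest.approx(1.0)
        assert float(term.resp["U2"]) == pytest.approx(1.0)

    def test_two_unit_chain_reachable_states(self):
        """Hand enumeration: init, U1-updated, U1+U2; U2 cannot fire first
        (its net input is unchanged while U1 is silent)."""
        spec, params = make_toy_chain(2)
        rs = enumerate_reachable(None, params, spec)
        assert len(rs) == 3
        assert sorted(rs.layer.values()) == [0, 1, 2]
        assert len(rs.terminal) == 1

    def test_inhibitory_middle_silences_third_unit(self):
        spec, params = make_toy_chain(3, weights=[1.0, -1.0])
        term = run_to_fixed_point(make_initial_state(spec), params, spec)
        assert float(term.resp["U3"]) == 0.0

    def test_chain_size_validated(self):
        with pytest.raises(ValueError):
            make_toy_chain(5)


class TestStepSemantics:
    def test_step_requires_applicability(self):
        spec, params = make_toy_chain(2)
        init = elaborate(make_initial_state(spec), params, spec)
        assert applicable_rules(init, params, spec) == ["U1"]
        with pytest.raises(StateSpaceError, match="not applicable"):
            step(init, "U2", params, spec)

    def test_single_unit_update_is_idempotent(self):
        spec, params = make_toy_chain(2)
        init = elaborate(make_initial_state(spec), params, spec)
        after = step(init, "U1", params, spec)
        assert "U1" not in applicable_rules(after, params, spec)

    def test_terminal_state_has_no_applicable_rules(self, spec, zero_error_params):
        term = run_to_fixed_point(make_initial_state(spec), zero_error_params, spec)
        assert applicable_rules(term, zero_error_params, spec) == []

    def test_initial_state_is_not_terminal(self, spec, zero_error_params):
        init = elaborate(make_initial_state(spec), zero_error_params, spec)
        assert applicable_rules(init, zero_error_params, spec)


class TestEnumeration:
    def test_zero_parameter_model_is_immediately_terminal(self, spec):
        params = ParameterVector.zeros(spec)
        rs = enumerate_reachable(None, params, spec)
        assert len(rs) == 1 and len(rs.terminal) == 1 and rs.max_layer == 0

    def test_matches_brute_force_on_shipped_toys(self):
        for n in (2, 3, 4):
            spec, params = make_toy_chain(n, weights=0.8)
            rs = enumerate_reachable(None, params, spec)
            oracle = brute_force_enumerate(spec, params)
            assert set(rs.states) == set(oracle)

    def test_matches_brute_force_on_random_toys(self):
        """Order-by-order recursion over all firing orders, collapsed to a
        set, equals the deduplicating breadth-first enumeration."""
        for seed in range(30):
            spec, params = make_random_toy(seed)
            rs = enumerate_reachable(None, params, spec)
            oracle = brute_force_enumerate(spec, params)
            assert set(rs.states) == set(oracle), f"toy seed {seed}"

    def test_confluence_on_random_toys(self):
        for seed in range(30):
            spec, params = make_random_toy(seed)
            rs, terminals, baseline = terminal_and_baseline(None, params, spec)
            assert len(terminals) == 1, f"toy seed {seed}"

    def test_state_cap_enforced(self, spec, zero_error_params):
        with pytest.raises(StateSpaceError, match="state cap"):
            enumerate_reachable(None, zero_error_params, spec, max_states=10)

    def test_layers_start_at_zero_and_are_contiguous(self, spec, zero_error_params):
        rs = enumerate_reachable(None, zero_error_params, spec)
        layers = sorted(set(rs.layer.values()))
        assert layers == list(range(rs.max_layer + 1))


class TestConfluenceCanonical:
    def test_declarative_imperative_agreement(self, spec, zero_error_params):
        rs, terminals, baseline = terminal_and_baseline(None, zero_error_params, spec)
        fixed = run_to_fixed_point(make_initial_state(spec), zero_error_params, spec)
        assert len(terminals) == 1
        assert state_key(fixed, spec) == state_key(terminals[0], spec)


class TestSearch:
    def test_contradictory_predicate_matches_nothing(self, spec, zero_error_params):
        rs = enumerate_reachable(None, zero_error_params, spec)
        pred = parse_predicate("FI>1,FI==0")
        _keys, count = search(rs, pred)
        assert count == 0

    def test_matches_brute_force_filter_on_toy(self):
        spec, params = make_toy_chain(3, weights=[1.0, 0.5])
        rs = enumerate_reachable(None, params, spec)
        pred = parse_predicate("U2>0")
        keys, count = search(rs, pred)
        oracle = {k for k, s in brute_force_enumerate(spec, params).items()
                  if float(s.resp["U2"]) > 0}
        init_key = rs.init_key
        assert set(keys) == oracle - {init_key}

    def test_init_excluded_unless_requested(self):
        spec, params = make_toy_chain(2)
        rs = enumerate_reachable(None, params, spec)
        always = parse_predicate("U1>-1")  # tautology over responses >= 0
        _k, count = search(rs, always)
        _k2, count_with_init = search(rs, always, include_init=True)
        assert count == len(rs) - 1
        assert count_with_init == len(rs)

    def test_baseline_relative_thresholds(self, spec, zero_error_params):
        rs, _t, baseline = terminal_and_baseline(None, zero_error_params, spec)
        pred = parse_predicate("AgRP==0,POMC>baseline,FI>1.3*baseline",
                               baseline=baseline, reachable=rs)
        keys, count = search(rs, pred)
        assert count >= 1  # paradoxical configurations exist
        for k in keys:
            s = rs.states[k]
            assert float(s.resp["AgRP"]) == 0.0
            assert float(s.resp["POMC"]) > float(baseline.resp["POMC"])
            assert float(s.resp["FI"]) > 1.3 * float(baseline.resp["FI"])

    def test_unknown_unit_rejected(self, spec, zero_error_params):
        rs = enumerate_reachable(None, zero_error_params, spec)
        with pytest.raises(ValueError, match="unknown unit"):
            parse_predicate("VMH>0", reachable=rs)


class TestStateKey:
    def test_key_distinguishes_substance_context(self, spec, random_params):
        a = elaborate(make_initial_state(spec), random_params, spec)
        b = elaborate(make_initial_state(spec, {"leptin": 0.0}), random_params, spec)
        assert state_key(a, spec) != state_key(b, spec)

    def test_key_stable_under_copy(self, spec, random_params):
        s = elaborate(make_initial_state(spec), random_params, spec)
        assert state_key(s, spec) == state_key(s.copy(), spec)
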