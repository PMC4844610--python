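"""Model/Results objects tying the circuit, truth table, calibration and analyses together.

Typical session::

    from hypofeed import FoodIntakeModel

    model = FoodIntakeModel()                 # canonical wiring + truth table
    results = model.fit(seed=1)               # GA calibration to zero error
    print(results.summary())
    reachable = results.enumerate()            # full state-transition tree
    results.invariants_agrp_pomc(), results.invariants_lh_gaba()         # paradox-resolution suites

``fit`` runs the genetic algorithm over successive internal seeds until
a zero-truth-table-error parameter vector is found (or the seed budget
is exhausted, in which case the best vector found is returned and
``results.error`` is nonzero).
"""

from __future__ import annotations

import numpy as np

from . import experiments as _exp
from . import logic as _logic
from . import report as _report
from . import statespace as _ss
from .network import NetworkSpec, ParameterVector, canonical_network, make_initial_state, run_to_fixed_point
from .optimize import GAConfig, SolutionArchive, run_ga

__all__ = ["FoodIntakeModel", "FoodIntakeResults"]


class FoodIntakeModel:
    """The food-intake control network plus its calibration corpus."""

    def __init__(self, network: NetworkSpec | None = None, truth_table=None,
                 stim_magnitude: float = _exp.DEFAULT_STIM):
        self.network = network if network is not None else canonical_network()
        self.truth_table = truth_table if truth_table is not None else _exp.load_truth_table()
        self.stim_magnitude = stim_magnitude

    def fit(self, seed: int = 0, config: GAConfig | None = None, max_runs: int = 10,
            collect: int = 1, time_budget: float | None = None,
            verbose: bool = False) -> "FoodIntakeResults":
        """Calibrate by GA; internal run seeds derive deterministically from ``seed``.

        Runs are warm-chained: each run after the first seeds a few rows
        of its population with (jittered copies of) the best genome so
        far, so the sequence behaves like one long search with restarts.
        Stops once ``collect`` zero-error vectors are archived, after
        ``max_runs`` GA runs, or when ``time_budget`` (seconds) is
        exhausted.
        """
        import time

        config = config or GAConfig()
        rng = np.random.default_rng(seed)
        run_seeds = rng.integers(0, 2**31 - 1, size=max_runs)
        archive = SolutionArchive(self.network)
        best_vec, best_err = None, None
        warm = None
        lo, hi = config.bounds(self.network)
        t0 = time.time()
        for s in run_seeds:
            vec, err = run_ga(config, self.network, self.truth_table, seed=int(s),
                              stim_magnitude=self.stim_magnitude, seed_population=warm)
            if verbose:
                print(f"GA run (seed {s}): error {err} [{time.time() - t0:.0f}s]")
            if best_err is None or err < best_err:
                best_vec, best_err = vec, err
            if err == 0:
                archive.add(vec, err, seed=int(s))
                warm = None
                if len(archive) >= collect:
                    break
            else:
                jitter = np.random.default_rng(int(s) % 2**31)
                warm = np.vstack([
                    best_vec.values + jitter.normal(0.0, sc, (4, self.network.n_params))
                    for sc in (0.0, 0.05, 0.2)
                ])
                warm = np.clip(warm, lo, hi)
            if time_budget is not None and time.time() - t0 > time_budget:
                break
        return FoodIntakeResults(self, best_vec, best_err, archive=archive)

    def results_from_params(self, params) -> "FoodIntakeResults":
        """Wrap an existing parameter vector (e.g. an archived solution)."""
        if not isinstance(params, ParameterVector):
            params = ParameterVector(self.network, params)
        err = _exp.truth_table_error(params, self.network, self.truth_table,
                                     self.stim_magnitude)
        return FoodIntakeResults(self, params, err)

    def evaluate(self, params):
        """Truth-table error of a parameter vector under this model's corpus."""
        return _exp.truth_table_error(params, self.network, self.truth_table,
                                      self.stim_magnitude)


class FoodIntakeResults:
    """A calibrated parameterization and the analyses it supports."""

    def __init__(self, model: FoodIntakeModel, params: ParameterVector, error: int,
                 archive: SolutionArchive | None = None):
        self.model = model
        self.params = params
        self.error = error
        self.archive = archive
        self._reachable = None
        self._baseline = None

    # -- basic quantities ---------------------------------------------------
    @property
    def baseline(self):
        """Terminal state reached from the normal initial state."""
        if self._baseline is None:
            self._baseline = run_to_fixed_point(
                make_initial_state(self.model.network), self.params, self.model.network
            )
        return self._baseline

    def enumerate(self, force: bool = False) -> _ss.ReachableSet:
        """Deduplicated state-transition tree from the normal initial state."""
        if self._reachable is None or force:
            rs, _terminals, baseline = _ss.terminal_and_baseline(
                None, self.params, self.model.network
            )
            self._reachable = rs
            self._baseline = baseline
        return self._reachable

    def search(self, predicate_text: str):
        """Count states matching a predicate such as
        ``"AgRP==0,POMC>baseline,FI>1.3*baseline"``."""
        rs = self.enumerate()
        pred = _ss.parse_predicate(predicate_text, baseline=self.baseline, reachable=rs)
        return _ss.search(rs, pred)

    def significance(self):
        return _exp.significance_check(self.params, self.model.network,
                                       self.model.truth_table, self.model.stim_magnitude)

    # -- invariant suites ---------------------------------------------------
    def invariants_agrp_pomc(self) -> list[bool]:
        rs = self.enumerate()
        return _logic.run_agrp_pomc_suite(rs, self.baseline, self.params)

    def invariants_lh_gaba(self) -> list[bool]:
        rs = self.enumerate()
        return _logic.run_lh_gaba_suite(rs, self.baseline, self.params)

    # -- reporting ------------------------------------------------------------
    def percent_activity(self, keys=None):
        return _report.percent_activity(self.enumerate(), keys)

    def summary(self) -> str:
        spec = self.model.network
        rs = self._reachable
        lines = [
            "Food-intake control model calibration",
            "=" * 46,
            f"units: {len(spec.units)} ({len(spec.rule_units)} hypothalamic rule units)",
            f"optimizable parameters: {spec.n_params}",
            f"truth-table error: {self.error} / 39 scored observations",
        ]
        if self.archive is not None:
            lines.append(f"archived zero-error solutions: {len(self.archive)}")
        base = self.baseline
        lines.append("")
        lines.append("baseline responses (normal substance levels):")
        for e in spec.elements:
            lines.append(f"  {e:8s} {float(base.resp[e]):10.4f}")
        if rs is not None:
            lines.append("")
            lines.append(f"reachable states: {len(rs)} (deepest layer {rs.max_layer}, "
                         f"{len(rs.terminal)} terminal)")
        return "\n".join(lines)
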