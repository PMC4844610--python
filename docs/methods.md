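# Methods

## The model

The food-intake control circuit is modeled as a feedforward network of
12 units, each standing for every neuron of one anatomically and
neurochemically defined subtype, plus a food-intake (FI) output
element. Eight units are hypothalamic (arcuate AgRP, POMC and NGABA;
paraventricular OXT; lateral-hypothalamic MCH, OX, LHGal and NT) and
four form the output stage (NTSCA and NTSGLP1 in the brainstem, VTA,
NAc). Five endogenous substances drive the network: leptin, ghrelin,
CCK, serotonin (5HT) and glucose; five exogenous drugs (risperidone,
5HT2C and 5HT1B agonists, α-MSH, GLP-1) enter as additional receptor
ligands.

A unit's net input is

    net_i = bias_i + Σ_receptors sign_r · strength_r · (Σ cognate ligand levels)

where ligands converging on one receptor are summed *before* weighting
(GABA from AgRP and NGABA share POMC's GABA receptor), and its response
is the net input bounded at zero, gated by a live flag and shifted by
any opto/chemogenetic somatic drive:

    response_i = live_i · max(0, net_i + stim_i)

Transmitter release equals the response. Three receptor-level
modulations are wired in:

* risperidone halves the 5HT2C receptor strength, clamped at zero:
  `max(0, R − risperidone/2)`;
* AgRP peptide is an inverse agonist at OXT's MC3R/MC4R: it is
  subtracted from the melanocortin ligand sum before weighting;
* NTSCA's CCK receptor is gated by a sensitization sum
  (leptin+, ghrelin−, OX−, OXT+): the CCK term enters the net input
  only when that sum is positive and both CCK and the CCK receptor
  strength are positive. This gate is the model's one switch-like
  nonlinearity besides response clipping, and it matters: several of
  the all-or-nothing behavioral contrasts in the calibration corpus are
  reproduced by configurations in which a manipulation does or does not
  trip the gate.

The 51 free parameters are the 38 receptor strengths (nonnegative;
excitation/inhibition is carried by wiring signs) and 13 biases (12
units + FI). The parameter count is a structural checksum enforced by
`NetworkSpec.validate_canonical`. Two wiring points were genuinely
open and were fixed as follows: NTSCA reaches FI through NTSGLP1
(adrenergic relay) rather than through a direct FI weight, and FI
keeps an intrinsic bias — without one, FI (= `max(0, bias − w·NAc)`)
would be identically zero. AgRP→OX excitation and POMC→OX inhibition
use dedicated receptor weights (AGRPR, MCR), with exogenous α-MSH a
ligand of OX's MCR; inverse agonism is applied only at OXT.

## Update semantics

Hypothalamic units update by *optional rules*: a unit may recompute its
net input whenever the recomputation would change it by more than the
tolerance (1e-9). Output-stage units and FI update by *forced
equations*, re-evaluated in the fixed topological order NTSCA →
NTSGLP1 → VTA → NAc → FI immediately after every rule firing. Two
equivalent executions are implemented and cross-checked:

* **imperative** (`run_to_fixed_point`): sweep all units until no net
  input changes; guaranteed to settle within 13 sweeps for the acyclic
  canonical wiring;
* **declarative** (`enumerate_reachable`): breadth-first exploration of
  every rule-firing order, deduplicated by a full-state key (all nets
  and responses rounded at the tolerance, plus the substance/drug/
  override context). Layer 0 is the elaborated initial state.

For any acyclic wiring all branches reach the same terminal state
(confluence); the terminal from the normal initial state (all
substances 1.0, drugs 0.0, units silent) defines baseline responses.
Non-terminal states — configurations in which some unit has not yet
updated — are read as response patterns imposed by neurons outside the
modeled network, and are the objects the searches and invariant checks
quantify over.

## Calibration corpus and error

The truth table encodes 32 experimental manipulations with 39 scored
categorical outcomes (31 food-intake cells, 8 unit-activity cells). A
simulated value counts as changed only when it departs more than 30%
from baseline (strictly above 1.3× or below 0.7×, compared
multiplicatively; a zero baseline can only "increase"). The error of a
parameter vector is the number of mismatched observations.

Manipulation encoding (full list in the fixture): receptor knockouts
zero strengths (globally for constitutive knockouts, per-unit for
cell-specific deletions); leptin-signaling loss sets leptin to 0;
lesions and chemogenetic inhibition clear the live flag;
photo/chemogenetic somatic stimulation adds a drive of 2.0 model units;
projection photo-stimulation forces all transmitters delivered along
one edge to 2.0 (blockade: 0); hormone administration doubles the
substance; drugs with normal level 0 are administered at 1.0. The
stimulation magnitude sits deliberately on the same scale as hormone
administration (substances double from 1.0): analysis of the constraint
system showed that forcing projections to levels far above endogenous
transmitter levels (e.g. 5 when baselines are O(1)) makes the
"projection stimulation + receptor blockade = no change" rows
geometrically irreconcilable with the receptor-knockout rows inside the
parameter bounds, whereas at 2.0 the corpus admits an open set of exact
solutions.

## Genetic-algorithm calibration

The integer error over 39 observations is a plateau landscape, so the
GA (seeded numpy implementation; population 200, up to 2000–3000
generations, early stop at zero error) layers three mechanisms over
tournament selection, uniform crossover, mixed-scale gaussian mutation
and elitism:

* **hinge margins**: each observation contributes a baseline-scaled
  hinge distance to satisfaction (with a small slack pushing strictly
  past the 30% boundary); margins only rank individuals within an
  error plateau, and archived solutions are always re-judged by the
  plain integer error;
* **dynamic constraint reweighting**: when the incumbent stagnates,
  observations it keeps getting wrong gain selection weight, forcing
  the population to restructure around the stubborn rows;
* **a local-search track**: each generation also evaluates a batch of
  small, adaptively scaled perturbations of the incumbent, accepted on
  lexicographic (error, margin) improvement — this walks plateaus to
  their edges.

The initial population is drawn from the inner 40% of the bounds
(strengths [0, 5], biases [−5, 5]): with all substances at 1.0 the
data live on an O(1) scale and uniform-over-bounds initialization
mostly samples saturated networks. A small viability term keeps the
baseline food intake away from degenerate near-zero regimes (the
normal state is supposed to produce a medium baseline intake).
`FoodIntakeModel.fit` chains runs, seeding each new population with
jittered copies of the best genome so far. Solution ensembles are
ordered by Euclidean distance from the zero vector;
Near/Middle/Far/Average representatives and the pairwise Pearson
correlation matrix (entries with p ≥ 0.01 masked to zero) are
computed from the archive.

Exact-zero calibration is a genuinely rare event at desk scale. The
zero-error set exists — the shipped archive holds exact solutions,
constructed by refining an analytically derived feasible corner with
the optimizer's local-search stage and diversifying it by
perturb-and-repolish — but its basin is narrow: roughly eight of the
51 dimensions are bracketed to relative widths of 5–15% by the
interacting projection-stimulation, melanocortin-knockout and
LepRB-deletion experiments, which jointly pin the NTSCA CCK-gate
slack. Desk-scale runs (order 10^6 evaluations) routinely reach 2–4
residual mismatches; for comparison, the original study reports that
only 4.2% of runs succeeded at a population of 1000 evolved for 5100
generations (roughly 5×10^6 evaluations per run). Users who need
fresh zero-error vectors should expect to spend cluster-scale compute
or to start near the archived solutions.

## Analyses

Searches and invariant checks run over the reachable set from the
normal initial state. Searches follow "one or more rule firings"
semantics (the elaborated initial state is excluded); counts are counts
of distinct states. Invariant checks ("whenever antecedent then
consequent") quantify over all enumerated states including the initial
one and return a lexicographically-smallest-key witness when false.
Proposition thresholds resolve against the parameterization's own
baseline and per-unit maxima: "high" = more than 30% above baseline,
"OX > 20%" = above 20% of OX's maximum over the reachable set, "fully
active" = updated to its equation-determined value and positive. Food
intake is classed on percent of its maximum over the reachable set:
low ≤ 43, high ≥ 81, medium between (real-valued extension of the
integer break points).

## What passing tests do and do not show

The truth-table fixture and wiring are reconstructions from published
qualitative findings; the synthetic corpus defines the study
conditions, and zero error means the network reproduces every
categorical outcome under those conditions — not that parameter values
are biologically measured quantities. Analyses that the original study
derived from its own calibrated ensembles (the exact state-space
search counts, the printed truth values of the two invariant suites,
and the exact tree depth) are parameterization- and wiring-detail-
sensitive: across the zero-error ensembles produced here the paradox
analyses reproduce qualitatively (paradoxical AgRP-inactive/
POMC-active/FI-high configurations exist and are fewer than the
expected AgRP-active/POMC-inactive ones; enumeration depth is close to
the published value), but the exact suite truth values are not
invariant across solution families in this reconstruction. The
supplementary parameter table of the original study, which would pin
these down, is not shipped; analyses that require it are skipped.

## Numerical choices

Net-change tolerance 1e-9 (also the state-key quantization);
fixed-point sweep bound 13; state-count safety cap 10^6 (canonical
enumerations run ~3–4×10^3 states); GA tie-breaks by genome
lexicographic order for reproducibility; correlation significance
threshold p < 0.01 two-sided with no multiple-testing correction;
degenerate (zero-variance) parameters masked and flagged. All
randomness flows from user-supplied integer seeds through
`numpy.random.default_rng`; derived seeds stay below 2^31.

## Known limitations

No VMH unit, no continuous-time dynamics, no learning, and no
dose–response modeling (single administration levels). Non-terminal
configurations arising from output-stage units failing to update are
excluded by construction. The GA is a desk-scale protocol; the
original cluster-scale success-rate statistics are out of scope.
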