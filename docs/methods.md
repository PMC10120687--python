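# Methods

## Model class and assumptions

`fibrosex` simulates intracellular signaling as a *logic-based ODE*
system in the Netflux tradition. Each molecular species *i* carries a
dimensionless activity *yᵢ ∈ [0, Ymaxᵢ]* relaxing toward a gated target,

    dyᵢ/dt = (Fᵢ(y) · Ymaxᵢ − yᵢ) / τᵢ ,

with *Fᵢ* the OR-combination (inclusion–exclusion fold,
`OR(a,b) = a + b − ab`) of all reactions producing *i*. A reaction's
contribution is its weight *w* times the AND-product of its term
activations; a term is the normalized Hill transform of the reactant's
activity, or one minus it when negated (`fINHIB(x) = 1 − f(x)`). Source
reactions (`=> X`) contribute the constant *w*, which doubles as the
input stimulus level. Species with no producers decay to zero; species
with Ymax = 0 are hard knockouts.

The normalized Hill function is

    f(x) = B xⁿ / (Kⁿ + xⁿ),  B = (EC50ⁿ − 1)/(2 EC50ⁿ − 1),  Kⁿ = B − 1 ,

the unique scaling with f(0)=0, f(EC50)=½, f(1)=1. The normalization
degenerates when EC50ⁿ = ½ (B's denominator vanishes); that parameter
point is rejected with an explicit error rather than regularized.

Assumptions inherited from this model class: activities are
semi-quantitative (no units, no concentrations), all interactions act
through the same saturating nonlinearity, and combinatorial regulation
is captured by continuous Boolean gates rather than mass-action kinetics.
Predictions are therefore directional (up / down / no change), not
quantitative dose–response curves.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| Hill coefficient n | 1.05 | – | near-linear sigmoid; the calibrated value for this network family |
| EC50 | 0.65 | – | calibrated half-max activation point |
| τ signaling / transcription / translation | 1 / 0.1 / 10 | h | class-default time constants; configurable per species and per model (`tau_by_class`), since conventions for the signaling/transcription pair differ between published variants of this framework |
| tension input weight | 0.65 | – | calibrated basal mechanical tone |
| stimulus weight | 1.0 | – | saturating single-input stimulus |
| Δ-activity threshold | 0.05 | – | 5% of the normalized 0–1 scale, absolute (not relative) change |
| knockdown Ymax | 0.1 | – | 90% knockdown clamp |
| screen basal input weight | 0.4 | – | fibrotic tone for perturbation and drug screens |
| drug weight | 0.85 | – | static dose for the drug screen |
| receptor Ymax | male 0.5, female 1.0 | – | halved receptor saturation encodes the male condition |
| E2 input weight | 0.25 / 0.5 / 1.0 | – | male / post-menopausal / pre-menopausal circulating-estrogen levels |

Integration uses `scipy.solve_ivp` with LSODA (τ spans two orders of
magnitude, so a stiff-capable method), rtol 1e-6, atol 1e-8. Endpoint
activities are clipped into [0, Ymax] only within a 1e-4 tolerance;
larger excursions raise instead of being silently repaired. Knockdown
continuations may legally *start* above the clamped Ymax and decay
toward it, so the upper bound check uses max(Ymax, y_start).

## Protocols

**Validation.** 40 h basal (tension at 0.65, every other input at a low
basal tone of 0.1) followed by 80 h with one input raised to 1.0,
continuing from the basal endpoint; Δ = endpoint(stimulus) −
endpoint(basal) per node, classified at ±0.05 with inclusive boundaries.
Records are routed by cell sex (male → male model, female → female
model, pooled → elementwise mean of both predictions — applied to deltas,
which equals averaging endpoints because the mean is linear);
unreported-sex records are excluded by default and can be routed to the
pooled prediction by flag. Records naming species absent from the model
are counted as unevaluable and reported, never dropped. Design choices
here: the 0.1 basal tone keeps inhibitory (NOT-gated) edges exercisable
— a zero basal would make them invisible; E2 carries no additional
sex-specific basal tone during validation and enters only as an explicit
stimulus; endpoints are last-time-point samples, not time averages.
Because the fixed horizons are protocol constants, slow (τ = 10 h) nodes
retain a ~1% residual relaxation at the basal endpoint; this drift is an
order of magnitude below the classification threshold.

**Combined treatment.** 80 h with all inputs at 0.25 (negative control
tone, tension 0.65), then 240 h with the named treatment set raised
to 1.0; readouts are the fibrosis markers (fibronectin, proCI, proCIII,
αSMA) present in the model.

**Knockdown screen.** 80 h fibrotic baseline (all inputs 0.4, E2 at the
condition weight) from y0, then per node a 240 h continuation with that
node's Ymax clamped to 0.1, starting from the baseline endpoint
(continuation, not a fresh start — matching the sequential protocol).
D[k,j] is the endpoint change of node j under knockdown of k. Influence
(row) and sensitivity (column) scores sum |D| by default — signed sums
would cancel opposing downstream effects and understate influence — with
a `signed` option. The diagonal (the knocked node's own, mechanistic,
change) is excluded from both aggregates by default (`include_self`
restores it); ties in the rankings break alphabetically.

**Drug screen.** Mechanisms: non-competitive antagonist scales the
target's Ymax by (1 − w); competitive antagonist scales the weight of
every reaction producing the target by (1 − w) (producer-weight scaling
chosen over an EC50 shift as the cleaner continuous-logic analogue of
competitive inhibition); agonist adds a source reaction of weight w,
OR-combined with existing producers. A zero dose returns the model
unchanged. The un-drugged fibrotic run is extended through the drug
horizon (80 + 240 h) so drugged and baseline states are compared at the
same simulated time. Panel means are arithmetic means of member deltas;
MCS = matrix − protease + inhibitor by default (proteases degrade
matrix, their inhibitors preserve it); the all-additive variant is
selectable by flag since both appear in the literature of this score.
Strategy labels use ε = 0.05 (the activity-change threshold reused) on
the MCS delta; ε is configurable and always recorded in the run
manifest.

## Synthetic data

The generators exist so every pipeline stage is testable with no
external files. Toy topologies (chain, fan-in, fan-out, negative
feedback, random DAG) are deterministic per seed; random DAGs fix the
topological order by node index and give each non-root 1–3 producers.
Acyclic networks are verified against an independent steady-state oracle
— damped fixed-point iteration over the rule tables, sharing no code
with the ODE integrator. Synthetic validation sets are built backwards
from the model's own predictions: a target concordance fixes exactly
which records agree, so the scorer must recover the ratio exactly; this
validates bookkeeping, not biology. The bundled 12-node mini-fibroblast
network packs the estrogen branch (E2 → ERα/ERβ/GPR30), an ERβ NOT-gate
on NF-κB, an OR-convergence on smad3, and one output per MCS panel into
an oracle-checkable size.

What the synthetic data does *not* emulate: curated literature records
have correlated errors, heterogeneous cell preparations and publication
bias; real network tables have hub structure, feedback loops and
class-specific τ mixtures that random DAGs lack. Passing the bundled
suite shows the machinery is correct, not that any particular biological
network is.

The extension builder merges species additions, reaction additions and
rule alterations (keyed by the exact old rule string) onto a base model.
`estrogen_extension_tables()` ships the documented receptor wiring
(E2, ERα, ERβ, GPR30, CyclinB1, CDK1) and is deliberately partial — the
seventh added node and the complete 29-edge enumeration exist only in
supplementary material of the source network; `synthetic_estrogen_extension`
is an explicitly synthetic 7-node/29-edge/6-alteration stand-in used to
exercise the 125 + 7 = 132 arithmetic at full scale.

## Numerical choices and degenerate inputs

- Gate inputs outside [0,1] beyond 1e-9 are domain errors; the RHS clips
  solver micro-excursions before the Hill transform.
- OR-folds are associative; n-ary gates left-fold.
- `steady_state` integrates in chunks (t_end/8) until max|dy/dt| < atol;
  non-convergence is flagged on the result, not raised.
- Empty record sets and all-unevaluable sets raise (accuracy undefined).
- Rules are case-sensitive tokens; whitespace is ignored; `|` is
  rejected with a pointer to the multiple-reactions-per-product
  convention.
- In spreadsheet output, source rules are padded with a leading space so
  `=>` is not parsed as a formula.

## Problem sizes

The bundled analyses run on the 12-node fixture and toy networks up to
132 nodes (extension arithmetic) and 50 random DAGs of 2–12 nodes
(oracle comparison); a full pipeline run completes in a few seconds and
the whole test suite in well under a minute on one CPU. These sizes were
chosen because the fixture suite is oracle-verifiable; the engine itself
is O(reactions) per RHS evaluation and handles the ~130-node scale of
published fibroblast networks directly.

## Known limitations

- Directional, semi-quantitative predictions only; no dose–response or
  pharmacokinetics.
- Sex differences are modeled solely through estrogen receptor
  saturation and estradiol input level — no other hormones, no
  hormone-independent genetic differences, no perimenopausal continuum.
- Fixed-horizon protocols approximate steady state; slow nodes carry a
  small protocol-inherent drift (quantified above).
- The competitive-antagonist semantics and the MCS sign convention are
  field conventions with published variants; both are explicit flags
  rather than silent choices.
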