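# Methods

This note records the modelling choices, defaults and numerical decisions
behind the package, and what the synthetic-data tests do and do not show.

## Stimulus graphs

The designs are 12-node graphs with two communities of six nodes. The
*full* design connects every pair within a community except the two border
nodes of each community, which instead carry the two between-community
edges; this is the unique layout in which every node has degree 5 while
exactly two edges bridge the communities. Communities are pinned to nodes
{0..5} and {6..11}, border nodes to (4, 5) and (6, 7), between edges to
(4, 7) and (5, 6); randomness enters through the sparse removals and,
downstream, through the node-to-stimulus assignment, so the pinning loses
no generality.

The *sparse* design removes one perfect matching over each community's
within-edges (every node loses exactly one edge, degree 4); *high sparse*
removes two edge-disjoint matchings (degree 3). Matchings are
rejection-sampled until the residual graph is connected; the matching
structure is forced by the requirement that "one (two) edges per node" be
removed while preserving degree regularity. Removed pairs are exactly the
candidate *new within-community* test transitions of the sparse designs;
in the full design the only unheard within pairs are the two
border–border pairs.

Because every node has the same degree, the uniform walk's transition
matrix has constant entries 1/degree on edges and a uniform stationary
distribution, so no frequency or local-probability cue distinguishes the
communities — only higher-order structure does.

Other (even) sizes than 12 build on the same pattern but only the 12-node
invariants are enforced.

## Streams and test battery

Items last 275 ms (4 Hz). Item counts are floor(duration / item duration)
with a 1e-9 guard against binary-representation artifacts (264 s gives
exactly 960 items; 132 s gives 480 items, 479 transitions). A transition's
time stamp is the onset of its second item.

Forced-choice trials pair a reference quadruplet (middle transition
familiar within-community) with a tested quadruplet whose middle
transition carries the tested condition; first and last transitions of
both quadruplets are always familiar within-community, flankers are drawn
jointly so no node repeats inside a quadruplet (border nodes of the
high-sparse design have only two within-community neighbours, so drawing
the flankers sequentially can dead-end). Counts per battery: 8 familiar
between, 8 new between, 4 new within (each sampled undirected pair
appears once per direction), plus 4 catch trials repeating one quadruplet.
New-between middles are sampled from the cross-community non-edges;
whether flanking transitions should be balanced across conditions is not
constrained and they are sampled uniformly.

## Model zoo

All models output a pairwise score matrix; condition scores are means over
the ordered pairs of each condition (diagonal excluded — self-transitions
cannot occur in a walk), divided by the familiar-within mean so the
reference condition is exactly 1.

- TP: `Â = A`. Identical to any Ngram model on a Markov walk.
- Non-adjacent TP: `Â = A²`.
- Communicability: `Â = expm(A)`, computed on the TP matrix rather than
  the adjacency matrix so edge weights, not mere existence, enter the
  series; `scipy.linalg.expm` does the work.
- FEMM: closed form `(1 − e^{−β}) A (I − e^{−β}A)^{−1}`, evaluated by a
  transposed linear solve. The spectral radius of `e^{−β}A` is `e^{−β} < 1`
  for any row-stochastic A, so the system is never singular and the result
  is row-stochastic. An independent truncated-series oracle (Boltzmann
  weights renormalized over 0..K) agrees to 1e-10 at K = 5000 and anchors
  the tests. Limits: β → ∞ recovers A (objective TPs); β → 0 drives every
  row to the walk's stationary distribution. Default β = 0.06, the value
  previously estimated on comparable human data.
- Hitting time: expected first-passage steps. The analytic solver treats
  one linear system per target column (`H[j,j] = 0`,
  `H[i,j] = 1 + Σ_k A[i,k] H[k,j]`) and raises on reducible chains. The
  simulation estimator replicates the study's procedure: one 50,000-item
  walk, for each occurrence of i the count of steps to the next j,
  averaged. Ordered pairs never realized raise by default and can be
  imputed from the solver on request. At 50,000 items the per-entry
  Monte-Carlo error is 1.5–4%, so entry-wise agreement with the solver is
  assessed as the mean absolute relative error (3–4% here); the maximum
  over the 132 ordered pairs is an order statistic that exceeds 5% for any
  seed at this stream length. The familiarity model is the inverse,
  `1/H[i,j]`, diagonal excluded.
- Hebbian learning with decay: one unit per node; at each step every
  trace decays by `e^{−β}`, the weights from all still-active units onto
  the current unit grow by the trace (learning rate 1 — the scale cancels
  under row normalization), then the current unit's trace is incremented.
  A lag-k pair is credited `e^{−βk}`, a constant factor `e^{−β}` away from
  the FEMM series weight `e^{−β(k−1)}`, so after row normalization the
  expected weights equal the FEMM closed form exactly; the learner is a
  consistent neural-style estimator of the FEMM, and at β = 0.06 a
  50,000-item stream per paradigm yields pooled correlations above 99.5%.

## Synthetic cohorts

The generator emulates the study's data layout, not its population:
per paradigm, 8 counterbalancing groups each get their own graph instance,
forced-choice battery and 2.2-min active-listening stream; every
participant contributes two blocks of choices, four catch outcomes and one
key-press train. Half the participants are tagged *tone*, half *syllable*;
the tag carries no generative difference (an optional block-1 temperature
multiplier can emulate the slow start observed with syllables).

Choices follow `P(choose tested) = lapse/2 + (1 − lapse) ·
logistic((v_t − v_r)/T)` with v the condition scores of the two middle
transitions (reference v_r = 1). Defaults T = 0.5, lapse = 0.2 place
FEMM-generated condition means in the 30–45% band the study observed, with
*new within* nearest chance. At T = 0.1 the logistic saturates: choices
become nearly deterministic (useful for model-recovery checks, where
dominance is then maximal) but the mapping from condition scores to choice
rates is no longer approximately affine, which destroys β identifiability —
the β sweep then prefers the low-β limit direction. β recovery is
therefore a property of the near-linear decision regime, and the recovery
tests run at the defaults.

Key presses are an inhomogeneous Poisson process: baseline 0.3 events/s
(≈ 40 presses per 132-s stream, inside the 10–200 retention window) plus,
after each between-community transition, Poisson(0.3) extra events at
Gaussian(offset + 0.5 s, 0.3 s) times — simulated exactly by superposition.
Catch accuracy is 0.95 per trial.

What the generator does **not** emulate: participant heterogeneity (all
share one parameter set, so exclusion rates at the defaults are near zero,
unlike the study's 10–20%), response times, syllable-specific linguistic
priors, and any learning dynamics within a block. Passing tests therefore
show that the pipelines recover the structure the generator puts in, not
that human data contain it.

## Behavioral pipelines

Active listening: press trains become Dirac combs on a 1-ms grid,
convolved with a causal unit-area exponential kernel (τ = 0.5 s by
default, truncated at 6τ; the original kernel constant is unspecified),
epoched from −2.75 to +2.75 s around every transition offset. The between
curve averages all familiar-between epochs; the within curve averages
1000 random groups of four directed familiar-within transitions
(occurrence-weighted, via per-transition-type mean epochs, which makes the
1000 groups cheap). Both curves are divided by the subject's within grand
mean — the specific normalization is a package choice, as the original is
described only as "normalizing and averaging across subjects" — and then
grand-averaged. Significance: unpaired t-tests every millisecond across
participants in the [−0.1, 2.75] s window, Bonferroni-corrected by the
window's sample count.

Forced choice: familiarity per participant and condition is
100 × chosen/total (block 2 by default), after excluding participants who
failed more than two of four catch trials; the press-count rule (< 10 or
> 200 presses) applies only to the press analysis, the two rules being
independent. Condition tests are one-sample t vs 50 and pairwise paired t,
each family Benjamini–Hochberg corrected; an unpaired tone-vs-syllable
test per condition is available when stimulus labels exist.

## Model comparison

The pooled data vector holds, per paradigm, the three non-reference
condition means divided by 50, matching the models' familiar-within
normalization (9 cells over three paradigms; a restricted 4-cell variant —
new within and familiar between in the two sparse designs — isolates the
conditions where communicability disagrees qualitatively with the
FEMM/hitting-time family). Bootstrap: participants resampled with
replacement within paradigm, 5000 occurrences; each resample's vector is
Pearson-correlated with every model vector (Spearman is available);
dominance(i, j) is the fraction of resamples where model i correlates
more, ties counted half. Degenerate zero-variance resample vectors get
correlation 0. The noise ceiling correlates two independent resamples of
the same cohort. Note a property of this estimator: both resamples share
the cohort's empirical pattern, so under pure-chance responding it
converges to ≈ 0.5 (shared sampling deviation and bootstrap noise have
equal variance), not to 0; it is an upper reference for model fits on real
data, where the data were not generated by any candidate model.

β sweeps use a log-spaced grid over [1e-15, 1e15] with 601 points
(0.05 decades per step — chosen so the grid resolves two significant
figures of an argmax near 0.05; a 100-point grid's 0.3-decade spacing
cannot) and a centered 5-point moving average. The plateau is the
contiguous region within 0.005 of the smoothed maximum.

The FEMM/hitting-time equivalence curve correlates, at each β, the pooled
FEMM condition vector with the pooled inverse-hitting-time vector
(hitting times simulated from one 50,000-item walk per paradigm graph).
Here the reference cells are included (12 cells): both models are
normalized to 1 on familiar-within, and including those cells makes the
comparison span the full condition pattern; this variant reproduces the
expected maximum of ≈ 99.3%. The curve is a near-flat dome — the smoothed
correlation varies by under 0.15 percentage points across β ∈ [0.02, 0.1] —
so the *location* of its maximum is weakly identified: with analytic
(noise-free) hitting times it sits at β ≈ 0.032, and 50,000-item
simulation noise moves it within roughly [0.025, 0.036]. The robust
statement is the plateau of high correlation spanning [1e-4, 1e-1],
which comfortably contains the working value β = 0.06.

## Problem sizes and runtime

The test suite exercises the pipelines at reduced scale chosen as the
smallest sizes at which each statistical property is stable: cohorts of
200/paradigm for model and β recovery (20 replicates each, 2000 bootstrap
resamples), 500 null cohorts of 50 for the type-I error check, and
50,000-item streams wherever the stream-based estimators are compared to
their analytic counterparts. The analysis drivers run the full study
sizes (250/249/228 participants, 5000 resamples, 1000 within-groups).

## Known limitations

- The exact Figure-level graph layout cannot be checked against the
  original stimuli; the pinned construction satisfies every stated
  structural constraint, and sparse removals are random matchings rather
  than the original drawn instances.
- The hippocampal (CA1) network model and audio rendering are out of
  scope; the Hebbian learner is the only neural-style model implemented.
- The β at which the FEMM best matches inverse hitting times is reported
  as the argmax of a nearly flat curve; treat it as "somewhere on the
  plateau", not as a sharply estimated parameter.
- Real-data fits (the published 81% model correlation and 84% ceiling)
  require the archived behavioral dataset, which the pipeline can ingest
  as CSV but which is not bundled; all quantitative tests run on the
  synthetic cohorts.
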