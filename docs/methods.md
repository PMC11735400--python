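# Methods

This note documents the conventions, models, default parameters and design
choices behind `socivis`, and what the synthetic-data tests do and do not
establish about real data.

## Connectivity tables and relative connection strengths

The substrate is a directed, ROI-resolved synapse-count edge list between
reconstructed neurons, with a neuron index carrying cell type, hemisphere
and neurotransmitter labels (the layout of neuPrint-style adjacency
exports: `bodyId_pre, bodyId_post, roi, weight` plus
`bodyId, type, hemisphere, nt`). Validation enforces positive integer
weights, referentially intact endpoints, and (by default) no self-edges.

**Denominator convention.** All relative connection strengths ("fraction of
X's input coming from Y") are computed over synapses from *typed* partners
only. Untyped bodies are mostly unidentified fragments of neurons that are
already counted under their type, so including them deflates every
fraction; they are retained in the table (flagged with an `UNTYPED`
sentinel) and an `include_untyped` flag exposes the alternative
denominator for comparison. A property test asserts that adding untyped
edges never changes any fraction.

**Type-level aggregation.** Fractions are computed type-to-type, summing
over member neurons, because the quantities of interest (selectivities,
input percentages) are reported at the type level. Hemispheres are pooled
by default.

**Signs.** Neurotransmitter → sign: ACh → +1, GABA → −1, Glu → −1
(GluCl-mediated inhibition in the fly), anything else → 0 (unresolved).
A cell type's sign comes from its members' labels; if labeled members
disagree, the majority label wins when ≥80% agree, otherwise the sign is 0
with a warning — types are treated as transmitter-homogeneous.

**Compartments.** "Dendritic inputs" are approximated by ROI filtering
(e.g. restricting a channel's input synapses to the lobula); the schema
carries no explicit compartment labels, so a compartment filter falls back
to ROI names with a warning.

## Motif definitions

All thresholds are parameters; the defaults encode the published screening
criteria, and "over"/"more than" are implemented as strict inequalities
(configurable via `strict=`).

* **Convergence**: a type with > 100 synapses from the state type *and*
  > 100 summed synapses from the sensory group; a second filter keeps
  targets with > 25% of their typed input from the sensory group and
  separately flags > 2% from the state type. The group input is decomposed
  into per-member pie fractions.
* **Disinhibition chain**: a path state → i₁ → i₂ → sensory with signs
  (+, −, −) (net positive: state activity releases the sensory type from
  inhibition), where each link carries at least a configured fraction of
  the *receiver's* typed input — defaults (0.02, 0.05, 0.01), chosen from
  the published link strengths (state→centrifugal 4.3%, centrifugal→lobula
  interneuron 5.7%, interneuron→channel dendrites 1–6%). An optional ROI
  constraint restricts the final link (numerator and denominator) to e.g.
  the dendritic neuropil. Repeated nodes are excluded; results are
  deduplicated by (i₁, i₂, sensory).
* **Toggle switch**: gates are inhibitory types projecting onto the channel
  group; a gate's *selectivity* is its largest within-group output share
  (denominator: synapses onto the whole group, per the way the published
  98% figure is stated). A switch requires both gates' selectivity ≥ 0.9
  for opposite channels, crossed excitatory feedback channel→gate above a
  synapse floor, a direct excitatory state→gate₁ edge, and a disynaptic
  state→X→gate₂ path through an inhibitory intermediate. The selectivity
  default of 0.9 is looser than the observed 0.98 so the planted motif
  survives sampling noise, yet tight enough that random graphs (tested
  against exhaustive enumeration) essentially never qualify. The channel
  pair is discovered, not supplied: all ordered gate pairs over the group
  are searched. Mirror duplicates are collapsed by an unordered pairing
  key. Only single-intermediate drive paths are implemented
  (`max_intermediates=1`).

Results sort deterministically (synapse count descending, then name), so
serialized outputs are byte-stable. Every detector is checked against an
independent brute-force enumeration oracle on random graphs (≤25 types,
≤400 edges, 50 seeds) and is invariant to edge order and body-id
relabeling; raising any threshold never enlarges a result set.

## Egocentric visual geometry

Per frame, the subject's pose is an oriented ellipse (semi-axes a ≥ b,
heading); the nose point is centroid + a·(cos h, sin h) — the anterior-most
point, which the tracker does not export directly. World coordinates are
translated/rotated so the subject's centroid sits at the origin facing 0°.

* θ = atan2(y′, x′) in (−180°, 180°] (the full-quadrant arctangent; the
  single-argument form loses the quadrant).
* φ = dθ/dt via central differences on the *unwrapped* angle (one-sided at
  the ends, 170 fps default). NaN frames propagate NaN — including at the
  NaN frame itself — and never fabricate values; unwrapping is restarted
  after each gap so one bad frame cannot corrupt the rest of the series.
* d is the subject-nose-to-target-centroid distance; the same convention is
  reused by the nearest-conspecific query for consistency.
* R is half the chord of the target ellipse through its centroid
  perpendicular to the sight line: R = ab / √(b²cos²α + a²sin²α) with α
  the chord direction in the ellipse frame; b ≤ R ≤ a always.
* w = 2·arctan(R/d), h = 2·arctan((H/2)/d) with real height H = 1 mm
  (configurable).
* The occluded angle is the angle between the two tangents from the nose
  point to the target ellipse, computed from the pair-of-tangents conic
  (SS₁ = T²): angle = atan2(2√(H²−AB), A+B) on the quadratic part. For a
  circle this reduces to 2·arcsin(r/d), which the tests verify to 1e-6°;
  for general ellipses a dense boundary-sampling oracle provides the
  reference. A nose point inside the ellipse yields NaN (or 360° via
  config).
* Body length = 2a of the subject ellipse (used by the
  flies-within-k-body-lengths count); ties in the nearest-fly query break
  to the lower fly id.
* The "fixation angle" used by the courtship rule is |θ| of the target in
  the subject's frame — an assumption, since the rule's source does not
  define it.

All features are invariant under global rigid motion of the arena
(property-tested); w, h and the occluded angle decrease strictly with
distance. Both signed and absolute φ are available to summaries.

## Behavior metrics

* **Percentage aggression** is arena-level: per frame, the sum of
  aggression scores over trajectories currently performing aggression,
  divided by the number of flies in the arena, × 100. "Performing
  aggression" is read per-frame (a trajectory contributes on frames where
  its label is on). Scores may be continuous classifier outputs or binary;
  the default binarizes at 0.5, and a continuous mode sums raw scores.
* **Stimulus protocol**: 30 s acclimation, then six 30 s stimulus blocks
  with 30 s gaps, at 170 fps; windows are half-open frame intervals that
  tile the session exactly at any frame rate.
* **Pre/during pairs**: "during" averages the first three stimulus-on
  windows; "pre" averages the equally long windows immediately preceding
  each analyzed block (`three_periods`), or only the first 15 s of the
  first pre-stimulus window (`first_15s`, for sessions where earlier
  stimuli contaminate later off periods). The paired values feed a
  standard Wilcoxon signed-rank test across arenas; the test itself is
  delegated to standard statistics routines, not re-implemented.
* **Time courses** are shown as means of non-overlapping 60-frame (0.35 s)
  bins; a trailing partial bin averages the frames it has, and exact
  multiples preserve the series mean.
* **Courtship epochs**: the first run with inter-fly distance < 3 mm and
  |fixation angle| < 20° lasting strictly longer than 1 min opens the
  epoch; it ends at a provided copulation frame or the end of the
  recording. Run duration is counted as n_frames/fps.
* **ΔF/F**: F₀ is the mean fluorescence over the 10 s before stimulation
  onset (after optional background-ROI subtraction); ΔF/F = (F − F₀)/F₀.
  Non-positive baselines and insufficient pre-onset data are errors, never
  silent division.

## Toggle rate model

The circuit diagram gives no dynamical equations, so the model is the
minimal rectified-linear structure consistent with the predicted outcomes,
and its acceptance is *qualitative directionality only* — never
quantitative rates.

Nodes: state S, gates I₁/I₂, inhibitory intermediate X, channels C₁/C₂.
Dynamics: τᵢ drᵢ/dt = −rᵢ + [Σⱼ Wᵢⱼ oⱼ + driveᵢ(t)]₊ with rates clamped
non-negative. Because the gates' synapses sit interspersed among the
channels' axonal output synapses, gate inhibition is *divisive on the
channel's output*, oⱼ = rⱼ / (1 + Σₖ Γₖⱼ rₖ), rather than subtractive on
its input; non-channel nodes transmit oⱼ = rⱼ. Channel "transmission" is
this gated output, and the transmission gain is measured by a small
perturbation of that channel's visual drive at steady state.

Wiring: S excites I₁ and X; X inhibits I₂; each channel feeds back
excitation onto the gate that protects it (C₁→I₁, C₂→I₂); I₁ gates C₂ and
I₂ gates C₁ (with the residual 1−selectivity share gating the other
channel). I₂ carries a tonic drive — the disynaptic branch can only
*release* it, so it needs a source of baseline activity to be the dominant
gate when the state is silent. Weight magnitudes are proportional to the
motif's synapse counts normalized by the largest count (scale-free:
doubling all counts changes nothing); signs come from the sign map.

Defaults (`DEFAULT_PARAMS`): τ = 10 ms, state→gate weight 1.5, X→I₂ weight
2.0, feedback 0.8, gating strength γ = 2.0, I₂ tonic 0.6; forward Euler at
dt = 0.5 ms (dt must be < τ/10; halving dt moves steady-state gains by
< 1e-3). A shipped parameter grid (`default_parameter_grid`, 24 points
over drive, gating, feedback and tonic values) is the region over which
the tests assert all four directional outcomes and both gate-2
perturbation directions.

Crossed feedback deepens the winner-take-all separation in the *state-on*
regime, where the tests assert it. At state-off the effect can reverse:
with divisive gating the winning channel is already nearly ungated, so the
partially transmitting loser's feedback onto its gate mainly suppresses
the winner. This is a genuine property of the output-gain formulation, not
a bug; the model also exposes the feedback weights (`remove_feedback`) so
the gain-control alternative reading of the same anatomy can be explored.

The disinhibition chain is built as the same rate equations without
gating: S excites i₁, i₁ inhibits i₂ (tonically driven), i₂ subtractively
inhibits the sensory node's input — dendritic, not axo-axonic. In the
sub-threshold linear regime its steady state matches the closed-form
solve (I − W)⁻¹·drive, which the tests use as an oracle.

## Synthetic data

The generators define the study conditions; their defaults are the
conditions the analyses assume.

**Planted connectome.** Background: a per-type-pair Bernoulli random graph
(15 types, p = 0.08) with log-normal synapse weights (connectome weight
distributions are heavy-tailed); these background parameters are
documented choices, not measured values. The planted circuit fixes every
denominator: each planted node's typed input total is filled to target by
dedicated excitatory feeder types, so the planted fractions are *exact* —
state→centrifugal 4.3% of 7000, centrifugal→interneuron 5.7% of 7000,
interneuron→channel dendritic fractions 3.5/1.1/5.1/5.9% of 20000 (the
male optic-lobe values), gate selectivity 0.98 over 1000 group synapses,
convergence targets with 150 state + 900 group synapses on a 3000-synapse
denominator. Pie splits use largest-remainder rounding. Background edges
run only among background types, so they can neither perturb a planted
fraction nor fabricate a motif (motifs all require a link from the state
type, which only contacts planted nodes); this is what makes
precision = recall = 1 a designed property rather than a statistical
accident, and the recovery tests verify the construction, not detector
robustness to adversarial backgrounds. Ground truth is derived by direct
arithmetic over the planted count table, independent of the detector code;
it honestly includes every structure meeting the definitions — e.g. gate 1
qualifies as a convergence target (state + channel feedback input), and
the state→intermediate→gate₂→channel₁ path *is* a disinhibition chain.
Untyped bodies with input synapses onto planted nodes are added to
exercise the denominator rule.

**Trajectories.** Kinematic scripts, not behavioral models: flies perform
a smooth heading-diffusion walk at 8 mm/s inside the 53.3 mm arena
(170 fps), turned toward the center at the wall. A scripted epoch places
the subject facing the target with its nose at d = a_target/tan(w/2), the
target broadside, so the programmed angular width (default 30°, inside the
32.1 ± 13.0° range measured during aggression) is recovered exactly by the
full geometry pipeline — the generator uses the inverse closed form, the
analyzer the forward construction. Epoch boundaries teleport the scripted
pair; speed bounds hold during free locomotion. The ethogram labels both
epoch flies as aggressing, giving a known arena percentage (2/6 flies ⇒
33.3%). None of this emulates real locomotor statistics, occlusions,
tracker identity swaps or classifier noise — passing tests show the
geometry and metrics are computed correctly, not that the classifiers'
inputs are realistic.

**Fictive-target stimulus.** θ(t) is a triangle wave spanning 107°
peak-to-peak at a constant 75° s⁻¹ (sampled, so the realized span is
within one sample step of 107°); the angular size is a Gaussian-copula
AR(1) process (timescale 0.5 s) with a Beta(8m, 8(1−m)) marginal scaled to
8–50°, constant-shifted to pin the sample mean at 22.5° (re-clipped, so
bounds stay strict). The real stimulus replayed measured courtship
distances; the synthetic one only matches its printed envelope (range,
mean, arc, speed).

**Fluorescence.** Baseline 1.0, multiplicative step of the requested ΔF/F
amplitude at onset, additive white noise. Monte-Carlo tests recover the
step within 3 s.e. over 50 seeds.

All generators are bit-reproducible given (config, seed); two seeds give
different realizations but identical planted ground truth.

## Problem sizes and numerical choices

Oracle comparisons run on graphs of ≤25 types / ≤400 edges over 50 seeds,
planted-recovery on 20 seeds, trajectory sessions default to 20 s × 6
flies, and simulations to T = 1 s at dt = 0.5 ms — sizes chosen so the
whole suite completes in well under a minute per module while every
comparison remains exhaustive. Fraction sums are checked to 1e-9; the
tangent-angle closed form agrees to better than 1e-9° in practice (1e-6°
asserted); equality of detector output with oracles is exact (set
equality), not approximate.

## Known limitations

* Pinned-release connectome percentages (hemibrain v1.2.1, male optic-lobe
  v1.0, FlyWire v783) require downloading those datasets; the loaders
  accept their export schema, but no network access is assumed anywhere.
* Neurotransmitter labels are inputs; no prediction is attempted.
* The toggle model is qualitative; it does not fit electrophysiology and
  does not model the persistence of the aggressive state.
* Degree-preserving null graphs for motif-enrichment statistics are out of
  scope (the synthetic background is not such a null).
* Geometry is 2-D; height is a fixed 1 mm constant, and the "anterior-most
  point" is approximated by the ellipse vertex along the heading.
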