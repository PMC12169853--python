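# Methods

This note documents the models and procedures implemented in danpipe,
the parameters that matter, the design choices made where the
literature leaves the procedure open, and what the synthetic-data
generators do and do not emulate.

## Connectome stage

**Graph model.** The connectome is a weighted directed graph: nodes are
neurons annotated with a class (sensory, interneuron, KC, MBON, DAN,
other), a DAN cluster (DL1/pPAM) for DANs, a sensory modality for
sensory neurons, and optionally a hemisphere and a bilateral pair id;
edges carry integer synapse counts. At load time duplicate
(pre, post) rows are summed into one edge and self-edges are dropped
with a warning — all downstream quantities are defined per ordered
neuron pair. Edge endpoints missing from the annotation table are
created with class `other` (warned) rather than rejected, since
real reconstructions routinely contain partially annotated fragments.

**Thresholded single-hop pathways.** An interneuron qualifies as a
sensory-to-DAN interneuron for DAN *d* when its edge onto *d* carries at
least `theta_dan` synapses (default 3) and at least one sensory neuron
synapses onto it with at least `theta_sensory` synapses (default 1).
The analysis is deliberately restricted to these length-two paths; no
two- or three-hop expansion is performed.

**Fractions and hub score.** All "total input" denominators are
computed on the *unthresholded* graph; the thresholds gate only which
pathways and partners qualify. The hub score of a connection is the
interneuron's sensory input fraction times the DAN's input fraction
from that interneuron; both factors lie in [0, 1], so the score does
too, and connections with score ≥ `hub_cutoff` (default 0.001) are
highlighted. For consistency with the pathway criterion, only sensory
edges with ≥ `theta_sensory` synapses enter the sensory-fraction
numerator (a no-op at the default threshold of 1).

Two points the published description leaves open are exposed as
configuration rather than fixed: whether input-decomposition
percentages are taken relative to the full or the thresholded input
(`thresholded_denominator`, default off), and whether the analysis runs
per neuron or per merged bilateral pair (`pair_mode`, default
per-neuron; pair aggregation sums parallel edge counts and drops
intra-pair edges, which would otherwise become self-edges).

**Determinism.** The hub table is sorted by DAN id, then descending
score, with ties broken by interneuron id, so repeated runs produce
identical output. Percentage/normalization identities are asserted at
1e-9 relative tolerance; hub scores are compared to the brute-force
oracle at 1e-12 absolute.

## Behavioral stage

Scores are plain count ratios; `#Total` includes neutral-zone and lid
larvae, so |PREF| < 1 whenever any larva sits in the neutral zone.
One performance index corresponds to one reciprocal pair of plates;
replicate *i* of the Odor2+-trained group is paired with replicate *i*
of the reciprocally trained group in acquisition order (the pairing
rule is not stated in the assay description; acquisition order is the
only ordering the data carry).

The comparison workflow takes the nonparametric branch when *any*
group fails Shapiro–Wilk at α = 0.05 (the mixed-outcome case is not
specified in the source protocol; requiring all groups to pass is the
conservative reading). Constant samples, for which Shapiro–Wilk is
undefined, are treated as non-normal. Dunn's multiple-comparisons test
is computed from pooled mean ranks with the standard tie correction,

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)),

and both unadjusted and Bonferroni-adjusted p-values are reported,
since the adjustment used for the published figures is not stated.
Significance is reported as a two-level convention only (n.s. / *).
Degenerate inputs are handled explicitly: identical groups report
p = 1, all-zero samples under Wilcoxon report p = 1 with a warning, and
a constant nonzero sample under the one-sample t-test raises an error
rather than emitting an undefined statistic.

## Imaging stage

ΔF/F uses the arithmetic mean raw fluorescence over the 10 s before
stimulus onset as F0 (the simplest reading of a "baseline response";
no median or percentile baseline, no smoothing, no bleach correction).
The per-larva summary is the mean ΔF/F over a 5-s window around the
peak of |ΔF/F| within the stimulus window; using the absolute trace
lets one operator quantify both activations and stimulus-evoked
reductions, with the response direction reported as the sign at the
peak. Chance level is ΔF/F = 0, tested per group with a one-sample
t-test (n ≥ 3 enforced; the emulated experiments use 5–7 larvae).

Window placement: the 5-s window is kept inside the stimulus
presentation — when the stimulus lasts at least 5 s the window is
shifted, not truncated, to fit. A centered-and-clipped window was
considered and rejected: whenever noise places the peak near a stimulus
edge, a centered window mixes washout or baseline samples into the
average and systematically underestimates plateau responses. For
stimuli shorter than the window the code falls back to a centered,
trace-clipped window with a logged warning. Exact ties in |ΔF/F|
(noise-free plateaus) resolve to the middle tied sample, centering the
window on the plateau. Window means are plain sample means on uniform
grids and time-weighted (trapezoidal) means under irregular sampling.

## Synthetic-data generators

All generators are deterministic given their seed and write the same
table dialects the analysis stages read.

**Connectome.** Node classes and sizes loosely follow the first-instar
larval brain: sensory neurons spread over gustatory compartments, ORNs
and thermo-/mechanosensors, 35 interneurons, 110 Kenyon cells, 24
MBONs and eight DANs in two clusters of four. Background edges are
drawn per connection family (sensory→interneuron,
interneuron→interneuron, interneuron→DAN, KC→DAN, MBON→DAN) with
family-specific probabilities, and synapse counts follow
1 + Geometric(p) — heavy-tailed, mostly weak edges. The family defaults
reproduce the real circuit's composition in the ways that matter for
hub scoring: DANs draw the bulk of their input from many weak KC
edges, interneurons draw mostly on other interneurons, and direct
sensory edges onto any given interneuron are sparse and weak, keeping
unplanted hub scores well below the 0.001 highlight cutoff (unplanted
99th percentile ≈ 5·10⁻⁴ across generator seeds, against planted
scores of order 10⁻²). Planted motifs write a configurable signal
count (default well above both thresholds) on a chosen
sensory-set → interneuron → DAN path; the truth record lists the
planted interneurons and their expected hub scores computed by direct
row arithmetic on the emitted table, independent of the graph code.
Not emulated: spatial structure, neurotransmitter identity, and the
long-tailed degree heterogeneity of real reconstructions — so passing
recovery tests demonstrates correctness of the scoring arithmetic and
threshold logic, not robustness to every real-data pathology.

**Behavior.** Each of 30 larvae per plate independently lands on
side 1, side 2 or the neutral zone (single three-outcome draw; no
larva–larva interaction). For a group with true preference θ and
neutral probability q (default 0.1), side probabilities are chosen so
the expected PREF of each reciprocal role — and hence the expected
PI — equals θ exactly; configurations with |θ| > 1 − q are rejected.
Defaults follow the emulated assay: 30 larvae per plate, 15 reciprocal
replicates per group.

**Traces.** Raw fluorescence is F(t) = F0·(1 + A·k(t)) + ε with
additive Gaussian noise on the raw signal (ε ~ N(0, 2) raw units
against F0 = 100 by default) and a kernel k that is exactly 1 inside
the stimulus window and decays exponentially after offset
(τ = 1.5 s). The default kernel is rectangular (rise time 0) so that
the planted amplitude A *is* the quantity the peak-window estimator
measures; a finite linear rise is available via `rise_s` for studying
onset transients. Stimulus duration defaults to 10 s within the
emulated protocol's 5–10 s range, with 15 s of pre-stimulus recording
and 15 s washout at 30 Hz. Not emulated: indicator kinetics
(rise/decay asymmetries of GCaMP6m), photobleaching, motion artifacts.

## Problem sizes

The validation suite runs the hub oracle comparison on 100 random
~36-node connectomes, planted-hub recovery on 20 full-size synthetic
connectomes, performance-index recovery on 200 simulated experiments of
15 reciprocal pairs, bound/antisymmetry checks on 10⁵ random count
tables, and amplitude recovery on groups of 6 simulated larvae — sizes
chosen to give stable statistics (standard errors an order of magnitude
below the tested effects) while keeping a full run in seconds.

## Known limitations

* The connectome stage treats annotations as ground truth; mislabeled
  neuron classes propagate directly into fractions and hub scores.
* Reciprocal pairing by acquisition order is an assumption; if plates
  were randomized between groups, per-pair PIs (though not their mean)
  differ.
* The Shapiro–Wilk gate at small n has low power; the workflow
  reproduces the emulated decision rule rather than recommending it.
* Peak-window quantification without smoothing localizes the extremum
  on the raw trace; for very noisy recordings a pre-smoothed peak may
  be preferable, and is deliberately not applied by default.
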