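# Methods

## Data model and conventions

A session is a set of simultaneously recorded units, each a sorted list of
spike times in seconds on `[0, duration]` with an area label; one area is
designated focal (default `"ZI"`).  Time bins are half-open,
`[iΔ, (i+1)Δ)`, anchored at t = 0; a spike exactly at `duration` is clipped
into the final bin so that binning always conserves the total spike count.
Duplicate timestamps within a unit are kept; the detector binarizes bins, so
multi-spike bins count once.  Units enter the analysis only with strictly
more than 100 spikes over the whole session (`filter_min_spikes`); the
filter is applied to the entire recording rather than per epoch.

## Pairwise coincidence test

At resolution Δ with maximal lag L, the lagged coincidence count between
binarized trains is

    c(ℓ) = Σ_t min(x_A(t), x_B(t+ℓ)),   ℓ ∈ [−L, +L].

The tested lag ℓ* maximizes c; ties go to the smallest |ℓ|, negative before
positive, so synchrony is preferred over spurious asymmetry when counts are
equal.  The null model must tolerate slow rate changes, which otherwise
masquerade as coordination: the T bins are split into `n_chunks = 5`
contiguous blocks, the expectation is μ = Σ_k T_k·p̂_{A,k}·p̂_{B,k} with
per-block empirical occupancies, and the null count is modeled as
Poisson(μ).  For binary bins the exact null is Binomial(T, p_A p_B)-like;
the Poisson tail is slightly heavier, making the test mildly conservative,
which we prefer for a discovery procedure.  The upper-tail p is multiplied
by the number of tested lags (2L+1) and capped at 1.  An all-zero train
yields p = 1.  The same μ is used at every lag (the overlap shrinks by at
most L bins out of tens of thousands; the bias is negligible and
conservative).

## Multiple-comparison control and the resolution grid

The default grid is Δ ∈ {10, 15, 20, 25, 30, 40, 50, 60, 80, 100} ms with
maximal lags {19, 12, 9, 7, 6, 4, 3, 2, 2, 1} bins, i.e. a characteristic
precision below 100 ms and at most 190 ms between consecutive activations.
All pair tests — every unordered unit pair at every resolution — form a
single Holm step-down family at α = 0.05 (`holm_scope="grid"`).  We chose
the grid-wide family, rather than one family per resolution, because the
quantity users act on is "did this *run* discover an assembly", and only the
grid-wide family bounds that probability by α; per-resolution control is
available via configuration.  Bonferroni over lags sits inside each
p-value, so the ordering of candidate pairs is unaffected.

An assembly found at several resolutions (same unit set) collapses to the
minimal-p one; that resolution is reported as its optimal temporal
precision.

## Agglomeration to triplets

Each significant pair becomes a pseudo-unit: the element-wise AND of the two
binarized trains after aligning the follower by ℓ*, expressed in the
leader's time frame.  This activation vector is tested against every unit
outside the pair with the same pairwise test; extension p-values form their
own Holm family within the resolution.  A significant extension yields a
triplet whose lags compose the pair's lag with the new unit's lag (relative
to the pair's leader, possibly negative, re-canonicalized so the earliest
unit has lag 0 and lags are non-decreasing; ties order lexicographically).
Agglomeration stops at order 3: loop-like motifs are defined on triplets,
and the combinatorial cost of higher orders buys nothing for this analysis.

## Motif taxonomy

Pairs: synchronous iff both lags are exactly 0 (lags are integers, so no
tolerance is involved); otherwise directional, "from" or "to" the focal
area by the area of the leading unit; internal pairs (both units in one
area) keep the same synchronous/directional distinction.  Triplets spanning
exactly two areas are loop-like iff the activation is strictly sequential
(three distinct lags) and the first and last units are distinct neurons of
one area with the middle unit in the other; `triplet_loop_focal` when the
chain starts and ends in the focal area, `triplet_loop_external` when the
focal unit is the middle one.  Everything else — synchronous
sub-activations, chains like X→X→ZI, triplets within one area or spanning
three — is `triplet_non_loop`.  Detection is normally run on the focal
area plus one partner area at a time, so three-area triplets cannot arise
in that workflow; the classifier still handles them defensively.

For each triplet we also record whether its two chain-adjacent pairs were
independently significant at the pairwise level (`pairwise_supported`);
with finite statistical power a genuine triplet's constituent pairs can
fall just short of pairwise significance, so this flag is an audit, not a
filter.

## Normalized probabilities and asymmetry tests

Counts are comparable across areas only after normalizing by the number of
possible configurations on the recorded unit sets:

- external pairs: `N / (|A|·|B|)`
- internal pairs: `N / C(|A|, 2)`
- loop-like triplets (either structure): `2N / (|A||B|(|A|−1) + |B||A|(|B|−1))`
- fixed-structure loops A→B→A: `2N / (|A||B|(|A|−1))`

The factor 2 appears because each unordered loop-like unit-triple supports
two chain orientations of its class, while detected assemblies are counted
once.  These denominators are verified in the tests against exhaustive
enumeration of labeled unit configurations for all |A|, |B| ≤ 6.

The Int-Ext index is P_ext/(P_ext+P_int) ∈ [0, 1]; it is left undefined
(an error, not 0) when both probabilities vanish.

Directional asymmetry (from- vs to-focal counts) uses an exact two-sided
binomial test at p₀ = 0.5.  Loop-structure asymmetry uses
p₀ = P(A→B→A) = (|A|−1)/(|A|+|B|−2), the ratio of possible chain counts,
which the tests also verify by enumeration.  Two-sided p-values use the
minimum-likelihood rule (sum of probabilities of all outcomes no more
likely than the observed one); a doubled-one-tail option is available.
Exact rather than normal-approximate computation matters because many area
pairs have few assemblies.  Tests run only with at least 10 assemblies of
the relevant kind (`tested=False` below), and no correction is applied
across the per-area tests — each area pair is reported on its own, which
users combining many areas should keep in mind.

Multi-session pooling sums numerators and denominators separately before
dividing (never a mean of per-session ratios), using post-filter unit
counts per session in the denominators.

## Circular-shift control

Surrogates rotate each unit's spike train by an independent
Uniform(0, duration) offset modulo the duration — continuous uniform
because it maximally decorrelates units while preserving each unit's rate
and all inter-spike intervals except the one crossing the wrap point.  The
control runs the full detector on (by default) 10 surrogates and reports
per-repetition normalized pair probabilities (detected pairs over
C(n_units, 2)), their mean and max, and the largest assembly count in any
single run.

## Synthetic data: what it emulates and what it does not

`gen_background` draws independent Poisson trains with per-unit rates
log-uniform in [0.5, 10] Hz (typical of cortical/subcortical single units
at this scale), optionally modulated by a shared 5-block rate profile
(factors uniform in [0.5, 1.5], mean-normalized) or a shared 0.1 Hz
sinusoid — the common slow non-stationarities that stress the chunked null.
`plant_assembly` superimposes coordinated events: each of `n_activations`
events recruits each member unit independently with probability 0.9
(default) and places its spike at the event time plus lag·Δ plus a uniform
jitter of half a bin, so planted lags survive bin misalignment in
expectation.  Registered scenarios (`null_independent`, `nonstationary`,
`pairs_easy`, `loops_mixed`) fix sizes and plants; the same (name, seed)
reproduces a byte-identical session.

What passing on these benchmarks does **not** show: real recordings have
refractoriness, burstiness, oscillatory phase-locking and common-input
correlations that independent Poisson background lacks; planted
participation (0.9) and event counts (300–400 over 20 min) are favorable;
and assemblies arising from shared oscillations are indistinguishable from
direct coordination by this method.  Recovery here validates the machinery,
not detectability in any particular dataset.

## Problem sizes used in the validation suite

Calibration uses 200 seeded homogeneous null sessions and 100
block-modulated ones (20 units, 1000 s each); recovery uses 3 seeds of each
planted scenario; the shuffle control uses 10 surrogates of one planted
session.  At these sizes the full suite runs in well under five minutes on
a single core, which is what we consider a reasonable desk-scale validation
loop.

## Known limitations

- Assemblies of order > 3 are out of scope by design.
- The parametric chunked-Poisson null is approximate; exactness claims are
  limited to what the calibration tests demonstrate (per-run discovery
  probability at or below nominal on the simulated nulls).
- The detector cannot represent inhibitory coordination; purely inhibitory
  relationships are missed or appear via rebound excitation.
- Area-level conclusions inherit whatever sampling bias the recorded unit
  sets carry; normalization corrects for counts, not for selection.
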