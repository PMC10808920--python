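# assemblymotifs

Cross-regional **cell-assembly** and **loop-like motif** analysis for
parallel spike trains.

Simultaneous multi-area extracellular recordings (e.g. Neuropixels sessions
spanning a focal subcortical region such as the zona incerta, ZI, plus many
cortical and subcortical areas) allow functional coordination between brain
regions to be read out as *cell assemblies*: groups of two or three units
whose synchronous or lagged co-activations recur far above chance.  This
package implements that analysis end to end for people who want to quantify
how a focal area couples to the rest of a recorded network:

- **Detection.**  A CAD-style agglomerative detector scans every unit pair
  over a grid of temporal resolutions Δ ∈ {10, …, 100} ms with matched
  maximal lags (bin × lag ≤ 200 ms), counts lagged coincidences
  c(ℓ) = Σ_t min(x_A(t), x_B(t+ℓ)) on binarized binned trains, tests the
  best lag against a chunked-Poisson independence null (robust to slow rate
  non-stationarities), Bonferroni-corrects over lags and Holm-corrects over
  the whole family of tests, then extends significant pairs to triplets by
  treating the aligned pair activation as a pseudo-unit.  Each assembly is
  reported at its optimal resolution (minimal p across the grid).
- **Motif taxonomy.**  Pairs are synchronous (all lags 0) or directional
  ("from" / "to" the focal area, by the sign of the lag); triplets spanning
  two areas are **loop-like** when they form a strictly sequential
  A→B→A chain (distinct first and last units in one area, middle unit in
  the other) — the candidate signature of reentrant signaling — and
  non-loop-like otherwise.
- **Statistics.**  Counts are normalized by the number of *possible*
  configurations: P_pairs^ext = N/(|A||B|), P_pairs^int = N/C(|A|,2),
  P_loop = 2N/(|A||B|(|A|−1) + |B||A|(|B|−1)), and
  P_loop^{A→B→A} = 2N/(|A||B|(|A|−1)).  The **Int-Ext index**
  P_ext/(P_ext+P_int) ∈ [0,1] is 0.5 exactly when internal and external
  pairing are equally likely.  Directional asymmetry uses an exact binomial
  test at p₀ = 0.5; loop-structure asymmetry uses the combinatorial null
  P(A→B→A) = (|A|−1)/(|A|+|B|−2).  Multi-session pooling sums numerators
  and denominators separately.
- **Controls.**  Circular-shift surrogates (independent random rotation of
  each train modulo the session duration) quantify chance-level discovery,
  and a synthetic-data module generates sessions with *planted* pairs and
  loops on heterogeneous Poisson background for ground-truth validation.

## Worked example

```sh
python examples/01_simulate_and_detect.py
```

builds a 1200 s session of 6 ZI + 6 MS units with one planted ZI→MS→ZI
loop (delays 0/30/60 ms), one MS→ZI→MS loop (0/40/80 ms) and one pair, and
prints:

```
detected 9 assemblies (order 2 and 3):
  order 2: ms_01 -> zi_02  bin 20 ms, delays ['0 ms', '40 ms'], p = 3.70e-180
  ...
  order 3: ms_01 -> zi_02 -> ms_02  bin 20 ms, delays ['0 ms', '40 ms', '80 ms'], p = 2.21e-231
  order 3: zi_00 -> ms_00 -> zi_01  bin 15 ms, delays ['0 ms', '30 ms', '60 ms'], p = 1.10e-130
```

Both planted triplets are recovered with their exact activation order and
delays; the extra order-2 entries are the genuinely coordinated chain pairs
of the planted loops.  `examples/02_motifs_and_stats.py` classifies these
into `triplet_loop_focal` / `triplet_loop_external` and prints the
normalized probabilities (here P_ext = 0.139, Int-Ext index 0.676: this
synthetic ZI couples outward more readily than internally), and
`examples/03_shuffle_control.py` shows the circular-shift control
collapsing the detection probability from 0.067 to 0 over 10 surrogates.
`examples/04_export_graphs.py` writes GraphML/DOT area and neuron graphs
plus TSV/JSON summary tables.

Real data enter through a plain TSV (`unit_id  area  session_id  time_s`,
one spike per row) via `read_session`; units with ≤ 100 spikes are dropped
by `filter_min_spikes` before analysis.

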