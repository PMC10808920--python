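"""Circular-shift surrogate control: chance level of assembly discovery.

Each unit's spike train is rotated by an independent random offset modulo
the session duration, preserving rates and inter-spike-interval structure
while destroying cross-correlations.  Detection on the surrogates quantifies
how many "assemblies" arise by chance.
"""

from math import comb

from assemblymotifs import detect, make_scenario, run_shuffle_control

session, _ = make_scenario("pairs_easy", seed=3)
original_pairs = sum(1 for a in detect(session) if a.order == 2)
n_possible = comb(session.n_units, 2)
original_prob = original_pairs / n_possible
print(f"original data: {original_pairs} pair assemblies of {n_possible} possible "
      f"(probability {original_prob:.3f})")

report = run_shuffle_control(session, n_reps=10, seed=11)
print(f"10 circularly shuffled surrogates: mean probability {report.mean_prob:.2e}, "
      f"max {report.max_prob:.2e}, most assemblies in a single run: "
      f"{report.max_assemblies_per_run}")

# On planted data the surrogate probability collapses (typically to zero),
# confirming that the detected assemblies are not chance coincidences.
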