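"""Why are some ORFs missed?  Short-ORF bias in false negatives.

Engines miss short genes far more often than long ones.  The 2x2
chi-square test (missed vs found, <750 nt vs longer) quantifies the
enrichment on the reference annotation.
"""

import morfpath as mp

reference = mp.generate_reference(n_orfs=2000, seed=31)
profile = mp.EngineProfile(name="engineA", p_fn_short=0.08,
                           p_fn_long=0.01, p_wrong_start=0.15,
                           fp_rate=3.0)
pset = mp.simulate_engine(reference, profile, seed=31)

morfs = mp.assign_morfs([pset], reference)
labels = mp.classify(morfs, "engineA")
missed = [m.reference_member for m in morfs
          if m.reference_member is not None
          and labels[m.morf_id] == mp.CallLabel.FALSE_NEGATIVE]

stat, p, table = mp.length_bias_test(missed, list(reference),
                                     threshold_nt=750)
(short_missed, long_missed), (short_found, long_found) = table
print(f"missed: {short_missed}/{short_missed + short_found} short ORFs "
      f"(<750 nt), {long_missed}/{long_missed + long_found} long ORFs")
print(f"chi-square = {stat:.1f}, p = {p:.3g}")
print("\nA tiny p-value says misses concentrate among short ORFs — the "
      "same length bias\nreported for real annotation engines against "
      "curated bacterial genomes.")
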