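"""Train a general consensus path on several reference genomes.

Each genome is trained greedily — every round picks the engine
combination with the highest start-codon specificity on the mORFs still
uncalled — and the cross-genome path takes, per round, the combination
with the highest average impact (specificity x sensitivity / round).
Each round's projected confidence is its average training specificity.
"""

import morfpath as mp

profiles = mp.default_panel_profiles()
panel = [p.name for p in profiles]
corr = mp.CorrelationSpec(0.5)

genomes = {}
for i, seed in enumerate((101, 102, 103), start=1):
    reference = mp.generate_reference(n_orfs=1500, seed=seed)
    sets = mp.simulate_panel(reference, profiles, corr, seed=seed)
    genomes[f"genome_{i}"] = (sets, reference)

path = mp.train_path_workflow(genomes)

print("general consensus path (reliable -> speculative):")
for rank, (combo, conf, imp) in enumerate(
        zip(path.combinations, path.projected_confidence,
            path.average_impact), start=1):
    print(f"  round {rank}: {combo.key:<30s} "
          f"projected confidence {conf:.3f}  avg impact {imp:.3f}")

path.save("scratch_path.json")
print("\nsaved to scratch_path.json; a round's projected confidence "
      "estimates, a priori,\nthe probability that a start codon it calls "
      "on a NEW genome is correct.")
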