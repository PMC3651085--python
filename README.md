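# morfpath

Ensemble start-codon curation for prokaryotic genome annotations.

Automated genome annotation engines (BASys, ISGA, RAST, xBASE, ...) return
*ab initio* ORF predictions that frequently disagree — on curated bacterial
genomes, roughly 14–58% of a single engine's start codons are wrong.
`morfpath` is for annotators who have the outputs of several engines for
one genome and want to know **which start codons can be trusted and which
need manual curation**. It:

1. groups ORF predictions from all engines (plus an optional trusted
   reference annotation) into **meta-ORFs (mORFs)** — equivalence classes
   of calls of the same gene;
2. scores each engine's start-codon call per mORF against the reference;
3. combines engines by **majority voting** or **exact consensus**, and
   trains a **consensus path**: an ordered sequence of engine combinations,
   from most to least specific, each round calling the mORFs the previous
   rounds could not;
4. attaches a **projected confidence** — the combination's average training
   specificity — to every start codon called on a new, reference-free
   genome.

## The method

**mORF grouping.** Two ORFs belong to the same mORF iff they lie on the
same contig and strand and either their 5′ (start) or their 3′ (stop)
coordinates differ by strictly less than 10% of the length of the shorter
ORF. mORFs are the connected components of this pairwise relation.

**Scoring.** Within a reference-bearing mORF, an engine's call is *correct*
when its strand-aware 5′ coordinate equals the reference start exactly,
otherwise *incorrect*; a call in a reference-free mORF is a *false
positive* (FP); a missing call in a reference-bearing mORF is a *false
negative* (FN). With counts C, I, FP, FN over a genome of N reference ORFs:

```
error-rate  = (I + FP) / (C + I + FP)
specificity = 1 − error-rate = C / (C + I + FP)
sensitivity = (C + I) / N
```

(specificity here is the fraction of made predictions that are correct —
precision — not the epidemiological TN-based quantity.)

**Consensus path.** A combination S of engines calls a mORF only when every
engine in S is present and all agree exactly on the start. Training is
greedy: each round scores every not-yet-selected combination on the mORFs
still uncalled, selects the most specific one, removes its calls, and
repeats (default 5 rounds). Across training genomes the per-round winner is
the combination with the highest average **impact**
`specificity × sensitivity / round`, and its mean training specificity
becomes the round's projected confidence.

## Worked example

Train a path on three synthetic genomes and apply it to a fourth
(`examples/03_train_consensus_path.py` and
`examples/04_apply_path_new_genome.py`):

```
general consensus path (reliable -> speculative):
  round 1: engineA+engineB+engineC+engineD projected confidence 0.953  avg impact 0.223
  round 2: engineA+engineB+engineC        projected confidence 0.942  avg impact 0.141
  round 3: engineA+engineB                projected confidence 0.912  avg impact 0.124
  round 4: engineA+engineC                projected confidence 0.828  avg impact 0.075
  round 5: engineA+engineD                projected confidence 0.697  avg impact 0.024
```

Round 1 is the full panel: when all four engines agree exactly, ~95% of
those start codons are correct. Later rounds rescue coverage at falling
reliability. Applying the path to a new genome:

```
1768 mORFs; 1370 called by the path (77.5%)

 path_round  projected_confidence  n_morfs
          1              0.963121      679
          2              0.929511      329
          3              0.827098      171
          4              0.700433       69
          5              0.651730      122
```

A curator can accept rounds 1–2 nearly as-is and spend their time on the
~400 uncalled mORFs and the low-confidence late rounds. For the real
BASys/ISGA/RAST/xBASE panel, `morfpath.default_four_engine_path()` ships
the published round order and confidences as a preset.

The other examples cover per-engine evaluation (`01`), majority voting vs
consensus (`02`) and the short-ORF (<750 nt) false-negative bias (`05`).
Every example builds its inputs with the seeded synthetic generator in
`morfpath.simulate`, which emulates per-engine wrong-start rates,
length-biased false negatives, intergenic false positives and correlated
(panel-shared) errors.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch at the given seed — simulates a
four-engine panel over three 2000-gene training genomes, prints each
engine's score summary, trains the general consensus path, and applies it
to a held-out genome — then writes the results JSON to `--out`.

## Layout

- `src/morfpath/io.py` — GFF3/GenBank/TSV readers, report writer
- `src/morfpath/morf.py` — the 10% grouping rule and mORF assignment
- `src/morfpath/metrics.py` — call classification, formulas, length-bias test
- `src/morfpath/combine.py` — majority vote and exact consensus
- `src/morfpath/path.py` — greedy training, impact, general path, apply
- `src/morfpath/simulate.py` — synthetic reference + engine error models
- `src/morfpath/workflows.py` — end-to-end evaluate/vote/train/apply
- `docs/methods.md` — model assumptions, parameters, numerical choices
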