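# Methods

This note documents the model behind `morfpath`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical/design choices made where the published description of the
procedure leaves the design open.

## Meta-ORF grouping

All ORFs — one set per engine, plus the optional reference — are
partitioned into meta-ORFs (mORFs). Two ORFs are *pair-compatible* iff
they share contig and strand and

```
|Δ5′| < 0.10 · min(len_a, len_b)   or   |Δ3′| < 0.10 · min(len_a, len_b)
```

with strict inequality and the margin computed as a real number (no
rounding). The 5′/3′ coordinates are strand-aware: the 5′ end of a
minus-strand ORF is its rightmost base. mORFs are the connected components
(single-linkage transitive closure) of this relation; closure is the only
way to obtain a true partition from a pairwise rule, at the cost that a
chain of mutually-close ORFs can bridge two reference genes. Two
alternatives are exposed, both off by default:

- `anchor="reference"` attaches each prediction to its nearest-start
  compatible reference ORF instead of closing the graph, so two close
  reference genes always head separate mORFs;
- `containment=True` also groups an ORF nested entirely inside another
  even when both boundary differences exceed the margin (this mode uses
  exact pairwise comparison, O(n²) per contig/strand group).

The default closure uses union-find over candidate pairs found by a
sorted sweep: a compatible pair differs by less than 10% of *each*
member's length on at least one end, so a window of `0.1 · len` around
every ORF covers all edges; the exact rule is re-checked before union.

If one source contributes several ORFs to one mORF, the mORF is flagged
`multi_call` and the member whose start is closest to the reference start
is scored; the others are logged and kept.

## Classification and score formulas

Per mORF and engine: `correct` (reference present, starts exactly equal —
no tolerance), `incorrect` (reference present, starts differ),
`false_positive` (no reference member), `false_negative` (reference
present, engine absent), `absent` (neither; bookkeeping only). Stop-codon
agreement is tracked by the grouping but not scored: real engines almost
never miscall stops. After multi-call resolution the labels partition the
reference exactly: `C + I + FN = N` per engine.

```
error-rate  = (I + FP) / (C + I + FP)        specificity = 1 − error-rate
sensitivity = (C + I) / N
```

The inclusion of FP in the error-rate was chosen so that specificity is
exactly "the fraction of made predictions that are correct";
`fp_mode="exclude"` gives the alternative `I / (C + I)`. Metrics on zero
predictions (or zero reference ORFs) raise `UndefinedMetricError` rather
than return a sentinel.

The short-ORF bias test builds the 2×2 table (flagged vs not) × (length
< 750 nt vs ≥) over reference ORFs and applies Pearson's chi-square
*without* continuity correction (scipy `chi2_contingency`,
`correction=False`); a zero marginal raises `DegenerateTableError`.

## Combiners

- **Majority vote**: the start coordinate predicted by strictly more than
  half of the panel. Absent engines count in the denominator by default
  (the vote is over the panel, not over responders); a responder
  denominator is available. A 2–2 split on a four-engine panel is a
  no-call.
- **Exact consensus of a combination**: every member engine must be
  present in the mORF and all must agree exactly. Requiring presence is
  what makes larger combinations more specific and less sensitive;
  consensus calls are anti-monotone in the combination
  (S ⊆ S′ ⇒ calls(S′) ⊆ calls(S)).

## Consensus-path training

Per genome, greedily: round r scores every not-yet-selected combination
(singletons included) on the mORFs still uncalled, skips combinations
with zero calls (undefined specificity), and selects the highest
specificity; ties break by more new mORFs, then larger combination, then
lexicographically smallest name — deterministic. Called mORFs (including
false-positive ones) are removed. Stops at `max_rounds` (default 5; later
rounds add few ORFs at poor specificity), when no combination adds
`min_new` mORFs, or when combinations are exhausted.

Across genomes, round r's candidates are the genomes' own round-r
winners; each candidate's **impact** is averaged over all genomes, with
a genome where it made no round-r call contributing 0. The default impact
form is

```
impact(spec, sens, rank) = spec · sens / rank
```

The functional form is a configurable strategy (`IMPACT_FORMS`,
recorded in every saved path): the published description fixes only its
ingredients — it must increase strictly in specificity and sensitivity
and not increase in rank. With a single training genome the general path
reduces exactly to that genome's greedy path.

A round's **projected confidence** is the chosen combination's mean
round-r training specificity over the genomes where it was evaluable. It
is an average precision carried to new genomes a priori — not a
calibrated per-ORF probability: it assumes the new genome's engine error
structure resembles the training genomes'.

`apply_path` needs no reference: each mORF takes the first round whose
combination reaches consensus on it. A path referencing an engine absent
from the supplied predictions is a configuration error.

## Synthetic data

The generator emulates the error taxonomy observed when engine calls are
compared with curated genomes. `generate_reference` places `n_orfs`
non-overlapping ORFs on one replicon, lengths log-normal (median 900 nt,
log-sd 0.55 — a typical bacterial gene-length profile), clipped to
150–4500 nt, codon-multiple, random strand, ~85% coding density.
`EngineProfile` controls, per engine:

- `p_fn_short` / `p_fn_long` — miss probabilities below/above 750 nt
  (defaults 0.08 / 0.01), reproducing the strong short-ORF bias among
  false negatives;
- `p_wrong_start` (default 0.15) with in-frame `offset_choices`
  (default ±3, ±6, ±9, ±30 nt; positive = downstream) — alternative
  start-codon choices; infeasible offsets (longer than the ORF, or
  pushing the 5′ end off the genome) are skipped with a log entry;
- `fp_rate` false ORFs per 100 reference ORFs, placed intergenically and
  short (<750 nt) by default;
- `p_stop_error` (default 0) for the rare wrong stop.

`default_panel_profiles()` is a four-engine panel with wrong-start rates
15/22/35/55% — inside the 14–58% band reported for real engines.

**Correlated errors.** `CorrelationSpec.shared_error_fraction = f` makes
each engine, per reference ORF, adopt a panel-shared wrong-start draw
(decision and offset) with probability f, independently of the other
engines. Engines adopting the shared draw err identically — emulating the
shared components (ORF callers, heuristics) of real engines. A subset of
k engines therefore errs in lockstep with probability ~fᵏ·p: *pairs err
together more often than the full panel*, which is what produces the
observed decrease of specificity along the path rounds. At f = 1 all
engines agree on every emitted ORF; at f = 0 exact agreement on a wrong
start requires an independent coincidence of offsets. An earlier
all-or-nothing design (the whole panel shares or nobody does) was
rejected: it lets round 1 absorb every shared error, after which later
rounds look spuriously clean and the specificity-per-round trend inverts.

What the generator does **not** emulate: nucleotide sequence (no start
codons are checked against a genome), GC%-dependent error rates,
multi-replicon genomes (supported by the grouping, not generated),
operon structure or overlapping genes, and engine-specific offset
preferences. A green test on synthetic panels therefore establishes the
correctness of grouping/scoring/path machinery and qualitative trend
reproduction — not the quantitative performance of any real engine panel.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive everywhere; GenBank's 0-based
  half-open locations are converted at the parsing boundary. Compound
  (`join`) locations and flagged pseudogenes are skipped with warnings;
  tRNA features are excluded from scoring unless requested.
- The 10% margin is strict (`<`) and unrounded; grouping is invariant
  under coordinate translation.
- Duplicate intervals within one prediction set are dropped on
  construction (logged).
- Reports are written as UTF-8 TSV with `NA` for missing values, sorted
  by mORF id with a stable sort: identical inputs give byte-identical
  files.
- All simulator randomness derives from a single integer seed combined
  with the engine name (CRC32), so panels are reproducible and engines
  decorrelated by construction; the shared-error stream is keyed by a
  separate `shared_seed`.

## Known limitations

- Projected confidence transfers across genomes only as far as engine
  behaviour does; the shipped four-engine preset reflects a 2013-era
  panel of web services and should be retrained for modern pipelines.
- Single-linkage closure can merge neighbouring genes through chains of
  intermediate predictions in dense regions (use `anchor="reference"`
  when a trusted annotation exists).
- The greedy path optimises per-round specificity, not any global
  objective; it is faithful to the published procedure rather than
  optimal in a decision-theoretic sense.
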