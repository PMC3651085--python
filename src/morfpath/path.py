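"""Greedy specificity-ordered consensus paths over engine combinations.

A *consensus path* is an ordered sequence of engine combinations.  Training
on a genome with a trusted reference proceeds in rounds: every not-yet
selected combination is scored (exact-consensus calls, specificity as the
fraction correct) on the mORFs still unassigned, the most specific
combination wins the round, its called mORFs are removed, and the next
round begins.  Iteration stops after ``max_rounds`` rounds (default 5),
when no combination adds at least ``min_new`` new mORFs, or when the
combinations are exhausted.

Across several training genomes a *general path* is chosen per round by the
highest average **impact**, a rank-penalised product of specificity and
sensitivity (default form ``spec * sens / rank``).  The chosen
combination's average specificity across the training genomes is its
*projected confidence* — an a priori estimate, for a new genome without a
reference, that a start codon called by that round is correct.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import yaml

from .combine import Combination, all_combinations
from .errors import ConfigurationError, UndefinedMetricError
from .io import REFERENCE_SOURCE
from .metrics import ScoreCounts, error_rate, sensitivity, specificity
from .morf import MOrf

logger = logging.getLogger(__name__)

DEFAULT_MAX_ROUNDS = 5

#: Available functional forms for the impact statistic.  Any registered form
#: must be strictly increasing in specificity and sensitivity and
#: non-increasing in rank.
IMPACT_FORMS: dict[str, Callable[[float, float, int], float]] = {
    "product_over_rank": lambda spec, sens, rank: spec * sens / rank,
}
DEFAULT_IMPACT_FORM = "product_over_rank"


def impact(spec: float, sens: float, rank: int,
           form: str = DEFAULT_IMPACT_FORM) -> float:
    """Rank-penalised merit of a combination: default ``spec * sens / rank``.

    ``rank`` is the 1-based round in which the combination would be applied;
    penalising late rounds keeps the general path ordered from reliable to
    speculative combinations.
    """
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    if not (0.0 <= spec <= 1.0 and 0.0 <= sens <= 1.0):
        raise ValueError("specificity and sensitivity must lie in [0, 1]")
    try:
        fn = IMPACT_FORMS[form]
    except KeyError:
        raise ValueError(f"unknown impact form {form!r}; available: "
                         f"{sorted(IMPACT_FORMS)}") from None
    return fn(spec, sens, rank)


@dataclass
class RoundResult:
    """Outcome of one training round: the winning combination, the mORFs it
    called (disjoint from all earlier rounds) and its scores on the
    remaining subset."""

    round_index: int
    combination: Combination
    called_morfs: dict[str, int]  # morf_id -> consensus start coordinate
    counts: ScoreCounts
    specificity: float
    sensitivity: float

    @property
    def n_new(self) -> int:
        return len(self.called_morfs)


@dataclass
class PathSpec:
    """An ordered consensus path with per-round projected confidences."""

    combinations: list[Combination]
    projected_confidence: list[float]
    average_impact: list[float] = field(default_factory=list)
    impact_form: str = DEFAULT_IMPACT_FORM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.combinations) != len(self.projected_confidence):
            raise ValueError("one projected confidence per round is required")
        keys = [c.key for c in self.combinations]
        if len(set(keys)) != len(keys):
            raise ValueError("a combination may appear at most once in a path")

    def __len__(self) -> int:
        return len(self.combinations)

    @property
    def engines(self) -> set[str]:
        out: set[str] = set()
        for combo in self.combinations:
            out |= combo.engines
        return out

    def to_dict(self) -> dict:
        return {
            "impact_form": self.impact_form,
            "rounds": [
                {"rank": i + 1,
                 "combination": combo.key,
                 "projected_confidence": float(conf),
                 **({"average_impact": float(self.average_impact[i])}
                    if i < len(self.average_impact) else {})}
                for i, (combo, conf) in enumerate(
                    zip(self.combinations, self.projected_confidence))
            ],
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PathSpec":
        rounds = sorted(data["rounds"], key=lambda r: r["rank"])
        return cls(
            combinations=[Combination.from_key(r["combination"])
                          for r in rounds],
            projected_confidence=[float(r["projected_confidence"])
                                  for r in rounds],
            average_impact=[float(r["average_impact"]) for r in rounds
                            if "average_impact" in r],
            impact_form=data.get("impact_form", DEFAULT_IMPACT_FORM),
            metadata=dict(data.get("metadata", {})),
        )

    def save(self, path: str | Path) -> None:
        """Serialise to YAML (``.yaml``/``.yml``) or JSON (anything else)."""
        path = Path(path)
        data = self.to_dict()
        with open(path, "w") as handle:
            if path.suffix.lower() in (".yaml", ".yml"):
                yaml.safe_dump(data, handle, sort_keys=False)
            else:
                json.dump(data, handle, indent=2)
                handle.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "PathSpec":
        path = Path(path)
        with open(path) as handle:
            if path.suffix.lower() in (".yaml", ".yml"):
                data = yaml.safe_load(handle)
            else:
                data = json.load(handle)
        return cls.from_dict(data)


def default_four_engine_path() -> PathSpec:
    """The shipped preset path for the BASys/ISGA/RAST/xBASE panel.

    Order and projected confidences come from a published benchmark of the
    four engines on eight curated moderate-GC% bacterial genomes; they are a
    starting point for that specific panel, not a property of the
    algorithm.  Retrain with :func:`train_general_path` for other panels.
    """
    combos = [Combination.of("BASys", "ISGA", "RAST", "xBASE"),
              Combination.of("ISGA", "RAST", "xBASE"),
              Combination.of("BASys", "ISGA", "RAST"),
              Combination.of("ISGA", "RAST"),
              Combination.of("BASys", "RAST", "xBASE")]
    confidences = [0.957, 0.756, 0.676, 0.531, 0.426]
    return PathSpec(combinations=combos,
                    projected_confidence=confidences,
                    impact_form=DEFAULT_IMPACT_FORM,
                    metadata={"preset": "moderate-gc-four-engine",
                              "training": "eight curated moderate-GC% "
                                          "bacterial genomes"})


# ---------------------------------------------------------------------------
# vectorised consensus scoring
# ---------------------------------------------------------------------------

class _CallMatrix:
    """Per-mORF start coordinates as a dense (mORF x engine) array, NaN for
    absent members; used to score many combinations quickly."""

    def __init__(self, morfs: Sequence[MOrf], panel: Sequence[str]) -> None:
        self.morf_ids = [m.morf_id for m in morfs]
        n = len(morfs)
        self.starts = np.full((n, len(panel)), np.nan)
        self.ref = np.full(n, np.nan)
        self.col = {engine: j for j, engine in enumerate(panel)}
        for i, morf in enumerate(morfs):
            for engine, j in self.col.items():
                s = morf.start_of(engine)
                if s is not None:
                    self.starts[i, j] = s
            ref = morf.reference_member
            if ref is not None:
                self.ref[i] = ref.start_coord
        self.has_ref = ~np.isnan(self.ref)
        self._consensus_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def consensus(self, combo: Combination) -> tuple[np.ndarray, np.ndarray]:
        cached = self._consensus_cache.get(combo.key)
        if cached is not None:
            return cached
        idx = [self.col[e] for e in sorted(combo.engines)]
        sub = self.starts[:, idx]
        called = ~np.isnan(sub).any(axis=1)
        if len(idx) > 1:
            called &= (sub == sub[:, [0]]).all(axis=1)
        result = (called, sub[:, 0])
        self._consensus_cache[combo.key] = result
        return result

    def score(self, combo: Combination,
              mask: np.ndarray) -> tuple[ScoreCounts, np.ndarray]:
        """Counts for the combination restricted to mORFs where ``mask`` is
        True, plus the boolean called-row mask."""
        called, values = self.consensus(combo)
        called = called & mask
        ok = called & (values == self.ref)
        n_correct = int(ok.sum())
        n_incorrect = int((called & self.has_ref).sum()) - n_correct
        n_fp = int(called.sum()) - n_correct - n_incorrect
        n_ref = int((mask & self.has_ref).sum())
        n_fn = n_ref - n_correct - n_incorrect
        counts = ScoreCounts(n_correct=n_correct, n_incorrect=n_incorrect,
                             n_fp=n_fp, n_fn=n_fn, n_reference=n_ref)
        return counts, called


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def run_path(morfs: Sequence[MOrf], panel: Sequence[str],
             max_rounds: int = DEFAULT_MAX_ROUNDS, min_new: int = 1,
             *, fp_mode: str = "include",
             record_tables: bool = False):
    """Greedy per-genome consensus-path training.

    Returns the list of :class:`RoundResult`; with ``record_tables=True``
    returns ``(rounds, tables)`` where ``tables[r]`` maps every candidate
    combination key evaluable in round ``r+1`` (not yet selected, at least
    one call on the remaining mORFs) to ``(specificity, sensitivity,
    n_new)`` — the raw material for :func:`general_path`.

    Round winner: highest specificity; ties broken by more new mORFs, then
    larger combination, then lexicographically smallest key.
    """
    if not panel:
        raise ConfigurationError("panel must name at least one engine")
    if not any(m.reference_member is not None for m in morfs):
        raise ConfigurationError("consensus-path training requires "
                                 "reference members in the mORFs")
    matrix = _CallMatrix(morfs, panel)
    remaining = np.ones(len(morfs), dtype=bool)
    candidates = all_combinations(panel)
    rounds: list[RoundResult] = []
    tables: list[dict[str, tuple[float, float]]] = []

    while len(rounds) < max_rounds and candidates and remaining.any():
        table: dict[str, tuple[float, float, int]] = {}
        best = None  # (sort key, combo, counts, called)
        for combo in candidates:
            counts, called = matrix.score(combo, remaining)
            if counts.predictions == 0:
                continue  # specificity undefined: skip this combination
            spec = specificity(counts, fp_mode=fp_mode)
            sens = (sensitivity(counts) if counts.n_reference > 0 else 0.0)
            n_new = int(called.sum())
            table[combo.key] = (spec, sens, n_new)
            key = (-spec, -n_new, -len(combo), combo.key)
            if best is None or key < best[0]:
                best = (key, combo, counts, called, spec, sens)
        if record_tables and table:
            tables.append(table)
        if best is None:
            if not rounds:
                logger.warning("no combination makes any call in round 1; "
                               "empty path")
            break
        _, combo, counts, called, spec, sens = best
        if int(called.sum()) < min_new:
            break
        _, values = matrix.consensus(combo)
        called_morfs = {matrix.morf_ids[i]: int(values[i])
                        for i in np.flatnonzero(called)}
        rounds.append(RoundResult(round_index=len(rounds) + 1,
                                  combination=combo,
                                  called_morfs=called_morfs,
                                  counts=counts,
                                  specificity=spec,
                                  sensitivity=sens))
        remaining &= ~called
        candidates = [c for c in candidates if c.key != combo.key]

    if record_tables:
        return rounds, tables
    return rounds


#: per-round score tables: one mapping per round, combination key ->
#: (specificity, sensitivity[, n_new])
ScoreTables = Sequence[Mapping[str, tuple]]


def _table_entry(entry: tuple) -> tuple[float, float, int]:
    spec, sens = entry[0], entry[1]
    n_new = int(entry[2]) if len(entry) > 2 else 0
    return float(spec), float(sens), n_new


def _round_winner(table: Mapping[str, tuple],
                  excluded: set[str]) -> Optional[str]:
    """The combination run_path would select from this table: highest
    specificity, ties by n_new, then size, then lexicographic key."""
    best = None
    for key, entry in table.items():
        if key in excluded:
            continue
        spec, _, n_new = _table_entry(entry)
        sort_key = (-spec, -n_new, -len(key.split("+")), key)
        if best is None or sort_key < best[0]:
            best = (sort_key, key)
    return None if best is None else best[1]


def general_path(per_genome_tables: Mapping[str, ScoreTables],
                 *, panel: Optional[Sequence[str]] = None,
                 impact_form: str = DEFAULT_IMPACT_FORM,
                 max_rounds: int = DEFAULT_MAX_ROUNDS) -> PathSpec:
    """Cross-genome consensus path by highest average impact per round.

    ``per_genome_tables`` maps each training genome to its per-round score
    tables from ``run_path(..., record_tables=True)``.  For round ``r``
    the candidates are the genomes' own round-``r`` specificity winners
    (the combinations the per-genome greedy paths would pick, excluding
    combinations already in the general path); each candidate's impact is
    averaged over *all* genomes — a genome where the combination made no
    call in round ``r`` contributes impact 0 — and the arg-max joins the
    path.  Its projected confidence is its mean round-``r`` specificity
    over the genomes where it was evaluable.

    With a single training genome this reduces exactly to that genome's
    own greedy path.

    When ``panel`` is given, any genome whose tables mention an engine
    outside it is rejected (the genomes must have been scored with one
    shared panel).
    """
    if not per_genome_tables:
        raise ConfigurationError("at least one training genome is required")
    if panel is not None:
        allowed = set(panel)
        for genome, tables in per_genome_tables.items():
            used = {e for table in tables for key in table
                    for e in key.split("+")}
            if not used <= allowed:
                raise ConfigurationError(
                    f"genome {genome!r} was scored with engines outside "
                    f"the panel: {sorted(used - allowed)}")
    genomes = sorted(per_genome_tables)

    chosen: list[Combination] = []
    chosen_keys: set[str] = set()
    confidences: list[float] = []
    impacts: list[float] = []
    for rank in range(1, max_rounds + 1):
        round_tables = {
            genome: per_genome_tables[genome][rank - 1]
            for genome in genomes
            if rank <= len(per_genome_tables[genome])
        }
        if not round_tables:
            break
        candidates = {
            winner for table in round_tables.values()
            if (winner := _round_winner(table, chosen_keys)) is not None
        }
        if not candidates:
            # every genome's round winner is already in the path; fall
            # back to anything still evaluable this round
            candidates = {key for table in round_tables.values()
                          for key in table} - chosen_keys
        best = None  # (sort key, key, avg impact, mean spec)
        for key in sorted(candidates):
            per_genome_impact = []
            specs = []
            for genome in genomes:
                entry = round_tables.get(genome, {}).get(key)
                if entry is None:
                    per_genome_impact.append(0.0)
                else:
                    spec, sens, _ = _table_entry(entry)
                    per_genome_impact.append(impact(spec, sens, rank,
                                                    form=impact_form))
                    specs.append(spec)
            avg = float(np.mean(per_genome_impact))
            if avg <= 0.0:
                continue
            sort_key = (-avg, -float(np.mean(specs)), key)
            if best is None or sort_key < best[0]:
                best = (sort_key, key, avg, float(np.mean(specs)))
        if best is None:
            break
        _, key, avg, conf = best
        chosen.append(Combination.from_key(key))
        chosen_keys.add(key)
        confidences.append(conf)
        impacts.append(avg)

    return PathSpec(combinations=chosen,
                    projected_confidence=confidences,
                    average_impact=impacts,
                    impact_form=impact_form,
                    metadata={"n_training_genomes": len(genomes),
                              "training_genomes": genomes})


def train_general_path(genome_morfs: Mapping[str, Sequence[MOrf]],
                       panel: Sequence[str],
                       *, max_rounds: int = DEFAULT_MAX_ROUNDS,
                       min_new: int = 1, fp_mode: str = "include",
                       impact_form: str = DEFAULT_IMPACT_FORM) -> PathSpec:
    """Convenience wrapper: per-genome greedy training on every genome's
    mORFs, then :func:`general_path` over the recorded score tables."""
    tables = {}
    for genome, morfs in genome_morfs.items():
        _, genome_tables = run_path(morfs, panel, max_rounds=max_rounds,
                                    min_new=min_new, fp_mode=fp_mode,
                                    record_tables=True)
        tables[genome] = genome_tables
    return general_path(tables, panel=panel, impact_form=impact_form,
                        max_rounds=max_rounds)


# ---------------------------------------------------------------------------
# application to a new genome
# ---------------------------------------------------------------------------

class PathCall(NamedTuple):
    """Consensus-path outcome for one mORF of a new genome."""

    start: Optional[int]
    round_index: Optional[int]
    projected_confidence: Optional[float]


def apply_path(morfs: Sequence[MOrf], path: PathSpec
               ) -> dict[str, PathCall]:
    """Apply a trained path to a new genome's mORFs (no reference needed).

    Rounds are applied in order; each mORF receives the call of the first
    round whose combination reaches exact consensus on it, stamped with
    that round's projected confidence.  mORFs no round can call are
    reported with a no-call entry.
    """
    present = {m.source for morf in morfs for m in morf.members}
    present.discard(REFERENCE_SOURCE)
    missing = path.engines - present
    if missing:
        raise ConfigurationError(
            f"path references engines absent from the predictions: "
            f"{sorted(missing)}")
    out: dict[str, PathCall] = {}
    from .combine import consensus_call
    for morf in morfs:
        call = PathCall(None, None, None)
        for rank, (combo, conf) in enumerate(
                zip(path.combinations, path.projected_confidence), start=1):
            s = consensus_call(morf, combo)
            if s is not None:
                call = PathCall(int(s), rank, float(conf))
                break
        out[morf.morf_id] = call
    return out
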