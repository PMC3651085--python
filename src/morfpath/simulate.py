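"""Synthetic reference annotations and emulated engine predictions.

The generator stands in for the outputs of real annotation engines so that
grouping, scoring and path training are testable without any web service.
Its error taxonomy mirrors what is observed when engine calls are compared
with curated genomes:

* **false negatives**, more likely for ORFs shorter than 750 nt
  (``p_fn_short`` vs ``p_fn_long``);
* **wrong start codons** — the emitted ORF keeps its stop but the start is
  shifted by an in-frame offset (a multiple of 3 nt, positive = downstream,
  mimicking an alternative start-codon choice);
* **false positives** — spurious short ORFs dropped into intergenic space
  at ``fp_rate`` per 100 reference ORFs;
* **rare stop errors** (``p_stop_error``, default 0: engines almost never
  miscall stops).

A :class:`CorrelationSpec` makes engines err *together*: for each
reference ORF, each engine independently uses the panel-shared wrong-start
draw (decision and offset) with probability ``shared_error_fraction``
instead of its own.  Engines that share the draw make the *same* mistake,
emulating the common components (ORF callers, training heuristics) real
engines share; subsets of the panel therefore err together more often than
the whole panel does, and at ``shared_error_fraction = 1`` every engine
agrees on every emitted ORF.  Without sharing, engine mistakes are
independent and exact agreement on a wrong start is rare.

No nucleotide sequence is generated — only coordinates.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import PlacementError
from .io import Orf, PredictionSet, REFERENCE_SOURCE

logger = logging.getLogger(__name__)

LENGTH_THRESHOLD_NT = 750

#: default in-frame start offsets (nt): near-cognate alternative starts a
#: few codons away plus an occasional distant one.
DEFAULT_OFFSETS = (-30, -9, -6, -3, 3, 6, 9, 30)


@dataclass(frozen=True)
class EngineProfile:
    """Error parameters for one emulated annotation engine.

    Rates are per reference ORF; ``fp_rate`` is the expected number of
    false ORFs per 100 reference ORFs.
    """

    name: str
    p_fn_short: float = 0.08
    p_fn_long: float = 0.01
    p_wrong_start: float = 0.15
    offset_choices: tuple[int, ...] = DEFAULT_OFFSETS
    fp_rate: float = 3.0
    p_stop_error: float = 0.0
    fp_length_range: tuple[int, int] = (90, 747)

    def __post_init__(self) -> None:
        for attr in ("p_fn_short", "p_fn_long", "p_wrong_start",
                     "p_stop_error"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")
        if not self.offset_choices:
            raise ValueError("offset_choices must not be empty")
        for off in self.offset_choices:
            if off == 0 or off % 3 != 0:
                raise ValueError(f"offsets must be non-zero multiples of 3, "
                                 f"got {off}")


@dataclass(frozen=True)
class CorrelationSpec:
    """Probability that an engine, for a given reference ORF, adopts the
    panel-shared wrong-start draw (decision and offset) instead of its own
    independent one; engines adopting it err identically."""

    shared_error_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_error_fraction <= 1.0:
            raise ValueError("shared_error_fraction must be in [0, 1]")


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def generate_reference(n_orfs: int,
                       genome_length: Optional[int] = None,
                       length_dist_params: Optional[tuple[float, float]] = None,
                       seed: int = 0,
                       contig: str = "chr1") -> PredictionSet:
    """Seeded synthetic reference annotation for one replicon.

    Lengths are log-normal with median ``length_dist_params[0]`` nt (default
    900, a typical bacterial gene) and log-sigma ``length_dist_params[1]``
    (default 0.55), clipped to 150-4500 nt and rounded to codon multiples.
    ORFs are placed left to right without overlap, separated by random
    intergenic gaps; strands are random.  ``genome_length`` defaults to a
    size giving roughly 85% coding density; an explicit length too small to
    hold the ORFs raises :class:`PlacementError`.
    """
    if n_orfs < 1:
        raise ValueError("n_orfs must be >= 1")
    median_nt, sigma_log = length_dist_params or (900.0, 0.55)
    rng = np.random.default_rng([int(seed), _name_key(REFERENCE_SOURCE)])
    lengths = rng.lognormal(mean=np.log(median_nt), sigma=sigma_log,
                            size=n_orfs)
    lengths = np.clip(lengths, 150, 4500)
    lengths = (np.rint(lengths / 3).astype(int) * 3)
    total = int(lengths.sum())
    if genome_length is None:
        genome_length = int(np.ceil(total / 0.85))
    free = genome_length - total
    if free < 0:
        raise PlacementError(
            f"cannot place {n_orfs} ORFs totalling {total} nt on a "
            f"{genome_length} nt genome")
    weights = rng.random(n_orfs + 1)
    gaps = np.floor(weights / weights.sum() * free).astype(int)
    strands = rng.choice(["+", "-"], size=n_orfs)
    orfs = []
    cursor = 1
    for i in range(n_orfs):
        cursor += int(gaps[i])
        left = cursor
        right = left + int(lengths[i]) - 1
        orfs.append(Orf(contig, left, right, str(strands[i]),
                        source=REFERENCE_SOURCE,
                        orf_id=f"ref_{i + 1:05d}"))
        cursor = right + 1
    return PredictionSet(source=REFERENCE_SOURCE, orfs=orfs)


def simulate_engine(reference: PredictionSet,
                    profile: EngineProfile,
                    corr: Optional[CorrelationSpec] = None,
                    seed: int = 0,
                    shared_seed: Optional[int] = None) -> PredictionSet:
    """Emulate one engine's predictions for a synthetic reference.

    ``seed`` drives the engine's own randomness (combined with the profile
    name, so two engines run at the same seed still differ).
    ``shared_seed`` (default: ``seed``) drives the panel-shared error
    stream; engines simulated with the same ``shared_seed`` make the *same*
    wrong-start mistake on any ORF where both adopt the shared draw, which
    each does independently with probability
    ``corr.shared_error_fraction``.  Sharing assumes the panel uses
    identical ``offset_choices``.
    """
    if len(reference) == 0:
        raise ValueError("reference must be non-empty")
    corr = corr or CorrelationSpec()
    if shared_seed is None:
        shared_seed = seed
    rng = np.random.default_rng([int(seed), _name_key(profile.name)])
    shared_rng = np.random.default_rng([int(shared_seed), 715])

    ref_orfs = list(reference)
    n = len(ref_orfs)
    u_wrong_shared = shared_rng.random(n)
    pick_shared = shared_rng.integers(0, 2**31, size=n)
    # each engine decides per ORF, from its own stream, whether it adopts
    # the shared draw; f=1 makes the whole panel err in lockstep
    is_shared = rng.random(n) < corr.shared_error_fraction
    u_fn = rng.random(n)
    u_wrong_own = rng.random(n)
    pick_own = rng.integers(0, 2**31, size=n)
    u_stop = rng.random(n)
    pick_stop = rng.integers(0, 2**31, size=n)

    out: list[Orf] = []
    for i, ref in enumerate(ref_orfs):
        p_fn = (profile.p_fn_short if ref.length < LENGTH_THRESHOLD_NT
                else profile.p_fn_long)
        if u_fn[i] < p_fn:
            continue  # false negative
        u_wrong = u_wrong_shared[i] if is_shared[i] else u_wrong_own[i]
        pick = pick_shared[i] if is_shared[i] else pick_own[i]
        left, right = ref.leftmost, ref.rightmost
        if u_wrong < profile.p_wrong_start:
            offset = _choose_offset(ref, profile.offset_choices, int(pick))
            if offset is None:
                logger.info("no feasible start offset for %s; emitted "
                            "unshifted", ref.orf_id)
            elif ref.strand == "+":
                left = left + offset
            else:
                right = right - offset
        if profile.p_stop_error > 0 and u_stop[i] < profile.p_stop_error:
            left, right = _shift_stop(left, right, ref.strand,
                                      int(pick_stop[i]))
        out.append(Orf(ref.contig, left, right, ref.strand,
                       source=profile.name, orf_id=ref.orf_id))

    out.extend(_false_positives(reference, profile, rng))
    return PredictionSet(source=profile.name, orfs=out)


def _choose_offset(ref: Orf, choices: Sequence[int],
                   pick: int) -> Optional[int]:
    """An in-frame start offset feasible for this ORF: shorter than the ORF
    and keeping the shifted 5' end on the genome."""
    valid = []
    for off in choices:
        if abs(off) >= ref.length:
            continue
        if ref.strand == "+" and ref.leftmost + off < 1:
            continue
        valid.append(off)
    if not valid:
        return None
    return valid[pick % len(valid)]


def _shift_stop(left: int, right: int, strand: str,
                pick: int) -> tuple[int, int]:
    """Move the 3' end by a small in-frame offset, keeping a valid
    interval."""
    for off in ((-3, 3, -6, 6)[pick % 4],) + (-3, 3, -6, 6):
        if strand == "+":
            new_left, new_right = left, right + off
        else:
            new_left, new_right = left - off, right
        if 1 <= new_left <= new_right:
            return new_left, new_right
    return left, right


def _false_positives(reference: PredictionSet, profile: EngineProfile,
                     rng: np.random.Generator) -> list[Orf]:
    """Spurious ORFs placed in intergenic space, short by default."""
    n_fp = int(rng.poisson(profile.fp_rate * len(reference) / 100.0))
    if n_fp == 0:
        return []
    gaps = _intergenic_gaps(reference)
    lo, hi = profile.fp_length_range
    out: list[Orf] = []
    for _ in range(n_fp):
        usable = [(contig, g_left, g_right) for contig, g_left, g_right
                  in gaps if g_right - g_left + 1 >= lo]
        if not usable:
            logger.info("no intergenic room for further false positives")
            break
        widths = np.array([g[2] - g[1] + 1 for g in usable], dtype=float)
        contig, g_left, g_right = usable[
            int(rng.choice(len(usable), p=widths / widths.sum()))]
        max_len = min(hi, g_right - g_left + 1)
        length = int(rng.integers(lo // 3, max_len // 3 + 1)) * 3
        left = int(rng.integers(g_left, g_right - length + 2))
        strand = str(rng.choice(["+", "-"]))
        out.append(Orf(contig, left, left + length - 1, strand,
                       source=profile.name, orf_id=None))
    return out


def _intergenic_gaps(reference: PredictionSet
                     ) -> list[tuple[str, int, int]]:
    gaps: list[tuple[str, int, int]] = []
    by_contig: dict[str, list[Orf]] = {}
    for orf in reference:
        by_contig.setdefault(orf.contig, []).append(orf)
    for contig, orfs in by_contig.items():
        orfs = sorted(orfs, key=lambda o: (o.leftmost, o.rightmost))
        cursor = 1
        for orf in orfs:
            if orf.leftmost > cursor:
                gaps.append((contig, cursor, orf.leftmost - 1))
            cursor = max(cursor, orf.rightmost + 1)
        # trailing gap, sized like a typical intergenic stretch
        gaps.append((contig, cursor, cursor + 499))
    return gaps


def simulate_panel(reference: PredictionSet,
                   profiles: Sequence[EngineProfile],
                   corr: Optional[CorrelationSpec] = None,
                   seed: int = 0) -> list[PredictionSet]:
    """Simulate a whole panel with a common shared-error stream; engine
    ``i`` uses its own stream derived from ``(seed, profile name)``."""
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("engine profiles must have distinct names")
    return [simulate_engine(reference, profile, corr,
                            seed=seed, shared_seed=seed)
            for profile in profiles]


def default_panel_profiles() -> list[EngineProfile]:
    """A four-engine panel with wrong-start rates inside the 14-58% band
    observed for real engines on curated genomes."""
    return [
        EngineProfile(name="engineA", p_wrong_start=0.15, p_fn_short=0.08,
                      p_fn_long=0.01, fp_rate=3.0),
        EngineProfile(name="engineB", p_wrong_start=0.22, p_fn_short=0.10,
                      p_fn_long=0.015, fp_rate=4.0),
        EngineProfile(name="engineC", p_wrong_start=0.35, p_fn_short=0.12,
                      p_fn_long=0.02, fp_rate=5.0),
        EngineProfile(name="engineD", p_wrong_start=0.55, p_fn_short=0.15,
                      p_fn_long=0.03, fp_rate=6.0),
    ]
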