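"""Combining per-engine start calls within a mORF.

Two fusion rules are provided:

* **majority vote** — trust a start coordinate iff strictly more than half
  of the panel's engines predict exactly that coordinate for the mORF.  By
  default engines with no member in the mORF still count in the
  denominator (the vote is over the panel, not over responders).
* **exact consensus of a combination** — a named subset of engines emits a
  call only when *every* member engine is present in the mORF and all of
  them agree exactly on the start coordinate.  Requiring presence of all
  members is what makes larger combinations more specific and less
  sensitive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations as _subsets
from typing import Iterable, Optional, Sequence

from .metrics import CallLabel, ScoreCounts, count_labels
from .morf import MOrf


@dataclass(frozen=True)
class Combination:
    """A non-empty subset of the engine panel, canonically named by the
    sorted '+'-joined engine names (e.g. ``"BASys+ISGA+RAST"``)."""

    engines: frozenset[str]

    def __post_init__(self) -> None:
        if not self.engines:
            raise ValueError("a combination needs at least one engine")
        object.__setattr__(self, "engines", frozenset(self.engines))

    @classmethod
    def of(cls, *engines: str) -> "Combination":
        return cls(frozenset(engines))

    @classmethod
    def from_key(cls, key: str) -> "Combination":
        return cls(frozenset(key.split("+")))

    @property
    def key(self) -> str:
        return "+".join(sorted(self.engines))

    def __len__(self) -> int:
        return len(self.engines)

    def __iter__(self):
        return iter(sorted(self.engines))

    def __le__(self, other: "Combination") -> bool:
        return self.engines <= other.engines

    def __repr__(self) -> str:
        return f"Combination({self.key})"


def all_combinations(panel: Sequence[str],
                     min_size: int = 1) -> list[Combination]:
    """Every subset of the panel of size >= ``min_size`` (singletons
    included by default), in deterministic (size, key) order."""
    combos = [Combination(frozenset(sub))
              for r in range(min_size, len(panel) + 1)
              for sub in _subsets(sorted(panel), r)]
    return sorted(combos, key=lambda c: (len(c), c.key))


def majority_vote(morf: MOrf, panel: Sequence[str],
                  denominator: str = "panel") -> Optional[int]:
    """Start coordinate backed by a strict majority of the panel, or None.

    ``denominator="panel"`` (default) counts absent engines in the total;
    ``denominator="responders"`` divides only by engines with a member in
    this mORF.
    """
    if len(panel) < 2:
        raise ValueError("majority voting needs a panel of >= 2 engines")
    starts = [morf.start_of(engine) for engine in panel]
    votes = Counter(s for s in starts if s is not None)
    if not votes:
        return None
    if denominator == "panel":
        total = len(panel)
    elif denominator == "responders":
        total = sum(1 for s in starts if s is not None)
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    coord, count = votes.most_common(1)[0]
    return coord if count > total / 2 else None


def consensus_call(morf: MOrf, combination: Combination) -> Optional[int]:
    """The combination's unanimous start coordinate for this mORF, or None.

    Every engine of the combination must have a member in the mORF and all
    their start coordinates must be identical; a singleton combination
    simply returns that engine's start when present.
    """
    starts = []
    for engine in combination.engines:
        s = morf.start_of(engine)
        if s is None:
            return None
        starts.append(s)
    return starts[0] if len(set(starts)) == 1 else None


def classify_consensus(morfs: Iterable[MOrf],
                       combination: Combination) -> dict[str, CallLabel]:
    """Classify the combination's consensus call per mORF against the
    reference, with the same label semantics as single-engine scoring."""
    labels: dict[str, CallLabel] = {}
    for morf in morfs:
        call = consensus_call(morf, combination)
        ref = morf.reference_member
        if call is not None:
            if ref is None:
                labels[morf.morf_id] = CallLabel.FALSE_POSITIVE
            elif call == ref.start_coord:
                labels[morf.morf_id] = CallLabel.CORRECT
            else:
                labels[morf.morf_id] = CallLabel.INCORRECT
        else:
            if ref is None:
                labels[morf.morf_id] = CallLabel.ABSENT
            else:
                labels[morf.morf_id] = CallLabel.FALSE_NEGATIVE
    return labels


def score_combination(morfs: Iterable[MOrf],
                      combination: Combination) -> ScoreCounts:
    """Tally the combination's consensus calls over the given mORF subset.

    Reference-bearing mORFs without a consensus call contribute false
    negatives; consensus calls in reference-free mORFs are false positives.
    An empty subset yields all-zero counts.
    """
    return count_labels(classify_consensus(morfs, combination).values())
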