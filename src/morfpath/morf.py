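"""Grouping ORFs from multiple sources into meta-ORFs (mORFs).

Two ORFs are considered calls of the same gene when they lie on the same
contig and strand and either their 5' (start) or their 3' (stop) coordinates
differ by strictly less than 10% of the length of the shorter of the two.
mORFs are the connected components (single-linkage transitive closure) of
this pairwise-compatibility graph, so every input ORF belongs to exactly
one mORF.

An alternative ``anchor="reference"`` mode attaches each engine ORF directly
to the compatible reference ORF (nearest start wins) instead of taking the
full closure; engine ORFs matching no reference ORF are still grouped among
themselves by closure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ConfigurationError
from .io import Orf, PredictionSet, REFERENCE_SOURCE

logger = logging.getLogger(__name__)

DEFAULT_MARGIN_FRACTION = 0.10


@dataclass
class MOrf:
    """An equivalence group of ORFs from different sources deemed to be the
    same gene.

    ``members`` normally holds at most one ORF per source; when one source
    contributes several ORFs the mORF is flagged ``multi_call`` and
    :meth:`member` resolves the ambiguity by picking, per source, the member
    whose start is closest to the reference start (or the leftmost-sorted
    first member when no reference is present).
    """

    morf_id: str
    contig: str
    strand: str
    members: list[Orf] = field(default_factory=list)

    @property
    def reference_member(self) -> Optional[Orf]:
        refs = [m for m in self.members if m.source == REFERENCE_SOURCE]
        if not refs:
            return None
        return min(refs, key=lambda o: (o.leftmost, o.rightmost))

    @property
    def sources(self) -> set[str]:
        return {m.source for m in self.members}

    @property
    def multi_call(self) -> bool:
        return len(self.members) > len(self.sources)

    def members_of(self, source: str) -> list[Orf]:
        return [m for m in self.members if m.source == source]

    def member(self, source: str) -> Optional[Orf]:
        """The single scored member for ``source``, resolving multi-calls."""
        candidates = self.members_of(source)
        if not candidates:
            return None
        if len(candidates) == 1:
            return candidates[0]
        ref = self.reference_member
        if ref is not None and source != REFERENCE_SOURCE:
            return min(candidates,
                       key=lambda o: (abs(o.start_coord - ref.start_coord),
                                      o.leftmost))
        return min(candidates, key=lambda o: (o.leftmost, o.rightmost))

    def start_of(self, source: str) -> Optional[int]:
        m = self.member(source)
        return None if m is None else m.start_coord


def pair_compatible(a: Orf, b: Orf,
                    margin_fraction: float = DEFAULT_MARGIN_FRACTION,
                    containment: bool = False) -> bool:
    """True when ``a`` and ``b`` should fall in the same mORF.

    The margin is ``margin_fraction * min(length(a), length(b))`` as a real
    number, compared with strict inequality against the absolute difference
    of the 5' coordinates and, independently, of the 3' coordinates.
    Opposite strands or different contigs are never compatible.

    With ``containment=True`` an ORF lying entirely inside the other also
    qualifies, even when both boundary differences exceed the margin.
    """
    if a.contig != b.contig or a.strand != b.strand:
        return False
    margin = margin_fraction * min(a.length, b.length)
    if abs(a.start_coord - b.start_coord) < margin:
        return True
    if abs(a.stop_coord - b.stop_coord) < margin:
        return True
    if containment:
        if (a.leftmost <= b.leftmost and b.rightmost <= a.rightmost) or \
           (b.leftmost <= a.leftmost and a.rightmost <= b.rightmost):
            return True
    return False


class _DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def assign_morfs(sets: Iterable[PredictionSet],
                 reference: Optional[PredictionSet] = None,
                 *,
                 margin_fraction: float = DEFAULT_MARGIN_FRACTION,
                 containment: bool = False,
                 anchor: Optional[str] = None) -> list[MOrf]:
    """Partition all ORFs from the given sets (plus the optional reference)
    into mORFs.

    Returns mORFs with deterministic ids ordered by (contig, min leftmost,
    min rightmost, strand).

    ``anchor="reference"`` switches from full transitive closure to
    reference-anchored grouping (see module docstring); it requires a
    reference set.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("at least one prediction set is required")
    orfs: list[Orf] = []
    for pset in sets:
        orfs.extend(pset)
    if reference is not None:
        if reference.source != REFERENCE_SOURCE:
            raise ConfigurationError(
                f"reference set must have source {REFERENCE_SOURCE!r}, "
                f"got {reference.source!r}")
        orfs.extend(reference)

    if anchor is None:
        components = _closure_components(orfs, margin_fraction, containment)
    elif anchor == "reference":
        if reference is None:
            raise ConfigurationError("anchor='reference' requires a "
                                     "reference set")
        components = _anchored_components(orfs, margin_fraction, containment)
    else:
        raise ConfigurationError(f"unknown anchor mode {anchor!r}")

    components.sort(key=lambda comp: (comp[0].contig,
                                      min(o.leftmost for o in comp),
                                      min(o.rightmost for o in comp),
                                      comp[0].strand))
    width = max(5, len(str(len(components))))
    morfs = []
    for i, comp in enumerate(components, start=1):
        morf = MOrf(morf_id=f"mORF_{i:0{width}d}",
                    contig=comp[0].contig,
                    strand=comp[0].strand,
                    members=sorted(comp))
        if morf.multi_call:
            dupes = sorted(s for s in morf.sources
                           if len(morf.members_of(s)) > 1)
            logger.info("mORF %s has multiple members from source(s) %s; "
                        "the start closest to the reference will be scored",
                        morf.morf_id, ", ".join(dupes))
        morfs.append(morf)
    return morfs


def _closure_components(orfs: Sequence[Orf], margin_fraction: float,
                        containment: bool) -> list[list[Orf]]:
    """Connected components of the pair-compatibility graph.

    Candidate pairs are found with a sorted sweep over 5' and 3'
    coordinates: a compatible pair differs by less than
    ``margin_fraction * length`` of *each* member on at least one end, so a
    window of that width around every ORF covers all edges.  Containment
    mode (rare, off by default) falls back to exact pairwise comparison
    within each (contig, strand) group.
    """
    dsu = _DisjointSet(len(orfs))
    by_group: dict[tuple[str, str], list[int]] = {}
    for i, orf in enumerate(orfs):
        by_group.setdefault((orf.contig, orf.strand), []).append(i)

    for indices in by_group.values():
        if containment:
            for a_pos, i in enumerate(indices):
                for j in indices[a_pos + 1:]:
                    if pair_compatible(orfs[i], orfs[j], margin_fraction,
                                       containment=True):
                        dsu.union(i, j)
            continue
        for coord_of in (lambda o: o.start_coord, lambda o: o.stop_coord):
            order = sorted(indices, key=lambda i: coord_of(orfs[i]))
            coords = [coord_of(orfs[i]) for i in order]
            for pos, i in enumerate(order):
                window = margin_fraction * orfs[i].length
                for pos2 in range(pos + 1, len(order)):
                    if coords[pos2] - coords[pos] >= window:
                        break
                    j = order[pos2]
                    if pair_compatible(orfs[i], orfs[j], margin_fraction):
                        dsu.union(i, j)

    groups: dict[int, list[Orf]] = {}
    for i, orf in enumerate(orfs):
        groups.setdefault(dsu.find(i), []).append(orf)
    return list(groups.values())


def _anchored_components(orfs: Sequence[Orf], margin_fraction: float,
                         containment: bool) -> list[list[Orf]]:
    ref_indices = [i for i, o in enumerate(orfs)
                   if o.source == REFERENCE_SOURCE]
    other_indices = [i for i, o in enumerate(orfs)
                     if o.source != REFERENCE_SOURCE]
    dsu = _DisjointSet(len(orfs))
    refs_by_group: dict[tuple[str, str], list[int]] = {}
    for i in ref_indices:
        refs_by_group.setdefault((orfs[i].contig, orfs[i].strand),
                                 []).append(i)

    unattached: list[Orf] = []
    unattached_idx: list[int] = []
    for i in other_indices:
        orf = orfs[i]
        candidates = [
            j for j in refs_by_group.get((orf.contig, orf.strand), [])
            if pair_compatible(orf, orfs[j], margin_fraction, containment)
        ]
        if candidates:
            best = min(candidates,
                       key=lambda j: (abs(orfs[j].start_coord
                                          - orf.start_coord),
                                      orfs[j].leftmost))
            dsu.union(best, i)
        else:
            unattached.append(orf)
            unattached_idx.append(i)

    # Engine ORFs with no reference anchor still cluster among themselves.
    sub = _closure_components(unattached, margin_fraction, containment)
    pos_of = {id(o): unattached_idx[k] for k, o in enumerate(unattached)}
    for comp in sub:
        first = pos_of[id(comp[0])]
        for o in comp[1:]:
            dsu.union(first, pos_of[id(o)])

    groups: dict[int, list[Orf]] = {}
    for i, orf in enumerate(orfs):
        groups.setdefault(dsu.find(i), []).append(orf)
    return list(groups.values())


def morf_dump_table(morfs: Sequence[MOrf]):
    """Long-format membership table: one row per (mORF, member)."""
    import pandas as pd

    rows = [
        {"morf_id": m.morf_id, "source": o.source, "contig": o.contig,
         "leftmost": o.leftmost, "rightmost": o.rightmost,
         "strand": o.strand}
        for m in morfs for o in m.members
    ]
    return pd.DataFrame(rows, columns=["morf_id", "source", "contig",
                                       "leftmost", "rightmost", "strand"])
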