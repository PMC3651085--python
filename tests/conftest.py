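"""Shared fixtures and independent oracles for the morfpath test suite."""

from __future__ import annotations

import numpy as np
import pytest

from morfpath import Orf, PredictionSet, REFERENCE_SOURCE


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no morfpath internals)
# ---------------------------------------------------------------------------

def oracle_compatible(a: Orf, b: Orf, margin_fraction: float = 0.10) -> bool:
    """The grouping rule, restated from scratch: same contig and strand,
    and 5' or 3' coordinates closer than 10% of the shorter ORF."""
    if a.contig != b.contig or a.strand != b.strand:
        return False
    len_a = a.rightmost - a.leftmost + 1
    len_b = b.rightmost - b.leftmost + 1
    margin = margin_fraction * min(len_a, len_b)
    start_a = a.leftmost if a.strand == "+" else a.rightmost
    start_b = b.leftmost if b.strand == "+" else b.rightmost
    stop_a = a.rightmost if a.strand == "+" else a.leftmost
    stop_b = b.rightmost if b.strand == "+" else b.leftmost
    return (abs(start_a - start_b) < margin) or (abs(stop_a - stop_b) < margin)


def oracle_components(orfs, margin_fraction: float = 0.10):
    """Connected components by O(n^2) edge enumeration + BFS transitive
    closure; returns a set of frozensets of ORF indices."""
    n = len(orfs)
    adjacency = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if oracle_compatible(orfs[i], orfs[j], margin_fraction):
                adjacency[i].append(j)
                adjacency[j].append(i)
    seen = [False] * n
    components = set()
    for start in range(n):
        if seen[start]:
            continue
        queue, comp = [start], set()
        seen[start] = True
        while queue:
            node = queue.pop()
            comp.add(node)
            for nxt in adjacency[node]:
                if not seen[nxt]:
                    seen[nxt] = True
                    queue.append(nxt)
        components.add(frozenset(comp))
    return components


def random_orfs(rng: np.random.Generator, n: int, source: str = "x",
                n_contigs: int = 2, coord_span: int = 5000):
    """Random small ORF instances for property tests; lengths 60-900 nt."""
    orfs = []
    for _ in range(n):
        contig = f"c{rng.integers(1, n_contigs + 1)}"
        left = int(rng.integers(1, coord_span))
        length = int(rng.integers(20, 300)) * 3
        strand = "+" if rng.random() < 0.5 else "-"
        orfs.append(Orf(contig, left, left + length - 1, strand,
                        source=source))
    return orfs


# ---------------------------------------------------------------------------
# hand-built three-mORF genome: known labels for every engine
# ---------------------------------------------------------------------------

@pytest.fixture
def three_morf_world():
    """Two engines and a reference over three loci.

    locus 1 (100-400,+): X correct, Y wrong start (130);
    locus 2 (1000-1600,-): X missing (FN), Y correct;
    locus 3 (3000-3300,+): no reference — X predicts it (FP), Y absent.
    """
    reference = PredictionSet(REFERENCE_SOURCE, [
        Orf("chr1", 100, 400, "+", REFERENCE_SOURCE, "g1"),
        Orf("chr1", 1000, 1600, "-", REFERENCE_SOURCE, "g2"),
    ])
    set_x = PredictionSet("X", [
        Orf("chr1", 100, 400, "+", "X"),
        Orf("chr1", 3000, 3300, "+", "X"),
    ])
    set_y = PredictionSet("Y", [
        Orf("chr1", 130, 400, "+", "Y"),
        Orf("chr1", 1000, 1600, "-", "Y"),
    ])
    return [set_x, set_y], reference
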