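"""Reading, normalising and writing prokaryotic gene predictions.

All coordinates are stored 1-based inclusive (the native convention of GFF3
and GenBank flat files); any 0-based half-open source must be converted at
the boundary before constructing an :class:`Orf`.

The "start codon coordinate" of an ORF is its strand-aware 5'-end genomic
position: ``leftmost`` on the plus strand, ``rightmost`` on the minus
strand.  Exact equality of this coordinate is what downstream scoring
compares.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gffutils
from Bio import SeqIO

from .errors import AnnotationFormatError

logger = logging.getLogger(__name__)

REFERENCE_SOURCE = "reference"

_TSV_COLUMNS = ("contig", "leftmost", "rightmost", "strand", "id")


@dataclass(frozen=True, order=True)
class Orf:
    """One oriented open reading frame.

    Parameters
    ----------
    contig:
        Replicon / sequence identifier.
    leftmost, rightmost:
        1-based inclusive genomic positions, ``leftmost <= rightmost``.
    strand:
        ``"+"`` or ``"-"``.
    source:
        Engine name, or ``"reference"`` for the trusted annotation.
    orf_id:
        Optional feature identifier (locus tag, GFF3 ID, ...).
    """

    contig: str
    leftmost: int
    rightmost: int
    strand: str
    source: str = REFERENCE_SOURCE
    orf_id: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.leftmost < 1 or self.rightmost < 1:
            raise ValueError(f"coordinates must be >= 1, got "
                             f"({self.leftmost}, {self.rightmost})")
        if self.leftmost > self.rightmost:
            raise ValueError(f"leftmost {self.leftmost} > rightmost "
                             f"{self.rightmost}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        """Nucleotide length, ``rightmost - leftmost + 1``."""
        return self.rightmost - self.leftmost + 1

    @property
    def start_coord(self) -> int:
        """Strand-aware 5' (biological start) coordinate."""
        return self.leftmost if self.strand == "+" else self.rightmost

    @property
    def stop_coord(self) -> int:
        """Strand-aware 3' (biological stop) coordinate."""
        return self.rightmost if self.strand == "+" else self.leftmost

    @property
    def coords_key(self) -> tuple[str, int, int, str]:
        """Identity of the interval irrespective of source and id."""
        return (self.contig, self.leftmost, self.rightmost, self.strand)


@dataclass
class PredictionSet:
    """All ORFs called by one source (one engine, or the reference).

    Duplicate intervals — identical (contig, leftmost, rightmost, strand) —
    are dropped on construction, keeping the first occurrence.
    """

    source: str
    orfs: list[Orf] = field(default_factory=list)

    def __post_init__(self) -> None:
        deduped: dict[tuple, Orf] = {}
        n_dupes = 0
        for orf in self.orfs:
            if orf.source != self.source:
                orf = Orf(orf.contig, orf.leftmost, orf.rightmost, orf.strand,
                          source=self.source, orf_id=orf.orf_id)
            if orf.coords_key in deduped:
                n_dupes += 1
                logger.info("dropping duplicate ORF %s in set %s",
                            orf.coords_key, self.source)
                continue
            deduped[orf.coords_key] = orf
        if n_dupes:
            logger.warning("%d duplicate ORFs removed from set %s",
                           n_dupes, self.source)
        self.orfs = sorted(deduped.values())

    def __len__(self) -> int:
        return len(self.orfs)

    def __iter__(self) -> Iterator[Orf]:
        return iter(self.orfs)

    @property
    def contigs(self) -> list[str]:
        return sorted({o.contig for o in self.orfs})


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path,
                    format: Optional[str] = None,
                    source_label: Optional[str] = None,
                    *,
                    include_trna: bool = False,
                    exclude_pseudogenes: bool = True) -> PredictionSet:
    """Read gene predictions from GFF3, GenBank or TSV into a PredictionSet.

    Parameters
    ----------
    path:
        Input file.
    format:
        One of ``"gff3"``, ``"genbank"``, ``"tsv"``; inferred from the file
        suffix when omitted.
    source_label:
        Source name stamped onto every ORF; defaults to the file stem.
    include_trna:
        Also keep tRNA features (GFF3 type ``tRNA`` / GenBank ``tRNA``).
        Off by default: start-codon scoring concerns protein-coding genes.
    exclude_pseudogenes:
        Skip features flagged as pseudogenes.

    Features with compound (``join``) locations are skipped with a warning —
    prokaryotic gene models are expected to be single intervals.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = _guess_format(path)
    source = source_label if source_label is not None else path.stem

    if format == "gff3":
        orfs = list(_iter_gff3(path, source, include_trna, exclude_pseudogenes))
    elif format in ("genbank", "gb", "gbk"):
        orfs = list(_iter_genbank(path, source, include_trna,
                                  exclude_pseudogenes))
    elif format == "tsv":
        orfs = list(_iter_tsv(path, source))
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    if not orfs:
        logger.warning("no eligible features found in %s (format %s)",
                       path, format)
    return PredictionSet(source=source, orfs=orfs)


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return "gff3"
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return "genbank"
    if suffix in (".tsv", ".txt", ".tab"):
        return "tsv"
    raise ValueError(f"cannot infer annotation format from suffix {suffix!r}")


def _iter_gff3(path: Path, source: str, include_trna: bool,
               exclude_pseudogenes: bool) -> Iterator[Orf]:
    eligible = {"CDS", "gene"}
    if include_trna:
        eligible.add("tRNA")
    try:
        features = [f for f in gffutils.iterators.DataIterator(str(path))
                    if f.featuretype in eligible]
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise AnnotationFormatError(f"cannot parse GFF3 {path}: {exc}") from exc

    # Multi-row features sharing one ID are compound (join) locations: skip.
    id_counts: dict[str, int] = {}
    for f in features:
        fid = f.attributes.get("ID", [None])[0]
        if fid is not None:
            id_counts[fid] = id_counts.get(fid, 0) + 1
    compound = {fid for fid, n in id_counts.items() if n > 1}
    if compound:
        logger.warning("skipping %d compound-location GFF3 features: %s",
                       len(compound), sorted(compound)[:5])

    # Prefer CDS rows; fall back to gene rows only when no CDS present, so a
    # file carrying both does not yield the same locus twice.
    have_cds = any(f.featuretype == "CDS" for f in features)
    for f in features:
        if f.featuretype == "gene" and have_cds:
            continue
        fid = f.attributes.get("ID", [None])[0]
        if fid in compound:
            continue
        if exclude_pseudogenes and _gff3_is_pseudo(f):
            logger.info("skipping pseudogene feature %s", fid)
            continue
        if f.strand not in ("+", "-"):
            logger.warning("skipping strandless GFF3 feature %s", fid)
            continue
        try:
            yield Orf(f.seqid, int(f.start), int(f.end), f.strand,
                      source=source, orf_id=fid)
        except ValueError as exc:
            raise AnnotationFormatError(
                f"bad GFF3 feature {fid} in {path}: {exc}") from exc


def _gff3_is_pseudo(feature) -> bool:
    attrs = {k.lower() for k in feature.attributes}
    if "pseudo" in attrs or "pseudogene" in attrs:
        return True
    return feature.featuretype == "pseudogene"


def _iter_genbank(path: Path, source: str, include_trna: bool,
                  exclude_pseudogenes: bool) -> Iterator[Orf]:
    eligible = {"CDS"}
    if include_trna:
        eligible.add("tRNA")
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise AnnotationFormatError(
            f"cannot parse GenBank {path}: {exc}") from exc
    for record in records:
        for feature in record.features:
            if feature.type not in eligible:
                continue
            fid = _genbank_id(feature)
            if exclude_pseudogenes and "pseudo" in feature.qualifiers:
                logger.info("skipping pseudogene %s", fid)
                continue
            if len(feature.location.parts) > 1:
                logger.warning("skipping compound-location feature %s in %s",
                               fid, record.id)
                continue
            strand = feature.location.strand
            if strand not in (1, -1):
                logger.warning("skipping strandless feature %s", fid)
                continue
            # Biopython locations are 0-based half-open.
            yield Orf(record.id,
                      int(feature.location.start) + 1,
                      int(feature.location.end),
                      "+" if strand == 1 else "-",
                      source=source, orf_id=fid)


def _genbank_id(feature) -> Optional[str]:
    for key in ("locus_tag", "gene", "protein_id"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return None


def _iter_tsv(path: Path, source: str) -> Iterator[Orf]:
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "contig":
                continue  # header line
            if len(row) < 4:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns "
                    f"(contig, leftmost, rightmost, strand[, id])")
            contig, left, right, strand = (v.strip() for v in row[:4])
            orf_id = row[4].strip() if len(row) > 4 and row[4].strip() else None
            try:
                yield Orf(contig, int(left), int(right), strand,
                          source=source, orf_id=orf_id)
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: {exc}") from exc


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_tsv(pset: PredictionSet, path: str | Path) -> None:
    """Write a PredictionSet as the plain TSV dialect read back by
    :func:`read_annotation`; round-trips all Orf fields exactly."""
    path = Path(path)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for orf in pset:
            writer.writerow([orf.contig, orf.leftmost, orf.rightmost,
                             orf.strand, orf.orf_id or ""])


def write_gff3(pset: PredictionSet, path: str | Path,
               feature_type: str = "CDS") -> None:
    """Write a PredictionSet as minimal GFF3 (one CDS row per ORF)."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for i, orf in enumerate(pset, start=1):
            fid = orf.orf_id or f"{pset.source}_{i:05d}"
            handle.write(f"{orf.contig}\t{pset.source}\t{feature_type}\t"
                         f"{orf.leftmost}\t{orf.rightmost}\t.\t{orf.strand}\t"
                         f"0\tID={fid}\n")


def write_report(morf_table, path: str | Path) -> None:
    """Write the per-mORF report DataFrame as UTF-8 TSV with NA for missing
    values; column order and formatting are bit-stable given equal input."""
    morf_table.to_csv(path, sep="\t", index=False, na_rep="NA",
                      encoding="utf-8", lineterminator="\n")
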