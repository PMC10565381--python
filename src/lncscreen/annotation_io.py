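"""Genomic data model and readers/writers for GTF, FASTA and TSV tables.

Coordinates are 1-based inclusive throughout (GTF convention): a feature on
``chr3:115,636,959-115,641,530`` has a genomic span of
``115641530 - 115636959 + 1 = 4572`` bp.  Strand must be ``+`` or ``-`` for
every transcript because positional classification of lncRNA candidates is
strand-aware; strandless (``.``) transcript features are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree
import pandas as pd
import yaml

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "AnnotationSet",
    "AnnotationFormatError",
    "read_annotation",
    "write_annotation",
    "genome_span",
    "transcript_length",
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "read_sample_config",
    "to_rna",
    "to_dna",
]

STRANDS = ("+", "-")


class AnnotationFormatError(ValueError):
    """Raised for malformed GTF input; carries the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >=1 bp on the same chromosome
        (strand is ignored here; callers decide whether strand matters)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """An exon chain on one chromosome and strand.

    ``annotated`` distinguishes reference transcripts from assembled novel
    ones; only unannotated transcripts are eligible lncRNA candidates.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    annotated: bool = True

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"{self.transcript_id}: exons span multiple chromosomes/strands"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def extent(self) -> GenomicInterval:
        """The genomic footprint from first exon start to last exon end."""
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start - a.end >= 2:
                out.append(
                    GenomicInterval(self.chrom, a.end + 1, b.start - 1, self.strand)
                )
        return tuple(out)


def genome_span(t: TranscriptModel) -> int:
    """Genomic footprint length in bp: last exon end - first exon start + 1."""
    return t.end - t.start + 1


def transcript_length(t: TranscriptModel) -> int:
    """Mature transcript length in nt: the sum of exon lengths."""
    return sum(len(e) for e in t.exons)


class AnnotationSet:
    """A queryable collection of transcripts with a per-chrom interval index."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, list[TranscriptModel]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
            self.genes.setdefault(t.gene_id, []).append(t)
            # half-open tree coordinates internally; API stays 1-based inclusive
            self._trees.setdefault(t.chrom, IntervalTree()).addi(
                t.start, t.end + 1, t.transcript_id
            )

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def query(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[TranscriptModel]:
        """Transcripts whose genomic extent overlaps [start, end] (1-based
        inclusive) on ``chrom``; optionally restricted to one strand."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.transcripts[iv.data] for iv in tree.overlap(start, end + 1)]
        if strand is not None:
            hits = [t for t in hits if t.strand == strand]
        return sorted(hits, key=lambda t: (t.start, t.transcript_id))


def _require_attr(feature, name: str, lineno: int):
    try:
        return feature.attributes[name][0]
    except (KeyError, IndexError):
        raise AnnotationFormatError(
            f"line {lineno}: missing required attribute {name!r}"
        ) from None


def read_annotation(path: str | Path, annotated: bool = True) -> AnnotationSet:
    """Read a GTF file into an :class:`AnnotationSet`.

    Exon features are grouped by ``transcript_id``; any GTF dialect carrying
    ``transcript_id`` and ``gene_id`` attributes is accepted.  Transcripts
    inherit ``annotated`` unless the record carries an ``annotated`` attribute
    ("true"/"false"), which round-trips the novel/reference flag.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    flag_of: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationFormatError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises several parse errors
                raise AnnotationFormatError(f"line {lineno}: {exc}") from None
            if feat.featuretype != "exon":
                continue
            if feat.end < feat.start:
                raise AnnotationFormatError(
                    f"line {lineno}: end ({feat.end}) < start ({feat.start})"
                )
            if feat.strand not in STRANDS:
                raise AnnotationFormatError(
                    f"line {lineno}: transcript exons must be stranded (+/-), "
                    f"got {feat.strand!r}"
                )
            tid = _require_attr(feat, "transcript_id", lineno)
            gid = _require_attr(feat, "gene_id", lineno)
            gene_of.setdefault(tid, gid)
            if "annotated" in feat.attributes:
                flag_of[tid] = feat.attributes["annotated"][0].lower() == "true"
            exons.setdefault(tid, []).append(
                GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
            )
    return AnnotationSet(
        TranscriptModel(
            transcript_id=tid,
            gene_id=gene_of[tid],
            exons=tuple(ivs),
            annotated=flag_of.get(tid, annotated),
        )
        for tid, ivs in exons.items()
    )


def write_annotation(annset: AnnotationSet, path: str | Path) -> None:
    """Write exon records as GTF; lossless on ids, coordinates and strand."""
    with open(path, "w") as fh:
        for t in sorted(annset, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'annotated "{"true" if t.annotated else "false"}";'
                )
                fh.write(
                    f"{e.chrom}\tlncscreen\texon\t{e.start}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


def to_rna(seq: str) -> str:
    """Uppercase and convert to the RNA alphabet (T -> U); lossless."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and convert to the DNA alphabet (U -> T); lossless."""
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{name: uppercased sequence}``.

    Both U and T are accepted and preserved as given (modulo case); duplicate
    record names are an error.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix: one header row, row labels in column 1, numeric body."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any() and not df.isna().any().any():
        bad = body.columns[body.isna().any()].tolist()
        raise ValueError(f"non-numeric cells in matrix columns {bad}")
    if body.isna().any().any():
        raise ValueError("non-numeric or missing cells in matrix")
    return body


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_sample_config(path: str | Path) -> dict[str, dict]:
    """Sidecar YAML mapping sample name -> {group, timepoint}."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("sample config must be a mapping of sample -> metadata")
    return cfg
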