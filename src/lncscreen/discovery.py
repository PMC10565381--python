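"""Candidate lncRNA calling, positional classification and composition summary.

A novel (unannotated) transcript becomes a lncRNA candidate when it is longer
than 200 nt, is multi-exonic, and all four coding-potential predictors
(CPC-, CNCI-, CPAT- and Pfam-style verdicts) agree it is noncoding — the
intersection-of-four consensus.  Candidates are then assigned exactly one of
four positional classes relative to the reference annotation:

sense
    shares >=1 bp of exonic sequence with a same-strand reference transcript.
intronic
    lies entirely within a single intron of a same-strand reference transcript.
antisense
    overlaps a reference gene's genomic extent on the opposite strand.
lincRNA
    intergenic: none of the above.

The classes are tested in that order of precedence, so classification is
total and mutually exclusive.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation_io import AnnotationSet, TranscriptModel, transcript_length

__all__ = [
    "CodingVerdicts",
    "LncRNACandidate",
    "CompositionSummary",
    "VERDICT_TOOLS",
    "POSITIONAL_CLASSES",
    "candidate_filter",
    "consensus_noncoding",
    "classify_position",
    "summarize_composition",
    "three_frame_orf_screen",
    "discover_lncrnas",
]

VERDICT_TOOLS = ("cpc_like", "cnci_like", "cpat_like", "pfam_like")
POSITIONAL_CLASSES = ("lincRNA", "intronic", "antisense", "sense")
_VALID_VERDICTS = frozenset({"coding", "noncoding"})


@dataclass(frozen=True)
class CodingVerdicts:
    """One coding/noncoding call per predictor for a single transcript.

    For the Pfam-style column, "noncoding" means no protein-domain hit.
    """

    cpc_like: str
    cnci_like: str
    cpat_like: str
    pfam_like: str

    def __post_init__(self) -> None:
        for tool in VERDICT_TOOLS:
            v = getattr(self, tool)
            if v not in _VALID_VERDICTS:
                raise ValueError(
                    f"{tool} verdict must be 'coding' or 'noncoding', got {v!r}"
                )

    def as_tuple(self) -> tuple[str, str, str, str]:
        return tuple(getattr(self, t) for t in VERDICT_TOOLS)


@dataclass(frozen=True)
class LncRNACandidate:
    transcript: TranscriptModel
    verdicts: CodingVerdicts
    positional_class: str

    def __post_init__(self) -> None:
        if self.positional_class not in POSITIONAL_CLASSES:
            raise ValueError(f"unknown positional class {self.positional_class!r}")


@dataclass(frozen=True)
class CompositionSummary:
    """Counts and one-decimal percentages per positional class."""

    counts: Mapping[str, int]
    percentages: Mapping[str, float | None]
    total: int


def candidate_filter(
    t: TranscriptModel, min_length: int = 200, min_exons: int = 2
) -> tuple[bool, str]:
    """Apply the structural candidate filters.

    Passes iff the transcript is not in the reference annotation, its mature
    length is strictly greater than ``min_length`` nt, and it has at least
    ``min_exons`` exons.  ``min_exons=2`` is the community multi-exon
    convention; pass 3 for the literal "more than two exons" reading.
    Returns ``(passed, reason)`` where reason names the first failed
    criterion ("annotated", "length", "exons") or is "pass".
    """
    if t.annotated:
        return False, "annotated"
    if transcript_length(t) <= min_length:
        return False, "length"
    if len(t.exons) < min_exons:
        return False, "exons"
    return True, "pass"


def consensus_noncoding(v: CodingVerdicts) -> bool:
    """True iff all four predictors call the transcript noncoding."""
    return all(x == "noncoding" for x in v.as_tuple())


def _exon_exon_overlap(t: TranscriptModel, r: TranscriptModel) -> bool:
    return any(te.overlaps(re_) for te in t.exons for re_ in r.exons)


def classify_position(t: TranscriptModel, ref: AnnotationSet) -> str:
    """Assign one positional class relative to reference transcripts.

    Precedence: sense > intronic > antisense > lincRNA (see module docstring).
    ``ref`` must contain only annotated transcripts.
    """
    same = ref.query(t.chrom, t.start, t.end, strand=t.strand)
    for r in same:
        if _exon_exon_overlap(t, r):
            return "sense"
    for r in same:
        for intron in r.introns():
            if intron.start <= t.start and t.end <= intron.end:
                return "intronic"
    opposite = "-" if t.strand == "+" else "+"
    if ref.query(t.chrom, t.start, t.end, strand=opposite):
        return "antisense"
    return "lincRNA"


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(
        decimal.Decimal(repr(x)).quantize(
            decimal.Decimal("0." + "0" * ndigits), rounding=decimal.ROUND_HALF_UP
        )
    )


def summarize_composition(
    candidates: Iterable[LncRNACandidate | str],
) -> CompositionSummary:
    """Count candidates per positional class and express each as a percentage
    of the total, rounded half-up to one decimal.

    Accepts classified candidates or bare class labels.  On empty input the
    total is 0 and every percentage is None.
    """
    counts = {c: 0 for c in POSITIONAL_CLASSES}
    for c in candidates:
        label = c if isinstance(c, str) else c.positional_class
        if label not in counts:
            raise ValueError(f"unknown positional class {label!r}")
        counts[label] += 1
    total = sum(counts.values())
    if total == 0:
        pct: dict[str, float | None] = {c: None for c in POSITIONAL_CLASSES}
    else:
        pct = {c: _round_half_up(100.0 * n / total) for c, n in counts.items()}
    return CompositionSummary(counts=counts, percentages=pct, total=total)


_STOPS = frozenset({"UAA", "UAG", "UGA"})


def three_frame_orf_screen(
    seq: str, coding_suspect_threshold: int = 300
) -> tuple[tuple[int, int, int], int, bool]:
    """Longest AUG...stop open reading frame per forward frame.

    Scans frames F1/F2/F3 of the given strand and reports the longest ORF in
    each (length in nt, stop codon included; 0 when a frame has none), the
    overall maximum, and a "coding-suspect" flag raised when the maximum is
    at least ``coding_suspect_threshold`` nt.  This is a deliberately
    transparent stand-in for trained coding-potential predictors: a long ORF
    is treated as evidence of coding capacity, nothing more.
    """
    rna = seq.upper().replace("T", "U")
    if len(rna) < 3:
        raise ValueError("sequence must be >= 3 nt")
    extra = set(rna) - set("ACGU")
    if extra:
        raise ValueError(f"ambiguity codes not supported: {sorted(extra)}")
    per_frame = []
    for frame in range(3):
        codons = [rna[i : i + 3] for i in range(frame, len(rna) - 2, 3)]
        best = 0
        open_from: int | None = None
        for ci, codon in enumerate(codons):
            if open_from is None and codon == "AUG":
                open_from = ci
            elif open_from is not None and codon in _STOPS:
                best = max(best, (ci - open_from + 1) * 3)
                open_from = None
        per_frame.append(best)
    lengths = tuple(per_frame)
    longest = max(lengths)
    return lengths, longest, longest >= coding_suspect_threshold


def discover_lncrnas(
    novel: Iterable[TranscriptModel],
    verdicts: Mapping[str, CodingVerdicts],
    ref: AnnotationSet,
    min_length: int = 200,
    min_exons: int = 2,
) -> tuple[list[LncRNACandidate], dict[str, str], list[str]]:
    """Run filter -> consensus -> classification over novel transcripts.

    Returns ``(candidates, rejected, missing_verdicts)``: classified
    candidates, a map of rejected transcript_id -> reason, and the ids that
    had no complete verdict set (reported separately, never silently
    dropped).
    """
    candidates: list[LncRNACandidate] = []
    rejected: dict[str, str] = {}
    missing: list[str] = []
    for t in novel:
        ok, reason = candidate_filter(t, min_length=min_length, min_exons=min_exons)
        if not ok:
            rejected[t.transcript_id] = reason
            continue
        v = verdicts.get(t.transcript_id)
        if v is None:
            missing.append(t.transcript_id)
            continue
        if not consensus_noncoding(v):
            rejected[t.transcript_id] = "coding"
            continue
        candidates.append(
            LncRNACandidate(
                transcript=t,
                verdicts=v,
                positional_class=classify_position(t, ref),
            )
        )
    return candidates, rejected, missing
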