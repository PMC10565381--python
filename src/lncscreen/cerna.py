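"""miRNA seed-site scanning and ceRNA (miRNA-sponge) candidate discovery.

Matching uses the canonical TargetScan-style seed-site classes on the target
sense strand (5'->3'), strict Watson-Crick only (no G:U wobble):

========  =====================================  ======
type      target site (5'->3')                   length
========  =====================================  ======
8mer      revcomp(miRNA 2-8) + A                 8
7mer-m8   revcomp(miRNA 2-8)                     7
7mer-A1   revcomp(miRNA 2-7) + A                 7
6mer      revcomp(miRNA 2-7)                     6
========  =====================================  ======

Every site is anchored at its 6-nt seed-match core (the revcomp of miRNA
positions 2-7); at one core locus only the highest-priority type is
reported (8mer > 7mer-m8 > 7mer-A1 > 6mer), while distinct core loci may
overlap one another.  A sponge candidate is a miRNA with sites on both a
lncRNA and an mRNA 3'UTR — the shared-site intersection that makes
competitive binding possible.  This transparent matcher replaces trained
target predictors deliberately: every reported site is verifiable by direct
string complementarity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation_io import to_rna

__all__ = [
    "MicroRNA",
    "SeedSite",
    "SpongeCandidate",
    "SITE_TYPES",
    "seed_region",
    "find_seed_sites",
    "shared_sponging_mirnas",
    "delete_sites",
    "reverse_complement",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")  # descending priority
SITE_LENGTHS = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(rna: str) -> str:
    """Reverse complement in RNA space (A-U, G-C)."""
    return rna.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MicroRNA:
    """A mature miRNA; positions are 1-based from the 5' end."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = to_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 18:
            raise ValueError(f"{self.name}: mature miRNA must be >= 18 nt")
        extra = set(seq) - set("ACGU")
        if extra:
            raise ValueError(f"{self.name}: non-ACGU characters {sorted(extra)}")


@dataclass(frozen=True)
class SeedSite:
    """One seed-complementary locus on a target, 1-based inclusive."""

    target: str
    start: int
    end: int
    site_type: str
    mirna: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start + 1 != SITE_LENGTHS[self.site_type]:
            raise ValueError(
                f"{self.site_type} span must be {SITE_LENGTHS[self.site_type]} nt"
            )


@dataclass(frozen=True)
class SpongeCandidate:
    mirna: MicroRNA
    sites_on_lncrna: tuple[SeedSite, ...]
    sites_on_utr: tuple[SeedSite, ...]


def seed_region(m: MicroRNA, span: str = "2-8") -> str:
    """The seed subsequence at 1-based miRNA positions 2-7 or 2-8, 5'->3'."""
    if span not in ("2-7", "2-8"):
        raise ValueError("span must be '2-7' or '2-8'")
    hi = 7 if span == "2-7" else 8
    if len(m.sequence) < 8:
        raise ValueError(f"{m.name}: sequence too short for a seed ({hi} nt needed)")
    return m.sequence[1:hi]


def find_seed_sites(target: str, m: MicroRNA) -> list[SeedSite]:
    """All classified seed-match sites of ``m`` on ``target``.

    The target may be DNA or RNA; matching runs in RNA space and positions
    refer to the given sequence 1-based.  Sites are returned sorted by start.
    """
    seq = to_rna(target)
    if len(seq) < 6:
        raise ValueError("target must be >= 6 nt")
    core = reverse_complement(seed_region(m, "2-7"))  # 6 nt
    m8 = reverse_complement(seed_region(m, "2-8"))[0]  # complement of miRNA pos 8
    sites: list[SeedSite] = []
    i = seq.find(core)
    while i != -1:
        has_m8 = i >= 1 and seq[i - 1] == m8
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            site_type, start, end = "8mer", i - 1, i + 6
        elif has_m8:
            site_type, start, end = "7mer-m8", i - 1, i + 5
        elif has_a1:
            site_type, start, end = "7mer-A1", i, i + 6
        else:
            site_type, start, end = "6mer", i, i + 5
        sites.append(
            SeedSite(
                target="target",
                start=start + 1,
                end=end + 1,
                site_type=site_type,
                mirna=m.name,
            )
        )
        i = seq.find(core, i + 1)
    return sorted(sites, key=lambda s: s.start)


def shared_sponging_mirnas(
    lnc: str,
    utr: str,
    panel: list[MicroRNA],
    min_sites: int = 1,
    lnc_name: str = "lncRNA",
    utr_name: str = "3putr",
) -> tuple[list[SpongeCandidate], dict[str, int]]:
    """miRNAs with >= ``min_sites`` seed sites on BOTH targets.

    Returns the candidates and Venn counts over the panel:
    ``{"lnc_only": ., "utr_only": ., "both": .}``.
    """
    candidates: list[SpongeCandidate] = []
    venn = {"lnc_only": 0, "utr_only": 0, "both": 0}
    for m in panel:
        on_lnc = tuple(
            SeedSite(lnc_name, s.start, s.end, s.site_type, s.mirna)
            for s in find_seed_sites(lnc, m)
        )
        on_utr = tuple(
            SeedSite(utr_name, s.start, s.end, s.site_type, s.mirna)
            for s in find_seed_sites(utr, m)
        )
        hit_lnc = len(on_lnc) >= min_sites
        hit_utr = len(on_utr) >= min_sites
        if hit_lnc and hit_utr:
            venn["both"] += 1
            candidates.append(SpongeCandidate(m, on_lnc, on_utr))
        elif hit_lnc:
            venn["lnc_only"] += 1
        elif hit_utr:
            venn["utr_only"] += 1
    return candidates, venn


def delete_sites(
    seq: str, sites: list[SeedSite]
) -> tuple[str, dict[int, int | None]]:
    """Excise site spans from ``seq``; mirror of a binding-site-deletion
    reporter construct.

    Returns the mutant sequence and a map from each original 1-based
    position to its new position (None for excised bases).  Sites must lie
    within the sequence and be mutually non-overlapping.
    """
    spans = sorted((s.start, s.end) for s in sites)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping sites: {s1}-{e1} and {s2}-{e2}")
    for s, e in spans:
        if s < 1 or e > len(seq):
            raise ValueError(f"site {s}-{e} outside sequence of length {len(seq)}")
    deleted = set()
    for s, e in spans:
        deleted.update(range(s, e + 1))
    out = []
    coord_map: dict[int, int | None] = {}
    new_pos = 0
    for pos in range(1, len(seq) + 1):
        if pos in deleted:
            coord_map[pos] = None
        else:
            new_pos += 1
            out.append(seq[pos - 1])
            coord_map[pos] = new_pos
    return "".join(out), coord_map


def audit_mutant(
    mutant: str,
    m: MicroRNA,
    coord_map: dict[int, int | None],
    deleted_sites: list[SeedSite],
) -> tuple[list[SeedSite], list[SeedSite]]:
    """Re-scan a deletion mutant and split remaining sites into those that
    survive away from the deletions versus junction-created sites whose
    mapped-back span overlaps a deleted span (reported with a warning by
    callers)."""
    inverse = {v: k for k, v in coord_map.items() if v is not None}
    deleted_spans = [(s.start, s.end) for s in deleted_sites]
    away, junction = [], []
    for site in find_seed_sites(mutant, m):
        old_start = inverse[site.start]
        old_end = inverse[site.end]
        # a junction site straddles excised bases: its original footprint is
        # wider than its length or touches a deleted span boundary
        straddles = (old_end - old_start + 1) != (site.end - site.start + 1) or any(
            old_start <= e and s <= old_end for s, e in deleted_spans
        )
        (junction if straddles else away).append(site)
    return away, junction


__all__.append("audit_mutant")
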