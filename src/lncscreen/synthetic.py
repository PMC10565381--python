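"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the statistical structure the corresponding analysis
assumes — not real genome content:

* :func:`gen_annotation` lays out reference genes on a toy chromosome and
  plants novel transcripts whose positional class (lincRNA / intronic /
  antisense / sense) is known by construction, plus transcripts built to
  fail the structural candidate filters.
* :func:`gen_timecourse_counts` draws negative-binomial counts for an
  LPS-style time course (0/2/8/24 h, n=3 per point), with planted
  fold-change profiles and one designated lncRNA whose induction peaks at
  2 h.
* :func:`gen_ko_screen_data` builds WT/KO x 0h/4h FPKM and count tables in
  which background genes have induction ratios near 1, a planted set of
  regulated genes (default 53) violates both ratio criteria strongly, split
  across three expression-profile archetypes, and a low-count stratum sits
  below the read cutoff in every group.
* :func:`gen_cerna_panel` writes a lncRNA, a 3'UTR and a miRNA panel with
  seed sites planted at recorded coordinates; six panel members bind both
  targets and the featured one carries two sites on each.

Every generator returns a :class:`TruthTable` and is byte-deterministic for
a fixed seed.  The negative binomial is parameterized as (mean ``mu``,
dispersion ``alpha``) with variance ``mu + alpha * mu**2``; dispersion 0
degenerates to Poisson.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import (
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    write_annotation,
    write_fasta,
    write_table,
)
from .cerna import MicroRNA, find_seed_sites, reverse_complement, seed_region
from .discovery import POSITIONAL_CLASSES

__all__ = [
    "GeneratorConfig",
    "TruthTable",
    "nb_counts",
    "gen_annotation",
    "gen_timecourse_counts",
    "gen_ko_screen_data",
    "gen_cerna_panel",
    "generate_workspace",
]

TIMEPOINTS = (0, 2, 8, 24)
KO_GROUPS = ("WT0h", "WT4h", "KO0h", "KO4h")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generators, with study-like defaults."""

    seed: int = 20369
    # annotation
    n_ref_genes: int = 20
    n_novel_per_class: int = 4
    chrom: str = "chrS"
    # time course
    n_genes: int = 2000
    n_rep: int = 3
    n_de: int = 100
    de_log2fc: float = 4.0
    dispersion: float = 0.05
    peak_gene: str = "lnc_peak2h"
    peak_profile: tuple[float, ...] = (1.0, 16.0, 4.0, 2.0)
    # KO screen
    n_background: int = 5000
    n_planted_regulated: int = 53
    n_lowcount: int = 200
    fpkm_noise_sd: float = 0.05
    # ceRNA
    panel_size: int = 10
    n_dual_binders: int = 6
    featured_sites_per_target: int = 2
    lnc_length: int = 1000
    utr_length: int = 600

    def __post_init__(self) -> None:
        ints = (
            self.n_ref_genes,
            self.n_novel_per_class,
            self.n_genes,
            self.n_rep,
            self.n_de,
            self.n_background,
            self.n_planted_regulated,
            self.n_lowcount,
            self.panel_size,
            self.n_dual_binders,
            self.featured_sites_per_target,
        )
        if any(v < 0 for v in ints):
            raise ValueError("counts must be >= 0")
        if self.n_dual_binders > self.panel_size:
            raise ValueError("n_dual_binders cannot exceed panel_size")


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside each synthetic dataset."""

    kind: str
    seed: int
    params: dict
    units: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with variance ``mean + dispersion * mean**2``."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------- annotation


def _ref_gene(chrom: str, gene_idx: int, origin: int, strand: str) -> TranscriptModel:
    # three 400-nt exons with 1400-nt introns -> extent 4000 bp
    exons = tuple(
        GenomicInterval(chrom, origin + k * 1800, origin + k * 1800 + 399, strand)
        for k in range(3)
    )
    gid = f"refgene_{gene_idx}"
    return TranscriptModel(f"{gid}.t1", gid, exons, annotated=True)


def gen_annotation(
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[AnnotationSet, AnnotationSet, TruthTable]:
    """Reference + novel annotation with planted positional classes.

    Returns ``(reference, novel, truth)``.  Truth records per novel
    transcript: ``true_class`` (or None for filter-failures),
    ``passes_filter`` and the failing reason.
    """
    rng = np.random.default_rng(cfg.seed)
    slot = 50_000  # bp between gene origins; gaps host lincRNAs
    need = cfg.n_novel_per_class * 3 + 2  # host genes + spare
    if cfg.n_ref_genes < need:
        raise ValueError(
            f"chromosome layout needs >= {need} reference genes for "
            f"{cfg.n_novel_per_class} novel transcripts per class"
        )
    refs = []
    for i in range(cfg.n_ref_genes):
        strand = "+" if i % 2 == 0 else "-"
        refs.append(_ref_gene(cfg.chrom, i, 10_000 + i * slot, strand))
    reference = AnnotationSet(refs)

    novel: list[TranscriptModel] = []
    truth_units: dict[str, dict] = {}

    def add(tid: str, exons, true_class, passes=True, reason="pass"):
        t = TranscriptModel(tid, f"novelgene_{tid}", tuple(exons), annotated=False)
        novel.append(t)
        truth_units[tid] = {
            "true_class": true_class,
            "passes_filter": passes,
            "reason": reason,
        }

    host_iter = iter(refs)
    for j in range(cfg.n_novel_per_class):
        # lincRNA: centred in the intergenic gap after gene 2j
        gap_start = refs[2 * j].end + 10_000
        strand = "+" if rng.integers(2) == 0 else "-"
        add(
            f"novel_linc_{j}",
            [
                GenomicInterval(cfg.chrom, gap_start, gap_start + 149, strand),
                GenomicInterval(cfg.chrom, gap_start + 400, gap_start + 549, strand),
            ],
            "lincRNA",
        )
    for j in range(cfg.n_novel_per_class):
        # intronic: entirely inside intron 1 of a host gene, same strand
        host = next(host_iter)
        intron = host.introns()[0]
        s = intron.start + 100
        add(
            f"novel_intronic_{j}",
            [
                GenomicInterval(cfg.chrom, s, s + 139, host.strand),
                GenomicInterval(cfg.chrom, s + 300, s + 439, host.strand),
            ],
            "intronic",
        )
    for j in range(cfg.n_novel_per_class):
        # antisense: opposite strand, overlapping the host's extent
        host = next(host_iter)
        anti = "-" if host.strand == "+" else "+"
        s = host.start + 200
        add(
            f"novel_antisense_{j}",
            [
                GenomicInterval(cfg.chrom, s, s + 199, anti),
                GenomicInterval(cfg.chrom, s + 500, s + 649, anti),
            ],
            "antisense",
        )
    for j in range(cfg.n_novel_per_class):
        # sense: same strand, first exon overlaps the host's first exon
        host = next(host_iter)
        s = host.exons[0].start + 100
        add(
            f"novel_sense_{j}",
            [
                GenomicInterval(cfg.chrom, s, s + 199, host.strand),
                GenomicInterval(cfg.chrom, s + 500, s + 649, host.strand),
            ],
            "sense",
        )
    # filter failures: too short, and single-exon
    tail = refs[-1].end + 20_000
    add(
        "novel_short",
        [
            GenomicInterval(cfg.chrom, tail, tail + 69, "+"),
            GenomicInterval(cfg.chrom, tail + 200, tail + 279, "+"),
        ],
        None,
        passes=False,
        reason="length",
    )
    add(
        "novel_monoexon",
        [GenomicInterval(cfg.chrom, tail + 1000, tail + 1299, "+")],
        None,
        passes=False,
        reason="exons",
    )

    truth = TruthTable(
        kind="annotation",
        seed=cfg.seed,
        params={
            "n_ref_genes": cfg.n_ref_genes,
            "n_novel_per_class": cfg.n_novel_per_class,
            "classes": list(POSITIONAL_CLASSES),
        },
        units=truth_units,
    )
    return reference, AnnotationSet(novel), truth


# -------------------------------------------------------------- time course


def gen_timecourse_counts(
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[pd.DataFrame, pd.Series, TruthTable]:
    """NB counts for the 0/2/8/24 h design with planted fold profiles.

    Returns ``(counts, lengths, truth)``.  Columns are ``t{h}_r{i}``.  The
    designated peak gene follows ``cfg.peak_profile`` (defaults to a strong
    2 h spike); ``cfg.n_de`` other genes get a +/- ``cfg.de_log2fc`` shift at
    one random non-zero timepoint; the rest are flat.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [cfg.peak_gene] + [f"gene_{i}" for i in range(cfg.n_genes - 1)]
    baseline = np.exp(rng.normal(np.log(100.0), 1.0, size=cfg.n_genes))
    profiles = np.ones((cfg.n_genes, len(TIMEPOINTS)))
    profiles[0] = np.asarray(cfg.peak_profile)
    truth_units = {
        cfg.peak_gene: {
            "role": "peak2h",
            "profile_fold": list(cfg.peak_profile),
        }
    }
    de_rows = 1 + rng.choice(
        cfg.n_genes - 1, size=min(cfg.n_de, cfg.n_genes - 1), replace=False
    )
    for row in de_rows:
        tp = int(rng.integers(1, len(TIMEPOINTS)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        fold = 2.0 ** (sign * cfg.de_log2fc)
        profiles[row, tp] = fold
        truth_units[genes[row]] = {
            "role": "planted_de",
            "timepoint_h": TIMEPOINTS[tp],
            "true_log2fc": sign * cfg.de_log2fc,
        }
    cols, blocks = [], []
    for tp_idx, tp in enumerate(TIMEPOINTS):
        mu = baseline * profiles[:, tp_idx]
        for rep in range(cfg.n_rep):
            cols.append(f"t{tp}_r{rep + 1}")
            blocks.append(nb_counts(rng, mu, cfg.dispersion))
    counts = pd.DataFrame(np.column_stack(blocks), index=genes, columns=cols)
    lengths = pd.Series(1000, index=genes, name="length")
    truth = TruthTable(
        kind="timecourse",
        seed=cfg.seed,
        params={
            "timepoints_h": list(TIMEPOINTS),
            "n_rep": cfg.n_rep,
            "n_genes": cfg.n_genes,
            "n_de": len(de_rows),
            "de_log2fc": cfg.de_log2fc,
            "dispersion": cfg.dispersion,
        },
        units=truth_units,
    )
    return counts, lengths, truth


# ---------------------------------------------------------------- KO screen

# archetype -> multipliers of the per-gene base level b for (WT0,WT4,KO0,KO4).
# All three violate both ratio criteria with >= 4x / <= 0.25 margins:
#   I  : KO hyper-induced       r_diff = 8,  r_fc = 17/3 = 5.67
#   II : KO repressed by LPS    r_diff = -1, r_fc = (2/4)/3 = 0.167
#   III: WT-induced, KO flat    r_diff = 0,  r_fc = 1/5 = 0.2
_ARCHETYPES = {
    "I": (1.0, 3.0, 1.0, 17.0),
    "II": (1.0, 3.0, 4.0, 2.0),
    "III": (1.0, 5.0, 1.0, 1.0),
}


def gen_ko_screen_data(
    cfg: GeneratorConfig = GeneratorConfig(), noise_sd: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """WT/KO x 0h/4h per-replicate FPKM and counts with a planted screen.

    Background genes are built so both induction ratios land in
    [0.8, 1.25]; regulated genes follow one of three archetype profiles with
    ratios beyond 4x or under 0.25; a low-count stratum falls below 5 reads
    in every group.  ``noise_sd`` (default ``cfg.fpkm_noise_sd``) is the sd
    of multiplicative log-normal replicate noise; pass 0 for noise-free
    tables.  Transcript length is fixed at 1 kb and depth at 1e6 fragments,
    so one normalized count equals one FPKM unit.

    Returns ``(fpkm, counts, truth)`` with columns ``{group}_r{i}``.
    """
    rng = np.random.default_rng(cfg.seed)
    sd = cfg.fpkm_noise_sd if noise_sd is None else noise_sd

    names: list[str] = []
    group_means: list[tuple[float, float, float, float]] = []
    truth_units: dict[str, dict] = {}

    for i in range(cfg.n_background):
        b = float(rng.uniform(5.0, 50.0))
        f = float(rng.uniform(1.5, 4.0))  # WT induction fold
        rho = float(rng.uniform(0.8, 1.25))  # planted r_diff
        wt0, wt4 = b, b * f
        ko0 = wt0
        ko4 = ko0 + rho * (wt4 - wt0)
        names.append(f"bg_{i}")
        group_means.append((wt0, wt4, ko0, ko4))
        truth_units[f"bg_{i}"] = {"role": "background", "regulated": False}

    classes = sorted(_ARCHETYPES)
    for i in range(cfg.n_planted_regulated):
        cls = classes[i % len(classes)]
        mult = _ARCHETYPES[cls]
        b = float(rng.uniform(5.0, 50.0))
        names.append(f"reg_{cls}_{i}")
        group_means.append(tuple(b * m for m in mult))
        truth_units[f"reg_{cls}_{i}"] = {
            "role": "regulated",
            "regulated": True,
            "true_class": cls,
        }

    for i in range(cfg.n_lowcount):
        names.append(f"low_{i}")
        group_means.append((1.0, 1.0, 1.0, 1.0))
        truth_units[f"low_{i}"] = {"role": "lowcount", "regulated": False}

    cols = [f"{g}_r{r + 1}" for g in KO_GROUPS for r in range(cfg.n_rep)]
    mean_arr = np.asarray(group_means)  # genes x 4
    reps = np.repeat(mean_arr, cfg.n_rep, axis=1)  # genes x 12
    if sd > 0:
        reps = reps * np.exp(rng.normal(0.0, sd, size=reps.shape))
    fpkm = pd.DataFrame(reps, index=names, columns=cols)
    # 1 kb transcripts at 1e6 depth: one count per FPKM unit per replicate
    counts = pd.DataFrame(
        np.floor(reps).astype(int), index=names, columns=cols
    )
    truth = TruthTable(
        kind="ko_screen",
        seed=cfg.seed,
        params={
            "n_background": cfg.n_background,
            "n_planted_regulated": cfg.n_planted_regulated,
            "n_lowcount": cfg.n_lowcount,
            "noise_sd": sd,
            "n_rep": cfg.n_rep,
            "archetypes": {k: list(v) for k, v in _ARCHETYPES.items()},
        },
        units=truth_units,
    )
    return fpkm, counts, truth


# -------------------------------------------------------------------- ceRNA

_BASES = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n))


def _site_string(m: MicroRNA) -> str:
    """The 8mer site text for a miRNA: revcomp(seed 2-8) + A anchor."""
    return reverse_complement(seed_region(m, "2-8")) + "A"


def _scrub_accidental(
    seq: list[str],
    cores: dict[str, str],
    protected: set[int],
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> None:
    """Re-randomize bases (outside ``protected`` 0-based positions) until no
    miRNA core occurs off-plant.  Mutates ``seq`` in place."""
    for _ in range(max_rounds):
        dirty = False
        text = "".join(seq)
        for core in cores.values():
            i = text.find(core)
            while i != -1:
                span = set(range(i, i + len(core)))
                if not span <= protected:
                    editable = sorted(span - protected)
                    pos = int(editable[len(editable) // 2])
                    choices = [b for b in "ACGU" if b != seq[pos]]
                    seq[pos] = choices[int(rng.integers(len(choices)))]
                    dirty = True
                i = text.find(core, i + 1)
        if not dirty:
            return
    raise RuntimeError("could not scrub accidental seed matches")


def _plant(seq: list[str], pos0: int, text: str, protected: set[int]) -> None:
    seq[pos0 : pos0 + len(text)] = list(text)
    protected.update(range(pos0, pos0 + len(text)))


def gen_cerna_panel(
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[dict[str, str], list[MicroRNA], TruthTable]:
    """Random lncRNA + 3'UTR sequences and a miRNA panel with planted sites.

    Panel members 1..n_dual_binders bind both targets (8mer sites); the
    first ("featured") carries ``cfg.featured_sites_per_target`` sites on
    each.  Of the rest, half get a site on the lncRNA only and the others
    bind neither.  Backgrounds are scrubbed of accidental seed cores before
    planting, and the truth table records the post-hoc audited site lists so
    recovery checks always compare against what is really present.

    Returns ``({"lncRNA": seq, "utr": seq}, panel, truth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.panel_size < cfg.n_dual_binders:
        raise ValueError("panel smaller than requested dual binders")

    panel: list[MicroRNA] = []
    cores: dict[str, str] = {}
    sites: dict[str, str] = {}
    while len(panel) < cfg.panel_size:
        seq = "".join(_random_rna(rng, 22))
        m = MicroRNA(f"synmiR-{len(panel) + 1}", seq)
        core = reverse_complement(seed_region(m, "2-7"))
        site = _site_string(m)
        # a panel member's core must not hide inside another's planted site,
        # and its own site text must anchor its core exactly once
        if any(core in s for s in sites.values()) or any(
            c in site for c in cores.values()
        ):
            continue
        if core in cores.values() or site.count(core) != 1:
            continue
        panel.append(m)
        cores[m.name] = core
        sites[m.name] = site

    n_sites_needed = {"lncRNA": {}, "utr": {}}
    featured = panel[0].name
    for idx, m in enumerate(panel):
        if idx == 0:
            n_sites_needed["lncRNA"][m.name] = cfg.featured_sites_per_target
            n_sites_needed["utr"][m.name] = cfg.featured_sites_per_target
        elif idx < cfg.n_dual_binders:
            n_sites_needed["lncRNA"][m.name] = 1
            n_sites_needed["utr"][m.name] = 1
        elif idx < cfg.n_dual_binders + (cfg.panel_size - cfg.n_dual_binders) // 2:
            n_sites_needed["lncRNA"][m.name] = 1  # single-target binder

    lengths = {"lncRNA": cfg.lnc_length, "utr": cfg.utr_length}
    seqs: dict[str, str] = {}
    truth_sites: dict[str, dict[str, list[dict]]] = {"lncRNA": {}, "utr": {}}
    for tgt, L in lengths.items():
        total = sum(n_sites_needed[tgt].values())
        if total * 30 > L:
            raise ValueError(f"{tgt} too short for {total} planted sites")
        seq = _random_rna(rng, L)
        protected: set[int] = set()
        # evenly spaced, non-adjacent slots
        slots = iter(np.linspace(10, L - 20, num=max(total, 1), dtype=int))
        for mname, k in n_sites_needed[tgt].items():
            for _ in range(k):
                pos0 = int(next(slots))
                _plant(seq, pos0, sites[mname], protected)
                truth_sites[tgt].setdefault(mname, []).append(
                    {
                        "start": pos0 + 1,
                        "end": pos0 + len(sites[mname]),
                        "site_type": "8mer",
                    }
                )
        _scrub_accidental(seq, cores, protected, rng)
        seqs[tgt] = "".join(seq)

    # post-hoc audit: what the matcher really finds, per panel member
    audited: dict[str, dict[str, list[dict]]] = {"lncRNA": {}, "utr": {}}
    for tgt, s in seqs.items():
        for m in panel:
            found = find_seed_sites(s, m)
            if found:
                audited[tgt][m.name] = [
                    {"start": x.start, "end": x.end, "site_type": x.site_type}
                    for x in found
                ]
    dual = sorted(set(audited["lncRNA"]) & set(audited["utr"]))

    truth = TruthTable(
        kind="cerna",
        seed=cfg.seed,
        params={
            "panel_size": cfg.panel_size,
            "n_dual_binders": cfg.n_dual_binders,
            "featured": featured,
            "featured_sites_per_target": cfg.featured_sites_per_target,
        },
        units={
            "planted_sites": truth_sites,
            "audited_sites": audited,
            "dual_binders": dual,
            "panel": {m.name: m.sequence for m in panel},
        },
    )
    return seqs, panel, truth


# ---------------------------------------------------------------- workspace


def generate_workspace(outdir: str | Path, cfg: GeneratorConfig = GeneratorConfig()):
    """Write a complete demo workspace: GTFs, verdicts, matrices, FASTAs,
    sample configs and truth JSONs.  Returns the paths written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    reference, novel, ann_truth = gen_annotation(cfg)
    paths["reference_gtf"] = out / "reference.gtf"
    paths["novel_gtf"] = out / "novel.gtf"
    write_annotation(reference, paths["reference_gtf"])
    write_annotation(novel, paths["novel_gtf"])
    ann_truth.to_json(out / "truth_annotation.json")
    # all structurally passing novels get unanimous noncoding verdicts
    verdicts = pd.DataFrame(
        {
            tool: ["noncoding"] * len(novel.transcripts)
            for tool in ("cpc_like", "cnci_like", "cpat_like", "pfam_like")
        },
        index=list(novel.transcripts),
    )
    verdicts.index.name = "transcript_id"
    paths["verdicts"] = out / "verdicts.tsv"
    verdicts.to_csv(paths["verdicts"], sep="\t")

    counts, lengths, tc_truth = gen_timecourse_counts(cfg)
    paths["timecourse_counts"] = out / "timecourse_counts.tsv"
    write_table(counts, paths["timecourse_counts"])
    lengths.to_frame().to_csv(out / "lengths.tsv", sep="\t")
    paths["lengths"] = out / "lengths.tsv"
    tc_truth.to_json(out / "truth_timecourse.json")

    fpkm, ko_counts, ko_truth = gen_ko_screen_data(cfg)
    paths["ko_fpkm"] = out / "ko_fpkm.tsv"
    paths["ko_counts"] = out / "ko_counts.tsv"
    write_table(fpkm, paths["ko_fpkm"])
    write_table(ko_counts, paths["ko_counts"])
    ko_truth.to_json(out / "truth_ko_screen.json")

    seqs, panel, ce_truth = gen_cerna_panel(cfg)
    paths["targets_fasta"] = out / "targets.fasta"
    write_fasta(seqs, paths["targets_fasta"])
    paths["panel_fasta"] = out / "mirna_panel.fasta"
    write_fasta({m.name: m.sequence for m in panel}, paths["panel_fasta"])
    ce_truth.to_json(out / "truth_cerna.json")

    for t in ("annotation", "timecourse", "ko_screen", "cerna"):
        paths[f"truth_{t}"] = out / f"truth_{t}.json"
    return paths
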