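"""End-to-end orchestration: discover -> DE -> screen -> ceRNA.

Stages communicate only through files (GTF/TSV/FASTA/JSON), so any stage's
input can be swapped for an externally produced table — e.g. a DESeq2
results table can replace the built-in differential-expression stand-in.
A run writes each stage's artifacts before the next stage starts and ends
with a ``report.json`` whose counts equal the counts in the emitted tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation_io import (
    read_annotation,
    read_fasta,
    read_table,
    write_table,
)
from .cerna import MicroRNA, shared_sponging_mirnas
from .diffexpr import DEConfig, cluster_transform, compute_fpkm, de_table
from .discovery import (
    CodingVerdicts,
    VERDICT_TOOLS,
    discover_lncrnas,
    summarize_composition,
)
from .ko_screen import GROUPS, ScreenConfig, ScreenRecord, run_screen
from .synthetic import GeneratorConfig, TIMEPOINTS, generate_workspace

log = logging.getLogger("lncscreen")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_run_config"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: Path
    workdir: Path | None = None  # input workspace; generated when synthetic
    seed: int = 20369
    synthetic: bool = True
    stages: tuple[str, ...] = ("discover", "de", "screen", "cerna")
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    de_config: DEConfig = field(default_factory=lambda: DEConfig(lfc_threshold=2.0))
    screen_config: ScreenConfig = field(default_factory=ScreenConfig)
    min_sites: int = 1

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "workdir": str(self.workdir) if self.workdir else None,
            "seed": self.seed,
            "synthetic": self.synthetic,
            "stages": list(self.stages),
            "generator": vars(self.generator) | {},
            "de_config": vars(self.de_config) | {},
            "screen_config": vars(self.screen_config) | {},
            "min_sites": self.min_sites,
        }


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("outdir", "workdir"):
        if key in raw:
            kwargs[key] = Path(raw.pop(key))
    for key in ("seed", "synthetic", "min_sites"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if "stages" in raw:
        kwargs["stages"] = tuple(raw.pop("stages"))
    if "generator" in raw:
        kwargs["generator"] = GeneratorConfig(**raw.pop("generator"))
    if "de_config" in raw:
        kwargs["de_config"] = DEConfig(**raw.pop("de_config"))
    if "screen_config" in raw:
        kwargs["screen_config"] = ScreenConfig(**raw.pop("screen_config"))
    if raw:
        raise PipelineError(f"config: unknown keys {sorted(raw)}")
    if "outdir" not in kwargs:
        raise PipelineError("config: 'outdir' is required")
    return RunConfig(**kwargs)


_STAGE_INPUTS = {
    "discover": ("reference.gtf", "novel.gtf", "verdicts.tsv"),
    "de": ("timecourse_counts.tsv", "lengths.tsv"),
    "screen": ("ko_fpkm.tsv", "ko_counts.tsv"),
    "cerna": ("targets.fasta", "mirna_panel.fasta"),
}


def _preflight(cfg: RunConfig) -> Path:
    if cfg.synthetic:
        return Path(cfg.outdir) / "workspace"
    if cfg.workdir is None:
        raise PipelineError("pre-flight: workdir required when synthetic=false")
    work = Path(cfg.workdir)
    missing = [
        f
        for stage in cfg.stages
        for f in _STAGE_INPUTS.get(stage, ())
        if not (work / f).exists()
    ]
    if missing:
        raise PipelineError(f"pre-flight: missing inputs {missing} in {work}")
    return work


def _read_verdicts(path: Path) -> dict[str, CodingVerdicts]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing_cols = set(VERDICT_TOOLS) - set(df.columns)
    if missing_cols:
        raise PipelineError(f"discover: verdict table lacks columns {missing_cols}")
    out = {}
    for tid, row in df.iterrows():
        out[str(tid)] = CodingVerdicts(**{t: row[t] for t in VERDICT_TOOLS})
    return out


def _stage_discover(cfg: RunConfig, work: Path, out: Path) -> dict:
    ref = read_annotation(work / "reference.gtf", annotated=True)
    novel = read_annotation(work / "novel.gtf", annotated=False)
    verdicts = _read_verdicts(work / "verdicts.tsv")
    candidates, rejected, missing = discover_lncrnas(list(novel), verdicts, ref)
    comp = summarize_composition(candidates)
    from .annotation_io import transcript_length

    table = pd.DataFrame(
        [
            {
                "transcript_id": c.transcript.transcript_id,
                "length_nt": transcript_length(c.transcript),
                "n_exons": len(c.transcript.exons),
                "class": c.positional_class,
                **dict(zip(VERDICT_TOOLS, c.verdicts.as_tuple())),
            }
            for c in candidates
        ]
    )
    table.to_csv(out / "lncrna_candidates.tsv", sep="\t", index=False)
    with open(out / "composition.json", "w") as fh:
        json.dump(
            {
                "counts": dict(comp.counts),
                "percentages": dict(comp.percentages),
                "total": comp.total,
            },
            fh,
            indent=1,
        )
    return {
        "novel_in": len(novel),
        "candidates": comp.total,
        "rejected": len(rejected),
        "missing_verdicts": len(missing),
        "composition": dict(comp.counts),
    }


def _stage_de(cfg: RunConfig, work: Path, out: Path) -> dict:
    counts = read_table(work / "timecourse_counts.tsv")
    lengths = read_table(work / "lengths.tsv").iloc[:, 0]
    fpkm = compute_fpkm(counts, lengths)
    write_table(fpkm, out / "timecourse_fpkm.tsv")
    base_cols = [c for c in counts.columns if c.startswith(f"t{TIMEPOINTS[0]}_")]
    de_counts = {}
    frames = []
    for tp in TIMEPOINTS[1:]:
        cols = [c for c in counts.columns if c.startswith(f"t{tp}_")]
        res = de_table(counts, base_cols, cols, cfg.de_config)
        res.insert(0, "contrast", f"t{tp}_vs_t{TIMEPOINTS[0]}")
        frames.append(res)
        de_counts[f"t{tp}h"] = int(res["significant"].sum())
    full = pd.concat(frames)
    full.to_csv(out / "de_table.tsv", sep="\t")
    sig_ids = full.index[full["significant"]].unique()
    write_table(cluster_transform(fpkm.loc[sig_ids]), out / "de_cluster_matrix.tsv")
    return {"genes": len(counts), "de_per_timepoint": de_counts}


def _stage_screen(cfg: RunConfig, work: Path, out: Path) -> dict:
    fpkm = read_table(work / "ko_fpkm.tsv")
    counts = read_table(work / "ko_counts.tsv")
    records = []
    for gene in fpkm.index:
        grp_fpkm, grp_reads = {}, {}
        for g in GROUPS:
            cols = [c for c in fpkm.columns if c.startswith(f"{g}_")]
            if not cols:
                raise PipelineError(f"screen: no samples for group {g}")
            grp_fpkm[g] = float(fpkm.loc[gene, cols].mean())
            grp_reads[g] = int(counts.loc[gene, cols].sum())
        records.append(ScreenRecord(str(gene), grp_fpkm, grp_reads))
    result, removed = run_screen(records, fpkm, cfg.screen_config)
    tab = result.ratios.copy()
    tab["class"] = pd.Series(result.classes).reindex(tab.index)
    tab.to_csv(out / "screen_table.tsv", sep="\t")
    with open(out / "screen_classes.json", "w") as fh:
        json.dump(result.classes, fh, indent=1, sort_keys=True)
    if result.selected:
        write_table(
            cluster_transform(fpkm.loc[result.selected]),
            out / "screen_cluster_matrix.tsv",
        )
    return {
        "genes_in": len(fpkm),
        "low_count_removed": len(removed),
        "selected": len(result.selected),
        "classes": {
            c: sum(1 for v in result.classes.values() if v == c)
            for c in sorted(set(result.classes.values()))
        },
    }


def _stage_cerna(cfg: RunConfig, work: Path, out: Path) -> dict:
    targets = read_fasta(work / "targets.fasta")
    panel_seqs = read_fasta(work / "mirna_panel.fasta")
    if "lncRNA" not in targets or "utr" not in targets:
        raise PipelineError(
            f"cerna: targets.fasta must contain 'lncRNA' and 'utr', "
            f"got {sorted(targets)}"
        )
    panel = [MicroRNA(n, s) for n, s in panel_seqs.items()]
    candidates, venn = shared_sponging_mirnas(
        targets["lncRNA"], targets["utr"], panel, min_sites=cfg.min_sites
    )
    rows = [
        {
            "mirna": c.mirna.name,
            "target": s.target,
            "start": s.start,
            "end": s.end,
            "type": s.site_type,
        }
        for c in candidates
        for s in (*c.sites_on_lncrna, *c.sites_on_utr)
    ]
    pd.DataFrame(rows, columns=["mirna", "target", "start", "end", "type"]).to_csv(
        out / "sponge_sites.tsv", sep="\t", index=False
    )
    with open(out / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=1)
    return {"panel": len(panel), "sponge_candidates": len(candidates), "venn": venn}


_STAGE_FNS = {
    "discover": _stage_discover,
    "de": _stage_de,
    "screen": _stage_screen,
    "cerna": _stage_cerna,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order and write ``report.json``.

    Synthetic mode first materializes a workspace from ``cfg.generator``
    (re-seeded with ``cfg.seed``).  Returns the report dict.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in cfg.stages if s not in _STAGE_FNS]
    if unknown:
        raise PipelineError(f"config: unknown stages {unknown}")
    work = _preflight(cfg)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
    }
    if cfg.synthetic:
        t0 = time.perf_counter()
        gen = GeneratorConfig(**(vars(cfg.generator) | {"seed": cfg.seed}))
        generate_workspace(work, gen)
        report["stages"]["generate"] = {
            "outdir": str(work),
            "wall_s": round(time.perf_counter() - t0, 3),
        }
        log.info("stage=generate outdir=%s", work)
    for stage in cfg.stages:
        t0 = time.perf_counter()
        try:
            info = _STAGE_FNS[stage](cfg, work, out)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"{stage}: {exc}") from exc
        info["wall_s"] = round(time.perf_counter() - t0, 3)
        report["stages"][stage] = info
        log.info("stage=%s %s", stage, {k: v for k, v in info.items()})
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
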