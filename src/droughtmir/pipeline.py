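"""End-to-end orchestration: simulate/read libraries, preprocess, annotate,
call novel miRNAs, screen differential expression, classify patterns and
predict targets, emitting the study-style summary tables at every stage.

Stage outputs are written before the next stage starts, so a failed run
leaves completed intermediates intact, and every emitted table is
recomputable from them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .annotate import (ReferenceSet, annotate_tags, annotation_summary,
                       partition_unannotated)
from .classify import G1_ONLY, G2_ONLY, UNCLASSIFIED, classify_pattern
from .diffexpr import ScreenCriteria, expression_table, screen, contrast_results
from .novel import HairpinCriteria, call_novel, write_gff3
from .preprocess import collapse, process_library, size_distribution, stats_table
from .synthetic import LIBRARIES, SimulationConfig, simulate_dataset
from .targets import PenaltyScheme, predictions_table, scan_transcripts

log = logging.getLogger("droughtmir")

CATEGORY_ORDER = ("rRNA", "tRNA", "snoRNA", "snRNA", "miRNA")


@dataclass
class PipelineConfig:
    """One structured configuration for a full run."""

    outdir: Path
    seed: int = 1
    simulation: SimulationConfig | None = None
    fastq: dict[str, str] | None = None          # library id -> path
    reference_paths: dict[str, str] = field(default_factory=dict)
    genome_path: str | None = None
    transcript_path: str | None = None
    adapter: str | None = None
    min_count: int = 1
    match_policy: str = "exact"
    criteria: ScreenCriteria = field(default_factory=ScreenCriteria)
    hairpin: HairpinCriteria = field(default_factory=HairpinCriteria)
    scheme: PenaltyScheme = field(default_factory=PenaltyScheme)
    test_method: str = "poisson"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(
            outdir=Path(raw.pop("outdir", "droughtmir-out")),
            seed=int(raw.pop("seed", 1)),
            fastq=raw.pop("fastq", None),
            reference_paths=raw.pop("references", {}),
            genome_path=raw.pop("genome", None),
            transcript_path=raw.pop("transcripts", None),
            adapter=raw.pop("adapter", None),
            min_count=int(raw.pop("min_count", 1)),
            match_policy=raw.pop("match_policy", "exact"),
            test_method=raw.pop("test_method", "poisson"),
        )
        for block, target in (("screen", cfg.criteria),
                              ("hairpin", cfg.hairpin),
                              ("targets", cfg.scheme)):
            for k, v in (raw.pop(block, {}) or {}).items():
                if not hasattr(target, k):
                    raise ValueError(f"unknown {block} parameter {k!r}")
                setattr(target, k, v)
        if sim is not None:
            cfg.simulation = SimulationConfig(seed=cfg.seed, **sim)
        if raw:
            raise ValueError(f"unknown configuration keys: {sorted(raw)}")
        return cfg


@dataclass
class ReportBundle:
    stats: pd.DataFrame
    sizes: pd.DataFrame
    annotation: pd.DataFrame
    novel_calls: list
    expression: pd.DataFrame
    de_results: dict[str, pd.DataFrame]
    classified: pd.DataFrame
    targets: pd.DataFrame
    manifest: dict


def _read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper().replace("U", "T"))
            for rec in SeqIO.parse(str(path), "fasta")]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 0: inputs (simulated or on disk) ---------------------------
    if config.simulation is not None:
        log.info("simulating dataset (seed=%d)", config.simulation.seed)
        bundle, _, paths = simulate_dataset(config.simulation, out / "sim")
        fastq = {lib: paths[lib] for lib in LIBRARIES}
        genome = bundle.genome
        categories = {cat: recs for cat, recs in bundle.categories.items()}
        mature = bundle.mature
        transcripts = bundle.transcripts
        adapter = config.adapter or config.simulation.adapter_sequence
    else:
        if not config.fastq or not config.adapter:
            raise ValueError("need fastq paths and adapter when not simulating")
        fastq = dict(config.fastq)
        genome = dict(_read_fasta(config.genome_path)) \
            if config.genome_path else {}
        categories = {cat: _read_fasta(p)
                      for cat, p in config.reference_paths.items()
                      if cat != "miRNA"}
        mature = _read_fasta(config.reference_paths["miRNA"]) \
            if "miRNA" in config.reference_paths else []
        transcripts = _read_fasta(config.transcript_path) \
            if config.transcript_path else []
        adapter = config.adapter

    # --- stage 1: preprocess ---------------------------------------------
    clean_sets = [process_library(fastq[lib], adapter, library=lib)
                  for lib in fastq]
    for cs in clean_sets:
        log.info("%s: %d raw -> %d clean", cs.library, cs.total_raw, cs.retained)
    tags = collapse(clean_sets, min_count=config.min_count)
    stats = stats_table(clean_sets, tags)
    sizes = size_distribution(tags)
    stats.to_csv(out / "library_stats.tsv", sep="\t")
    sizes.to_csv(out / "size_distribution.tsv", sep="\t")

    # --- stage 2: annotation ---------------------------------------------
    refsets = [ReferenceSet(cat, categories[cat], policy=config.match_policy)
               for cat in CATEGORY_ORDER if cat in categories and categories[cat]]
    if mature:
        refsets.append(ReferenceSet("miRNA", mature, policy=config.match_policy))
    annotated = annotate_tags(tags, refsets)
    summary = annotation_summary(annotated)
    summary.to_csv(out / "annotation_summary.tsv", sep="\t", index=False)
    annotated.to_csv(out / "tags_annotated.tsv", sep="\t")

    # --- stage 3: novel miRNA calling ------------------------------------
    unannotated = partition_unannotated(annotated)
    novel_calls = call_novel(list(unannotated.index), genome,
                             criteria=config.hairpin) if genome else []
    log.info("novel miRNA calls: %d", len(novel_calls))
    libs = [cs.library for cs in clean_sets]
    novel_rows = []
    for k, call in enumerate(novel_calls, 1):
        row = {"novel_id": f"novel-{k:03d}", "mature": call.mature,
               "precursor": call.precursor,
               "structure": call.structure.dot_bracket,
               "paired_fraction": round(call.paired_fraction, 3),
               "duplex_mismatches": call.duplex_mismatches,
               "star": call.star}
        novel_rows.append(row)
    pd.DataFrame(novel_rows).to_csv(out / "novel_calls.tsv", sep="\t",
                                    index=False)
    with open(out / "novel_precursors.fa", "w") as fh:
        for row in novel_rows:
            fh.write(f">{row['novel_id']}\n{row['precursor']}\n"
                     f";{row['structure']}\n")
    write_gff3(novel_calls, out / "novel_loci.gff3")

    # --- stage 4: expression counting ------------------------------------
    mirna_tags = annotated[annotated["category"] == "miRNA"]
    counts = (mirna_tags.groupby("match_id")[libs].sum()
              if len(mirna_tags) else pd.DataFrame(columns=libs))
    for k, call in enumerate(novel_calls, 1):
        if call.mature in annotated.index:
            counts.loc[f"novel-{k:03d}"] = annotated.loc[call.mature, libs]
    counts.index.name = "mirna_id"
    counts = counts.astype(int).sort_index()
    counts.to_csv(out / "mirna_counts.tsv", sep="\t")

    totals = {cs.library: cs.retained for cs in clean_sets}
    expression = (expression_table(counts, totals,
                                   config.criteria.pseudocount)
                  if len(counts) and min(totals.values()) > 0
                  else pd.DataFrame())
    expression.to_csv(out / "expression_tpm.tsv", sep="\t")

    # --- stage 5: differential expression + classification ---------------
    de_results: dict[str, pd.DataFrame] = {}
    classified = pd.DataFrame(
        columns=["log2_g1", "log2_g2", "pattern", "de_g1", "de_g2"])
    if len(counts) and min(totals.values()) > 0:
        g1 = contrast_results(counts, totals, "C1", "T1",
                           config.criteria, config.test_method)
        g2 = contrast_results(counts, totals, "C2", "T2",
                           config.criteria, config.test_method)
        de_results = {"genotype1": g1, "genotype2": g2}
        de1, de2 = screen(g1, config.criteria), screen(g2, config.criteria)
        de_union = sorted(set(de1.index) | set(de2.index))
        rows = []
        for mid in counts.index:
            l1 = g1.loc[mid, "log2_ratio"]
            l2 = g2.loc[mid, "log2_ratio"]
            pattern = (classify_pattern(l1, l2, config.criteria.log2_threshold)
                       if mid in de_union else UNCLASSIFIED)
            rows.append({"mirna_id": mid, "log2_g1": l1, "log2_g2": l2,
                         "pattern": pattern,
                         "de_g1": mid in de1.index, "de_g2": mid in de2.index})
        classified = pd.DataFrame(rows).set_index("mirna_id")
        g1.to_csv(out / "de_genotype1.tsv", sep="\t")
        g2.to_csv(out / "de_genotype2.tsv", sep="\t")
    classified.to_csv(out / "patterns.tsv", sep="\t")
    emit_pattern_tables(classified, expression, out)

    # --- stage 6: target prediction --------------------------------------
    target_hits = []
    if transcripts and len(classified):
        de_ids = classified.index[classified["pattern"] != UNCLASSIFIED]
        seqs = dict(mature)
        for k, call in enumerate(novel_calls, 1):
            seqs[f"novel-{k:03d}"] = call.mature
        for mid in de_ids:
            if mid in seqs:
                target_hits.extend(
                    scan_transcripts(mid, seqs[mid], transcripts, config.scheme))
    targets = predictions_table(target_hits)
    targets.to_csv(out / "target_predictions.tsv", sep="\t", index=False)

    manifest = {
        "package": "droughtmir", "version": __version__,
        "seed": config.seed, "libraries": libs,
        "test_method": config.test_method,
        "screen": vars(config.criteria), "hairpin": vars(config.hairpin),
        "n_tags": int(len(tags)), "n_novel_calls": len(novel_calls),
        "n_de": {k: int(len(screen(v, config.criteria)))
                 for k, v in de_results.items()},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return ReportBundle(stats, sizes, summary, novel_calls, expression,
                        de_results, classified, targets, manifest)


_PATTERN_FILES = {
    "up_both": "table_up_both.tsv",
    "down_both": "table_down_both.tsv",
    "opposite": "table_opposite.tsv",
    "single": "table_single_genotype.tsv",
}


def emit_pattern_tables(
    classified: pd.DataFrame, expression: pd.DataFrame, outdir: str | Path
) -> None:
    """Four classified DE tables with 2-decimal TPM and log2 columns."""
    outdir = Path(outdir)
    groups = {
        "up_both": classified[classified["pattern"] == "up_both"],
        "down_both": classified[classified["pattern"] == "down_both"],
        "opposite": classified[classified["pattern"] == "opposite"],
        "single": classified[classified["pattern"].isin([G1_ONLY, G2_ONLY])],
    }
    for key, sub in groups.items():
        rows = []
        for mid in sub.index:
            row = {"mirna_id": mid}
            for lib in ("C1", "T1", "C2", "T2"):
                col = f"tpm_{lib}"
                if col in expression.columns:
                    row[col] = f"{expression.loc[mid, col]:.2f}"
            row["log2_t1_c1"] = f"{sub.loc[mid, 'log2_g1']:.2f}"
            row["log2_t2_c2"] = f"{sub.loc[mid, 'log2_g2']:.2f}"
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / _PATTERN_FILES[key],
                                  sep="\t", index=False)
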