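"""Synthetic four-library small-RNA-seq study generator.

Emulates the design of a two-genotype dehydration-stress experiment: four
libraries (genotype 1 control/stress = C1/T1, genotype 2 control/stress =
C2/T2) of 3'-adapter-ligated small RNA reads drawn from a mixture of
structural-RNA contaminants (rRNA/tRNA/snoRNA/snRNA), conserved mature
miRNAs, novel miRNAs whose hairpin precursors are planted in a toy genome,
and unassignable background sequences.  Per-genotype fold changes are
planted so that every cross-genotype expression-pattern category
(up in both, down in both, opposite, single-genotype, null) is represented,
and a truth manifest records the ground truth for recovery tests.

All randomness flows from one root seed through named substreams, so partial
re-runs (e.g. re-drawing counts only) are reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import revcomp

LIBRARIES = ("C1", "T1", "C2", "T2")
CATEGORIES = ("rRNA", "tRNA", "snoRNA", "snRNA", "miRNA", "other")
PATTERN_CATEGORIES = (
    "up_both",
    "down_both",
    "opposite",
    "genotype1_only",
    "genotype2_only",
    "null",
)

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: Insert-length distribution over 16..30 nt with the mode at 24 nt, the
#: shape typical of plant small-RNA libraries (21-24 nt classes dominant).
DEFAULT_LENGTH_DISTRIBUTION = {
    16: 0.01, 17: 0.01, 18: 0.02, 19: 0.03, 20: 0.05,
    21: 0.10, 22: 0.10, 23: 0.12, 24: 0.30, 25: 0.08,
    26: 0.05, 27: 0.04, 28: 0.04, 29: 0.03, 30: 0.02,
}

DEFAULT_CATEGORY_FRACTIONS = {
    "rRNA": 0.30, "tRNA": 0.30, "snoRNA": 0.08,
    "snRNA": 0.04, "miRNA": 0.08, "other": 0.20,
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the root seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, int(length))].tobytes().decode()


@dataclass
class SimulationConfig:
    """Parameters of the emulated study.

    ``dispersion`` is the overdispersion of the negative-binomial count model
    (variance = mean + dispersion * mean^2); 0 gives Poisson sampling, which
    is the assumption of the downstream exact test, so the default keeps it
    small.  ``fold_change_plan`` maps miRNA index (0-based over conserved
    then novel miRNAs) to (pattern_category, fold); when ``None`` the
    categories are assigned round-robin with four miRNAs per non-null
    category and the remainder null, at ``default_fold``.
    """

    seed: int = 1
    n_reads_per_library: int = 200_000
    adapter_sequence: str = DEFAULT_ADAPTER
    read_length: int = 36
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION))
    category_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FRACTIONS))
    n_conserved_mirnas: int = 30
    n_novel_precursors: int = 6
    genome_length: int = 100_000
    fold_change_plan: dict[int, tuple[str, float]] | None = None
    default_fold: float = 4.0
    dispersion: float = 0.005
    error_rate: float = 0.005
    low_quality_fraction: float = 0.02
    n_transcripts: int = 8
    transcript_length: int = 300

    def validate(self) -> None:
        if abs(sum(self.length_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("length_distribution probabilities must sum to 1")
        if set(self.category_fractions) != set(CATEGORIES):
            raise ValueError(f"category_fractions must cover {CATEGORIES}")
        if abs(sum(self.category_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("category_fractions probabilities must sum to 1")
        if any(not 16 <= k <= 30 for k in self.length_distribution):
            raise ValueError("insert lengths must lie in 16..30 nt")
        if min(self.n_reads_per_library, self.n_conserved_mirnas,
               self.n_novel_precursors, self.genome_length) <= 0:
            raise ValueError("all counts must be positive")
        if self.fold_change_plan is not None:
            for cat, fold in self.fold_change_plan.values():
                if cat not in PATTERN_CATEGORIES:
                    raise ValueError(f"unknown pattern category {cat!r}")
                if fold <= 0:
                    raise ValueError("planted folds must be positive")


@dataclass
class ReferenceBundle:
    """References, toy genome and ground truth produced by build_references."""

    genome: dict[str, str]
    categories: dict[str, list[tuple[str, str]]]
    mature: list[tuple[str, str]]          # conserved mature miRNA catalog
    transcripts: list[tuple[str, str]]
    manifest: pd.DataFrame                 # TruthManifest


def _default_plan(n_total: int, fold: float) -> list[tuple[str, float]]:
    nonnull = [c for c in PATTERN_CATEGORIES if c != "null"]
    cycle = nonnull + ["null"] * 4          # 4 per non-null category per 9
    plan = []
    for i in range(n_total):
        cat = cycle[i % len(cycle)]
        plan.append((cat, fold if cat != "null" else 1.0))
    return plan


def _plant_precursor(rng: np.random.Generator) -> tuple[str, str, int]:
    """One hairpin precursor: (precursor, mature, mature offset).

    Stem arms are reverse-complementary except for <= 2 planted substitutions,
    the loop is 4-8 nt, and the 20-24 nt mature sits in the 5' arm at least
    2 nt from the loop, so the hairpin passes the annotation criteria by
    construction.
    """
    arm_len = int(rng.integers(30, 46))
    loop_len = int(rng.integers(4, 9))
    mat_len = int(rng.integers(20, 25))
    arm5 = _random_seq(rng, arm_len)
    loop = _random_seq(rng, loop_len)
    arm3 = list(revcomp(arm5))
    for pos in rng.choice(arm_len, size=int(rng.integers(0, 3)), replace=False):
        old = arm3[pos]
        arm3[pos] = str(rng.choice([b for b in "ACGT" if b != old]))
    offset = int(rng.integers(0, arm_len - mat_len - 2 + 1))
    precursor = arm5 + loop + "".join(arm3)
    return precursor, arm5[offset:offset + mat_len], offset


def build_references(config: SimulationConfig) -> ReferenceBundle:
    """Generate the genome, category references, mature catalog and truth."""
    config.validate()
    seed = config.seed

    genome = np.frombuffer(
        _random_seq(_rng(seed, "genome"), config.genome_length).encode(), dtype="S1"
    ).copy()

    rng_p = _rng(seed, "precursors")
    occupied: list[tuple[int, int]] = []
    novel_rows = []
    for i in range(config.n_novel_precursors):
        precursor, mature, offset = _plant_precursor(rng_p)
        plen = len(precursor)
        for _ in range(200):
            pos = int(rng_p.integers(0, config.genome_length - plen + 1)) \
                if config.genome_length > plen else -1
            if pos >= 0 and all(pos + plen + 30 <= a or pos >= b + 30
                                for a, b in occupied):
                break
        else:
            raise ValueError("genome too short to host requested precursors")
        if pos < 0:
            raise ValueError("genome too short to host requested precursors")
        occupied.append((pos, pos + plen))
        strand = "+" if rng_p.random() < 0.5 else "-"
        inserted = precursor if strand == "+" else revcomp(precursor)
        genome[pos:pos + plen] = np.frombuffer(inserted.encode(), dtype="S1")
        if strand == "+":
            m_start, m_end = pos + offset, pos + offset + len(mature)
        else:
            m_start = pos + plen - (offset + len(mature))
            m_end = pos + plen - offset
        novel_rows.append({
            "mirna_id": f"novel-mir-{i + 1:03d}",
            "mature_sequence": mature,
            "kind": "novel",
            "chrom": "chr1",
            "start": m_start, "end": m_end, "strand": strand,
            "precursor_start": pos, "precursor_end": pos + plen,
        })
    genome_seq = genome.tobytes().decode()

    rng_c = _rng(seed, "conserved")
    conserved: list[tuple[str, str]] = []
    seen: set[str] = set()
    lengths = np.array([20, 21, 22, 23, 24])
    probs = np.array([0.10, 0.35, 0.20, 0.10, 0.25])
    while len(conserved) < config.n_conserved_mirnas:
        seq = _random_seq(rng_c, int(rng_c.choice(lengths, p=probs)))
        if seq not in seen and seq not in genome_seq:
            seen.add(seq)
            conserved.append((f"con-miR{len(conserved) + 1:03d}", seq))

    rng_r = _rng(seed, "references")
    sizes = {"rRNA": (3, 1500), "tRNA": (8, 75),
             "snoRNA": (6, 120), "snRNA": (5, 150)}
    categories = {
        cat: [(f"{cat}-{j + 1}", _random_seq(rng_r, length))
              for j in range(n)]
        for cat, (n, length) in sizes.items()
    }

    manifest_rows = [
        {"mirna_id": mid, "mature_sequence": seq, "kind": "conserved",
         "chrom": None, "start": -1, "end": -1, "strand": None,
         "precursor_start": -1, "precursor_end": -1}
        for mid, seq in conserved
    ] + novel_rows
    plan = (
        [config.fold_change_plan.get(i, ("null", 1.0))
         for i in range(len(manifest_rows))]
        if config.fold_change_plan is not None
        else _default_plan(len(manifest_rows), config.default_fold)
    )
    for row, (cat, fold) in zip(manifest_rows, plan):
        row["pattern_category"] = cat
        row["fold"] = fold
    manifest = pd.DataFrame(manifest_rows).set_index("mirna_id", drop=False)

    rng_t = _rng(seed, "transcripts")
    transcripts = []
    for j in range(config.n_transcripts):
        t = _random_seq(rng_t, config.transcript_length)
        if j < min(4, len(conserved)):       # plant a perfect target site
            site = revcomp(conserved[j][1])
            pos = int(rng_t.integers(0, len(t) - len(site) + 1))
            t = t[:pos] + site + t[pos + len(site):]
        transcripts.append((f"transcript-{j + 1}", t))

    return ReferenceBundle(
        genome={"chr1": genome_seq},
        categories=categories,
        mature=conserved,
        transcripts=transcripts,
        manifest=manifest,
    )


def expected_means(manifest: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Per-library expected read counts implementing the fold-change plan.

    Opposite-pattern miRNAs go down in genotype 1 and up in genotype 2,
    mirroring downregulation in the drought-tolerant cultivar alongside
    upregulation in the drought-susceptible one.  Single-genotype miRNAs
    alternate direction within their category.
    """
    n = len(manifest)
    w = _rng(config.seed, "abundance").lognormal(0.0, 1.0, n)
    base = w / w.sum() * config.category_fractions["miRNA"] * config.n_reads_per_library

    means = pd.DataFrame(
        {lib: base.copy() for lib in LIBRARIES}, index=manifest.index)
    direction_counter: dict[str, int] = {}
    for i, (mid, row) in enumerate(manifest.iterrows()):
        cat, f = row["pattern_category"], row["fold"]
        if cat == "up_both":
            means.loc[mid, ["T1", "T2"]] = base[i] * f
        elif cat == "down_both":
            means.loc[mid, ["T1", "T2"]] = base[i] / f
        elif cat == "opposite":
            means.loc[mid, "T1"] = base[i] / f
            means.loc[mid, "T2"] = base[i] * f
        elif cat in ("genotype1_only", "genotype2_only"):
            k = direction_counter.get(cat, 0)
            direction_counter[cat] = k + 1
            lib = "T1" if cat == "genotype1_only" else "T2"
            means.loc[mid, lib] = base[i] * f if k % 2 == 0 else base[i] / f
    return means


def simulate_counts(
    manifest: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Draw the true per-library count table (miRNA x C1,T1,C2,T2).

    Counts are negative binomial with the planned means and common
    dispersion; dispersion 0 degenerates to Poisson.
    """
    bad = set(manifest["pattern_category"]) - set(PATTERN_CATEGORIES)
    if bad:
        raise ValueError(f"manifest categories inconsistent with plan: {bad}")
    means = expected_means(manifest, config)
    rng = _rng(config.seed, "counts")
    counts = pd.DataFrame(index=means.index, columns=list(LIBRARIES), dtype=int)
    for lib in LIBRARIES:
        m = means[lib].to_numpy(float)
        if config.dispersion <= 0:
            counts[lib] = rng.poisson(m)
        else:
            size = 1.0 / config.dispersion
            counts[lib] = rng.negative_binomial(size, size / (size + m))
    return counts


def _mutate(rng: np.random.Generator, seqs: list[str], error_rate: float) -> list[str]:
    if error_rate <= 0:
        return seqs
    lens = np.fromiter((len(s) for s in seqs), dtype=int, count=len(seqs))
    n_err = rng.binomial(lens, error_rate)
    out = seqs
    for i in np.nonzero(n_err)[0]:
        s = list(out[i])
        for pos in rng.choice(lens[i], size=n_err[i], replace=False):
            s[pos] = str(rng.choice([b for b in "ACGT" if b != s[pos]]))
        out[i] = "".join(s)
    return out


def synthesize_reads(
    counts: pd.DataFrame,
    bundle: ReferenceBundle,
    config: SimulationConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the four FASTQ libraries; returns library -> path.

    Each read is insert + 3' adapter truncated to the read length, with
    Sanger/Phred+33 qualities in a two-level scheme: high-quality reads at
    Q40 and a configured fraction of low-quality (Q2) reads.
    """
    config.validate()
    if (counts < 0).any().any():
        raise ValueError("counts must be nonnegative")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mature_by_id = dict(zip(bundle.manifest["mirna_id"],
                            bundle.manifest["mature_sequence"]))
    lengths = np.array(sorted(config.length_distribution))
    probs = np.array([config.length_distribution[k] for k in lengths], float)
    probs = probs / probs.sum()
    other_cats = [c for c in CATEGORIES if c not in ("miRNA", "other")]
    frac = np.array([config.category_fractions[c] for c in other_cats]
                    + [config.category_fractions["other"]], float)
    frac = frac / frac.sum()

    paths: dict[str, Path] = {}
    for lib in LIBRARIES:
        rng = _rng(config.seed, f"reads-{lib}")
        inserts: list[str] = []
        for mid in counts.index:
            inserts.extend([mature_by_id[mid]] * int(counts.loc[mid, lib]))
        remaining = config.n_reads_per_library - len(inserts)
        if remaining < 0:
            raise ValueError("miRNA counts exceed n_reads_per_library")
        alloc = rng.multinomial(remaining, frac)
        for cat, m in zip(other_cats, alloc[:-1]):
            records = bundle.categories[cat]
            ridx = rng.integers(0, len(records), m)
            ilen = rng.choice(lengths, p=probs, size=m)
            for r, l in zip(ridx, ilen):
                seq = records[int(r)][1]
                start = int(rng.integers(0, len(seq) - int(l) + 1))
                inserts.append(seq[start:start + int(l)])
        for l in rng.choice(lengths, p=probs, size=alloc[-1]):
            inserts.append(_random_seq(rng, int(l)))

        inserts = _mutate(rng, inserts, config.error_rate)
        order = rng.permutation(len(inserts))
        low = rng.random(len(inserts)) < config.low_quality_fraction

        path = outdir / f"{lib}.fastq"
        with open(path, "w") as fh:
            for out_i, i in enumerate(order):
                s = inserts[i] + config.adapter_sequence
                while len(s) < config.read_length:
                    s += config.adapter_sequence
                s = s[:config.read_length]
                qual = ("#" if low[i] else "I") * len(s)
                fh.write(f"@{lib}_{out_i + 1}\n{s}\n+\n{qual}\n")
        paths[lib] = path
    return paths


def write_references(bundle: ReferenceBundle, outdir: str | Path) -> dict[str, Path]:
    """Write genome/category/mature/transcript FASTA files and the truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def fasta(name: str, records: list[tuple[str, str]]) -> None:
        p = outdir / f"{name}.fa"
        with open(p, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        paths[name] = p

    fasta("genome", list(bundle.genome.items()))
    for cat, recs in bundle.categories.items():
        fasta(cat, recs)
    fasta("mature_mirna", bundle.mature)
    fasta("transcripts", bundle.transcripts)
    p = outdir / "truth_manifest.tsv"
    bundle.manifest.to_csv(p, sep="\t", index=False)
    paths["manifest"] = p
    return paths


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path
) -> tuple[ReferenceBundle, pd.DataFrame, dict[str, Path]]:
    """Full generator run: references, true counts, four FASTQ libraries."""
    outdir = Path(outdir)
    bundle = build_references(config)
    paths = write_references(bundle, outdir / "references")
    counts = simulate_counts(bundle.manifest, config)
    counts_path = outdir / "true_counts.tsv"
    counts.to_csv(counts_path, sep="\t")
    paths["true_counts"] = counts_path
    paths.update(synthesize_reads(counts, bundle, config, outdir / "reads"))
    return bundle, counts, paths


def simulate_qpcr_table(
    mirna_ids: list[str],
    fold_g1: dict[str, float],
    fold_g2: dict[str, float],
    seed: int = 1,
    ct_noise: float = 0.05,
) -> pd.DataFrame:
    """Emulated qPCR CT table (reference gene 18S) consistent with planted folds.

    Target-gene rows are generated as noisy inverses of their miRNA, the
    expectation under cleavage-type regulation.
    """
    rng = _rng(seed, "qpcr")
    rows = []
    for mid in mirna_ids:
        ref_ct = 15.0
        base_ct = float(rng.uniform(22, 28))
        for sample, cond, fold in (
            ("C1", "control", 1.0), ("T1", "stress", fold_g1.get(mid, 1.0)),
            ("C2", "control", 1.0), ("T2", "stress", fold_g2.get(mid, 1.0)),
        ):
            for rep in range(1, 4):
                rows.append({"sample": sample, "gene": mid, "role": "target",
                             "condition": cond, "replicate": rep,
                             "ct": base_ct - np.log2(fold)
                             + float(rng.normal(0, ct_noise))})
                rows.append({"sample": sample, "gene": "18S", "role": "reference",
                             "condition": cond, "replicate": rep,
                             "ct": ref_ct + float(rng.normal(0, ct_noise))})
    return pd.DataFrame(rows)
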