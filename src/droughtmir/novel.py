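"""Novel miRNA calling: genome mapping, precursor excision, folding, criteria.

Unannotated tags are mapped to the genome requiring perfect matches, two
candidate precursor windows are excised around each locus, folded with an
internal weighted maximum-pairing (Nussinov) dynamic program, and evaluated
against plant miRNA annotation criteria: the mature sits entirely in one
stem arm, the miRNA/miRNA* duplex has at most 4 unpaired mature bases and
no asymmetric bulge larger than 2 nt, at least 60% of stem bases are
paired, and the mature is 20-24 nt.  The folder scores GC=3, AU=2, GU=1
over nested structures with a minimum loop, a deterministic stand-in for a
thermodynamic model that needs no external binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._seq import normalize, revcomp

#: pair weights (DNA alphabet, T == U): GC=3, AU=2, GU=1
_PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_WMAT = np.zeros((5, 5), dtype=np.int64)
for (_a, _b), _w in _PAIR_WEIGHT.items():
    _WMAT[_CODE[_a], _CODE[_b]] = _w


@dataclass(frozen=True)
class GenomeLocus:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("invalid locus interval")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass
class HairpinStructure:
    """Nested secondary structure with its pairing score."""

    sequence: str
    pairs: list[tuple[int, int]]
    score: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def partner(self) -> np.ndarray:
        p = np.full(len(self.sequence), -1, dtype=int)
        for i, j in self.pairs:
            p[i], p[j] = j, i
        return p

    @property
    def dot_bracket(self) -> str:
        db = ["."] * len(self.sequence)
        for i, j in self.pairs:
            db[i], db[j] = "(", ")"
        return "".join(db)

    def innermost_pair(self) -> tuple[int, int] | None:
        """The pair with the smallest span — the hairpin loop closure."""
        if not self.pairs:
            return None
        return min(self.pairs, key=lambda p: (p[1] - p[0], p[0]))


def map_exact(tag: str, genome: dict[str, str]) -> list[GenomeLocus]:
    """All perfect-match loci of the tag on both strands.

    Minus-strand loci are occurrences of the reverse complement, reported
    on forward coordinates.
    """
    tag = normalize(tag)
    loci = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        for query, strand in ((tag, "+"), (revcomp(tag), "-")):
            pos = seq.find(query)
            while pos >= 0:
                loci.append(GenomeLocus(chrom, pos, pos + len(tag), strand))
                pos = seq.find(query, pos + 1)
    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    return loci


@dataclass
class PrecursorCandidate:
    sequence: str           # oriented 5'->3' on the mature strand
    chrom: str
    start: int              # genomic interval (forward coordinates)
    end: int
    strand: str
    mature_offset: int      # mature start within the oriented sequence


def excise_candidates(
    locus: GenomeLocus,
    genome: dict[str, str],
    upstream: int = 20,
    downstream: int = 200,
) -> list[PrecursorCandidate]:
    """Two windows per locus: short-5' (up+L+down) and short-3' (down+L+up).

    Windows are clipped at contig edges and reported in the orientation of
    the mature strand; up/downstream are measured 5'/3' of the mature.
    """
    seq = genome[locus.chrom]
    n = len(seq)
    if locus.strand == "+":
        ivs = [(locus.start - upstream, locus.end + downstream),
               (locus.start - downstream, locus.end + upstream)]
    else:
        ivs = [(locus.start - downstream, locus.end + upstream),
               (locus.start - upstream, locus.end + downstream)]
    out = []
    for a, b in ivs:
        a, b = max(0, a), min(n, b)
        window = seq[a:b]
        if locus.strand == "+":
            offset = locus.start - a
        else:
            window = revcomp(window)
            offset = b - locus.end
        out.append(PrecursorCandidate(window, locus.chrom, a, b,
                                      locus.strand, offset))
    return out


def fold(sequence: str, min_loop: int = 3) -> HairpinStructure:
    """Weighted maximum-pairing fold (GC=3, AU=2, GU=1), nested, loop >= min_loop.

    Dynamic program over interval diagonals, numpy-vectorised over the
    start index; traceback prefers a pair at the smallest i and then the
    largest j, making the reported structure deterministic.
    """
    s = normalize(sequence)
    n = len(s)
    if n < min_loop + 2:
        raise ValueError("sequence too short to fold")
    codes = np.fromiter((_CODE.get(c, 4) for c in s), dtype=np.int64, count=n)
    W = _WMAT[codes[:, None], codes[None, :]]

    diag: dict[int, np.ndarray] = {-1: np.zeros(n + 1, dtype=np.int64)}
    for d in range(0, min(min_loop + 1, n)):
        diag[d] = np.zeros(n - d, dtype=np.int64)
    for d in range(min_loop + 1, n):
        m = n - d
        best = diag[d - 1][1:1 + m].copy()
        for t in range(min_loop + 1, d + 1):
            w = np.diagonal(W, t)[:m]
            inner = diag[t - 2][1:1 + m]
            right = diag[d - t - 1][t + 1:t + 1 + m] if d - t - 1 >= 0 \
                else np.zeros(m, dtype=np.int64)
            np.maximum(best, w + inner + right, out=best)
        diag[d] = best

    M = np.zeros((n, n), dtype=np.int64)
    for d in range(1, n):
        idx = np.arange(n - d)
        M[idx, idx + d] = diag[d]

    def m_at(i: int, j: int) -> int:
        return int(M[i, j]) if i <= j else 0

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        target = m_at(i, j)
        if target == 0:
            continue
        chosen = None
        for k in range(j, i + min_loop, -1):      # largest j first
            w = int(W[i, k])
            if w and w + m_at(i + 1, k - 1) + m_at(k + 1, j) == target:
                chosen = k
                break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pairs.append((i, chosen))
            stack.append((chosen + 1, j))
            stack.append((i + 1, chosen - 1))
    pairs.sort()
    return HairpinStructure(s, pairs, int(M[0, n - 1]))


@lru_cache(maxsize=4096)
def _fold_cached(sequence: str, min_loop: int) -> HairpinStructure:
    return fold(sequence, min_loop)


@dataclass
class HairpinCriteria:
    """Operationalised plant miRNA annotation thresholds."""

    max_duplex_mismatches: int = 4
    max_asymmetric_bulge: int = 2
    min_paired_fraction: float = 0.6
    mature_min_len: int = 20
    mature_max_len: int = 24
    min_loop: int = 3


@dataclass
class NovelMiRNACall:
    mature: str
    precursor: str
    structure: HairpinStructure
    star: str
    duplex_mismatches: int
    largest_bulge: int
    paired_fraction: float
    flags: dict[str, bool]
    passed: bool
    locus: GenomeLocus | None = None
    candidate: PrecursorCandidate | None = None


def evaluate_hairpin(
    precursor: str,
    mature: str,
    criteria: HairpinCriteria | None = None,
    mature_offset: int | None = None,
) -> NovelMiRNACall:
    """Judge one excised candidate against the annotation criteria."""
    criteria = criteria or HairpinCriteria()
    precursor = normalize(precursor)
    mature = normalize(mature)
    if mature_offset is None:
        mature_offset = precursor.find(mature)
    if mature_offset < 0 or precursor[mature_offset:mature_offset + len(mature)] != mature:
        raise ValueError("mature sequence not found in candidate precursor")
    a, b = mature_offset, mature_offset + len(mature)

    structure = _fold_cached(precursor, criteria.min_loop)
    partner = structure.partner
    inner = structure.innermost_pair()

    flags = {"mature_length_ok":
             criteria.mature_min_len <= len(mature) <= criteria.mature_max_len}
    if inner is None:
        flags.update(in_one_arm=False, duplex_mismatches_ok=False,
                     bulge_ok=False, stem_pairing_ok=False)
        return NovelMiRNACall(mature, precursor, structure, "", len(mature),
                              0, 0.0, flags, False)
    li, lj = inner
    flags["in_one_arm"] = b <= li + 1 or a >= lj

    mature_partners = partner[a:b]
    mismatches = int((mature_partners < 0).sum())
    flags["duplex_mismatches_ok"] = mismatches <= criteria.max_duplex_mismatches

    paired_pos = [p for p in range(a, b) if partner[p] >= 0]
    largest_bulge = 0
    for p1, p2 in zip(paired_pos, paired_pos[1:]):
        gap_m = p2 - p1 - 1
        gap_s = abs(partner[p1] - partner[p2]) - 1
        largest_bulge = max(largest_bulge, abs(gap_m - gap_s))
    flags["bulge_ok"] = largest_bulge <= criteria.max_asymmetric_bulge

    loop_len = lj - li - 1
    stem_bases = len(precursor) - loop_len
    paired_total = 2 * structure.n_pairs
    paired_fraction = paired_total / stem_bases if stem_bases else 0.0
    flags["stem_pairing_ok"] = paired_fraction >= criteria.min_paired_fraction

    star = ""
    if paired_pos:
        qa = partner[paired_pos[0]]
        # mature 3' end minus the canonical 2-nt overhang pairs the star 5' end
        anchor = [p for p in paired_pos if p <= b - 3]
        qb = partner[anchor[-1]] if anchor else partner[paired_pos[-1]]
        lo, hi = sorted((int(qa), int(qb)))
        star = precursor[max(0, lo):min(len(precursor), hi + 3)]
        if a >= lj:                      # mature in 3' arm: star is 5' side
            star = precursor[max(0, lo - 2):hi + 1]

    passed = all(flags.values())
    return NovelMiRNACall(mature, precursor, structure, star, mismatches,
                          largest_bulge, paired_fraction, flags, passed)


def _genome_kmer_index(
    genome: dict[str, str], lengths: range
) -> dict[int, set[str]]:
    """Substring membership index per tag length (forward strand only;
    queries test the tag and its reverse complement)."""
    index: dict[int, set[str]] = {k: set() for k in lengths}
    for seq in genome.values():
        n = len(seq)
        for k in lengths:
            index[k].update(seq[i:i + k] for i in range(n - k + 1))
    return index


def call_novel(
    tags: list[str],
    genome: dict[str, str],
    criteria: HairpinCriteria | None = None,
    upstream: int = 20,
    downstream: int = 200,
    max_loci: int = 20,
) -> list[NovelMiRNACall]:
    """Best passing hairpin call per distinct unannotated tag, if any.

    Tags outside the mature length range are not mapped (they cannot pass);
    at most ``max_loci`` genomic loci are evaluated per tag, two candidate
    windows each.  The best candidate is the passing one with the highest
    paired fraction, ties resolved by window order.
    """
    criteria = criteria or HairpinCriteria()
    lengths = range(criteria.mature_min_len, criteria.mature_max_len + 1)
    index = _genome_kmer_index(genome, lengths)
    calls = []
    for tag in sorted(set(normalize(t) for t in tags)):
        if len(tag) not in index:
            continue
        if tag not in index[len(tag)] and revcomp(tag) not in index[len(tag)]:
            continue
        best: NovelMiRNACall | None = None
        for locus in map_exact(tag, genome)[:max_loci]:
            for cand in excise_candidates(locus, genome, upstream, downstream):
                call = evaluate_hairpin(cand.sequence, tag, criteria,
                                        mature_offset=cand.mature_offset)
                call.locus = locus
                call.candidate = cand
                if call.passed and (best is None
                                    or call.paired_fraction > best.paired_fraction):
                    best = call
        if best is not None:
            calls.append(best)
    return calls


def write_gff3(calls: list[NovelMiRNACall], path) -> None:
    """Precursor and mature loci of passing calls as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, call in enumerate(calls, 1):
            if call.candidate is None:
                continue
            c = call.candidate
            fh.write(f"{c.chrom}\tdroughtmir\tmiRNA_primary_transcript\t"
                     f"{c.start + 1}\t{c.end}\t.\t{c.strand}\t.\t"
                     f"ID=novel-{k:03d}\n")
            if call.locus is not None:
                l = call.locus
                fh.write(f"{l.chrom}\tdroughtmir\tmiRNA\t{l.start + 1}\t{l.end}"
                         f"\t.\t{l.strand}\t.\tID=novel-{k:03d}-mature;"
                         f"Parent=novel-{k:03d}\n")
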