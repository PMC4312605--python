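"""miRNA-target complementarity scoring with a miRU-style penalty scheme.

A candidate site is scored by aligning the miRNA (5'->3') against the site
antiparallel and summing position-wise penalties over the first
``scoring_length`` miRNA positions: Watson-Crick pair 0, G:U wobble 0.5,
mismatch 1.0, gap (bulged base on either strand) 2.0, with every penalty
doubled inside the seed region (miRNA positions 2-13 from the 5' end).
At most one gap is allowed; sites with total penalty E at or below the
cutoff (default 3.0) are reported.  Putative translational repression is
flagged when any of the central miRNA positions 9-11 is unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._seq import check_nucleotides

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass
class PenaltyScheme:
    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 2.0
    seed_start: int = 2          # 1-based miRNA positions, inclusive
    seed_end: int = 13
    seed_multiplier: float = 2.0
    scoring_length: int = 20
    cutoff: float = 3.0
    max_gaps: int = 1

    def __post_init__(self):
        if min(self.mismatch, self.wobble, self.gap) < 0:
            raise ValueError("penalties must be nonnegative")
        if not 1 <= self.seed_start <= self.seed_end <= self.scoring_length:
            raise ValueError("seed range must lie within the scoring length")

    def multiplier(self, position: int) -> float:
        """Weight of a 1-based miRNA position."""
        return (self.seed_multiplier
                if self.seed_start <= position <= self.seed_end else 1.0)

    def column_penalty(self, m: str, t: str, position: int) -> float:
        if (m, t) in _WC:
            base = 0.0
        elif (m, t) in _WOBBLE:
            base = self.wobble
        else:
            base = self.mismatch
        return base * self.multiplier(position)


@dataclass
class DuplexAlignment:
    score: float
    mirna_row: str        # miRNA 5'->3' ('-' = bulged site base)
    pairing_row: str      # '|' Watson-Crick, ':' wobble, ' ' otherwise
    target_row: str       # site 3'->5', antiparallel to the miRNA row
    n_gaps: int
    translational: bool   # central miRNA position (9-11) unpaired


@dataclass
class TargetPrediction:
    mirna_id: str
    transcript_id: str
    start: int            # site interval on the transcript, 0-based half-open
    end: int
    score: float
    alignment: DuplexAlignment


def _pair_symbol(m: str, t: str) -> str:
    if (m, t) in _WC:
        return "|"
    if (m, t) in _WOBBLE:
        return ":"
    return " "


def best_alignment(
    mirna: str, window: str, scheme: PenaltyScheme | None = None
) -> DuplexAlignment:
    """Minimum-penalty gapped duplex of a miRNA and a candidate site window.

    ``window`` is in transcript orientation (5'->3'); internally it is
    reversed so column k of the alignment pairs miRNA position k+1 with the
    site read 3'->5'.  Gap penalties take the multiplier of the miRNA
    position they interrupt.  Ties prefer fewer gaps, then the leftmost gap.
    """
    scheme = scheme or PenaltyScheme()
    m = check_nucleotides(mirna, allow_n=False)[:scheme.scoring_length]
    w = check_nucleotides(window, allow_n=False)[::-1]
    n, L = len(m), len(w)
    if abs(L - n) > scheme.max_gaps:
        raise ValueError("window length incompatible with max_gaps")

    NO_GAP = n + 1
    # The gap limit confines states to the band |i - j| <= max_gaps, so the
    # table is O(n * max_gaps) regardless of window length.
    # state (i, j, g) -> (cost, leftmost gap position); parents for traceback
    value: dict[tuple[int, int, int], tuple[float, int]] = {(0, 0, 0): (0.0, NO_GAP)}
    parent: dict[tuple[int, int, int], tuple[tuple[int, int, int], str]] = {}

    for i in range(n + 1):
        for j in range(max(0, i - scheme.max_gaps),
                       min(L, i + scheme.max_gaps) + 1):
            for g in range(abs(i - j), scheme.max_gaps + 1):
                if (i, j, g) == (0, 0, 0):
                    continue
                cands = []
                if i > 0 and j > 0:
                    prev = value.get((i - 1, j - 1, g))
                    if prev is not None:
                        pen = scheme.column_penalty(m[i - 1], w[j - 1], i)
                        cands.append(((prev[0] + pen, prev[1], 0),
                                      (i - 1, j - 1, g), "column"))
                if g > 0:
                    gp_site = scheme.gap * scheme.multiplier(min(i + 1, n))
                    prev = value.get((i, j - 1, g - 1)) if j > 0 else None
                    if prev is not None:
                        cands.append(((prev[0] + gp_site, min(prev[1], i), 1),
                                      (i, j - 1, g - 1), "gap_site"))
                    gp_mir = scheme.gap * scheme.multiplier(min(i, n) or 1)
                    prev = value.get((i - 1, j, g - 1)) if i > 0 else None
                    if prev is not None:
                        cands.append(((prev[0] + gp_mir, min(prev[1], i - 1), 1),
                                      (i - 1, j, g - 1), "gap_mirna"))
                if not cands:
                    continue
                best = min(cands, key=lambda c: c[0])
                value[(i, j, g)] = best[0][:2]
                parent[(i, j, g)] = (best[1], best[2])

    final_state = None
    final_key = None
    for g in range(scheme.max_gaps + 1):
        v = value.get((n, L, g))
        if v is None:
            continue
        key = (v[0], g, v[1])           # cost, then fewer gaps, then leftmost
        if final_key is None or key < final_key:
            final_key, final_state = key, (n, L, g)
    if final_state is None:
        raise ValueError("no alignment within the gap limit")

    steps = []
    s = final_state
    while s != (0, 0, 0):
        prev, kind = parent[s]
        steps.append((prev, kind))
        s = prev
    steps.reverse()

    rows_m, rows_p, rows_t = [], [], []
    unpaired_positions = set()
    for (i, j, g), kind in steps:
        if kind == "column":
            sym = _pair_symbol(m[i], w[j])
            rows_m.append(m[i])
            rows_p.append(sym)
            rows_t.append(w[j])
            if sym == " ":
                unpaired_positions.add(i + 1)
        elif kind == "gap_site":
            rows_m.append("-")
            rows_p.append(" ")
            rows_t.append(w[j])
        else:
            rows_m.append(m[i])
            rows_p.append(" ")
            rows_t.append("-")
            unpaired_positions.add(i + 1)

    translational = bool(unpaired_positions & {9, 10, 11})
    cost = value[final_state][0]
    return DuplexAlignment(cost, "".join(rows_m), "".join(rows_p),
                           "".join(rows_t), final_state[2], translational)


def score_duplex(
    mirna: str, site: str, scheme: PenaltyScheme | None = None
) -> DuplexAlignment:
    """Penalty score E of a miRNA against one candidate site (transcript 5'->3')."""
    return best_alignment(mirna, site, scheme)


def scan_transcripts(
    mirna_id: str,
    mirna: str,
    transcripts: list[tuple[str, str]],
    scheme: PenaltyScheme | None = None,
) -> list[TargetPrediction]:
    """All non-overlapping sites with E <= cutoff across the transcripts.

    Windows of every length the gap limit allows slide over each
    transcript; overlapping hits keep the best (lowest E, then leftmost)
    site.  Results are sorted by E, then transcript and coordinate.
    """
    scheme = scheme or PenaltyScheme()
    m = check_nucleotides(mirna, allow_n=False)[:scheme.scoring_length]
    n = len(m)
    hits: list[TargetPrediction] = []
    for tid, tseq in transcripts:
        tseq = check_nucleotides(tseq, allow_n=False)
        cand: list[TargetPrediction] = []
        for L in range(n - scheme.max_gaps, n + scheme.max_gaps + 1):
            if L < 1 or L > len(tseq):
                continue
            for start in range(len(tseq) - L + 1):
                aln = best_alignment(m, tseq[start:start + L], scheme)
                if aln.score <= scheme.cutoff:
                    cand.append(TargetPrediction(
                        mirna_id, tid, start, start + L, aln.score, aln))
        cand.sort(key=lambda h: (h.score, h.start, h.end))
        chosen: list[TargetPrediction] = []
        for h in cand:
            if all(h.end <= c.start or h.start >= c.end for c in chosen):
                chosen.append(h)
        hits.extend(chosen)
    hits.sort(key=lambda h: (h.score, h.transcript_id, h.start))
    return hits


def predictions_table(hits: list[TargetPrediction]) -> pd.DataFrame:
    """Flat TSV-ready table of target predictions."""
    return pd.DataFrame([{
        "mirna_id": h.mirna_id, "transcript_id": h.transcript_id,
        "start": h.start, "end": h.end, "score": h.score,
        "mirna_5to3": h.alignment.mirna_row,
        "pairing": h.alignment.pairing_row,
        "site_3to5": h.alignment.target_row,
        "gaps": h.alignment.n_gaps,
        "translational": h.alignment.translational,
    } for h in hits])
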