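"""TPM normalisation and differential-expression screening for unreplicated
count libraries.

Expression is normalised to tags per million (mapped reads / clean-library
total x 10^6) with a 0.01 pseudocount substituted when the underlying count
is zero, so log2 stress/control ratios are always defined.  Significance
between two libraries uses the exact Poisson (Audic-Claverie) test: given a
count x in a library of total N1, the probability of observing y' in a
second library of total N2 is

    p(y' | x) = f^y' * (x + y')! / (x! * y'! * (1 + f)^(x + y' + 1)),
    f = N2 / N1,

evaluated in log-space via log-gamma; the two-sided p doubles the smaller
tail, capped at 1.  A Pearson chi-square on the 2x2 count table is provided
as the alternative test, FDR control is Benjamini-Hochberg, and the screen
keeps miRNAs with p < 0.01, q < 0.01 and fold change >= 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.01


@dataclass
class ScreenCriteria:
    p_threshold: float = 0.01
    fdr_threshold: float = 0.01
    fold_threshold: float = 2.0
    log2_threshold: float = 1.0
    pseudocount: float = PSEUDOCOUNT

    def __post_init__(self):
        if min(self.p_threshold, self.fdr_threshold, self.fold_threshold,
               self.log2_threshold, self.pseudocount) <= 0:
            raise ValueError("all screening thresholds must be positive")


def tpm(mapped_reads: float, clean_total: float) -> float:
    """Tags per million: mapped / clean-library total x 10^6 (unrounded)."""
    if clean_total <= 0:
        raise ValueError("clean_total must be positive")
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be nonnegative")
    return mapped_reads / clean_total * 1e6


def apply_pseudocount(
    value: float, count: int, pseudocount: float = PSEUDOCOUNT
) -> tuple[float, bool]:
    """Substitute the pseudocount for zero-count TPMs; returns (value, flagged)."""
    if value < 0:
        raise ValueError("TPM must be nonnegative")
    if count == 0:
        return pseudocount, True
    return value, False


def log2_ratio(stress: float, control: float) -> float:
    """log2(stress/control); both inputs must be pseudocount-substituted."""
    if stress <= 0 or control <= 0:
        raise ValueError("log2 ratio requires positive TPMs "
                         "(apply the pseudocount first)")
    return math.log2(stress / control)


def _ac_log_pmf(y: np.ndarray, x: int, f: float) -> np.ndarray:
    return (y * math.log(f) + gammaln(x + y + 1) - gammaln(x + 1)
            - gammaln(y + 1) - (x + y + 1) * math.log1p(f))


def ac_test(x: int, n1: int, y: int, n2: int) -> float:
    """Two-sided exact Poisson (Audic-Claverie) p-value.

    Depends on the totals only through f = N2/N1; doubling the smaller of
    P(Y <= y) and P(Y >= y), capped at 1.
    """
    if min(x, y) < 0:
        raise ValueError("counts must be nonnegative")
    if min(n1, n2) <= 0:
        raise ValueError("library totals must be positive")
    f = n2 / n1
    lower = float(np.exp(logsumexp(_ac_log_pmf(np.arange(0, y + 1), x, f))))
    # upper tail summed explicitly far past the mode so that tiny tails
    # keep full relative precision (no 1 - CDF cancellation)
    mean = (x + 1) * f
    y_max = int(max(y, mean) + 40 * math.sqrt(max(mean * (1 + f), 1.0)) + 256)
    upper = float(np.exp(logsumexp(_ac_log_pmf(np.arange(y, y_max + 1), x, f))))
    lower = min(lower, 1.0)
    upper = min(upper, 1.0)
    return min(1.0, 2.0 * min(lower, upper))


def chisq_test(x: int, n1: int, y: int, n2: int) -> tuple[float, float, bool]:
    """Pearson chi-square on [[x, N1-x], [y, N2-y]], 1 df, no correction.

    Returns (statistic, p, degenerate) where degenerate marks tables with a
    zero expected cell (p reported as 1).
    """
    if min(x, y) < 0 or x > n1 or y > n2:
        raise ValueError("invalid 2x2 table")
    a, b, c, d = x, n1 - x, y, n2 - y
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        return 0.0, 1.0, True
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1]
                                       * margins[2] * margins[3])
    return float(stat), float(chi2.sf(stat, 1)), False


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def expression_table(
    counts: pd.DataFrame,
    totals: dict[str, int],
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-miRNA TPM table with zero-substitution flags.

    ``counts`` has one row per miRNA and one column per library; ``totals``
    are the clean-read totals (the TPM denominators).
    """
    out = pd.DataFrame(index=counts.index)
    for lib in counts.columns:
        vals, flags = [], []
        for c in counts[lib]:
            v, flagged = apply_pseudocount(tpm(int(c), totals[lib]),
                                           int(c), pseudocount)
            vals.append(v)
            flags.append(flagged)
        out[f"tpm_{lib}"] = vals
        out[f"zero_{lib}"] = flags
    return out


def contrast_results(
    counts: pd.DataFrame,
    totals: dict[str, int],
    control: str,
    stress: str,
    criteria: ScreenCriteria | None = None,
    method: str = "poisson",
) -> pd.DataFrame:
    """All per-miRNA test results for one control-vs-stress contrast."""
    criteria = criteria or ScreenCriteria()
    if method not in ("poisson", "chisq"):
        raise ValueError("method must be 'poisson' or 'chisq'")
    n1, n2 = totals[control], totals[stress]
    rows = []
    for mid, row in counts.iterrows():
        x, y = int(row[control]), int(row[stress])
        tc, _ = apply_pseudocount(tpm(x, n1), x, criteria.pseudocount)
        ts, _ = apply_pseudocount(tpm(y, n2), y, criteria.pseudocount)
        if method == "poisson":
            p = ac_test(x, n1, y, n2)
        else:
            _, p, _ = chisq_test(x, n1, y, n2)
        ratio = ts / tc
        rows.append({
            "mirna_id": mid, "x": x, "y": y, "N1": n1, "N2": n2,
            "tpm_control": tc, "tpm_stress": ts,
            "p": max(p, np.finfo(float).tiny),
            "fold": max(ratio, 1.0 / ratio),
            "log2_ratio": log2_ratio(ts, tc),
        })
    result = pd.DataFrame(rows).set_index("mirna_id")
    result["q"] = np.maximum(bh_fdr(result["p"]), result["p"]) if len(result) \
        else pd.Series(dtype=float)
    return result


def screen(
    results: pd.DataFrame, criteria: ScreenCriteria | None = None
) -> pd.DataFrame:
    """Differentially expressed subset: p < alpha, q < FDR, fold >= threshold."""
    criteria = criteria or ScreenCriteria()
    if len(results) == 0:
        return results
    keep = ((results["p"] < criteria.p_threshold)
            & (results["q"] < criteria.fdr_threshold)
            & (results["fold"] >= criteria.fold_threshold))
    return results[keep]
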