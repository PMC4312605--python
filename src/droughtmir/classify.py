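"""Cross-genotype expression-pattern classification and qPCR arithmetic.

Each miRNA carries a pair of stress/control log2 ratios, one per genotype
(L1 for the drought-tolerant genotype, L2 for the drought-susceptible one).
With threshold t (default 1), the four-way rule assigns: up in both when
L1 > t and L2 > t; down in both when L1 < -t and L2 < -t; opposite when
both exceed t in magnitude with opposite signs; single-genotype when
exactly one does; otherwise unclassified.

qPCR relative expression uses the 2^-ddCT method against a reference gene
(18S rRNA), with technical-replicate CTs averaged before differencing.
"""

from __future__ import annotations

from collections import Counter
from math import isfinite

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

UP_BOTH = "up_both"
DOWN_BOTH = "down_both"
OPPOSITE = "opposite"
G1_ONLY = "genotype1_only"
G2_ONLY = "genotype2_only"
UNCLASSIFIED = "unclassified"

CATEGORIES = (UP_BOTH, DOWN_BOTH, OPPOSITE, G1_ONLY, G2_ONLY, UNCLASSIFIED)


def classify_pattern(l1: float, l2: float, threshold: float = 1.0) -> str:
    """Four-way pattern category from the two genotype log2 ratios."""
    if not (isfinite(l1) and isfinite(l2)):
        raise ValueError("log2 ratios must be finite")
    big1, big2 = abs(l1) > threshold, abs(l2) > threshold
    if big1 and big2:
        if l1 > 0 and l2 > 0:
            return UP_BOTH
        if l1 < 0 and l2 < 0:
            return DOWN_BOTH
        return OPPOSITE
    if big1:
        return G1_ONLY
    if big2:
        return G2_ONLY
    return UNCLASSIFIED


def summarize_classes(categories) -> dict[str, int]:
    """Per-category counts (all categories present, zeros included)."""
    counts = Counter(categories)
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    return {cat: counts.get(cat, 0) for cat in CATEGORIES}


def ddct(
    target_ct_stress: float,
    ref_ct_stress: float,
    target_ct_control: float,
    ref_ct_control: float,
) -> float:
    """Relative expression 2^-[(Ct_t,s - Ct_r,s) - (Ct_t,c - Ct_r,c)]."""
    for ct in (target_ct_stress, ref_ct_stress,
               target_ct_control, ref_ct_control):
        if ct <= 0:
            raise ValueError("CT values must be positive")
    ddct_value = ((target_ct_stress - ref_ct_stress)
                  - (target_ct_control - ref_ct_control))
    return float(2.0 ** (-ddct_value))


def relative_expression_table(
    ct_table: pd.DataFrame,
    reference_gene: str = "18S",
    calibrator_sample: str | None = None,
) -> pd.DataFrame:
    """Per-gene, per-sample 2^-ddCT levels from a replicated CT table.

    ``ct_table`` columns: sample, gene, role, condition, replicate, ct.
    Replicates are averaged per (sample, gene) first; the calibrator sample
    (default: the first control sample in column order) is set to 1.0.
    """
    required = {"sample", "gene", "condition", "replicate", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    mean_ct = ct_table.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    if reference_gene not in mean_ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent")
    if calibrator_sample is None:
        controls = ct_table.loc[ct_table["condition"] == "control", "sample"]
        if controls.empty:
            raise ValueError("no control sample to calibrate against")
        calibrator_sample = controls.iloc[0]
    rows = []
    for gene in mean_ct.columns:
        if gene == reference_gene:
            continue
        for sample in mean_ct.index:
            rows.append({
                "gene": gene, "sample": sample,
                "relative_expression": ddct(
                    mean_ct.loc[sample, gene],
                    mean_ct.loc[sample, reference_gene],
                    mean_ct.loc[calibrator_sample, gene],
                    mean_ct.loc[calibrator_sample, reference_gene]),
            })
    return pd.DataFrame(rows)


def mirna_target_concordance(
    mirna_levels, target_levels
) -> tuple[int, float, bool]:
    """Sign of association between paired miRNA and target relative levels.

    Pearson correlation of log2 levels across conditions; returns
    (sign, coefficient, degenerate).  Cleavage-type regulation predicts a
    negative sign.  Fewer than 3 pairs is an error; zero variance in either
    series is flagged degenerate (coefficient nan).
    """
    m = np.log2(np.asarray(mirna_levels, dtype=float))
    t = np.log2(np.asarray(target_levels, dtype=float))
    if m.shape != t.shape or m.ndim != 1:
        raise ValueError("levels must be equal-length 1-d sequences")
    if m.size < 3:
        raise ValueError("need at least 3 paired conditions")
    if np.allclose(m, m[0]) or np.allclose(t, t[0]):
        return 0, float("nan"), True
    r = float(pearsonr(m, t).statistic)
    return int(np.sign(r)), r, False
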