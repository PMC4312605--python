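"""Cascade annotation of unique tags against ordered reference sets.

Tags are assigned first-match-wins down a fixed priority order
(rRNA > tRNA > snoRNA > snRNA > [repeat] > miRNA > other), mirroring the
convention of annotating structural RNA classes before the mature miRNA
catalog so that multi-hit tags resolve deterministically.  The default
match policy is exact substring containment of the tag (either strand) in a
reference record; an optional <= 1-mismatch policy is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._seq import normalize, revcomp

PRIORITY = ("rRNA", "tRNA", "snoRNA", "snRNA", "repeat", "miRNA")
OTHER = "other"

try:
    import edlib
    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False


@dataclass
class ReferenceSet:
    """One category's reference records with a match policy."""

    category: str
    records: list[tuple[str, str]]
    policy: str = "exact"           # "exact" | "mm1"

    def __post_init__(self):
        if self.policy not in ("exact", "mm1"):
            raise ValueError(f"unknown match policy {self.policy!r}")
        if self.policy == "mm1" and not _HAVE_EDLIB:
            raise RuntimeError("mm1 policy requires the edlib package")
        if not self.records:
            raise ValueError(f"empty reference set for {self.category}")
        self.records = [(rid, normalize(seq)) for rid, seq in self.records]
        # concatenated with separators for fast exact containment scans
        self._blob = "#".join(seq for _, seq in self.records)

    def match(self, tag: str) -> str | None:
        """Id of the first record containing the tag, or None."""
        for query in (tag, revcomp(tag)):
            if self.policy == "exact":
                if query in self._blob:
                    for rid, seq in self.records:
                        if query in seq:
                            return rid
            else:
                for rid, seq in self.records:
                    res = edlib.align(query, seq, mode="HW", task="distance", k=1)
                    if res["editDistance"] >= 0:
                        return rid
        return None


def order_references(references: list[ReferenceSet]) -> list[ReferenceSet]:
    """Sort reference sets by cascade priority; unknown categories error."""
    ranks = {cat: i for i, cat in enumerate(PRIORITY)}
    unknown = [r.category for r in references if r.category not in ranks]
    if unknown:
        raise ValueError(f"unknown reference categories: {unknown}")
    if len({r.category for r in references}) != len(references):
        raise ValueError("duplicate reference categories")
    return sorted(references, key=lambda r: ranks[r.category])


def classify_tag(
    sequence: str, references: list[ReferenceSet]
) -> tuple[str, str | None]:
    """(category, matched reference id) of the first hit, or ("other", None).

    ``references`` must already be in priority order (see
    :func:`order_references`).
    """
    tag = normalize(sequence)
    for ref in references:
        rid = ref.match(tag)
        if rid is not None:
            return ref.category, rid
    return OTHER, None


def annotate_tags(
    tags: pd.DataFrame, references: list[ReferenceSet]
) -> pd.DataFrame:
    """Tag table with added ``category`` and ``match_id`` columns."""
    references = order_references(references)
    cats, mids = [], []
    for seq in tags.index:
        cat, mid = classify_tag(seq, references)
        cats.append(cat)
        mids.append(mid)
    out = tags.copy()
    out["category"] = cats
    out["match_id"] = mids
    return out


def annotation_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-category, per-library unique-tag and read counts with percentages.

    Unique percentages are denominated by each library's unique-tag total
    and read percentages by its total tag-table reads; because every clean
    read is collapsed into some tag, the latter denominator equals the
    clean-read total, so the two published denominator conventions coincide
    here.
    """
    libs = [c for c in annotated.columns if c not in ("category", "match_id")]
    cats = [c for c in (*PRIORITY, OTHER) if c in set(annotated["category"])]
    rows = []
    clean_totals = annotated[libs].sum()
    for cat in cats:
        sub = annotated[annotated["category"] == cat]
        for lib in libs:
            present = sub[lib] > 0
            rows.append({
                "category": cat, "library": lib,
                "unique_tags": int(present.sum()),
                "total_reads": int(sub[lib].sum()),
            })
    summary = pd.DataFrame(rows)
    unique_totals = {
        lib: int((annotated[lib] > 0).sum()) for lib in libs}
    summary["unique_pct"] = [
        round(r.unique_tags / unique_totals[r.library] * 100, 2)
        if unique_totals[r.library] else 0.0
        for r in summary.itertuples()]
    summary["reads_pct"] = [
        round(r.total_reads / clean_totals[r.library] * 100, 2)
        if clean_totals[r.library] else 0.0
        for r in summary.itertuples()]
    return summary


def partition_unannotated(annotated: pd.DataFrame) -> pd.DataFrame:
    """Tags labelled "other" — the input set for novel-miRNA calling."""
    return annotated[annotated["category"] == OTHER]
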