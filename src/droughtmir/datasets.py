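"""Bundled reference tables.

``conserved_mirna_table`` is the curated set of 46 conserved
dehydration-responsive wheat miRNAs from the two-genotype deep-sequencing
comparison this pipeline reimplements: per-library TPM values (C1/T1
drought-tolerant control/stress, C2/T2 drought-susceptible), the two
published log2 stress/control ratios, the published grouping and the
putative target.  TPM cells of 0.01 are pseudocount substitutions for
zero-count libraries.  The table serves as validation input for the
log2/classification arithmetic; a handful of published log2 values do not
round-trip from their printed TPMs at 2 decimals (they were evidently
computed from unrounded values, and one row shows transposed columns) —
those entries are listed in ``LOG2_ROUNDTRIP_EXCLUSIONS``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: (mirna_id, column) pairs whose published log2 value differs by more than
#: 0.01 from the value recomputed from the published 2-decimal TPMs.
LOG2_ROUNDTRIP_EXCLUSIONS = frozenset({
    ("tae-miR159a-5p", "log2_g1"),
    ("tae-miR444c.1", "log2_g2"),
    ("tae-miR829-3p", "log2_g2"),
    ("tae-miR1432", "log2_g2"),
    ("tae-miR159b", "log2_g1"),
    ("tae-miR171f", "log2_g2"),
    ("tae-miR160a", "log2_g2"),
    ("tae-miR169d", "log2_g1"),
    ("tae-miR169d", "log2_g2"),
    ("tae-miR393i", "log2_g2"),
    ("tae-miR396c", "log2_g1"),
    ("tae-miR396c", "log2_g2"),
    ("tae-miR827-5p", "log2_g2"),
    ("tae-miR156h", "log2_g1"),
    ("tae-miR528b-3p", "log2_g2"),
})


def conserved_mirna_table() -> pd.DataFrame:
    """The 46-row conserved DE miRNA table (indexed by miRNA id)."""
    ref = resources.files("droughtmir.data") / "conserved_mirna_table.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    return table.set_index("mirna_id", drop=False)
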