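"""Published reference results for the Nnat white-adipose co-expression module.

The bundled table lists the 27 genes reported to co-vary with Nnat
across four mouse white-adipose-tissue expression studies (GSE8831,
GSE4671, BAIR, DGAP), with per-dataset Pearson correlations (empty
where the gene is missing from a dataset), the combined meta Z-score,
its two-tailed p-value and the Bonferroni-adjusted value over the
6120-gene post-filter universe. It serves as a worked example for the
p-value -> Bonferroni -> significance-count arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Bonferroni multiplier of the reference analysis: unique genes passing
#: the per-dataset filters in at least one of the four studies.
REFERENCE_UNIVERSE_M = 6120

#: Genes significant in the meta-analysis but excluded afterwards because
#: they are not conserved in rat (the multi-species promoter stage needs
#: rat orthologs).
RAT_NONCONSERVED = (
    "ACP5",
    "TCTA",
    "ZNRF2",
    "SERPINA3C",
    "S3-12",
    "SGCE",
    "LRG1",
)

DATASET_COLUMNS = ("GSE8831", "GSE4671", "BAIR", "DGAP")


def load_reference_table() -> pd.DataFrame:
    """Return the 27-row reference co-expression table as a DataFrame."""
    with resources.files("coexpr_meta.data").joinpath(
        "nnat_wat_reference.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
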