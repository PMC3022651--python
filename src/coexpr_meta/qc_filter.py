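"""Probeset-level quality filters and probeset-to-gene collapse.

Three exclusion rules are applied independently within each dataset:
(a) mean intensity across samples below ``expr_min`` (default 100),
(b) absolute Pearson correlation with the target below ``abs_r_min``
(default 0.2), and (c) fraction of samples with a present (P) detection
call below ``present_frac_min`` (default 30%; marginal calls count as
not present). Rule (c) is skipped for datasets that ship no call matrix.

Surviving probesets are collapsed to one record per gene by keeping the
probeset with the largest absolute correlation (signed value reported);
ties break to the lexicographically smallest probeset id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coexpr_meta.errors import AnalysisError, ValidationError
from coexpr_meta.expression_io import ExpressionDataset


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three probeset exclusion rules.

    expr_min : minimum mean intensity (intensity units), default 100.
    abs_r_min : minimum |Pearson r| with the target, default 0.2.
    present_frac_min : minimum fraction of P calls, default 0.30.
    """

    expr_min: float = 100.0
    abs_r_min: float = 0.2
    present_frac_min: float = 0.30

    def __post_init__(self) -> None:
        if self.expr_min < 0:
            raise ValidationError("expr_min must be >= 0")
        if not 0 <= self.abs_r_min < 1:
            raise ValidationError("abs_r_min must be in [0, 1)")
        if not 0 <= self.present_frac_min <= 1:
            raise ValidationError("present_frac_min must be in [0, 1]")


def probeset_qc(
    dataset: ExpressionDataset,
    r_by_probeset: dict[str, float],
    config: FilterConfig | None = None,
) -> list[str]:
    """Return the probesets retained by exclusion rules (a), (b), (c).

    A probeset is retained iff mean intensity >= ``expr_min`` AND
    |r| >= ``abs_r_min`` AND (no call matrix OR present fraction >=
    ``present_frac_min``). Order follows the dataset. A probeset with an
    undefined correlation (NaN, e.g. a constant profile) fails rule (b).

    Raises
    ------
    AnalysisError
        If a probeset of the dataset has no entry in ``r_by_probeset``.
    """
    config = config or FilterConfig()
    missing = [p for p in dataset.probeset_ids if p not in r_by_probeset]
    if missing:
        raise AnalysisError(f"no correlation supplied for probeset {missing[0]!r}")
    r = np.array([r_by_probeset[p] for p in dataset.probeset_ids], dtype=float)
    keep = dataset.mean_intensity() >= config.expr_min
    with np.errstate(invalid="ignore"):
        keep &= np.abs(r) >= config.abs_r_min
    pfrac = dataset.present_fraction()
    if pfrac is not None:
        keep &= pfrac >= config.present_frac_min
    return [p for p, k in zip(dataset.probeset_ids, keep) if k]


def collapse_probesets(
    gene_of: dict[str, str], r_by_probeset: dict[str, float]
) -> dict[str, tuple[str, float]]:
    """Collapse retained probesets to one (probeset, r) per gene by max |r|.

    Probesets missing from ``gene_of`` are ignored (they carry no gene
    label). The signed r of the winning probeset is reported. Ties on
    |r| go to the lexicographically smallest probeset id.
    """
    best: dict[str, tuple[str, float]] = {}
    for probeset in sorted(r_by_probeset):
        gene = gene_of.get(probeset)
        if gene is None:
            continue
        r = r_by_probeset[probeset]
        incumbent = best.get(gene)
        if incumbent is None or abs(r) > abs(incumbent[1]):
            best[gene] = (probeset, r)
    return best
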