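"""Weighted Z-score meta-analysis of Pearson correlations with a target gene.

Per dataset *i*, every gene's expression profile is correlated with the
target gene's profile (Pearson r). The correlation is converted to a
t-statistic, ``t = r * sqrt(n-2) / sqrt(1 - r^2)`` with ``df = n - 2``,
and normalized to a z-score ``T_i`` through the t-CDF -> normal-quantile
transform. Per gene the dataset z-scores are combined with sample-size
weights ``w_i = n_i``:

    Z = sum_i(w_i * T_i) / D,   D = sum_i(w_i)            (sum_weights)
                                D = sqrt(sum_i(w_i^2))    (rss_weights)

``sum_weights`` is the default; ``rss_weights`` is the classical
Stouffer denominator that makes Z standard normal under the null (the
sum_weights variant is conservative). Genes missing from a dataset are
combined over the available datasets only, with the missing dataset's
weight dropped from the denominator. A two-tailed normal p-value is
taken from Z and Bonferroni-adjusted over the post-filter gene universe.

An inverse-variance Fisher z-transform combination is provided as an
alternative: ``zeta = atanh(r)`` with variance ``1/(n-3)``, combined as
``sum((n_i-3) * zeta_i) / sqrt(sum(n_i-3))``.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from coexpr_meta.errors import AnalysisError, ValidationError
from coexpr_meta.expression_io import ExpressionDataset
from coexpr_meta.qc_filter import FilterConfig, collapse_probesets, probeset_qc

METHODS = ("weighted_z", "fisher_z")
DENOMINATORS = ("sum_weights", "rss_weights")
T_TO_Z_MODES = ("quantile", "identity")


@dataclass(frozen=True)
class CorrelationRecord:
    """One gene's correlation evidence from one dataset."""

    gene: str
    dataset: str
    r: float
    n: int
    t: float
    z: float


@dataclass(frozen=True)
class MetaConfig:
    """Configuration of the combination step.

    method : "weighted_z" (default) or "fisher_z".
    denominator : "sum_weights" (default) or "rss_weights" (Stouffer).
    t_to_z_mode : "quantile" (default) or "identity" (large-df shortcut).
    universe_m : Bonferroni multiplier; defaults to the post-filter
        union of genes across datasets when None.
    alpha : family-wise significance level, default 0.05.
    """

    method: str = "weighted_z"
    denominator: str = "sum_weights"
    t_to_z_mode: str = "quantile"
    universe_m: int | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.denominator not in DENOMINATORS:
            raise ValidationError(f"unknown denominator {self.denominator!r}")
        if self.t_to_z_mode not in T_TO_Z_MODES:
            raise ValidationError(f"unknown t_to_z_mode {self.t_to_z_mode!r}")
        if self.universe_m is not None and self.universe_m < 1:
            raise ValidationError("universe_m must be positive")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class MetaResult:
    """One output row: a gene's combined evidence across datasets."""

    gene: str
    r_by_dataset: dict[str, float]
    z_combined: float
    p_two: float
    p_bonf: float
    n_datasets: int


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("x and y must be equal-length vectors")
    if x.size < 3:
        raise AnalysisError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise AnalysisError("correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / math.sqrt(vx * vy), -1.0, 1.0))


def r_to_t(r: float, n: int) -> float:
    """t-statistic of a Pearson correlation, df = n - 2."""
    if n < 4:
        raise AnalysisError(f"need n >= 4 samples, got {n}")
    if abs(r) >= 1.0:
        raise AnalysisError(f"|r| must be < 1 for a finite t (r={r})")
    return r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)


def t_to_z(t: float, df: int, mode: str = "quantile") -> float:
    """Map a t-statistic to a standard-normal z.

    ``quantile`` mode pushes t through its CDF and back through the
    normal quantile (sign-preserving, monotone); ``identity`` returns t
    unchanged (adequate at large df).
    """
    if df < 1:
        raise AnalysisError(f"df must be >= 1, got {df}")
    if mode == "identity":
        return float(t)
    if mode != "quantile":
        raise AnalysisError(f"unknown t_to_z mode {mode!r}")
    # Work in the upper tail for accuracy at large |t|.
    a = abs(float(t))
    z = float(stats.norm.isf(stats.t.sf(a, df)))
    return math.copysign(z, t) if t != 0 else 0.0


def _t_to_z_vec(t: np.ndarray, df: int, mode: str) -> np.ndarray:
    if mode == "identity":
        return np.asarray(t, dtype=float)
    a = np.abs(t)
    z = stats.norm.isf(stats.t.sf(a, df))
    return np.where(t < 0, -z, z)


def combine_weighted_z(records, weights: dict[str, float], config: MetaConfig) -> float:
    """Combine one gene's per-dataset z-scores with the configured denominator."""
    records = list(records)
    if not records:
        raise AnalysisError("cannot combine an empty record set")
    for rec in records:
        if rec.dataset not in weights:
            raise AnalysisError(f"no weight for dataset {rec.dataset!r}")
        if weights[rec.dataset] <= 0:
            raise AnalysisError(f"non-positive weight for dataset {rec.dataset!r}")
    w = np.array([weights[rec.dataset] for rec in records], dtype=float)
    z = np.array([rec.z for rec in records], dtype=float)
    num = float(w @ z)
    if config.denominator == "rss_weights":
        return num / math.sqrt(float(w @ w))
    return num / float(w.sum())


def fisher_z_combine(records, weights: dict[str, float], config: MetaConfig) -> float:
    """Inverse-variance combination of Fisher-transformed correlations.

    ``weights`` is accepted for interface symmetry; the variance weights
    ``n_i - 3`` come from the records themselves.
    """
    records = list(records)
    if not records:
        raise AnalysisError("cannot combine an empty record set")
    for rec in records:
        if rec.n < 4:
            raise AnalysisError(f"need n >= 4, got {rec.n} in {rec.dataset!r}")
    w = np.array([rec.n - 3 for rec in records], dtype=float)
    zeta = np.array([math.atanh(rec.r) for rec in records], dtype=float)
    return float(w @ zeta) / math.sqrt(float(w.sum()))


def p_from_z(z: float) -> float:
    """Two-tailed standard-normal p-value, accurate deep into the tail."""
    if not math.isfinite(z):
        raise AnalysisError("z must be finite")
    return math.erfc(abs(z) / math.sqrt(2.0))


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni family-wise adjustment: min(1, p * m)."""
    if not 0 < p <= 1:
        raise AnalysisError(f"p must be in (0, 1], got {p}")
    if m < 1:
        raise AnalysisError(f"m must be a positive integer, got {m}")
    return min(1.0, p * m)


def _pearson_rows(matrix: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Pearson r of every matrix row against ``profile``; NaN where undefined."""
    xc = matrix - matrix.mean(axis=1, keepdims=True)
    yc = profile - profile.mean()
    denom = np.sqrt((xc * xc).sum(axis=1) * float(yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    return np.clip(r, -1.0, 1.0)


def choose_target_probeset(dataset: ExpressionDataset, candidates) -> str:
    """Pick the target gene's representative probeset.

    Preference order: most present (P) calls, then highest mean
    intensity, then lexicographically smallest id.
    """
    pfrac = dataset.present_fraction()
    means = dataset.mean_intensity()

    def key(pid: str):
        i = dataset.row_index(pid)
        presence = pfrac[i] if pfrac is not None else 0.0
        return (-presence, -means[i], pid)

    return min(candidates, key=key)


@dataclass
class DatasetSummary:
    """Per-dataset bookkeeping from a meta-analysis run."""

    name: str
    n_samples: int
    target_probeset: str
    n_probesets: int
    n_retained_probesets: int
    n_genes: int


@dataclass
class MetaAnalysis:
    """Ordered collection of significant :class:`MetaResult` rows plus run stats.

    Iterating, indexing and ``len`` act on the significant rows (after
    the optional exclusion list), sorted by decreasing combined Z.
    """

    results: list[MetaResult]
    universe_m: int
    alpha: float
    pre_exclusion_count: int
    excluded_hits: list[str]
    dataset_summaries: list[DatasetSummary] = field(default_factory=list)
    all_results: list[MetaResult] = field(default_factory=list)

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, i):
        return self.results[i]

    @property
    def genes(self) -> list[str]:
        return [r.gene for r in self.results]


def run_meta(
    datasets,
    target: str,
    filter_cfg: FilterConfig | None = None,
    meta_cfg: MetaConfig | None = None,
    exclusions=None,
) -> MetaAnalysis:
    """Run the full correlate -> filter -> collapse -> combine meta-analysis.

    Parameters
    ----------
    datasets
        ExpressionDatasets with gene annotation attached; the target
        gene must be annotated in every one.
    target
        Gene symbol whose co-expression partners are sought (case
        insensitive). The target itself is never reported.
    exclusions
        Optional gene symbols dropped from the significant rows *after*
        the significance cut (so both counts are reported).

    Returns
    -------
    MetaAnalysis
        Significant rows (Bonferroni-adjusted p < alpha) sorted by
        decreasing combined Z, plus the universe size and per-dataset
        summaries.
    """
    datasets = list(datasets)
    if not datasets:
        raise AnalysisError("need at least one dataset")
    target = target.upper()
    filter_cfg = filter_cfg or FilterConfig()
    meta_cfg = meta_cfg or MetaConfig()
    exclusions = {g.upper() for g in (exclusions or ())}

    records_by_gene: dict[str, list[CorrelationRecord]] = defaultdict(list)
    weights: dict[str, float] = {}
    summaries: list[DatasetSummary] = []

    for ds in datasets:
        target_probes = [p for p in ds.probeset_ids if ds.gene_of.get(p) == target]
        if not target_probes:
            raise AnalysisError(
                f"target gene {target!r} is not annotated in dataset {ds.name!r}"
            )
        tprobe = choose_target_probeset(ds, target_probes)
        profile = ds.intensities[ds.row_index(tprobe)]
        if np.ptp(profile) == 0:
            raise AnalysisError(
                f"target profile is constant in dataset {ds.name!r}"
            )
        r_vec = _pearson_rows(ds.intensities, profile)
        r_by_probeset = dict(zip(ds.probeset_ids, r_vec))
        retained = probeset_qc(ds, r_by_probeset, filter_cfg)
        candidates = {
            p: float(r_by_probeset[p])
            for p in retained
            if ds.gene_of.get(p) is not None and ds.gene_of[p] != target
        }
        collapsed = collapse_probesets(ds.gene_of, candidates)
        n = ds.n_samples
        weights[ds.name] = float(n)
        genes = list(collapsed)
        r_arr = np.array([collapsed[g][1] for g in genes], dtype=float)
        if np.any(np.abs(r_arr) >= 1.0):
            bad = genes[int(np.argmax(np.abs(r_arr) >= 1.0))]
            raise AnalysisError(
                f"|r| = 1 for gene {bad!r} in dataset {ds.name!r}: t undefined"
            )
        t_arr = r_arr * math.sqrt(n - 2) / np.sqrt(1.0 - r_arr * r_arr)
        z_arr = _t_to_z_vec(t_arr, n - 2, meta_cfg.t_to_z_mode)
        for gene, r, t, z in zip(genes, r_arr, t_arr, z_arr):
            records_by_gene[gene].append(
                CorrelationRecord(
                    gene=gene, dataset=ds.name, r=float(r), n=n,
                    t=float(t), z=float(z),
                )
            )
        summaries.append(
            DatasetSummary(
                name=ds.name,
                n_samples=n,
                target_probeset=tprobe,
                n_probesets=len(ds.probeset_ids),
                n_retained_probesets=len(retained),
                n_genes=len(collapsed),
            )
        )

    n_tested = len(records_by_gene)
    if meta_cfg.universe_m is not None:
        if meta_cfg.universe_m < n_tested:
            raise ValidationError(
                f"universe_m={meta_cfg.universe_m} smaller than the "
                f"{n_tested} tested genes"
            )
        m = meta_cfg.universe_m
    else:
        m = max(n_tested, 1)

    combine = combine_weighted_z if meta_cfg.method == "weighted_z" else fisher_z_combine
    all_results: list[MetaResult] = []
    for gene, records in records_by_gene.items():
        z = combine(records, weights, meta_cfg)
        p = p_from_z(z)
        all_results.append(
            MetaResult(
                gene=gene,
                r_by_dataset={rec.dataset: rec.r for rec in records},
                z_combined=z,
                p_two=p,
                p_bonf=bonferroni_adjust(p, m),
                n_datasets=len(records),
            )
        )
    all_results.sort(key=lambda res: (-res.z_combined, res.gene))
    significant = [res for res in all_results if res.p_bonf < meta_cfg.alpha]
    excluded_hits = sorted(res.gene for res in significant if res.gene in exclusions)
    kept = [res for res in significant if res.gene not in exclusions]
    return MetaAnalysis(
        results=kept,
        universe_m=m,
        alpha=meta_cfg.alpha,
        pre_exclusion_count=len(significant),
        excluded_hits=excluded_hits,
        dataset_summaries=summaries,
        all_results=all_results,
    )


def fold_change(
    dataset: ExpressionDataset, group_a, group_b
) -> dict[str, float]:
    """Per-gene linear-scale ratio of group mean intensities (A over B).

    Each gene is represented by its highest-mean probeset (over all
    samples; ties to the lexicographically smallest id). Probesets
    without gene annotation are ignored.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise AnalysisError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise AnalysisError("groups must be disjoint")
    for sid in group_a + group_b:
        if sid not in dataset.sample_ids:
            raise AnalysisError(f"unknown sample id {sid!r}")
    col = {s: j for j, s in enumerate(dataset.sample_ids)}
    ja = [col[s] for s in group_a]
    jb = [col[s] for s in group_b]
    means = dataset.mean_intensity()
    winner: dict[str, str] = {}
    for pid in sorted(dataset.probeset_ids):
        gene = dataset.gene_of.get(pid)
        if gene is None:
            continue
        if gene not in winner or means[dataset.row_index(pid)] > means[
            dataset.row_index(winner[gene])
        ]:
            winner[gene] = pid
    ratios: dict[str, float] = {}
    for gene, pid in winner.items():
        row = dataset.intensities[dataset.row_index(pid)]
        mb = float(row[jb].mean())
        if mb == 0.0:
            raise AnalysisError(f"zero group-B mean for gene {gene!r}")
        ratios[gene] = float(row[ja].mean()) / mb
    return ratios
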