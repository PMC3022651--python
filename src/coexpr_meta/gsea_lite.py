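"""GSEA-style gene-set enrichment against a correlation ranking.

Genes are ranked by decreasing Pearson correlation with the target
gene's expression profile. For a gene set, a weighted Kolmogorov-
Smirnov running sum walks the ranked list: a hit at position *i*
increments by ``|s_i|^p / N_R`` (``N_R`` = sum of ``|s|^p`` over hits,
exponent ``p`` = 1 by default; ``p`` = 0 gives the classic KS
statistic), a miss decrements by ``1 / (N - N_hits)``. The enrichment
score (ES) is the running sum's signed maximum deviation from zero.

Significance comes from a phenotype permutation null: the target
profile is permuted across samples, genes re-ranked, and ES recomputed;
the add-one permutation p-value counts same-sign null scores at least
as extreme. NES normalizes ES by the mean |null ES| of the same sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coexpr_meta.errors import AnalysisError, ValidationError
from coexpr_meta.expression_io import ExpressionDataset
from coexpr_meta.qc_filter import FilterConfig, collapse_probesets, probeset_qc
from coexpr_meta.correlation_meta import _pearson_rows, choose_target_probeset


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique, uppercased gene symbols."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        members = frozenset(str(m).upper() for m in self.members)
        if not members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", members)


@dataclass(frozen=True)
class RankedList:
    """Genes with a non-increasing ranking metric (correlation with target)."""

    genes: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "scores", scores)
        if len(genes) != scores.size:
            raise ValidationError("genes and scores differ in length")
        if len(set(genes)) != len(genes):
            raise ValidationError("ranked genes must be unique")
        if np.any(np.diff(scores) > 0):
            raise ValidationError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    overlap: int
    q_approx: float | None = None  # pooled-null q-value, approximate


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, members...; tab-delimited)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT line {lineno}: need name, description and >= 1 member"
                )
            members = [p for p in parts[2:] if p.strip()]
            if not members:
                raise ValidationError(f"GMT line {lineno}: no members")
            sets.append(GeneSet(name=parts[0], members=frozenset(members)))
    return sets


def _collapsed_gene_matrix(
    dataset: ExpressionDataset,
    target: str,
    filter_cfg: FilterConfig | None,
):
    """Collapse a dataset to one row per gene, ranked-ready.

    Returns (genes, matrix, target_profile) where each gene's row is its
    max-|r| probeset (after optional QC filtering with the |r| rule
    disabled — the ranking keeps weak correlations, mirroring a
    presence/abundance-only pre-filter).
    """
    target = target.upper()
    target_probes = [p for p in dataset.probeset_ids if dataset.gene_of.get(p) == target]
    if not target_probes:
        raise AnalysisError(f"target gene {target!r} not annotated in {dataset.name!r}")
    tprobe = choose_target_probeset(dataset, target_probes)
    profile = dataset.intensities[dataset.row_index(tprobe)]
    r_vec = _pearson_rows(dataset.intensities, profile)
    r_by_probeset = dict(zip(dataset.probeset_ids, r_vec))
    if filter_cfg is not None:
        cfg = FilterConfig(
            expr_min=filter_cfg.expr_min,
            abs_r_min=0.0,
            present_frac_min=filter_cfg.present_frac_min,
        )
        pool = probeset_qc(dataset, r_by_probeset, cfg)
    else:
        pool = list(dataset.probeset_ids)
    candidates = {
        p: float(r_by_probeset[p])
        for p in pool
        if dataset.gene_of.get(p) not in (None, target)
        and np.isfinite(r_by_probeset[p])
    }
    collapsed = collapse_probesets(dataset.gene_of, candidates)
    genes = list(collapsed)
    rows = [dataset.row_index(collapsed[g][0]) for g in genes]
    return genes, dataset.intensities[rows], profile


def _rank(genes, r) -> tuple[tuple[str, ...], np.ndarray]:
    order = sorted(range(len(genes)), key=lambda i: (-r[i], genes[i]))
    return tuple(genes[i] for i in order), r[order]


def rank_by_correlation(
    dataset: ExpressionDataset,
    target: str,
    filter_cfg: FilterConfig | None = None,
) -> RankedList:
    """Rank genes by decreasing Pearson correlation with the target profile.

    The dataset is collapsed to gene level first (max-|r| probeset per
    gene); the target itself is excluded; ties break lexicographically.
    When ``filter_cfg`` is given, the abundance and present-call rules
    are applied before ranking (the |r| rule is not, so the full ranking
    is retained).
    """
    genes, matrix, profile = _collapsed_gene_matrix(dataset, target, filter_cfg)
    r = _pearson_rows(matrix, profile)
    genes_sorted, scores = _rank(genes, r)
    return RankedList(genes=genes_sorted, scores=scores)


def filter_gene_sets(
    sets, min_size: int = 15, max_size: int = 500, universe=None
) -> list[GeneSet]:
    """Keep sets whose overlap with the ranked universe is strictly between
    ``min_size`` and ``max_size``."""
    if universe is None:
        raise ValidationError("a ranked universe is required")
    uni = {g.upper() for g in universe}
    kept = []
    for s in sets:
        overlap = len(s.members & uni)
        if min_size < overlap < max_size:
            kept.append(s)
    return kept


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, exponent: float = 1.0
):
    """Weighted KS enrichment score and its running sum.

    Returns ``(es, running_sum)``; the running sum has one entry per
    ranked gene and returns to 0 at the end.
    """
    hit = np.array([g in gene_set.members for g in ranked.genes], dtype=bool)
    n = len(ranked)
    n_hits = int(hit.sum())
    if n_hits == 0 or n_hits == n:
        raise AnalysisError(
            f"gene set {gene_set.name!r}: overlap {n_hits} of {n} is degenerate"
        )
    running = _running_sum(ranked.scores, hit, exponent)
    es = float(running[int(np.argmax(np.abs(running)))])
    return es, running


def _running_sum(scores: np.ndarray, hit: np.ndarray, exponent: float) -> np.ndarray:
    n = scores.size
    n_hits = int(hit.sum())
    w = np.abs(scores[hit]) ** exponent
    total = w.sum()
    steps = np.full(n, -1.0 / (n - n_hits))
    if total > 0:
        steps[hit] = w / total
    else:  # all in-set scores exactly 0: fall back to equal hit weights
        steps[hit] = 1.0 / n_hits
    return np.cumsum(steps)


def _es_only(scores: np.ndarray, hit: np.ndarray, exponent: float) -> float:
    running = _running_sum(scores, hit, exponent)
    return float(running[int(np.argmax(np.abs(running)))])


def permutation_test(
    dataset: ExpressionDataset,
    target: str,
    sets,
    n_perm: int = 1000,
    exponent: float = 1.0,
    seed: int = 0,
    filter_cfg: FilterConfig | None = None,
) -> list[EnrichmentResult]:
    """Phenotype-permutation significance for each gene set.

    The target profile is permuted across samples ``n_perm`` times;
    genes are re-ranked against each permuted profile and ES recomputed
    (the probeset-to-gene collapse stays fixed from the observed
    profile). ``p_perm = (1 + #{same-sign |ES*| >= |ES|}) / (1 + n_perm)``
    and ``NES = ES / mean |same-sign null ES|``. Deterministic for a
    fixed seed.
    """
    if n_perm < 1:
        raise AnalysisError("n_perm must be >= 1")
    sets = list(sets)
    genes, matrix, profile = _collapsed_gene_matrix(dataset, target, filter_cfg)
    r_obs = _pearson_rows(matrix, profile)
    genes_sorted, scores_obs = _rank(genes, r_obs)

    hits_obs = []
    es_obs = []
    masks = []  # membership over the *unsorted* gene list, for permutations
    for s in sets:
        ranked = RankedList(genes=genes_sorted, scores=scores_obs)
        es, _ = enrichment_score(ranked, s, exponent)
        es_obs.append(es)
        hits_obs.append(sum(1 for g in genes_sorted if g in s.members))
        masks.append(np.array([g in s.members for g in genes], dtype=bool))

    rng = np.random.default_rng(seed)
    null_es = np.empty((n_perm, len(sets)))
    for b in range(n_perm):
        perm_profile = profile[rng.permutation(profile.size)]
        r_null = _pearson_rows(matrix, perm_profile)
        order = np.argsort(-r_null, kind="stable")
        scores_null = r_null[order]
        for j, mask in enumerate(masks):
            null_es[b, j] = _es_only(scores_null, mask[order], exponent)

    results = []
    for j, s in enumerate(sets):
        es = es_obs[j]
        same_sign = null_es[:, j] * es >= 0 if es != 0 else np.ones(n_perm, bool)
        nulls = null_es[same_sign, j]
        count = int(np.sum(np.abs(nulls) >= abs(es)))
        p = (1 + count) / (1 + n_perm)
        mean_abs = float(np.mean(np.abs(nulls))) if nulls.size else np.nan
        nes = es / mean_abs if mean_abs and np.isfinite(mean_abs) else float("nan")
        results.append(
            EnrichmentResult(
                set_name=s.name, es=es, nes=nes, p_perm=p, overlap=hits_obs[j]
            )
        )
    return _attach_q(results, null_es, es_obs)


def _attach_q(results, null_es, es_obs):
    """Approximate q-values from the pooled same-sign null NES distribution."""
    out = []
    # normalize nulls per set by that set's same-sign mean |null|
    pooled = []
    for j in range(null_es.shape[1]):
        col = null_es[:, j]
        for sign in (1, -1):
            part = col[col * sign > 0]
            if part.size:
                pooled.extend(sign * np.abs(part) / np.mean(np.abs(part)))
    pooled = np.asarray(pooled) if pooled else np.array([0.0])
    nes_all = np.array([r.nes for r in results])
    for res in results:
        if not np.isfinite(res.nes):
            out.append(res)
            continue
        if res.nes >= 0:
            frac_null = np.mean(pooled >= res.nes)
            denom = np.mean(nes_all[np.isfinite(nes_all)] >= res.nes)
        else:
            frac_null = np.mean(pooled <= res.nes)
            denom = np.mean(nes_all[np.isfinite(nes_all)] <= res.nes)
        q = float(min(1.0, frac_null / denom)) if denom > 0 else 1.0
        out.append(
            EnrichmentResult(
                set_name=res.set_name, es=res.es, nes=res.nes,
                p_perm=res.p_perm, overlap=res.overlap, q_approx=q,
            )
        )
    return out


def write_enrichment_table(results, path) -> None:
    """TSV report: set, size, ES, NES, p, q."""
    with open(path, "w") as fh:
        fh.write("set\tsize\tes\tnes\tp_perm\tq_approx\n")
        for res in sorted(results, key=lambda r: (r.p_perm, r.set_name)):
            q = "" if res.q_approx is None else f"{res.q_approx:.4f}"
            fh.write(
                f"{res.set_name}\t{res.overlap}\t{res.es:.4f}\t{res.nes:.4f}"
                f"\t{res.p_perm:.4g}\t{q}\n"
            )
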