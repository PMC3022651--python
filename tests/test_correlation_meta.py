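import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coexpr_meta.errors import AnalysisError, ValidationError
from coexpr_meta.correlation_meta import (
    CorrelationRecord,
    MetaConfig,
    bonferroni_adjust,
    combine_weighted_z,
    fisher_z_combine,
    fold_change,
    p_from_z,
    pearson_r,
    r_to_t,
    run_meta,
    t_to_z,
)
from coexpr_meta.qc_filter import FilterConfig
from coexpr_meta.synthetic_data import SyntheticConfig, generate

from conftest import make_dataset


def rec(z, dataset="d1", r=0.5, n=10):
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    return CorrelationRecord("G", dataset, r, n, t, z)


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            # hand evaluation: cov-sum 4.0, var-sums 5.0 each -> 4/5
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(AnalysisError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestRToT:
    def test_null_case(self):
        assert r_to_t(0.0, 25) == 0.0

    def test_hand_value(self):
        # 0.8 * sqrt(2) / 0.6
        assert r_to_t(0.8, 4) == pytest.approx(1.8856180831641276, rel=1e-12)

    @pytest.mark.parametrize("r,n", [(1.0, 10), (-1.0, 10), (0.5, 3)])
    def test_domain_errors(self, r, n):
        with pytest.raises(AnalysisError):
            r_to_t(r, n)


class TestTToZ:
    def test_zero_maps_to_zero_in_both_modes(self):
        assert t_to_z(0.0, 5, "quantile") == 0.0
        assert t_to_z(0.0, 5, "identity") == 0.0

    def test_large_df_approaches_identity(self):
        assert t_to_z(2.0, 10**6, "quantile") == pytest.approx(2.0, abs=1e-3)

    def test_small_df_quantile_value(self):
        # t = 0.8*sqrt(2)/0.6 sits exactly at the 0.9 quantile of t(df=2);
        # frozen from an arbitrary-precision CDF evaluation
        z = t_to_z(1.8856180831641276, 2, "quantile")
        assert z == pytest.approx(1.2815515655446004, rel=1e-10)

    def test_sign_symmetry(self):
        assert t_to_z(-3.2, 7) == pytest.approx(-t_to_z(3.2, 7), rel=1e-12)

    @given(st.floats(-30, 30), st.integers(3, 200))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_strictly_increasing_in_t(self, t, df):
        eps = 1e-3
        assert t_to_z(t + eps, df) > t_to_z(t, df)


class TestCombineWeightedZ:
    def test_single_record_identity_both_modes(self):
        for denominator in ("sum_weights", "rss_weights"):
            cfg = MetaConfig(denominator=denominator)
            assert combine_weighted_z([rec(2.5)], {"d1": 40}, cfg) == pytest.approx(2.5)

    def test_equal_weight_identities(self):
        records = [rec(1.0, "d1"), rec(1.0, "d2")]
        w = {"d1": 10, "d2": 10}
        assert combine_weighted_z(records, w, MetaConfig()) == pytest.approx(1.0)
        assert combine_weighted_z(
            records, w, MetaConfig(denominator="rss_weights")
        ) == pytest.approx(math.sqrt(2))

    def test_equal_weights_reduce_to_mean_and_stouffer(self):
        zs = [0.3, -1.2, 2.4]
        records = [rec(z, f"d{i}") for i, z in enumerate(zs)]
        w = {f"d{i}": 7 for i in range(3)}
        assert combine_weighted_z(records, w, MetaConfig()) == pytest.approx(
            np.mean(zs)
        )
        assert combine_weighted_z(
            records, w, MetaConfig(denominator="rss_weights")
        ) == pytest.approx(np.mean(zs) * math.sqrt(3))

    def test_monotone_in_each_z(self):
        w = {"d1": 40, "d2": 13}
        lo = combine_weighted_z([rec(1.0, "d1"), rec(0.5, "d2")], w, MetaConfig())
        hi = combine_weighted_z([rec(1.0, "d1"), rec(0.9, "d2")], w, MetaConfig())
        assert hi > lo

    def test_empty_and_unknown_dataset_errors(self):
        with pytest.raises(AnalysisError):
            combine_weighted_z([], {"d1": 1}, MetaConfig())
        with pytest.raises(AnalysisError, match="weight"):
            combine_weighted_z([rec(1.0, "dX")], {"d1": 1}, MetaConfig())


class TestFisherZCombine:
    def test_all_zero_r(self):
        records = [rec(0.0, f"d{i}", r=0.0, n=10) for i in range(3)]
        assert fisher_z_combine(records, {}, MetaConfig()) == 0.0

    def test_single_record_value(self):
        # atanh(0.5) * sqrt(12 - 3) = 0.549306 * 3
        r = rec(1.0, "d1", r=0.5, n=12)
        assert fisher_z_combine([r], {}, MetaConfig()) == pytest.approx(
            1.6479184330021643, rel=1e-12
        )

    def test_duplicating_records_scales_by_sqrt2(self):
        one = [rec(1.0, "d1", r=0.4, n=20)]
        two = one + [rec(1.0, "d2", r=0.4, n=20)]
        assert fisher_z_combine(two, {}, MetaConfig()) == pytest.approx(
            fisher_z_combine(one, {}, MetaConfig()) * math.sqrt(2)
        )


class TestPFromZ:
    def test_zero(self):
        assert p_from_z(0.0) == 1.0

    def test_symmetry(self):
        assert p_from_z(3.7) == p_from_z(-3.7)

    def test_deep_tail_value(self):
        # frozen from an arbitrary-precision erfc evaluation
        assert p_from_z(6.155) == pytest.approx(7.5077495560085e-10, rel=1e-10)

    @given(st.floats(0, 8), st.floats(0.01, 2))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_strictly_decreasing_in_abs_z(self, z, step):
        assert p_from_z(z + step) < p_from_z(z)


class TestBonferroni:
    def test_worked_example_rows(self):
        assert bonferroni_adjust(7.50e-10, 6120) == pytest.approx(4.59e-6, rel=1e-3)
        assert bonferroni_adjust(7.42e-6, 6120) == pytest.approx(0.0454, rel=1e-2)

    def test_cap_and_identity(self):
        assert bonferroni_adjust(0.5, 3) == 1.0
        assert bonferroni_adjust(0.123, 1) == 0.123

    @given(st.floats(1e-12, 1), st.integers(1, 10**6))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_never_below_raw_p(self, p, m):
        adj = bonferroni_adjust(p, m)
        assert p <= adj <= 1.0


# --- full-pipeline oracle --------------------------------------------------


def brute_force_meta(datasets, target, filter_cfg, meta_cfg):
    """Straight-line re-implementation of the meta-analysis.

    Scalar, dictionary-based, using numpy.corrcoef and scipy CDFs
    directly; independent of the vectorized production path.
    """
    target = target.upper()
    per_gene = {}
    weights = {}
    for ds in datasets:
        idx = {p: i for i, p in enumerate(ds.probeset_ids)}
        tprobes = sorted(
            (p for p in ds.probeset_ids if ds.gene_of.get(p) == target),
            key=lambda p: (
                -(ds.calls[idx[p]] == "P").mean() if ds.calls is not None else 0.0,
                -ds.intensities[idx[p]].mean(),
                p,
            ),
        )
        profile = ds.intensities[idx[tprobes[0]]]
        n = len(ds.sample_ids)
        weights[ds.name] = n
        per_probe_r = {}
        for p in ds.probeset_ids:
            row = ds.intensities[idx[p]]
            if row.std() == 0 or profile.std() == 0:
                continue
            per_probe_r[p] = float(np.corrcoef(row, profile)[0, 1])
        best = {}
        for p, r in sorted(per_probe_r.items()):
            gene = ds.gene_of.get(p)
            if gene is None or gene == target:
                continue
            if ds.intensities[idx[p]].mean() < filter_cfg.expr_min:
                continue
            if abs(r) < filter_cfg.abs_r_min:
                continue
            if ds.calls is not None:
                if (ds.calls[idx[p]] == "P").mean() < filter_cfg.present_frac_min:
                    continue
            if gene not in best or abs(r) > abs(best[gene][1]):
                best[gene] = (p, r)
        for gene, (p, r) in best.items():
            t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
            if meta_cfg.t_to_z_mode == "quantile":
                z = float(stats.norm.ppf(stats.t.cdf(t, n - 2)))
            else:
                z = t
            per_gene.setdefault(gene, []).append((ds.name, r, n, z))
    m = len(per_gene)
    rows = {}
    for gene, entries in per_gene.items():
        num = sum(weights[name] * z for (name, _r, _n, z) in entries)
        den = sum(weights[name] for (name, _, _, _) in entries)
        zc = num / den
        p = 2 * stats.norm.sf(abs(zc))
        rows[gene] = (zc, p, min(1.0, p * m))
    return rows, m


@pytest.fixture(scope="module")
def small_fixture():
    cfg = SyntheticConfig(
        n_genes=40,
        n_planted=8,
        n_datasets=2,
        samples_per_dataset=(12, 9),
        probesets_per_gene=2,
        seed=11,
    )
    return generate(cfg)


class TestRunMeta:
    def test_matches_brute_force_oracle(self, small_fixture):
        datasets, _ = small_fixture
        filter_cfg, meta_cfg = FilterConfig(), MetaConfig(alpha=1.0)
        analysis = run_meta(datasets, "NNAT", filter_cfg, meta_cfg)
        expected, m = brute_force_meta(datasets, "NNAT", filter_cfg, meta_cfg)
        assert analysis.universe_m == m
        got = {r.gene: r for r in analysis.all_results}
        assert set(got) == set(expected)
        for gene, (zc, p, pb) in expected.items():
            assert got[gene].z_combined == pytest.approx(zc, rel=1e-10)
            assert got[gene].p_two == pytest.approx(p, rel=1e-10)
            assert got[gene].p_bonf == pytest.approx(pb, rel=1e-10)

    def test_single_dataset_z_equals_own_z(self, small_fixture):
        datasets, _ = small_fixture
        analysis = run_meta(datasets[:1], "NNAT", meta_cfg=MetaConfig(alpha=1.0))
        for res in analysis.all_results:
            r = res.r_by_dataset[datasets[0].name]
            n = datasets[0].n_samples
            t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
            assert res.z_combined == pytest.approx(t_to_z(t, n - 2), rel=1e-12)

    def test_planted_module_recovered_at_default_config(self):
        datasets, truth = generate(SyntheticConfig(seed=0))
        analysis = run_meta(datasets, truth.target)
        assert set(truth.planted_genes) <= set(analysis.genes)

    def test_target_never_reported(self, small_fixture):
        datasets, _ = small_fixture
        analysis = run_meta(datasets, "NNAT", meta_cfg=MetaConfig(alpha=1.0))
        assert "NNAT" not in {r.gene for r in analysis.all_results}

    def test_exclusions_applied_after_significance(self, small_fixture):
        datasets, truth = small_fixture
        full = run_meta(datasets, "NNAT")
        assert len(full) > 0
        excluded_gene = full.genes[0]
        pruned = run_meta(datasets, "NNAT", exclusions=[excluded_gene.lower()])
        assert excluded_gene not in pruned.genes
        assert pruned.pre_exclusion_count == full.pre_exclusion_count
        assert pruned.excluded_hits == [excluded_gene]

    def test_target_absent_names_dataset(self, small_fixture):
        datasets, _ = small_fixture
        with pytest.raises(AnalysisError, match=datasets[0].name):
            run_meta(datasets, "NO_SUCH_GENE")

    def test_universe_override_must_cover_tested_genes(self, small_fixture):
        datasets, _ = small_fixture
        with pytest.raises(ValidationError, match="universe_m"):
            run_meta(datasets, "NNAT", meta_cfg=MetaConfig(universe_m=2))

    def test_fisher_method_agrees_on_ranking(self, small_fixture):
        """The alternative combination gives a similar gene ordering."""
        datasets, _ = small_fixture
        a = run_meta(datasets, "NNAT", meta_cfg=MetaConfig(alpha=1.0))
        b = run_meta(
            datasets, "NNAT", meta_cfg=MetaConfig(method="fisher_z", alpha=1.0)
        )
        za = {r.gene: r.z_combined for r in a.all_results}
        zb = {r.gene: r.z_combined for r in b.all_results}
        genes = sorted(za)
        rho = stats.spearmanr([za[g] for g in genes], [zb[g] for g in genes])
        assert rho.statistic > 0.95


class TestFoldChange:
    def _ds(self):
        return make_dataset(
            probesets=("p1", "p2", "p3"),
            samples=("a1", "a2", "b1", "b2"),
            values=((200, 200, 100, 100), (30, 50, 40, 40), (9, 11, 4, 6)),
            gene_of={"p1": "G1", "p2": "G2", "p3": "G3"},
        )

    def test_hand_computed_ratios(self):
        fc = fold_change(self._ds(), ["a1", "a2"], ["b1", "b2"])
        assert fc == pytest.approx({"G1": 2.0, "G2": 1.0, "G3": 2.0})

    def test_identical_groups_disallowed(self):
        with pytest.raises(AnalysisError, match="disjoint"):
            fold_change(self._ds(), ["a1"], ["a1"])

    def test_highest_mean_probeset_represents_gene(self):
        ds = make_dataset(
            probesets=("p1", "p2"),
            samples=("a1", "b1", "b2"),
            values=((100, 50, 50), (1000, 250, 250)),
            gene_of={"p1": "G1", "p2": "G1"},
        )
        fc = fold_change(ds, ["a1"], ["b1", "b2"])
        assert fc == pytest.approx({"G1": 4.0})

    def test_zero_denominator_is_an_error(self):
        ds = make_dataset(
            probesets=("p1",),
            samples=("a1", "b1"),
            values=((5.0, 0.0),),
            gene_of={"p1": "G1"},
        )
        with pytest.raises(AnalysisError, match="zero"):
            fold_change(ds, ["a1"], ["b1"])
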