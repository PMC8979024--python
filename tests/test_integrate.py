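"""DEG selection, strata, Spearman, DMPs, and methylome-expression links."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rrbsmeth.dmr import annotate_dmrs, call_dmrs
from rrbsmeth.integrate import (build_pairs, correlated_gene_set,
                                fisher_exact_two_sided, find_dmps,
                                rho_distribution, select_degs, spearman_rho,
                                stratified_profiles, stratify_by_expression)
from conftest import make_sites


def expression_table(levels, log2fc=None, fdr=None):
    n = len(levels)
    return pd.DataFrame({
        "gene_id": [f"g{i:03d}" for i in range(n)],
        "level_control": levels,
        "level_treated": levels,
        "log2fc": log2fc if log2fc is not None else [0.0] * n,
        "fdr": fdr if fdr is not None else [1.0] * n,
    })


class TestSelectDegs:
    def test_threshold_is_strict(self):
        table = expression_table([1, 1, 1], log2fc=[1, -1, 2],
                                 fdr=[0.04, 0.05, 0.051])
        degs = select_degs(table, 0.05)
        assert degs["gene_id"].tolist() == ["g000"]
        assert degs["direction"].tolist() == ["up"]

    def test_flat_direction_flagged(self):
        table = expression_table([1], log2fc=[0.0], fdr=[0.01])
        assert select_degs(table)["direction"].tolist() == ["flat"]

    def test_missing_fdr_skipped_with_warning(self, caplog):
        table = expression_table([1, 1], log2fc=[1, 1], fdr=[0.01, np.nan])
        with caplog.at_level("WARNING", logger="rrbsmeth"):
            degs = select_degs(table)
        assert len(degs) == 1 and "skipped 1" in caplog.text


class TestStrata:
    def test_tertiles_of_nonzero_genes(self):
        table = expression_table(list(range(10)))
        strata = stratify_by_expression(table)
        as_levels = {k: sorted(int(g[1:]) for g in v)
                     for k, v in strata.items()}
        assert as_levels == {"none": [0], "low": [1, 2, 3],
                             "moderate": [4, 5, 6], "high": [7, 8, 9]}

    def test_all_zero_goes_to_none(self):
        strata = stratify_by_expression(expression_table([0.0] * 4))
        assert len(strata["none"]) == 4
        assert not (strata["low"] or strata["moderate"] or strata["high"])

    def test_two_nonzero_fill_lower_strata_first(self):
        strata = stratify_by_expression(expression_table([0, 3.0, 7.0]))
        assert strata["low"] == ["g001"] and strata["moderate"] == ["g002"]
        assert strata["high"] == []

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        table = expression_table(rng.lognormal(1, 1, 50).round(2))
        strata = stratify_by_expression(table)
        members = [g for genes in strata.values() for g in genes]
        assert sorted(members) == sorted(table["gene_id"])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x ** 3)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -np.exp(x))[0] == pytest.approx(-1.0)

    def test_midrank_oracle_with_ties(self):
        x, y = [1, 2, 2, 4], [3, 1, 5, 2]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(_midrank_rho(x, y), abs=1e-12)

    def test_random_tied_vectors_match_midrank_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman_rho(x, y)
            assert rho == pytest.approx(_midrank_rho(x, y), abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=40), rng.normal(size=40)
        base = spearman_rho(x, y)[0]
        assert spearman_rho(np.exp(x), y)[0] == pytest.approx(base)
        assert spearman_rho(x, y ** 3)[0] == pytest.approx(base)

    @pytest.mark.parametrize("x,y", [([1, 2], [3, 4]),
                                     ([1, 1, 1], [1, 2, 3])])
    def test_degenerate_inputs_are_undefined(self, x, y):
        rho, p = spearman_rho(x, y)
        assert math.isnan(rho) and math.isnan(p)

    def test_null_distribution_centered_at_zero(self):
        rng = np.random.default_rng(6)
        rhos = [spearman_rho(rng.normal(size=500), rng.normal(size=500))[0]
                for _ in range(200)]
        assert abs(np.mean(rhos)) < 2 / math.sqrt(500)


def _midrank_rho(x, y):
    """Explicit midrank assignment + Pearson correlation of the ranks."""
    def midranks(values):
        values = np.asarray(values, dtype=float)
        order = np.argsort(values, kind="stable")
        ranks = np.empty(len(values))
        i = 0
        while i < len(values):
            j = i
            while j + 1 < len(values) and (values[order[j + 1]]
                                           == values[order[i]]):
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx ** 2).sum()
                                             * (ry ** 2).sum()))


class TestFisherAndDmps:
    def test_vectorized_fisher_matches_scipy(self):
        rng = np.random.default_rng(11)
        tables = rng.integers(0, 50, size=(300, 4))
        mine = fisher_exact_two_sided(*tables.T)
        for row, p in zip(tables, mine):
            ref = stats.fisher_exact([[row[0], row[1]],
                                      [row[2], row[3]]])[1]
            assert p == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_clear_dmp_detected(self):
        a = make_sites([("c", 10, "+", "CG", 24, 30)])
        b = make_sites([("c", 10, "+", "CG", 3, 30)])
        dmps = find_dmps(a, b)
        assert len(dmps) == 1
        assert dmps["delta"].iloc[0] == pytest.approx(-0.7)

    def test_small_difference_not_a_dmp(self):
        a = make_sites([("c", 10, "+", "CG", 15, 30)])
        b = make_sites([("c", 10, "+", "CG", 14, 30)])
        assert find_dmps(a, b).empty

    def test_low_coverage_excluded(self):
        a = make_sites([("c", 10, "+", "CG", 9, 10)])
        b = make_sites([("c", 10, "+", "CG", 0, 10)])
        assert find_dmps(a, b).empty  # coverage bound is strict (> 10)


class TestRhoDistribution:
    @staticmethod
    def _pairs(n, rng, dependent=False):
        meth = rng.uniform(0.1, 0.9, n)
        lfc = -meth * 3 + rng.normal(0, 0.1, n) if dependent \
            else rng.normal(0, 1, n)
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "region": "genebody", "context": "CG",
            "log2_meth_ratio": meth, "delta_meth": meth, "log2fc": lfc,
        })

    def test_independent_pair_has_small_rho(self):
        rng = np.random.default_rng(21)
        out = rho_distribution(self._pairs(500, rng))
        assert abs(out["rho"].iloc[0]) < 2 / math.sqrt(500)
        assert out["p_value"].iloc[0] > 0.05

    def test_dependent_pair_detected(self):
        rng = np.random.default_rng(22)
        out = rho_distribution(self._pairs(100, rng, dependent=True))
        assert out["rho"].iloc[0] < -0.9

    def test_small_groups_skipped(self, caplog):
        rng = np.random.default_rng(23)
        with caplog.at_level("WARNING", logger="rrbsmeth"):
            out = rho_distribution(self._pairs(2, rng))
        assert out.empty and "skipped" in caplog.text

    def test_dmp_by_deg_with_no_degs_is_empty(self):
        rng = np.random.default_rng(24)
        pairs = self._pairs(10, rng)
        degs = select_degs(expression_table([1.0] * 10))  # nothing passes
        dmps = pd.DataFrame(columns=["chrom", "pos", "strand", "context",
                                     "level_a", "level_b", "delta", "p_value"])
        out = rho_distribution(pairs, "dmp_by_deg", degs=degs, dmps=dmps,
                               features=[])
        assert out.empty


class TestCorrelatedGenes:
    def test_no_dmrs_gives_empty_set(self):
        degs = select_degs(expression_table([1.0], [2.0], [0.01]))
        assert correlated_gene_set([], degs) == []

    def test_deg_with_linked_dmr_returned(self, calls_pair, dataset):
        calls_a, calls_b = calls_pair
        degs = select_degs(dataset.expression)
        dmrs = call_dmrs(calls_a, calls_b, contexts=("CG",))
        annotate_dmrs(dmrs, dataset.features)
        genes = correlated_gene_set(dmrs, degs)
        # every promoter-demethylated gene is a DEG carrying an up2k DMR
        assert set(dataset.truth.promoter_genes) <= set(genes)
        assert set(genes) <= set(degs["gene_id"])


class TestIntegrationOnSimulatedData:
    def test_promoter_demethylation_correlates_with_upregulation(
            self, calls_pair, dataset):
        calls_a, calls_b = calls_pair
        pairs = build_pairs(calls_a, calls_b, dataset.features,
                            dataset.expression)
        rho = rho_distribution(pairs)
        up2k_cg = rho[(rho["region"] == "up2k") & (rho["context"] == "CG")]
        assert up2k_cg["rho"].iloc[0] < 0

    def test_silenced_genes_show_elevated_downstream_methylation(
            self, calls_pair, dataset):
        calls_a, _ = calls_pair
        strata = stratify_by_expression(dataset.expression)
        profiles = stratified_profiles(calls_a, dataset.features, strata)

        def downstream_level(label):
            prof = profiles[label]
            sub = prof[(prof["kind"] == "gene") & (prof["context"] == "CG")
                       & (prof["region"] == "down2k")]
            return sub["n_meth"].sum() / sub["n_total"].sum()

        assert downstream_level("none") > downstream_level("high")

    def test_identical_strata_give_identical_profiles(self, calls_pair,
                                                      dataset):
        calls_a, _ = calls_pair
        genes = [f.id for f in dataset.features if f.kind == "gene"][:5]
        profiles = stratified_profiles(calls_a, dataset.features,
                                       {"x": genes, "y": list(genes)})
        pd.testing.assert_frame_equal(profiles["x"], profiles["y"])

    def test_single_gene_stratum_is_that_genes_profile(self, calls_pair,
                                                       dataset):
        from rrbsmeth.profiles import profile_features

        calls_a, _ = calls_pair
        gene = next(f for f in dataset.features if f.kind == "gene")
        profiles = stratified_profiles(calls_a, dataset.features,
                                       {"solo": [gene.id]})
        direct = profile_features(calls_a, [gene])
        pd.testing.assert_frame_equal(profiles["solo"], direct)
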