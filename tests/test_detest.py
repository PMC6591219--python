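"""Expression filtering, dispersion estimation, NB exact test, FDR, enrichment."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb, gammaln
from scipy.stats import binom, hypergeom, kstest

from flylife.containers import CountMatrix
from flylife.detest import (
    FilterSpec,
    bh_fdr,
    classify_deg,
    conditional_nb_loglik,
    enrich_top_n,
    estimate_common_dispersion,
    exact_test_nb,
    exact_test_pvalue,
    filter_by_cpm,
    fisher_enrichment,
    run_exact_test_de,
)


def _cm(values, lib=None):
    values = pd.DataFrame(values)
    values.index = [f"g{i}" for i in range(len(values))]
    values.columns = [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(
        values=values,
        gene_lengths=pd.Series(750.0, index=values.index),
        lib_sizes=None if lib is None else pd.Series(lib, index=values.columns),
    )


class TestFilter:
    def test_zero_gene_removed_identity_otherwise(self):
        cm = _cm([[0, 0, 0, 0], [100, 100, 100, 100]], lib=[100.0] * 4)
        groups = pd.Series(["a", "a", "b", "b"], index=cm.samples)
        assert filter_by_cpm(cm, groups) == ["g1"]

    def test_smallest_group_arithmetic(self):
        # groups of size 3 and 5: ceil(0.5*3)=2 qualifying samples suffice
        values = np.zeros((1, 8))
        values[0, :2] = 1000  # CPM > 1 in exactly 2 samples
        cm = _cm(values, lib=[1e6] * 8)
        groups = pd.Series(["a"] * 3 + ["b"] * 5, index=cm.samples)
        assert filter_by_cpm(cm, groups) == ["g0"]
        values2 = np.zeros((1, 8))
        values2[0, 0] = 1000
        cm2 = _cm(values2, lib=[1e6] * 8)
        assert filter_by_cpm(cm2, groups) == []

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FilterSpec(cpm=0)
        with pytest.raises(ValueError):
            FilterSpec(fraction=1.5)


class TestDispersion:
    def test_poisson_limit(self):
        rng = np.random.default_rng(1)
        values = rng.poisson(500, size=(500, 20))
        cm = _cm(values)
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=cm.samples)
        assert estimate_common_dispersion(cm, groups) < 0.01

    def test_nb_recovery(self):
        rng = np.random.default_rng(2)
        r = 1 / 0.1
        mu = np.exp(rng.normal(5, 1, size=1000))[:, None]
        values = rng.negative_binomial(r, r / (r + mu), size=(1000, 6))
        cm = _cm(values)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=cm.samples)
        assert 0.08 <= estimate_common_dispersion(cm, groups) <= 0.12

    def test_single_gene_grid_argmax(self):
        # brute-force grid evaluation of the conditional likelihood for (3, 97)
        arr = np.array([[3.0, 97.0]])
        grid = np.logspace(-6, 1, 2000)
        ll = [conditional_nb_loglik(arr, [2], phi) for phi in grid]
        brute = grid[int(np.argmax(ll))]
        cm = _cm(arr, lib=[100.0, 100.0])  # same-library samples
        groups = pd.Series(["a", "a"], index=cm.samples)
        est = estimate_common_dispersion(cm, groups)
        assert est == pytest.approx(brute, rel=0.01)

    def test_no_replication_falls_back(self):
        cm = _cm([[5, 9]])
        groups = pd.Series(["a", "b"], index=cm.samples)
        assert estimate_common_dispersion(cm, groups, fallback=0.07) == 0.07


class TestExactTest:
    def test_modal_outcome_p_one(self):
        assert exact_test_pvalue(5, 5, 2, 2, 0.0) == pytest.approx(1.0)

    def test_binomial_boundary(self):
        assert exact_test_pvalue(0, 10, 1, 1, 0.0) == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_binomial_oracle_exhaustive_totals(self):
        # phi=0 must equal the exact binomial two-sided (minlike) p for every
        # split of every total <= 50, equal group sizes
        for s in range(1, 51):
            pmf = binom.pmf(np.arange(s + 1), s, 0.5)
            for a in range(s + 1):
                expected = pmf[pmf <= pmf[a] * (1 + 1e-9)].sum()
                got = exact_test_pvalue(a, s - a, 3, 3, 0.0)
                assert got == pytest.approx(min(1.0, expected), abs=1e-12)

    def test_unequal_group_sizes_null_mean(self):
        # with n_a=1, n_b=3 the conditional mean proportion is 1/4
        p = exact_test_pvalue(25, 75, 1, 3, 0.0)
        assert p == pytest.approx(1.0, rel=1e-9)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        phi = 0.05
        r = 1 / phi
        mu = np.exp(rng.normal(5.5, 1, size=2000))[:, None]
        values = rng.negative_binomial(r, r / (r + mu), size=(2000, 6))
        counts = pd.DataFrame(values, columns=[f"s{j}" for j in range(6)])
        lib = pd.Series(float(values.sum() / 6), index=counts.columns)
        res = exact_test_nb(counts.iloc[:, :3], counts.iloc[:, 3:], phi, lib[:3], lib[3:])
        assert kstest(res["p"], "uniform").pvalue > 0.01

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_edger_exact_test(self, tmp_path):
        rng = np.random.default_rng(9)
        mat = rng.negative_binomial(5, 0.01, size=(50, 6))
        counts = pd.DataFrame(mat, columns=list("abcdef"))
        lib = pd.Series(1e5, index=counts.columns)
        res = exact_test_nb(counts[["a", "b", "c"]], counts[["d", "e", "f"]], 0.1,
                            lib[["a", "b", "c"]], lib[["d", "e", "f"]])
        mat_path = tmp_path / "m.tsv"
        np.savetxt(mat_path, mat, fmt="%d", delimiter="\t")
        script = (
            "suppressMessages(library(edgeR));"
            f"m <- as.matrix(read.table('{mat_path}'));"
            "d <- DGEList(counts=m, group=c(1,1,1,2,2,2), lib.size=rep(1e5,6));"
            "d$samples$norm.factors <- 1;"
            "res <- exactTest(d, dispersion=0.1, rejection.region='smallp');"
            "cat(sprintf('%.10f', res$table$PValue), sep='\\n')"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        theirs = np.array([float(x) for x in out.stdout.split()])
        assert np.allclose(res["p"].to_numpy(), theirs, atol=1e-3)

    def test_negative_counts_rejected(self):
        a = pd.DataFrame({"s1": [-1]})
        b = pd.DataFrame({"s2": [3]})
        with pytest.raises(ValueError):
            exact_test_nb(a, b, 0.1)


class TestBH:
    def test_worked_examples(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50), st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, pvals, rnd):
        p = np.array(pvals)
        perm = np.array(rnd.sample(range(p.size), p.size))
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestClassify:
    def test_tier_labels(self):
        res = pd.DataFrame(
            {
                "logFC": [2.5, -0.5, 1.5, 0.1],
                "logCPM": [5.0] * 4,
                "p": [1e-6, 0.01, 0.002, 0.9],
                "FDR": [0.01, 0.20, 0.04, 0.95],
            },
            index=["up_top", "first_tier", "mid", "null"],
        )
        out = classify_deg(res)
        assert out.loc["up_top", "tier"] == "top" and out.loc["up_top", "direction"] == "up"
        assert out.loc["first_tier", "tier"] == "p" and out.loc["first_tier", "direction"] == "down"
        assert out.loc["mid", "tier"] == "p+lfc"
        assert out.loc["null", "tier"] == "ns"


class TestEnrichment:
    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(100)]
        res = fisher_enrichment(universe[:50], set(universe[90:]), universe)
        assert res.p_value <= 1.0 and res.p_value > 0.99

    def test_direct_pmf_summation_oracle(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = set(universe[:10])
        top = universe[2:10] + universe[50:92]  # overlap 8, |top| = 50
        expected = sum(
            comb(10, k) * comb(90, 50 - k) / comb(100, 50) for k in range(8, 11)
        )
        res = fisher_enrichment(top, gene_set, universe)
        assert res.statistic == 8
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_set_equals_top_is_minimal(self):
        universe = [f"g{i}" for i in range(30)]
        res = fisher_enrichment(universe[:5], set(universe[:5]), universe)
        assert res.p_value == pytest.approx(1 / comb(30, 5), rel=1e-9)

    def test_top_n_merge_and_bh(self):
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(500)]
        ranked = list(universe)
        rng.shuffle(ranked)
        sets = {"hit": set(ranked[:30]), "miss": set(rng.choice(universe, 30, replace=False))}
        table = enrich_top_n(ranked, sets, universe, top_grid=(50, 100, 200))
        assert set(table["set"]) == {"hit", "miss"}
        hit = table.set_index("set").loc["hit"]
        assert hit["p"] < 1e-6 and hit["N"] == 50

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fisher_enrichment(["a"], {"z"}, ["a", "b"])


def test_run_exact_test_de_end_to_end():
    rng = np.random.default_rng(8)
    mu = np.exp(rng.normal(5, 1, size=300))[:, None] * np.ones((1, 6))
    mu[:20, 3:] *= 4.0  # plant 2-fold-change-squared genes in group b
    r = 1 / 0.05
    values = rng.negative_binomial(r, r / (r + mu))
    cm = _cm(values)
    groups = pd.Series(["a"] * 3 + ["b"] * 3, index=cm.samples)
    res = run_exact_test_de(cm, groups, "b", "a")
    assert {"logFC", "logCPM", "p", "FDR", "tier", "direction"} <= set(res.columns)
    planted = [f"g{i}" for i in range(20) if f"g{i}" in res.index]
    assert (res.loc[planted, "FDR"] < 0.05).mean() > 0.8
    assert res.attrs["phi"] == pytest.approx(0.05, abs=0.04)
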