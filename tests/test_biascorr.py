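"""Coverage profiling, truncated counting and (binned) TMM normalization."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from conftest import uniform_positional
from flylife.annotation import Transcript, TranscriptCatalog
from flylife.biascorr import (
    binned_tmm,
    compute_coverage_profile,
    correct_counts,
    count_total,
    count_truncated,
    cpm_binned_adjustment,
    select_dominant_transcript,
    tmm_factor,
    truncate_transcripts,
)
from flylife.containers import CountMatrix, PositionalCounts


def make_pc_exponential(lam: float, length: int = 2000, total: int = 200_000, bin_width: int = 25):
    """Deterministic positional counts following the exponential decay exactly."""
    pc = PositionalCounts(bin_width=bin_width, samples=["s1"])
    edges = np.arange(0, length + bin_width, bin_width, dtype=float)
    mass = np.exp(-edges[:-1] / lam) - np.exp(-edges[1:] / lam)
    mass /= mass.sum()
    pc.counts["t1"] = np.round(total * mass)[:, None].astype(np.int64)
    pc.gene_of["t1"] = "g1"
    pc.length_of["t1"] = length
    return pc


class TestCoverageProfile:
    def test_flat_under_uniform_coverage(self):
        pc = uniform_positional({"t1": 2000, "t2": 3000}, total=50)
        prof = compute_coverage_profile(pc, min_length=1500)
        assert np.allclose(prof.dropna().to_numpy(), 1.0)

    def test_exponential_decay_value(self):
        pc = make_pc_exponential(lam=500.0)
        prof = compute_coverage_profile(pc, min_length=1500)
        at_1500 = prof.loc[1500, "s1"]
        near_3p = prof.iloc[0, 0]
        assert at_1500 / near_3p == pytest.approx(np.exp(-1500 / 500), rel=0.05)

    def test_high_rin_profile_dominates_beyond_truncation(self, confounded_pc):
        pc, info, _ = confounded_pc
        prof = compute_coverage_profile(pc, min_length=1500)
        low = prof[info["RIN"].idxmin()]
        high = prof[info["RIN"].idxmax()]
        beyond = prof.index >= 750
        both = beyond & low.notna() & high.notna()
        assert (high[both] >= low[both]).mean() > 0.95

    def test_no_qualifying_transcripts(self):
        pc = uniform_positional({"t1": 800}, total=10)
        with pytest.raises(ValueError):
            compute_coverage_profile(pc, min_length=1500)


class TestDominantSelection:
    def _catalog(self, lengths):
        cat = TranscriptCatalog()
        for tid, L in lengths.items():
            cat.add(Transcript(tid, "g1", "c", "+", ((0, L),)))
        return cat

    def test_argmax_and_single(self):
        cat = self._catalog({"g1.t1": 1000, "g1.t2": 900})
        assert select_dominant_transcript(pd.Series({"g1.t1": 10.0, "g1.t2": 30.0}), cat) == {"g1": "g1.t2"}
        assert select_dominant_transcript(pd.Series({"g1.t1": 5.0}), self._catalog({"g1.t1": 1000})) == {"g1": "g1.t1"}

    def test_tie_breaks(self):
        cat = self._catalog({"g1.t1": 900, "g1.t2": 1000})
        assert select_dominant_transcript(pd.Series({"g1.t1": 10.0, "g1.t2": 10.0}), cat) == {"g1": "g1.t2"}
        cat2 = self._catalog({"g1.t1": 1000, "g1.t2": 1000})
        assert select_dominant_transcript(pd.Series({"g1.t2": 10.0, "g1.t1": 10.0}), cat2) == {"g1": "g1.t1"}


class TestTruncatedCounting:
    def test_uniform_proportionality(self):
        pc = uniform_positional({"t1": 2000}, total=1)  # 1 read per 25-bp bin
        cat = TranscriptCatalog()
        cat.add(Transcript("t1", "g1", "c", "+", ((0, 2000),)))
        ann = truncate_transcripts(cat, {"g1": "t1"}, keep=750)
        cm = count_truncated(pc, ann)
        # 30 of 80 bins lie within 750 bp: exactly 750/2000 of the reads
        assert cm.values.loc["g1", "s1"] == 30
        assert cm.gene_lengths["g1"] == 750 and cm.full_lengths["g1"] == 2000

    def test_short_transcript_keeps_full_count(self):
        pc = uniform_positional({"t1": 500}, total=3)
        cat = TranscriptCatalog()
        cat.add(Transcript("t1", "g1", "c", "-", ((0, 500),)))
        ann = truncate_transcripts(cat, {"g1": "t1"}, keep=750)
        cm = count_truncated(pc, ann)
        assert cm.values.loc["g1", "s1"] == pc.counts["t1"].sum()

    def test_degraded_truncated_fraction_matches_closed_form(self):
        lam, L = 500.0, 2000
        pc = make_pc_exponential(lam=lam, length=L)
        cat = TranscriptCatalog()
        cat.add(Transcript("t1", "g1", "c", "+", ((0, L),)))
        ann = truncate_transcripts(cat, {"g1": "t1"}, keep=750)
        trunc = count_truncated(pc, ann).values.loc["g1", "s1"]
        full = count_total(pc).values.loc["g1", "s1"]
        expected = (1 - np.exp(-750 / lam)) / (1 - np.exp(-L / lam))  # ~0.791
        assert trunc / full == pytest.approx(expected, abs=0.005)

    def test_truncated_never_exceeds_full(self, confounded_pc, small_catalog):
        pc, info, _ = confounded_pc
        dominant = {tx.gene_id: tid for tid, tx in small_catalog.transcripts.items()}
        ann = truncate_transcripts(small_catalog, dominant)
        cm_t = count_truncated(pc, ann)
        cm_f = count_total(pc, dominant=dominant)
        assert (cm_t.values <= cm_f.values.loc[cm_t.genes, cm_t.samples]).all().all()


def brute_force_tmm(y_s, y_r, n_s, n_r, trim_m=0.30, trim_a=0.05):
    """Independent TMM oracle: explicit sort-based double trimming."""
    y_s, y_r = np.asarray(y_s, float), np.asarray(y_r, float)
    keep = (y_s > 0) & (y_r > 0)
    y_s, y_r = y_s[keep], y_r[keep]
    m = np.log2((y_s / n_s) / (y_r / n_r))
    a = 0.5 * np.log2((y_s / n_s) * (y_r / n_r))
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = int(np.floor(n * trim_m)) + 1, n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)) + 1, n - int(np.floor(n * trim_a))
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    w = 1.0 / ((n_s - y_s) / (n_s * y_s) + (n_r - y_r) / (n_r * y_r))
    return 2 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel]))


class TestTMM:
    def test_identical_and_scaled_samples(self):
        y = np.array([10, 50, 100, 400, 80])
        assert tmm_factor(y, y) == 1.0
        assert tmm_factor(2 * y, y) == pytest.approx(1.0, abs=1e-12)

    def test_hand_trim_example(self):
        ref = np.array([100, 100, 100, 100])
        smp = np.array([50, 100, 100, 150])
        assert tmm_factor(smp, ref, 400, 400) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            y_s = rng.integers(1, 500, size=20).astype(float)
            y_r = rng.integers(1, 500, size=20).astype(float)
            n_s, n_r = y_s.sum(), y_r.sum()
            assert tmm_factor(y_s, y_r, n_s, n_r) == pytest.approx(
                brute_force_tmm(y_s, y_r, n_s, n_r), abs=1e-10
            )

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_edger(self, tmp_path):
        rng = np.random.default_rng(5)
        mat = rng.negative_binomial(10, 0.02, size=(200, 4))
        counts = pd.DataFrame(mat, columns=["s1", "s2", "s3", "s4"])
        lib = counts.sum(axis=0).astype(float)
        ours = np.array([tmm_factor(counts[s], counts["s1"], lib[s], lib["s1"]) for s in counts])
        ours /= np.exp(np.log(ours).mean())
        mat_path = tmp_path / "m.tsv"
        np.savetxt(mat_path, mat, fmt="%d", delimiter="\t")
        script = (
            "suppressMessages(library(edgeR));"
            f"m <- as.matrix(read.table('{mat_path}'));"
            "f <- calcNormFactors(DGEList(counts=m), method='TMM', refColumn=1);"
            "cat(sprintf('%.10f', f$samples$norm.factors), sep='\\n')"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        theirs = np.array([float(x) for x in out.stdout.split()])
        assert np.allclose(ours, theirs, atol=1e-8)


def _random_count_matrix(seed, n_genes=400, n_samples=4):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    values = pd.DataFrame(
        rng.negative_binomial(5, 0.01, size=(n_genes, n_samples)), index=genes, columns=samples
    )
    lengths = pd.Series(np.exp(rng.uniform(np.log(400), np.log(8000), n_genes)), index=genes)
    return CountMatrix(values=values, gene_lengths=lengths)


class TestBinnedTMM:
    def test_identical_samples_unchanged(self):
        cm = _random_count_matrix(1, n_samples=1)
        values = pd.concat([cm.values["s0"]] * 4, axis=1)
        values.columns = [f"s{j}" for j in range(4)]
        cm4 = CountMatrix(values=values, gene_lengths=cm.gene_lengths)
        factors, adj = binned_tmm(cm4)
        assert np.allclose(factors["factor"], 1.0)
        assert np.allclose(adj.values, cm4.values, rtol=1e-12)

    def test_factor_geometric_mean_one_per_bin(self):
        cm = _random_count_matrix(2)
        factors, _ = binned_tmm(cm)
        gm = factors.groupby("bin")["factor"].apply(lambda f: np.exp(np.log(f).mean()))
        assert np.allclose(gm, 1.0, atol=1e-12)

    def test_column_totals_preserved(self):
        cm = _random_count_matrix(3)
        _, adj = binned_tmm(cm)
        assert np.allclose(adj.values.sum(axis=0), cm.lib_sizes, rtol=5e-3)

    def test_requires_populated_bins(self):
        cm = _random_count_matrix(4, n_genes=50)
        with pytest.raises(ValueError, match="at least"):
            binned_tmm(cm, n_bins=10)

    def test_length_dependent_distortion_removed(self, confounded_pc, small_catalog):
        """Planted null with RIN confounded with group: after truncation plus
        length-binned TMM the per-length-bin median log fold change is ~0."""
        pc, info, _ = confounded_pc
        _, adj, factors = correct_counts(pc, small_catalog, sample_info=info)
        a_cols = list(info.index[info["genotype"] == "w/w"])
        b_cols = list(info.index[info["genotype"] == "E(z)/w"])
        cpm = adj.cpm()
        logfc = np.log2((cpm[a_cols].mean(axis=1) + 0.5) / (cpm[b_cols].mean(axis=1) + 0.5))
        bins = pd.qcut(adj.full_lengths, 5, labels=False)
        assert logfc.groupby(bins).median().abs().max() < 0.1

    def test_cpm_level_distortion_removed(self):
        # low-noise counts so the planted distortion is the only signal
        rng = np.random.default_rng(6)
        n = 1000
        genes = [f"g{i}" for i in range(n)]
        mu = np.exp(rng.normal(6, 1, size=n))
        values = pd.DataFrame(
            rng.poisson(mu[:, None], size=(n, 4)),
            index=genes, columns=[f"s{j}" for j in range(4)],
        )
        lengths = pd.Series(750.0, index=genes)
        cm = CountMatrix(values=values, gene_lengths=lengths)
        distorted = values.astype(float).copy()
        high = cm.cpm().mean(axis=1) > cm.cpm().mean(axis=1).median()
        distorted.loc[high, "s0"] *= 1.3  # expression-level-dependent distortion
        cm_d = CountMatrix(values=distorted, gene_lengths=lengths)
        _, adj = cpm_binned_adjustment(cm_d)
        cpm = adj.cpm()
        others = [c for c in cpm.columns if c != "s0"]
        logfc = np.log2((cpm["s0"] + 0.5) / (cpm[others].mean(axis=1) + 0.5))
        bins = pd.qcut(np.log2(cm.cpm().mean(axis=1) + 0.25), 5, labels=False)
        assert logfc.groupby(bins).median().abs().max() < 0.1

    def test_near_idempotence(self):
        # low-noise matrix: the second pass must find nothing left to remove
        rng = np.random.default_rng(7)
        n = 1000
        genes = [f"g{i}" for i in range(n)]
        mu = np.exp(rng.normal(6, 1, size=n))
        values = pd.DataFrame(
            rng.poisson(mu[:, None], size=(n, 4)),
            index=genes, columns=[f"s{j}" for j in range(4)],
        )
        distorted = values.astype(float)
        distorted.iloc[: n // 2, 0] *= 1.2
        cm = CountMatrix(values=distorted, gene_lengths=pd.Series(750.0, index=genes))
        f1, adj1 = cpm_binned_adjustment(cm)
        f2, adj2 = cpm_binned_adjustment(adj1)
        assert (f2["factor"] - 1).abs().max() < 0.01
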