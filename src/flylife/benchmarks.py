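"""Seeded end-to-end studies quantifying what the pipeline delivers.

Each function runs the package on freshly simulated data with known ground
truth and returns a dictionary of plain-number metrics: bias removal on a
degradation-confounded null, Gompertz / dispersion parameter recovery,
planted-DE power, and the null calibration of the demographic tests.  The
same functions back the acceptance checks and are usable as a quick-look
benchmark by users.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._rng import derive_rng, derive_seedseq
from .biascorr import correct_counts, count_total, tmm_effective_libsizes
from .containers import CountMatrix
from .detest import (
    FilterSpec,
    estimate_common_dispersion,
    exact_test_nb,
    filter_by_cpm,
    run_exact_test_de,
)
from .simulate import (
    DegradationModel,
    GompertzParams,
    make_catalog,
    make_truth,
    simulate_lifespans,
    simulate_positional_counts,
    _rnbinom,
)
from .survival import (
    fit_gompertz,
    ks_test_survival,
    logrank_test,
    wang_allison_test,
)

__all__ = [
    "bias_removal_study",
    "gompertz_recovery",
    "dispersion_recovery",
    "de_power_study",
    "null_calibration",
]


def _confounded_design(seed: int, rins_a, rins_b, libsize: float = 1e6) -> pd.DataFrame:
    """3+3 sample sheet with RIN fully confounded with genotype."""
    degradation = DegradationModel()
    rng = derive_rng(seed, "benchmark", index=7)
    rows = []
    for i, rin in enumerate(rins_a):
        rows.append(("ctrl_%d" % (i + 1), "w/w", rin))
    for i, rin in enumerate(rins_b):
        rows.append(("mut_%d" % (i + 1), "E(z)/w", rin))
    info = pd.DataFrame(rows, columns=["sample", "genotype", "RIN"]).set_index("sample")
    info["sex"] = "male"
    info["age_weeks"] = 1
    info["replicate"] = np.arange(len(info)) % 3 + 1
    info["libsize"] = np.round(libsize * rng.uniform(0.9, 1.1, size=len(info)))
    info["lam"] = [degradation.lam(r) for r in info["RIN"]]
    return info


def _de_metrics(res: pd.DataFrame, lengths: pd.Series, alpha: float = 0.05) -> dict:
    """Length-bias diagnostics of an exact-test result frame."""
    x = np.log10(lengths.loc[res.index].astype(float))
    ols = sm.OLS(res["logFC"].to_numpy(), sm.add_constant(x.to_numpy())).fit()
    deciles = pd.qcut(x, 10, labels=False, duplicates="drop")
    reject = res["p"] < alpha
    rate = reject.groupby(deciles).mean()
    counts = pd.crosstab(deciles, reject)
    if counts.shape[1] == 2 and (counts.to_numpy().sum(axis=0) > 0).all():
        chi2_p = float(stats.chi2_contingency(counts)[1])
    else:
        chi2_p = 1.0
    heterogeneity = float(rate.max() / max(rate.min(), 1e-12))
    return {
        "slope": float(ols.params[1]),
        "slope_p": float(ols.pvalues[1]),
        "rejection_rate": float(reject.mean()),
        "decile_heterogeneity": heterogeneity,
        "decile_chi2_p": chi2_p,
    }


def bias_removal_study(
    seed: int,
    n_genes: int = 2000,
    rins_a=(5.0, 5.5, 6.0),
    rins_b=(7.0, 7.5, 8.0),
    alpha: float = 0.05,
) -> dict:
    """Global-null study with RIN confounded with group.

    No fold changes are planted; group A is degraded (low RIN), group B
    intact.  Returns length-bias diagnostics of the naive full-length
    pipeline and of the corrected (truncation + binned TMM) pipeline.
    """
    catalog = make_catalog(n_genes, seed, max_transcripts=1)
    info = _confounded_design(seed, rins_a, rins_b)
    truth = make_truth(catalog, info, seed, n_de=0)
    pc = simulate_positional_counts(catalog, truth, seed)
    groups = info["genotype"]
    cols_a = list(info.index[groups == "w/w"])
    cols_b = list(info.index[groups == "E(z)/w"])

    def _test(cm: CountMatrix) -> pd.DataFrame:
        kept = filter_by_cpm(cm, groups, FilterSpec())
        sub = cm.with_values(cm.values.loc[kept])
        sub.lib_sizes = cm.lib_sizes
        phi = estimate_common_dispersion(sub, groups)
        res = exact_test_nb(
            sub.values[cols_a], sub.values[cols_b], phi,
            lib_a=sub.lib_sizes[cols_a], lib_b=sub.lib_sizes[cols_b],
        )
        res.attrs["phi"] = phi
        return res

    raw = count_total(pc, sample_info=info)
    res_raw = _test(raw)
    m_raw = _de_metrics(res_raw, raw.full_lengths, alpha)

    _, adjusted, _ = correct_counts(pc, catalog, sample_info=info)
    res_adj = _test(adjusted)
    m_adj = _de_metrics(res_adj, adjusted.full_lengths, alpha)

    return {
        "uncorrected": m_raw,
        "corrected": m_adj,
        "phi_uncorrected": float(res_raw.attrs["phi"]),
        "phi_corrected": float(res_adj.attrs["phi"]),
        "n_genes": n_genes,
    }


def gompertz_recovery(
    seed: int, n: int = 5000, a: float = 0.001, g: float = 0.1, bin_width: float = 7.0
) -> dict:
    """Recover the Gompertz slope and MRDT from simulated daily death records."""
    sample = simulate_lifespans(GompertzParams(a=a, g=g), n, seed)
    fit = fit_gompertz(sample, bin_width=bin_width)
    return {
        "g_true": g,
        "g_hat": fit.g,
        "g_rel_error": abs(fit.g - g) / g,
        "mrdt_true": float(np.log(2) / g),
        "mrdt_hat": fit.mrdt,
        "n": n,
    }


def _nb_matrix(
    seed: int,
    n_genes: int,
    n_samples: int,
    phi: float,
    n_de: int = 0,
    de_logfc: float = 2.0,
    depth: float = 1e6,
) -> tuple[CountMatrix, pd.Series, pd.Series]:
    """Plain NB gene x sample matrix (no degradation), two equal groups."""
    rng = derive_rng(seed, "benchmark")
    genes = [f"g{i+1:05d}" for i in range(n_genes)]
    half = n_samples // 2
    samples = [f"A{i+1}" for i in range(half)] + [f"B{i+1}" for i in range(n_samples - half)]
    groups = pd.Series(["A"] * half + ["B"] * (n_samples - half), index=samples)
    base = np.exp(rng.normal(0.0, 1.2, size=n_genes))
    logfc = np.zeros(n_genes)
    if n_de:
        idx = rng.choice(n_genes, size=n_de, replace=False)
        logfc[idx] = np.where(np.arange(n_de) % 2 == 0, de_logfc, -de_logfc)
    values = np.empty((n_genes, n_samples), dtype=np.int64)
    for j, s in enumerate(samples):
        expr = base * np.where(groups[s] == "B", 2.0**logfc, 1.0)
        mean = expr / expr.sum() * depth
        values[:, j] = _rnbinom(rng, mean, phi)
    cm = CountMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        gene_lengths=pd.Series(750.0, index=genes),
    )
    return cm, groups, pd.Series(logfc, index=genes)


def dispersion_recovery(
    seed: int, n_genes: int = 1000, n_samples: int = 6, phi: float = 0.10
) -> dict:
    """Recover a common NB dispersion by conditional maximum likelihood."""
    cm, groups, _ = _nb_matrix(seed, n_genes, n_samples, phi)
    phi_hat = estimate_common_dispersion(cm, groups)
    return {"phi_true": phi, "phi_hat": phi_hat, "n_genes": n_genes, "n_samples": n_samples}


def de_power_study(
    seed: int,
    n_genes: int = 2000,
    n_de: int = 200,
    de_logfc: float = 2.0,
    phi: float = 0.05,
    fdr_threshold: float = 0.05,
) -> dict:
    """Sensitivity and observed FDR for planted fold changes of +-de_logfc."""
    cm, groups, logfc = _nb_matrix(seed, n_genes, 6, phi, n_de=n_de, de_logfc=de_logfc)
    # planted fold changes shift column composition; TMM-effective library
    # sizes remove that bias before the exact test, as in the real pipeline
    cm.lib_sizes = tmm_effective_libsizes(cm)
    res = run_exact_test_de(cm, groups, "B", "A")
    truth_de = logfc.loc[res.index] != 0
    called = res["FDR"] < fdr_threshold
    planted_total = int((logfc != 0).sum())
    sensitivity = float((called & truth_de).sum() / planted_total)
    observed_fdr = float((called & ~truth_de).sum() / max(int(called.sum()), 1))
    return {
        "sensitivity": sensitivity,
        "observed_fdr": observed_fdr,
        "n_called": int(called.sum()),
        "phi_hat": float(res.attrs["phi"]),
        "n_genes": n_genes,
        "n_de": planted_total,
    }


def null_calibration(
    seed: int,
    n_reps: int = 1000,
    n_per_group: int = 300,  # scale of the pooled lifespan cohorts
    params: GompertzParams = GompertzParams(a=0.0018, g=0.075),
    alpha: float = 0.05,
) -> dict:
    """Rejection rates of the demographic tests on identical Gompertz cohorts."""
    # spawned child streams: numpy's recommended scheme for independent replicates
    children = derive_seedseq(seed, "calibration").spawn(2 * n_reps)
    hits = {"logrank": 0, "ks": 0, "wang_allison": 0}
    for i in range(n_reps):
        a = simulate_lifespans(params, n_per_group, children[2 * i], label="A")
        b = simulate_lifespans(params, n_per_group, children[2 * i + 1], label="B")
        if logrank_test(a, b).p_value < alpha:
            hits["logrank"] += 1
        if ks_test_survival(a, b).p_value < alpha:
            hits["ks"] += 1
        if wang_allison_test(a, b).p_value < alpha:
            hits["wang_allison"] += 1
    return {
        "logrank_rate": hits["logrank"] / n_reps,
        "ks_rate": hits["ks"] / n_reps,
        "wang_allison_rate": hits["wang_allison"] / n_reps,
        "n_reps": n_reps,
        "n_per_group": n_per_group,
    }
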