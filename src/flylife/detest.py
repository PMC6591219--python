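"""Negative-binomial exact-test differential expression on adjusted pseudo-counts.

The test is the classical conditional exact test for two groups of NB counts
sharing a common dispersion phi (variance mu + phi*mu^2): given the total of
the two group sums, the group-A sum follows a beta-binomial-type distribution
with shapes n_A/phi and n_B/phi, and the two-sided p-value is the summed
probability of all outcomes no more likely than the observed one.  At phi = 0
this reduces to the exact binomial test.  Library sizes are equalized by
linear scaling to their geometric mean before the test; dispersion is
estimated by maximizing the conditional NB log-likelihood given group totals.
Multiple testing uses Benjamini-Hochberg; enrichment of top-N DEG lists
against flat gene sets uses the hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .survival import TestResult

log = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "filter_by_cpm",
    "equalize_libsizes",
    "estimate_common_dispersion",
    "conditional_nb_loglik",
    "exact_test_nb",
    "exact_test_pvalue",
    "bh_fdr",
    "classify_deg",
    "fisher_enrichment",
    "enrich_top_n",
    "run_exact_test_de",
]


@dataclass(frozen=True)
class FilterSpec:
    """Expression filter: CPM above ``cpm`` in at least ``fraction`` of the
    smallest group's worth of samples (counted over all samples)."""

    cpm: float = 1.0
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.cpm <= 0:
            raise ValueError("cpm threshold must be positive")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")


def filter_by_cpm(
    cm: CountMatrix, groups: pd.Series, spec: FilterSpec = FilterSpec()
) -> list[str]:
    """Genes kept by the expression filter.

    A gene survives iff its CPM exceeds ``spec.cpm`` in at least
    ceil(fraction * n_smallest_group) samples, counted over *any* samples.
    """
    groups = pd.Series(groups)
    sizes = groups.value_counts()
    if len(sizes) < 2 or (sizes == 0).any():
        raise ValueError("need at least two non-empty groups")
    need = int(np.ceil(spec.fraction * sizes.min()))
    cpm = cm.cpm()[list(groups.index)]
    keep = (cpm > spec.cpm).sum(axis=1) >= need
    return list(cm.genes[keep])


# ---------------------------------------------------------------------------
# dispersion


def equalize_libsizes(values: pd.DataFrame, lib_sizes: pd.Series) -> tuple[pd.DataFrame, float]:
    """Scale every column to the geometric-mean library size (pseudo-counts)."""
    common = float(np.exp(np.log(lib_sizes.astype(float)).mean()))
    return values.mul(common / lib_sizes, axis=1), common


def conditional_nb_loglik(values: np.ndarray, group_sizes: list[int], phi: float) -> float:
    """Summed conditional NB log-likelihood given group totals (common phi).

    ``values`` has genes in rows and samples in columns, columns ordered so
    the first ``group_sizes[0]`` belong to group 1, etc.  Library sizes must
    already be equalized.
    """
    if phi <= 0:
        raise ValueError("phi must be positive for the conditional likelihood")
    r = 1.0 / phi
    total = 0.0
    start = 0
    for n_g in group_sizes:
        y = values[:, start : start + n_g]
        start += n_g
        if n_g < 2:
            continue  # a single sample carries no within-group information
        s = y.sum(axis=1)
        total += float(
            (gammaln(y + r).sum(axis=1) - n_g * gammaln(r) + gammaln(n_g * r) - gammaln(s + n_g * r)).sum()
        )
    return total


def estimate_common_dispersion(
    cm: CountMatrix,
    groups: pd.Series,
    bounds: tuple[float, float] = (1e-6, 10.0),
    fallback: float = 0.05,
) -> float:
    """Common NB dispersion maximizing the conditional likelihood.

    Counts are first scaled to a common library size; the maximization runs
    on log10(phi) over ``bounds``.  Without replication the conditional
    likelihood is flat and ``fallback`` is returned with a loud warning.
    """
    groups = pd.Series(groups)
    if not (groups.value_counts() >= 2).any():
        log.warning(
            "no group has >= 2 replicates; dispersion cannot be estimated, using fallback %.3g",
            fallback,
        )
        return fallback
    ordered = list(groups.sort_values(kind="stable").index)
    sizes = [int(n) for n in groups.value_counts(sort=False).loc[groups.sort_values(kind="stable").unique()]]
    pseudo, _ = equalize_libsizes(cm.values[ordered].astype(float), cm.lib_sizes[ordered])
    arr = pseudo.to_numpy()
    arr = arr[arr.sum(axis=1) > 0]

    def neg(log_phi: float) -> float:
        return -conditional_nb_loglik(arr, sizes, 10.0**log_phi)

    res = minimize_scalar(
        neg, bounds=(np.log10(bounds[0]), np.log10(bounds[1])), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(10.0**res.x)


# ---------------------------------------------------------------------------
# exact test


def exact_test_pvalue(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p for group sums (s_a, s_b).

    Conditional on s = s_a + s_b the group-A sum is beta-binomial with shapes
    n_a/phi and n_b/phi (binomial(s, n_a/(n_a+n_b)) at phi = 0); the p-value
    sums the probabilities of all outcomes no more likely than observed.
    """
    if min(s_a, s_b) < 0:
        raise ValueError("group sums must be non-negative")
    s = s_a + s_b
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if phi <= 0:
        p = n_a / (n_a + n_b)
        logpmf = (
            gammaln(s + 1) - gammaln(k + 1) - gammaln(s - k + 1)
            + k * np.log(p) + (s - k) * np.log1p(-p)
        )
    else:
        r_a = n_a / phi
        r_b = n_b / phi
        logpmf = (
            gammaln(k + r_a) - gammaln(k + 1)
            + gammaln(s - k + r_b) - gammaln(s - k + 1)
        )
        logpmf -= logsumexp(logpmf)
    obs = logpmf[s_a]
    keep = logpmf <= obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logpmf[keep]))))


def exact_test_nb(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    phi: float,
    lib_a: pd.Series | None = None,
    lib_b: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene conditional exact test of group A vs group B.

    Returns a frame with columns logFC (log2, A over B, 0.5 prior on sums),
    logCPM (average), and p.  Unequal library sizes are equalized internally
    by linear scaling to the geometric mean; scaled sums are rounded to the
    nearest integer for the exact computation.
    """
    if (counts_a.to_numpy() < 0).any() or (counts_b.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    all_counts = pd.concat([counts_a, counts_b], axis=1)
    if lib_a is None:
        lib_a = counts_a.sum(axis=0).astype(float)
    if lib_b is None:
        lib_b = counts_b.sum(axis=0).astype(float)
    libs = pd.concat([lib_a, lib_b])
    pseudo, common = equalize_libsizes(all_counts.astype(float), libs)
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    s_a = pseudo.iloc[:, :n_a].sum(axis=1).round().astype(np.int64)
    s_b = pseudo.iloc[:, n_a:].sum(axis=1).round().astype(np.int64)
    pvals = np.array(
        [exact_test_pvalue(int(a), int(b), n_a, n_b, phi) for a, b in zip(s_a, s_b)]
    )
    logfc = np.log2(((s_a + 0.5) / n_a) / ((s_b + 0.5) / n_b))
    logcpm = np.log2((s_a + s_b + 0.5) / ((n_a + n_b) * common) * 1e6)
    return pd.DataFrame(
        {"logFC": logfc, "logCPM": logcpm, "p": pvals}, index=all_counts.index
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_deg(
    results: pd.DataFrame,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
    top_lfc: float = 2.0,
) -> pd.DataFrame:
    """Attach FDR, direction, and tier labels to an exact-test result frame.

    Tiers: ``p`` (p below threshold), ``p+lfc`` (additionally |logFC| above
    ``lfc_threshold``), ``top`` (FDR below threshold and |logFC| above
    ``top_lfc`` - the most differentially expressed genes), else ``ns``.
    """
    out = results.copy()
    if "FDR" not in out.columns:
        out["FDR"] = bh_fdr(out["p"].to_numpy())
    out["direction"] = np.where(out["logFC"] > 0, "up", "down")
    tier = np.full(len(out), "ns", dtype=object)
    tier[out["p"] < p_threshold] = "p"
    tier[(out["p"] < p_threshold) & (out["logFC"].abs() > lfc_threshold)] = "p+lfc"
    tier[(out["FDR"] < fdr_threshold) & (out["logFC"].abs() > top_lfc)] = "top"
    out["tier"] = tier
    return out


# ---------------------------------------------------------------------------
# enrichment


def fisher_enrichment(top: list[str], gene_set: set[str], universe: list[str]) -> TestResult:
    """One-sided hypergeometric upper-tail enrichment of ``gene_set`` in ``top``."""
    uni = set(universe)
    if not uni or not gene_set:
        raise ValueError("gene set and universe must be non-empty")
    if not set(gene_set) <= uni:
        raise ValueError("gene set must be a subset of the universe")
    top_set = set(top)
    if not top_set <= uni:
        raise ValueError("top list must be a subset of the universe")
    from scipy.stats import hypergeom

    n_univ = len(uni)
    n_set = len(gene_set)
    n_top = len(top_set)
    overlap = len(top_set & gene_set)
    p = float(hypergeom.sf(overlap - 1, n_univ, n_set, n_top))
    table = pd.DataFrame(
        {
            "in_set": [overlap, n_set - overlap],
            "not_in_set": [n_top - overlap, n_univ - n_set - (n_top - overlap)],
        },
        index=["in_top", "not_in_top"],
    )
    return TestResult(name="hypergeometric-enrichment", statistic=float(overlap), p_value=min(1.0, p), table=table)


def enrich_top_n(
    ranked_genes: list[str],
    gene_sets: dict[str, set[str]],
    universe: list[str],
    top_grid: tuple[int, ...] = (50, 100, 200, 500, 1000),
) -> pd.DataFrame:
    """Enrichment of each set against top-N DEG lists, merged over the N grid.

    For every set the minimum p over the grid is kept (with the N achieving
    it); BH adjustment runs across sets on the merged p-values.
    """
    rows = []
    for name, members in gene_sets.items():
        best = None
        for n in top_grid:
            if n > len(ranked_genes):
                continue
            res = fisher_enrichment(ranked_genes[:n], members, universe)
            if best is None or res.p_value < best["p"]:
                best = {
                    "set": name,
                    "N": n,
                    "overlap": int(res.statistic),
                    "set_size": len(members),
                    "p": res.p_value,
                }
        if best is not None:
            rows.append(best)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["FDR"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# high-level


def run_exact_test_de(
    cm: CountMatrix,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    filter_spec: FilterSpec | None = FilterSpec(),
    phi: float | None = None,
) -> pd.DataFrame:
    """Filter, estimate dispersion, exact-test A vs B, BH-adjust, classify."""
    groups = pd.Series(groups)
    use = groups[groups.isin([group_a, group_b])]
    sub = cm.with_values(cm.values[list(use.index)])
    sub.lib_sizes = cm.lib_sizes[list(use.index)]
    if filter_spec is not None:
        kept = filter_by_cpm(sub, use, filter_spec)
        sub = sub.with_values(sub.values.loc[kept])
        sub.lib_sizes = cm.lib_sizes[list(use.index)]
        log.info("expression filter kept %d genes", len(kept))
    if phi is None:
        phi = estimate_common_dispersion(sub, use)
        log.info("common dispersion estimate: %.4f", phi)
    cols_a = list(use.index[use == group_a])
    cols_b = list(use.index[use == group_b])
    res = exact_test_nb(
        sub.values[cols_a], sub.values[cols_b], phi,
        lib_a=sub.lib_sizes[cols_a], lib_b=sub.lib_sizes[cols_b],
    )
    res.attrs["phi"] = phi
    return classify_deg(res)
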