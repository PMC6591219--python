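"""Synthetic study generator with known ground truth.

Emulates the design of a fly-longevity transcriptomics study: two genotypes
(control ``w/w``, experimental ``E(z)/w``) x two sexes x three ages x three
replicates; Gompertz-distributed lifespans recorded daily; activity-monitor
stress assays on a 30-minute grid; weekly fecundity counts; and RNA-seq
positional read counts whose 3' coverage decays exponentially with distance
from the 3' end at a rate set by each sample's RNA integrity number (RIN).

Degradation model.  A fragment at 3'-distance d survives library prep with
probability exp(-d/lambda), with lambda = lambda0 * 2**(RIN - 5) (default
lambda0 = 400 bp, so RIN 5..8 spans lambda 400..3200 bp).  A transcript of
spliced length L therefore keeps the fraction (lambda/L)(1 - exp(-L/lambda))
of its reads, and surviving reads fall at 3'-distance d with density
proportional to exp(-d/lambda).  Columns are rescaled to the target library
size (sequencers deliver a fixed depth), which is what makes degradation a
*relative*, length-dependent bias between samples rather than a global loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .annotation import Transcript, TranscriptCatalog
from .containers import PositionalCounts
from .survival import SurvivalSample

__all__ = [
    "GompertzParams",
    "CohortSpec",
    "DegradationModel",
    "SimTruth",
    "GENOTYPES",
    "SEXES",
    "AGES_WEEKS",
    "simulate_lifespans",
    "gompertz_median",
    "simulate_activity_bins",
    "simulate_fecundity",
    "make_catalog",
    "default_design",
    "make_truth",
    "simulate_positional_counts",
]

GENOTYPES = ("w/w", "E(z)/w")
SEXES = ("male", "female")
AGES_WEEKS = (1, 4, 6)


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard h(t) = a * exp(g * t); MRDT = ln(2)/g."""

    a: float  # baseline hazard, per day
    g: float  # slope, per day

    def __post_init__(self) -> None:
        if self.a <= 0 or self.g <= 0:
            raise ValueError("Gompertz parameters a and g must be positive")

    @property
    def mrdt(self) -> float:
        return float(np.log(2) / self.g)


@dataclass(frozen=True)
class CohortSpec:
    genotype: str
    sex: str
    replicate: int
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")

    @property
    def label(self) -> str:
        return f"{self.genotype}:{self.sex}:r{self.replicate}"


@dataclass(frozen=True)
class DegradationModel:
    """Maps RIN to the exponential 3'-decay scale lambda (bp)."""

    lambda0: float = 400.0  # scale at RIN 5

    def lam(self, rin: float) -> float:
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        return float(self.lambda0 * 2.0 ** (rin - 5.0))

    def survival_fraction(self, lam: float, length: float) -> float:
        """Fraction of a length-L transcript's fragments surviving degradation."""
        if lam <= 0:
            raise ValueError("lambda must be positive")
        x = length / lam
        return float((lam / length) * -np.expm1(-x))


@dataclass
class SimTruth:
    """Planted parameters against which recovery is tested."""

    baseline: pd.Series  # per-gene expected count share (arbitrary positive scale)
    logfc: pd.Series  # per-gene log2 fold change, experimental vs control
    dispersion: pd.Series  # per-gene NB dispersion phi (var = mu + phi*mu^2)
    tx_fraction: pd.Series  # per-transcript share of its gene's expression
    sample_info: pd.DataFrame  # sample, genotype, sex, age_weeks, replicate, RIN, libsize, lam
    gompertz: dict[str, GompertzParams] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.baseline <= 0).any():
            raise ValueError("baseline means must be positive")
        if (self.dispersion < 0).any():
            raise ValueError("dispersions must be non-negative")


# ---------------------------------------------------------------------------
# demography


def gompertz_median(params: GompertzParams) -> float:
    """Analytic median of the Gompertz law, (1/g) ln(1 + (g/a) ln 2)."""
    return float(np.log1p(params.g / params.a * np.log(2)) / params.g)


def simulate_lifespans(params: GompertzParams, n: int, seed: int, label: str = "") -> SurvivalSample:
    """Draw ``n`` death times (whole days, deaths recorded daily) from a Gompertz law.

    Inverse-CDF sampling of S(t) = exp(-(a/g)(e^{gt}-1)); continuous times are
    rounded up to the day on which the death would be recorded.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = derive_rng(seed, "lifespan")
    u = rng.uniform(size=n)
    # S(t) = u  =>  t = (1/g) ln(1 - (g/a) ln u)
    t = np.log1p(-(params.g / params.a) * np.log(u)) / params.g
    days = np.maximum(np.ceil(t), 1.0)
    return SurvivalSample(times=days, events=np.ones(n, dtype=bool), label=label)


def simulate_activity_bins(
    death_time: float,
    activity_rate: float,
    seed: int,
    bin_width: float = 0.5,
    n_bins: int | None = None,
) -> np.ndarray:
    """One fly's activity counts on a 30-minute grid, silent after death.

    Counts before death are Poisson(activity_rate) per bin; every bin after
    the bin containing ``death_time`` is zero.  Unless the rate is zero, at
    least one pre-death bin is guaranteed non-zero (a living fly moves at
    least once over the assay).
    """
    if death_time <= 0:
        raise ValueError("death_time must be positive")
    if activity_rate < 0:
        raise ValueError("activity_rate must be non-negative")
    death_bin = int(np.floor(death_time / bin_width))
    if n_bins is None:
        n_bins = death_bin + 4
    rng = derive_rng(seed, "activity")
    row = np.zeros(n_bins, dtype=np.int64)
    last = min(death_bin, n_bins - 1)
    row[: last + 1] = rng.poisson(activity_rate, size=last + 1)
    if activity_rate > 0 and row[: last + 1].sum() == 0:
        row[rng.integers(0, last + 1)] = 1
    row[death_bin + 1 :] = 0
    return row


def simulate_fecundity(
    mean_eggs: float,
    dispersion: float,
    n_females: int,
    weeks: int,
    seed: int,
) -> pd.DataFrame:
    """Eggs laid per female per daily assay, once a week (female x week table)."""
    if mean_eggs < 0:
        raise ValueError("mean_eggs must be non-negative")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = derive_rng(seed, "fecundity")
    shape = (n_females, weeks)
    counts = _rnbinom(rng, np.full(shape, float(mean_eggs)), dispersion)
    return pd.DataFrame(
        counts,
        index=[f"female_{i+1}" for i in range(n_females)],
        columns=[f"week_{w+1}" for w in range(weeks)],
    )


def _rnbinom(rng: np.random.Generator, mean: np.ndarray, phi) -> np.ndarray:
    """NB draws with variance mu + phi*mu^2 (phi = 0 -> Poisson)."""
    mean = np.asarray(mean, dtype=float)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    zero = (phi_arr <= 0) | (mean <= 0)
    out[zero] = rng.poisson(np.where(mean[zero] > 0, mean[zero], 0.0))
    if (~zero).any():
        r = 1.0 / phi_arr[~zero]
        p = r / (r + mean[~zero])
        out[~zero] = rng.negative_binomial(r, p)
    return out


# ---------------------------------------------------------------------------
# annotation and expression


def make_catalog(
    n_genes: int,
    seed: int,
    min_length: int = 400,
    max_length: int = 8000,
    max_transcripts: int = 2,
    max_exons: int = 4,
) -> TranscriptCatalog:
    """Random transcript catalog: log-uniform spliced lengths, random strands,
    1..max_transcripts isoforms per gene, exons laid head-to-tail with random
    intron gaps on a single synthetic chromosome."""
    rng = derive_rng(seed, "catalog")
    catalog = TranscriptCatalog()
    cursor = 1000
    width = max(len(str(n_genes)), 4)
    for i in range(n_genes):
        gid = f"gene{i+1:0{width}d}"
        strand = "+" if rng.uniform() < 0.5 else "-"
        n_tx = int(rng.integers(1, max_transcripts + 1))
        gene_len = int(np.exp(rng.uniform(np.log(min_length), np.log(max_length))))
        for j in range(n_tx):
            length = gene_len if j == 0 else max(min_length, int(gene_len * rng.uniform(0.5, 1.0)))
            n_exons = int(rng.integers(1, max_exons + 1))
            cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
            sizes = np.diff(np.concatenate(([0], cuts, [length])))
            exons = []
            pos = cursor
            for size in sizes:
                exons.append((pos, pos + int(size)))
                pos += int(size) + int(rng.integers(50, 500))  # intron
            catalog.add(
                Transcript(
                    transcript_id=f"{gid}.t{j+1}",
                    gene_id=gid,
                    chrom="chrSim",
                    strand=strand,
                    exons=tuple(exons),
                )
            )
            cursor = pos + 1000
    return catalog


def default_design(
    seed: int,
    n_replicates: int = 3,
    rin_range: tuple[float, float] = (5.0, 8.0),
    mean_libsize: float = 1e6,
    ages: tuple[int, ...] = AGES_WEEKS,
    sexes: tuple[str, ...] = SEXES,
    degradation: DegradationModel | None = None,
) -> pd.DataFrame:
    """Sample sheet for the full design: 2 genotypes x sexes x ages x replicates.

    RIN is drawn uniformly on ``rin_range`` per sample; library sizes vary
    +-20% around ``mean_libsize``.
    """
    degradation = degradation or DegradationModel()
    rng = derive_rng(seed, "truth", index=1)
    rows = []
    for genotype in GENOTYPES:
        for sex in sexes:
            for age in ages:
                for rep in range(1, n_replicates + 1):
                    tag = "E" if genotype == "E(z)/w" else "C"
                    name = f"{'Y' if age == 1 else 'M' if age == 4 else 'O'}{sex[0].upper()}{tag}{rep:02d}"
                    rin = float(np.round(rng.uniform(*rin_range), 1))
                    rows.append(
                        {
                            "sample": name,
                            "genotype": genotype,
                            "sex": sex,
                            "age_weeks": age,
                            "replicate": rep,
                            "RIN": rin,
                            "libsize": float(np.round(mean_libsize * rng.uniform(0.8, 1.2))),
                            "lam": degradation.lam(rin),
                        }
                    )
    return pd.DataFrame(rows).set_index("sample")


def make_truth(
    catalog: TranscriptCatalog,
    sample_info: pd.DataFrame,
    seed: int,
    n_de: int = 0,
    de_logfc: float = 2.0,
    phi: float = 0.05,
    gompertz_control: GompertzParams = GompertzParams(a=0.0018, g=0.075),
    gompertz_experimental: GompertzParams = GompertzParams(a=0.0012, g=0.082),
) -> SimTruth:
    """Planted ground truth: log-normal baselines, a chosen number of DE genes
    at +-``de_logfc`` (half up, half down), common dispersion ``phi``."""
    rng = derive_rng(seed, "truth")
    genes = catalog.gene_ids()
    n_genes = len(genes)
    baseline = pd.Series(np.exp(rng.normal(0.0, 1.2, size=n_genes)), index=genes)
    logfc = pd.Series(0.0, index=genes)
    if n_de > 0:
        de_genes = rng.choice(genes, size=n_de, replace=False)
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        logfc.loc[de_genes] = signs * de_logfc
    fractions = {}
    for gid, txs in catalog.genes().items():
        k = len(txs)
        if k == 1:
            fractions[txs[0].transcript_id] = 1.0
        else:
            raw = np.sort(rng.dirichlet(np.ones(k)))[::-1]
            order = sorted(txs, key=lambda t: t.transcript_id)
            for tx, fr in zip(order, raw):
                fractions[tx.transcript_id] = float(fr)
    return SimTruth(
        baseline=baseline,
        logfc=logfc,
        dispersion=pd.Series(phi, index=genes),
        tx_fraction=pd.Series(fractions),
        sample_info=sample_info.copy(),
        gompertz={"w/w": gompertz_control, "E(z)/w": gompertz_experimental},
        seed=seed,
    )


def _bin_probs(length: int, lam: float, bin_width: int) -> np.ndarray:
    """Multinomial probabilities over 3'-distance bins, density ~ exp(-d/lam)."""
    edges = np.arange(0, length + bin_width, bin_width, dtype=float)
    edges[-1] = float(length)
    if edges.size < 2:
        edges = np.array([0.0, float(length)])
    mass = np.exp(-edges[:-1] / lam) - np.exp(-edges[1:] / lam)
    return mass / mass.sum()


def simulate_positional_counts(
    catalog: TranscriptCatalog,
    truth: SimTruth,
    seed: int,
    bin_width: int = 25,
    degradation: DegradationModel | None = None,
) -> PositionalCounts:
    """Simulate 3'-degraded positional read counts for every sample in the truth.

    Per transcript and sample the expected count is the library-rescaled
    product of gene baseline, isoform share, planted fold change (applied to
    the experimental genotype), and the degradation survival fraction for the
    sample's lambda; totals are NB(mean, phi) and positions multinomial with
    mass proportional to exp(-d/lambda) integrated over 25-bp bins.
    """
    degradation = degradation or DegradationModel()
    info = truth.sample_info
    missing = [c for c in ("genotype", "libsize", "lam") if c not in info.columns]
    if missing:
        raise ValueError(f"sample_info lacks columns: {missing}")
    if (info["lam"] <= 0).any():
        raise ValueError("lambda must be positive for every sample")
    unknown = set(truth.tx_fraction.index) - set(catalog.transcripts)
    if unknown:
        raise ValueError(f"truth references transcripts absent from catalog: {sorted(unknown)[:5]}")
    rng = derive_rng(seed, "counts")
    samples = list(info.index)
    tids = sorted(truth.tx_fraction.index)
    lengths = np.array([catalog[t].length for t in tids], dtype=float)
    genes = np.array([catalog[t].gene_id for t in tids])
    base = truth.baseline.loc[genes].to_numpy() * truth.tx_fraction.loc[tids].to_numpy()
    lfc = truth.logfc.loc[genes].to_numpy()
    phi = truth.dispersion.loc[genes].to_numpy()

    pc = PositionalCounts(
        bin_width=bin_width,
        samples=samples,
        gene_of={t: g for t, g in zip(tids, genes)},
        length_of={t: int(l) for t, l in zip(tids, lengths)},
    )
    totals = np.empty((len(tids), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        lam = float(info.loc[s, "lam"])
        expr = base * np.where(info.loc[s, "genotype"] == "E(z)/w", 2.0**lfc, 1.0)
        surv = (lam / lengths) * -np.expm1(-lengths / lam)
        raw = expr * surv
        mean = raw * float(info.loc[s, "libsize"]) / raw.sum()
        totals[:, j] = _rnbinom(rng, mean, phi)
    for i, tid in enumerate(tids):
        n_bins = pc.n_bins(tid)
        arr = np.zeros((n_bins, len(samples)), dtype=np.int64)
        for j, s in enumerate(samples):
            if totals[i, j] > 0:
                probs = _bin_probs(int(lengths[i]), float(info.loc[s, "lam"]), bin_width)
                arr[:, j] = rng.multinomial(totals[i, j], probs)
        pc.counts[tid] = arr
    return pc
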