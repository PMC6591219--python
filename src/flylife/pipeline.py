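"""Run orchestration: validated configs, staged execution, reproducible manifests.

A run is described by a YAML config with a master seed; every stage derives
its randomness from that seed, stamps its outputs with the config hash, and
the manifest records a checksum per file so that identical config + seed
reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__, io
from .annotation import read_gtf, write_gtf
from .biascorr import compute_coverage_profile, correct_counts
from .detest import FilterSpec, enrich_top_n, run_exact_test_de
from .simulate import (
    AGES_WEEKS,
    GENOTYPES,
    SEXES,
    DegradationModel,
    GompertzParams,
    default_design,
    make_catalog,
    make_truth,
    simulate_activity_bins,
    simulate_fecundity,
    simulate_lifespans,
    simulate_positional_counts,
)
from .survival import (
    SurvivalSample,
    ks_test_survival,
    logrank_test,
    relative_difference,
    summarize_lifespan,
    wang_allison_test,
)

log = logging.getLogger(__name__)


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = Field(1000, ge=200)
    sexes: list[str] = ["male"]
    ages_weeks: list[int] = [1]
    n_replicates: int = Field(3, ge=1)
    mean_libsize: float = Field(1e6, gt=0)
    n_de: int = Field(0, ge=0)
    de_logfc: float = 2.0
    phi: float = Field(0.05, ge=0)
    lambda0: float = Field(400.0, gt=0)
    rin_min: float = 5.0
    rin_max: float = 8.0
    position_bin_width: int = Field(25, ge=1)
    cohort_n: int = Field(100, ge=10)
    gompertz_control: dict = {"a": 0.0018, "g": 0.075}
    gompertz_experimental: dict = {"a": 0.0012, "g": 0.082}
    fecundity_mean: float = 40.0
    fecundity_dispersion: float = 0.05
    n_females: int = 100
    fecundity_weeks: int = 10
    activity_rate: float = 5.0
    stress_n: int = 32


class BiascorrConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    truncate_bp: int = Field(750, gt=0)
    bins: int = Field(10, ge=2)
    trim_m: float = Field(0.30, ge=0, lt=0.5)
    trim_a: float = Field(0.05, ge=0, lt=0.5)
    order: str = Field("length-first", pattern="^(length-first|cpm-first)$")
    coverage_min_length: int = 1500


class DetestConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    group_column: str = "genotype"
    group_a: str = "E(z)/w"
    group_b: str = "w/w"
    cpm_filter: float = Field(1.0, gt=0)
    cpm_fraction: float = Field(0.5, gt=0, le=1)
    lfc: float = 1.0
    fdr: float = 0.05
    topn: list[int] = [50, 100, 200, 500, 1000]


class SurvivalStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bin_width_days: float = Field(7.0, gt=0)
    percentiles: list[float] = [0.25, 0.5, 0.75, 0.9]
    activity_bin_width: float = Field(0.5, gt=0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = Field("full", pattern="^(simulate|survival|biascorr|detest|full|validate)$")
    seed: int = 0
    outdir: str = "flylife_run"
    gtf: str | None = None
    positional_counts: str | None = None
    counts: str | None = None
    sample_sheet: str | None = None
    survival_csv: str | None = None
    activity_tsv: str | None = None
    gene_sets: str | None = None
    simulate: SimulateConfig = SimulateConfig()
    biascorr: BiascorrConfig = BiascorrConfig()
    detest: DetestConfig = DetestConfig()
    survival: SurvivalStageConfig = SurvivalStageConfig()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    started: float = dfield(default_factory=time.time)
    files: dict[str, str] = dfield(default_factory=dict)

    def record(self, path: Path) -> None:
        self.files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        payload = {
            "version": self.version,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "started": self.started,
            "finished": time.time(),
            "files": self.files,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as err:
        # surface every violated field at once
        fields = "; ".join(
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ValueError(f"invalid config {path}: {fields}") from err


def config_hash(cfg: RunConfig) -> str:
    payload = cfg.model_dump()
    payload.pop("outdir", None)  # run location is not part of the science
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stages


def _require(cfg: RunConfig, stage: str, **paths) -> None:
    missing = [name for name, p in paths.items() if p is None]
    if missing:
        raise ValueError(f"{stage} mode requires config fields: {', '.join(missing)}")
    absent = [str(p) for p in paths.values() if p is not None and not Path(p).exists()]
    if absent:
        raise FileNotFoundError(f"{stage}: missing input files: {', '.join(absent)}")


def run_simulate(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> dict[str, Path]:
    sim = cfg.simulate
    seed = cfg.seed
    hdr = {"seed": seed, "config_hash": manifest.config_hash}
    degradation = DegradationModel(lambda0=sim.lambda0)
    catalog = make_catalog(sim.n_genes, seed)
    info = default_design(
        seed,
        n_replicates=sim.n_replicates,
        rin_range=(sim.rin_min, sim.rin_max),
        mean_libsize=sim.mean_libsize,
        ages=tuple(sim.ages_weeks),
        sexes=tuple(sim.sexes),
        degradation=degradation,
    )
    truth = make_truth(
        catalog,
        info,
        seed,
        n_de=sim.n_de,
        de_logfc=sim.de_logfc,
        phi=sim.phi,
        gompertz_control=GompertzParams(**sim.gompertz_control),
        gompertz_experimental=GompertzParams(**sim.gompertz_experimental),
    )
    pc = simulate_positional_counts(
        catalog, truth, seed, bin_width=sim.position_bin_width, degradation=degradation
    )
    cohorts = []
    for gi, genotype in enumerate(GENOTYPES):
        params = truth.gompertz[genotype]
        for si, sex in enumerate(sim.sexes):
            for rep in range(1, sim.n_replicates + 1):
                sub_seed = (seed * 1000 + gi * 100 + si * 10 + rep) % 2**31
                s = simulate_lifespans(params, sim.cohort_n, sub_seed,
                                       label=f"{genotype}:{sex}:r{rep}")
                s.sex = sex
                s.replicate = rep
                cohorts.append(s)
    rng = np.random.default_rng(seed % 2**31)
    activity = np.vstack(
        [
            simulate_activity_bins(
                death_time=float(rng.uniform(10, 80)),
                activity_rate=sim.activity_rate,
                seed=int(rng.integers(0, 2**31)),
                n_bins=200,
            )
            for _ in range(sim.stress_n)
        ]
    )
    fecundity = simulate_fecundity(
        sim.fecundity_mean, sim.fecundity_dispersion, sim.n_females,
        sim.fecundity_weeks, seed,
    )

    paths = {
        "gtf": outdir / "annotation.gtf",
        "sample_sheet": outdir / "samples.csv",
        "positional": outdir / "positional_counts.tsv",
        "survival": outdir / "survival.csv",
        "activity": outdir / "activity.tsv",
        "fecundity": outdir / "fecundity.tsv",
        "truth": outdir / "truth_genes.tsv",
    }
    write_gtf(catalog, paths["gtf"], header_lines=[f" flylife v{__version__} seed={seed}"])
    io.write_sample_sheet(info, paths["sample_sheet"], **hdr)
    io.write_positional_tsv(pc, paths["positional"], **hdr)
    io.write_survival_csv(cohorts, paths["survival"], **hdr)
    io.write_activity_tsv(activity, paths["activity"], **hdr)
    io.write_table(fecundity, paths["fecundity"], **hdr)
    truth_table = pd.DataFrame(
        {"baseline": truth.baseline, "logFC": truth.logfc, "phi": truth.dispersion}
    ).rename_axis(index="gene_id")
    io.write_table(truth_table, paths["truth"], **hdr)
    for p in paths.values():
        manifest.record(p)
    log.info("simulate: %d genes, %d samples, %d cohorts", sim.n_genes, len(info), len(cohorts))
    return paths


def run_biascorr(cfg: RunConfig, outdir: Path, manifest: RunManifest,
                 gtf=None, positional=None, sample_sheet=None) -> dict[str, Path]:
    bc = cfg.biascorr
    gtf = gtf or cfg.gtf
    positional = positional or cfg.positional_counts
    sample_sheet = sample_sheet or cfg.sample_sheet
    _require(cfg, "biascorr", gtf=gtf, positional_counts=positional, sample_sheet=sample_sheet)
    hdr = {"seed": cfg.seed, "config_hash": manifest.config_hash}
    catalog = read_gtf(gtf)
    info = io.read_sample_sheet(sample_sheet)
    gene_of = {tid: tx.gene_id for tid, tx in catalog.transcripts.items()}
    length_of = {tid: tx.length for tid, tx in catalog.transcripts.items()}
    pc = io.read_positional_tsv(positional, cfg.simulate.position_bin_width, gene_of, length_of)
    profile = compute_coverage_profile(pc, min_length=bc.coverage_min_length)
    annotation, adjusted, factors = correct_counts(
        pc, catalog, sample_info=info, keep=bc.truncate_bp, n_bins=bc.bins, order=bc.order
    )
    paths = {
        "coverage": outdir / "coverage_profile.tsv",
        "truncated_gtf": outdir / "annotation.truncated.gtf",
        "adjusted": outdir / "adjusted_counts.tsv",
        "factors": outdir / "tmm_factors.tsv",
    }
    io.write_table(profile, paths["coverage"], **hdr)
    write_gtf(annotation.catalog, paths["truncated_gtf"],
              header_lines=[f" flylife v{__version__} truncated to {bc.truncate_bp} bp"])
    io.write_counts_tsv(adjusted, paths["adjusted"], **hdr)
    io.write_table(factors, paths["factors"], index=False, **hdr)
    for p in paths.values():
        manifest.record(p)
    log.info("biascorr: %d genes adjusted, factor range [%.3f, %.3f]",
             len(adjusted.genes), factors["factor"].min(), factors["factor"].max())
    return paths


def run_detest(cfg: RunConfig, outdir: Path, manifest: RunManifest,
               counts=None, sample_sheet=None) -> dict[str, Path]:
    dt = cfg.detest
    counts = counts or cfg.counts
    sample_sheet = sample_sheet or cfg.sample_sheet
    _require(cfg, "detest", counts=counts, sample_sheet=sample_sheet)
    hdr = {"seed": cfg.seed, "config_hash": manifest.config_hash}
    info = io.read_sample_sheet(sample_sheet)
    cm = io.read_counts_tsv(counts, sample_info=info)
    groups = info.loc[list(cm.samples), dt.group_column]
    res = run_exact_test_de(
        cm, groups, dt.group_a, dt.group_b,
        filter_spec=FilterSpec(cpm=dt.cpm_filter, fraction=dt.cpm_fraction),
    )
    paths = {"de": outdir / "de_results.tsv"}
    io.write_table(res.rename_axis(index="gene_id"), paths["de"], **hdr)
    if cfg.gene_sets is not None:
        sets = io.read_gmt(cfg.gene_sets)
        ranked = list(res[res["p"] < 0.05].sort_values("p").index)
        universe = list(res.index)
        enrichment = enrich_top_n(ranked, sets, universe, top_grid=tuple(dt.topn))
        paths["enrichment"] = outdir / "enrichment.tsv"
        io.write_table(enrichment, paths["enrichment"], index=False, **hdr)
    for p in paths.values():
        manifest.record(p)
    n_sig = int((res["FDR"] < dt.fdr).sum())
    log.info("detest: %d genes tested, %d below FDR %.2f", len(res), n_sig, dt.fdr)
    return paths


def run_survival_stage(cfg: RunConfig, outdir: Path, manifest: RunManifest,
                       survival_csv=None, activity_tsv=None) -> dict[str, Path]:
    sv = cfg.survival
    survival_csv = survival_csv or cfg.survival_csv
    _require(cfg, "survival", survival_csv=survival_csv)
    hdr = {"seed": cfg.seed, "config_hash": manifest.config_hash}
    cohorts = io.read_survival_csv(survival_csv)
    rows = []
    for s in cohorts:
        summ = summarize_lifespan(s, bin_width=sv.bin_width_days)
        rows.append(
            {
                "cohort": s.label,
                "n": summ.n,
                "median": summ.median,
                "q90": summ.q90,
                "MRDT": summ.mrdt,
                "gompertz_a": summ.gompertz_a,
                "gompertz_g": summ.gompertz_g,
            }
        )
    summary = pd.DataFrame(rows)
    # pairwise genotype comparisons within sex, replicates pooled
    by_key: dict[tuple, list[SurvivalSample]] = {}
    for s in cohorts:
        genotype = s.label.split(":")[0]
        by_key.setdefault((genotype, s.sex), []).append(s)
    pooled = {
        key: SurvivalSample(
            times=np.concatenate([s.times for s in group]),
            events=np.concatenate([s.events for s in group]),
            label=f"{key[0]}:{key[1]}",
            sex=key[1],
        )
        for key, group in by_key.items()
    }
    tests = []
    sexes = sorted({sex for _, sex in pooled})
    for sex in sexes:
        a = pooled.get(("w/w", sex))
        b = pooled.get(("E(z)/w", sex))
        if a is None or b is None:
            continue
        lr = logrank_test(a, b)
        ks = ks_test_survival(a, b)
        wa = wang_allison_test(a, b)
        med_a = summarize_lifespan(a, bin_width=sv.bin_width_days)
        med_b = summarize_lifespan(b, bin_width=sv.bin_width_days)
        tests.append(
            {
                "sex": sex,
                "dM_percent": relative_difference(med_a.median, med_b.median),
                "d90_percent": relative_difference(med_a.q90, med_b.q90),
                "dMRDT_percent": relative_difference(med_a.mrdt, med_b.mrdt)
                if np.isfinite(med_a.mrdt) and np.isfinite(med_b.mrdt)
                else np.nan,
                "logrank_p": lr.p_value,
                "ks_p": ks.p_value,
                "wang_allison_p": wa.p_value,
            }
        )
    paths = {
        "summary": outdir / "lifespan_summary.tsv",
        "tests": outdir / "survival_tests.tsv",
    }
    io.write_table(summary, paths["summary"], index=False, **hdr)
    io.write_table(pd.DataFrame(tests), paths["tests"], index=False, **hdr)
    if activity_tsv or cfg.activity_tsv:
        from .survival import call_death_times, stress_percentiles

        activity = io.read_activity_tsv(activity_tsv or cfg.activity_tsv)
        called = call_death_times(activity.to_numpy(), bin_width=sv.activity_bin_width,
                                  label="stress-assay")
        perc = stress_percentiles(called, levels=tuple(sv.percentiles))
        stress = pd.DataFrame(
            [{"percentile": q, "hours": t} for q, t in sorted(perc.items())]
        )
        paths["stress"] = outdir / "stress_percentiles.tsv"
        io.write_table(stress, paths["stress"], index=False, **hdr)
    for p in paths.values():
        manifest.record(p)
    log.info("survival: %d cohorts summarized, %d contrasts tested", len(summary), len(tests))
    return paths


# ---------------------------------------------------------------------------
# entry points


def run(cfg: RunConfig) -> RunManifest:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(cfg), seed=cfg.seed)
    stage = "config"
    try:
        if cfg.mode in ("simulate", "full"):
            stage = "simulate"
            sim_paths = run_simulate(cfg, outdir, manifest)
        else:
            sim_paths = {}
        if cfg.mode in ("biascorr", "full"):
            stage = "biascorr"
            bc_paths = run_biascorr(
                cfg, outdir, manifest,
                gtf=sim_paths.get("gtf"), positional=sim_paths.get("positional"),
                sample_sheet=sim_paths.get("sample_sheet"),
            )
        else:
            bc_paths = {}
        if cfg.mode in ("detest", "full"):
            stage = "detest"
            run_detest(
                cfg, outdir, manifest,
                counts=bc_paths.get("adjusted"),
                sample_sheet=sim_paths.get("sample_sheet"),
            )
        if cfg.mode in ("survival", "full"):
            stage = "survival"
            run_survival_stage(
                cfg, outdir, manifest,
                survival_csv=sim_paths.get("survival"),
                activity_tsv=sim_paths.get("activity"),
            )
        if cfg.mode == "validate":
            stage = "validate"
            report = validate_formats(
                [p for p in (cfg.gtf, cfg.counts, cfg.sample_sheet) if p]
            )
            (outdir / "validation_report.txt").write_text(
                "\n".join(report) + ("\n" if report else "")
            )
    except Exception:
        log.error("pipeline failed in stage %r", stage)
        raise
    manifest.write(outdir / "manifest.json")
    return manifest


def validate_formats(paths: list[str]) -> list[str]:
    """Schema checks with line-numbered diagnostics; empty list means clean."""
    problems: list[str] = []
    sheets: dict[str, pd.DataFrame] = {}
    counts_cols: dict[str, list[str]] = {}
    for path in paths:
        p = Path(path)
        if not p.exists():
            problems.append(f"{p}: file not found")
            continue
        if p.suffix == ".gtf":
            problems.extend(_check_gtf(p))
        elif p.suffix == ".csv":
            try:
                sheets[str(p)] = io.read_sample_sheet(p)
            except Exception as exc:
                problems.append(f"{p}: unreadable sample sheet ({exc})")
        else:
            problems.extend(_check_counts(p, counts_cols))
    for sheet_path, sheet in sheets.items():
        for counts_path, cols in counts_cols.items():
            extra = set(cols) - set(sheet.index)
            if extra:
                problems.append(
                    f"{counts_path}: sample columns missing from sheet {sheet_path}: "
                    + ", ".join(sorted(extra))
                )
    return problems


def _check_gtf(path: Path) -> list[str]:
    problems = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                problems.append(f"{path}:{lineno}: expected 9 tab-separated fields")
                continue
            if 'gene_id "' not in fields[8] or 'transcript_id "' not in fields[8]:
                problems.append(f"{path}:{lineno}: missing gene_id/transcript_id attribute")
            try:
                start, end = int(fields[3]), int(fields[4])
                if start < 1 or end < start:
                    problems.append(f"{path}:{lineno}: invalid coordinates {start}-{end}")
            except ValueError:
                problems.append(f"{path}:{lineno}: non-integer coordinates")
    return problems


def _check_counts(path: Path, counts_cols: dict) -> list[str]:
    problems = []
    try:
        df = io.read_table(path)
    except Exception as exc:
        return [f"{path}: unreadable table ({exc})"]
    sample_cols = [c for c in df.columns if c not in ("length", "full_length")]
    counts_cols[str(path)] = sample_cols
    numeric = df[sample_cols].select_dtypes(include=[np.number])
    neg = numeric.lt(0)
    if neg.any().any():
        for gene, row in neg[neg.any(axis=1)].iterrows():
            for col in row.index[row]:
                problems.append(f"{path}: negative count for gene {gene}, sample {col}")
    return problems
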