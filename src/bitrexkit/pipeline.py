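"""End-to-end orchestration: simulate -> sequence -> genotype -> model.

A single RunConfig (JSON or TOML) drives genome construction, population
dynamics, qPCR-style measurement, long-read spanning genotyping, masked-
depth copy number, the rearrangement screen, and kinetics, producing one
RunReport in which every estimate is paired with its truth.  The master
seed deterministically derives one child seed per stage, so a run is
bit-reproducible end to end.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, depthcn, kinetics, rearrange, spanscan
from . import io as _io
from .synthetic_data import (
    ArraySpec,
    ReadSimParams,
    SimParams,
    build_array_genome,
    reads_truth_frame,
    simulate_population,
    simulate_qpcr_series,
    simulate_reads,
)

logger = logging.getLogger("bitrexkit.pipeline")

_STAGES = (
    "genome",
    "population",
    "qpcr",
    "long_reads",
    "short_reads",
    "bootstrap",
    "screen",
    "spare",
)


def derive_stage_seeds(master_seed: int) -> dict[str, int]:
    """One deterministic child seed per pipeline stage (all < 2**31)."""
    state = np.random.SeedSequence(master_seed).generate_state(len(_STAGES))
    return {name: int(s % 2**31) for name, s in zip(_STAGES, state)}


@dataclass(frozen=True)
class AnalysisParams:
    min_identity: float = 0.8
    min_unit_fraction: float = 0.6
    seed_k: int = 15
    bin_size: int = 100
    gain_threshold: float = 1.25
    loss_threshold: float = 0.75
    min_flank_length: int = 200
    n_bootstrap: int = 200

    def __post_init__(self):
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_unit_fraction <= 1:
            raise ValueError("min_unit_fraction must be in (0, 1]")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    array: ArraySpec
    population: SimParams
    long_reads: ReadSimParams
    short_reads: ReadSimParams
    analysis: AnalysisParams = AnalysisParams()
    background_length: int = 45000
    n_extra_chromosomes: int = 1
    n_generations: int = 30
    n_replicates: int = 3
    qpcr_noise_sd: float = 1.0
    g_per_day: float = 6.0
    seed: int = 1

    def __post_init__(self):
        if self.array.n_units < 1:
            raise ValueError("pipeline runs require n_units >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.qpcr_noise_sd < 0:
            raise ValueError("qpcr_noise_sd must be >= 0")
        if self.g_per_day <= 0:
            raise ValueError("g_per_day must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_demo_config(seed: int = 1) -> RunConfig:
    """The demo study: a 14-unit array of 2.0-kb units under mild expansion."""
    return RunConfig(
        array=ArraySpec(n_units=14, unit_length=2000, flank_anchor_length=1000),
        population=SimParams(p_exp=0.05, step_mean=1.5, k=1e-5, population_cap=300),
        long_reads=ReadSimParams(
            length_distribution="lognormal",
            log_mu=float(np.log(35000.0)),
            log_sigma=0.4,
            n_reads=120,
            substitution_error_rate=0.005,
        ),
        short_reads=ReadSimParams(
            length_distribution="fixed", read_length=150, depth=25.0
        ),
        background_length=45000,
        n_generations=30,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# config loading / validation
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "array": ArraySpec,
    "population": SimParams,
    "long_reads": ReadSimParams,
    "short_reads": ReadSimParams,
    "analysis": AnalysisParams,
}
_TOP_SCALARS = (
    "background_length",
    "n_extra_chromosomes",
    "n_generations",
    "n_replicates",
    "qpcr_noise_sd",
    "g_per_day",
    "seed",
)


def validate_config(source) -> tuple[RunConfig | None, list[str]]:
    """Build a RunConfig from a path or dict, collecting *all* errors.

    Unknown keys are rejected; defaults fill everything absent except
    ``array.n_units``.  Returns ``(config, errors)``; config is None when
    any error was found.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        try:
            text = path.read_bytes()
        except OSError as e:
            return None, [f"cannot read config: {e}"]
        if path.suffix == ".toml":
            data = tomllib.loads(text.decode())
        else:
            try:
                data = json.loads(text)
            except json.JSONDecodeError:
                try:
                    data = tomllib.loads(text.decode())
                except tomllib.TOMLDecodeError as e:
                    return None, [f"config is neither valid JSON nor TOML: {e}"]
    else:
        data = dict(source)

    errors: list[str] = []
    kwargs: dict = {}

    for key in data:
        if key not in _SECTION_TYPES and key not in _TOP_SCALARS:
            errors.append(f"unknown key {key!r}")

    for key in _TOP_SCALARS:
        if key in data:
            v = data[key]
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                errors.append(f"{key}: expected a number, got {v!r}")
            else:
                kwargs[key] = v

    if "array" not in data or not isinstance(data.get("array"), dict) or "n_units" not in data.get("array", {}):
        errors.append("array.n_units: required")

    for section, cls in _SECTION_TYPES.items():
        sub = data.get(section)
        if sub is None:
            continue  # defaults filled below
        if not isinstance(sub, dict):
            errors.append(f"{section}: expected a table/object")
            continue
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(sub) - names
        errors.extend(f"{section}.{k}: unknown key" for k in sorted(bad))
        clean = {k: v for k, v in sub.items() if k in names}
        if section == "array" and "n_units" not in clean:
            continue
        try:
            kwargs[section] = cls(**clean)
        except (ValueError, TypeError) as e:
            errors.append(f"{section}: {e}")

    if errors:
        return None, errors

    demo = default_demo_config()
    kwargs.setdefault("long_reads", demo.long_reads)
    kwargs.setdefault("short_reads", demo.short_reads)
    kwargs.setdefault("population", SimParams())
    try:
        return RunConfig(**kwargs), []
    except (ValueError, TypeError) as e:
        return None, [str(e)]


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    provenance: dict
    genome: dict
    population: dict
    kinetics: dict
    spanning: dict
    depth: dict
    rearrangements: dict
    ploidy: dict
    truth_vs_estimate: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _stage(name: str, t0: float) -> None:
    logger.info("stage=%s wall_time=%.2fs", name, time.perf_counter() - t0)


def run_end_to_end(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the full synthetic study and consolidate a truth/estimate report."""
    seeds = derive_stage_seeds(config.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    genome = build_array_genome(
        config.array,
        config.background_length,
        seeds["genome"],
        n_extra_chromosomes=config.n_extra_chromosomes,
    )
    _stage("genome", t0)

    # population dynamics + qPCR-style measurement
    t0 = time.perf_counter()
    trajs = [
        simulate_population(
            config.array.n_units,
            dataclasses.replace(config.population, seed=seeds["population"] + rep),
            config.n_generations,
        )
        for rep in range(config.n_replicates)
    ]
    series = simulate_qpcr_series(
        trajs, config.qpcr_noise_sd, seeds["qpcr"], g_per_day=config.g_per_day
    )
    traj_meas = kinetics.Trajectory.from_series(series)
    cna_emp = (
        kinetics.cna_g_empirical(
            float(traj_meas.mean_copy[-1]),
            float(traj_meas.mean_copy[0]),
            config.n_generations,
        )
        if config.n_generations > 0
        else 0.0
    )
    if config.population.k > 0:
        cna_model = kinetics.cna_g_model(
            kinetics.KineticParams(
                k=config.population.k * config.g_per_day,
                T=config.n_generations / config.g_per_day,
                G=config.n_generations,
                X0=config.array.n_units,
            )
        )
    else:
        cna_model = 0.0
    fit_warning = None
    try:
        fit = kinetics.fit_k(
            traj_meas,
            config.g_per_day,
            n_bootstrap=config.analysis.n_bootstrap,
            seed=seeds["bootstrap"],
        )
        fit_summary = {
            "k_per_day": fit.k,
            "k_ci": list(fit.k_ci),
            "x0": fit.x0,
            "k_per_generation": fit.k_per_generation,
            "warning": fit.warning,
        }
    except (ValueError, RuntimeError) as e:
        fit_warning = str(e)
        fit_summary = {"error": fit_warning}
    _stage("population", t0)

    # long reads -> spanning genotyping
    t0 = time.perf_counter()
    long_params = dataclasses.replace(config.long_reads, seed=seeds["long_reads"])
    long_reads = simulate_reads(genome, long_params)
    results = spanscan.genotype_spanning_reads(
        long_reads,
        genome.unit_sequence,
        genome.left_anchor_sequence,
        genome.right_anchor_sequence,
        min_identity=config.analysis.min_identity,
        min_unit_fraction=config.analysis.min_unit_fraction,
        k=config.analysis.seed_k,
    )
    n_truth_spanning = sum(1 for r in long_reads if r.spans_array)
    try:
        summary = spanscan.copy_number_distribution(results)
        span_summary = {
            "n_spanning": summary.n,
            "histogram": {str(k): v for k, v in summary.histogram.items()},
            "modal_units": summary.mode,
            "max_units": summary.max,
        }
    except ValueError:
        span_summary = {"n_spanning": 0, "histogram": {}, "modal_units": None, "max_units": None}
    span_summary["n_truth_spanning"] = n_truth_spanning
    _stage("long_reads", t0)

    # short reads -> masked-depth copy number + ploidy
    t0 = time.perf_counter()
    short_params = dataclasses.replace(config.short_reads, seed=seeds["short_reads"])
    short_reads = simulate_reads(genome, short_params)
    t = genome.truth
    # mask everything in the array except the first unit copy (the retained
    # copy), including any repeated intervening spacers between later copies
    first_unit_end = t.unit_intervals[0][1]
    mask = (
        [(t.array_chrom, first_unit_end, t.array_end)]
        if t.array_end > first_unit_end
        else []
    )
    locus_excl = [
        (t.array_chrom, t.left_anchor[0], t.right_anchor[1]),
    ]
    profile = depthcn.compute_depth(
        genome,
        reads=short_reads,
        bin_size=config.analysis.bin_size,
        mask_intervals=mask,
    )
    norm = depthcn.normalize_depth(profile, mask_intervals=mask, background_exclude=locus_excl)
    unit0 = t.unit_intervals[0]
    cn = depthcn.region_copy_number(norm, (t.array_chrom, unit0[0], unit0[1]))
    ploidy = depthcn.chromosome_ploidy(
        norm,
        locus_excl,
        gain_threshold=config.analysis.gain_threshold,
        loss_threshold=config.analysis.loss_threshold,
    )
    _stage("short_reads", t0)

    # rearrangement screen on the long reads
    t0 = time.perf_counter()
    calls, screen_summary = rearrange.screen_reads(
        long_reads,
        genome.unit_sequence,
        genome,
        min_length=config.analysis.min_flank_length,
        min_unit_fraction=config.analysis.min_unit_fraction,
    )
    _stage("screen", t0)

    final_mean = float(np.mean([tr.mean_copy[-1] for tr in trajs]))
    report = RunReport(
        provenance={
            "package_version": __version__,
            "master_seed": config.seed,
            "stage_seeds": seeds,
            "config_hash": config.config_hash(),
        },
        genome={
            "n_units_truth": config.array.n_units,
            "unit_length": config.array.unit_length,
            "array_locus": list(genome.array_locus),
            "chromosomes": [n for n, _ in genome.chromosomes],
        },
        population={
            "x0": config.array.n_units,
            "n_generations": config.n_generations,
            "final_mean_copy": final_mean,
            "cna_g_empirical": cna_emp,
            "cna_g_model": cna_model,
        },
        kinetics=fit_summary,
        spanning=span_summary,
        depth={
            "copy_number_estimate": cn.mean,
            "copy_number_sd": None if np.isnan(cn.sd) else cn.sd,
            "n_bins": cn.n_bins,
            "truth": config.array.n_units,
            "placement_stats": norm.stats,
        },
        rearrangements=screen_summary,
        ploidy={c: {"mean_depth": p.mean_depth, "call": p.call} for c, p in ploidy.items()},
    )
    report.truth_vs_estimate = [
        {
            "quantity": "array_copy_number",
            "truth": config.array.n_units,
            "estimate": cn.mean,
            "method": "masked_depth",
        },
        {
            "quantity": "array_copy_number",
            "truth": config.array.n_units,
            "estimate": span_summary["modal_units"],
            "method": "spanning_read_mode",
        },
        {
            "quantity": "cna_per_generation",
            "truth": cna_model,
            "estimate": cna_emp,
            "method": "qpcr_series",
        },
    ]

    if out is not None:
        genome.write_fasta(out / "genome.fa")
        genome.write_truth_bed(out / "truth.bed")
        genome.write_truth_json(out / "truth.json")
        _io.write_fastq(long_reads, out / "long_reads.fq.gz")
        _io.write_fastq(short_reads, out / "short_reads.fq.gz")
        reads_truth_frame(long_reads).to_csv(out / "long_reads_truth.tsv", sep="\t", index=False)
        _io.write_series_tsv(series, out / "qpcr_series.tsv")
        _io.write_bedgraph(norm, out / "depth_normalized.bedgraph")
        with open(out / "rearrangement_calls.tsv", "w") as fh:
            fh.write("read_id\tclassification\n")
            for c in calls:
                fh.write(f"{c.read_id}\t{c.classification}\n")
        report.write_json(out / "report.json")
    return report
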