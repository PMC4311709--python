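"""File formats, configuration and the pipeline driver.

All tabular formats are plain text: OTU counts as TSV (first column OTU id,
one column per sample), sample metadata and taxonomy as TSV, sensor / gas /
gradient-fraction data as headered CSV, ground truth and fit summaries as
JSON, distance matrices as square TSV. Readers validate and report the
offending line number on malformed input; every writer's output is accepted
by its reader (round-trip property).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, responders, simulate, sip, tracegas
from .exceptions import InvalidParameterError, ParseError, PipelineError
from .otu import OtuTable
from .pulse import PulseModel, SensorSeries, aggregate
from .sip import FractionProfile
from .simulate import (
    GasSimParams,
    GradientSimParams,
    GroundTruth,
    SeedBankParams,
    SensorSimParams,
)
from .tracegas import GasTimeCourse

log = logging.getLogger("rarepulse")


# ---------------------------------------------------------------------------
# OTU table TSV
# ---------------------------------------------------------------------------

def write_otu_table(table: OtuTable, counts_path, metadata_path, taxonomy_path=None) -> None:
    """Write counts (OTUs as rows, samples as columns), metadata and taxonomy."""
    out = table.counts.T
    out.index.name = "otu_id"
    out.to_csv(counts_path, sep="\t")
    meta = table.metadata.copy()
    meta.index.name = "sample"
    meta.to_csv(metadata_path, sep="\t")
    if taxonomy_path is not None:
        with open(taxonomy_path, "w") as fh:
            fh.write("otu_id\tlineage\n")
            for otu in table.otu_ids:
                if otu in table.taxonomy:
                    fh.write(f"{otu}\t{table.taxonomy[otu]}\n")


def read_otu_table(counts_path, metadata_path, taxonomy_path=None) -> OtuTable:
    """Read and validate an OTU table; errors name the offending line.

    Accepts the BIOM-TSV dialect: a leading ``# Constructed from biom file``
    comment line is skipped.
    """
    counts_path = Path(counts_path)
    with open(counts_path) as fh:
        lines = fh.read().splitlines()
    line_no = 0
    while line_no < len(lines) and lines[line_no].startswith("#"):
        line_no += 1
    if line_no >= len(lines):
        raise ParseError(counts_path, 1, "empty count table")
    header = lines[line_no].split("\t")
    if len(header) < 2:
        raise ParseError(counts_path, line_no + 1, "header needs an OTU-id column and >=1 sample")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise ParseError(counts_path, line_no + 1, "duplicate sample id in header")
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    seen = set()
    for i, line in enumerate(lines[line_no + 1 :], start=line_no + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(counts_path, i, f"expected {len(header)} fields, got {len(parts)}")
        otu = parts[0]
        if otu in seen:
            raise ParseError(counts_path, i, f"duplicate OTU id {otu!r}")
        seen.add(otu)
        row = []
        for v in parts[1:]:
            try:
                iv = int(v)
            except ValueError:
                raise ParseError(counts_path, i, f"non-integer count {v!r}") from None
            if iv < 0:
                raise ParseError(counts_path, i, f"negative count {iv}")
            row.append(iv)
        otu_ids.append(otu)
        rows.append(row)
    counts = pd.DataFrame(rows, index=otu_ids, columns=samples, dtype=np.int64).T

    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    taxonomy: dict[str, str] = {}
    if taxonomy_path is not None and Path(taxonomy_path).exists():
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        taxonomy = tax["lineage"].to_dict()
    return OtuTable(counts=counts, metadata=meta, taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# sensor / gas / fraction CSV
# ---------------------------------------------------------------------------

def write_sensor_series(series: SensorSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_sensor_series(path) -> SensorSeries:
    df = pd.read_csv(path)
    required = {"timestamp", "moisture", "co2_ppmv"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns {sorted(missing)}")
    return SensorSeries.from_frame(df)


def write_fraction_profiles(profiles: list[FractionProfile], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["unit", "treatment", "fraction", "density_g_per_mL", "copies"])
        for p in profiles:
            for i, d, c in zip(p.index, p.density, p.copies):
                writer.writerow([p.unit, p.label, i, f"{d:.6f}", f"{c:.6g}"])


def read_fraction_profiles(path) -> list[FractionProfile]:
    df = pd.read_csv(path)
    required = {"unit", "treatment", "fraction", "density_g_per_mL", "copies"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns {sorted(missing)}")
    out = []
    for (unit, treatment), sub in df.groupby(["unit", "treatment"], sort=True):
        sub = sub.sort_values("fraction")
        out.append(
            FractionProfile(
                index=sub["fraction"].to_numpy(),
                density=sub["density_g_per_mL"].to_numpy(),
                copies=sub["copies"].to_numpy(),
                label=str(treatment),
                unit=str(unit),
            )
        )
    return out


def write_gas_timecourses(courses: list[GasTimeCourse], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["unit", "ecosystem", "treatment", "species", "time_h", "conc_ppmv"])
        for tc in courses:
            for t, c in zip(tc.times_h, tc.conc_ppmv):
                writer.writerow([tc.unit, tc.ecosystem, tc.treatment, tc.species, t, f"{c:.6g}"])


def read_gas_timecourses(
    path, soil_g=3.0, headspace_mL=37.7, temp_C=25.0, pressure_atm=1.0
) -> list[GasTimeCourse]:
    df = pd.read_csv(path)
    required = {"unit", "ecosystem", "treatment", "species", "time_h", "conc_ppmv"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns {sorted(missing)}")
    out = []
    for (unit, species), sub in df.groupby(["unit", "species"], sort=True):
        sub = sub.sort_values("time_h")
        out.append(
            GasTimeCourse(
                unit=str(unit),
                ecosystem=str(sub["ecosystem"].iloc[0]),
                treatment=str(sub["treatment"].iloc[0]),
                species=str(species),
                times_h=sub["time_h"].to_numpy(),
                conc_ppmv=sub["conc_ppmv"].to_numpy(),
                soil_g=soil_g,
                headspace_mL=headspace_mL,
                temp_C=temp_C,
                pressure_atm=pressure_atm,
            )
        )
    return out


def write_distance_matrix(dist, path) -> None:
    pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids).to_csv(path, sep="\t")


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "dormant": sorted(truth.dormant),
        "resuscitated": {k: sorted(v) for k, v in truth.resuscitated.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        dormant=set(payload["dormant"]),
        resuscitated={k: set(v) for k, v in payload["resuscitated"].items()},
        true_abundances=None,
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat configuration of one pipeline run.

    Paths left as ``None`` are produced by the simulate stage; the pipeline
    aborts if an analysis stage's input is missing.
    """

    outdir: str = "rarepulse_out"
    seed: int = 0
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    sensor_path: str | None = None
    gas_path: str | None = None
    fractions_path: str | None = None
    rarefy_depth: str | int = "auto"
    n_permutations: int = 999
    dominance_threshold: float = 0.01
    taxonomy_level: str = "family"
    window_h: float = 12.0
    correction: str = "ar1"
    min_shift: float = 0.01
    peak_width_fractions: int = 2
    soil_g: float = 3.0
    headspace_mL: float = 37.7
    temp_C: float = 25.0
    pressure_atm: float = 1.0
    sampling_correction_mL: float = 0.0
    simulate_first: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError(path, 1, "config must be a flat key: value mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _require(path, what: str, stage: str):
    if path is None or not Path(path).exists():
        raise PipelineError(stage, f"missing input file for {what}: {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis: simulate (optional) -> sip -> pulse -> gas ->
    community -> rare. Writes every intermediate under ``config.outdir`` and
    returns the manifest (also written as ``manifest.json``).

    Reruns with the same config produce byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "rarepulse",
        "seed": config.seed,
        "stages": [],
        "outputs": {},
        "parameters": asdict(config),
    }

    cfg = config
    if config.simulate_first:
        cfg = _stage_simulate(config, outdir, manifest)
    _stage_sip(cfg, outdir, manifest)
    _stage_pulse(cfg, outdir, manifest)
    _stage_gas(cfg, outdir, manifest)
    table = _stage_community(cfg, outdir, manifest)
    _stage_rare(cfg, outdir, manifest, table)

    write_json(manifest, outdir / "manifest.json")
    return manifest


def _log_stage(stage: str, **info):
    kv = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s %s", stage, kv)


def _stage_simulate(config: RunConfig, outdir: Path, manifest: dict) -> RunConfig:
    stage = "simulate"
    _log_stage(stage, event="start", seed=config.seed)
    params = SeedBankParams(seed=config.seed)
    table, truth = simulate.generate_paired_otu_tables(params)
    table.taxonomy = simulate.assign_random_taxonomy(table.otu_ids, seed=config.seed)
    counts_path = outdir / "otu_counts.tsv"
    metadata_path = outdir / "sample_metadata.tsv"
    taxonomy_path = outdir / "taxonomy.tsv"
    write_otu_table(table, counts_path, metadata_path, taxonomy_path)
    write_ground_truth(truth, outdir / "ground_truth.json")

    series, _ = simulate.generate_sensor_series(SensorSimParams(seed=config.seed))
    sensor_path = outdir / "sensor_series.csv"
    write_sensor_series(series, sensor_path)

    design = simulate.generate_design(params.n_ecosystems, 2, params.n_replicates)
    gparams = GradientSimParams(seed=config.seed)
    profiles = []
    for i, unit in enumerate(design):
        profiles.append(
            simulate.generate_fraction_profiles(
                gparams,
                labeled=(unit.treatment == "rewetted"),
                unit=unit.pair_id,
                seed=config.seed * 100003 + i,
            )
        )
    fractions_path = outdir / "gradient_fractions.csv"
    write_fraction_profiles(profiles, fractions_path)

    courses = []
    for species in ("CO2", "CH4", "N2O"):
        sp = simulate.default_gas_params_for_species(species, seed=config.seed)
        courses.extend(simulate.generate_gas_timecourses(sp, design, species=species))
    gas_path = outdir / "gas_timecourses.csv"
    write_gas_timecourses(courses, gas_path)

    manifest["stages"].append(stage)
    manifest["outputs"][stage] = [
        str(p)
        for p in (counts_path, metadata_path, taxonomy_path, sensor_path, fractions_path, gas_path)
    ]
    _log_stage(stage, event="end", n_samples=table.n_samples, n_otus=table.n_otus)
    from dataclasses import replace as _replace

    return _replace(
        config,
        counts_path=str(counts_path),
        metadata_path=str(metadata_path),
        taxonomy_path=str(taxonomy_path),
        sensor_path=str(sensor_path),
        fractions_path=str(fractions_path),
        gas_path=str(gas_path),
    )


def _stage_sip(config: RunConfig, outdir: Path, manifest: dict) -> None:
    stage = "sip"
    _require(config.fractions_path, "gradient fractions", stage)
    _log_stage(stage, event="start", path=config.fractions_path)
    profiles = read_fraction_profiles(config.fractions_path)
    by_unit: dict[str, dict[str, FractionProfile]] = {}
    for p in profiles:
        by_unit.setdefault(p.unit, {})[p.label] = p
    verdicts = []
    for unit, pair in sorted(by_unit.items()):
        if "dry" in pair and "rewetted" in pair:
            verdicts.append(
                sip.classify_incorporation(
                    pair["dry"],
                    pair["rewetted"],
                    width=config.peak_width_fractions,
                    min_shift=config.min_shift,
                ).to_dict()
            )
    if not verdicts:
        raise PipelineError(stage, "no dry/rewetted gradient pairs found")
    pd.DataFrame(verdicts).to_csv(outdir / "sip_verdicts.tsv", sep="\t", index=False)
    write_json(verdicts, outdir / "sip_verdicts.json")
    manifest["stages"].append(stage)
    manifest["outputs"][stage] = [str(outdir / "sip_verdicts.tsv"), str(outdir / "sip_verdicts.json")]
    _log_stage(stage, event="end", n_units=len(verdicts))


def _stage_pulse(config: RunConfig, outdir: Path, manifest: dict) -> None:
    stage = "pulse"
    _require(config.sensor_path, "sensor series", stage)
    _log_stage(stage, event="start", path=config.sensor_path, window_h=config.window_h)
    series = read_sensor_series(config.sensor_path)
    if config.window_h and len(series) > 1 and config.window_h > series.step_h:
        series = aggregate(series, config.window_h)
    results = PulseModel(series).fit(correction=config.correction)
    write_json(results.to_dict(), outdir / "pulse_fit.json")
    results.predict().to_csv(outdir / "pulse_predictions.tsv", sep="\t", index=False)
    manifest["stages"].append(stage)
    manifest["outputs"][stage] = [
        str(outdir / "pulse_fit.json"),
        str(outdir / "pulse_predictions.tsv"),
    ]
    _log_stage(stage, event="end", n_obs=results.n_obs, rsquared=round(results.rsquared, 4))


def _stage_gas(config: RunConfig, outdir: Path, manifest: dict) -> None:
    stage = "gas"
    _require(config.gas_path, "gas time courses", stage)
    _log_stage(stage, event="start", path=config.gas_path)
    courses = read_gas_timecourses(
        config.gas_path,
        soil_g=config.soil_g,
        headspace_mL=config.headspace_mL,
        temp_C=config.temp_C,
        pressure_atm=config.pressure_atm,
    )
    prods = [
        tracegas.net_production(tc, sampling_correction_mL=config.sampling_correction_mL)
        for tc in courses
    ]
    table = tracegas.net_production_table(prods)
    table.to_csv(outdir / "net_production.tsv", sep="\t", index=False)
    anova_results = {}
    for species, sub in table.groupby("species"):
        if sub["treatment"].nunique() < 2 or sub["ecosystem"].nunique() < 2:
            continue
        tab = tracegas.two_way_anova(
            sub["net_production_ug_per_g"], sub["ecosystem"], sub["treatment"]
        )
        anova_results[species] = {
            term: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            for term, row in tab.iterrows()
        }
    write_json(anova_results, outdir / "gas_anova.json")
    manifest["stages"].append(stage)
    manifest["outputs"][stage] = [str(outdir / "net_production.tsv"), str(outdir / "gas_anova.json")]
    _log_stage(stage, event="end", n_vials=len(prods))


def _load_table(config: RunConfig, stage: str) -> OtuTable:
    _require(config.counts_path, "OTU counts", stage)
    _require(config.metadata_path, "sample metadata", stage)
    return read_otu_table(config.counts_path, config.metadata_path, config.taxonomy_path)


def _stage_community(config: RunConfig, outdir: Path, manifest: dict) -> OtuTable:
    stage = "community"
    table = _load_table(config, stage)
    _log_stage(stage, event="start", n_samples=table.n_samples, n_otus=table.n_otus)
    depth = None if config.rarefy_depth in ("auto", None) else int(config.rarefy_depth)
    rarefied = community.rarefy(table, depth=depth, seed=config.seed)
    dist = community.distance_matrix(rarefied)
    write_distance_matrix(dist, outdir / "bray_curtis.tsv")
    community.richness_table(rarefied).to_csv(outdir / "richness.tsv", sep="\t")
    community.pairwise_turnover(rarefied).to_csv(outdir / "pair_turnover.tsv", sep="\t")
    perm = community.permanova_table(
        rarefied, n_perm=config.n_permutations, seed=config.seed
    )
    write_json(
        {
            term: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            for term, row in perm.iterrows()
        },
        outdir / "permanova.json",
    )
    manifest["stages"].append(stage)
    manifest["outputs"][stage] = [
        str(outdir / "bray_curtis.tsv"),
        str(outdir / "richness.tsv"),
        str(outdir / "pair_turnover.tsv"),
        str(outdir / "permanova.json"),
    ]
    _log_stage(stage, event="end")
    return table


def _stage_rare(config: RunConfig, outdir: Path, manifest: dict, table: OtuTable | None = None) -> None:
    stage = "rare"
    if table is None:
        table = _load_table(config, stage)
    _log_stage(stage, event="start", n_pairs=len(table.pair_ids()))
    pairs = [
        responders.PairedSample.from_table(table, pid, seed=config.seed)
        for pid in table.pair_ids()
    ]
    if not pairs:
        raise PipelineError(stage, "no dry/rewetted pairs in metadata")
    reports = [
        responders.RareResponderReport.from_pair(p, threshold=config.dominance_threshold)
        for p in pairs
    ]
    responders.report_table(reports).to_csv(outdir / "rare_responders.tsv", sep="\t")
    responders.summarize_by_ecosystem(reports).to_csv(outdir / "rare_by_ecosystem.tsv", sep="\t")
    shifts = []
    for p in pairs:
        df = responders.rank_shift(p)
        df.insert(0, "pair", p.pair_id)
        shifts.append(df[(df["dry_rank"].notna()) | (df["rewet_rank"].notna())])
    pd.concat(shifts).to_csv(outdir / "rank_shifts.tsv", sep="\t")
    if table.taxonomy:
        mat = responders.taxonomy_recovery_matrix(
            pairs, table.taxonomy, level=config.taxonomy_level
        )
        mat.to_csv(outdir / "taxonomy_recovery.tsv", sep="\t")
    manifest["stages"].append(stage)
    manifest["outputs"][stage] = [str(outdir / "rare_responders.tsv"), str(outdir / "rank_shifts.tsv")]
    _log_stage(stage, event="end", n_pairs=len(pairs))
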