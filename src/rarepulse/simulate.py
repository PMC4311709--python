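"""Synthetic data emulating a paired dry/rewetted soil microcosm study.

Four generators share the study's factorial design (ecosystems x watering
treatments x replicates):

* :func:`generate_paired_otu_tables` — lognormal rank-abundance communities
  with a dormant seed-bank fraction; rewetting resuscitates a random subset
  of dormant taxa, which then grow by a lognormal factor; observed counts
  are multinomial reads, so "below detection" emerges from sampling.
* :func:`generate_sensor_series` — soil moisture with exponentially decaying
  rain pulses driving soil CO2 through a lagged autoregressive response with
  AR(1) innovations (the generative inverse of the pulse regression).
* :func:`generate_fraction_profiles` — density-gradient qPCR profiles: a
  Gaussian DNA peak on a linear buoyant-density axis, centred higher for
  isotopically labelled (rewetted) than unlabelled (dry) DNA.
* :func:`generate_gas_timecourses` — headspace gas accumulation curves:
  decaying pulse increments for rewetted vials, slow drift for dry vials.

Every generator takes an explicit integer seed and is bit-reproducible.
Random streams are spawned per experimental unit from one root seed
sequence, so enlarging the design never perturbs earlier units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .otu import OtuTable
from .pulse import SensorSeries
from .sip import FractionProfile
from .tracegas import GasTimeCourse

#: Residual relative abundance of a dormant taxon: small but nonzero, so that
#: failure to detect it arises from multinomial sampling, as in real sequencing.
DORMANT_RESIDUAL = 1e-6


# ---------------------------------------------------------------------------
# experimental design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentalUnit:
    """One microcosm / sample in the factorial design."""

    ecosystem: str
    treatment: str
    replicate: int
    pair_id: str

    @property
    def unit_id(self) -> str:
        return f"{self.pair_id}_{self.treatment}"


def _treatment_labels(n_treatments: int) -> list[str]:
    base = ["dry", "rewetted"]
    if n_treatments <= 2:
        return base[:n_treatments]
    return base + [f"treatment{i}" for i in range(3, n_treatments + 1)]


def generate_design(n_ecosystems: int, n_treatments: int, n_replicates: int) -> list[ExperimentalUnit]:
    """Full factorial list of experimental units.

    Dry and rewetted units of the same (ecosystem, replicate) share a pair id,
    mirroring the paired sampling of one experimental unit before and after
    rewetting.
    """
    for name, value in (
        ("n_ecosystems", n_ecosystems),
        ("n_treatments", n_treatments),
        ("n_replicates", n_replicates),
    ):
        if not isinstance(value, (int, np.integer)) or value < 1:
            raise InvalidParameterError(f"{name} must be a positive integer, got {value!r}")
    units = []
    treatments = _treatment_labels(n_treatments)
    for e in range(1, n_ecosystems + 1):
        for r in range(1, n_replicates + 1):
            pair = f"E{e}R{r}"
            for t in treatments:
                units.append(ExperimentalUnit(ecosystem=f"E{e}", treatment=t, replicate=r, pair_id=pair))
    return units


# ---------------------------------------------------------------------------
# paired OTU tables with a dormant seed bank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedBankParams:
    """Parameters of the seed-bank community generator.

    Defaults emulate the study design: 4 ecosystems x 3 replicate paired
    units, a soil community with a long lognormal tail, a large dormant
    fraction, and strong multiplicative growth of resuscitated taxa (fast
    growers that come to dominate the rewetted community).
    """

    n_taxa: int = 2000
    lognormal_mean: float = 0.0
    lognormal_sd: float = 2.0
    dormant_fraction: float = 0.7
    resuscitation_prob: float = 0.5
    growth_log_mean: float = math.log(2.0e6)
    growth_log_sd: float = 1.0
    seq_depth: int = 1500
    n_ecosystems: int = 4
    n_replicates: int = 3
    ecosystem_effect_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise InvalidParameterError("n_taxa must be >= 2")
        if self.seq_depth < 1:
            raise InvalidParameterError("seq_depth must be >= 1")
        for name in ("dormant_fraction", "resuscitation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if self.lognormal_sd < 0 or self.growth_log_sd < 0 or self.ecosystem_effect_sd < 0:
            raise InvalidParameterError("standard deviations must be nonnegative")
        if self.n_ecosystems < 1 or self.n_replicates < 1:
            raise InvalidParameterError("design dimensions must be positive")


@dataclass
class GroundTruth:
    """Latent state of the simulated communities, for classifier evaluation.

    Attributes
    ----------
    dormant
        OTU ids that were dormant (suppressed) in every dry sample.
    resuscitated
        Per pair id: the set of dormant OTU ids that resuscitated and grew
        in that unit's rewetted sample.
    true_abundances
        Relative abundances before multinomial read sampling
        (samples x OTUs, rows sum to 1).
    """

    dormant: set[str]
    resuscitated: dict[str, set[str]]
    true_abundances: pd.DataFrame = field(repr=False, default=None)


def generate_paired_otu_tables(params: SeedBankParams) -> tuple[OtuTable, GroundTruth]:
    """Simulate paired dry/rewetted OTU count tables with known ground truth."""
    params.validate()
    n = params.n_taxa
    otu_ids = [f"OTU{i + 1:05d}" for i in range(n)]

    root_seq = np.random.SeedSequence(params.seed)
    root = np.random.default_rng(root_seq)

    baseline = root.lognormal(params.lognormal_mean, params.lognormal_sd, size=n)
    n_dormant = int(round(params.dormant_fraction * n))
    dormant_idx = root.choice(n, size=n_dormant, replace=False)
    dormant_mask = np.zeros(n, dtype=bool)
    dormant_mask[dormant_idx] = True
    eco_effects = root.lognormal(0.0, params.ecosystem_effect_sd, size=(params.n_ecosystems, n))

    design = generate_design(params.n_ecosystems, 2, params.n_replicates)
    pairs = list(dict.fromkeys(u.pair_id for u in design))

    counts = {}
    truth_res: dict[str, set[str]] = {}
    true_rows = {}
    for pair in pairs:
        eco = int(pair[1:pair.index("R")]) - 1
        rep = int(pair[pair.index("R") + 1 :]) - 1
        # stream keyed by pair identity: enlarging the design never perturbs
        # the draws of existing pairs
        rng = np.random.default_rng(
            np.random.SeedSequence(params.seed, spawn_key=(eco, rep))
        )

        dry_true = baseline * eco_effects[eco]
        dry_true = np.where(dormant_mask, dry_true * DORMANT_RESIDUAL, dry_true)

        resusc_mask = dormant_mask & (rng.random(n) < params.resuscitation_prob)
        growth = rng.lognormal(params.growth_log_mean, params.growth_log_sd, size=n)
        rewet_true = np.where(resusc_mask, dry_true * growth, dry_true)

        dry_p = dry_true / dry_true.sum()
        wet_p = rewet_true / rewet_true.sum()
        counts[f"{pair}_dry"] = rng.multinomial(params.seq_depth, dry_p)
        counts[f"{pair}_rewetted"] = rng.multinomial(params.seq_depth, wet_p)
        true_rows[f"{pair}_dry"] = dry_p
        true_rows[f"{pair}_rewetted"] = wet_p
        truth_res[pair] = {otu_ids[i] for i in np.flatnonzero(resusc_mask)}

    count_df = pd.DataFrame.from_dict(counts, orient="index", dtype=np.int64)
    count_df.columns = otu_ids
    meta = pd.DataFrame(
        [
            {
                "ecosystem": u.ecosystem,
                "treatment": u.treatment,
                "replicate": u.replicate,
                "pair": u.pair_id,
            }
            for u in design
        ],
        index=[u.unit_id for u in design],
    )
    table = OtuTable(counts=count_df.loc[meta.index], metadata=meta, taxonomy={})
    truth = GroundTruth(
        dormant={otu_ids[i] for i in dormant_idx},
        resuscitated=truth_res,
        true_abundances=pd.DataFrame.from_dict(true_rows, orient="index").set_axis(otu_ids, axis=1).loc[meta.index],
    )
    return table, truth


def assign_random_taxonomy(
    otu_ids,
    seed: int = 0,
    phyla: dict[str, float] | None = None,
) -> dict[str, str]:
    """Random but reproducible lineages ``Phylum;Class;Order;Family``.

    The default phylum frequencies loosely follow common soil communities
    (Proteobacteria-dominated); within Proteobacteria, classes are the alpha,
    beta, and gamma subdivisions with family names drawn from the fast-growing
    copiotroph families prominent in rewetting responses.
    """
    if phyla is None:
        phyla = {
            "Proteobacteria": 0.45,
            "Actinobacteria": 0.2,
            "Acidobacteria": 0.15,
            "Bacteroidetes": 0.1,
            "Gemmatimonadetes": 0.05,
            "Firmicutes": 0.05,
        }
    families = {
        "Alphaproteobacteria": ["Sphingomonadaceae", "Methylocystaceae", "Rhizobiaceae"],
        "Betaproteobacteria": ["Comamonadaceae", "Oxalobacteraceae", "Burkholderiaceae"],
        "Gammaproteobacteria": ["Pseudomonadaceae", "Xanthomonadaceae"],
    }
    rng = np.random.default_rng(seed)
    names = list(phyla)
    probs = np.array([phyla[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    out = {}
    for otu in otu_ids:
        phylum = names[rng.choice(len(names), p=probs)]
        if phylum == "Proteobacteria":
            cls = list(families)[rng.choice(3, p=[0.4, 0.4, 0.2])]
            fams = families[cls]
            fam = fams[rng.integers(len(fams))]
            order = fam.replace("aceae", "ales")
        else:
            cls = f"{phylum}_cl"
            order = f"{phylum}_or"
            fam = f"{phylum}_fam{rng.integers(1, 4)}"
        out[otu] = f"{phylum};{cls};{order};{fam}"
    return out


# ---------------------------------------------------------------------------
# field sensor series (moisture pulses driving CO2)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorSimParams:
    """Generative parameters of the moisture -> CO2 pulse process.

    Defaults emulate a 17-day field manipulation sampled every 30 min with
    three simulated rain events (days 4, 7 and 14) that raise volumetric
    moisture ~2.5-fold above its dry baseline; CO2 follows the lagged linear
    response with positive current-moisture and negative lagged-moisture
    coefficients and AR(1) residuals.
    """

    duration_h: float = 408.0
    step_h: float = 0.5
    rain_times_h: tuple[float, ...] = (96.0, 168.0, 336.0)
    rain_magnitude: float = 0.12
    decay_rate: float = 0.02
    moisture_baseline: float = 0.08
    beta_lag_co2: float = 0.6
    beta_moist: float = 23292.0
    beta_moist_lag: float = -3949.0
    intercept: float = 400.0
    noise_sd: float = 50.0
    ar_rho: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.duration_h <= 0 or self.step_h <= 0:
            raise InvalidParameterError("duration_h and step_h must be positive")
        n = self.duration_h / self.step_h
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError("step_h must divide duration_h")
        if not abs(self.ar_rho) < 1:
            raise InvalidParameterError("ar_rho must satisfy |rho| < 1")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be nonnegative")
        for rt in self.rain_times_h:
            if not 0 <= rt <= self.duration_h:
                raise InvalidParameterError(f"rain time {rt} outside [0, {self.duration_h}]")


def generate_sensor_series(params: SensorSimParams) -> tuple[SensorSeries, dict[str, float]]:
    """Simulate a sensor series; returns the series and the true coefficients."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_h / params.step_h))
    t = np.arange(n) * params.step_h

    moisture = np.full(n, params.moisture_baseline, dtype=float)
    for rt in params.rain_times_h:
        after = t >= rt
        moisture[after] += params.rain_magnitude * np.exp(-params.decay_rate * (t[after] - rt))

    co2 = np.empty(n)
    m0 = moisture[0]
    co2[0] = (params.intercept + (params.beta_moist + params.beta_moist_lag) * m0) / (
        1.0 - params.beta_lag_co2
    )
    eps = 0.0
    for i in range(1, n):
        eps = params.ar_rho * eps + rng.normal(0.0, params.noise_sd)
        co2[i] = (
            params.intercept
            + params.beta_lag_co2 * co2[i - 1]
            + params.beta_moist * moisture[i]
            + params.beta_moist_lag * moisture[i - 1]
            + eps
        )

    temperature = 20.0 + 5.0 * np.sin(2 * np.pi * t / 24.0)
    series = SensorSeries(time_h=t, moisture=moisture, co2=co2, temperature=temperature)
    coefficients = {
        "intercept": params.intercept,
        "co2_lag": params.beta_lag_co2,
        "moisture": params.beta_moist,
        "moisture_lag": params.beta_moist_lag,
        "ar_rho": params.ar_rho,
    }
    return series, coefficients


# ---------------------------------------------------------------------------
# density gradient fraction profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientSimParams:
    """Parameters of the CsTFA density-gradient qPCR profile generator.

    The density axis is linear in fraction number from ``density_top``
    (fraction 1, bottom of the tube, densest) down to ``density_bottom``
    (fraction 20). The defaults place the unlabelled DNA peak at
    1.5395 g/mL — so the densest 2-fraction window straddles fractions
    12-13 at 1.531-1.548 g/mL — and the labelled peak at 1.5795 g/mL
    (fractions 9-10), reproducing the characteristic ~0.03-0.05 g/mL
    buoyant-density increase of heavy-oxygen-labelled DNA.
    """

    n_fractions: int = 20
    fraction_volume_uL: float = 235.0
    density_top: float = 1.5795 + 8.5 / 75.0
    density_bottom: float = 1.5795 + 8.5 / 75.0 - 19.0 / 75.0
    peak_density_unlabeled: float = 1.5395
    peak_density_labeled: float = 1.5795
    peak_width: float = 0.02
    peak_copies: float = 1.0e7
    noise_cv: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_fractions < 2:
            raise InvalidParameterError("n_fractions must be >= 2")
        if self.fraction_volume_uL <= 0:
            raise InvalidParameterError("fraction_volume_uL must be positive")
        if self.density_top == self.density_bottom:
            raise InvalidParameterError("density axis must be strictly monotone")
        if self.peak_width <= 0:
            raise InvalidParameterError("peak_width must be positive")
        if self.peak_copies < 0:
            raise InvalidParameterError("peak_copies must be nonnegative")
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be nonnegative")
        if self.peak_density_labeled <= self.peak_density_unlabeled:
            raise InvalidParameterError("labelled peak must be denser than unlabelled peak")

    @property
    def gradient_volume_mL(self) -> float:
        """Total fractionated volume (n_fractions x fraction volume), in mL."""
        return self.n_fractions * self.fraction_volume_uL / 1000.0


def generate_fraction_profiles(
    params: GradientSimParams, labeled: bool, unit: str = "unit1", seed: int | None = None
) -> FractionProfile:
    """Simulate one gradient's qPCR-across-fractions profile.

    ``labeled=True`` emulates the rewetted (heavy-water incubated) gradient,
    ``labeled=False`` the dry control.
    """
    params.validate()
    center = params.peak_density_labeled if labeled else params.peak_density_unlabeled
    density = np.linspace(params.density_top, params.density_bottom, params.n_fractions)
    lo, hi = min(density[0], density[-1]), max(density[0], density[-1])
    if not lo <= center <= hi:
        raise InvalidParameterError(
            f"peak density {center} outside gradient axis [{lo}, {hi}]"
        )
    copies = params.peak_copies * np.exp(-((density - center) ** 2) / (2 * params.peak_width**2))
    if params.noise_cv > 0:
        rng = np.random.default_rng(params.seed if seed is None else seed)
        sigma = math.sqrt(math.log(1 + params.noise_cv**2))
        copies = copies * rng.lognormal(-sigma**2 / 2, sigma, size=copies.shape)
    return FractionProfile(
        index=np.arange(1, params.n_fractions + 1),
        density=density,
        copies=copies,
        label="rewetted" if labeled else "dry",
        unit=unit,
    )


# ---------------------------------------------------------------------------
# headspace gas time courses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GasSimParams:
    """Parameters of the microcosm headspace gas generator.

    Defaults emulate sealed 40 mL vials with 3 g soil incubated 96 h and
    sampled every 12 h (8 increments). Rewetted vials receive a decaying
    pulse of concentration increments; dry vials only a slow drift. The
    default CO2 amplitude/drift pair gives roughly a 20-fold rewetted:dry
    net-production ratio, the top of the range the microcosms showed.
    """

    n_increments: int = 8
    step_h: float = 12.0
    baseline_ppmv: float = 400.0
    pulse_amplitude_ppmv: float = 2500.0
    pulse_decay: float = 0.03
    dry_drift_ppmv: float = 50.0
    noise_sd: float = 0.0
    headspace_mL: float = 37.7
    soil_g: float = 3.0
    temp_C: float = 25.0
    pressure_atm: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_increments < 1:
            raise InvalidParameterError("n_increments must be >= 1")
        if self.step_h <= 0:
            raise InvalidParameterError("step_h must be positive")
        for name in ("headspace_mL", "soil_g", "pressure_atm"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be nonnegative")


def generate_gas_timecourses(
    params: GasSimParams,
    design: list[ExperimentalUnit],
    species: str = "CO2",
) -> list[GasTimeCourse]:
    """Simulate headspace concentration time courses for every design unit.

    Rewetted units accumulate ``pulse_amplitude_ppmv * exp(-pulse_decay * t)``
    per sampling interval (evaluated at the interval start); dry units drift
    by ``dry_drift_ppmv`` per interval. Negative amplitudes model net
    consumption (e.g. methane uptake in rewetted soils). Concentrations are
    clipped at zero.
    """
    params.validate()
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(len(design))
    times = np.arange(params.n_increments + 1) * params.step_h
    out = []
    for unit, child in zip(design, children):
        rng = np.random.default_rng(child)
        conc = np.empty(params.n_increments + 1)
        conc[0] = params.baseline_ppmv
        for k in range(1, params.n_increments + 1):
            if unit.treatment == "rewetted":
                inc = params.pulse_amplitude_ppmv * math.exp(-params.pulse_decay * times[k - 1])
            else:
                inc = params.dry_drift_ppmv
            if params.noise_sd > 0:
                inc += rng.normal(0.0, params.noise_sd)
            conc[k] = max(conc[k - 1] + inc, 0.0)
        out.append(
            GasTimeCourse(
                unit=unit.unit_id,
                ecosystem=unit.ecosystem,
                treatment=unit.treatment,
                species=species,
                times_h=times,
                conc_ppmv=conc,
                soil_g=params.soil_g,
                headspace_mL=params.headspace_mL,
                temp_C=params.temp_C,
                pressure_atm=params.pressure_atm,
            )
        )
    return out


def default_gas_params_for_species(species: str, seed: int = 0) -> GasSimParams:
    """Per-species defaults: CO2 pulse, CH4 net consumption, N2O small pulse."""
    base = GasSimParams(seed=seed)
    if species == "CO2":
        return base
    if species == "CH4":
        return replace(base, baseline_ppmv=10.0, pulse_amplitude_ppmv=-1.0, dry_drift_ppmv=0.5, pulse_decay=0.01)
    if species == "N2O":
        return replace(base, baseline_ppmv=0.33, pulse_amplitude_ppmv=2.0, dry_drift_ppmv=0.05, pulse_decay=0.02)
    raise InvalidParameterError(f"unknown species {species!r}")
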