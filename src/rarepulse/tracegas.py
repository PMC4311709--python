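"""Headspace trace-gas budgets for sealed soil microcosms.

Concentration time courses (ppmv of CO2, CH4 or N2O in the vial headspace,
sampled every 12 h over a 96-h incubation) are converted, via the ideal gas
law, to micrograms of element (C or N) and summed interval-by-interval into
a signed net production per gram of dry soil. Negative values indicate net
consumption (e.g. methane uptake). Treatment and ecosystem effects on net
production are tested with a balanced two-way fixed-effects ANOVA and
Tukey's HSD, including the compact letter display used in figures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import (
    InvalidParameterError,
    UndefinedRatioError,
    UnsupportedDesignError,
)

#: Ideal gas constant, L atm / (mol K).
R_L_ATM = 0.0820574

#: Element accounted per gas species: (atoms of element per molecule, atomic mass g/mol).
SPECIES_ELEMENT = {
    "CO2": (1, 12.011),   # C
    "CH4": (1, 12.011),   # C
    "N2O": (2, 14.007),   # N
}


@dataclass
class GasTimeCourse:
    """Headspace concentrations of one gas in one microcosm over time."""

    unit: str
    ecosystem: str
    treatment: str
    species: str
    times_h: np.ndarray
    conc_ppmv: np.ndarray
    soil_g: float
    headspace_mL: float
    temp_C: float
    pressure_atm: float

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_ppmv = np.asarray(self.conc_ppmv, dtype=float)
        if self.species not in SPECIES_ELEMENT:
            raise InvalidParameterError(f"unknown gas species {self.species!r}")
        if len(self.times_h) != len(self.conc_ppmv):
            raise InvalidParameterError("times and concentrations must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(self.conc_ppmv < 0):
            raise InvalidParameterError("concentrations must be nonnegative")
        if self.soil_g <= 0 or self.headspace_mL <= 0 or self.pressure_atm <= 0:
            raise InvalidParameterError("soil mass, headspace volume and pressure must be positive")


@dataclass(frozen=True)
class NetProduction:
    """Signed cumulative gas production of one vial, per gram soil."""

    unit: str
    ecosystem: str
    treatment: str
    species: str
    value: float                      # ug element / g soil
    per_interval: tuple[float, ...]   # ug element / g soil per sampling interval

    def __post_init__(self):
        if not np.isclose(self.value, sum(self.per_interval)):
            raise InvalidParameterError("value must equal the sum of per-interval increments")


def headspace_mass(
    conc_ppmv: float,
    headspace_mL: float,
    temp_C: float,
    pressure_atm: float,
    species: str,
) -> float:
    """Micrograms of element (C or N) present in the headspace at one instant.

    Ideal gas: total moles ``n = P V / (R T)``; the species contributes
    ``n * conc * 1e-6`` moles of gas, each molecule carrying one C (CO2,
    CH4) or two N (N2O) atoms.
    """
    if conc_ppmv < 0:
        raise InvalidParameterError("concentration must be nonnegative")
    if headspace_mL <= 0 or pressure_atm <= 0:
        raise InvalidParameterError("volume and pressure must be positive")
    if species not in SPECIES_ELEMENT:
        raise InvalidParameterError(f"unknown gas species {species!r}")
    atoms, mass = SPECIES_ELEMENT[species]
    temp_K = temp_C + 273.15
    if temp_K <= 0:
        raise InvalidParameterError("temperature below absolute zero")
    n_total = pressure_atm * (headspace_mL / 1000.0) / (R_L_ATM * temp_K)
    n_species = n_total * conc_ppmv * 1e-6
    return n_species * atoms * mass * 1e6  # g -> ug


def net_production(tc: GasTimeCourse, sampling_correction_mL: float = 0.0) -> NetProduction:
    """Net gas production over the incubation: summed 12-h increments / g soil.

    Each interval's increment is the change in headspace element mass between
    consecutive samplings; increments may be negative (net consumption).

    If ``sampling_correction_mL`` > 0, the mass removed by withdrawing that
    gas volume at each earlier sampling (at the concentration then present)
    is added back, compensating the cumulative dilution of repeated
    sampling. By default no correction is applied.
    """
    if len(tc.times_h) < 2:
        raise InvalidParameterError("need at least 2 time points")
    masses = np.array(
        [
            headspace_mass(c, tc.headspace_mL, tc.temp_C, tc.pressure_atm, tc.species)
            for c in tc.conc_ppmv
        ]
    )
    increments = np.diff(masses)
    if sampling_correction_mL > 0:
        frac = sampling_correction_mL / tc.headspace_mL
        # mass withdrawn with the sample taken at the start of each interval
        removed = masses[:-1] * frac
        increments = increments + removed
    per_interval = tuple(float(x) / tc.soil_g for x in increments)
    return NetProduction(
        unit=tc.unit,
        ecosystem=tc.ecosystem,
        treatment=tc.treatment,
        species=tc.species,
        value=float(sum(per_interval)),
        per_interval=per_interval,
    )


def fold_change(rewetted: NetProduction, dry: NetProduction) -> float:
    """Ratio of rewetted to dry net production (raw signed ratio)."""
    if dry.value == 0:
        raise UndefinedRatioError(rewetted.value, dry.value)
    return rewetted.value / dry.value


def gravimetric_moisture(initial_g_per_g: float, water_mL: float, soil_g: float,
                         water_density_g_per_mL: float = 1.0) -> float:
    """Gravimetric moisture (g H2O per g dry soil) after adding water.

    E.g. field-dry soil at ~0.05 g/g receiving 0.6 mL water per 3 g soil
    reaches 0.05 + 0.6/3 = 0.25 g/g, a five-fold increase.
    """
    if soil_g <= 0:
        raise InvalidParameterError("soil mass must be positive")
    if initial_g_per_g < 0 or water_mL < 0:
        raise InvalidParameterError("moisture and water volume must be nonnegative")
    return initial_g_per_g + water_mL * water_density_g_per_mL / soil_g


# ---------------------------------------------------------------------------
# two-way ANOVA and Tukey HSD
# ---------------------------------------------------------------------------

def _check_balanced(df: pd.DataFrame) -> None:
    cells = df.groupby(["a", "b"], observed=True).size()
    n_a = df["a"].nunique()
    n_b = df["b"].nunique()
    if len(cells) != n_a * n_b:
        raise UnsupportedDesignError("design is not a complete factorial")
    if cells.nunique() != 1:
        raise UnsupportedDesignError("design is unbalanced (unequal cell sizes)")
    if cells.iloc[0] < 2:
        raise UnsupportedDesignError("need >= 2 replicates per cell")


def two_way_anova(values, factor_a, factor_b) -> pd.DataFrame:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Returns a table with rows ``A, B, A:B, Residual`` and columns
    ``df, sum_sq, F, p``. Sums of squares partition exactly:
    ``SS_A + SS_B + SS_AB + SS_res = SS_total``. If the residual variance is
    exactly zero while an effect is nonzero, its F is reported as ``inf``
    with p = 0.
    """
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "a": list(factor_a), "b": list(factor_b)}
    )
    if len(df) == 0:
        raise InvalidParameterError("empty data")
    _check_balanced(df)
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    out = tab.rename(
        index={"C(a)": "A", "C(b)": "B", "C(a):C(b)": "A:B"},
        columns={"PR(>F)": "p"},
    )[["df", "sum_sq", "F", "p"]]
    ss_res = out.loc["Residual", "sum_sq"]
    ss_total = out["sum_sq"].sum()
    if ss_total > 0 and ss_res <= 1e-12 * ss_total:
        for term in ("A", "B", "A:B"):
            if out.loc[term, "sum_sq"] > 0:
                out.loc[term, "F"] = np.inf
                out.loc[term, "p"] = 0.0
    return out


def _letter_display(groups: list[str], means: dict[str, float], ns_pairs: set[frozenset]) -> dict[str, str]:
    """Compact letter display by a sweep over mean-ordered groups.

    Groups sorted by ascending mean; every maximal run of consecutive groups
    that are pairwise non-significant receives one letter (the greedy clique
    cover of the non-significance graph, valid because Tukey significance
    with equal cell sizes depends only on the mean difference).
    """
    order = sorted(groups, key=lambda g: (means[g], g))
    n = len(order)
    runs = []
    for i in range(n):
        j = i
        while j + 1 < n and all(
            frozenset((order[k], order[j + 1])) in ns_pairs for k in range(i, j + 1)
        ):
            j += 1
        runs.append((i, j))
    # drop runs contained in another run
    maximal = [r for r in runs if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    letters = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (lo, hi) in enumerate(sorted(maximal)):
        for g in order[lo : hi + 1]:
            letters[g] += alphabet[idx % len(alphabet)]
    return letters


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons among group (cell) means.

    Returns one row per group with its mean and compact letter display:
    groups sharing a letter are not significantly different at ``alpha``.
    Pairwise results are attached as the ``pairwise`` attribute
    (DataFrame: group1, group2, meandiff, p_adj, reject).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise InvalidParameterError("need at least two groups")
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pairwise = pd.DataFrame(
        res.summary().data[1:], columns=[c.strip() for c in res.summary().data[0]]
    )
    pair_labels = list(itertools.combinations(res.groupsunique, 2))
    ns_pairs = {
        frozenset(pair) for pair, rej in zip(pair_labels, res.reject) if not rej
    }
    means = {g: float(values[groups == g].mean()) for g in labels}
    letters = _letter_display(labels, means, ns_pairs)
    out = pd.DataFrame(
        {
            "group": labels,
            "mean": [means[g] for g in labels],
            "letters": [letters[g] for g in labels],
        }
    ).set_index("group")
    out.attrs["pairwise"] = pairwise
    return out


def net_production_table(productions: list[NetProduction]) -> pd.DataFrame:
    """Tidy table of net productions (one row per vial)."""
    return pd.DataFrame(
        [
            {
                "unit": p.unit,
                "ecosystem": p.ecosystem,
                "treatment": p.treatment,
                "species": p.species,
                "net_production_ug_per_g": p.value,
            }
            for p in productions
        ]
    )
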