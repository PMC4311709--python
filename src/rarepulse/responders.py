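"""Rare-responder analysis of paired dry/rewetted communities.

A *rare responder* is an OTU below the detection limit (rarefied count of
zero) in the dry sample of an experimental unit but recovered in the same
unit's rewetted sample. Both samples of a pair are rarefied to their common
minimum depth first, so detection effort is equal. The module partitions
the detected OTU universe into shared / dry-only / rewetted-only sets,
computes the responders' share of taxa and of sequences, the
singleton/doubleton makeup of the shared pool, rank-abundance shifts,
dominant responders (those reaching at least 1% relative recovery after
rewetting), and a taxon-group x ecosystem matrix of responder recovery.

Note the statistic has a nonzero null floor: even with identical dry and
rewetted communities, finite sequencing depth misses some taxa in one
sample and catches them in the other, so a fraction of "responders" arises
from resampling alone. :func:`expected_null_rare_otu_fraction` computes
this floor analytically for a known abundance profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import rarefy_counts
from .exceptions import InvalidParameterError, UndefinedFractionError
from .otu import OtuTable, lineage_level


@dataclass
class PairedSample:
    """The dry and rewetted count vectors of one experimental unit."""

    pair_id: str
    ecosystem: str
    otu_ids: list[str]
    dry: np.ndarray
    rewetted: np.ndarray

    def __post_init__(self):
        self.dry = np.asarray(self.dry, dtype=np.int64)
        self.rewetted = np.asarray(self.rewetted, dtype=np.int64)
        if not (len(self.otu_ids) == len(self.dry) == len(self.rewetted)):
            raise InvalidParameterError("paired vectors must share the OTU universe")
        if (self.dry < 0).any() or (self.rewetted < 0).any():
            raise InvalidParameterError("counts must be nonnegative")

    @classmethod
    def from_table(
        cls, table: OtuTable, pair_id: str, rarefy_to_min: bool = True, seed: int = 0
    ) -> "PairedSample":
        """Extract a pair from a table, rarefying both samples to their common
        minimum depth (equal detection effort) unless disabled."""
        dry_id, wet_id = table.samples_for_pair(pair_id)
        dry = table.counts.loc[dry_id].to_numpy()
        wet = table.counts.loc[wet_id].to_numpy()
        if rarefy_to_min:
            depth = int(min(dry.sum(), wet.sum()))
            rng = np.random.default_rng(seed)
            dry = rarefy_counts(dry, depth, rng)
            wet = rarefy_counts(wet, depth, rng)
        return cls(
            pair_id=pair_id,
            ecosystem=str(table.metadata.loc[dry_id, "ecosystem"]),
            otu_ids=table.otu_ids,
            dry=dry,
            rewetted=wet,
        )


def partition_shared(pair: PairedSample) -> tuple[set[str], set[str], set[str]]:
    """Disjoint partition of the detected OTU universe.

    Returns ``(shared, dry_only, rewet_only)``; ``rewet_only`` is the
    rare-responder set.
    """
    ids = np.asarray(pair.otu_ids)
    in_dry = pair.dry > 0
    in_wet = pair.rewetted > 0
    shared = set(ids[in_dry & in_wet])
    dry_only = set(ids[in_dry & ~in_wet])
    rewet_only = set(ids[~in_dry & in_wet])
    return shared, dry_only, rewet_only


def rare_fractions(pair: PairedSample) -> tuple[float, float]:
    """Responders' share of rewetted taxa and of rewetted sequences.

    ``rare_otu_fraction`` = |rewetted-only OTUs| / |OTUs detected in the
    rewetted sample|; ``rare_seq_fraction`` = fraction of rewetted reads
    belonging to rewetted-only OTUs.
    """
    total_wet = int(pair.rewetted.sum())
    if total_wet == 0:
        raise UndefinedFractionError("rewetted sample has no reads")
    in_wet = pair.rewetted > 0
    responder = in_wet & (pair.dry == 0)
    rare_otu_fraction = float(responder.sum() / in_wet.sum())
    rare_seq_fraction = float(pair.rewetted[responder].sum() / total_wet)
    return rare_otu_fraction, rare_seq_fraction


def singleton_doubleton_fraction(pair: PairedSample) -> float:
    """Fraction of shared OTUs represented by <= 2 reads in the dry sample."""
    shared_mask = (pair.dry > 0) & (pair.rewetted > 0)
    n_shared = int(shared_mask.sum())
    if n_shared == 0:
        raise UndefinedFractionError("no shared OTUs between dry and rewetted sample")
    low = int((shared_mask & (pair.dry <= 2)).sum())
    return low / n_shared


def _ranks(counts: np.ndarray, otu_ids) -> np.ndarray:
    """Descending-count ranks among detected OTUs (1 = most abundant);
    ties broken by ascending OTU id; undetected OTUs get NaN."""
    ranks = np.full(len(counts), np.nan)
    detected = np.flatnonzero(counts > 0)
    order = sorted(detected, key=lambda i: (-counts[i], otu_ids[i]))
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def rank_shift(pair: PairedSample) -> pd.DataFrame:
    """Rank-abundance positions of every OTU before and after rewetting.

    Returns a DataFrame indexed by OTU with columns ``dry_rank,
    rewet_rank`` (NaN = below detection) and the relative recoveries
    ``dry_recovery, rewet_recovery``. Within each sample the ranks of
    detected OTUs form a permutation of 1..n_detected.
    """
    dry_total = pair.dry.sum()
    wet_total = pair.rewetted.sum()
    return pd.DataFrame(
        {
            "dry_rank": _ranks(pair.dry, pair.otu_ids),
            "rewet_rank": _ranks(pair.rewetted, pair.otu_ids),
            "dry_recovery": pair.dry / dry_total if dry_total else np.zeros(len(pair.dry)),
            "rewet_recovery": pair.rewetted / wet_total if wet_total else np.zeros(len(pair.rewetted)),
        },
        index=pd.Index(pair.otu_ids, name="otu_id"),
    )


def dominant_responders(pair: PairedSample, threshold: float = 0.01) -> pd.DataFrame:
    """Rare responders reaching at least ``threshold`` relative recovery.

    The threshold is inclusive (default 1% recovery). Returns a DataFrame
    indexed by OTU with ``recovery`` and ``rewet_rank``, sorted by rank.
    """
    if not 0 < threshold <= 1:
        raise InvalidParameterError("threshold must be in (0, 1]")
    total_wet = pair.rewetted.sum()
    if total_wet == 0:
        raise UndefinedFractionError("rewetted sample has no reads")
    responder = (pair.dry == 0) & (pair.rewetted > 0)
    recovery = pair.rewetted / total_wet
    keep = responder & (recovery >= threshold)
    ranks = _ranks(pair.rewetted, pair.otu_ids)
    ids = np.asarray(pair.otu_ids)
    out = pd.DataFrame(
        {
            "recovery": recovery[keep],
            "rewet_rank": ranks[keep],
        },
        index=pd.Index(ids[keep], name="otu_id"),
    )
    return out.sort_values("rewet_rank")


@dataclass(frozen=True)
class RareResponderReport:
    """Per-unit summary of the rare-responder analysis."""

    pair_id: str
    ecosystem: str
    n_shared: int
    n_dry_only: int
    n_rewet_only: int
    rare_otu_fraction: float
    rare_seq_fraction: float
    singleton_doubleton_fraction: float
    n_dominant: int

    @classmethod
    def from_pair(cls, pair: PairedSample, threshold: float = 0.01) -> "RareResponderReport":
        shared, dry_only, rewet_only = partition_shared(pair)
        rof, rsf = rare_fractions(pair)
        try:
            sdf = singleton_doubleton_fraction(pair)
        except UndefinedFractionError:
            sdf = float("nan")
        dom = dominant_responders(pair, threshold=threshold)
        return cls(
            pair_id=pair.pair_id,
            ecosystem=pair.ecosystem,
            n_shared=len(shared),
            n_dry_only=len(dry_only),
            n_rewet_only=len(rewet_only),
            rare_otu_fraction=rof,
            rare_seq_fraction=rsf,
            singleton_doubleton_fraction=sdf,
            n_dominant=len(dom),
        )


def report_table(reports: list[RareResponderReport]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in reports]).set_index("pair_id")
    return df


def summarize_by_ecosystem(reports: list[RareResponderReport]) -> pd.DataFrame:
    """Mean and SEM of the per-unit fractions within each ecosystem.

    Percentages are computed per experimental unit and then averaged across
    replicates (not pooled), matching how paired designs are summarised.
    """
    df = report_table(reports)
    num = df[["rare_otu_fraction", "rare_seq_fraction", "singleton_doubleton_fraction"]]
    grouped = num.groupby(df["ecosystem"])
    mean = grouped.mean().add_suffix("_mean")
    sem = grouped.sem().add_suffix("_sem")
    return pd.concat([mean, sem], axis=1).sort_index(axis=1)


# ---------------------------------------------------------------------------
# taxonomy summaries
# ---------------------------------------------------------------------------

def taxon_composition(otu_ids, taxonomy: dict[str, str], level: str) -> pd.Series:
    """Fraction of a set of OTUs falling in each taxon group at ``level``.

    Counts OTUs (not reads); OTUs without taxonomy go to ``unclassified``.
    Used e.g. to express the family makeup of a dominant-responder set.
    """
    otu_ids = list(otu_ids)
    if not otu_ids:
        raise UndefinedFractionError("empty OTU set")
    groups = [lineage_level(taxonomy.get(o), level) for o in otu_ids]
    return pd.Series(groups).value_counts(normalize=True).sort_index()


def taxonomy_recovery_matrix(
    pairs: list[PairedSample],
    taxonomy: dict[str, str],
    level: str = "family",
    contribution_floor: float = 0.01,
) -> pd.DataFrame:
    """Taxon-group x ecosystem matrix of mean responder recovery.

    For each unit, the summed rewetted relative recovery of the
    rewetted-only (responder) OTUs is attributed to taxon groups at
    ``level``; units are averaged within ecosystems. Groups contributing
    less than ``contribution_floor`` of the grand total recovery are
    collapsed into ``other``. Row order: descending grand total.
    """
    if not pairs:
        raise InvalidParameterError("need at least one pair")
    if not 0 <= contribution_floor < 1:
        raise InvalidParameterError("contribution_floor must be in [0, 1)")
    rows = []
    for pair in pairs:
        total_wet = pair.rewetted.sum()
        if total_wet == 0:
            raise UndefinedFractionError(f"rewetted sample of {pair.pair_id} has no reads")
        responder = (pair.dry == 0) & (pair.rewetted > 0)
        rec = pair.rewetted / total_wet
        ids = np.asarray(pair.otu_ids)
        by_group: dict[str, float] = {}
        for i in np.flatnonzero(responder):
            g = lineage_level(taxonomy.get(ids[i]), level)
            by_group[g] = by_group.get(g, 0.0) + float(rec[i])
        rows.append({"ecosystem": pair.ecosystem, **by_group})
    wide = pd.DataFrame(rows).fillna(0.0)
    mat = wide.groupby("ecosystem").mean().T  # groups x ecosystems
    totals = mat.sum(axis=1)
    grand = totals.sum()
    if grand > 0:
        minor = totals[totals / grand < contribution_floor].index
        if len(minor):
            other = mat.loc[minor].sum()
            mat = mat.drop(index=minor)
            mat.loc["other"] = other
    order = mat.sum(axis=1).sort_values(ascending=False).index
    return mat.loc[order]


# ---------------------------------------------------------------------------
# classifier evaluation against simulation ground truth
# ---------------------------------------------------------------------------

def classifier_performance(pair: PairedSample, true_resuscitated: set[str]) -> dict[str, float]:
    """Sensitivity/specificity of the responder call against ground truth.

    The positive class is the set of truly resuscitated taxa of the unit;
    the predicted positives are the rewetted-only OTUs. Specificity is
    computed over the remaining OTU universe.
    """
    _, _, rewet_only = partition_shared(pair)
    universe = set(pair.otu_ids)
    truth = set(true_resuscitated) & universe
    predicted = rewet_only
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    sensitivity = tp / len(truth) if truth else float("nan")
    negatives = len(universe) - len(truth)
    specificity = tn / negatives if negatives else float("nan")
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }


def expected_null_rare_otu_fraction(
    p: np.ndarray, depth_dry: int, depth_rewetted: int
) -> float:
    """Analytic resampling floor of the rare-OTU fraction under no response.

    With dry and rewetted samples drawn independently from the same
    relative-abundance vector ``p``, an OTU is detected in a multinomial
    sample of depth ``D`` with probability ``1 - (1 - p_i)^D``. The expected
    responder fraction is then

        sum_i q_wet_i (1 - q_dry_i) / sum_i q_wet_i

    (ratio of expectations), a nonzero floor attained purely by detection
    resampling.
    """
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    q_dry = 1.0 - (1.0 - p) ** depth_dry
    q_wet = 1.0 - (1.0 - p) ** depth_rewetted
    return float(np.sum(q_wet * (1.0 - q_dry)) / np.sum(q_wet))
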