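"""OTU count table container with per-sample metadata and per-OTU taxonomy.

The table is the atom of the community analyses: an integer matrix of
``samples x OTUs`` plus the experimental-design labels (ecosystem, watering
treatment, replicate, and the pair id joining the dry and rewetted sample of
one experimental unit) and an optional taxonomy lineage per OTU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

METADATA_COLUMNS = ("ecosystem", "treatment", "replicate", "pair")

#: Lineage levels used throughout, shallowest first.
LINEAGE_LEVELS = ("phylum", "class", "order", "family")


def split_lineage(lineage: str) -> list[str]:
    """Split a semicolon-delimited lineage ``"Phylum;Class;Order;Family"``."""
    return [part.strip() for part in str(lineage).split(";")]


def lineage_level(lineage: str | None, level: str) -> str:
    """Return the named level of a lineage, or ``"unclassified"`` if absent."""
    if level not in LINEAGE_LEVELS:
        raise InvalidParameterError(
            f"unknown taxonomy level {level!r}; expected one of {LINEAGE_LEVELS}"
        )
    if lineage is None:
        return "unclassified"
    parts = split_lineage(lineage)
    idx = LINEAGE_LEVELS.index(level)
    if idx >= len(parts) or not parts[idx]:
        return "unclassified"
    return parts[idx]


@dataclass
class OtuTable:
    """Integer OTU count matrix (samples x OTUs) with design metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one column per OTU id;
        entries are nonnegative integers (reads).
    metadata
        DataFrame indexed by sample id with columns
        ``ecosystem, treatment, replicate, pair``.
    taxonomy
        Optional mapping ``otu_id -> "Phylum;Class;Order;Family"``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = self.counts.copy()
        self.metadata = self.metadata.copy()
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise InvalidParameterError("duplicate sample ids in count table")
        if self.counts.columns.has_duplicates:
            raise InvalidParameterError("duplicate OTU ids in count table")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise InvalidParameterError("OTU counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise InvalidParameterError("OTU counts must be nonnegative")
        missing = set(self.counts.index) - set(self.metadata.index)
        if missing:
            raise InvalidParameterError(f"samples missing from metadata: {sorted(missing)}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise InvalidParameterError(f"metadata missing column {col!r}")
        # keep metadata aligned to the count rows
        self.metadata = self.metadata.loc[self.counts.index]

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def pair_ids(self) -> list[str]:
        """Pair ids that have both a dry and a rewetted sample."""
        out = []
        for pair, sub in self.metadata.groupby("pair", sort=True):
            treatments = set(sub["treatment"])
            if {"dry", "rewetted"} <= treatments:
                out.append(pair)
        return out

    def samples_for_pair(self, pair_id: str) -> tuple[str, str]:
        """Return (dry sample id, rewetted sample id) for a pair."""
        sub = self.metadata[self.metadata["pair"] == pair_id]
        if sub.empty:
            raise InvalidParameterError(f"unknown pair id {pair_id!r}")
        try:
            dry = sub.index[sub["treatment"] == "dry"][0]
            wet = sub.index[sub["treatment"] == "rewetted"][0]
        except IndexError:
            raise InvalidParameterError(
                f"pair {pair_id!r} lacks a dry or rewetted sample"
            ) from None
        return dry, wet

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(
            counts=self.counts.loc[list(sample_ids)],
            metadata=self.metadata.loc[list(sample_ids)],
            taxonomy=dict(self.taxonomy),
        )
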