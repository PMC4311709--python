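"""Community-level turnover statistics: rarefaction, Bray-Curtis, PERMANOVA.

Counts are first rarefied (random subsampling without replacement) to a
common depth so that detection effort is equal across samples; richness is
then the observed number of OTUs, and compositional turnover is quantified
with Bray-Curtis dissimilarity. Treatment and ecosystem effects on the
distance matrix are tested with a two-factor crossed PERMANOVA built on the
Gower-centred inner-product matrix with sequential (Type I) sums of squares
and free permutation of samples; restricted permutation within strata
(e.g. within ecosystems, respecting the paired design) is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .exceptions import (
    DegenerateFactorError,
    InsufficientDepthError,
    InvalidParameterError,
    UndefinedDistanceError,
)
from .otu import OtuTable


# ---------------------------------------------------------------------------
# rarefaction and richness
# ---------------------------------------------------------------------------

def rarefy_counts(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample one count vector without replacement to exactly ``depth`` reads."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if depth > total:
        raise InsufficientDepthError("<vector>", total, depth)
    if depth == total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Rarefy every sample of a table to a common depth.

    ``depth=None`` uses the minimum sample total (the default policy when
    the study's own depth is unknown). Deterministic under ``seed``.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise InvalidParameterError("rarefaction depth must be >= 1")
    offenders = totals[totals < depth]
    if len(offenders):
        sample = offenders.index[0]
        raise InsufficientDepthError(sample, int(offenders.iloc[0]), depth)
    rng = np.random.default_rng(seed)
    new = table.counts.copy()
    for sample_id in table.sample_ids:
        new.loc[sample_id] = rarefy_counts(table.counts.loc[sample_id].to_numpy(), depth, rng)
    return OtuTable(counts=new, metadata=table.metadata, taxonomy=dict(table.taxonomy))


def observed_richness(counts) -> int:
    """Observed number of OTUs: entries with count > 0."""
    return int(np.count_nonzero(np.asarray(counts) > 0))


def richness_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample observed richness with design labels."""
    rows = []
    for sample_id in table.sample_ids:
        rows.append(
            {
                "sample": sample_id,
                "richness": observed_richness(table.counts.loc[sample_id]),
                **table.metadata.loc[sample_id, ["ecosystem", "treatment", "replicate", "pair"]].to_dict(),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: ``1 - 2 sum(min(x, y)) / (sum(x) + sum(y))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("count vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise InvalidParameterError("counts must be nonnegative")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise UndefinedDistanceError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def distance_matrix(table: OtuTable) -> DistanceMatrix:
    """All pairwise Bray-Curtis dissimilarities as a scikit-bio DistanceMatrix."""
    if table.n_samples < 2:
        raise InvalidParameterError("need at least 2 samples")
    counts = table.counts.to_numpy(dtype=float)
    n = counts.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = bray_curtis(counts[i], counts[j])
    return DistanceMatrix(mat, ids=table.sample_ids)


def pairwise_turnover(table: OtuTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between the dry and rewetted sample of each pair."""
    rows = []
    for pair in table.pair_ids():
        dry_id, wet_id = table.samples_for_pair(pair)
        rows.append(
            {
                "pair": pair,
                "ecosystem": table.metadata.loc[dry_id, "ecosystem"],
                "bray_curtis": bray_curtis(
                    table.counts.loc[dry_id], table.counts.loc[wet_id]
                ),
            }
        )
    return pd.DataFrame(rows).set_index("pair")


# ---------------------------------------------------------------------------
# two-factor PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(dist: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G = -1/2 J D^2 J."""
    a = -0.5 * dist**2
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _hat(X: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the column space of X.

    Uses the pseudoinverse: dummy-coded designs are rank deficient, where
    plain QR would pick up spurious directions.
    """
    return X @ np.linalg.pinv(X)


def _dummies(labels: np.ndarray) -> np.ndarray:
    return pd.get_dummies(pd.Series(labels)).to_numpy(dtype=float)


def permanova(
    dist: DistanceMatrix,
    factor_a,
    factor_b,
    n_perm: int = 999,
    seed: int = 0,
    strata=None,
) -> pd.DataFrame:
    """Two-factor crossed PERMANOVA with sequential (Type I) sums of squares.

    Squared distances are partitioned via the Gower-centred matrix; terms
    are entered in the order A, B, A x B (enter the blocking-like factor,
    e.g. ecosystem, as A). The pseudo-F of each term uses the full-model
    residual. Significance comes from ``n_perm`` free permutations of the
    samples (rows of the distance matrix); with ``strata`` given, samples
    are permuted only within each stratum. p-values use the standard
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` estimator.

    Returns a table with rows ``A, B, A:B, Residual, Total`` and columns
    ``df, SS, pseudo_F, p``.
    """
    a = np.asarray([str(v) for v in factor_a])
    b = np.asarray([str(v) for v in factor_b])
    d = np.asarray(dist.data if hasattr(dist, "data") else dist, dtype=float)
    n = d.shape[0]
    if len(a) != n or len(b) != n:
        raise InvalidParameterError("factor labels must align with the distance matrix")
    if n_perm < 99:
        raise InvalidParameterError("n_perm must be >= 99")
    levels_a = np.unique(a)
    levels_b = np.unique(b)
    if len(levels_a) < 2:
        raise DegenerateFactorError("factor A has a single level")
    if len(levels_b) < 2:
        raise DegenerateFactorError("factor B has a single level")

    cell = pd.Series(list(zip(a, b)))
    ones = np.ones((n, 1))
    X1 = np.hstack([ones, _dummies(a)])
    X2 = np.hstack([X1, _dummies(b)])
    X3 = np.hstack([ones, pd.get_dummies(cell).to_numpy(dtype=float)])

    H0 = _hat(ones)
    H1 = _hat(X1)
    H2 = _hat(X2)
    H3 = _hat(X3)

    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b
    df_res = n - cell.nunique()
    if df_res <= 0:
        raise InvalidParameterError("no residual degrees of freedom (need replication)")

    G = _gower_center(d)

    def terms(Gp: np.ndarray) -> tuple[float, float, float, float]:
        t0 = float(np.sum(H0 * Gp))  # == tr(H0 G), H symmetric
        t1 = float(np.sum(H1 * Gp))
        t2 = float(np.sum(H2 * Gp))
        t3 = float(np.sum(H3 * Gp))
        total = float(np.trace(Gp))
        ss_a = t1 - t0
        ss_b = t2 - t1
        ss_ab = t3 - t2
        ss_res = total - (t3 - t0)
        return ss_a, ss_b, ss_ab, ss_res

    ss_a, ss_b, ss_ab, ss_res = terms(G)
    ms_res = ss_res / df_res

    def pseudo_f(ss, dfx, msr):
        if msr <= 0:
            return np.inf if ss > 0 else np.nan
        return (ss / dfx) / msr

    f_obs = (
        pseudo_f(ss_a, df_a, ms_res),
        pseudo_f(ss_b, df_b, ms_res),
        pseudo_f(ss_ab, df_ab, ms_res),
    )

    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray([str(s) for s in strata])
        if len(strata) != n:
            raise InvalidParameterError("strata must align with samples")
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]

    exceed = np.zeros(3)
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for idx in groups:
                perm[idx] = idx[rng.permutation(len(idx))]
        Gp = G[np.ix_(perm, perm)]
        sa, sb, sab, sr = terms(Gp)
        msr = sr / df_res
        fp = (pseudo_f(sa, df_a, msr), pseudo_f(sb, df_b, msr), pseudo_f(sab, df_ab, msr))
        for k in range(3):
            if fp[k] >= f_obs[k]:
                exceed[k] += 1

    pvals = (1.0 + exceed) / (1.0 + n_perm)
    ss_total = float(np.trace(G))
    return pd.DataFrame(
        {
            "df": [df_a, df_b, df_ab, df_res, n - 1],
            "SS": [ss_a, ss_b, ss_ab, ss_res, ss_total],
            "pseudo_F": [*f_obs, np.nan, np.nan],
            "p": [*pvals, np.nan, np.nan],
        },
        index=["A", "B", "A:B", "Residual", "Total"],
    )


def permanova_table(
    table: OtuTable,
    n_perm: int = 999,
    seed: int = 0,
    restrict_within_ecosystem: bool = False,
) -> pd.DataFrame:
    """PERMANOVA of Bray-Curtis distances on ecosystem (A) and treatment (B)."""
    dist = distance_matrix(table)
    meta = table.metadata
    return permanova(
        dist,
        meta["ecosystem"].to_numpy(),
        meta["treatment"].to_numpy(),
        n_perm=n_perm,
        seed=seed,
        strata=meta["ecosystem"].to_numpy() if restrict_within_ecosystem else None,
    )
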