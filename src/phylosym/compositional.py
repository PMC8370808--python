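"""Normalization, diversity and aggregation for count tables.

Rarefaction is without replacement (multivariate hypergeometric) and drops
sub-depth samples with an explicit report. CLR uses a unit pseudocount by
default, with the half-minimum-nonzero rule available for sensitivity
checks. Shannon diversity uses natural logs; the inverse Simpson index is
1 / sum(p^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import binomtest
from skbio import DistanceMatrix

from .io_formats import (
    RANKS,
    FeatureTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)

PSEUDOCOUNT_RULES = ("unit", "half_min_nonzero", "none")


@dataclass(frozen=True)
class ClrMatrix:
    """Centred log-ratio values, samples in rows; every row sums to zero."""

    values: pd.DataFrame
    pseudocount: float
    source: str | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError("CLR values must be finite")
        if arr.size and np.max(np.abs(arr.sum(axis=1))) > 1e-9 * max(1, arr.shape[1]):
            raise ValidationError("CLR rows must sum to zero")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class RarefactionResult:
    table: FeatureTable
    dropped: list[str]
    depth: int
    seed: int


def rarefy(table: FeatureTable, depth: int, seed: int) -> RarefactionResult:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose library size is below ``depth`` are dropped and listed in
    the result. Deterministic for a given seed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    kept = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    out = np.zeros((len(table.feature_ids), len(kept)), dtype=np.int64)
    counts = table.counts.to_numpy()
    col_of = {s: j for j, s in enumerate(table.sample_ids)}
    for j, s in enumerate(kept):
        col = counts[:, col_of[s]]
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    frame = pd.DataFrame(out, index=table.feature_ids, columns=kept)
    return RarefactionResult(FeatureTable(frame, table.kingdom_label), dropped, depth, seed)


def _pseudocount(counts: np.ndarray, rule: str) -> float:
    if rule == "unit":
        return 1.0
    if rule == "half_min_nonzero":
        nz = counts[counts > 0]
        if nz.size == 0:
            raise ValidationError("table is all zeros; cannot derive a pseudocount")
        return float(nz.min()) / 2.0
    if rule == "none":
        return 0.0
    raise ValueError(f"pseudocount_rule must be one of {PSEUDOCOUNT_RULES}, got {rule!r}")


def clr_transform(table: FeatureTable, pseudocount_rule: str = "unit") -> ClrMatrix:
    """Per-sample centred log-ratio: clr_j = ln(x_j) - mean_k ln(x_k), x = counts + delta."""
    counts = table.counts.to_numpy(dtype=float)
    if counts.size == 0:
        raise ValidationError("cannot CLR-transform an empty table")
    zero_samples = [s for s, tot in table.sample_sums().items() if tot == 0]
    if zero_samples:
        raise ValidationError(
            f"all-zero samples cannot form a composition: {', '.join(zero_samples)}"
        )
    delta = _pseudocount(counts, pseudocount_rule)
    x = counts + delta
    if np.any(x <= 0):
        bad = [table.sample_ids[j] for j in np.unique(np.argwhere(x <= 0)[:, 1])]
        raise ValidationError(
            f"zero counts with pseudocount_rule='none' in samples: {', '.join(bad)}"
        )
    logx = np.log(x)
    clr = logx - logx.mean(axis=0, keepdims=True)  # centre within each sample column
    values = pd.DataFrame(clr.T, index=table.sample_ids, columns=table.feature_ids)
    return ClrMatrix(values, delta, table.kingdom_label)


def aitchison_distance(clr: ClrMatrix) -> DistanceMatrix:
    """Euclidean distance between CLR rows (the Aitchison distance)."""
    if len(clr.sample_ids) < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    d = squareform(pdist(clr.values.to_numpy(), metric="euclidean"))
    return DistanceMatrix(d, ids=clr.sample_ids)


def lineage_key(taxonomy: TaxonomyTable, rank: str) -> pd.Series:
    """Joined kingdom..rank lineage string, one per feature.

    Using the full parent lineage keeps every "unassigned" label in its own
    bin per parent rather than pooling unrelated unassigned features.
    """
    idx = RANKS.index(rank)
    cols = list(RANKS[: idx + 1])
    return taxonomy.lineages[cols].agg("|".join, axis=1)


def agglomerate(table: FeatureTable, taxonomy: TaxonomyTable, rank: str) -> FeatureTable:
    """Sum features sharing the same lineage down to ``rank``; conserves counts."""
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    missing = [f for f in table.feature_ids if f not in taxonomy.lineages.index]
    if missing:
        raise ValidationError(f"features missing from taxonomy: {', '.join(missing)}")
    keys = lineage_key(taxonomy, rank).loc[table.feature_ids]
    grouped = table.counts.groupby(keys.to_numpy(), sort=False).sum()
    grouped.index.name = "feature_id"
    return FeatureTable(grouped, table.kingdom_label)


def agglomerate_taxonomy(taxonomy: TaxonomyTable, rank: str) -> TaxonomyTable:
    """Taxonomy for the bins produced by :func:`agglomerate` at ``rank``."""
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    idx = RANKS.index(rank)
    keys = lineage_key(taxonomy, rank)
    rows = {}
    for feature, key in keys.items():
        if key in rows:
            continue
        lineage = taxonomy.lineages.loc[feature]
        rows[key] = [lineage[r] if i <= idx else "unassigned" for i, r in enumerate(RANKS)]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    frame.index.name = "feature_id"
    return TaxonomyTable(frame)


def merge_by_species(table: FeatureTable, metadata: SampleMetadata) -> FeatureTable:
    """Sum sample columns within each host species (one column per species)."""
    missing = [s for s in table.sample_ids if s not in metadata.frame.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {', '.join(missing)}")
    species = metadata.species_of(table.sample_ids)
    merged = table.counts.T.groupby(species.to_numpy(), sort=False).sum().T
    return FeatureTable(merged, table.kingdom_label)


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Observed richness, Shannon (natural log) and inverse Simpson per sample."""
    totals = table.sample_sums()
    empty = [s for s, t in totals.items() if t == 0]
    if empty:
        raise ValidationError(f"empty samples have no diversity: {', '.join(empty)}")
    counts = table.counts.to_numpy(dtype=float)
    p = counts / counts.sum(axis=0, keepdims=True)
    observed = (counts > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=0)
    inv_simpson = 1.0 / (p**2).sum(axis=0)
    return pd.DataFrame(
        {
            "observed_richness": observed.astype(np.int64),
            "shannon": shannon,
            "inverse_simpson": inv_simpson,
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def paired_richness_summary(
    fungi_alpha: pd.DataFrame,
    bacteria_alpha: pd.DataFrame,
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Proportion of individuals with bacterial richness above fungal richness.

    Computed per host class and overall on the paired-sample intersection,
    with an exact (Clopper-Pearson) binomial 95% CI. Ties are excluded from
    numerator and denominator and reported separately.
    """
    shared = [s for s in fungi_alpha.index if s in set(bacteria_alpha.index)]
    if not shared:
        raise ValidationError("no samples shared between the two diversity tables")
    fr = fungi_alpha.loc[shared, "observed_richness"]
    br = bacteria_alpha.loc[shared, "observed_richness"]
    cls = metadata.frame.loc[shared, "host_class"]
    rows = []
    for label, idx in [("overall", pd.Index(shared))] + [
        (c, cls.index[cls == c]) for c in sorted(cls.unique())
    ]:
        b, f = br.loc[idx], fr.loc[idx]
        ties = int((b == f).sum())
        greater = int((b > f).sum())
        n_nontied = len(idx) - ties
        if n_nontied > 0:
            prop = greater / n_nontied
            ci = binomtest(greater, n_nontied).proportion_ci(0.95, method="exact")
            lo, hi = ci.low, ci.high
        else:
            prop, lo, hi = np.nan, np.nan, np.nan
        rows.append(
            {
                "group": label,
                "n": len(idx),
                "n_bacteria_greater": greater,
                "n_ties": ties,
                "proportion": prop,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows).set_index("group")
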