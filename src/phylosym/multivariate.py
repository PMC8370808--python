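"""Ordination and the core inference: PCA, sequential PERMANOVA,
Procrustes/PROTEST with bootstrap rank sweeps, Mantel tests, and the
phylosymbiosis and diet analyses.

PERMANOVA uses sequential (Type-I) sums of squares on the Gower-centred
inner-product matrix, with pseudo-F tested against unrestricted permutations
of sample labels — terms are marginalized in the caller-given order.
Procrustes correlation is the symmetric statistic sqrt(1 - m12^2); PROTEST
permutes rows of the second configuration. All permutation p-values follow
the (b + 1) / (n_perm + 1) convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from . import phylo
from .compositional import (
    ClrMatrix,
    agglomerate,
    aitchison_distance,
    alpha_diversity,
    clr_transform,
    merge_by_species,
)
from .io_formats import (
    DietTable,
    FeatureTable,
    HostTree,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)

RANK_LEVELS = ("asv", "genus", "family", "order")


# ---------------------------------------------------------------------------
# PCA and principal-coordinate embedding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # samples x axes
    explained_variance: np.ndarray
    loadings: pd.DataFrame  # features x axes


def pca(clr: ClrMatrix | pd.DataFrame, n_axes: int | None = None) -> PcaResult:
    """Centred (not scaled) PCA of a samples-by-features matrix.

    Axes are ordered by decreasing variance; each axis is oriented so its
    largest-magnitude loading is positive.
    """
    values = clr.values if isinstance(clr, ClrMatrix) else clr
    x = values.to_numpy(dtype=float)
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValidationError("PCA needs at least 2 samples and 2 features")
    max_axes = min(n - 1, p)
    if n_axes is None:
        n_axes = max_axes
    if n_axes > max_axes:
        raise ValueError(f"n_axes must be <= min(n-1, p) = {max_axes}, got {n_axes}")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    # deterministic sign: largest-magnitude loading positive per axis
    for k in range(n_axes):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    axes = [f"PC{k + 1}" for k in range(n_axes)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=values.index, columns=axes),
        explained_variance=s**2 / max(n - 1, 1),
        loadings=pd.DataFrame(vt.T, index=values.columns, columns=axes),
    )


def pcoa_embed(dm: DistanceMatrix) -> pd.DataFrame:
    """Classical principal-coordinates embedding of a distance matrix.

    Axes with negative eigenvalues are dropped with a warning (the embedding
    is then approximate for non-Euclidean distances).
    """
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(abs(eigval[0]), 1.0)
    if eigval[-1] < -tol:
        warnings.warn(
            "distance matrix is not Euclidean-embeddable; dropping "
            f"{int(np.sum(eigval < -tol))} negative-eigenvalue axes",
            stacklevel=2,
        )
    keep = eigval > tol
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    return pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"Axis{k + 1}" for k in range(int(keep.sum()))]
    )


# ---------------------------------------------------------------------------
# sequential PERMANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaTable:
    table: pd.DataFrame  # rows: terms in order + "residual"; cols: df, ss, r2, f, p
    n_perm: int
    seed: int

    @property
    def total_ss(self) -> float:
        return float(self.table["ss"].sum())


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


def _dummies(values: pd.Series) -> np.ndarray:
    levels = pd.unique(values)
    return (values.to_numpy()[:, None] == levels[None, :]).astype(float)


def permanova_sequential(
    dist: DistanceMatrix,
    metadata: SampleMetadata,
    term_order: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaTable:
    """Sequential (Type-I) PERMANOVA with unrestricted label permutations.

    Each term's sum of squares is the increase in explained trace of the
    Gower-centred matrix when the term joins the design after all preceding
    terms; pseudo-F is tested against the residual of the full model, with
    the full sequential decomposition recomputed per permutation.
    """
    if not term_order:
        raise ValueError("term_order must be non-empty")
    ids = list(dist.ids)
    n = len(ids)
    md = metadata.frame.reindex(ids)
    if md.isna().to_numpy().any():
        missing = sorted(set(ids) - set(metadata.sample_ids))
        raise ValidationError(f"samples missing from metadata: {', '.join(missing)}")
    for term in term_order:
        if term not in md.columns:
            raise ValueError(f"term {term!r} is not a metadata column")
        if md[term].nunique() < 2:
            raise ValidationError(f"term {term!r} has a single level")

    g = _gower_center(np.asarray(dist.data, dtype=float))
    total_ss = float(np.trace(g))

    # orthonormal bases of the growing design; Q_k spans intercept + terms 1..k
    design = np.ones((n, 1))
    qs: list[np.ndarray] = []
    dfs: list[int] = []
    prev_rank = 1
    for term in term_order:
        design = np.hstack([design, _dummies(md[term])])
        q, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        rank = int(np.sum(diag > 1e-8 * max(diag.max(), 1.0)))
        # keep only independent columns of Q
        keep = diag > 1e-8 * max(diag.max(), 1.0)
        q = q[:, keep]
        df = rank - prev_rank
        if df == 0:
            raise ValidationError(f"term {term!r} is aliased by preceding terms")
        qs.append(q)
        dfs.append(df)
        prev_rank = rank
    resid_df = n - prev_rank
    if resid_df <= 0:
        raise ValidationError("no residual degrees of freedom")

    def seq_stats(gmat: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        explained = np.array([np.einsum("ia,ij,ja->", q, gmat, q) for q in qs])
        ss = np.diff(np.concatenate([[0.0], explained]))
        ss_res = float(np.trace(gmat)) - explained[-1]
        f = (ss / np.array(dfs)) / (ss_res / resid_df)
        return ss, ss_res, f

    ss, ss_res, f_obs = seq_stats(g)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(term_order), dtype=int)
    # relative tolerance so permutations tied with the observed labelling
    # (e.g. group-label swaps) count as >= despite floating error
    tol = 1e-8 * np.maximum(np.abs(f_obs), 1.0)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, _, f_perm = seq_stats(gp)
        exceed += f_perm >= f_obs - tol
    p = (exceed + 1) / (n_perm + 1)

    rows = []
    for i, term in enumerate(term_order):
        rows.append(
            {"term": term, "df": dfs[i], "ss": ss[i], "r2": ss[i] / total_ss, "f": f_obs[i], "p": p[i]}
        )
    rows.append(
        {"term": "residual", "df": resid_df, "ss": ss_res, "r2": ss_res / total_ss, "f": np.nan, "p": np.nan}
    )
    return PermanovaTable(pd.DataFrame(rows).set_index("term"), n_perm, seed)


# ---------------------------------------------------------------------------
# Procrustes / PROTEST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProcrustesResult:
    correlation: float
    m12_squared: float
    p: float | None = None
    n_perm: int = 0
    seed: int | None = None
    rank_level: str | None = None
    n_shared: int = 0


def _align_scores(x: pd.DataFrame, y: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    shared = [i for i in x.index if i in set(y.index)]
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared rows, got {len(shared)}")
    xa = x.loc[shared].to_numpy(dtype=float)
    ya = y.loc[shared].to_numpy(dtype=float)
    width = max(xa.shape[1], ya.shape[1])
    xa = np.pad(xa, ((0, 0), (0, width - xa.shape[1])))
    ya = np.pad(ya, ((0, 0), (0, width - ya.shape[1])))
    return xa, ya, shared


def _procrustes_corr(xa: np.ndarray, ya: np.ndarray) -> float:
    xc = xa - xa.mean(axis=0, keepdims=True)
    yc = ya - ya.mean(axis=0, keepdims=True)
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValidationError("degenerate (constant) configuration in Procrustes")
    s = np.linalg.svd(xc.T @ yc / (nx * ny), compute_uv=False)
    return float(min(s.sum(), 1.0))


def procrustes_correlation(
    x: pd.DataFrame,
    y: pd.DataFrame,
    symmetric: bool = True,
    rank_level: str | None = None,
) -> ProcrustesResult:
    """Least-squares superimposition correlation between two score matrices.

    Rows are matched by ID (intersection), configurations centred and, in
    the symmetric variant, both scaled to unit total variance; the
    correlation sqrt(1 - m12^2) equals the sum of singular values of the
    cross-product and is invariant to rigid motions and global scaling of
    either input. (The asymmetric variant scales only the second matrix
    onto the first; the correlation statistic is identical.)
    """
    del symmetric  # both variants share the correlation statistic
    xa, ya, shared = _align_scores(x, y)
    corr = _procrustes_corr(xa, ya)
    return ProcrustesResult(
        correlation=corr,
        m12_squared=1.0 - corr**2,
        rank_level=rank_level,
        n_shared=len(shared),
    )


def protest(
    x: pd.DataFrame,
    y: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    rank_level: str | None = None,
) -> ProcrustesResult:
    """Permutation significance of the Procrustes correlation (rows of y shuffled)."""
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    xa, ya, shared = _align_scores(x, y)
    observed = _procrustes_corr(xa, ya)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(shared))
        if _procrustes_corr(xa, ya[perm]) >= observed - 1e-12:
            b += 1
    return ProcrustesResult(
        correlation=observed,
        m12_squared=1.0 - observed**2,
        p=(b + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
        rank_level=rank_level,
        n_shared=len(shared),
    )


# ---------------------------------------------------------------------------
# bootstrap sweeps across taxonomic ranks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapDistribution:
    rank_level: str
    correlations: np.ndarray
    interval: tuple[float, float]
    subsample_fraction: float
    full_correlation: float
    p: float | None = None
    n_perm: int = 0


def _maybe_agglomerate(table: FeatureTable, taxonomy: TaxonomyTable, rank: str) -> FeatureTable:
    if rank == "asv":
        return table
    return agglomerate(table, taxonomy, rank)


def _bootstrap_corrs(
    xa: pd.DataFrame,
    ya: pd.DataFrame,
    frac: float,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    shared = [i for i in xa.index if i in set(ya.index)]
    n = len(shared)
    m = math.ceil(frac * n)
    xs = xa.loc[shared].to_numpy(dtype=float)
    ys = ya.loc[shared].to_numpy(dtype=float)
    width = max(xs.shape[1], ys.shape[1])
    xs = np.pad(xs, ((0, 0), (0, width - xs.shape[1])))
    ys = np.pad(ys, ((0, 0), (0, width - ys.shape[1])))
    out = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.choice(n, size=m, replace=False)
        out[b] = _procrustes_corr(xs[idx], ys[idx])
    return out


def bootstrap_procrustes(
    fungi: FeatureTable,
    bacteria: FeatureTable,
    taxonomy_fungi: TaxonomyTable,
    taxonomy_bacteria: TaxonomyTable,
    rank_levels: list[str] = list(RANK_LEVELS),
    frac: float = 0.9,
    n_boot: int = 999,
    seed: int = 0,
    pseudocount_rule: str = "unit",
    n_perm: int = 0,
) -> dict[str, BootstrapDistribution]:
    """Cross-kingdom Procrustes correlation per taxonomic rank with a
    subsampling bootstrap (the same subsample is applied to both kingdoms).

    The paired-sample intersection is computed once and reused across ranks
    so replicates are comparable. Set ``n_perm`` > 0 to add a PROTEST
    p-value per rank on the full data.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    shared = [s for s in fungi.sample_ids if s in set(bacteria.sample_ids)]
    if len(shared) < 10:
        raise ValidationError(f"need >= 10 paired samples, got {len(shared)}")
    rng = np.random.default_rng(seed)
    results: dict[str, BootstrapDistribution] = {}
    for rank in rank_levels:
        fx = _maybe_agglomerate(fungi, taxonomy_fungi, rank).subset_samples(shared)
        bx = _maybe_agglomerate(bacteria, taxonomy_bacteria, rank).subset_samples(shared)
        fscores = pca(clr_transform(fx, pseudocount_rule)).scores
        bscores = pca(clr_transform(bx, pseudocount_rule)).scores
        full = procrustes_correlation(fscores, bscores).correlation
        corrs = _bootstrap_corrs(fscores, bscores, frac, n_boot, rng)
        lo, hi = np.percentile(corrs, [2.5, 97.5])
        p = None
        if n_perm:
            p = protest(fscores, bscores, n_perm=n_perm, seed=seed).p
        results[rank] = BootstrapDistribution(
            rank_level=rank,
            correlations=corrs,
            interval=(float(lo), float(hi)),
            subsample_fraction=frac,
            full_correlation=full,
            p=p,
            n_perm=n_perm,
        )
    return results


def phylosymbiosis_test(
    table: FeatureTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadata,
    tree: HostTree,
    rank_levels: list[str] = list(RANK_LEVELS),
    n_boot: int = 999,
    frac: float = 0.9,
    seed: int = 0,
    epsilon: float | None = None,
    pseudocount_rule: str = "unit",
    n_perm: int = 0,
) -> dict[str, BootstrapDistribution]:
    """Correlation between microbial and host patristic distances per rank.

    Samples are grafted onto the host tree at negligible branch lengths; the
    sample-level patristic and Aitchison distance matrices are embedded by
    principal coordinates and compared by Procrustes rotation, with the same
    90%-subsampling bootstrap as the cross-kingdom sweep.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    sample_to_species = metadata.species_of(table.sample_ids).to_dict()
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(sample_to_species.values()) - tips)
    if missing:
        raise ValidationError(f"species missing from tree: {', '.join(missing)}")
    grafted = phylo.graft_samples(tree, sample_to_species, epsilon)
    host_coords = pcoa_embed(phylo.patristic_distance(grafted))
    rng = np.random.default_rng(seed)
    results: dict[str, BootstrapDistribution] = {}
    for rank in rank_levels:
        tx = _maybe_agglomerate(table, taxonomy, rank)
        micro_coords = pcoa_embed(aitchison_distance(clr_transform(tx, pseudocount_rule)))
        full = procrustes_correlation(micro_coords, host_coords, rank_level=rank)
        corrs = _bootstrap_corrs(micro_coords, host_coords, frac, n_boot, rng)
        lo, hi = np.percentile(corrs, [2.5, 97.5])
        p = None
        if n_perm:
            p = protest(micro_coords, host_coords, n_perm=n_perm, seed=seed).p
        results[rank] = BootstrapDistribution(
            rank_level=rank,
            correlations=corrs,
            interval=(float(lo), float(hi)),
            subsample_fraction=frac,
            full_correlation=full.correlation,
            p=p,
            n_perm=n_perm,
        )
    return results


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    method: str
    n_perm: int
    seed: int
    n: int


def _rank_matrix(d: np.ndarray) -> np.ndarray:
    """Rank-transform the off-diagonal upper triangle, mirrored symmetric."""
    iu = np.triu_indices(d.shape[0], k=1)
    ranks = rankdata(d[iu])
    out = np.zeros_like(d, dtype=float)
    out[iu] = ranks
    return out + out.T


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Permutation correlation between two distance matrices (upper triangles).

    ``d2`` is aligned to ``d1``'s label order; its rows/columns are permuted
    jointly. Upper-tail p-value by the (b + 1)/(n_perm + 1) rule.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    if set(d1.ids) != set(d2.ids):
        raise ValidationError("distance matrices must share the same labels")
    n = len(d1.ids)
    if n < 4:
        raise ValidationError(f"Mantel needs >= 4 objects, got {n}")
    m1 = np.asarray(d1.data, dtype=float)
    m2 = np.asarray(d2.filter(d1.ids).data, dtype=float)
    if method == "spearman":
        # rank once: a joint row/column permutation permutes the same multiset
        m1, m2 = _rank_matrix(m1), _rank_matrix(m2)
    iu = np.triu_indices(n, k=1)
    v1 = m1[iu]
    v1 = (v1 - v1.mean()) / v1.std()
    v2 = m2[iu]

    def corr_with(mat: np.ndarray) -> float:
        v = mat[iu]
        return float(np.mean(v1 * (v - v.mean()) / v.std()))

    observed = corr_with(m2)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(m2[np.ix_(perm, perm)]) >= observed - 1e-12:
            b += 1
    return MantelResult(
        r=observed, p=(b + 1) / (n_perm + 1), method=method, n_perm=n_perm, seed=seed, n=n
    )


# ---------------------------------------------------------------------------
# diet analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DietAnalysisResult:
    pca_scores: pd.DataFrame  # species x PCs of the standardized diet matrix
    explained_variance_ratio: np.ndarray
    mantel: dict[str, MantelResult]  # per kingdom: community vs diet distance
    slopes: pd.DataFrame  # per kingdom x axis: OLS slope of Shannon + bootstrap CI
    dropped_species: list[str] = field(default_factory=list)


def diet_analysis(
    fungi: FeatureTable,
    bacteria: FeatureTable,
    metadata: SampleMetadata,
    diet: DietTable,
    n_perm: int = 999,
    n_boot: int = 499,
    seed: int = 0,
    pseudocount_rule: str = "unit",
) -> DietAnalysisResult:
    """Diet PCA, per-kingdom diet-composition Mantel tests, and OLS slopes of
    species-level Shannon diversity on the two leading diet axes.

    Tables are merged to one column per host species; species without diet
    rows are dropped with a report. Slope CIs are percentile bootstrap over
    species resampling.
    """
    merged = {
        "fungi": merge_by_species(fungi, metadata),
        "bacteria": merge_by_species(bacteria, metadata),
    }
    species = [
        sp
        for sp in merged["fungi"].sample_ids
        if sp in set(merged["bacteria"].sample_ids) and sp in set(diet.species)
    ]
    dropped = sorted(
        (set(merged["fungi"].sample_ids) | set(merged["bacteria"].sample_ids)) - set(species)
    )
    if len(species) < 4:
        raise ValidationError(f"need >= 4 species with diet data, got {len(species)}")

    dmat = diet.proportions.loc[species]
    std = dmat.std(axis=0, ddof=1).replace(0.0, 1.0)
    dstd = (dmat - dmat.mean(axis=0)) / std
    diet_pca = pca(dstd)
    total_var = float(diet_pca.explained_variance.sum())
    evr = diet_pca.explained_variance / total_var if total_var > 0 else diet_pca.explained_variance
    diet_dm = DistanceMatrix(squareform(pdist(dstd.to_numpy())), ids=species)

    rng = np.random.default_rng(seed)
    mantels: dict[str, MantelResult] = {}
    slope_rows = []
    for kingdom in ("fungi", "bacteria"):
        tbl = merged[kingdom].subset_samples(species)
        comm_dm = aitchison_distance(clr_transform(tbl, pseudocount_rule))
        mantels[kingdom] = mantel(comm_dm, diet_dm, n_perm=n_perm, seed=seed)
        shannon = alpha_diversity(tbl)["shannon"].loc[species].to_numpy()
        n_axes = min(2, diet_pca.scores.shape[1])
        x = np.column_stack(
            [np.ones(len(species)), diet_pca.scores.iloc[:, :n_axes].to_numpy()]
        )
        beta = np.linalg.lstsq(x, shannon, rcond=None)[0]
        boots = np.empty((n_boot, n_axes))
        for b in range(n_boot):
            idx = rng.integers(len(species), size=len(species))
            xb, yb = x[idx], shannon[idx]
            try:
                boots[b] = np.linalg.lstsq(xb, yb, rcond=None)[0][1 : n_axes + 1]
            except np.linalg.LinAlgError:
                boots[b] = np.nan
        for k in range(n_axes):
            lo, hi = np.nanpercentile(boots[:, k], [2.5, 97.5])
            slope_rows.append(
                {
                    "kingdom": kingdom,
                    "axis": f"PC{k + 1}",
                    "slope": beta[k + 1],
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    slopes = pd.DataFrame(slope_rows).set_index(["kingdom", "axis"])
    return DietAnalysisResult(
        pca_scores=diet_pca.scores,
        explained_variance_ratio=np.asarray(evr),
        mantel=mantels,
        slopes=slopes,
        dropped_species=dropped,
    )
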