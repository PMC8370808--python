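"""Ground-truth test bed: host trees and paired two-kingdom count tables.

Generative model
----------------
1. A shared latent trait matrix ``Z_shared`` and kingdom-specific matrices
   ``Z_fungi``, ``Z_bacteria`` are drawn by Brownian motion on the host tree
   with scale ``phylo_strength`` (per-branch variance = sigma_B^2 * length),
   one dimension per feature.
2. The latent log-composition of species ``s`` in a kingdom is
   ``sqrt(coupling) * Z_shared[s] + sqrt(1 - coupling) * Z_kingdom[s]``;
   the square-root weights keep total latent variance constant across the
   coupling parameter, isolating coupling from overall signal strength.
3. A sample's latent vector adds Normal(0, sigma_within) noise plus one
   offset vector of scale ``batch_effect_size`` per batch factor level
   (factor levels are assigned uniformly at random, independent of species).
4. Counts are Multinomial(depth_i, softmax(latent)) with
   depth_i ~ 1 + Poisson(depth - 1).

Taxonomy bins features into a fixed nested hierarchy (10 phyla, 3 orders
per phylum, 2 families per order, 2 genera per family). The two leading
diet axes are Brownian motion on the tree mixed with uniform noise at the
``diet_signal`` variance ratio, then mapped through a softmax onto the 10
diet categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import (
    DIET_CATEGORIES,
    METADATA_COLUMNS,
    RANKS,
    DietTable,
    FeatureTable,
    HostTree,
    SampleMetadata,
    TaxonomyTable,
    write_diet,
    write_feature_table,
    write_metadata,
    write_newick,
    write_taxonomy,
)

BATCH_FACTORS = ("sample_type", "tissue_storage", "extraction_kit")


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 8
    samples_per_species: int = 4
    n_features_per_kingdom: int = 60
    depth: int = 500
    phylo_strength: float = 1.0  # Brownian drift scale sigma_B (per kingdom)
    coupling: float = 0.5  # fraction of latent variance shared between kingdoms
    sigma_within: float = 0.5
    batch_effect_size: float = 0.5
    n_batch_levels: int = 3
    diet_signal: float = 0.5
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_species < 3:
            raise ValueError(f"n_species must be >= 3, got {self.n_species}")
        for name in ("samples_per_species", "n_features_per_kingdom", "depth", "n_batch_levels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError(f"coupling must be in [0, 1], got {self.coupling}")
        if not 0.0 <= self.diet_signal <= 1.0:
            raise ValueError(f"diet_signal must be in [0, 1], got {self.diet_signal}")
        for name in ("phylo_strength", "batch_effect_size", "sigma_within"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Latent per-species composition matrices underlying the counts."""

    species_latent_fungi: pd.DataFrame
    species_latent_bacteria: pd.DataFrame
    shared_latent: pd.DataFrame
    config: SimulationConfig


@dataclass(frozen=True)
class SimulatedDataset:
    tree: HostTree
    fungi: FeatureTable
    bacteria: FeatureTable
    taxonomy_fungi: TaxonomyTable
    taxonomy_bacteria: TaxonomyTable
    metadata: SampleMetadata
    diet: DietTable
    ground_truth: GroundTruth


def simulate_host_tree(n_species: int, seed: int) -> HostTree:
    """Pure-birth (Yule) ultrametric tree, depth scaled to 1.0, tips sp001..spN."""
    if n_species < 3:
        raise ValueError(f"n_species must be >= 3, got {n_species}")
    rng = np.random.default_rng(seed)
    root = TreeNode(length=None)
    birth_time = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        for _ in range(2):
            child = TreeNode(length=None)
            birth_time[id(child)] = t
            node.append(child)
            active.append(child)
    present = t + rng.exponential(1.0 / n_species)
    for node in root.traverse(include_self=False):
        end = present if node.is_tip() else birth_time[id(node.children[0])]
        node.length = end - birth_time[id(node)]
    # scale root-to-tip depth to exactly 1.0 (the stem below the first split
    # carries no length, so depth = present - first split time)
    first_split = birth_time[id(root.children[0])]
    depth_now = present - first_split
    scale = 1.0 / depth_now if depth_now > 0 else 1.0
    for node in root.traverse(include_self=False):
        node.length *= scale
    for i, tip in enumerate(root.tips()):
        tip.name = f"sp{i + 1:03d}"
    return root


def brownian_on_tree(tree: HostTree, n_dims: int, sigma: float, rng: np.random.Generator) -> pd.DataFrame:
    """Brownian trait values at the tips (root value 0), tips x dims."""
    values: dict[int, np.ndarray] = {id(tree): np.zeros(n_dims)}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, 1.0, n_dims) * sigma * np.sqrt(max(node.length or 0.0, 0.0))
        values[id(node)] = values[id(node.parent)] + step
    tips = [t for t in tree.tips()]
    return pd.DataFrame(
        np.vstack([values[id(t)] for t in tips]), index=[t.name for t in tips]
    )


def _nested_taxonomy(feature_ids: list[str], kingdom: str) -> TaxonomyTable:
    prefix = kingdom[0]
    rows = []
    for i, fid in enumerate(feature_ids):
        fam_idx = i % 60
        gen_sub = (i // 60) % 2
        order_idx = fam_idx // 2
        phylum_idx = order_idx // 3
        rows.append(
            [
                kingdom,
                f"{prefix}Phy{phylum_idx + 1:02d}",
                f"{prefix}Cls{phylum_idx + 1:02d}",
                f"{prefix}Ord{order_idx + 1:02d}",
                f"{prefix}Fam{fam_idx + 1:02d}",
                f"{prefix}Fam{fam_idx + 1:02d}_g{gen_sub + 1}",
            ]
        )
    frame = pd.DataFrame(rows, index=pd.Index(feature_ids, name="feature_id"), columns=list(RANKS))
    return TaxonomyTable(frame)


def _host_groups(tree: HostTree) -> tuple[dict[str, str], dict[str, str]]:
    """Host class/order labels derived from the clades under the root."""
    host_class: dict[str, str] = {}
    host_order: dict[str, str] = {}
    for ci, child in enumerate(tree.children):
        subtips = [child] if child.is_tip() else list(child.tips())
        grandchildren = [child] if child.is_tip() else child.children
        for oi, gchild in enumerate(grandchildren):
            gtips = [gchild] if gchild.is_tip() else list(gchild.tips())
            for tip in gtips:
                host_class[tip.name] = f"HC{ci + 1}"
                host_order[tip.name] = f"HC{ci + 1}_HO{oi + 1}"
        for tip in subtips:
            host_class.setdefault(tip.name, f"HC{ci + 1}")
    return host_class, host_order


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def simulate_paired_microbiome(tree: HostTree, config: SimulationConfig) -> SimulatedDataset:
    """Draw a full paired fungal/bacterial dataset from the documented model."""
    config.validate()
    species = [t.name for t in tree.tips()]
    if len(species) != config.n_species:
        config = replace(config, n_species=len(species))
    rng = np.random.default_rng(config.seed)
    p = config.n_features_per_kingdom
    lam = config.coupling

    z_shared = brownian_on_tree(tree, p, config.phylo_strength, rng)
    z_king = {k: brownian_on_tree(tree, p, config.phylo_strength, rng) for k in ("fungi", "bacteria")}
    latent_species = {
        k: np.sqrt(lam) * z_shared + np.sqrt(1.0 - lam) * z_king[k] for k in ("fungi", "bacteria")
    }

    sample_ids = [f"{sp}_{i + 1:02d}" for sp in species for i in range(config.samples_per_species)]
    sample_species = [sp for sp in species for _ in range(config.samples_per_species)]
    n = len(sample_ids)

    # batch factor levels: uniform at random, independent of species
    level_idx = {f: rng.integers(config.n_batch_levels, size=n) for f in BATCH_FACTORS}
    levels = {
        f: np.array([f"{f[:3]}L{v + 1}" for v in level_idx[f]]) for f in BATCH_FACTORS
    }
    host_class, host_order = _host_groups(tree)

    tables: dict[str, FeatureTable] = {}
    taxonomies: dict[str, TaxonomyTable] = {}
    for kingdom in ("fungi", "bacteria"):
        offsets = {
            f: rng.normal(0.0, config.batch_effect_size, (config.n_batch_levels, p))
            for f in BATCH_FACTORS
        }
        latent = np.empty((n, p))
        for i, sp in enumerate(sample_species):
            vec = latent_species[kingdom].loc[sp].to_numpy().copy()
            vec += rng.normal(0.0, config.sigma_within, p)
            for f in BATCH_FACTORS:
                vec += offsets[f][level_idx[f][i]]
            latent[i] = vec
        probs = _softmax(latent, axis=1)
        depths = 1 + rng.poisson(max(config.depth - 1, 0), size=n)
        counts = np.empty((p, n), dtype=np.int64)
        for i in range(n):
            counts[:, i] = rng.multinomial(depths[i], probs[i])
        prefix = kingdom[0]
        feature_ids = [f"{prefix}ASV{j + 1:04d}" for j in range(p)]
        frame = pd.DataFrame(counts, index=feature_ids, columns=sample_ids)
        tables[kingdom] = FeatureTable(frame, kingdom)
        taxonomies[kingdom] = _nested_taxonomy(feature_ids, kingdom)

    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "host_species": sample_species,
                "host_order": [host_order.get(sp, "HO_unknown") for sp in sample_species],
                "host_class": [host_class[sp] for sp in sample_species],
                "sample_type": levels["sample_type"],
                "tissue_storage": levels["tissue_storage"],
                "extraction_kit": levels["extraction_kit"],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # diet: two latent axes, Brownian vs uniform mix at the diet_signal ratio
    bm_axes = brownian_on_tree(tree, 2, 1.0, rng).to_numpy()
    sd = bm_axes.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    bm_axes = bm_axes / sd
    noise = rng.uniform(-np.sqrt(3), np.sqrt(3), size=bm_axes.shape)  # unit variance
    axes = np.sqrt(config.diet_signal) * bm_axes + np.sqrt(1.0 - config.diet_signal) * noise
    loadings = rng.normal(0.0, 1.0, (2, len(DIET_CATEGORIES)))
    diet_props = _softmax(axes @ loadings, axis=1) * 100.0
    diet = DietTable(
        pd.DataFrame(diet_props, index=pd.Index(species, name="species"), columns=list(DIET_CATEGORIES))
    )

    ground_truth = GroundTruth(
        species_latent_fungi=latent_species["fungi"],
        species_latent_bacteria=latent_species["bacteria"],
        shared_latent=z_shared,
        config=config,
    )
    return SimulatedDataset(
        tree=tree,
        fungi=tables["fungi"],
        bacteria=tables["bacteria"],
        taxonomy_fungi=taxonomies["fungi"],
        taxonomy_bacteria=taxonomies["bacteria"],
        metadata=metadata,
        diet=diet,
        ground_truth=ground_truth,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Convenience wrapper: tree and dataset from a single config/seed."""
    tree = simulate_host_tree(config.n_species, config.seed)
    return simulate_paired_microbiome(tree, config)


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def ground_truth_summary(dataset: SimulatedDataset) -> pd.DataFrame:
    """Realized signal statistics of the latent (pre-noise) layer.

    Reports the Pearson correlation between latent-species Euclidean
    distances and patristic distances per kingdom (a noiseless Mantel
    statistic), and the correlation between the two kingdoms' centred latent
    matrices. Statistics are NaN when the latent layer is constant
    (phylo_strength = 0).
    """
    from scipy.spatial.distance import pdist

    gt = dataset.ground_truth
    tree_dm = dataset.tree.tip_tip_distances()
    species = list(gt.species_latent_fungi.index)
    patristic = _upper(tree_dm.filter(species).data)
    rows = {}
    for kingdom, latent in (
        ("fungi", gt.species_latent_fungi),
        ("bacteria", gt.species_latent_bacteria),
    ):
        d = pdist(latent.to_numpy())
        if d.std() == 0 or patristic.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(d, patristic)[0, 1])
        rows[f"latent_phylo_mantel_r_{kingdom}"] = r
    f = gt.species_latent_fungi.to_numpy().ravel()
    b = gt.species_latent_bacteria.to_numpy().ravel()
    f = f - f.mean()
    b = b - b.mean()
    if f.std() == 0 or b.std() == 0:
        rows["cross_kingdom_latent_correlation"] = np.nan
    else:
        rows["cross_kingdom_latent_correlation"] = float(np.corrcoef(f, b)[0, 1])
    rows["coupling"] = gt.config.coupling
    rows["phylo_strength"] = gt.config.phylo_strength
    return pd.DataFrame({"value": rows})


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, str]:
    """Write the five standard files plus ground_truth.tsv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "host_tree.nwk",
        "fungi": outdir / "fungi_counts.tsv",
        "bacteria": outdir / "bacteria_counts.tsv",
        "taxonomy_fungi": outdir / "fungi_taxonomy.tsv",
        "taxonomy_bacteria": outdir / "bacteria_taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "diet": outdir / "diet.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_newick(dataset.tree, paths["tree"])
    write_feature_table(dataset.fungi, paths["fungi"])
    write_feature_table(dataset.bacteria, paths["bacteria"])
    write_taxonomy(dataset.taxonomy_fungi, paths["taxonomy_fungi"])
    write_taxonomy(dataset.taxonomy_bacteria, paths["taxonomy_bacteria"])
    write_metadata(dataset.metadata, paths["metadata"])
    write_diet(dataset.diet, paths["diet"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        fh.write("# phylosym-v1\tground_truth\n")
        ground_truth_summary(dataset).to_csv(fh, sep="\t", index_label="statistic", lineterminator="\n")
    return {k: str(v) for k, v in paths.items()}
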