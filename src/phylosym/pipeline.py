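"""End-to-end orchestration: run every analysis stage in a fixed order and
write TSV results plus a machine-readable run manifest.

The config is flat ``key=value`` text (lists comma-separated, ``#`` comments
allowed). Determinism contract: the same config and seed produce
byte-identical output files; the manifest records a sha256 per file so
re-runs can be compared mechanically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import compositional, io_formats, multivariate, networks, phylo, synthetic_data
from .io_formats import SCHEMA_VERSION

log = logging.getLogger("phylosym")

PERMANOVA_TERMS_DEFAULT = (
    "sample_type",
    "tissue_storage",
    "extraction_kit",
    "host_class",
    "host_order",
    "host_species",
)


@dataclass
class RunConfig:
    # input paths; when absent, a dataset is simulated from the sim_* keys
    fungi_table: str | None = None
    bacteria_table: str | None = None
    taxonomy_fungi: str | None = None
    taxonomy_bacteria: str | None = None
    metadata: str | None = None
    tree: str | None = None
    diet: str | None = None
    # simulation parameters (used only when input paths are absent)
    sim_n_species: int = 10
    sim_samples_per_species: int = 4
    sim_n_features: int = 80
    sim_depth: int = 1000
    sim_phylo_strength: float = 1.0
    sim_coupling: float = 0.6
    sim_sigma_within: float = 0.5
    sim_batch_effect_size: float = 0.4
    sim_n_batch_levels: int = 3
    sim_diet_signal: float = 0.6
    # analysis parameters (reference defaults: depth 500, 999 perms, 90% x 999, rho 0.5)
    rarefy_depth: int = 500
    pseudocount_rule: str = "unit"
    permanova_terms: tuple[str, ...] = PERMANOVA_TERMS_DEFAULT
    rank_levels: tuple[str, ...] = ("asv", "genus", "family", "order")
    bootstrap_frac: float = 0.9
    n_boot: int = 999
    n_perm: int = 999
    rho_threshold: float = 0.5
    min_prevalence: float = 0.2
    min_samples: int = 5
    seed: int = 1

    def validate(self) -> "RunConfig":
        if not self.permanova_terms:
            raise ValueError("permanova_terms must be non-empty")
        if self.seed is None:
            raise ValueError("seed is required")
        return self


_LIST_KEYS = {"permanova_terms", "rank_levels"}


def load_config(path) -> RunConfig:
    """Parse a flat key=value config file into a RunConfig."""
    kwargs: dict = {}
    valid = {f.name: f for f in fields(RunConfig)}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key in _LIST_KEYS:
                kwargs[key] = tuple(v.strip() for v in raw.split(",") if v.strip())
            else:
                default = valid[key].default
                if isinstance(default, bool):
                    kwargs[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(raw)
                elif isinstance(default, float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw if raw.lower() != "none" else None
    return RunConfig(**kwargs).validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, kind: str, index_label: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {SCHEMA_VERSION}\t{kind}\n")
        frame.to_csv(fh, sep="\t", index_label=index_label, lineterminator="\n", float_format="%.10g")


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {name: {"path": str(p), "sha256": _sha256(Path(p))} for name, p in outputs.items()},
            "seconds": round(seconds, 3),
        }

    def warn(self, stage: str, message: str) -> None:
        log.warning("%s: %s", stage, message)
        self.warnings.append({"stage": stage, "message": message})

    def write(self, path: Path) -> None:
        payload = {
            "schema": SCHEMA_VERSION,
            "version": self.version,
            "config": self.config,
            "stages": self.stages,
            "warnings": self.warnings,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(config: RunConfig, outdir: Path, manifest: RunManifest):
    if config.fungi_table is None:
        sim_config = synthetic_data.SimulationConfig(
            n_species=config.sim_n_species,
            samples_per_species=config.sim_samples_per_species,
            n_features_per_kingdom=config.sim_n_features,
            depth=config.sim_depth,
            phylo_strength=config.sim_phylo_strength,
            coupling=config.sim_coupling,
            sigma_within=config.sim_sigma_within,
            batch_effect_size=config.sim_batch_effect_size,
            n_batch_levels=config.sim_n_batch_levels,
            diet_signal=config.sim_diet_signal,
            seed=config.seed,
        )
        dataset = synthetic_data.simulate_dataset(sim_config)
        paths = synthetic_data.write_dataset(dataset, outdir / "inputs")
        return dataset, {k: Path(v) for k, v in paths.items()}
    required = ("fungi_table", "bacteria_table", "taxonomy_fungi", "taxonomy_bacteria", "metadata", "tree")
    missing = [k for k in required if getattr(config, k) is None]
    if missing:
        raise ValueError(f"missing input paths: {', '.join(missing)}")
    fungi = io_formats.read_feature_table(config.fungi_table, "fungi")
    bacteria = io_formats.read_feature_table(config.bacteria_table, "bacteria")
    tax_f = io_formats.read_taxonomy(config.taxonomy_fungi)
    tax_b = io_formats.read_taxonomy(config.taxonomy_bacteria)
    metadata = io_formats.read_metadata(config.metadata)
    tree = io_formats.read_newick(config.tree)
    diet = io_formats.read_diet(config.diet) if config.diet else None
    io_formats.validate_alignment(fungi, metadata, tax_f)
    io_formats.validate_alignment(bacteria, metadata, tax_b)
    dataset = synthetic_data.SimulatedDataset(
        tree=tree,
        fungi=fungi,
        bacteria=bacteria,
        taxonomy_fungi=tax_f,
        taxonomy_bacteria=tax_b,
        metadata=metadata,
        diet=diet,
        ground_truth=None,
    )
    paths = {k: Path(getattr(config, k)) for k in required}
    if config.diet:
        paths["diet"] = Path(config.diet)
    return dataset, paths


def run_all(config: RunConfig, outdir) -> RunManifest:
    """Execute every stage in fixed order; abort with the stage name on failure."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config={f.name: getattr(config, f.name) for f in fields(config)})
    manifest.config["permanova_terms"] = list(config.permanova_terms)
    manifest.config["rank_levels"] = list(config.rank_levels)

    def stage(name, fn):
        t0 = time.monotonic()
        log.info("stage %s: start", name)
        try:
            outputs = fn() or {}
        except Exception as exc:
            raise StageError(name, exc) from exc
        manifest.record(name, outputs, time.monotonic() - t0)
        log.info("stage %s: done (%.2fs)", name, time.monotonic() - t0)

    state: dict = {}

    def s_inputs():
        dataset, paths = _load_inputs(config, outdir, manifest)
        state["dataset"] = dataset
        return paths

    def s_normalize():
        ds = state["dataset"]
        outputs = {}
        for kingdom in ("fungi", "bacteria"):
            table = getattr(ds, kingdom)
            rr = compositional.rarefy(table, config.rarefy_depth, config.seed)
            if rr.dropped:
                manifest.warn("normalize", f"{kingdom}: dropped sub-depth samples: {', '.join(rr.dropped)}")
            state[f"rarefied_{kingdom}"] = rr.table
            path = outdir / f"{kingdom}_rarefied.tsv"
            io_formats.write_feature_table(rr.table, path)
            outputs[f"{kingdom}_rarefied"] = path
            state[f"clr_{kingdom}"] = compositional.clr_transform(table, config.pseudocount_rule)
        return outputs

    def s_diversity():
        ds = state["dataset"]
        outputs = {}
        alphas = {}
        for kingdom in ("fungi", "bacteria"):
            alpha = compositional.alpha_diversity(state[f"rarefied_{kingdom}"])
            alphas[kingdom] = alpha
            path = outdir / f"{kingdom}_alpha_diversity.tsv"
            _write_tsv(alpha, path, "alpha_diversity", index_label="sample_id")
            outputs[f"{kingdom}_alpha"] = path
        summary = compositional.paired_richness_summary(alphas["fungi"], alphas["bacteria"], ds.metadata)
        path = outdir / "paired_richness.tsv"
        _write_tsv(summary, path, "paired_richness", index_label="group")
        outputs["paired_richness"] = path
        state["alphas"] = alphas
        return outputs

    def s_phylosignal():
        ds = state["dataset"]
        results = []
        for kingdom in ("fungi", "bacteria"):
            alpha = state["alphas"][kingdom]
            species = ds.metadata.species_of(alpha.index)
            for trait_col in ("observed_richness", "shannon"):
                tip_trait = alpha[trait_col].groupby(species.to_numpy()).mean()
                tips = {t.name for t in ds.tree.tips()}
                tip_trait = tip_trait[tip_trait.index.isin(tips)]
                sheared = ds.tree.shear(set(tip_trait.index))
                results.append(
                    phylo.abouheif_test(
                        tip_trait,
                        sheared,
                        n_perm=config.n_perm,
                        seed=config.seed,
                        trait_name=f"{kingdom}_{trait_col}",
                    )
                )
        table = phylo.signal_test_table(results)
        path = outdir / "phylosignal.tsv"
        _write_tsv(table, path, "phylosignal", index_label="trait")
        return {"phylosignal": path}

    def s_permanova():
        ds = state["dataset"]
        outputs = {}
        for kingdom in ("fungi", "bacteria"):
            dm = compositional.aitchison_distance(state[f"clr_{kingdom}"])
            result = multivariate.permanova_sequential(
                dm, ds.metadata, list(config.permanova_terms), n_perm=config.n_perm, seed=config.seed
            )
            path = outdir / f"{kingdom}_permanova.tsv"
            _write_tsv(result.table, path, "permanova", index_label="term")
            outputs[f"{kingdom}_permanova"] = path
        return outputs

    def s_phylosymbiosis():
        ds = state["dataset"]
        outputs = {}
        for kingdom in ("fungi", "bacteria"):
            res = multivariate.phylosymbiosis_test(
                getattr(ds, kingdom),
                getattr(ds, f"taxonomy_{kingdom}"),
                ds.metadata,
                ds.tree,
                rank_levels=list(config.rank_levels),
                n_boot=config.n_boot,
                frac=config.bootstrap_frac,
                seed=config.seed,
                pseudocount_rule=config.pseudocount_rule,
                n_perm=config.n_perm,
            )
            frame = _boot_frame(res)
            path = outdir / f"{kingdom}_phylosymbiosis.tsv"
            _write_tsv(frame, path, "phylosymbiosis", index_label="rank_level")
            outputs[f"{kingdom}_phylosymbiosis"] = path
        return outputs

    def s_procrustes():
        ds = state["dataset"]
        res = multivariate.bootstrap_procrustes(
            ds.fungi,
            ds.bacteria,
            ds.taxonomy_fungi,
            ds.taxonomy_bacteria,
            rank_levels=list(config.rank_levels),
            frac=config.bootstrap_frac,
            n_boot=config.n_boot,
            seed=config.seed,
            pseudocount_rule=config.pseudocount_rule,
            n_perm=config.n_perm,
        )
        frame = _boot_frame(res)
        path = outdir / "cross_kingdom_procrustes.tsv"
        _write_tsv(frame, path, "procrustes", index_label="rank_level")
        return {"cross_kingdom_procrustes": path}

    def s_diet():
        ds = state["dataset"]
        if ds.diet is None:
            manifest.warn("diet", "no diet table provided; stage skipped")
            return {}
        res = multivariate.diet_analysis(
            ds.fungi,
            ds.bacteria,
            ds.metadata,
            ds.diet,
            n_perm=config.n_perm,
            seed=config.seed,
            pseudocount_rule=config.pseudocount_rule,
        )
        if res.dropped_species:
            manifest.warn("diet", f"species without diet data dropped: {', '.join(res.dropped_species)}")
        outputs = {}
        path = outdir / "diet_pca_scores.tsv"
        _write_tsv(res.pca_scores, path, "diet_pca", index_label="species")
        outputs["diet_pca_scores"] = path
        mantel_frame = pd.DataFrame(
            {
                kingdom: {"r": m.r, "p": m.p, "n_perm": m.n_perm, "n_species": m.n}
                for kingdom, m in res.mantel.items()
            }
        ).T
        path = outdir / "diet_mantel.tsv"
        _write_tsv(mantel_frame, path, "diet_mantel", index_label="kingdom")
        outputs["diet_mantel"] = path
        path = outdir / "diet_slopes.tsv"
        _write_tsv(res.slopes.reset_index(), path, "diet_slopes")
        outputs["diet_slopes"] = path
        return outputs

    def s_networks():
        ds = state["dataset"]
        sweep = networks.species_and_class_networks(
            ds.fungi,
            ds.bacteria,
            ds.taxonomy_fungi,
            ds.taxonomy_bacteria,
            ds.metadata,
            depth=config.rarefy_depth,
            threshold=config.rho_threshold,
            min_prevalence=config.min_prevalence,
            min_samples=config.min_samples,
            seed=config.seed,
        )
        for level, group, reason in sweep.skipped:
            manifest.warn("networks", f"skipped {level} {group}: {reason}")
        outputs = {}
        path = outdir / "network_traits.tsv"
        _write_tsv(
            sweep.traits.reset_index() if not sweep.traits.empty else pd.DataFrame(),
            path,
            "network_traits",
        )
        outputs["network_traits"] = path
        netdir = outdir / "networks"
        netdir.mkdir(exist_ok=True)
        null_rows = []
        for (level, group), net in sorted(sweep.networks.items()):
            epath = netdir / f"{level}_{group}_edges.tsv"
            _write_tsv(net.edges_frame(), epath, "network_edges")
            npath = netdir / f"{level}_{group}_nodes.tsv"
            _write_tsv(net.nodes_frame(), npath, "network_nodes", index_label="node")
            outputs[f"{level}_{group}_edges"] = epath
            outputs[f"{level}_{group}_nodes"] = npath
            if level != "class" or net.n_edges == 0:
                continue
            kingdoms = {d.get("kingdom") for _, d in net.graph.nodes(data=True)}
            if {"fungi", "bacteria"} <= kingdoms:
                bt = networks.betweenness_null_test(net, n_perm=config.n_perm, seed=config.seed)
                null_rows.append(
                    {"level": level, "group": group, "statistic": bt.statistic,
                     "observed": bt.observed, "p": bt.p, "direction": bt.direction}
                )
            try:
                freq = networks.phylum_pair_frequency(net)
            except io_formats.ValidationError:
                continue
            top = freq.stack().idxmax()
            pt = networks.phylum_pair_null_test(net, top, n_perm=config.n_perm, seed=config.seed)
            null_rows.append(
                {"level": level, "group": group, "statistic": pt.statistic,
                 "observed": pt.observed, "p": pt.p, "direction": pt.direction}
            )
        path = outdir / "network_null_tests.tsv"
        _write_tsv(pd.DataFrame(null_rows), path, "network_null_tests")
        outputs["network_null_tests"] = path
        return outputs

    stage("inputs", s_inputs)
    stage("normalize", s_normalize)
    stage("diversity", s_diversity)
    stage("phylosignal", s_phylosignal)
    stage("permanova", s_permanova)
    stage("phylosymbiosis", s_phylosymbiosis)
    stage("procrustes", s_procrustes)
    stage("diet", s_diet)
    stage("networks", s_networks)

    manifest.write(outdir / "manifest.json")
    return manifest


def _boot_frame(results: dict[str, multivariate.BootstrapDistribution]) -> pd.DataFrame:
    rows = []
    for rank, res in results.items():
        rows.append(
            {
                "rank_level": rank,
                "correlation": res.full_correlation,
                "ci_low": res.interval[0],
                "ci_high": res.interval[1],
                "n_boot": len(res.correlations),
                "subsample_fraction": res.subsample_fraction,
                "p": res.p if res.p is not None else np.nan,
                "n_perm": res.n_perm,
            }
        )
    return pd.DataFrame(rows).set_index("rank_level")


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def report(outdir) -> str:
    """Render run outputs into a markdown summary; missing stages are marked."""
    outdir = Path(outdir)

    def section(title: str, filename: str, index_col=0) -> str:
        path = outdir / filename
        if not path.exists():
            return f"## {title}\n\n*skipped — {filename} not found*\n"
        frame = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
        try:
            rendered = frame.to_markdown()
        except ImportError:  # tabulate unavailable
            rendered = "```\n" + frame.to_string() + "\n```"
        return f"## {title}\n\n{rendered}\n"

    parts = ["# phylosym run report\n"]
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        parts.append(f"Software version: {manifest.get('version')}\n")
        if manifest.get("warnings"):
            parts.append("## Warnings\n")
            for w in manifest["warnings"]:
                parts.append(f"- **{w['stage']}**: {w['message']}")
            parts.append("")
    parts.append(section("Paired richness", "paired_richness.tsv"))
    parts.append(section("Phylogenetic signal", "phylosignal.tsv"))
    parts.append(section("PERMANOVA — fungi", "fungi_permanova.tsv"))
    parts.append(section("PERMANOVA — bacteria", "bacteria_permanova.tsv"))
    parts.append(section("Phylosymbiosis — fungi", "fungi_phylosymbiosis.tsv"))
    parts.append(section("Phylosymbiosis — bacteria", "bacteria_phylosymbiosis.tsv"))
    parts.append(section("Cross-kingdom Procrustes by rank", "cross_kingdom_procrustes.tsv"))
    parts.append(section("Diet Mantel", "diet_mantel.tsv"))
    parts.append(section("Network traits", "network_traits.tsv"))
    parts.append(section("Network null tests", "network_null_tests.tsv"))
    text = "\n".join(parts)
    (outdir / "report.md").write_text(text, encoding="utf-8")
    return text
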