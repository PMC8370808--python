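"""Readers, writers and validated in-memory structures for all pipeline inputs.

The canonical on-disk dialect is TSV (UTF-8, tab-separated, ``.`` decimal)
with a leading ``#``-comment schema line emitted by every writer; trees are
single-tree Newick files. Validation is strict: duplicate identifiers,
negative counts, missing metadata values and row-sum violations are all
errors at read time, never silent fixes. Missing taxonomy ranks are the one
exception — they are normalized to the literal token ``"unassigned"`` so
that downstream agglomeration has deterministic bins.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

SCHEMA_VERSION = "phylosym-v1"

#: Fixed taxonomy rank order, finest last.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Sample metadata factor columns required by the sequential PERMANOVA.
METADATA_COLUMNS = (
    "host_species",
    "host_order",
    "host_class",
    "sample_type",
    "tissue_storage",
    "extraction_kit",
)

#: EltonTraits-style diet categories (percentages, row sum 100).
DIET_CATEGORIES = (
    "inv",
    "vend",
    "vect",
    "vfish",
    "vunk",
    "scav",
    "fruit",
    "nect",
    "seed",
    "planto",
)

UNASSIGNED = "unassigned"

KINGDOMS = ("fungi", "bacteria")


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


class SchemaError(ValidationError):
    """A file does not match the documented column schema."""


class FormatError(ValueError):
    """A file cannot be parsed at all."""


def _check_unique(values, what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for v in values:
        if v in seen and v not in dups:
            dups.append(v)
        seen.add(v)
    if dups:
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dups))}")


@dataclass(frozen=True)
class FeatureTable:
    """Non-negative integer count matrix, features in rows, samples in columns."""

    counts: pd.DataFrame
    kingdom_label: str | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if not isinstance(counts, pd.DataFrame):
            raise ValidationError("counts must be a pandas DataFrame")
        _check_unique(counts.index, "feature IDs")
        _check_unique(counts.columns, "sample IDs")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if arr.size:
            if not np.all(np.isfinite(arr)):
                raise ValidationError("counts must be finite")
            if np.any(arr < 0):
                raise ValidationError("counts must be non-negative")
            if not np.all(arr == np.floor(arr)):
                raise ValidationError("counts must be integers")
        if arr.dtype != np.int64:
            counts = counts.astype(np.int64)
        # normalize axis names so round-trips compare equal
        counts = counts.rename_axis(index="feature_id", columns=None)
        object.__setattr__(self, "counts", counts)
        if self.kingdom_label is not None and self.kingdom_label not in KINGDOMS:
            raise ValidationError(
                f"kingdom_label must be one of {KINGDOMS}, got {self.kingdom_label!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids) -> "FeatureTable":
        """Explicit sample filter (the pipeline never drops samples silently)."""
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"samples not in table: {', '.join(missing)}")
        return FeatureTable(self.counts.loc[:, list(sample_ids)], self.kingdom_label)

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class TaxonomyTable:
    """Per-feature ranked lineage (kingdom..genus), missing ranks = 'unassigned'."""

    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.lineages
        if list(df.columns) != list(RANKS):
            raise SchemaError(f"taxonomy columns must be exactly {RANKS}, got {list(df.columns)}")
        _check_unique(df.index, "feature IDs")
        cleaned = df.astype("string")
        stripped = cleaned.apply(lambda s: s.str.strip())
        cleaned = cleaned.where(cleaned.notna() & (stripped != ""), UNASSIGNED)
        object.__setattr__(self, "lineages", cleaned.astype(str))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.lineages.index)

    def rank_labels(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}")
        return self.lineages[rank]


@dataclass(frozen=True)
class SampleMetadata:
    """One row per sample; six complete categorical factor columns."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"metadata missing required columns: {', '.join(missing_cols)}")
        _check_unique(df.index, "sample IDs")
        sub = df[list(METADATA_COLUMNS)].astype("string")
        bad = sub.isna() | (sub.apply(lambda s: s.str.strip()) == "")
        if bad.to_numpy().any():
            rows = df.index[bad.any(axis=1)]
            raise ValidationError(
                f"metadata has missing factor values for samples: {', '.join(map(str, rows))}"
            )
        object.__setattr__(self, "frame", df[list(METADATA_COLUMNS)].astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def species_of(self, sample_ids=None) -> pd.Series:
        if sample_ids is None:
            return self.frame["host_species"]
        return self.frame.loc[list(sample_ids), "host_species"]


@dataclass(frozen=True)
class DietTable:
    """Per-species diet proportions over the 10 categories, summing to 100."""

    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.proportions
        if list(df.columns) != list(DIET_CATEGORIES):
            raise SchemaError(
                f"diet columns must be exactly {DIET_CATEGORIES}, got {list(df.columns)}"
            )
        _check_unique(df.index, "species")
        arr = df.to_numpy(dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 100):
            raise ValidationError("diet proportions must be finite and in [0, 100]")
        sums = arr.sum(axis=1)
        bad = np.abs(sums - 100.0) > 0.5
        if np.any(bad):
            offenders = [f"{sp} (sum {s:.2f})" for sp, s in zip(df.index[bad], sums[bad])]
            raise ValidationError(f"diet rows must sum to 100 +/- 0.5: {', '.join(offenders)}")
        object.__setattr__(self, "proportions", df.astype(float))

    @property
    def species(self) -> list[str]:
        return list(self.proportions.index)


# A host tree is a rooted skbio TreeNode with unique tips and non-negative
# branch lengths, validated at read/construction time (see validate_host_tree).
HostTree = TreeNode


def validate_host_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if any(t is None for t in tips):
        raise ValidationError("tree has unnamed tips")
    _check_unique(tips, "tree tips")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    return tree


def tree_depth(tree: TreeNode) -> float:
    """Maximum root-to-tip path length."""
    return max(_root_to_tip(tree, tip) for tip in tree.tips())


def _root_to_tip(tree: TreeNode, tip: TreeNode) -> float:
    d = 0.0
    node = tip
    while node is not tree:
        d += node.length or 0.0
        node = node.parent
    return d


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: no content")
    header = lines[0].rstrip("\n").split("\t")
    _check_unique(header[1:], "sample/column IDs in header")
    return pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0, dtype=str)


def _comment(kind: str, **extra) -> str:
    items = [SCHEMA_VERSION, kind] + [f"{k}={v}" for k, v in extra.items() if v is not None]
    return "# " + "\t".join(items) + "\n"


def read_feature_table(path, kingdom_label: str | None = None) -> FeatureTable:
    """Read a features-in-rows integer TSV count table.

    The first column holds feature IDs, the header row sample IDs. A
    ``kingdom=`` token in the schema comment (as emitted by
    :func:`write_feature_table`) supplies ``kingdom_label`` when the caller
    does not.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if kingdom_label is None and first.startswith("#"):
        for tok in first[1:].strip().split("\t"):
            if tok.startswith("kingdom="):
                val = tok.split("=", 1)[1]
                kingdom_label = val if val != "None" else None
    df = _read_tsv(path)
    _check_unique(df.index, "feature IDs")
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer cell at row {df.index[i]!r}, column {col!r}: {raw!r}"
                ) from None
            if val < 0:
                raise FormatError(
                    f"{path}: negative count at row {df.index[i]!r}, column {col!r}: {val}"
                )
            parsed.iloc[i, j] = val
    return FeatureTable(parsed, kingdom_label)


def write_feature_table(table: FeatureTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment("feature_table", kingdom=table.kingdom_label))
        table.counts.to_csv(fh, sep="\t", index_label="feature_id", lineterminator="\n")


def read_taxonomy(path) -> TaxonomyTable:
    df = _read_tsv(path)
    missing = [c for c in RANKS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: taxonomy missing columns: {', '.join(missing)}")
    return TaxonomyTable(df[list(RANKS)])


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment("taxonomy"))
        tax.lineages.to_csv(fh, sep="\t", index_label="feature_id", lineterminator="\n")


def read_metadata(path) -> SampleMetadata:
    df = _read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: metadata missing columns: {', '.join(missing)}")
    return SampleMetadata(df)


def write_metadata(md: SampleMetadata, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment("metadata"))
        md.frame.to_csv(fh, sep="\t", index_label="sample_id", lineterminator="\n")


def read_diet(path) -> DietTable:
    df = _read_tsv(path)
    missing = [c for c in DIET_CATEGORIES if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: diet table missing columns: {', '.join(missing)}")
    return DietTable(df[list(DIET_CATEGORIES)].astype(float))


def write_diet(diet: DietTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment("diet"))
        diet.proportions.to_csv(fh, sep="\t", index_label="species", lineterminator="\n")


def read_newick(path) -> HostTree:
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"{path}: cannot parse Newick: {exc}") from None
    return validate_host_tree(tree)


def write_newick(tree: HostTree, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# cross-object alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentReport:
    samples_missing_metadata: list[str] = field(default_factory=list)
    features_missing_taxonomy: list[str] = field(default_factory=list)
    extra_metadata_samples: list[str] = field(default_factory=list)
    extra_taxonomy_features: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.samples_missing_metadata and not self.features_missing_taxonomy


def validate_alignment(
    table: FeatureTable,
    metadata: SampleMetadata | None = None,
    taxonomy: TaxonomyTable | None = None,
    strict: bool = True,
) -> AlignmentReport:
    """Check table sample IDs against metadata and feature IDs against taxonomy.

    Samples present in the table but absent from the metadata (or features
    absent from the taxonomy) are an error under ``strict``; the report
    carries the set differences either way.
    """
    report = AlignmentReport()
    if metadata is not None:
        md_ids = set(metadata.sample_ids)
        tb_ids = set(table.sample_ids)
        report.samples_missing_metadata = sorted(tb_ids - md_ids)
        report.extra_metadata_samples = sorted(md_ids - tb_ids)
    if taxonomy is not None:
        tax_ids = set(taxonomy.feature_ids)
        ft_ids = set(table.feature_ids)
        report.features_missing_taxonomy = sorted(ft_ids - tax_ids)
        report.extra_taxonomy_features = sorted(tax_ids - ft_ids)
    if strict and not report.ok:
        parts = []
        if report.samples_missing_metadata:
            parts.append(
                "samples without metadata: " + ", ".join(report.samples_missing_metadata)
            )
        if report.features_missing_taxonomy:
            parts.append(
                "features without taxonomy: " + ", ".join(report.features_missing_taxonomy)
            )
        raise ValidationError("; ".join(parts))
    return report
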