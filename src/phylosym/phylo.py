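"""Host-tree computations: patristic distances, sample grafting and
phylogenetic-signal testing.

The signal statistic is a Moran-type autocorrelation of a standardized
tip trait under the Abouheif proximity matrix. The proximity between two
tips is the reciprocal of the product of the numbers of direct descendants
of the interior nodes on the path joining them (including their most recent
common ancestor); rows are then normalized to sum to one off-diagonal, so
the permutation-null expectation is -1/(n-1).

Worked 4-tip example for the pectinate tree ``(((a,b),c),d)``: the path
a-b crosses one binary node so A(a,b) = 1/2; a-c crosses two, A(a,c) = 1/4;
a-d crosses all three, A(a,d) = 1/8. Row-normalizing the row of ``a``
(sum 7/8) gives weights 4/7, 2/7, 1/7 for b, c, d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .io_formats import HostTree, ValidationError, tree_depth, validate_host_tree


@dataclass(frozen=True)
class SignalTestResult:
    trait: str
    cmean: float
    p_raw: float
    p_bh: float | None
    n_perm: int
    seed: int
    n_tips: int


def patristic_distance(tree: HostTree) -> DistanceMatrix:
    """Sum of branch lengths on the path between every pair of tips."""
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValidationError("patristic distances need at least 2 tips")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(f"branch length missing at node {node.name!r}")
    return tree.tip_tip_distances()


def graft_samples(
    tree: HostTree, sample_to_species: dict[str, str], epsilon: float | None = None
) -> HostTree:
    """Replace each species tip by a polytomy of its sample tips at length epsilon.

    Every sample hangs at distance ``epsilon`` below its species tip (also
    when a species has a single sample), so the grafted patristic matrix of
    any one-sample-per-species restriction equals the species matrix plus
    2*epsilon off-diagonal exactly. Species without samples are pruned.
    """
    if epsilon is None:
        epsilon = 1e-6 * tree_depth(tree)
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    species_samples: dict[str, list[str]] = {}
    for sample, species in sample_to_species.items():
        species_samples.setdefault(species, []).append(sample)
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(set(species_samples) - tip_names)
    if missing:
        raise ValidationError(f"species not in tree: {', '.join(missing)}")
    grafted = tree.copy()
    for tip in list(grafted.tips()):
        samples = species_samples.get(tip.name)
        if samples is None:
            continue
        tip.name = None
        for sample in samples:
            tip.append(TreeNode(name=sample, length=epsilon))
    # prune species that received no samples
    keep = {s for samples in species_samples.values() for s in samples}
    grafted = grafted.shear(keep)
    grafted.prune()
    return validate_host_tree(grafted)


def abouheif_proximity(tree: HostTree) -> tuple[np.ndarray, list[str]]:
    """Row-normalized Abouheif proximity matrix and its tip order."""
    tips = list(tree.tips())
    names = [t.name for t in tips]
    n = len(tips)
    if n < 3:
        raise ValidationError("Abouheif proximity needs at least 3 tips")
    # ancestor chains (tip excluded, root included)
    chains = []
    for tip in tips:
        chain = []
        node = tip.parent
        while node is not None:
            chain.append(node)
            node = node.parent
        chains.append(chain)
    a = np.zeros((n, n))
    for i in range(n):
        anc_i = {id(node): k for k, node in enumerate(chains[i])}
        for j in range(i + 1, n):
            # interior nodes on the path = nodes below the MRCA on either
            # side, plus the MRCA itself
            prod = 1.0
            mrca_rank = None
            for node in chains[j]:
                if id(node) in anc_i:
                    mrca_rank = anc_i[id(node)]
                    prod *= len(node.children)
                    break
                prod *= len(node.children)
            for node in chains[i][:mrca_rank]:
                prod *= len(node.children)
            a[i, j] = a[j, i] = 1.0 / prod
    a /= a.sum(axis=1, keepdims=True)
    return a, names


def abouheif_cmean(trait: pd.Series, tree: HostTree) -> float:
    """Moran-type autocorrelation of the trait under the Abouheif proximity."""
    a, names = abouheif_proximity(tree)
    missing = [t for t in names if t not in trait.index]
    if missing:
        raise ValidationError(f"trait missing for tips: {', '.join(missing)}")
    x = trait.loc[names].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("trait has non-finite values")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValidationError("trait has zero variance")
    x = x / np.sqrt(denom / len(x))
    return float(x @ a @ x) / float(x @ x)


def abouheif_test(
    trait: pd.Series,
    tree: HostTree,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    trait_name: str | None = None,
) -> SignalTestResult:
    """Permutation test of Abouheif's Cmean (trait shuffled across tips).

    One-tailed for positive autocorrelation by default, since phylosymbiosis
    predicts positive signal; ``alternative="two-sided"`` is available.
    p = (b + 1) / (n_perm + 1), so p = 0 is impossible.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")
    a, names = abouheif_proximity(tree)
    missing = [t for t in names if t not in trait.index]
    if missing:
        raise ValidationError(f"trait missing for tips: {', '.join(missing)}")
    x = trait.loc[names].to_numpy(dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValidationError("trait has zero variance")
    observed = float(x @ a @ x) / denom
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(len(x)) for _ in range(n_perm)])
    xp = x[perms]  # (n_perm, n)
    nulls = np.einsum("ij,jk,ik->i", xp, a, xp) / denom
    if alternative == "greater":
        b = int(np.sum(nulls >= observed))
    else:
        b = int(np.sum(np.abs(nulls) >= abs(observed)))
    p = (b + 1) / (n_perm + 1)
    return SignalTestResult(
        trait=trait_name or (trait.name or "trait"),
        cmean=observed,
        p_raw=p,
        p_bh=None,
        n_perm=n_perm,
        seed=seed,
        n_tips=len(x),
    )


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def signal_test_table(results: list[SignalTestResult]) -> pd.DataFrame:
    """Assemble test results into a table with BH-corrected p-values."""
    p_bh = bh_correct([r.p_raw for r in results])
    return pd.DataFrame(
        {
            "trait": [r.trait for r in results],
            "cmean": [r.cmean for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_bh": p_bh,
            "n_perm": [r.n_perm for r in results],
            "seed": [r.seed for r in results],
            "n_tips": [r.n_tips for r in results],
        }
    ).set_index("trait")
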