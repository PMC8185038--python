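"""Phenotype diversity: Faith PD and weighted UniFrac over carriers.

Phenotype Alpha Diversity (PAD) is the Faith phylogenetic diversity of
a sample's sub-community of phenotype carriers (ASVs with PI above a
threshold, default 0.6, abundances renormalised to 1).  Phenotype Beta
Diversity (PBD) is the weighted UniFrac distance between such carrier
sub-communities, and rPBD relates the intragroup mean PBD to the
intragroup mean total beta diversity.

Faith PD and weighted UniFrac are computed with scikit-bio (Faith PD
root-inclusive, UniFrac unnormalised by default); trees are rooted at
the midpoint of their longest tip-to-tip path.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .indices import PhenotypeProfile
from .reference import ASVTable

DEFAULT_CARRIER_THRESHOLD = 0.6


def read_tree(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def parse_tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), format="newick")


def total_branch_length(tree: TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse() if not n.is_root())


def tip_names(tree: TreeNode) -> list[str]:
    return [t.name for t in tree.tips()]


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest tip-to-tip path.

    Total branch length is conserved.  The two-tip tree is handled
    directly (the root splits the single path into equal halves).
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("midpoint rooting needs at least 2 tips")
    if total_branch_length(tree) <= 0:
        raise ValueError("tree has zero total branch length")
    if len(tips) == 2:
        half = sum(t.length or 0.0 for t in tips) / 2.0
        a = TreeNode(name=tips[0].name, length=half)
        b = TreeNode(name=tips[1].name, length=half)
        return TreeNode(children=[a, b])
    return tree.root_at_midpoint()


def prune_to(tree: TreeNode, keep: set[str]) -> TreeNode:
    """Subtree spanning ``keep`` (robust to tips absent from tables)."""
    return tree.shear(sorted(keep))


def faith_pd(tree: TreeNode, observed: set[str]) -> float:
    """Faith phylogenetic diversity of the observed tip set.

    Sum of branch lengths on the union of root-to-tip paths; an empty
    set yields 0 with a warning.
    """
    if not observed:
        warnings.warn("Faith PD of an empty tip set is 0")
        return 0.0
    taxa = tip_names(tree)
    missing = observed - set(taxa)
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)[:3]}")
    counts = [1 if t in observed else 0 for t in taxa]
    return float(_skbio_faith_pd(counts, taxa=taxa, tree=tree))


def weighted_unifrac(
    tree: TreeNode,
    x: Mapping[str, float],
    y: Mapping[str, float],
    normalized: bool = False,
) -> float:
    """Weighted UniFrac distance between two abundance vectors.

    Unnormalised by default: sum over branches of branch length times
    the absolute difference in descendant abundance fraction; the
    normalised variant divides by the abundance-weighted sum of
    root-to-tip depths.  Computed by exact postorder accumulation on
    float abundances (no count quantisation), with each vector scaled
    to proportions first.
    """
    tipset = set(tip_names(tree))
    for vec in (x, y):
        extra = set(vec) - tipset
        if extra:
            raise ValueError(f"abundance on unknown tips: {sorted(extra)[:3]}")
    xs = sum(x.values())
    ys = sum(y.values())
    if xs <= 0 or ys <= 0:
        raise ValueError("abundance vectors must have positive total")

    dist = 0.0
    denom = 0.0
    masses: dict[int, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_tip():
            m = (x.get(node.name, 0.0) / xs, y.get(node.name, 0.0) / ys)
        else:
            xm = ym = 0.0
            for child in node.children:
                cm = masses.pop(id(child))
                xm += cm[0]
                ym += cm[1]
            m = (xm, ym)
        masses[id(node)] = m
        if not node.is_root():
            dist += (node.length or 0.0) * abs(m[0] - m[1])
    if not normalized:
        return dist
    for tip in tree.tips():
        depth = tip.accumulate_to_ancestor(tree)
        denom += depth * (
            x.get(tip.name, 0.0) / xs + y.get(tip.name, 0.0) / ys
        )
    return dist / denom if denom > 0 else 0.0


@dataclass
class CarrierSubcommunity:
    """Per-sample carrier ASVs with renormalised abundances."""

    phenotype: str
    threshold: float
    abundances: dict[str, pd.Series]
    empty_samples: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.abundances)


def carrier_subcommunity(
    profile: PhenotypeProfile,
    table: ASVTable,
    phenotype: str,
    threshold: float = DEFAULT_CARRIER_THRESHOLD,
) -> CarrierSubcommunity:
    """Select ASVs with PI strictly above the threshold, per sample.

    Selected abundances are renormalised to sum 1 within each sample;
    samples with no carrier abundance are flagged empty.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    pi = profile.pi[phenotype]
    carriers = [a for a in pi.index if pi[a] > threshold]
    abundances: dict[str, pd.Series] = {}
    empty: list[str] = []
    for sample in table.samples:
        rel = table.relative.loc[
            [a for a in carriers if a in table.relative.index], sample
        ]
        rel = rel[rel > 0]
        if rel.empty or rel.sum() <= 0:
            empty.append(sample)
            continue
        abundances[sample] = rel / rel.sum()
    return CarrierSubcommunity(phenotype, threshold, abundances, empty)


def pad(sub: CarrierSubcommunity, tree: TreeNode) -> pd.Series:
    """Faith PD of each sample's carrier set (NaN for empty samples)."""
    out = {}
    for sample, rel in sub.abundances.items():
        out[sample] = faith_pd(tree, set(rel.index))
    for sample in sub.empty_samples:
        out[sample] = np.nan
    return pd.Series(out, name=f"pad_{sub.phenotype}")


def unifrac_matrix(
    abundances: Mapping[str, pd.Series],
    tree: TreeNode,
    normalized: bool = False,
) -> pd.DataFrame:
    """Symmetric pairwise weighted UniFrac matrix, zero diagonal."""
    samples = list(abundances)
    n = len(samples)
    mat = np.zeros((n, n))
    vecs = {s: abundances[s].to_dict() for s in samples}
    for i, j in itertools.combinations(range(n), 2):
        d = weighted_unifrac(
            tree, vecs[samples[i]], vecs[samples[j]], normalized=normalized
        )
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=samples, columns=samples)


def pbd_matrix(
    sub: CarrierSubcommunity, tree: TreeNode
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise PBD over samples with non-empty carrier sets.

    Returns the distance matrix and the list of excluded (empty)
    samples.
    """
    if len(sub.abundances) < 2:
        raise ValueError(
            f"phenotype '{sub.phenotype}': fewer than 2 samples with carriers"
        )
    if sub.empty_samples:
        warnings.warn(
            f"phenotype '{sub.phenotype}': {len(sub.empty_samples)} sample(s) "
            "without carriers excluded from PBD"
        )
    return unifrac_matrix(sub.abundances, tree), list(sub.empty_samples)


def intragroup_mean_distance(
    dm: pd.DataFrame, groups: Mapping[str, str]
) -> pd.Series:
    """Mean pairwise distance within each group (diagonal excluded)."""
    members: dict[str, list[str]] = {}
    for sample in dm.index:
        if sample in groups:
            members.setdefault(groups[sample], []).append(sample)
    out = {}
    for group, samples in members.items():
        if len(samples) < 2:
            warnings.warn(f"group '{group}' has fewer than 2 samples")
            out[group] = np.nan
            continue
        pairs = list(itertools.combinations(samples, 2))
        out[group] = float(np.mean([dm.at[a, b] for a, b in pairs]))
    return pd.Series(out, name="mean_pairwise_distance")


def relative_pbd(pbd_mean: float, bd_mean: float) -> float:
    """Intragroup mean PBD over intragroup mean total beta diversity.

    Values near 1 mean the carrier sub-communities are about as
    dissimilar across samples as the full communities; NaN when the
    total beta diversity mean is 0.
    """
    if not np.isfinite(bd_mean) or bd_mean == 0:
        return float("nan")
    return pbd_mean / bd_mean
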