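"""Ward minimum-variance clustering of individuals on quantitative traits.

Ward's method treats agglomeration as an analysis-of-variance problem:
starting from singletons, each step merges the pair of clusters whose union
least increases the total within-cluster sum of squares,

    dSS = (n_i n_j)/(n_i + n_j) * ||c_i - c_j||^2,

with c_i the cluster centroids.  Merge heights in the :class:`MergeTree` are
these dSS increments, so the heights over all n-1 merges sum exactly to the
total sum of squares of the data about its grand centroid — a conservation
law the tests verify.  Traits are z-scored before clustering by default:
trait SDs span three orders of magnitude and unscaled Ward would be dominated
by the largest-variance traits (yield, tree height).

Individuals with any missing quantitative trait are dropped with a warning
(complete-case analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .exceptions import InsufficientDataError, ZeroVarianceError
from .schema_io import PhenotypeMatrix, TraitSchema


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float  # dSS: the within-cluster SS increase of this merge
    size: int


@dataclass
class MergeTree:
    """Agglomeration schedule.  Leaves are 0..n-1; merge i creates node n+i."""

    n_leaves: int
    merges: list[Merge]

    def to_linkage(self) -> np.ndarray:
        """Scipy linkage array (heights on scipy's Ward distance scale
        d = sqrt(2*dSS)) for dendrogram/cut interop."""
        Z = np.zeros((len(self.merges), 4))
        for i, m in enumerate(self.merges):
            Z[i] = [m.left, m.right, np.sqrt(2.0 * m.height), m.size]
        return Z

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])


def standardize(block: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """z-score columns (mean 0, sample SD 1); raises on zero-variance columns."""
    values = np.asarray(block, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    if not (sd > 0).all():
        bad = np.where(~(sd > 0))[0]
        names = (
            [block.columns[i] for i in bad] if isinstance(block, pd.DataFrame) else list(bad)
        )
        raise ZeroVarianceError(f"zero-SD column(s): {names}")
    z = (values - mean) / sd
    if isinstance(block, pd.DataFrame):
        return pd.DataFrame(z, index=block.index, columns=block.columns)
    return z


def ward_linkage(points: pd.DataFrame | np.ndarray) -> MergeTree:
    """Full Ward agglomeration schedule of the rows of ``points``."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise InsufficientDataError(f"need >= 2 individuals to cluster, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values; use complete cases")
    Z = hierarchy.linkage(X, method="ward")
    merges = [
        Merge(left=int(a), right=int(b), height=float(d) ** 2 / 2.0, size=int(s))
        for a, b, d, s in Z
    ]
    return MergeTree(n_leaves=n, merges=merges)


def cut_tree(tree: MergeTree, k: int) -> np.ndarray:
    """Partition into k groups by undoing the last k-1 merges.

    Groups are labeled 1..k in decreasing size order (ties broken by the
    smallest member index).
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.cut_tree(tree.to_linkage(), n_clusters=k).ravel()
    order = sorted(
        np.unique(raw),
        key=lambda g: (-(raw == g).sum(), int(np.argmax(raw == g))),
    )
    relabel = {g: i + 1 for i, g in enumerate(order)}
    return np.array([relabel[g] for g in raw], dtype=int)


@dataclass
class GroupProfile:
    group: int
    count: int
    means: pd.Series
    deviations: pd.Series  # (group mean - overall mean) / overall sample SD
    salient: list[tuple[str, str]]  # (trait, "higher"|"lower")


def group_profiles(
    block: pd.DataFrame,
    assignments: np.ndarray,
    threshold: float = 0.5,
) -> list[GroupProfile]:
    """Characterize each group by its trait means and SD-unit deviations from
    the overall mean; traits with |deviation| >= ``threshold`` are salient."""
    assignments = np.asarray(assignments)
    if len(assignments) != len(block):
        raise ValueError("assignments must cover all individuals")
    overall_mean = block.mean(axis=0)
    overall_sd = block.std(axis=0, ddof=1)
    profiles = []
    for g in sorted(np.unique(assignments)):
        members = block.loc[np.asarray(assignments == g)]
        if members.empty:
            raise ValueError(f"group {g} is empty")
        means = members.mean(axis=0)
        dev = (means - overall_mean) / overall_sd
        salient = [
            (trait, "higher" if dev[trait] > 0 else "lower")
            for trait in block.columns
            if abs(dev[trait]) >= threshold
        ]
        profiles.append(
            GroupProfile(
                group=int(g), count=len(members), means=means, deviations=dev, salient=salient
            )
        )
    return profiles


def cluster_matrix(
    matrix: PhenotypeMatrix,
    k: int = 4,
    standardize_traits: bool = True,
) -> tuple[MergeTree, np.ndarray, list[GroupProfile], pd.DataFrame]:
    """Complete-case Ward clustering of a phenotype matrix.

    Returns (tree, group assignments, group profiles, the complete-case
    quantitative block used).  Profiles are computed on the original trait
    scales regardless of standardization.
    """
    block = matrix.quantitative_block(complete_cases=True)
    dropped = matrix.n_individuals - len(block)
    if dropped:
        warnings.warn(
            f"{dropped} individual(s) with missing quantitative traits dropped "
            "before clustering",
            stacklevel=2,
        )
    points = standardize(block) if standardize_traits else block
    tree = ward_linkage(points)
    assignments = cut_tree(tree, k)
    profiles = group_profiles(block, assignments)
    return tree, assignments, profiles, block


def export_newick(tree: MergeTree, ids: list[str] | None = None) -> str:
    """Rooted binary Newick string; each child branch spans half the height
    difference to its parent (midpoint convention), so leaf-to-root path
    lengths equal half the root height."""
    n = tree.n_leaves
    if ids is None:
        ids = [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids length must equal number of leaves")
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for i, m in enumerate(tree.merges):
        node = n + i
        height[node] = m.height
        children[node] = (m.left, m.right)

    def render(node: int, parent_height: float) -> str:
        branch = (parent_height - height[node]) / 2.0
        if node < n:
            label = ids[node].replace(" ", "_")
            return f"{label}:{branch:.6g}"
        left, right = children[node]
        inner = f"({render(left, height[node])},{render(right, height[node])})"
        return f"{inner}:{branch:.6g}" if parent_height != height[node] else inner

    root = n + len(tree.merges) - 1
    return render(root, height[root]) + ";"
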