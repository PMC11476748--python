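"""Nei's standard genetic distance and UPGMA dendrogram construction.

Nei's standard distance between two units (single accessions or
populations) is computed over the loci scored in both units::

    Jxy = mean_l sum_i x_i y_i     Jx = mean_l sum_i x_i^2
    Jy  = mean_l sum_i y_i^2       D  = -ln( Jxy / sqrt(Jx * Jy) )

For a single diploid accession the "frequencies" are 0, 0.5 or 1 from
its two allele copies.  ``D`` is 0 for identical frequency vectors and
+infinity when the units share no allele at any commonly scored locus.

UPGMA (average linkage) is implemented with a deterministic tie-break —
among equally close pairs, the pair whose clusters carry the
lexicographically smallest leaf labels merges first — so the tree is a
pure function of the distance matrix.  Node height is merge distance / 2
and the result is exactly ultrametric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "TreeNode",
    "IncomparableUnitsError",
    "nei_standard_distance",
    "pairwise_distances",
    "upgma",
    "to_newick",
]


class IncomparableUnitsError(ValueError):
    """Two units share no commonly scored locus: no distance is defined."""


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(
            self.values[self.labels.index(a), self.labels.index(b)]
        )


def _unit_frequencies(
    matrix: GenotypeMatrix, unit: str, level: str
) -> list[dict[int, float] | None]:
    """Per-locus allele frequency dicts for one unit; None where unscored."""
    if level == "accession":
        members = [unit]
    elif level == "population":
        members = matrix.samples_in_population(unit)
        if not members:
            raise ValueError(f"unknown population {unit!r}")
    else:
        raise ValueError("level must be 'accession' or 'population'")
    idx = [matrix.sample_index(s) for s in members]
    out: list[dict[int, float] | None] = []
    for j in range(matrix.n_loci):
        counts: dict[int, int] = {}
        for i in idx:
            a, b = matrix.calls[i, j]
            if a == 0:
                continue
            counts[int(a)] = counts.get(int(a), 0) + 1
            counts[int(b)] = counts.get(int(b), 0) + 1
        n = sum(counts.values())
        out.append({al: c / n for al, c in counts.items()} if n else None)
    return out


def _nei_from_freqs(
    fx: list[dict[int, float] | None], fy: list[dict[int, float] | None]
) -> float:
    jxy = jx = jy = 0.0
    shared = 0
    for px, py in zip(fx, fy):
        if px is None or py is None:
            continue  # pairwise deletion of loci unscored in either unit
        shared += 1
        jx += sum(p * p for p in px.values())
        jy += sum(p * p for p in py.values())
        jxy += sum(p * py.get(al, 0.0) for al, p in px.items())
    if shared == 0:
        raise IncomparableUnitsError(
            "no commonly scored locus; distance undefined (not infinite)"
        )
    if jxy == 0.0:
        return math.inf
    return max(0.0, -math.log(jxy / math.sqrt(jx * jy)))


def nei_standard_distance(
    matrix: GenotypeMatrix,
    unit_a: str,
    unit_b: str,
    level: str = "accession",
) -> float:
    """Nei (1972) standard distance between two accessions or populations."""
    return _nei_from_freqs(
        _unit_frequencies(matrix, unit_a, level),
        _unit_frequencies(matrix, unit_b, level),
    )


def pairwise_distances(
    matrix: GenotypeMatrix, level: str = "accession"
) -> DistanceMatrix:
    """Full symmetric Nei-distance matrix.

    Infinite entries (no shared alleles) are capped at one more than the
    largest finite entry, with a warning, so that UPGMA stays defined.
    """
    labels = (
        list(matrix.sample_ids)
        if level == "accession"
        else matrix.population_labels()
    )
    freqs = [_unit_frequencies(matrix, u, level) for u in labels]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _nei_from_freqs(freqs[i], freqs[j])
    if np.isinf(d).any():
        cap = float(d[np.isfinite(d)].max()) + 1.0
        warnings.warn(
            f"{int(np.isinf(d).sum() // 2)} infinite distance(s) capped "
            f"at {cap:g} (max finite + 1)",
            stacklevel=2,
        )
        d[np.isinf(d)] = cap
    return DistanceMatrix(tuple(labels), d)


# -- UPGMA -----------------------------------------------------------------


@dataclass(frozen=True)
class TreeNode:
    """Rooted (sub)tree; leaves have height 0 and a label."""

    height: float
    label: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return [x for c in self.children for x in c.leaf_labels()]


@dataclass(frozen=True)
class Dendrogram:
    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    def cophenetic(self, a: str, b: str) -> float:
        """Twice the height of the lowest node containing both leaves."""

        def walk(node: TreeNode) -> float | None:
            if node.is_leaf:
                return None
            for c in node.children:
                got = walk(c)
                if got is not None:
                    return got
            leaves = set(node.leaf_labels())
            if a in leaves and b in leaves:
                return 2.0 * node.height
            return None

        if a == b:
            return 0.0
        got = walk(self.root)
        if got is None:
            raise KeyError((a, b))
        return got


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration; node height = merge distance / 2.

    Ties are resolved deterministically: among pairs at the minimal
    distance, merge the one whose two clusters have the lexicographically
    smallest (sorted) pair of minimal leaf labels.
    """
    if len(dist.labels) < 2:
        raise ValueError("need at least two units")
    if not np.isfinite(dist.values).all():
        raise ValueError("UPGMA requires finite distances")
    nodes = [TreeNode(0.0, label=l) for l in dist.labels]
    sizes = [1] * len(nodes)
    mins = [l for l in dist.labels]  # min leaf label per live cluster
    d = dist.values.astype(float).copy()
    live = list(range(len(nodes)))
    while len(live) > 1:
        best = None
        for ii, i in enumerate(live):
            for j in live[ii + 1:]:
                key = (d[i, j], *sorted((mins[i], mins[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        h = d[i, j] / 2.0
        a, b = nodes[i], nodes[j]
        if min(b.leaf_labels()) < min(a.leaf_labels()):
            a, b = b, a
        merged = TreeNode(h, children=(a, b))
        # average-linkage update into slot i
        for k in live:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (
                sizes[i] * d[i, k] + sizes[j] * d[j, k]
            ) / (sizes[i] + sizes[j])
        nodes[i] = merged
        sizes[i] += sizes[j]
        mins[i] = min(mins[i], mins[j])
        live.remove(j)
    return Dendrogram(nodes[live[0]])


def _quote(label: str) -> str:
    if any(c in label for c in "()[]{}:;,'\" \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: Dendrogram) -> str:
    """Serialize with branch lengths; labels are quoted when needed."""

    def fmt(node: TreeNode, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{_quote(node.label)}:{bl:g}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{bl:g}"

    root = tree.root
    if root.is_leaf:
        return f"{_quote(root.label)};"
    inner = ",".join(fmt(c, root.height) for c in root.children)
    return f"({inner});"
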