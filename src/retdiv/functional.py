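"""Trait-space distances, UPGMA dendrograms, and functional richness.

Functional richness of a community is measured as the total branch length of
the subtree of an ultrametric trait dendrogram spanning the species present.
The dendrogram is built from three traits — mean body mass (g), diet guild,
and activity stratum — combined with Gower's mixed-type distance (range
normalised numeric difference for mass, 0/1 mismatch for the categorical
traits, equal weights) and clustered with UPGMA (average linkage), placing
each merge node at half the average distance so all tips sit at height 0.

The default functional-richness convention is root-inclusive (the spanning
subtree always contains the root); the unrooted minimal-span variant is
available via ``root_inclusive=False``.  Both give 0 for empty and singleton
communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DIET_GUILDS = ("carnivore", "insectivore", "granivore_mycophage")
ACTIVITY_STRATA = ("arboreal", "semi_arboreal", "ground", "fossorial")


@dataclass(frozen=True)
class TraitTable:
    """Species trait table: body mass (g), diet guild, activity stratum."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"species", "mass_g", "diet", "stratum"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"trait table missing columns: {sorted(missing)}")
        if self.table["species"].duplicated().any():
            raise ValueError("duplicate species in trait table")
        if (self.table["mass_g"] <= 0).any():
            raise ValueError("body mass must be positive")
        bad_diet = set(self.table["diet"]) - set(DIET_GUILDS)
        if bad_diet:
            raise ValueError(f"unknown diet guilds: {sorted(bad_diet)}")
        bad_str = set(self.table["stratum"]) - set(ACTIVITY_STRATA)
        if bad_str:
            raise ValueError(f"unknown activity strata: {sorted(bad_str)}")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.table["species"])

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = self.d
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")


@dataclass(frozen=True)
class Dendrogram:
    """Rooted ultrametric tree from agglomerative clustering.

    Nodes are indexed 0..n-1 for tips (in ``labels`` order, height 0) and
    n..2n-2 for internal nodes in merge order; the last node is the root.
    ``parent[v]`` is -1 for the root.  The branch above node ``v`` has length
    ``height[parent[v]] - height[v]``.
    """

    labels: tuple[str, ...]
    parent: np.ndarray
    height: np.ndarray
    children: Mapping[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return len(self.parent) - 1

    def branch_length(self, v: int) -> float:
        p = self.parent[v]
        return 0.0 if p < 0 else float(self.height[p] - self.height[v])

    @property
    def total_branch_length(self) -> float:
        return float(sum(self.branch_length(v) for v in range(len(self.parent))))

    def tip_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"species {label!r} not a tip of the dendrogram") from None

    def check_ultrametric(self, rtol: float = 1e-9) -> bool:
        """All tip-to-root path lengths equal the root height (within rtol)."""
        root_h = float(self.height[self.root])
        for t in range(self.n_tips):
            path = 0.0
            v = t
            while self.parent[v] >= 0:
                path += self.branch_length(v)
                v = self.parent[v]
            if abs(path - root_h) > rtol * max(root_h, 1.0):
                return False
        return True


def gower_matrix(
    traits: TraitTable, log_mass: bool = False
) -> DistanceMatrix:
    """Gower distance over (mass, diet, stratum) with equal trait weights.

    Mass contributes |m_i - m_j| / range(mass) with the range taken over the
    full trait table (not a community subset); diet and stratum contribute
    0/1 mismatches.  With ``log_mass`` the mass axis is log10-transformed
    first, which compresses the dominance of the largest-bodied species.
    If every species has identical mass the mass term contributes 0.
    """
    if len(traits) < 2:
        raise ValueError("Gower distance needs at least 2 species")
    df = traits.table
    mass = df["mass_g"].to_numpy(dtype=float)
    if log_mass:
        mass = np.log10(mass)
    rng = mass.max() - mass.min()
    if rng > 0:
        d_mass = np.abs(mass[:, None] - mass[None, :]) / rng
    else:
        d_mass = np.zeros((len(df), len(df)))
    diet = df["diet"].to_numpy()
    strat = df["stratum"].to_numpy()
    d_diet = (diet[:, None] != diet[None, :]).astype(float)
    d_strat = (strat[:, None] != strat[None, :]).astype(float)
    d = (d_mass + d_diet + d_strat) / 3.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=tuple(df["species"]), d=d)


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA (average-linkage) agglomeration of a distance matrix.

    Clusters merging at average distance ``h`` produce a node at height
    ``h/2``, so the tree is ultrametric with tips at height 0.  Ties in the
    minimum linkage are broken by the lexicographically lowest pair of
    cluster representative labels, making the topology deterministic.
    """
    n = len(dm.labels)
    if n == 1:
        return Dendrogram(
            labels=dm.labels, parent=np.array([-1]), height=np.zeros(1), children={}
        )
    d = dm.d.astype(float).copy()
    # active clusters: node id -> (size, representative label, row index in d)
    active: dict[int, tuple[int, str]] = {i: (1, dm.labels[i]) for i in range(n)}
    row_of = {i: i for i in range(n)}
    dist = {}
    ids = list(range(n))
    for a_pos in range(n):
        for b_pos in range(a_pos + 1, n):
            dist[(a_pos, b_pos)] = d[a_pos, b_pos]

    parent = np.full(2 * n - 1, -1, dtype=int)
    height = np.zeros(2 * n - 1, dtype=float)
    children: dict[int, tuple[int, int]] = {}

    next_id = n
    while len(ids) > 1:
        best = None
        for i_pos in range(len(ids)):
            for j_pos in range(i_pos + 1, len(ids)):
                a, b = ids[i_pos], ids[j_pos]
                key = (min(a, b), max(a, b))
                dd = dist[key]
                la, lb = active[a][1], active[b][1]
                tie_key = tuple(sorted((la, lb)))
                cand = (dd, tie_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dd, _, a, b = best
        sa, la = active[a]
        sb, lb = active[b]
        new = next_id
        next_id += 1
        parent[a] = new
        parent[b] = new
        height[new] = dd / 2.0
        children[new] = (a, b)
        # average-linkage update against all remaining clusters
        for c in ids:
            if c in (a, b):
                continue
            dca = dist[(min(a, c), max(a, c))]
            dcb = dist[(min(b, c), max(b, c))]
            dist[(min(new, c), max(new, c))] = (sa * dca + sb * dcb) / (sa + sb)
        ids = [c for c in ids if c not in (a, b)] + [new]
        active[new] = (sa + sb, min(la, lb))
        del active[a], active[b]

    return Dendrogram(labels=dm.labels, parent=parent, height=height, children=children)


def functional_richness(
    tree: Dendrogram, present: Iterable[str], root_inclusive: bool = True
) -> float:
    """Total branch length of the dendrogram subtree spanning ``present``.

    Root-inclusive (default): the subtree is the union of every present tip's
    path to the root.  With ``root_inclusive=False`` only the minimal subtree
    connecting the tips themselves is measured (edges above their most recent
    common ancestor are dropped).  Empty and singleton communities score 0 by
    convention.
    """
    present = set(present)
    if len(present) <= 1:
        for s in present:
            tree.tip_index(s)  # still validate membership
        return 0.0
    tips = [tree.tip_index(s) for s in present]
    on_path: set[int] = set()
    for t in tips:
        v = t
        while v != tree.root and v not in on_path:
            on_path.add(v)
            v = int(tree.parent[v])
    if root_inclusive:
        return float(sum(tree.branch_length(v) for v in on_path))
    # drop edges above the MRCA: nodes whose path to root is shared by all tips
    counts: dict[int, int] = {}
    for t in tips:
        v = t
        while v != tree.root:
            counts[v] = counts.get(v, 0) + 1
            v = int(tree.parent[v])
    # MRCA: deepest node on every tip's root path (or the root itself)
    v = tips[0]
    while v != tree.root and counts.get(v, 0) < len(tips):
        v = int(tree.parent[v])
    mrca = v
    # keep only edges strictly below the MRCA
    total = 0.0
    for w in on_path:
        if _below(tree, w, mrca):
            total += tree.branch_length(w)
    return float(total)


def _below(tree: Dendrogram, v: int, anc: int) -> bool:
    """True when ``v`` is a strict descendant of ``anc``."""
    if v == anc:
        return False
    while v != tree.root:
        v = int(tree.parent[v])
        if v == anc:
            return True
    return False


def to_newick(tree: Dendrogram) -> str:
    """Serialise the dendrogram as a Newick string with branch lengths.

    Single-tip trees render as ``A:0.0;``.  Branch lengths use full float
    precision so the string round-trips exactly through standard parsers.
    """
    if tree.n_tips == 1:
        return f"{tree.labels[0]}:0.0;"

    def render(v: int) -> str:
        if v < tree.n_tips:
            body = tree.labels[v]
        else:
            a, b = tree.children[v]
            body = f"({render(a)},{render(b)})"
        if v == tree.root:
            return body
        return f"{body}:{tree.branch_length(v)!r}"

    return render(tree.root) + ";"
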