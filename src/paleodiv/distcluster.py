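"""Assemblage dissimilarities and stratigraphically constrained clustering.

Pairwise faunal distances between stratigraphic units are measured with
a corrected Forbes similarity,

    F = a(n + sqrt(n)) / [ a(n + sqrt(n)) + (3/2) b c ],    n = a + b + c,

where a is the number of taxa shared by the two units and b, c the
numbers unique to each (double absences are ignored).  The distance is
D = 1 - F.  Because uneven relative-abundance distributions bias
presence-based comparisons under incomplete sampling, an evenness
standardisation is applied first: both units are subsampled to the same
number of specimens, the subsamples are reduced to presence sets, and
the Forbes distance is averaged over many such draws.

Zone redefinition uses constrained incremental sum-of-squares
clustering (CONISS-style): agglomerative clustering in which only
stratigraphically adjacent clusters may merge, choosing at each step
the merge with the smallest Ward-type dispersion increment computed
from squared dissimilarities via the Lance-Williams recurrence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import BinningScheme, TimeBin
from .occurrence import SpecimenOccurrenceTable, StratigraphicUnit

__all__ = [
    "PairwiseComparison",
    "DissimilarityMatrix",
    "ClusterDendrogram",
    "forbes_corrected",
    "rac_corrected_distance",
    "distance_matrix",
    "coniss",
    "redefine_zones",
]


@dataclass(frozen=True)
class PairwiseComparison:
    """Shared/unique taxon counts and corrected Forbes similarity for a
    pair of presence sets."""

    a: int  # shared
    b: int  # only in first
    c: int  # only in second
    similarity: float

    @property
    def n(self) -> int:
        return self.a + self.b + self.c

    @property
    def distance(self) -> float:
        return 1.0 - self.similarity


def forbes_corrected(first: set, second: set) -> PairwiseComparison:
    """Corrected Forbes similarity between two presence sets.

    Endpoints are forced: identical non-empty sets give F = 1, sets
    sharing no taxon give F = 0.  Two empty sets are undefined.
    """
    first, second = set(first), set(second)
    a = len(first & second)
    b = len(first - second)
    c = len(second - first)
    n = a + b + c
    if n == 0:
        raise ValueError("Forbes similarity is undefined for two empty sets")
    if a == 0:
        return PairwiseComparison(a, b, c, 0.0)
    core = a * (n + np.sqrt(n))
    sim = core / (core + 1.5 * b * c)
    return PairwiseComparison(a, b, c, float(sim))


def rac_corrected_distance(
    first: Sequence[int],
    second: Sequence[int],
    replicates: int = 1000,
    seed: int = 0,
    cap: int = 1000,
) -> float:
    """Evenness-standardised Forbes distance between two abundance vectors.

    For each replicate, m = min(total_first, total_second, cap)
    specimens are drawn without replacement from each unit's abundance
    vector; each draw is reduced to a presence set and the corrected
    Forbes distance computed; the mean distance over replicates is
    returned.  This standardises the relative-abundance evenness of the
    two assemblages before comparison.

    With m < 2 the comparison is unreliable and a warning is emitted.
    """
    x = np.asarray(first, dtype=int)
    y = np.asarray(second, dtype=int)
    if x.sum() < 1 or y.sum() < 1:
        raise ValueError("both abundance vectors need a positive total")
    m = int(min(x.sum(), y.sum(), cap))
    if m < 2:
        warnings.warn(
            f"evenness standardisation with m={m} specimens is unreliable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    draws_x = rng.multivariate_hypergeometric(x, m, size=replicates)
    draws_y = rng.multivariate_hypergeometric(y, m, size=replicates)
    px = draws_x > 0
    py = draws_y > 0
    a = (px & py).sum(axis=1)
    b = (px & ~py).sum(axis=1)
    c = (~px & py).sum(axis=1)
    n = a + b + c
    core = a * (n + np.sqrt(n))
    with np.errstate(invalid="ignore"):
        sim = np.where(a == 0, 0.0, core / (core + 1.5 * b * c))
    return float(np.mean(1.0 - sim))


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square and match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "unit"
        frame.to_csv(path)


def distance_matrix(
    table: SpecimenOccurrenceTable,
    method: str = "forbes_rac",
    replicates: int = 1000,
    seed: int = 0,
    cap: int = 1000,
) -> DissimilarityMatrix:
    """All-pairs unit dissimilarities.

    ``forbes_rac`` (default) applies the evenness standardisation
    before the Forbes comparison, matching the pipeline's intended
    order (abundance correction first); ``forbes`` uses raw incidence.
    """
    labels = table.unit_names
    n = len(labels)
    values = np.zeros((n, n))
    counts = table.counts.to_numpy()
    presence = counts > 0
    for i in range(n):
        for j in range(i + 1, n):
            if method == "forbes_rac":
                d = rac_corrected_distance(
                    counts[:, i],
                    counts[:, j],
                    replicates=replicates,
                    seed=int(np.random.SeedSequence(entropy=[seed, i, j]).generate_state(1)[0] % (2**31)),
                    cap=cap,
                )
            elif method == "forbes":
                si = {t for t, p in zip(table.taxa, presence[:, i]) if p}
                sj = {t for t, p in zip(table.taxa, presence[:, j]) if p}
                d = forbes_corrected(si, sj).distance
            else:
                raise ValueError(f"unknown distance method {method!r}")
            values[i, j] = values[j, i] = d
    return DissimilarityMatrix(labels=labels, values=values)


@dataclass(frozen=True)
class Merge:
    """One agglomeration step.  ``left`` and ``right`` are node ids:
    0..n-1 are leaves in stratigraphic order, n+k is the cluster formed
    at step k."""

    left: int
    right: int
    increment: float
    height: float  # cumulative dispersion after this merge
    size: int


@dataclass
class ClusterDendrogram:
    """Merge tree from stratigraphically constrained clustering.

    Leaves are in stratigraphic order; every merge joins two clusters
    adjacent in that order, so any cut yields contiguous zones.
    """

    leaves: list[str]
    merges: list[Merge]

    def cut(self, k: int) -> list[list[str]]:
        """Cut into k clusters (contiguous runs of leaves, in order)."""
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for step, m in enumerate(self.merges[: n - k]):
            members[n + step] = members.pop(m.left) + members.pop(m.right)
        clusters = sorted(members.values(), key=min)
        return [[self.leaves[i] for i in sorted(c)] for c in clusters]

    def to_newick(self) -> str:
        """Newick string with branch lengths equal to height increments
        between a node and its parent."""
        n = len(self.leaves)
        heights = {i: 0.0 for i in range(n)}
        reprs = {i: _quote_newick(self.leaves[i]) for i in range(n)}
        for step, m in enumerate(self.merges):
            node = n + step
            heights[node] = m.height
            bl_left = m.height - heights[m.left]
            bl_right = m.height - heights[m.right]
            reprs[node] = f"({reprs[m.left]}:{bl_left:.6g},{reprs[m.right]}:{bl_right:.6g})"
        root = n + len(self.merges) - 1
        return reprs[root] + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _quote_newick(label: str) -> str:
    if any(ch in label for ch in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def coniss(distances: DissimilarityMatrix) -> ClusterDendrogram:
    """Stratigraphically constrained incremental sum-of-squares clustering.

    Works on squared dissimilarities with the Ward-type Lance-Williams
    update; only adjacent clusters may merge, and at each step the
    admissible merge with the smallest dispersion increment is taken.
    Heights are the cumulative dispersion (non-decreasing; increments
    are floored at zero in the rare non-embeddable case).
    """
    n = len(distances.labels)
    if n < 2:
        raise ValueError("clustering needs at least 2 units")
    work = distances.values.astype(float) ** 2
    # active clusters in stratigraphic order: (node_id, size, row index in work)
    order = list(range(n))  # row indices into work
    node_of = list(range(n))
    sizes = [1] * n
    merges: list[Merge] = []
    cumulative = 0.0
    for step in range(n - 1):
        costs = [work[order[i], order[i + 1]] for i in range(len(order) - 1)]
        best = int(np.argmin(costs))
        inc = max(float(costs[best]), 0.0)
        cumulative += inc
        li, ri = order[best], order[best + 1]
        ni, nj = sizes[best], sizes[best + 1]
        new_node = n + step
        merges.append(
            Merge(
                left=node_of[best],
                right=node_of[best + 1],
                increment=inc,
                height=cumulative,
                size=ni + nj,
            )
        )
        # Lance-Williams Ward update, written into row/col li
        for pos, rk in enumerate(order):
            if rk in (li, ri):
                continue
            nk = sizes[pos]
            d_new = (
                (ni + nk) * work[li, rk] + (nj + nk) * work[ri, rk] - nk * work[li, ri]
            ) / (ni + nj + nk)
            work[li, rk] = work[rk, li] = d_new
        sizes[best] = ni + nj
        node_of[best] = new_node
        del order[best + 1], node_of[best + 1], sizes[best + 1]
    return ClusterDendrogram(leaves=list(distances.labels), merges=merges)


def redefine_zones(
    dendrogram: ClusterDendrogram,
    k: int,
    units: Sequence[StratigraphicUnit] | None = None,
    original_zones: Mapping[str, str] | None = None,
) -> BinningScheme:
    """Cut the constrained dendrogram into k contiguous zones.

    Zone labels are inherited from the original zone map by majority
    membership (ties broken in favour of the stratigraphically older
    zone); without an original map the zones are labelled Z1..Zk.
    When ``units`` metadata is given, each zone bin carries the age
    span of its member units.
    """
    groups = dendrogram.cut(k)
    unit_lookup = {u.name: u for u in units} if units is not None else {}
    if original_zones is None and units is not None:
        original_zones = {u.name: u.zone for u in units if u.zone is not None}

    zone_rank: dict[str, int] = {}
    if original_zones:
        for name in dendrogram.leaves:
            z = original_zones.get(name)
            if z is not None and z not in zone_rank:
                zone_rank[z] = len(zone_rank)

    bins: list[TimeBin] = []
    used: set[str] = set()
    for gi, group in enumerate(groups):
        if original_zones:
            tally: dict[str, int] = {}
            for name in group:
                z = original_zones.get(name)
                if z is not None:
                    tally[z] = tally.get(z, 0) + 1
            if tally:
                best = min(
                    tally.items(), key=lambda kv: (-kv[1], zone_rank.get(kv[0], 1 << 30))
                )[0]
            else:
                best = f"Z{gi + 1}"
        else:
            best = f"Z{gi + 1}"
        label = best
        suffix = 2
        while label in used:  # two clusters may share a majority zone
            label = f"{best}.{suffix}"
            suffix += 1
        used.add(label)
        if unit_lookup:
            base = unit_lookup[group[0]].age_base
            top = unit_lookup[group[-1]].age_top
        else:
            base, top = float(len(groups) - gi), float(len(groups) - gi - 1)
        bins.append(TimeBin(label=label, age_base=base, age_top=top, units=tuple(group)))
    return BinningScheme(kind="zone_redefined", bins=bins)
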