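"""Time-binning schemes for occurrence data.

Four schemes are supported, from coarsest to finest:

* ``zone_original`` — biostratigraphic zones (e.g. land vertebrate
  faunachrons) taken from the unit metadata;
* ``zone_redefined`` — zones redefined by constrained clustering (see
  :mod:`paleodiv.distcluster`);
* ``per_unit`` — every stratigraphic unit is its own bin;
* ``stochastic_uniform_age`` — equal-width absolute-age bins with each
  individual specimen assigned at random to one of the bins overlapping
  its unit's age bracket, replicated many times.

The stochastic scheme addresses time averaging: a specimen is only
known to lie somewhere between its unit's base and top ages, so its bin
membership is resampled rather than fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .occurrence import SpecimenOccurrenceTable, StratigraphicUnit

__all__ = [
    "TimeBin",
    "BinningScheme",
    "BinnedOccurrences",
    "bin_by_zone",
    "bin_per_unit",
    "make_age_bins",
    "assign_specimens_stochastic",
]

_EPS = 1e-9

SchemeKind = Literal["zone_original", "zone_redefined", "per_unit", "stochastic_uniform_age"]


@dataclass(frozen=True)
class TimeBin:
    """One time bin: a label, an age interval, and (for unit-based
    schemes) the member unit names."""

    label: str
    age_base: float
    age_top: float
    units: tuple[str, ...] = ()


@dataclass
class BinningScheme:
    kind: str
    bins: list[TimeBin]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("a binning scheme needs at least one bin")
        for older, younger in zip(self.bins, self.bins[1:]):
            if older.age_top > younger.age_base + 1e-6:
                raise ValueError(
                    f"bins {older.label!r} and {younger.label!r} overlap or are out of order"
                )

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass
class BinnedOccurrences:
    """Occurrence counts aggregated into the bins of a scheme.

    ``counts`` is taxon x bin; ``replicate_id`` is 0 for deterministic
    schemes and indexes the stochastic replicate otherwise.
    """

    scheme: BinningScheme
    counts: pd.DataFrame
    replicate_id: int = 0
    level: str = "species"

    def __post_init__(self) -> None:
        if list(self.counts.columns) != self.scheme.labels:
            raise ValueError("counts columns must match scheme bin labels")

    @property
    def n_bins(self) -> int:
        return self.scheme.n_bins

    def presence(self) -> pd.DataFrame:
        return self.counts > 0


def _zone_bins_from_runs(
    units: Sequence[StratigraphicUnit], zones: Sequence[str]
) -> list[TimeBin]:
    """Collapse contiguous runs of equal zone labels into bins; error on
    non-contiguous zone membership."""
    seen: dict[str, int] = {}
    bins: list[TimeBin] = []
    run_start = 0
    for i in range(1, len(zones) + 1):
        if i == len(zones) or zones[i] != zones[run_start]:
            label = zones[run_start]
            if label in seen:
                raise ValueError(
                    f"zone {label!r} is not a contiguous run of units "
                    "(stratigraphic binning requires contiguity)"
                )
            seen[label] = run_start
            members = units[run_start:i]
            bins.append(
                TimeBin(
                    label=label,
                    age_base=members[0].age_base,
                    age_top=members[-1].age_top,
                    units=tuple(u.name for u in members),
                )
            )
            run_start = i
    return bins


def bin_by_zone(
    table: SpecimenOccurrenceTable,
    zone_map: Mapping[str, str] | None = None,
    kind: str = "zone_original",
) -> BinnedOccurrences:
    """Aggregate unit columns into biostratigraphic-zone bins.

    ``zone_map`` maps unit name to zone label; by default the zones in
    the unit metadata are used.  Zones must be contiguous runs of units.
    """
    if zone_map is None:
        zone_map = {u.name: u.zone for u in table.units}
    missing = [u.name for u in table.units if zone_map.get(u.name) is None]
    if missing:
        raise ValueError(f"units without a zone assignment: {missing}")
    zones = [str(zone_map[u.name]) for u in table.units]
    bins = _zone_bins_from_runs(table.units, zones)
    scheme = BinningScheme(kind=kind, bins=bins)
    data = {b.label: table.counts[list(b.units)].sum(axis=1) for b in bins}
    counts = pd.DataFrame(data, index=table.counts.index)
    return BinnedOccurrences(scheme=scheme, counts=counts, level=table.level)


def bin_per_unit(table: SpecimenOccurrenceTable) -> BinnedOccurrences:
    """Treat every stratigraphic unit as its own time bin (identity)."""
    bins = [
        TimeBin(label=u.name, age_base=u.age_base, age_top=u.age_top, units=(u.name,))
        for u in table.units
    ]
    scheme = BinningScheme(kind="per_unit", bins=bins)
    return BinnedOccurrences(scheme=scheme, counts=table.counts.copy(), level=table.level)


def make_age_bins(
    units: Sequence[StratigraphicUnit],
    width: float,
    edge_alignment: str = "multiple_of_width",
) -> BinningScheme:
    """Equal-width absolute-age bins spanning the section.

    With ``multiple_of_width`` alignment (default) the bin edges fall on
    multiples of ``width``, expanded outward to cover the section's full
    [oldest base, youngest top] range; with ``section_base`` the oldest
    edge is anchored at the oldest unit's base age.
    """
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    oldest = max(u.age_base for u in units)
    youngest = min(u.age_top for u in units)
    if edge_alignment == "multiple_of_width":
        start = np.ceil(oldest / width - _EPS) * width
        stop = np.floor(youngest / width + _EPS) * width
        n = int(round((start - stop) / width))
    elif edge_alignment == "section_base":
        start = oldest
        n = int(np.ceil((oldest - youngest) / width - _EPS))
        stop = start - n * width
    else:
        raise ValueError(f"unknown edge_alignment {edge_alignment!r}")
    n = max(n, 1)
    bins = []
    for i in range(n):
        base = start - i * width
        top = start - (i + 1) * width
        bins.append(TimeBin(label=f"{base:.3f}-{top:.3f}", age_base=base, age_top=top))
    return BinningScheme(kind="stochastic_uniform_age", bins=bins)


def _eligible_bins(unit: StratigraphicUnit, scheme: BinningScheme) -> np.ndarray:
    """Indices of bins whose age interval overlaps the unit's (positive
    overlap length; edge-touching does not count)."""
    overlaps = []
    for j, b in enumerate(scheme.bins):
        length = min(unit.age_base, b.age_base) - max(unit.age_top, b.age_top)
        if length > _EPS:
            overlaps.append(j)
    return np.asarray(overlaps, dtype=int)


def _overlap_weights(unit: StratigraphicUnit, scheme: BinningScheme, idx: np.ndarray) -> np.ndarray:
    lengths = np.array(
        [
            min(unit.age_base, scheme.bins[j].age_base) - max(unit.age_top, scheme.bins[j].age_top)
            for j in idx
        ]
    )
    return lengths / lengths.sum()


def assign_specimens_stochastic(
    table: SpecimenOccurrenceTable,
    scheme: BinningScheme,
    n_replicates: int = 100,
    seed: int = 0,
    assignment: str = "uniform_bins",
) -> list[BinnedOccurrences]:
    """Randomly assign each specimen to an age bin overlapping its unit.

    Each individual specimen of each taxon in a unit is placed
    independently and uniformly at random into one of the bins
    intersecting the unit's [age_base, age_top] bracket (or with
    probability proportional to overlap length when
    ``assignment="overlap_weighted"``).  Replicate ``r`` uses its own
    generator derived from ``(seed, r)``, so any replicate is
    reproducible in isolation.  Specimen totals are conserved exactly.
    """
    if scheme.kind != "stochastic_uniform_age":
        raise ValueError("stochastic assignment requires a stochastic_uniform_age scheme")
    if assignment not in ("uniform_bins", "overlap_weighted"):
        raise ValueError(f"unknown assignment rule {assignment!r}")

    eligibility: list[tuple[np.ndarray, np.ndarray]] = []
    for unit in table.units:
        idx = _eligible_bins(unit, scheme)
        if idx.size == 0:
            raise ValueError(
                f"unit {unit.name!r} ({unit.age_base}-{unit.age_top} Ma) overlaps no age bin"
            )
        if assignment == "overlap_weighted":
            probs = _overlap_weights(unit, scheme, idx)
        else:
            probs = np.full(idx.size, 1.0 / idx.size)
        eligibility.append((idx, probs))

    source = table.counts.to_numpy()
    total = source.sum()
    out: list[BinnedOccurrences] = []
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=[seed, r]))
        binned = np.zeros((table.n_taxa, scheme.n_bins), dtype=int)
        for u, (idx, probs) in enumerate(eligibility):
            col = source[:, u]
            if col.sum() == 0:
                continue
            if idx.size == 1:
                binned[:, idx[0]] += col
                continue
            draws = rng.multinomial(col, probs)  # (n_taxa, n_eligible)
            binned[:, idx] += draws
        assert binned.sum() == total
        counts = pd.DataFrame(binned, index=table.counts.index, columns=scheme.labels)
        out.append(
            BinnedOccurrences(scheme=scheme, counts=counts, replicate_id=r, level=table.level)
        )
    return out
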