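"""Core containers and I/O for specimen-count occurrence data.

The central object is :class:`SpecimenOccurrenceTable`: a taxon x
stratigraphic-unit matrix of non-negative integer specimen counts,
together with ordered unit metadata (ages in Ma, optional
biostratigraphic-zone labels).  Every downstream stage — time binning,
assemblage distances, coverage-standardised richness, turnover rates —
consumes this one container, so validation is strict at load time.

A cell is a number of *specimens*, not collections: "occurrence"
throughout this package means a single specimen record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StratigraphicUnit",
    "SpecimenOccurrenceTable",
    "DatasetSummary",
    "read_occurrence_csv",
    "write_occurrence_csv",
    "read_genus_map_csv",
    "summarize",
    "aggregate_to_genus",
    "split_binomial",
]


@dataclass(frozen=True)
class StratigraphicUnit:
    """One stratigraphic unit (formation) of the measured section.

    Ages are in Ma and decrease toward the present, so ``age_base``
    (the older bound) must exceed ``age_top``.  ``ordinal`` 0 is the
    oldest unit.
    """

    name: str
    ordinal: int
    age_base: float
    age_top: float
    zone: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("unit name must be non-empty")
        if not self.age_base > self.age_top:
            raise ValueError(
                f"unit {self.name!r}: age_base ({self.age_base}) must be > "
                f"age_top ({self.age_top}); ages are in Ma"
            )

    @property
    def duration(self) -> float:
        return self.age_base - self.age_top


def _validate_units(units: Sequence[StratigraphicUnit]) -> None:
    names = [u.name for u in units]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate unit names: {dupes}")
    ordinals = [u.ordinal for u in units]
    if ordinals != sorted(ordinals) or len(set(ordinals)) != len(ordinals):
        raise ValueError("units must be sorted by unique ordinal")
    for older, younger in zip(units, units[1:]):
        if older.age_base < younger.age_base - 1e-9 or older.age_top < younger.age_top - 1e-9:
            raise ValueError(
                f"units {older.name!r} and {younger.name!r} violate stratigraphic "
                "order (ages must be non-increasing with ordinal)"
            )


@dataclass
class SpecimenOccurrenceTable:
    """Taxon x unit matrix of specimen counts plus unit metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon label with one column per unit name,
        in unit-ordinal order.  Integer, non-negative, and every taxon
        row sums to at least 1.
    units
        Ordered :class:`StratigraphicUnit` metadata matching the columns.
    level
        ``"species"`` or ``"genus"``.
    """

    counts: pd.DataFrame
    units: list[StratigraphicUnit]
    level: str = "species"

    def __post_init__(self) -> None:
        if self.level not in ("species", "genus"):
            raise ValueError(f"level must be 'species' or 'genus', got {self.level!r}")
        _validate_units(self.units)
        unit_names = [u.name for u in self.units]
        if list(self.counts.columns) != unit_names:
            raise ValueError("counts columns must equal unit names in ordinal order")
        if self.counts.index.duplicated().any():
            dupes = sorted(self.counts.index[self.counts.index.duplicated()].unique())
            raise ValueError(f"duplicate taxon labels: {dupes}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("specimen counts must be integers")
            self.counts = self.counts.astype(int)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("specimen counts must be non-negative")
        if (values.sum(axis=1) < 1).any():
            empty = list(self.counts.index[values.sum(axis=1) < 1])
            raise ValueError(f"taxa with zero total specimens: {empty}")

    # -- convenience views ------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def unit_names(self) -> list[str]:
        return [u.name for u in self.units]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    @property
    def n_specimens(self) -> int:
        return int(self.counts.to_numpy().sum())

    def zone_map(self) -> dict[str, str | None]:
        return {u.name: u.zone for u in self.units}

    def presence(self) -> pd.DataFrame:
        """Boolean taxon x unit incidence matrix."""
        return self.counts > 0


@dataclass(frozen=True)
class DatasetSummary:
    """Headline shape statistics of an occurrence table.

    ``n_singleton_specimens`` counts taxa known from exactly one
    specimen; ``n_single_occurrence`` counts taxa found in exactly one
    unit (possibly by many specimens).  The two are independent counts.
    """

    n_taxa: int
    n_units: int
    n_specimens: int
    n_singleton_specimens: int
    n_single_occurrence: int

    @property
    def singleton_specimen_fraction(self) -> float:
        return self.n_singleton_specimens / self.n_taxa

    @property
    def single_occurrence_fraction(self) -> float:
        return self.n_single_occurrence / self.n_taxa


def summarize(table: SpecimenOccurrenceTable) -> DatasetSummary:
    """Compute the :class:`DatasetSummary` of a table (deterministic)."""
    values = table.counts.to_numpy()
    row_totals = values.sum(axis=1)
    return DatasetSummary(
        n_taxa=table.n_taxa,
        n_units=table.n_units,
        n_specimens=int(values.sum()),
        n_singleton_specimens=int((row_totals == 1).sum()),
        n_single_occurrence=int(((values > 0).sum(axis=1) == 1).sum()),
    )


# -- I/O -------------------------------------------------------------------


def _read_unit_metadata(path: str | Path) -> list[StratigraphicUnit]:
    meta = pd.read_csv(path)
    required = {"name", "ordinal", "age_base", "age_top"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"unit metadata {path}: missing columns {sorted(missing)}")
    units = []
    for row in meta.sort_values("ordinal").itertuples(index=False):
        zone = getattr(row, "zone", None)
        if zone is not None and (pd.isna(zone) or zone == ""):
            zone = None
        units.append(
            StratigraphicUnit(
                name=str(row.name),
                ordinal=int(row.ordinal),
                age_base=float(row.age_base),
                age_top=float(row.age_top),
                zone=zone,
            )
        )
    _validate_units(units)
    return units


def read_occurrence_csv(
    path: str | Path,
    unit_meta_path: str | Path,
    level: str = "species",
) -> SpecimenOccurrenceTable:
    """Load an occurrence matrix CSV plus its unit-metadata CSV.

    The matrix CSV has taxon labels in the first column (header
    ``taxon``) and one column per unit.  Every matrix unit must appear
    in the metadata; metadata units absent from the matrix are kept as
    all-zero columns (a unit that yielded no specimens is still part of
    the section).  Taxa whose total count is zero are dropped with a
    warning — analyses only ever see sampled taxa.
    """
    raw = pd.read_csv(path, index_col=0)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dupes = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValueError(f"duplicate taxon labels in {path}: {dupes}")

    units = _read_unit_metadata(unit_meta_path)
    known = {u.name for u in units}
    unknown = [c for c in raw.columns if c not in known]
    if unknown:
        raise ValueError(
            f"units in occurrence matrix missing from metadata: {unknown}"
        )

    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric specimen count in {path}: {exc}") from exc
    if not np.all(np.equal(np.mod(values.to_numpy(), 1), 0)):
        raise ValueError(f"non-integer specimen counts in {path}")
    if (values.to_numpy() < 0).any():
        raise ValueError(f"negative specimen counts in {path}")
    values = values.astype(int)

    # align to metadata order, zero-filling units without specimens
    counts = values.reindex(columns=[u.name for u in units], fill_value=0)

    empty = counts.sum(axis=1) == 0
    if empty.any():
        dropped = list(counts.index[empty])
        logger.warning("dropping %d zero-count taxa at load: %s", len(dropped), dropped)
        counts = counts.loc[~empty]

    return SpecimenOccurrenceTable(counts=counts, units=units, level=level)


def write_occurrence_csv(
    table: SpecimenOccurrenceTable,
    path: str | Path,
    unit_meta_path: str | Path | None = None,
) -> None:
    """Write the matrix (and optionally unit metadata) back to CSV.

    Round-trips exactly through :func:`read_occurrence_csv`.
    """
    out = table.counts.copy()
    out.index.name = "taxon"
    out.to_csv(path)
    if unit_meta_path is not None:
        meta = pd.DataFrame(
            {
                "name": [u.name for u in table.units],
                "ordinal": [u.ordinal for u in table.units],
                "age_base": [u.age_base for u in table.units],
                "age_top": [u.age_top for u in table.units],
                "zone": [u.zone if u.zone is not None else "" for u in table.units],
            }
        )
        meta.to_csv(unit_meta_path, index=False)


def read_genus_map_csv(path: str | Path) -> dict[str, str]:
    """Read a two-column species -> genus lookup (columns species, genus)."""
    frame = pd.read_csv(path)
    if not {"species", "genus"} <= set(frame.columns):
        raise ValueError(f"genus map {path}: needs columns 'species' and 'genus'")
    return dict(zip(frame["species"].astype(str), frame["genus"].astype(str)))


def split_binomial(taxon: str) -> str:
    """Convenience splitter: genus = first whitespace token.

    Never applied silently — callers must opt in when building a genus
    map from binomial species labels.
    """
    return taxon.split()[0]


def aggregate_to_genus(
    table: SpecimenOccurrenceTable, mapping: Mapping[str, str]
) -> SpecimenOccurrenceTable:
    """Sum congeneric species rows into genus rows.

    Every taxon label must have a genus assignment; unmapped taxa raise
    with the full list.  Total specimens and per-unit column sums are
    conserved.
    """
    unmapped = [t for t in table.taxa if t not in mapping]
    if unmapped:
        raise ValueError(f"taxa without genus assignment: {unmapped}")
    genus_index = pd.Index([mapping[t] for t in table.taxa], name="taxon")
    grouped = table.counts.set_axis(genus_index).groupby(level=0, sort=False).sum()
    return SpecimenOccurrenceTable(counts=grouped, units=list(table.units), level="genus")
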