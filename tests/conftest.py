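import numpy as np
import pandas as pd
import pytest

from paleodiv.occurrence import SpecimenOccurrenceTable, StratigraphicUnit


def make_units(n, age_base=290.0, width=1.0, zones=None):
    return [
        StratigraphicUnit(
            name=f"U{i}",
            ordinal=i,
            age_base=age_base - i * width,
            age_top=age_base - (i + 1) * width,
            zone=None if zones is None else zones[i],
        )
        for i in range(n)
    ]


def make_table(counts, zones=None, taxa=None, **unit_kw):
    counts = np.asarray(counts)
    n_taxa, n_units = counts.shape
    units = make_units(n_units, zones=zones, **unit_kw)
    if taxa is None:
        taxa = [f"t{i}" for i in range(n_taxa)]
    frame = pd.DataFrame(counts, index=pd.Index(taxa, name="taxon"),
                         columns=[u.name for u in units])
    return SpecimenOccurrenceTable(counts=frame, units=units)


@pytest.fixture
def two_by_two():
    return make_table([[1, 0], [2, 3]])


@pytest.fixture
def random_table():
    rng = np.random.default_rng(98765)
    counts = rng.poisson(1.2, size=(20, 8))
    counts = counts[counts.sum(axis=1) > 0]
    return make_table(counts)
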