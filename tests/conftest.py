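import itertools

import pytest

from paleoassoc import load_table1_fixture
from paleoassoc.records import (
    Epoch,
    OccurrenceRecord,
    Paleoenv,
    TaphCategory,
    Taxon,
)

_COUNTER = itertools.count(1)


def make_record(
    taxon=Taxon.SPINOSAURIDAE,
    paleoenv=Paleoenv.TERRESTRIAL,
    epoch=Epoch.EARLY_CRETACEOUS,
    taph_category=TaphCategory.CAT2,
    dubious=False,
    paralogy_group=None,
    locality_id=None,
    strat_unit="unitA",
    occurrence_id=None,
):
    n = next(_COUNTER)
    return OccurrenceRecord(
        occurrence_id=occurrence_id or f"O{n:05d}",
        locality_id=locality_id or f"L{n:05d}",
        taxon=taxon,
        strat_unit=strat_unit,
        epoch=epoch,
        paleoenv=paleoenv,
        taph_category=taph_category,
        dubious=dubious,
        paralogy_group=paralogy_group,
    )


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()
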