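import numpy as np
import pytest

from avicond import (
    CauseDefinition,
    Dataset,
    MonthKey,
    MonthlyRecord,
    Species,
)
from avicond import reference_tables as rt

TWO_CAUSES = (
    CauseDefinition("contamination", "Contamination", technological=True),
    CauseDefinition("dermatosis", "Dermatosis", asi_eligible=True),
)


def make_record(year, month, heavy=1000, turkey=0, griller=0, excluded=False, **condemned):
    slaughtered = {Species.HEAVY: heavy, Species.TURKEY: turkey, Species.GRILLER: griller}
    return MonthlyRecord(MonthKey(year, month), slaughtered, dict(condemned), excluded)


@pytest.fixture
def toy_dataset():
    """Three months, two causes, hand-written counts."""
    records = [
        make_record(2017, 5, heavy=1000, contamination=70, dermatosis=10),
        make_record(2017, 6, heavy=1200, contamination=90, dermatosis=12),
        make_record(2017, 7, heavy=900, contamination=60, dermatosis=9),
    ]
    return Dataset(records, TWO_CAUSES, provenance="toy")


@pytest.fixture
def table1_dataset():
    """The published period-total cause counts folded into a single
    record, for exercising the frequency accounting."""
    rec = MonthlyRecord(
        MonthKey(2019, 11),
        {Species.HEAVY: rt.TOTAL_SLAUGHTERED},
        dict(rt.CAUSE_COUNTS),
    )
    return Dataset([rec])


def constant_series_dataset(n_years=3, heavy=1000, per_month=70):
    """Deterministic flat series: identical counts every month."""
    records = []
    for y in range(2010, 2010 + n_years):
        for m in range(1, 13):
            records.append(
                make_record(y, m, heavy=heavy, contamination=per_month, dermatosis=per_month // 7)
            )
    return Dataset(records, TWO_CAUSES)


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(test_seed)
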