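import sys
from pathlib import Path

import pytest

import ccxburden as cx

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture(scope="session")
def small_study():
    """One simulated year, 5 districts: exposure, lagged table, records, ccdata."""
    cfg = cx.SimulationConfig(
        n_districts=5,
        date_start="2015-01-01",
        date_end="2015-12-31",
        baseline_deaths_per_district_day=1.5,
        seed=42,
    )
    exposure = cx.simulate_exposure(cfg)
    lagged = cx.build_lagged_exposure(exposure)
    records = cx.simulate_mortality(exposure, cfg)
    ccdata, summary = cx.build_case_crossover(records, lagged)
    return {
        "config": cfg,
        "exposure": exposure,
        "lagged": lagged,
        "records": records,
        "ccdata": ccdata,
        "summary": summary,
    }
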