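import numpy as np
import pandas as pd
import pytest

from coveychoice.data import COVARIATES, assemble_choice_sets


def make_choice_rows(n_sets=30, n_coveys=6, seed=0, season=None):
    """Small valid choice-set table with random in-range covariates."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_sets):
        covey = f"c{i % n_coveys}"
        s = int(rng.integers(0, 2)) if season is None else season
        used_slot = int(rng.integers(0, 4))
        for j in range(4):
            rec = {"set_id": f"s{i}", "covey_id": covey, "season": s,
                   "used": j == used_slot,
                   "FB": rng.uniform(0, 100), "GS": rng.uniform(0, 100),
                   "BR": rng.uniform(0, 100), "VO": rng.uniform(0, 100),
                   "SC": float(rng.integers(0, 200)),
                   "NG": rng.uniform(0, 1), "PG": rng.uniform(0, 1),
                   "TD": rng.uniform(0, 300), "WE": rng.uniform(0, 1500)}
            records.append(rec)
    cols = ["set_id", "covey_id", "season", "used", *COVARIATES]
    return pd.DataFrame.from_records(records)[cols]


@pytest.fixture(scope="session")
def small_sets():
    return assemble_choice_sets(make_choice_rows())
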