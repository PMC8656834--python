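import numpy as np
import pandas as pd
import pytest

from amimap import SyntheticConfig, build_adjacency, generate_city, generate_township_map


@pytest.fixture(scope="session")
def tiny_config():
    return SyntheticConfig(n_districts=2, townships_per_district=4, seed=11)


@pytest.fixture(scope="session")
def tiny_city(tiny_config):
    return generate_city(tiny_config)


@pytest.fixture(scope="session")
def map100():
    return generate_township_map(
        SyntheticConfig(n_districts=10, townships_per_district=10)
    )


@pytest.fixture(scope="session")
def adj100(map100):
    return build_adjacency(map100)


def hosp_frame(rows):
    """Build a hospital-record frame from (person, adm, disch, status) tuples;
    dx I21.0, age 60, male, township T001 unless overridden."""
    recs = []
    for r in rows:
        rec = {
            "person_id": r[0],
            "admission_date": pd.Timestamp(r[1]),
            "discharge_date": pd.Timestamp(r[2]),
            "discharge_status": r[3] if len(r) > 3 else "alive",
            "dx_code": r[4] if len(r) > 4 else "I21.0",
            "age": r[5] if len(r) > 5 else 60,
            "sex": "male",
            "township_id": "T001",
        }
        recs.append(rec)
    return pd.DataFrame(
        recs,
        columns=[
            "person_id",
            "admission_date",
            "discharge_date",
            "discharge_status",
            "dx_code",
            "age",
            "sex",
            "township_id",
        ],
    )


def death_frame(rows):
    """Death-record frame from (person, date, place) tuples."""
    recs = []
    for r in rows:
        recs.append(
            {
                "person_id": r[0],
                "death_date": pd.Timestamp(r[1]),
                "place": r[2] if len(r) > 2 else "in_hospital",
                "cause_code": r[3] if len(r) > 3 else "I21.9",
                "age": r[4] if len(r) > 4 else 60,
                "sex": "male",
                "township_id": "T001",
            }
        )
    return pd.DataFrame(
        recs,
        columns=[
            "person_id",
            "death_date",
            "place",
            "cause_code",
            "age",
            "sex",
            "township_id",
        ],
    )


def random_person_records(rng, person_id, max_records=6, span_days=90):
    """One person's random record set for oracle comparisons.

    Up to `max_records` records total: hospital stays with 0-10 day lengths
    and random died statuses, plus 0-2 death records; a sprinkling of
    ineligible codes and under-age records exercises the filter too.
    """
    n_total = rng.integers(1, max_records + 1)
    n_death = min(int(rng.integers(0, 3)), n_total)
    n_hosp = n_total - n_death
    base = np.datetime64("2010-01-01")
    h_rows, d_rows = [], []
    age = int(rng.integers(30, 95))
    for _ in range(n_hosp):
        adm = base + int(rng.integers(0, span_days))
        los = int(rng.integers(0, 11))
        status = "died" if rng.random() < 0.15 else "alive"
        code = "I21.4" if rng.random() < 0.9 else "I50.1"
        h_rows.append((person_id, str(adm), str(adm + los), status, code, age))
    for _ in range(n_death):
        day = base + int(rng.integers(0, span_days))
        place = "in_hospital" if rng.random() < 0.5 else "out_of_hospital"
        code = "I22.0" if rng.random() < 0.9 else "C34.9"
        d_rows.append((person_id, str(day), place, code, age))
    return h_rows, d_rows
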