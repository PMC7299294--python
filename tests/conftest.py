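"""Shared fixtures: tiny handcrafted pedigrees and lifetime histories."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sowlong.simulate import LifetimeData, Pedigree


def make_pedigree(rows):
    """rows: (animal, sire, dam, breed, sex) with auto dates/litters."""
    tab = pd.DataFrame(rows, columns=["animal", "sire", "dam", "breed", "sex"])
    tab["birth_date"] = pd.Timestamp("2013-01-01") + pd.to_timedelta(
        10 * np.arange(len(tab)), unit="D"
    )
    tab["litter_id"] = np.arange(1, len(tab) + 1)
    tab["dam_parity"] = 1
    return Pedigree(tab)


def make_lifetime(parity_rows, sow_rows, observation_end=dt.date(2018, 1, 1)):
    """Handcrafted lifetime data.

    parity_rows: (animal, parity, insem_day, farrow_day_or_None, n_weaned)
    sow_rows: (animal, breed, culled_after_parity_or_None)
    Days count from 2015-01-01.
    """
    base = pd.Timestamp("2015-01-01")
    recs = pd.DataFrame(
        [
            {
                "animal": a,
                "parity": p,
                "insemination_date": base + pd.Timedelta(days=ins),
                "farrowing_date": (base + pd.Timedelta(days=far)) if far is not None else pd.NaT,
                "n_weaned": w,
                "herd": 1,
                "country": 1,
                "season": 1,
                "year": 2015,
            }
            for a, p, ins, far, w in parity_rows
        ]
    )
    sows = pd.DataFrame(
        [
            {
                "animal": a,
                "breed": b,
                "birth_date": base - pd.Timedelta(days=300),
                "litter_id": 100 + a,
                "dam_parity": 1,
                "herd": 1,
                "country": 1,
                "culled_after_parity": c if c is not None else np.nan,
                "observation_end_date": pd.Timestamp(observation_end),
            }
            for a, b, c in sow_rows
        ]
    )
    return LifetimeData(records=recs, sows=sows, observation_end=observation_end)


@pytest.fixture
def trio_pedigree():
    """Sire, dam and their offspring."""
    return make_pedigree(
        [(1, 0, 0, "A", "M"), (2, 0, 0, "A", "F"), (3, 1, 2, "A", "F")]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20200601)


def random_pedigree(rng, n_founders=20, n_extra=80):
    """Random valid pedigree: founders then animals with random earlier parents."""
    rows = []
    for i in range(1, n_founders + 1):
        rows.append((i, 0, 0, "A", "M" if i % 2 else "F"))
    for i in range(n_founders + 1, n_founders + n_extra + 1):
        males = [a for a, s, d, b, sx in rows if sx == "M"]
        females = [a for a, s, d, b, sx in rows if sx == "F"]
        sire = int(rng.choice(males)) if rng.random() < 0.9 else 0
        dam = int(rng.choice(females)) if rng.random() < 0.9 else 0
        rows.append((i, sire, dam, "A", "M" if rng.random() < 0.5 else "F"))
    return make_pedigree(rows)
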