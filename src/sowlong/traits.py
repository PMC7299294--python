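"""Construction of the three longevity traits from sow lifetime records.

* LGY12 - whether the sow was inseminated for a second litter within 85 d
  of first farrowing (0/1).
* LGY15 - number of litters within 570 d of first farrowing, capped at 5
  (the first farrowing counts, so the minimum is 1).
* Survival - per-parity repeatability trait: 1 for the parity after which
  the sow was culled, 0 otherwise; a sow without a 1 is censored.

Sows whose observation window is too short to decide LGY12/LGY15 are
excluded (a linear model cannot carry censored records); every exclusion
is logged with its reason.  Cohort filters retain farms and countries
with enough animals and breed diversity, iterated to a fixed point so the
filter is idempotent.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .simulate import LifetimeData

log = logging.getLogger(__name__)

LGY12_WINDOW_DAYS = 85
LGY15_WINDOW_DAYS = 570
LGY15_CAP = 5


def _per_sow_frames(lifetime: LifetimeData):
    recs = lifetime.records
    sows = lifetime.sows.set_index("animal")
    farrowed = recs.dropna(subset=["farrowing_date"])
    first = farrowed[farrowed["parity"] == 1].set_index("animal")
    return recs, sows, farrowed, first


def _base_columns(sows: pd.DataFrame, animals, first: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=animals)
    out["breed"] = sows.loc[animals, "breed"]
    out["litter_id"] = sows.loc[animals, "litter_id"]
    out["dam_parity"] = sows.loc[animals, "dam_parity"]
    out["herd"] = first.loc[animals, "herd"]
    out["country"] = first.loc[animals, "country"]
    out["year"] = first.loc[animals, "insemination_date"].dt.year
    out["birth_date"] = sows.loc[animals, "birth_date"]
    return out


def build_lgy12(lifetime: LifetimeData):
    """0/1 rebreeding within 85 d of first farrowing, plus an exclusion log."""
    recs, sows, farrowed, first = _per_sow_frames(lifetime)
    end = pd.Timestamp(lifetime.observation_end)
    excl = []
    no_farrow = sows.index.difference(first.index)
    excl.extend((a, "no_farrowing") for a in no_farrow)

    second_ins = recs[recs["parity"] == 2].set_index("animal")["insemination_date"]
    ff = first["farrowing_date"]
    has2 = ff.index.intersection(second_ins.index)
    delta = pd.Series(pd.NaT, index=ff.index, dtype="timedelta64[ns]")
    delta.loc[has2] = second_ins.loc[has2] - ff.loc[has2]
    value = (delta <= pd.Timedelta(days=LGY12_WINDOW_DAYS)).astype(float)

    # no second insemination and the 85-d window not yet elapsed: unobservable
    window_open = (end - ff) < pd.Timedelta(days=LGY12_WINDOW_DAYS)
    unobservable = delta.isna() & window_open
    excl.extend((a, "window_incomplete") for a in ff.index[unobservable])
    keep = ff.index[~unobservable]

    out = _base_columns(sows, keep, first)
    out["trait"] = "LGY12"
    out["parity"] = 1
    out["value"] = value.loc[keep]
    exclusions = pd.DataFrame(excl, columns=["animal", "reason"])
    if len(exclusions):
        log.info("LGY12: excluded %d sows (%s)", len(exclusions),
                 exclusions["reason"].value_counts().to_dict())
    return out.reset_index(names="animal"), exclusions


def build_lgy15(lifetime: LifetimeData):
    """Litter count within 570 d of first farrowing (1..5), plus exclusions.

    Sows still alive whose window has not elapsed and who have not reached
    the cap are censored and excluded; culled sows have complete counts.
    """
    recs, sows, farrowed, first = _per_sow_frames(lifetime)
    end = pd.Timestamp(lifetime.observation_end)
    excl = []
    no_farrow = sows.index.difference(first.index)
    excl.extend((a, "no_farrowing") for a in no_farrow)

    ff = first["farrowing_date"]
    joined = farrowed.merge(ff.rename("first_farrowing"), left_on="animal", right_index=True)
    in_window = joined["farrowing_date"] <= joined["first_farrowing"] + pd.Timedelta(
        days=LGY15_WINDOW_DAYS
    )
    counts = joined[in_window].groupby("animal").size().reindex(ff.index, fill_value=0)
    value = counts.clip(upper=LGY15_CAP)

    alive = sows.loc[ff.index, "culled_after_parity"].isna()
    window_open = (end - ff) < pd.Timedelta(days=LGY15_WINDOW_DAYS)
    censored = alive & window_open & (value < LGY15_CAP)
    excl.extend((a, "window_incomplete") for a in ff.index[censored])
    keep = ff.index[~censored]

    out = _base_columns(sows, keep, first)
    out["trait"] = "LGY15"
    out["parity"] = 1
    out["value"] = value.loc[keep].astype(float)
    exclusions = pd.DataFrame(excl, columns=["animal", "reason"])
    if len(exclusions):
        log.info("LGY15: excluded %d sows (%s)", len(exclusions),
                 exclusions["reason"].value_counts().to_dict())
    return out.reset_index(names="animal"), exclusions


def build_survival(lifetime: LifetimeData):
    """Per-parity culling indicator records for the repeatability model.

    A sow culled after parity k yields records 0, ..., 0, 1 for parities
    1..k; a censored sow yields all zeros for her completed parities.
    Each record carries parity, dam parity, herd-year of insemination,
    country, season and weaned count.
    """
    recs, sows, farrowed, first = _per_sow_frames(lifetime)
    excl = []
    no_farrow = sows.index.difference(first.index)
    excl.extend((a, "no_farrowing") for a in no_farrow)

    done = farrowed[farrowed["animal"].isin(first.index)].copy()
    np_parities = done.groupby("animal")["parity"].max()
    culled = sows.loc[np_parities.index, "culled_after_parity"]
    bad = culled.notna() & (culled > np_parities)
    if bad.any():
        raise DataError(
            f"culling parity exceeds observed parities for animals {list(np_parities.index[bad])[:5]}"
        )

    done["value"] = 0.0
    is_cull_row = done["parity"].to_numpy() == culled.reindex(done["animal"]).to_numpy()
    done.loc[is_cull_row, "value"] = 1.0
    done["trait"] = "Survival"
    done["herd_year"] = (
        done["herd"].astype(str) + "_" + done["year"].astype(str)
    )
    done = done.merge(
        sows[["breed", "litter_id", "dam_parity", "birth_date"]],
        left_on="animal", right_index=True,
    )
    cols = [
        "animal", "trait", "parity", "value", "breed", "litter_id", "dam_parity",
        "herd", "herd_year", "year", "country", "season", "n_weaned", "birth_date",
    ]
    exclusions = pd.DataFrame(excl, columns=["animal", "reason"])
    if len(exclusions):
        log.info("Survival: excluded %d sows without farrowing", len(exclusions))
    return done[cols].reset_index(drop=True), exclusions


def apply_cohort_filters(
    trait_records: pd.DataFrame,
    min_farm_size: int = 50,
    min_country_size: int = 1000,
    min_breeds: int = 2,
):
    """Keep farms and countries with enough animals and breed diversity.

    The farm and country rules are iterated to a fixed point, which makes
    the filter idempotent.  Returns (filtered records, exclusion summary).
    """
    df = trait_records
    removed = {"farm": 0, "country": 0}
    while True:
        farm_n = df.groupby("herd")["animal"].nunique()
        ok_farms = farm_n[farm_n >= min_farm_size].index
        kept = df[df["herd"].isin(ok_farms)]
        removed["farm"] += len(df) - len(kept)
        df2 = kept
        cn = df2.groupby("country")["animal"].nunique()
        cb = df2.groupby("country")["breed"].nunique()
        ok_countries = cn.index[(cn >= min_country_size) & (cb >= min_breeds)]
        kept2 = df2[df2["country"].isin(ok_countries)]
        removed["country"] += len(df2) - len(kept2)
        if len(kept2) == len(df):
            break
        df = kept2
    log.info("cohort filters removed %s records", removed)
    return df.reset_index(drop=True), removed


def assemble_dataset(trait_records: pd.DataFrame, breeds, trait_mode: str = "same"):
    """Analysis table for a breed subset.

    In mode "same" all records share one response slot; in mode
    "different" the response is mapped to breed-specific slots so that
    across-breed genetic covariances become estimable (each animal only
    records its own breed's slot).
    """
    breeds = sorted(set(breeds))
    missing = set(breeds) - set(trait_records["breed"].unique())
    if missing:
        raise DataError(f"requested breeds not present: {missing}")
    if trait_mode not in ("same", "different"):
        raise ConfigurationError(f"unknown trait_mode {trait_mode!r}")
    if trait_mode == "different" and len(breeds) < 2:
        raise ConfigurationError("mode 'different' needs at least two breeds")
    out = trait_records[trait_records["breed"].isin(breeds)].copy()
    out["slot"] = out["breed"] if trait_mode == "different" else "all"
    return out.reset_index(drop=True)
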