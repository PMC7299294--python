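"""Forward (masked-cohort) validation of breeding-value prediction.

Young animals are masked by breed-specific birth-date cutoffs, the model
is refitted without their phenotypes, and predictions are scored as
cor(CP, EBV) / sqrt(h2) where CP is the phenotype corrected for fixed
and non-genetic random effects from the full-data fit.  Also provides
EBV-set correlation comparisons and the SD-of-scaled-EBVs-by-birth-year
series used to see when information becomes available for young
animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .mixed_model import EvaluationResult

log = logging.getLogger(__name__)


@dataclass
class ValidationPlan:
    cutoff_date_pb: pd.Timestamp
    cutoff_date_cb: pd.Timestamp
    n_validation_per_breed: int = 5000
    anchor_trait: str = "LGY15"

    def cutoff_for(self, breed: str) -> pd.Timestamp:
        return pd.Timestamp(self.cutoff_date_cb if breed == "X" else self.cutoff_date_pb)


def make_training_validation_split(
    analysis_table: pd.DataFrame, plan: ValidationPlan, anchor_table: pd.DataFrame | None = None
):
    """Mask post-cutoff phenotypes; pick the n youngest masked animals per breed.

    Eligibility for the validation set requires an observation for the
    anchor trait (``anchor_table``; defaults to the analysis table
    itself).  Returns (training table, {breed: validation ids}, summary).
    """
    tab = analysis_table
    if "birth_date" not in tab.columns:
        raise DataError("analysis table needs a birth_date column for masking")
    cut = tab["breed"].map(plan.cutoff_for)
    masked = pd.to_datetime(tab["birth_date"]) > cut
    training = tab[~masked].reset_index(drop=True)
    if training.empty:
        raise DataError("masking removed every training phenotype")
    masked_animals = tab.loc[masked, ["animal", "breed", "birth_date"]].drop_duplicates("animal")
    if masked_animals.empty:
        raise DataError("no animals masked: validation set would be empty")

    anchor = anchor_table if anchor_table is not None else tab
    eligible = masked_animals[masked_animals["animal"].isin(anchor["animal"])]
    validation_ids = {}
    rows = []
    for breed, grp in eligible.groupby("breed"):
        n_req = plan.n_validation_per_breed
        if len(grp) < n_req:
            log.warning(
                "breed %s: only %d eligible validation animals (requested %d)",
                breed, len(grp), n_req,
            )
            n_req = len(grp)
        youngest = grp.sort_values("birth_date", ascending=False).head(n_req)
        validation_ids[breed] = youngest["animal"].to_numpy()
        rows.append(
            {
                "breed": breed,
                "n_training": int(training.loc[training["breed"] == breed, "animal"].nunique()),
                "n_masked": int((masked_animals["breed"] == breed).sum()),
                "n_validation": len(youngest),
            }
        )
    summary = pd.DataFrame(rows)
    return training, validation_ids, summary


def corrected_phenotypes(
    full_fit: EvaluationResult, analysis_table: pd.DataFrame, combine: str = "mean"
) -> pd.Series:
    """CP = y - Xb - Vv per record from the full-data fit, aggregated per animal.

    For the repeatability trait the per-animal CP is the mean of the
    corrected per-parity records (``combine`` may also be "sum" or
    "first").
    """
    dm = full_fit.design
    if len(analysis_table) != dm.n_records:
        raise DataError("analysis table does not match the fit's design rows")
    cp = dm.y - dm.X @ full_fit.b_hat.to_numpy()
    if dm.V is not None and full_fit.v_hat is not None:
        cp = cp - dm.V @ full_fit.v_hat.to_numpy()
    per_rec = pd.DataFrame({"animal": analysis_table["animal"].to_numpy(), "cp": cp})
    if combine == "mean":
        return per_rec.groupby("animal")["cp"].mean()
    if combine == "sum":
        return per_rec.groupby("animal")["cp"].sum()
    if combine == "first":
        return per_rec.groupby("animal")["cp"].first()
    raise ConfigurationError(f"unknown CP combination {combine!r}")


def prediction_accuracy(cp: pd.Series, ebv: pd.Series, h2: float) -> dict:
    """Scaled validation accuracy cor(CP, EBV) / sqrt(h2) with a Fisher-z SE."""
    common = cp.index.intersection(ebv.index)
    if len(common) < 30:
        raise DataError(f"only {len(common)} validation animals with both CP and EBV")
    x = cp.loc[common].to_numpy(float)
    y = ebv.loc[common].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return {"accuracy": np.nan, "raw_correlation": np.nan, "se": np.nan, "n": len(common)}
    r = float(np.corrcoef(x, y)[0, 1])
    se_r = (1.0 - r * r) / np.sqrt(max(len(common) - 3, 1))
    return {
        "accuracy": r / np.sqrt(h2),
        "raw_correlation": r,
        "se": se_r / np.sqrt(h2),
        "n": int(len(common)),
    }


def ebv_correlation_matrix(ebv_sets: dict) -> pd.DataFrame:
    """Pairwise Pearson correlations of named EBV sets over their common animals."""
    names = list(ebv_sets)
    common = None
    for s in ebv_sets.values():
        common = s.index if common is None else common.intersection(s.index)
    if common is None or len(common) < 2:
        raise DataError("EBV sets share fewer than two animals")
    mat = np.corrcoef(np.vstack([ebv_sets[n].loc[common].to_numpy(float) for n in names]))
    return pd.DataFrame(mat, index=names, columns=names)


def ebv_sd_by_birthyear(
    ebvs: pd.Series,
    genetic_sd: float,
    birth_dates: pd.Series,
    genotyped_ids=None,
    plot_path=None,
    label: str = "EBV",
) -> pd.Series:
    """SD of EBVs scaled by the genetic SD, per birth year.

    A rising series (read young to old) shows information accumulating;
    restricting to genotyped animals mirrors the published figures.
    """
    if genetic_sd <= 0:
        raise ConfigurationError("genetic_sd must be positive")
    sel = ebvs.index
    if genotyped_ids is not None:
        sel = sel.intersection(pd.Index(genotyped_ids))
    years = pd.to_datetime(birth_dates.loc[sel]).dt.year
    series = ebvs.loc[sel].groupby(years).std(ddof=1).fillna(0.0) / genetic_sd
    series.name = label
    series.index.name = "birth_year"
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(series.index, series.to_numpy(), marker="o", label=label)
        ax.set_xlabel("birth year")
        ax.set_ylabel("SD(EBV) / genetic SD")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return series
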