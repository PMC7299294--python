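"""Synthetic multi-breed breeding-program simulator.

Emulates two purebred maternal pig lines (A, B) and their F1 cross X
(predominantly A-sire x B-dam), 50K-style SNP panels produced by gene
dropping, per-parity binary culling on an underlying liability, and the
calendar machinery (insemination/farrowing dates, weaned counts, herd /
country / season assignments) that the longevity traits are built from.

Two record generators are exposed:

* ``simulate_lifetime_records`` - the liability-threshold culling process
  that produces per-parity sow histories; the longevity traits LGY12 and
  LGY15 *emerge* from that process rather than being parameterised
  directly.
* ``simulate_quantitative_records`` - single continuous records per
  animal with the configured heritability / litter fraction, used for
  variance-component and prediction recovery experiments where the truth
  must be exactly the configured value.

All randomness flows from ``SimulationConfig.seed``: the same config and
seed reproduce every output byte-for-byte.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, DataError, PedigreeError
from .relationships import mendelian_variance_factors, _parent_indices

TRAITS = ("LGY12", "LGY15", "Survival")
BREEDS = ("A", "B", "X")
GESTATION_DAYS = 115

# Study-condition defaults.  Per-breed heritabilities follow the published
# single-breed estimates (LGY12/LGY15 on the observed scale; Survival
# entered on the liability scale, converted from the observed-scale
# estimates 0.017/0.026/0.013 at the per-breed culling rates below).
_DEFAULT_H2 = {
    "LGY12": {"A": 0.074, "B": 0.063, "X": 0.073},
    "LGY15": {"A": 0.096, "B": 0.132, "X": 0.049},
    "Survival": {"A": 0.033, "B": 0.068, "X": 0.047},
}
# Purebred-crossbred genetic correlations; the Survival values reuse the
# LGY15 ones (the PB-CB correlation for Survival was never estimable and
# is expected to be of similar size).
_DEFAULT_RG = {
    ("A", "LGY12"): 0.308,
    ("B", "LGY12"): 0.231,
    ("A", "LGY15"): 0.485,
    ("B", "LGY15"): 0.614,
    ("A", "Survival"): 0.485,
    ("B", "Survival"): 0.614,
}
# Per-parity culling probabilities matching the published per-breed mean
# Survival rates (0.22 / 0.12 / 0.07).
_DEFAULT_CULL = {
    "A": (0.22,) * 10,
    "B": (0.12,) * 10,
    "X": (0.07,) * 10,
}


def robertson_liability_to_observed(h2_liab: float, p: float) -> float:
    """Observed-scale h2 of a 0/1 trait from its liability-scale h2."""
    z = norm.pdf(norm.ppf(1.0 - p))
    return h2_liab * z * z / (p * (1.0 - p))


def robertson_observed_to_liability(h2_obs: float, p: float) -> float:
    z = norm.pdf(norm.ppf(1.0 - p))
    return h2_obs * p * (1.0 - p) / (z * z)


@dataclass
class SimulationConfig:
    """Declarative description of one simulated breeding program.

    Variance fractions are on a unit total (u + v + e) scale per trait
    slot; fixed-effect dispersions come on top and are accounted for when
    calibrating the culling thresholds.
    """

    n_founders_per_line: int = 400
    n_generations: int = 3
    litters_per_dam: int = 2
    litter_size_mean: float = 7.0
    f1_fraction: float = 0.3
    cross_a_sire_fraction: float = 0.8
    sire_fraction: float = 0.10
    n_snp: int = 1000
    founder_maf_range: tuple = (0.02, 0.5)
    true_h2: dict = field(default_factory=lambda: {t: dict(v) for t, v in _DEFAULT_H2.items()})
    litter_variance_fraction: float = 0.007
    rg_pb_cb: dict = field(default_factory=lambda: dict(_DEFAULT_RG))
    fixed_effect_levels: dict = field(
        default_factory=lambda: {"herd": 40, "country": 4, "season": 4}
    )
    fixed_effect_sd: dict = field(
        default_factory=lambda: {
            "herd": 0.10,
            "year": 0.05,
            "country": 0.10,
            "season": 0.03,
            "dam_parity": 0.03,
        }
    )
    culling_base_rate_per_parity: dict = field(
        default_factory=lambda: {b: tuple(v) for b, v in _DEFAULT_CULL.items()}
    )
    weaned_mean: float = 10.0
    weaned_herd_sd: float = 1.0
    weaned_liability_slope: float = -0.02
    first_insemination_age: tuple = (240.0, 15.0)
    wean_to_service: tuple = (33.0, 8.0)
    max_parities: int = 10
    founder_birth_year: int = 2012
    observation_end: dt.date | None = None
    permanent_env_fraction: float = 0.0
    seed: int = 2020

    def validate(self) -> None:
        if self.n_founders_per_line <= 0 or self.n_generations <= 0:
            raise ConfigurationError("founder and generation counts must be positive")
        if self.litters_per_dam <= 0 or self.litter_size_mean <= 0:
            raise ConfigurationError("litter counts must be positive")
        if not 0.0 <= self.f1_fraction <= 1.0:
            raise ConfigurationError("f1_fraction must lie in [0, 1]")
        if not 0.0 <= self.cross_a_sire_fraction <= 1.0:
            raise ConfigurationError("cross_a_sire_fraction must lie in [0, 1]")
        for trait, per_breed in self.true_h2.items():
            for breed, h2 in per_breed.items():
                if not 0.0 <= h2 < 1.0:
                    raise ConfigurationError(f"h2 out of range for {trait}/{breed}")
                if h2 + self.litter_variance_fraction + self.permanent_env_fraction >= 1.0:
                    raise ConfigurationError(
                        f"variance fractions for {trait}/{breed} sum to >= 1"
                    )
        for key, r in self.rg_pb_cb.items():
            if not -1.0 <= r <= 1.0:
                raise ConfigurationError(f"rg_pb_cb[{key}] outside [-1, 1]")
        for breed, rates in self.culling_base_rate_per_parity.items():
            if np.any(np.array(rates) < 0) or np.any(np.array(rates) > 1):
                raise ConfigurationError(f"culling rates for breed {breed} outside [0, 1]")
        for trait in self.true_h2:
            self.slot_covariance(trait)  # raises if not PSD

    def slot_covariance(self, trait: str) -> np.ndarray:
        """3x3 genetic covariance across breed slots (A, B, X) for one trait.

        Slot variances are the configured heritabilities (unit phenotypic
        scale); r(A,X) and r(B,X) are the configured purebred-crossbred
        correlations and r(A,B) = r(AX) * r(BX), which keeps the matrix PSD.
        """
        h2 = self.true_h2[trait]
        sd = np.sqrt([h2.get(b, 0.0) for b in BREEDS])
        r_ax = self.rg_pb_cb.get(("A", trait), 0.0)
        r_bx = self.rg_pb_cb.get(("B", trait), 0.0)
        corr = np.array(
            [[1.0, r_ax * r_bx, r_ax], [r_ax * r_bx, 1.0, r_bx], [r_ax, r_bx, 1.0]]
        )
        G0 = corr * np.outer(sd, sd)
        ev = np.linalg.eigvalsh(corr)
        if ev.min() < -1e-10:
            raise ConfigurationError(
                f"implied genetic covariance for {trait} is not positive semidefinite"
            )
        return G0

    def resolved_observation_end(self) -> dt.date:
        if self.observation_end is not None:
            return self.observation_end
        return dt.date(self.founder_birth_year + self.n_generations + 2, 7, 1)


@dataclass
class Pedigree:
    """Parents-first pedigree table.

    Columns: animal, sire, dam (0 = unknown), breed in {A,B,X}, sex in
    {M,F}, birth_date, litter_id, dam_parity (litter sequence of the dam).
    """

    table: pd.DataFrame

    def __post_init__(self):
        _parent_indices(self.table)  # validates ordering and uniqueness
        bad = set(self.table["breed"]) - set(BREEDS)
        if bad:
            raise PedigreeError(f"unknown breed labels: {bad}")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["animal"].to_numpy()

    def parent_indices(self):
        return _parent_indices(self.table)


@dataclass
class GenotypeData:
    ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray  # n_animals x n_snp, int8 in {0,1,2}


@dataclass
class TrueGeneticValues:
    """True breeding values per breed-trait slot and common-litter effects."""

    slots: tuple
    u: dict  # trait -> (n_animals x 3) array, slot order = BREEDS
    litter_effects: dict  # trait -> pd.Series indexed by litter_id
    animal_ids: np.ndarray

    def own_slot_u(self, trait: str, breeds: pd.Series) -> np.ndarray:
        """Breeding value of each animal for its own breed's slot."""
        cols = np.array([BREEDS.index(b) for b in breeds])
        return self.u[trait][np.arange(len(cols)), cols]


@dataclass
class LifetimeData:
    """Per-parity sow event history plus per-sow summary."""

    records: pd.DataFrame  # one row per parity attempt
    sows: pd.DataFrame  # one row per sow
    observation_end: dt.date


# ---------------------------------------------------------------------------
# pedigree simulation


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Multi-generation two-line pedigree with F1 cross litters.

    ``n_generations`` counts the founder generation: with
    ``n_generations=1`` only unrelated founders of lines A and B exist.
    Cross litters (breed X offspring) are A-sire x B-dam with probability
    ``cross_a_sire_fraction``, B-sire x A-dam otherwise; X animals are
    terminal and never bred.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    next_id = 1
    next_litter = 1

    def year_dates(year, k):
        days = rng.integers(0, 365, size=k)
        base = dt.date(year, 1, 1).toordinal()
        return [dt.date.fromordinal(base + int(d)) for d in days]

    n_sires = max(1, int(round(config.sire_fraction * config.n_founders_per_line)))
    males = {}
    females = {}
    for line in ("A", "B"):
        ids = []
        dates = year_dates(config.founder_birth_year, config.n_founders_per_line)
        for k in range(config.n_founders_per_line):
            sex = "M" if k < n_sires else "F"
            rows.append(
                (next_id, 0, 0, line, sex, dates[k], next_litter, 1)
            )
            ids.append((next_id, sex))
            next_id += 1
            next_litter += 1
        males[line] = [a for a, s in ids if s == "M"]
        females[line] = [a for a, s in ids if s == "F"]

    for g in range(1, config.n_generations):
        year = config.founder_birth_year + g
        # matings: every current dam of each line produces litters_per_dam litters
        dams = [(line, d) for line in ("A", "B") for d in females[line]]
        litters = [(line, d, p + 1) for line, d in dams for p in range(config.litters_per_dam)]
        n_litters = len(litters)
        n_cross = int(round(config.f1_fraction * n_litters))
        b_dam_litters = [i for i, (line, _, _) in enumerate(litters) if line == "B"]
        a_dam_litters = [i for i, (line, _, _) in enumerate(litters) if line == "A"]
        n_cross_b = min(len(b_dam_litters), int(round(config.cross_a_sire_fraction * n_cross)))
        n_cross_a = min(
            len(a_dam_litters), int(round((1.0 - config.cross_a_sire_fraction) * n_cross))
        )
        cross_set = set(rng.choice(b_dam_litters, size=n_cross_b, replace=False)) | set(
            rng.choice(a_dam_litters, size=n_cross_a, replace=False)
        )
        new_members = {"A": {"M": [], "F": []}, "B": {"M": [], "F": []}}
        for idx, (line, dam, parity) in enumerate(litters):
            cross = idx in cross_set
            sire_line = ("A" if line == "B" else "B") if cross else line
            if not males[sire_line]:
                continue
            sire = int(rng.choice(males[sire_line]))
            size = max(1, int(rng.poisson(config.litter_size_mean)))
            breed = "X" if cross else line
            dates = year_dates(year, size)
            sexes = rng.random(size) < 0.5
            for k in range(size):
                sex = "F" if sexes[k] else "M"
                rows.append((next_id, sire, dam, breed, sex, dates[k], next_litter, parity))
                if breed in ("A", "B"):
                    new_members[breed][sex].append(next_id)
                next_id += 1
            next_litter += 1
        for line in ("A", "B"):
            cand_m, cand_f = new_members[line]["M"], new_members[line]["F"]
            n_dams_target = config.n_founders_per_line - n_sires
            if cand_m:
                males[line] = list(
                    rng.choice(cand_m, size=min(n_sires, len(cand_m)), replace=False)
                )
            if cand_f:
                females[line] = list(
                    rng.choice(cand_f, size=min(n_dams_target, len(cand_f)), replace=False)
                )

    table = pd.DataFrame(
        rows,
        columns=["animal", "sire", "dam", "breed", "sex", "birth_date", "litter_id", "dam_parity"],
    )
    table["birth_date"] = pd.to_datetime(table["birth_date"])
    return Pedigree(table)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(pedigree: Pedigree, config: SimulationConfig) -> GenotypeData:
    """Gene-dropped SNP dosages: line-specific founder frequencies, fair-coin meiosis."""
    rng = np.random.default_rng(config.seed + 1)
    ids, sire, dam = pedigree.parent_indices()
    breeds = pedigree.table["breed"].to_numpy()
    m = config.n_snp
    lo, hi = config.founder_maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError("founder MAF range must lie in (0, 0.5]")
    freq = {line: rng.uniform(lo, hi, size=m) for line in ("A", "B")}
    n = len(ids)
    hap = np.zeros((n, 2, m), dtype=np.int8)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            line = breeds[i]
            if line == "X":
                raise PedigreeError("crossbred founder without parents")
            hap[i] = rng.random((2, m)) < freq[line]
        elif s >= 0 and d >= 0:
            pick_s = rng.integers(0, 2, size=m)
            pick_d = rng.integers(0, 2, size=m)
            cols = np.arange(m)
            hap[i, 0] = hap[s, pick_s, cols]
            hap[i, 1] = hap[d, pick_d, cols]
        else:  # one unknown parent: sample the missing gamete from the line pool
            known = s if s >= 0 else d
            pick = rng.integers(0, 2, size=m)
            hap[i, 0] = hap[known, pick, np.arange(m)]
            hap[i, 1] = rng.random(m) < freq[breeds[i] if breeds[i] != "X" else "A"]
    dosages = hap.sum(axis=1, dtype=np.int8)
    snp_ids = np.array([f"snp{j+1}" for j in range(m)])
    return GenotypeData(ids=ids, snp_ids=snp_ids, dosages=dosages)


# ---------------------------------------------------------------------------
# true genetic values


def simulate_genetic_values(pedigree: Pedigree, config: SimulationConfig) -> TrueGeneticValues:
    """Breeding values for every breed-trait slot by pedigree flow-down.

    Founders draw from N(0, G0); descendants are the parent average plus a
    Mendelian-sampling deviation with variance d_i * G0, where d_i accounts
    for parental inbreeding and unknown parents.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    ids, sire, dam = pedigree.parent_indices()
    d, _ = mendelian_variance_factors(sire, dam)
    n = len(ids)
    u = {}
    for trait in config.true_h2:
        G0 = config.slot_covariance(trait)
        # guard: chol of PSD-but-singular matrices (e.g. rg = 1)
        L = np.linalg.cholesky(G0 + 1e-12 * np.eye(3))
        z = rng.standard_normal((n, 3)) @ L.T
        ut = np.zeros((n, 3))
        for i in range(n):
            s, m_ = sire[i], dam[i]
            pa = np.zeros(3)
            if s >= 0:
                pa += 0.5 * ut[s]
            if m_ >= 0:
                pa += 0.5 * ut[m_]
            ut[i] = pa + np.sqrt(d[i]) * z[i]
        u[trait] = ut
    litter_ids = pedigree.table["litter_id"].unique()
    sv = np.sqrt(config.litter_variance_fraction)
    litter_effects = {
        trait: pd.Series(rng.standard_normal(len(litter_ids)) * sv, index=litter_ids)
        for trait in config.true_h2
    }
    return TrueGeneticValues(
        slots=BREEDS, u=u, litter_effects=litter_effects, animal_ids=ids
    )


# ---------------------------------------------------------------------------
# fixed-effect machinery shared by both record generators


def _herd_country_map(config, rng):
    n_herd = config.fixed_effect_levels.get("herd", 40)
    n_country = config.fixed_effect_levels.get("country", 4)
    herd_country = np.arange(n_herd) % n_country
    effects = {
        "herd": rng.normal(0.0, config.fixed_effect_sd.get("herd", 0.0), n_herd),
        "country": rng.normal(0.0, config.fixed_effect_sd.get("country", 0.0), n_country),
        "season": rng.normal(0.0, config.fixed_effect_sd.get("season", 0.0), 4),
        "dam_parity": rng.normal(
            0.0, config.fixed_effect_sd.get("dam_parity", 0.0), max(2, config.litters_per_dam)
        ),
    }
    herd_weaned_mean = rng.normal(config.weaned_mean, config.weaned_herd_sd, n_herd)
    return herd_country, effects, herd_weaned_mean


def _fixed_effect_variance(config):
    sds = config.fixed_effect_sd
    v = sum(sds.get(k, 0.0) ** 2 for k in ("herd", "year", "country", "season", "dam_parity"))
    v += config.weaned_liability_slope**2 * config.weaned_mean
    return v


# ---------------------------------------------------------------------------
# lifetime records


def simulate_lifetime_records(
    pedigree: Pedigree, values: TrueGeneticValues, config: SimulationConfig
) -> LifetimeData:
    """Per-parity culling histories on a liability threshold.

    Each parity's liability is the sum of the sow's Survival breeding
    value, her birth-litter effect, herd/year/country/season/dam-parity
    effects, a weaned-count term and an i.i.d. residual; she is culled
    when it exceeds the threshold calibrated so the marginal culling
    probability equals the configured per-breed, per-parity base rate.
    Sows still alive at the observation end are censored.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    tab = pedigree.table
    fem = tab[tab["sex"] == "F"].reset_index(drop=True)
    if fem.empty:
        raise DataError("pedigree contains no females")
    n = len(fem)
    idx_in_ped = {a: i for i, a in enumerate(tab["animal"].to_numpy())}
    rows_ped = np.array([idx_in_ped[a] for a in fem["animal"]])

    herd_country, eff, herd_weaned_mean = _herd_country_map(config, rng)
    n_herd = len(herd_country)
    herd = rng.integers(0, n_herd, size=n)
    country = herd_country[herd]

    slot = np.array([BREEDS.index(b) for b in fem["breed"]])
    u = values.u["Survival"][rows_ped, slot]
    v = values.litter_effects["Survival"].reindex(fem["litter_id"]).to_numpy()
    h2 = np.array([config.true_h2["Survival"][b] for b in fem["breed"]])
    sigma_e = np.sqrt(1.0 - h2 - config.litter_variance_fraction - config.permanent_env_fraction)
    perm = (
        np.sqrt(config.permanent_env_fraction) * rng.standard_normal(n)
        if config.permanent_env_fraction > 0
        else np.zeros(n)
    )
    dam_par = fem["dam_parity"].to_numpy().clip(1) - 1
    dam_par = np.minimum(dam_par, len(eff["dam_parity"]) - 1)
    base_fixed = (
        eff["herd"][herd]
        + eff["country"][country]
        + eff["dam_parity"][dam_par]
    )
    year_sd = config.fixed_effect_sd.get("year", 0.0)
    year_effects = {}

    v_total = 1.0 + _fixed_effect_variance(config)
    obs_end = config.resolved_observation_end()
    end_ts = pd.Timestamp(obs_end)

    rates = {
        b: np.asarray(config.culling_base_rate_per_parity[b], dtype=float)
        for b in config.culling_base_rate_per_parity
    }
    breed_arr = fem["breed"].to_numpy()

    mu_age, sd_age = config.first_insemination_age
    mu_ws, sd_ws = config.wean_to_service

    alive = np.ones(n, dtype=bool)
    insem = fem["birth_date"].to_numpy().astype("datetime64[D]") + np.round(
        rng.normal(mu_age, sd_age, n)
    ).astype("timedelta64[D]")
    culled_after = np.full(n, -1)
    rec = {k: [] for k in (
        "animal", "parity", "insemination_date", "farrowing_date", "n_weaned",
        "herd", "country", "season", "year",
    )}

    for k in range(1, config.max_parities + 1):
        if not alive.any():
            break
        act = np.where(alive)[0]
        ins_k = insem[act]
        # insemination after the cut-off is unobserved entirely
        observed_ins = ins_k <= np.datetime64(obs_end)
        farrow = ins_k + np.timedelta64(GESTATION_DAYS, "D")
        farrow_obs = farrow <= np.datetime64(obs_end)
        # sows whose next farrowing falls beyond the window are censored now
        censor = ~farrow_obs
        # record the dangling insemination if it was observed
        for j in np.where(censor & observed_ins)[0]:
            i = act[j]
            rec["animal"].append(fem["animal"].iloc[i])
            rec["parity"].append(k)
            rec["insemination_date"].append(ins_k[j])
            rec["farrowing_date"].append(np.datetime64("NaT"))
            rec["n_weaned"].append(-1)
            rec["herd"].append(herd[i])
            rec["country"].append(country[i])
            rec["season"].append(int(pd.Timestamp(ins_k[j]).quarter))
            rec["year"].append(int(pd.Timestamp(ins_k[j]).year))
        alive[act[censor]] = False
        act = act[farrow_obs]
        if len(act) == 0:
            continue
        ins_k = ins_k[farrow_obs]
        farrow = farrow[farrow_obs]

        years = ins_k.astype("datetime64[Y]").astype(int) + 1970
        for y in np.unique(years):
            if y not in year_effects:
                year_effects[y] = rng.normal(0.0, year_sd)
        year_eff = np.array([year_effects[y] for y in years])
        quarters = (ins_k.astype("datetime64[M]").astype(int) % 12) // 3  # 0..3
        weaned = rng.poisson(herd_weaned_mean[herd[act]])
        e_k = rng.normal(0.0, sigma_e[act])
        liab = (
            u[act]
            + v[act]
            + perm[act]
            + base_fixed[act]
            + year_eff
            + eff["season"][quarters]
            + config.weaned_liability_slope * (weaned - config.weaned_mean)
            + e_k
        )
        p_k = np.array([rates[b][min(k - 1, len(rates[b]) - 1)] for b in breed_arr[act]])
        tau = norm.ppf(1.0 - p_k) * np.sqrt(v_total)
        culled = liab > tau

        for pos, i in enumerate(act):
            rec["animal"].append(fem["animal"].iloc[i])
            rec["parity"].append(k)
            rec["insemination_date"].append(ins_k[pos])
            rec["farrowing_date"].append(farrow[pos])
            rec["n_weaned"].append(int(weaned[pos]))
            rec["herd"].append(herd[i])
            rec["country"].append(country[i])
            rec["season"].append(int(quarters[pos]) + 1)
            rec["year"].append(int(years[pos]))

        culled_after[act[culled]] = k
        alive[act[culled]] = False
        nxt = act[~culled]
        insem[nxt] = farrow[~culled] + np.round(
            rng.normal(mu_ws, sd_ws, len(nxt))
        ).astype("timedelta64[D]")

    records = pd.DataFrame(rec)
    records["insemination_date"] = pd.to_datetime(records["insemination_date"])
    records["farrowing_date"] = pd.to_datetime(records["farrowing_date"])
    records.loc[records["n_weaned"] < 0, "n_weaned"] = pd.NA
    sows = pd.DataFrame(
        {
            "animal": fem["animal"],
            "breed": fem["breed"],
            "birth_date": fem["birth_date"],
            "litter_id": fem["litter_id"],
            "dam_parity": fem["dam_parity"],
            "herd": herd,
            "country": country,
            "culled_after_parity": np.where(culled_after > 0, culled_after, np.nan),
            "observation_end_date": end_ts,
        }
    )
    return LifetimeData(records=records, sows=sows, observation_end=obs_end)


# ---------------------------------------------------------------------------
# direct quantitative records (for recovery experiments)


def simulate_quantitative_records(
    pedigree: Pedigree,
    values: TrueGeneticValues,
    trait: str,
    config: SimulationConfig,
    breeds=None,
    include: str = "nonfounders",
) -> pd.DataFrame:
    """One continuous record per animal with exactly the configured components.

    y = herd + u(own slot) + v(birth litter) + e with var(u) = h2(slot),
    var(v) = litter fraction and var(e) the complement (unit phenotypic
    variance).  Used by variance-component and prediction recovery
    experiments where the generating truth must be known exactly.

    include: "nonfounders" (default), "females" or "all".
    """
    rng = np.random.default_rng(config.seed + 4)
    tab = pedigree.table
    mask = np.ones(len(tab), dtype=bool)
    if include == "nonfounders":
        mask &= (tab["sire"] != 0).to_numpy() | (tab["dam"] != 0).to_numpy()
    elif include == "females":
        mask &= (tab["sex"] == "F").to_numpy()
    elif include != "all":
        raise ConfigurationError(f"unknown include mode {include!r}")
    if breeds is not None:
        mask &= tab["breed"].isin(list(breeds)).to_numpy()
    sel = tab[mask]
    if sel.empty:
        raise DataError("no animals selected for quantitative records")

    rows = np.where(mask)[0]
    slot = np.array([BREEDS.index(b) for b in sel["breed"]])
    u = values.u[trait][rows, slot]
    v = values.litter_effects[trait].reindex(sel["litter_id"]).to_numpy()
    h2 = np.array([config.true_h2[trait][b] for b in sel["breed"]])
    sigma_e = np.sqrt(1.0 - h2 - config.litter_variance_fraction)
    herd_country, eff, _ = _herd_country_map(config, rng)
    herd = rng.integers(0, len(herd_country), size=len(sel))
    y = eff["herd"][herd] + u + v + sigma_e * rng.standard_normal(len(sel))
    return pd.DataFrame(
        {
            "animal": sel["animal"].to_numpy(),
            "slot": sel["breed"].to_numpy(),
            "value": y,
            "herd": herd,
            "litter_id": sel["litter_id"].to_numpy(),
            "true_u": u,
        }
    )
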