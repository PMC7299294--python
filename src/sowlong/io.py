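"""File formats, configuration and pipeline orchestration.

Everything is plain text: CSV/TSV tables with documented headers,
optional PLINK .ped/.map genotype emission, coordinate-list matrix
export, YAML configuration and a JSON manifest with SHA-256 checksums so
every numbers-bearing output is traceable to a config and seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import relationships, traits, validation as vld
from .errors import ConfigurationError, DataError
from .mixed_model import ModelSpec, VarianceComponents, fit_blup
from .reml import estimate_reml, genetic_correlation, heritability
from .simulate import (
    GenotypeData,
    LifetimeData,
    Pedigree,
    SimulationConfig,
    simulate_genetic_values,
    simulate_genotypes,
    simulate_lifetime_records,
    simulate_pedigree,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "traits", "relmat", "reml", "blup", "validate")


# ---------------------------------------------------------------------------
# readers / writers


def write_pedigree(pedigree: Pedigree, path):
    pedigree.table.to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    tab = pd.read_csv(path, parse_dates=["birth_date"])
    if tab.empty:
        log.warning("empty pedigree file %s", path)
    if tab["animal"].duplicated().any():
        raise DataError(f"duplicated animal ids in {path}")
    tab["sire"] = tab["sire"].fillna(0).astype(tab["animal"].dtype)
    tab["dam"] = tab["dam"].fillna(0).astype(tab["animal"].dtype)
    return Pedigree(tab)


def write_genotypes(gt: GenotypeData, path):
    """Tab-separated dosage matrix; first column animal id, header = SNP ids."""
    df = pd.DataFrame(gt.dosages, columns=gt.snp_ids)
    df.insert(0, "animal", gt.ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeData:
    df = pd.read_csv(path, sep="\t")
    dosages = df.drop(columns="animal").to_numpy()
    bad = ~np.isin(dosages, (0, 1, 2))
    if bad.any():
        rows = np.unique(np.where(bad)[0])[:5] + 2  # header + 1-based
        raise DataError(f"dosages outside {{0,1,2}} near lines {list(rows)} of {path}")
    return GenotypeData(
        ids=df["animal"].to_numpy(),
        snp_ids=df.columns[1:].to_numpy(),
        dosages=dosages.astype(np.int8),
    )


def write_plink(gt: GenotypeData, prefix):
    """Minimal PLINK .ped/.map pair (alleles coded A/B, dummy positions)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as f:
        for j, s in enumerate(gt.snp_ids):
            f.write(f"1 {s} 0 {j + 1}\n")
    code = {0: "A A", 1: "A B", 2: "B B"}
    with open(prefix.with_suffix(".ped"), "w") as f:
        for i, a in enumerate(gt.ids):
            geno = " ".join(code[int(d)] for d in gt.dosages[i])
            f.write(f"0 {a} 0 0 0 -9 {geno}\n")


def read_plink(prefix) -> GenotypeData:
    prefix = Path(prefix)
    snp_ids = [line.split()[1] for line in open(prefix.with_suffix(".map"))]
    ids, rows = [], []
    for line in open(prefix.with_suffix(".ped")):
        parts = line.split()
        ids.append(parts[1])
        alleles = parts[6:]
        d = [
            (alleles[2 * j] == "B") + (alleles[2 * j + 1] == "B")
            for j in range(len(snp_ids))
        ]
        rows.append(d)
    return GenotypeData(
        ids=np.array(ids), snp_ids=np.array(snp_ids), dosages=np.array(rows, dtype=np.int8)
    )


def write_lifetime(lifetime: LifetimeData, records_path, sows_path):
    lifetime.records.to_csv(records_path, index=False)
    lifetime.sows.to_csv(sows_path, index=False)


def read_lifetime(records_path, sows_path) -> LifetimeData:
    recs = pd.read_csv(records_path, parse_dates=["insemination_date", "farrowing_date"])
    sows = pd.read_csv(
        sows_path, parse_dates=["birth_date", "observation_end_date"]
    )
    end = pd.Timestamp(sows["observation_end_date"].iloc[0]).date() if len(sows) else dt.date.today()
    return LifetimeData(records=recs, sows=sows, observation_end=end)


def write_matrix_coo(rel, path, id_map_path):
    """Coordinate-list text export (row-id, col-id, value) with an id-map sidecar."""
    M = rel.values
    coo = sp.coo_matrix(M) if sp.issparse(M) else sp.coo_matrix(np.asarray(M))
    with open(path, "w") as f:
        f.write("row\tcol\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            f.write(f"{rel.ids[i]}\t{rel.ids[j]}\t{v:.10g}\n")
    pd.DataFrame({"animal": rel.ids, "row": np.arange(len(rel.ids))}).to_csv(
        id_map_path, index=False
    )


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class PipelineConfig:
    """One run: either a simulation block or input file paths, plus options."""

    out_dir: str = "run"
    seed: int = 2020
    simulation: SimulationConfig | None = None
    pedigree_path: str | None = None
    genotypes_path: str | None = None
    lifetime_records_path: str | None = None
    lifetime_sows_path: str | None = None
    traits: tuple = ("LGY12", "LGY15", "Survival")
    breeds: tuple = ("A", "B", "X")
    trait_mode: str = "same"
    min_farm_size: int = 50
    min_country_size: int = 1000
    min_breeds: int = 2
    maf_threshold: float = 0.01
    genotyped_fraction: float = 0.3
    blend_weight: float = 0.05
    tau: float = 1.0
    omega: float = 1.0
    reml_method: str = "ai"
    reml_max_iter: int | None = None
    validation_fraction_masked: float = 0.3
    n_validation_per_breed: int = 1000

    def __post_init__(self):
        has_sim = self.simulation is not None
        has_files = self.pedigree_path is not None
        if has_sim == has_files:
            raise ConfigurationError(
                "exactly one of a simulation block or input paths must be configured"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "rg_pb_cb" in sim:
                sim["rg_pb_cb"] = {
                    (k.split("/")[0], k.split("/")[1]): v for k, v in sim["rg_pb_cb"].items()
                }
            if "observation_end" in sim and sim["observation_end"] is not None:
                sim["observation_end"] = pd.Timestamp(sim["observation_end"]).date()
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"]["rg_pb_cb"] = {
                f"{k[0]}/{k[1]}": v for k, v in self.simulation.rg_pb_cb.items()
            }
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: PipelineConfig, stages=STAGES) -> Path:
    """Execute the requested stages in order, writing artifacts and a manifest.

    Later stages resume from the files earlier stages wrote, so any
    suffix of the stage list can be re-run on an existing directory.
    """
    stages = [s for s in STAGES if s in set(stages)]
    if not stages:
        raise ConfigurationError("no known stages requested")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest["config"] = json.loads(json.dumps(config.resolved(), default=str))
    manifest.setdefault("stages", {})

    def record(stage, files):
        manifest["stages"][stage] = {
            "files": {str(Path(f).name): _sha256(f) for f in files},
            "timestamp": dt.datetime.now().isoformat(),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    def need(path, stage):
        if not Path(path).exists():
            raise DataError(f"missing artifact {path}: run stage '{stage}' first")
        return path

    sim = config.simulation

    if "simulate" in stages:
        if sim is None:
            raise ConfigurationError("simulate stage requires a simulation block")
        ped = simulate_pedigree(sim)
        gt = simulate_genotypes(ped, sim)
        vals = simulate_genetic_values(ped, sim)
        life = simulate_lifetime_records(ped, vals, sim)
        write_pedigree(ped, out / "pedigree.csv")
        write_genotypes(gt, out / "genotypes.tsv")
        write_lifetime(life, out / "lifetime_records.csv", out / "lifetime_sows.csv")
        np.savez(out / "true_values.npz", **{t: vals.u[t] for t in vals.u})
        record("simulate", [out / "pedigree.csv", out / "genotypes.tsv",
                            out / "lifetime_records.csv", out / "lifetime_sows.csv"])

    if "traits" in stages:
        life = read_lifetime(
            need(out / "lifetime_records.csv", "simulate"),
            need(out / "lifetime_sows.csv", "simulate"),
        )
        builders = {
            "LGY12": traits.build_lgy12,
            "LGY15": traits.build_lgy15,
            "Survival": traits.build_survival,
        }
        files = []
        excl_lines = []
        for t in config.traits:
            tab, excl = builders[t](life)
            tab, removed = traits.apply_cohort_filters(
                tab, config.min_farm_size, config.min_country_size, config.min_breeds
            )
            path = out / f"trait_{t}.csv"
            tab.to_csv(path, index=False)
            files.append(path)
            excl_lines.append(f"{t}: excluded {len(excl)} sows, filter removals {removed}")
        (out / "exclusions.log").write_text("\n".join(excl_lines) + "\n")
        record("traits", files)

    if "relmat" in stages:
        ped = read_pedigree(need(out / "pedigree.csv", "simulate"))
        gt = read_genotypes(need(out / "genotypes.tsv", "simulate"))
        A_inv = relationships.build_A_inverse(ped)
        rng = np.random.default_rng(config.seed)
        tab = ped.table.set_index("animal")
        n_g = int(config.genotyped_fraction * len(gt.ids))
        g_idx = np.sort(rng.choice(len(gt.ids), size=max(n_g, 2), replace=False))
        g_ids = gt.ids[g_idx]
        breeds_g = tab.loc[g_ids, "breed"].to_numpy()
        retained, report = relationships.filter_snps(
            gt.dosages[g_idx], breeds_g, config.maf_threshold, strict=False
        )
        G = relationships.build_G(gt.dosages[g_idx], g_ids, retained)
        A22 = relationships.build_A22(ped, g_ids)
        H_inv = relationships.build_H_inverse(
            A_inv, A22, G, tau=config.tau, omega=config.omega, blend_weight=config.blend_weight
        )
        write_matrix_coo(A_inv, out / "A_inverse.txt", out / "A_inverse_ids.csv")
        write_matrix_coo(H_inv, out / "H_inverse.txt", out / "H_inverse_ids.csv")
        (out / "snp_filter.json").write_text(json.dumps({
            "n_input": report.n_input,
            "n_removed_not_segregating": report.n_removed_not_segregating,
            "n_removed_maf": report.n_removed_maf,
            "n_retained": report.n_retained,
        }, indent=2))
        pd.Series(g_ids, name="animal").to_csv(out / "genotyped_ids.csv", index=False)
        record("relmat", [out / "A_inverse.txt", out / "H_inverse.txt", out / "snp_filter.json"])

    if "reml" in stages or "blup" in stages or "validate" in stages:
        ped = read_pedigree(need(out / "pedigree.csv", "simulate"))
        A_inv = relationships.build_A_inverse(ped)

    if "reml" in stages:
        results = {}
        files = []
        for t in config.traits:
            tab = pd.read_csv(need(out / f"trait_{t}.csv", "traits"))
            present = [b for b in config.breeds if b in set(tab["breed"])]
            mode = config.trait_mode if len(present) > 1 else "same"
            data = traits.assemble_dataset(tab, present, mode)
            spec = ModelSpec.for_trait(t, trait_mode=mode)
            vc = estimate_reml(
                data, spec, A_inv, method=config.reml_method,
                max_iter=config.reml_max_iter, seed=config.seed,
            )
            entry = {
                "slots": list(vc.slots),
                "G0": np.atleast_2d(vc.G0).tolist(),
                "sigma_v2": None if vc.sigma_v2 is None else list(map(float, vc.sigma_v2)),
                "sigma_e2": list(map(float, vc.sigma_e2)),
                "converged": bool(vc.converged),
                "n_iterations": vc.n_iterations,
                "loglik": vc.loglik,
                "h2": [heritability(vc, s)["h2"] for s in range(len(vc.slots))],
            }
            if len(vc.slots) > 1:
                corr, _ = genetic_correlation(vc)
                entry["genetic_correlations"] = corr.to_dict()
            results[t] = entry
        path = out / "variance_components.json"
        path.write_text(json.dumps(results, indent=2))
        files.append(path)
        record("reml", files)

    if "blup" in stages or "validate" in stages:
        vc_json = json.loads(Path(need(out / "variance_components.json", "reml")).read_text())

        def vc_of(t):
            e = vc_json[t]
            return VarianceComponents(
                slots=tuple(e["slots"]),
                G0=np.array(e["G0"]),
                sigma_v2=None if e["sigma_v2"] is None else np.array(e["sigma_v2"]),
                sigma_e2=np.array(e["sigma_e2"]),
            )

    if "blup" in stages:
        gt = read_genotypes(need(out / "genotypes.tsv", "simulate"))
        g_ids = pd.read_csv(need(out / "genotyped_ids.csv", "relmat"))["animal"].to_numpy()
        tabp = ped.table.set_index("animal")
        gsel = np.isin(gt.ids, g_ids)
        retained, _ = relationships.filter_snps(
            gt.dosages[gsel], tabp.loc[gt.ids[gsel], "breed"], config.maf_threshold, strict=False
        )
        G = relationships.build_G(gt.dosages[gsel], gt.ids[gsel], retained)
        A22 = relationships.build_A22(ped, gt.ids[gsel])
        H_inv = relationships.build_H_inverse(
            A_inv, A22, G, config.tau, config.omega, config.blend_weight
        )
        files = []
        for t in config.traits:
            tab = pd.read_csv(need(out / f"trait_{t}.csv", "traits"))
            present = [b for b in config.breeds if b in set(tab["breed"])]
            mode = config.trait_mode if len(present) > 1 else "same"
            data = traits.assemble_dataset(tab, present, mode)
            spec = ModelSpec.for_trait(t, trait_mode=mode, relationship="H")
            fit = fit_blup(data, spec, vc_of(t), H_inv)
            path = out / f"ebv_{t}.csv"
            fit.u_hat.rename_axis("animal").to_csv(path)
            files.append(path)
            meta = {
                "trait": t, "relationship": fit.relationship_kind,
                "solver": fit.diagnostics, "n_records": int(len(data)),
            }
            (out / f"ebv_{t}_meta.json").write_text(json.dumps(meta, indent=2, default=str))
        record("blup", files)

    if "validate" in stages:
        rows = []
        for t in config.traits:
            tab = pd.read_csv(need(out / f"trait_{t}.csv", "traits"), parse_dates=["birth_date"])
            present = [b for b in config.breeds if b in set(tab["breed"])]
            data = traits.assemble_dataset(tab, present, "same")
            cut = data["birth_date"].quantile(1.0 - config.validation_fraction_masked)
            plan = vld.ValidationPlan(
                cutoff_date_pb=cut, cutoff_date_cb=cut,
                n_validation_per_breed=config.n_validation_per_breed, anchor_trait=t,
            )
            training, val_ids, summary = vld.make_training_validation_split(data, plan)
            spec = ModelSpec.for_trait(t)
            vc = vc_of(t)
            full = fit_blup(data, spec, vc, A_inv)
            reduced = fit_blup(training, spec, vc, A_inv)
            cp = vld.corrected_phenotypes(full, data)
            h2 = heritability(vc)["h2"]
            for breed, ids in val_ids.items():
                idx = pd.Index(ids)
                try:
                    acc = vld.prediction_accuracy(
                        cp.loc[cp.index.intersection(idx)],
                        reduced.u_hat.iloc[:, 0].loc[
                            reduced.u_hat.index.intersection(idx)
                        ],
                        h2,
                    )
                except DataError:
                    continue
                rows.append({"trait": t, "breed": breed, **acc})
        acc_df = pd.DataFrame(rows)
        acc_df.to_csv(out / "accuracy.csv", index=False)
        record("validate", [out / "accuracy.csv"])

    return out
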