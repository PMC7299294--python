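"""MME assembly and BLUP solutions against dense GLS oracles and known limits."""

import numpy as np
import pandas as pd
import pytest

import sowlong as sl
from conftest import make_pedigree, random_pedigree
from sowlong.errors import ConfigurationError
from sowlong.mixed_model import build_design_matrices, assemble_mme, solve_mme


def quant_sim(rng, n_founders=12, n_extra=48, h2=0.3, litter_frac=0.1, breeds=("A",)):
    """Small continuous dataset on a random pedigree with known components."""
    ped = random_pedigree(rng, n_founders, n_extra)
    cfg = sl.SimulationConfig(
        n_snp=10, seed=int(rng.integers(2**31)),
        true_h2={"LGY15": {b: h2 for b in "ABX"}},
        litter_variance_fraction=litter_frac,
    )
    vals = sl.simulate_genetic_values(ped, cfg)
    tab = sl.simulate_quantitative_records(ped, vals, "LGY15", cfg, include="all")
    tab["slot"] = "all"
    return ped, tab, cfg


def gls_oracle(dm, vc, A):
    """Dense GLS/BLUP: u = G Z' Vy^-1 (y - X beta)."""
    G0 = np.atleast_2d(vc.G0)
    Gbig = np.kron(G0, A)
    Z = dm.Z.toarray()
    X = dm.X.toarray()
    R = np.diag(np.asarray(vc.sigma_e2, float)[dm.slot_of_record])
    Vy = Z @ Gbig @ Z.T + R
    if dm.V is not None:
        codes = np.array([dm.slots.index(s) for s, _ in dm.litter_index])
        D = np.diag(np.asarray(vc.sigma_v2, float)[codes])
        Vy = Vy + dm.V.toarray() @ D @ dm.V.toarray().T
    Vi = np.linalg.inv(Vy)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ dm.y)
    u = Gbig @ Z.T @ Vi @ (dm.y - X @ beta)
    return beta, u


class TestDesign:
    def test_single_record_intercept_only(self):
        tab = pd.DataFrame(
            {"animal": [1], "slot": ["all"], "value": [2.0], "litter_id": [5]}
        )
        spec = sl.ModelSpec(trait="LGY15")
        dm = build_design_matrices(tab, spec, animal_ids=np.array([1]))
        assert dm.X.toarray().tolist() == [[1.0]]
        assert dm.Z.toarray().tolist() == [[1.0]]
        assert dm.V.toarray().tolist() == [[1.0]]

    def test_repeated_records_share_animal_column(self):
        tab = pd.DataFrame(
            {
                "animal": [7, 7, 7], "slot": ["all"] * 3, "value": [0.0, 0.0, 1.0],
                "litter_id": [1, 1, 1],
            }
        )
        spec = sl.ModelSpec(trait="Survival", fixed_factors=(), covariate_by={})
        dm = build_design_matrices(tab, spec, animal_ids=np.array([6, 7]))
        Z = dm.Z.toarray()
        assert Z.shape == (3, 2)
        assert (Z[:, 1] == 1).all()

    def test_different_mode_blocks_are_disjoint(self):
        tab = pd.DataFrame(
            {
                "animal": [1, 2], "slot": ["B", "X"], "value": [0.5, -0.5],
                "litter_id": [1, 2], "herd": [1, 2],
            }
        )
        spec = sl.ModelSpec(trait="LGY15", trait_mode="different")
        dm = build_design_matrices(tab, spec, animal_ids=np.array([1, 2]))
        q = 2
        Z = dm.Z.toarray()
        assert Z[0, 0 * q + 0] == 1  # B record -> slot 0
        assert Z[1, 1 * q + 1] == 1  # X record -> slot 1

    def test_confounded_columns_are_dropped(self):
        tab = pd.DataFrame(
            {
                "animal": [1, 2, 3, 4], "slot": ["all"] * 4, "value": [0.1, 0.2, 0.3, 0.4],
                "herd": [1, 1, 2, 2], "country": [1, 1, 2, 2], "litter_id": [1, 2, 3, 4],
            }
        )
        spec = sl.ModelSpec(trait="LGY15", fixed_factors=("herd", "country"))
        dm = build_design_matrices(tab, spec, animal_ids=np.array([1, 2, 3, 4]))
        assert len(dm.dropped_labels) == 1  # country duplicates herd


class TestAssembly:
    def test_zero_variances_rejected(self, rng):
        ped, tab, cfg = quant_sim(rng)
        spec = sl.ModelSpec(trait="LGY15", fixed_factors=("herd",))
        dm = build_design_matrices(tab, spec, ped.ids)
        vc = sl.VarianceComponents(
            slots=("all",), G0=np.array([[0.0]]), sigma_v2=np.array([0.1]),
            sigma_e2=np.array([0.8]),
        )
        with pytest.raises(ConfigurationError):
            assemble_mme(dm, vc, sl.build_A_inverse(ped).values)

    def test_huge_litter_shrinkage_sends_v_to_zero(self, rng):
        ped, tab, cfg = quant_sim(rng, litter_frac=0.1)
        spec = sl.ModelSpec(trait="LGY15", fixed_factors=("herd",))
        vc_small = sl.VarianceComponents(
            slots=("all",), G0=np.array([[0.3]]), sigma_v2=np.array([1e-8]),
            sigma_e2=np.array([0.6]),
        )
        fit = sl.fit_blup(tab, spec, vc_small, sl.build_A_inverse(ped))
        assert np.abs(fit.v_hat.to_numpy()).max() < 1e-6

    def test_uncorrelated_multitrait_equals_independent_fits(self, rng):
        ped = random_pedigree(rng, 12, 48)
        cfg = sl.SimulationConfig(
            n_snp=10, seed=3,
            true_h2={"LGY15": {"A": 0.3, "B": 0.3, "X": 0.3}},
            rg_pb_cb={("A", "LGY15"): 0.0, ("B", "LGY15"): 0.0},
            litter_variance_fraction=0.05,
        )
        tabA = ped.table.copy()
        tabA.loc[tabA.index[::2], "breed"] = "B"  # mix breeds for two slots
        ped2 = sl.Pedigree(tabA)
        vals = sl.simulate_genetic_values(ped2, cfg)
        tab = sl.simulate_quantitative_records(ped2, vals, "LGY15", cfg, include="all")
        spec = sl.ModelSpec(trait="LGY15", trait_mode="different")
        Ainv = sl.build_A_inverse(ped2)
        vc = sl.VarianceComponents(
            slots=("A", "B"), G0=np.diag([0.3, 0.3]), sigma_v2=np.array([0.05, 0.05]),
            sigma_e2=np.array([0.65, 0.65]),
        )
        joint = sl.fit_blup(tab, spec, vc, Ainv)
        for s in ("A", "B"):
            sub = tab[tab["slot"] == s].copy()
            sub["slot"] = "all"
            vc1 = sl.VarianceComponents(
                slots=("all",), G0=np.array([[0.3]]), sigma_v2=np.array([0.05]),
                sigma_e2=np.array([0.65]),
            )
            single = sl.fit_blup(sub, sl.ModelSpec(trait="LGY15"), vc1, Ainv)
            assert np.allclose(joint.u_hat[s], single.u_hat["all"], atol=1e-8)


class TestSolve:
    def test_identity_system(self):
        import scipy.sparse as sp

        rhs = np.array([1.0, -2.0, 3.0])
        sol, diag = solve_mme(sp.eye(3).tocsc(), rhs)
        assert np.allclose(sol, rhs)

    def test_direct_and_pcg_agree(self, rng):
        ped, tab, cfg = quant_sim(rng, 15, 85)
        spec = sl.ModelSpec(trait="LGY15", fixed_factors=("herd",))
        dm = build_design_matrices(tab, spec, ped.ids)
        vc = sl.VarianceComponents(
            slots=("all",), G0=np.array([[0.3]]), sigma_v2=np.array([0.1]),
            sigma_e2=np.array([0.6]),
        )
        LHS, RHS = assemble_mme(dm, vc, sl.build_A_inverse(ped).values)
        direct, _ = solve_mme(LHS, RHS, method="direct")
        pcg, diag = solve_mme(LHS, RHS, method="pcg", tol=1e-12)
        assert np.abs(direct - pcg).max() / np.abs(direct).max() < 1e-6

    def test_blup_matches_gls_oracle(self, rng):
        for _ in range(5):
            ped, tab, cfg = quant_sim(rng, 10, 40)
            spec = sl.ModelSpec(trait="LGY15", fixed_factors=("herd",))
            Ainv = sl.build_A_inverse(ped)
            vc = sl.VarianceComponents(
                slots=("all",), G0=np.array([[0.3]]), sigma_v2=np.array([0.1]),
                sigma_e2=np.array([0.6]),
            )
            fit = sl.fit_blup(tab, spec, vc, Ainv)
            beta, u = gls_oracle(fit.design, vc, sl.build_A(ped).values)
            scale = max(np.abs(u).max(), 1e-12)
            assert np.abs(fit.u_hat["all"].to_numpy() - u).max() / scale < 1e-8

    def test_phenotypeless_offspring_gets_parent_average(self, rng):
        ped, tab, cfg = quant_sim(rng, 10, 40)
        # add an extra offspring of two existing animals, with no record
        tabp = ped.table
        males = tabp[tabp["sex"] == "M"]["animal"]
        females = tabp[tabp["sex"] == "F"]["animal"]
        new = pd.DataFrame(
            [{
                "animal": 999, "sire": males.iloc[0], "dam": females.iloc[0],
                "breed": "A", "sex": "F", "birth_date": pd.Timestamp("2016-01-01"),
                "litter_id": 999, "dam_parity": 1,
            }]
        )
        ped2 = sl.Pedigree(pd.concat([tabp, new], ignore_index=True))
        spec = sl.ModelSpec(trait="LGY15", fixed_factors=("herd",))
        vc = sl.VarianceComponents(
            slots=("all",), G0=np.array([[0.3]]), sigma_v2=np.array([0.1]),
            sigma_e2=np.array([0.6]),
        )
        fit = sl.fit_blup(tab, spec, vc, sl.build_A_inverse(ped2))
        u = fit.u_hat["all"]
        expected = 0.5 * (u.loc[males.iloc[0]] + u.loc[females.iloc[0]])
        assert u.loc[999] == pytest.approx(expected, abs=1e-8)

    def test_repeatability_weighted_record_equivalence(self, rng):
        # k identical-mean records with residual sigma_e^2 equal one record at sigma_e^2/k
        ped = random_pedigree(rng, 10, 30)
        rng2 = np.random.default_rng(5)
        animals = ped.ids[-20:]
        k = 3
        recs = pd.DataFrame(
            {
                "animal": np.repeat(animals, k),
                "slot": "all",
                "value": np.repeat(rng2.normal(size=20), k) + rng2.normal(0, 0.3, 60),
                "litter_id": np.repeat(np.arange(20), k),
            }
        )
        spec = sl.ModelSpec(trait="Survival", fixed_factors=(), covariate_by={},
                            repeatability=True, random_litter=True)
        Ainv = sl.build_A_inverse(ped)
        vc = sl.VarianceComponents(
            slots=("all",), G0=np.array([[0.2]]), sigma_v2=np.array([0.1]),
            sigma_e2=np.array([0.9]),
        )
        full = sl.fit_blup(recs, spec, vc, Ainv)
        collapsed = recs.groupby(["animal", "litter_id"], as_index=False)["value"].mean()
        collapsed["slot"] = "all"
        vc_w = sl.VarianceComponents(
            slots=("all",), G0=np.array([[0.2]]), sigma_v2=np.array([0.1]),
            sigma_e2=np.array([0.9 / k]),
        )
        red = sl.fit_blup(collapsed, spec, vc_w, Ainv)
        assert np.abs(
            full.u_hat["all"].to_numpy() - red.u_hat["all"].to_numpy()
        ).max() < 1e-8

    def test_same_vs_different_mode_at_unit_correlation(self, rng):
        ped, tab, cfg = quant_sim(rng, 12, 48)
        tab2 = tab.copy()
        tab2["slot"] = np.where(np.arange(len(tab2)) % 2 == 0, "B", "X")
        Ainv = sl.build_A_inverse(ped)
        spec_d = sl.ModelSpec(trait="LGY15", trait_mode="different")
        r = 1.0 - 1e-8
        vc_d = sl.VarianceComponents(
            slots=("B", "X"), G0=np.array([[0.3, 0.3 * r], [0.3 * r, 0.3]]),
            sigma_v2=np.array([0.1, 0.1]), sigma_e2=np.array([0.6, 0.6]),
        )
        fit_d = sl.fit_blup(tab2, spec_d, vc_d, Ainv)
        vc_s = sl.VarianceComponents(
            slots=("all",), G0=np.array([[0.3]]), sigma_v2=np.array([0.1]),
            sigma_e2=np.array([0.6]),
        )
        tab_s = tab2.copy()
        tab_s["slot"] = "all"
        fit_s = sl.fit_blup(tab_s, sl.ModelSpec(trait="LGY15"), vc_s, Ainv)
        # litter effects differ (slot-specific), so compare genetic rankings
        c = np.corrcoef(
            fit_d.u_hat["B"].to_numpy() + fit_d.u_hat["X"].to_numpy(),
            fit_s.u_hat["all"].to_numpy(),
        )[0, 1]
        assert c > 0.99
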