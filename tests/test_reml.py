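"""REML: likelihood ascent, EM/AI agreement, derived genetic parameters."""

import numpy as np
import pandas as pd
import pytest

import sowlong as sl
from conftest import random_pedigree
from sowlong.errors import ConfigurationError
from sowlong.mixed_model import VarianceComponents


def quant_data(seed, n_founders=60, n_generations=2, h2=0.3, litter_frac=0.05,
               litter_size=5, breeds=("A",)):
    cfg = sl.SimulationConfig(
        n_founders_per_line=n_founders, n_generations=n_generations,
        litter_size_mean=litter_size, f1_fraction=0.0, n_snp=10, seed=seed,
        true_h2={"LGY15": {b: h2 for b in "ABX"}},
        litter_variance_fraction=max(litter_frac, 1e-6),
    )
    ped = sl.simulate_pedigree(cfg)
    vals = sl.simulate_genetic_values(ped, cfg)
    tab = sl.simulate_quantitative_records(ped, vals, "LGY15", cfg, breeds=list(breeds))
    tab["slot"] = "all"
    return ped, tab


def repeated_records_data(seed, n_animals=150, k=5, su2=0.3, se2=0.7):
    """High-information repeatability design: k records per unrelated animal."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(su2), n_animals)
    tab = pd.DataFrame(
        {
            "animal": np.repeat(np.arange(1, n_animals + 1), k),
            "slot": "all",
            "value": np.repeat(u, k) + rng.normal(0, np.sqrt(se2), n_animals * k),
        }
    )
    ped_tab = pd.DataFrame(
        {
            "animal": np.arange(1, n_animals + 1), "sire": 0, "dam": 0,
            "breed": "A", "sex": "F",
            "birth_date": pd.Timestamp("2013-01-01"), "litter_id": np.arange(n_animals),
            "dam_parity": 1,
        }
    )
    return sl.Pedigree(ped_tab), tab


class TestEstimate:
    def test_null_data_estimates_near_zero_heritability(self):
        ped, tab = quant_data(11, n_founders=300, h2=0.0, breeds=("A", "B"))
        Ainv = sl.build_A_inverse(ped)
        spec = sl.ModelSpec(trait="LGY15", fixed_factors=("herd",))
        vc = sl.estimate_reml(tab, spec, Ainv, method="ai", seed=0)
        assert sl.heritability(vc)["h2"] < 0.02

    def test_em_loglik_never_decreases(self):
        ped, tab = quant_data(12, n_founders=40)
        Ainv = sl.build_A_inverse(ped)
        spec = sl.ModelSpec(trait="LGY15", fixed_factors=("herd",))
        vc = sl.estimate_reml(tab, spec, Ainv, method="em", max_iter=60)
        lls = [h["loglik"] for h in vc.history]
        diffs = np.diff(lls)
        assert (diffs > -1e-7 * np.abs(lls[:-1])).all()

    def test_em_and_ai_reach_the_same_optimum(self):
        # repeated records give EM a fast contraction rate, so the two
        # algorithms can be compared at a tight tolerance
        ped, tab = repeated_records_data(13)
        Ainv = sl.build_A_inverse(ped)
        spec = sl.ModelSpec(trait="Survival", fixed_factors=(), covariate_by={},
                            repeatability=True, random_litter=False)
        ai = sl.estimate_reml(tab, spec, Ainv, method="ai", seed=0)
        em = sl.estimate_reml(tab, spec, Ainv, method="em", max_iter=2000, tol=1e-10)
        assert ai.converged
        assert abs(ai.G0[0, 0] - em.G0[0, 0]) < 1e-4
        assert abs(ai.sigma_e2[0] - em.sigma_e2[0]) < 1e-4

    def test_small_and_large_path_agree(self):
        ped, tab = quant_data(14, n_founders=50)
        Ainv = sl.build_A_inverse(ped)
        spec = sl.ModelSpec(trait="LGY15", fixed_factors=("herd",))
        exact = sl.estimate_reml(tab, spec, Ainv, method="ai", seed=0, exact_limit=10**6)
        large = sl.estimate_reml(tab, spec, Ainv, method="ai", seed=0, exact_limit=0)
        assert abs(exact.G0[0, 0] - large.G0[0, 0]) < 1e-3
        assert abs(exact.sigma_e2[0] - large.sigma_e2[0]) < 1e-3

    def test_unknown_method_rejected(self):
        ped, tab = quant_data(15, n_founders=20)
        with pytest.raises(ConfigurationError):
            sl.estimate_reml(tab, sl.ModelSpec(trait="LGY15"), sl.build_A_inverse(ped),
                             method="newton")

    def test_nonconvergence_is_surfaced_not_raised(self):
        ped, tab = quant_data(16, n_founders=40)
        Ainv = sl.build_A_inverse(ped)
        spec = sl.ModelSpec(trait="LGY15", fixed_factors=("herd",))
        vc = sl.estimate_reml(tab, spec, Ainv, method="em", max_iter=3)
        assert vc.converged is False
        assert len(vc.history) == 3
        assert np.isfinite(vc.loglik)


class TestDerived:
    def _vc(self, g, v, e):
        return VarianceComponents(
            slots=("all",), G0=np.array([[g]]),
            sigma_v2=np.array([v]), sigma_e2=np.array([e]),
        )

    def test_heritability_trivial_decompositions(self):
        assert sl.heritability(self._vc(1.0, 1e-12, 1e-12))["h2"] == pytest.approx(1.0)
        assert sl.heritability(self._vc(0.026, 0.007, 0.967))["h2"] == pytest.approx(0.026)

    def test_adjusted_heritability_reduces_to_h2_at_one_record(self):
        vc = self._vc(0.1, 0.05, 0.85)
        rep = sl.adjusted_heritability(vc, n=1.0)
        assert rep["h_n2"] == pytest.approx(rep["h2"])

    @pytest.mark.parametrize(
        "g, v, e, n, expected",
        [
            (0.026, 0.0, 0.974, 3.97, 0.0958),   # 4 dp of the direct evaluation
            (0.017, 0.0071, 0.9759, 2.95, 0.048),
        ],
    )
    def test_adjusted_heritability_formula_values(self, g, v, e, n, expected):
        assert sl.adjusted_h2(g, v, e, n) == pytest.approx(expected, abs=5e-4)

    def test_adjusted_heritability_monotone_and_bounded(self):
        vc = self._vc(0.026, 0.007, 0.967)
        values = [sl.adjusted_heritability(vc, n)["h_n2"] for n in (1, 2, 4, 8, 50)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert values[-1] < 0.026 / (0.026 + 0.007)

    def test_adjusted_heritability_rejects_fractional_records_below_one(self):
        with pytest.raises(ConfigurationError):
            sl.adjusted_h2(0.1, 0.0, 0.9, 0.5)

    def test_feasible_litter_variance_inversion_round_trip(self):
        sv = sl.feasible_litter_variance(0.026, 3.97, 0.094)
        assert sl.adjusted_h2(0.026, sv, 1.0 - 0.026 - sv, 3.97) == pytest.approx(0.094)

    def test_genetic_correlation_diagonal_and_rank_one(self):
        vc = VarianceComponents(
            slots=("B", "X"), G0=np.diag([0.2, 0.1]),
            sigma_v2=np.array([0.1, 0.1]), sigma_e2=np.array([0.7, 0.8]),
        )
        corr, _ = sl.genetic_correlation(vc)
        assert corr.iloc[0, 1] == pytest.approx(0.0)
        g = np.array([[0.2, np.sqrt(0.2 * 0.1)], [np.sqrt(0.2 * 0.1), 0.1]])
        vc2 = VarianceComponents(
            slots=("B", "X"), G0=g, sigma_v2=np.array([0.1, 0.1]),
            sigma_e2=np.array([0.7, 0.8]),
        )
        corr2, _ = sl.genetic_correlation(vc2)
        assert abs(corr2.iloc[0, 1]) == pytest.approx(1.0)

    def test_reml_reports_standard_errors(self):
        ped, tab = quant_data(17, n_founders=50)
        Ainv = sl.build_A_inverse(ped)
        vc = sl.estimate_reml(tab, sl.ModelSpec(trait="LGY15", fixed_factors=("herd",)),
                              Ainv, method="ai", seed=0)
        rep = sl.heritability(vc)
        assert rep["h2_se"] is not None and 0 < rep["h2_se"] < 1


def test_mme_loglik_matches_dense_matrix_oracle():
    """The MME-factorisation restricted log-likelihood equals the textbook
    dense form -0.5(log|V_y| + log|X'V_y^-1 X| + y'Py) at several points."""
    from sowlong import mixed_model as mm, reml as rl

    ped, tab = quant_data(19, n_founders=25, litter_size=4)
    Ainv = sl.build_A_inverse(ped)
    A = sl.build_A(ped).values
    spec = sl.ModelSpec(trait="LGY15", fixed_factors=("herd",))
    dm = mm.build_design_matrices(tab, spec, Ainv.ids)
    lay = rl._ParamLayout(1, True)
    prob = rl._RemlProblem(dm, Ainv.values, lay, np.random.default_rng(0), 8, True)
    codes = np.array([dm.slots.index(s) for s, _ in dm.litter_index])
    for g, v, e in [(0.3, 0.05, 0.65), (0.1, 0.2, 0.9), (0.5, 0.01, 0.2)]:
        vc = VarianceComponents(
            slots=dm.slots, G0=np.array([[g]]), sigma_v2=np.array([v]),
            sigma_e2=np.array([e]),
        )
        LHS, RHS = mm.assemble_mme(dm, vc, Ainv.values)
        lu = mm.splu_symmetric(LHS)
        th = lu.solve(RHS)
        r_inv = np.full(dm.n_records, 1.0 / e)
        ll_mme = rl._loglik(prob, vc, lu, th, RHS, r_inv)

        Z, X, V = dm.Z.toarray(), dm.X.toarray(), dm.V.toarray()
        Vy = g * (Z @ A @ Z.T) + V @ np.diag(np.full(len(codes), v)) @ V.T + e * np.eye(dm.n_records)
        Vi = np.linalg.inv(Vy)
        XtVX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.solve(XtVX, X.T @ Vi)
        ll_dense = -0.5 * (
            np.linalg.slogdet(Vy)[1] + np.linalg.slogdet(XtVX)[1] + dm.y @ P @ dm.y
        )
        assert ll_mme == pytest.approx(ll_dense, abs=1e-6)


def test_binary_survival_calibration_recovers_observed_scale_h2():
    """Observed-scale h2 of first-parity culling records matches the Robertson
    conversion of the liability-scale setting.

    First-parity records carry no survivor selection, so the conversion
    applies cleanly; whole-history repeatability analyses of the same data
    are structurally different (a sow's record count depends on her own
    outcomes) and are not expected to match the single-record conversion.
    """
    p = 0.22
    h2_liab = 0.1
    h2_obs = sl.robertson_liability_to_observed(h2_liab, p)
    cfg = sl.SimulationConfig(
        n_founders_per_line=900, n_generations=3, litters_per_dam=2,
        litter_size_mean=6, f1_fraction=0.0, n_snp=10, seed=31,
        true_h2={"Survival": {b: h2_liab for b in "ABX"}},
        litter_variance_fraction=0.02,
        fixed_effect_sd={k: 0.0 for k in ("herd", "year", "country", "season", "dam_parity")},
        weaned_liability_slope=0.0,
        culling_base_rate_per_parity={b: (p,) * 10 for b in "ABX"},
    )
    ped = sl.simulate_pedigree(cfg)
    vals = sl.simulate_genetic_values(ped, cfg)
    life = sl.simulate_lifetime_records(ped, vals, cfg)
    surv, _ = sl.build_survival(life)
    data = sl.assemble_dataset(surv[surv["parity"] == 1], ["A", "B"], "same")
    spec = sl.ModelSpec(trait="Survival", fixed_factors=(), covariate_by={})
    Ainv = sl.build_A_inverse(ped)
    vc = sl.estimate_reml(data, spec, Ainv, method="ai", seed=0)
    est = sl.heritability(vc)["h2"]
    assert abs(est - h2_obs) < 0.01, (est, h2_obs)
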