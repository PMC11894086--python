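import math

import numpy as np
import pytest

from evograph.errors import ValidationError
from evograph.graph_core import make_named_graph
from evograph.longterm import (
    MutationModel,
    complete_phi_provider,
    detailed_balance_stationary,
    discrete_chain_stationary,
    exact_phi_provider,
    fit_nu,
    fit_nu_from_phi,
    hoc_stationary,
    origin_fixation_mc,
    psi_ratio,
    star_phi_provider,
)
from evograph.update_rules import BD_O, BD_P, DB_O, DB_P

FIG5_GRID = (0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)


class TestPsiRatio:
    def test_neutral_is_one(self):
        phi = complete_phi_provider(8)
        assert psi_ratio(phi, 1.0, 1.0) == pytest.approx(1.0)

    def test_complete_n8_power_law(self):
        phi = complete_phi_provider(8)
        assert psi_ratio(phi, 2.0, 1.0) == pytest.approx(64.0, abs=1e-10)

    def test_exact_solver_agrees_with_closed(self, complete8):
        phi = exact_phi_provider(complete8, DB_O)
        assert psi_ratio(phi, 2.0, 1.0) == pytest.approx(64.0, abs=1e-8)

    def test_cycle_same_as_complete(self, cycle8):
        phi = exact_phi_provider(cycle8, DB_O)
        assert psi_ratio(phi, 2.0, 1.0) == pytest.approx(64.0, abs=1e-8)
        assert psi_ratio(phi, 0.5, 1.0) == pytest.approx(2.0**-6, abs=1e-10)

    def test_infinite_ratio_signalled(self):
        from evograph.fixation_exact import limit_complete

        assert psi_ratio(limit_complete, 2.0, 1.0) == math.inf


class TestFitNu:
    def test_flat_psi_gives_zero(self):
        fit = fit_nu([0.5, 0.8, 1.25, 2.0], [1.0, 1.0, 1.0, 1.0])
        assert fit.nu == pytest.approx(0.0)
        assert fit.max_residual == pytest.approx(0.0)

    def test_exact_power_law_recovered(self):
        ratios = [0.5, 0.8, 1.25, 2.0]
        fit = fit_nu(ratios, [r**3.7 for r in ratios])
        assert fit.nu == pytest.approx(3.7)
        assert fit.max_residual < 1e-12

    def test_complete_n8_gives_n_minus_2(self):
        fit = fit_nu_from_phi(complete_phi_provider(8))
        assert fit.nu == pytest.approx(6.0, abs=1e-10)
        assert fit.max_residual < 1e-10

    def test_star_dbp_large_n_gives_one(self):
        phi = star_phi_provider(2000, DB_P)
        fit = fit_nu_from_phi(phi, ratios=(0.9, 0.95, 1.05, 1.1))
        assert fit.nu == pytest.approx(1.0, rel=0.02)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValidationError):
            fit_nu([1.5], [2.0])
        with pytest.raises(ValidationError):
            fit_nu([1.5, 1.5], [2.0, 2.0])


class TestHocStationary:
    def test_nu0_uniform_mean(self):
        st = hoc_stationary(0.0, 1.0, 10.0)
        assert st.mean == pytest.approx(5.5)
        assert st.std == pytest.approx(math.sqrt(81 / 12))

    def test_nu6_mean(self):
        # (7/8) (fmax^8 - fmin^8) / (fmax^7 - fmin^7) on [1, 10]
        st = hoc_stationary(6.0, 1.0, 10.0)
        assert st.mean == pytest.approx(0.875 * (1e8 - 1) / (1e7 - 1), abs=1e-10)

    def test_nu1_mean(self):
        st = hoc_stationary(1.0, 1.0, 10.0)
        assert st.mean == pytest.approx((2 / 3) * 999 / 99, abs=1e-12)

    def test_mean_inside_support(self):
        for nu in (0.0, 0.5, 3.0, 12.0):
            st = hoc_stationary(nu, 2.0, 7.0)
            assert 2.0 < st.mean < 7.0

    def test_negative_nu_rejected(self):
        with pytest.raises(ValidationError):
            hoc_stationary(-0.5, 1.0, 10.0)


class TestDiscreteChain:
    def test_complete_n8_boundary_ratio(self):
        st = discrete_chain_stationary(complete_phi_provider(8), FIG5_GRID)
        assert st.pmf[-1] / st.pmf[0] == pytest.approx(4096.0, rel=1e-8)

    def test_global_balance_and_normalisation(self, star8):
        st = discrete_chain_stationary(exact_phi_provider(star8, DB_P), FIG5_GRID)
        assert sum(st.pmf) == pytest.approx(1.0, abs=1e-12)
        assert st.balance_residual < 1e-10

    def test_detailed_balance_cross_check_complete(self):
        phi = complete_phi_provider(8)
        st = discrete_chain_stationary(phi, FIG5_GRID)
        db = detailed_balance_stationary(phi, FIG5_GRID)
        np.testing.assert_allclose(st.pmf, db, atol=1e-10)

    def test_single_point_grid(self):
        st = discrete_chain_stationary(complete_phi_provider(8), (1.5,))
        assert st.pmf == (1.0,)
        assert st.mean == 1.5

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValidationError):
            discrete_chain_stationary(complete_phi_provider(8), (1.0, 0.5))

    def test_star_dbp_lower_mean_than_complete(self, star8):
        st_star = discrete_chain_stationary(exact_phi_provider(star8, DB_P), FIG5_GRID)
        st_comp = discrete_chain_stationary(complete_phi_provider(8), FIG5_GRID)
        assert st_star.mean < st_comp.mean


class TestOriginFixationMc:
    def test_always_accept_recovers_proposal(self):
        res = origin_fixation_mc(
            lambda a, b: 1.0, MutationModel(fmin=1, fmax=10), 20000, seed=1, burn_in=1000
        )
        assert res.mean == pytest.approx(5.5, abs=4 * res.standard_error)

    def test_complete_n8_matches_closed_form(self):
        phi = complete_phi_provider(8)
        res = origin_fixation_mc(
            phi, MutationModel(fmin=1, fmax=10), 50000, seed=2, burn_in=5000
        )
        oracle = hoc_stationary(6.0, 1.0, 10.0).mean
        assert res.mean == pytest.approx(oracle, abs=4 * res.standard_error)

    def test_star_bd_rules_agree_and_beat_complete(self):
        # Fig-4A-style directional check at small N
        n, steps = 8, 30000
        means = {}
        for rule in (BD_O, BD_P):
            res = origin_fixation_mc(
                star_phi_provider(n, rule),
                MutationModel(fmin=1, fmax=10),
                steps,
                seed=5,
                burn_in=3000,
            )
            means[rule.spelled()] = (res.mean, res.standard_error)
        comp = origin_fixation_mc(
            complete_phi_provider(n, "Bd"),
            MutationModel(fmin=1, fmax=10),
            steps,
            seed=5,
            burn_in=3000,
        )
        (mo, so), (mp, sp) = means["Bd-o"], means["Bd-p"]
        assert abs(mo - mp) < 4 * (so + sp)
        assert min(mo, mp) > comp.mean

    def test_discrete_model_matches_chain_solve(self):
        phi = complete_phi_provider(8)
        res = origin_fixation_mc(
            phi,
            MutationModel(kind="discrete", grid=FIG5_GRID),
            40000,
            seed=3,
            burn_in=4000,
        )
        st = discrete_chain_stationary(phi, FIG5_GRID)
        assert res.mean == pytest.approx(st.mean, abs=4 * res.standard_error)

    def test_seed_reproducibility(self):
        phi = complete_phi_provider(8)
        kw = dict(model=MutationModel(fmin=1, fmax=10), n_steps=2000, seed=9, burn_in=100)
        a = origin_fixation_mc(phi, kw["model"], kw["n_steps"], kw["seed"], kw["burn_in"])
        b = origin_fixation_mc(phi, kw["model"], kw["n_steps"], kw["seed"], kw["burn_in"])
        assert np.array_equal(a.trajectory, b.trajectory)

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            origin_fixation_mc(lambda a, b: 1.0, MutationModel(), 100, seed=0, burn_in=100)
        with pytest.raises(ValidationError):
            MutationModel(fmin=5, fmax=1)
        with pytest.raises(ValidationError):
            MutationModel(kind="discrete")


@pytest.fixture(scope="module")
def stats(star8, complete8):
    out = {}
    for name, g, rule in [
        ("complete-dB", complete8, DB_O),
        ("star-dBo", star8, DB_O),
        ("star-dBp", star8, DB_P),
        ("complete-Bd", complete8, BD_O),
        ("star-Bdo", star8, BD_O),
        ("star-Bdp", star8, BD_P),
    ]:
        out[name] = discrete_chain_stationary(exact_phi_provider(g, rule), FIG5_GRID)
    return out


class TestSteadyStateOrderings:
    """Directional reproductions of the published mean/std orderings at N=8."""

    def test_db_mean_ordering(self, stats):
        assert stats["complete-dB"].mean > stats["star-dBo"].mean > stats["star-dBp"].mean

    def test_bd_star_beats_complete(self, stats):
        assert stats["star-Bdo"].mean > stats["complete-Bd"].mean
        assert stats["star-Bdp"].mean > stats["complete-Bd"].mean

    def test_db_std_ordering_reversed(self, stats):
        assert (
            stats["star-dBp"].std > stats["star-dBo"].std > stats["complete-dB"].std
        )
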