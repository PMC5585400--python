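import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandem5ss.psi_inference import (
    DEFAULT_GRID_STEP,
    FilterThresholds,
    apply_filters,
    bayes_factor,
    compare_conditions,
    psi_posterior,
    read_results,
    write_results,
)
from tandem5ss.io_formats import CountRecord

from conftest import beta_moments, fine_grid_posterior_mean


class TestPosterior:
    def test_no_data_returns_flat_prior(self):
        post = psi_posterior(0, 0)
        assert post.no_data
        assert post.posterior_mean == pytest.approx(0.5, abs=1e-9)
        assert np.allclose(post.density, 1.0, atol=1e-9)

    def test_symmetric_counts_give_half(self):
        post = psi_posterior(5, 5)
        assert post.posterior_mean == pytest.approx(0.5, abs=1e-9)

    def test_beta_closed_form_oracle(self):
        post = psi_posterior(3, 9)
        assert post.posterior_mean == pytest.approx(10 / 14, abs=1e-3)

    @pytest.mark.parametrize("n_distal,n_proximal", [(0, 1), (1, 0), (3, 9), (40, 7), (250, 250)])
    def test_mean_and_ci_match_beta(self, n_distal, n_proximal):
        post = psi_posterior(n_distal, n_proximal)
        mean, lo, hi = beta_moments(n_distal, n_proximal)
        tol = 2 * DEFAULT_GRID_STEP
        assert post.posterior_mean == pytest.approx(mean, abs=tol)
        assert post.ci_low == pytest.approx(lo, abs=tol)
        assert post.ci_high == pytest.approx(hi, abs=tol)
        assert post.ci_low <= post.posterior_mean <= post.ci_high

    def test_unequal_effective_lengths_shift_mean(self):
        post = psi_posterior(5, 5, l_inc=2.0, l_exc=1.0)
        assert post.posterior_mean < 0.5
        oracle = fine_grid_posterior_mean(5, 5, 2.0, 1.0)
        assert post.posterior_mean == pytest.approx(oracle, abs=2 * DEFAULT_GRID_STEP)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            psi_posterior(-1, 3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n_distal=st.integers(0, 300),
        n_proximal=st.integers(0, 300),
        l_ratio=st.floats(0.25, 4.0),
    )
    def test_normalization_invariant(self, n_distal, n_proximal, l_ratio):
        post = psi_posterior(n_distal, n_proximal, l_inc=l_ratio, l_exc=1.0)
        h = post.grid[1] - post.grid[0]
        assert h * post.density.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(post.density >= 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n_distal=st.integers(0, 50), n_proximal=st.integers(0, 50))
    def test_mean_strictly_increases_in_proximal_count(self, n_distal, n_proximal):
        m1 = psi_posterior(n_distal, n_proximal).posterior_mean
        m2 = psi_posterior(n_distal, n_proximal + 1).posterior_mean
        assert m2 > m1


class TestBayesFactor:
    def test_identical_large_samples_favor_h0(self):
        r = bayes_factor((50, 50), (50, 50))
        assert r.bayes_factor < 1

    def test_opposite_extremes_favor_h1(self):
        r = bayes_factor((50, 0), (0, 50))
        assert r.bayes_factor > 10
        assert abs(r.delta_psi) > 0.9

    def test_fine_grid_oracle(self):
        # independent trapezoid integration of the three marginals
        psi = np.linspace(1e-9, 1 - 1e-9, 200_001)
        l1 = psi**4 * (1 - psi) ** 10
        l2 = psi**12 * (1 - psi) ** 2
        m1 = np.trapezoid(l1, psi)
        m2 = np.trapezoid(l2, psi)
        m0 = np.trapezoid(l1 * l2, psi)
        expected = m1 * m2 / m0
        r = bayes_factor((10, 4), (2, 12))
        assert r.bayes_factor == pytest.approx(expected, rel=1e-3)

    def test_empty_sample_fails_read_filters(self):
        r = bayes_factor((0, 0), (5, 0))
        assert not r.pass_num_inc  # no inclusion reads anywhere
        assert r.pass_num_exc  # 5 exclusion reads
        assert np.isfinite(r.bayes_factor) and r.bayes_factor > 0

    def test_bad_grid_step_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor((1, 1), (1, 1), h=0.0)


class TestFilters:
    def _result(self, delta, bf, counts=(3, 4, 5, 1)):
        from tandem5ss.psi_inference import DeltaPsiResult

        nd1, np1, nd2, np2 = counts
        r = DeltaPsiResult(
            event_id="e",
            psi1=0.5,
            psi2=0.5 + delta,
            delta_psi=delta,
            bayes_factor=bf,
            n_distal1=nd1,
            n_proximal1=np1,
            n_distal2=nd2,
            n_proximal2=np2,
        )
        return apply_filters(r)

    def test_all_thresholds_met(self):
        assert self._result(0.25, 12.0).significant

    def test_delta_below_threshold_fails(self):
        r = self._result(0.19, 500.0)
        assert not r.pass_delta and not r.significant

    def test_bf_below_threshold_fails(self):
        r = self._result(0.5, 9.99)
        assert not r.pass_bf and not r.significant

    def test_boundary_values_pass(self):
        r = self._result(0.2, 10.0)
        assert r.pass_delta and r.pass_bf

    def test_read_minima_sum_across_samples(self):
        r = self._result(0.5, 100.0, counts=(0, 0, 1, 1))
        assert r.pass_num_inc and r.pass_num_exc
        r = self._result(0.5, 100.0, counts=(3, 0, 2, 0))
        assert not r.pass_num_inc


class TestCohortInterface:
    def test_compare_and_round_trip(self, tmp_path):
        records = [
            CountRecord("ev1", "control", 30, 70),
            CountRecord("ev1", "knockdown", 70, 30),
            CountRecord("ev2", "control", 50, 50),
            CountRecord("ev2", "knockdown", 48, 52),
        ]
        results = compare_conditions(records, "control", "knockdown")
        assert [r.event_id for r in results] == ["ev1", "ev2"]
        assert results[0].significant
        assert not results[1].significant
        p = tmp_path / "res.tsv"
        write_results(results, p)
        back = read_results(p)
        assert [r.event_id for r in back] == ["ev1", "ev2"]
        assert back[0].significant and not back[1].significant
        assert back[0].delta_psi == pytest.approx(results[0].delta_psi, abs=1e-5)

    def test_missing_sample_contributes_zero_counts(self):
        records = [CountRecord("ev1", "control", 10, 10)]
        (r,) = compare_conditions(records, "control", "knockdown")
        assert r.n_distal2 == 0 and r.n_proximal2 == 0
        assert not r.significant
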