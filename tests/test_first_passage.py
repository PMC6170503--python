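"""First-passage times to the phosphorylation threshold."""

import numpy as np
import pytest

from phostime import (FirstPassageQuery, KineticRates, ModelSpec,
                      absorbing_reduction, build_generator, fpt_lst,
                      fpt_moments)


def toy_rates():
    return KineticRates(alpha_plus=0.02, alpha_minus=0.5, beta_plus=0.03,
                        beta_minus=0.1, gamma_plus=0.4, gamma_minus=0.05)


class TestAbsorbingReduction:
    def test_transient_set_sizes(self, ip23):
        sys5 = absorbing_reduction(ip23, 5)
        assert len(sys5.transient) == sum(23 + 1 - l for l in range(5)) == 110
        sys1 = absorbing_reduction(ip23, 1)
        assert len(sys1.transient) == 24

    def test_row_deficits_only_adjacent_to_target(self, ip23):
        sys5 = absorbing_reduction(ip23, 5)
        rs = np.asarray(sys5.sub_generator.sum(axis=1)).ravel()
        assert rs.max() <= 1e-12
        lv = ip23.space.levels[sys5.transient]
        assert (sys5.absorption[lv == 4] > 0).any()
        assert np.allclose(sys5.absorption[lv < 4], 0.0, atol=1e-15)

    def test_threshold_out_of_range_rejected(self, ip23):
        with pytest.raises(ValueError):
            absorbing_reduction(ip23, 24)


class TestMoments:
    def test_toy_mean_matches_dense_solve(self):
        """n_R=2, n_L=1, N=1: the 2x2 dense inverse is the oracle."""
        spec = ModelSpec(kind="IP", n_R=2, n_L=1)
        rates = toy_rates()
        res = fpt_moments(FirstPassageQuery(spec=spec, rates=rates, threshold=1))
        # transient states (0,0) and (1,0)
        Qd = np.array([[-2 * rates.alpha_plus * 1 * 2, 2 * rates.alpha_plus * 1 * 2],
                       [rates.alpha_minus, -(rates.alpha_minus + rates.beta_plus * 1)]])
        m = np.linalg.solve(-Qd, np.ones(2))
        assert res.at((0, 0))["mean_s"] == pytest.approx(m[0], rel=1e-12)

    def test_block_sweep_agrees_with_sparse_lu(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            vals = 10.0 ** rng.uniform(-3, 0, size=6)
            rates = KineticRates(*vals)
            spec = ModelSpec(kind="DP", n_R=24, n_L=6)
            q = FirstPassageQuery(spec=spec, rates=rates, threshold=3)
            a = fpt_moments(q, method="qbd").moments
            b = fpt_moments(q, method="sparse").moments
            assert np.max(np.abs(a - b) / np.abs(b)) <= 1e-8

    def test_variance_nonnegative_and_means_positive(self, ip23, kin):
        q = FirstPassageQuery(spec=ip23.spec, rates=kin, threshold=5)
        res = fpt_moments(q, gen=ip23)
        assert (res.mean > 0).all()
        assert (res.moments[1] >= res.mean ** 2 - 1e-9 * res.moments[1]).all()

    def test_mean_increases_with_threshold(self, ip23, kin):
        means = [fpt_moments(FirstPassageQuery(spec=ip23.spec, rates=kin,
                                               threshold=N),
                             gen=ip23).mean_from_empty()
                 for N in (1, 3, 5, 8, 12)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_mean_decreases_with_ligand_count(self, kin):
        means = []
        for n_L in (23, 58, 116):
            spec = ModelSpec(kind="IP", n_R=232, n_L=n_L)
            means.append(fpt_moments(
                FirstPassageQuery(spec=spec, rates=kin, threshold=5)
            ).mean_from_empty())
        assert means[0] > means[1] > means[2]

    def test_delayed_phosphorylation_is_slower(self, ip23, dp23, kin):
        for N in (2, 5, 8):
            t_ip = fpt_moments(FirstPassageQuery(spec=ip23.spec, rates=kin,
                                                 threshold=N),
                               gen=ip23).mean_from_empty()
            t_dp = fpt_moments(FirstPassageQuery(spec=dp23.spec, rates=kin,
                                                 threshold=N),
                               gen=dp23).mean_from_empty()
            assert t_dp >= t_ip

    def test_initial_state_at_or_above_threshold_has_zero_time(self, ip23, kin):
        res = fpt_moments(FirstPassageQuery(spec=ip23.spec, rates=kin,
                                            threshold=3), gen=ip23)
        assert res.at((0, 3)) == {"mean_s": 0.0, "sd_s": 0.0}


class TestLaplaceStieltjes:
    def test_certain_absorption_at_zero(self, ip23, kin):
        q = FirstPassageQuery(spec=ip23.spec, rates=kin, threshold=4)
        phi = fpt_lst(q, [0.0], gen=ip23)
        assert np.allclose(phi, 1.0, atol=1e-10)

    def test_values_in_unit_interval_and_vanishing_at_large_s(self, ip23, kin):
        q = FirstPassageQuery(spec=ip23.spec, rates=kin, threshold=4)
        phi = fpt_lst(q, [1e-3, 1e6], gen=ip23)
        assert ((phi > 0) & (phi <= 1)).all()
        sys4 = absorbing_reduction(ip23, 4)
        far = ip23.space.levels[sys4.transient] < 3
        assert phi[1][far].max() < 1e-4

    def test_pure_birth_path_closed_form(self):
        """On a 1-ligand IP chain the LST is a product of rate/(rate+s)."""
        spec = ModelSpec(kind="IP", n_R=4, n_L=1)
        # alpha_minus ~ 0, beta_minus ~ 0: (0,0) -> (1,0) -> (0,1) is a pure
        # birth path with rates 2*a+*4 and b+*3
        rates = KineticRates(alpha_plus=0.05, alpha_minus=1e-14,
                             beta_plus=0.07, beta_minus=1e-14)
        q = FirstPassageQuery(spec=spec, rates=rates, threshold=1)
        s = 0.31
        lam1 = 2 * 0.05 * 1 * 4
        lam2 = 0.07 * 3
        phi = fpt_lst(q, [s])
        expected = (lam1 / (lam1 + s)) * (lam2 / (lam2 + s))
        gen = build_generator(spec, rates)
        sys1 = absorbing_reduction(gen, 1)
        pos = list(sys1.transient).index(gen.space.ordinal((0, 0)))
        assert phi[0][pos] == pytest.approx(expected, rel=1e-6)

    def test_lst_slope_at_origin_matches_mean(self, ip23, kin):
        q = FirstPassageQuery(spec=ip23.spec, rates=kin, threshold=3)
        res = fpt_moments(q, gen=ip23)
        h = 1e-9
        phi = fpt_lst(q, [0.0, h], gen=ip23)
        slope = (phi[0] - phi[1]) / h
        assert np.max(np.abs(slope - res.mean) / res.mean) <= 1e-4

    def test_negative_s_rejected(self, ip23, kin):
        q = FirstPassageQuery(spec=ip23.spec, rates=kin, threshold=3)
        with pytest.raises(ValueError):
            fpt_lst(q, [-1.0], gen=ip23)
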