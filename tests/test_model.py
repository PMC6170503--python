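"""State-space enumeration and generator structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phostime import (KineticRates, ModelSpec, StateSpace, build_generator,
                      generator_derivative, state_count)

RATE_NAMES_DP = ("alpha_plus", "alpha_minus", "beta_plus", "beta_minus",
                 "gamma_plus", "gamma_minus")


def random_rates(rng, kind="DP"):
    vals = 10.0 ** rng.uniform(-4, -1, size=6)
    if kind == "IP":
        vals[4:] = 0.0
    return KineticRates(*vals)


class TestEnumeration:
    def test_small_ip_enumeration_is_exhaustive(self):
        space = StateSpace.enumerate(ModelSpec(kind="IP", n_R=4, n_L=2))
        assert space.states == ((0, 0), (1, 0), (2, 0), (0, 1), (1, 1), (0, 2))

    @pytest.mark.parametrize("kind,expected", [("IP", 300), ("DP", 2600)])
    def test_ligand_limited_counts_at_study_size(self, kind, expected):
        space = StateSpace.enumerate(ModelSpec(kind=kind, n_R=232, n_L=23))
        assert len(space) == expected

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(n_L=st.integers(1, 25), extra=st.integers(0, 40))
    def test_counts_match_closed_form_in_ligand_limited_regime(self, n_L, extra):
        n_R = 2 * n_L + extra
        for kind in ("IP", "DP"):
            space = StateSpace.enumerate(ModelSpec(kind=kind, n_R=n_R, n_L=n_L))
            assert len(space) == state_count(kind, n_L)

    @pytest.mark.parametrize("n_R,n_L", [(5, 4), (5, 10), (6, 3)])
    def test_other_regimes_enumerate_admissible_states_only(self, n_R, n_L):
        spec = ModelSpec(kind="IP", n_R=n_R, n_L=n_L)
        space = StateSpace.enumerate(spec)
        brute = {(n1, n2) for n1 in range(n_L + 1) for n2 in range(n_L + 1)
                 if n1 + n2 <= n_L and n1 + 2 * n2 <= n_R}
        assert set(space.states) == brute
        assert len(space.states) == len(set(space.states))

    def test_ordinal_maps_are_mutually_inverse(self):
        space = StateSpace.enumerate(ModelSpec(kind="DP", n_R=30, n_L=8))
        for i, s in enumerate(space.states):
            assert space.ordinal(s) == i

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(kind="IP", n_R=0, n_L=5)
        with pytest.raises(ValueError):
            ModelSpec(kind="DP", n_R=10, n_L=-1)


class TestGenerator:
    def test_empty_state_single_destination_and_rate(self, ip23):
        """From (0,0) the only event is monomer binding at 2*a+*n_L*n_R."""
        row = ip23.matrix.getrow(ip23.space.ordinal((0, 0))).tocoo()
        off = {(j, v) for j, v in zip(row.col, row.data) if v > 0}
        assert len(off) == 1
        (j, v), = off
        assert ip23.space.states[j] == (1, 0)
        assert v == pytest.approx(2 * ip23.rates.alpha_plus * 23 * 232, rel=1e-12)
        assert v == pytest.approx(3.899e-3, rel=1e-3)

    def test_interior_ip_state_has_four_outgoing_transitions(self, ip23):
        row = ip23.matrix.getrow(ip23.space.ordinal((3, 2))).tocoo()
        assert sum(1 for v in row.data if v > 0) == 4

    @pytest.mark.parametrize("kind", ["IP", "DP"])
    def test_row_sums_vanish(self, kind):
        rng = np.random.default_rng(7)
        for _ in range(5):
            spec = ModelSpec(kind=kind, n_R=int(rng.integers(12, 40)),
                             n_L=int(rng.integers(2, 6)))
            gen = build_generator(spec, random_rates(rng, kind))
            rs = np.asarray(gen.matrix.sum(axis=1)).ravel()
            scale = np.abs(gen.matrix.diagonal()).max()
            assert np.abs(rs).max() <= 1e-12 * max(scale, 1.0)

    @pytest.mark.parametrize("kind", ["IP", "DP"])
    def test_base_chain_is_irreducible(self, kind):
        spec = ModelSpec(kind=kind, n_R=20, n_L=6)
        gen = build_generator(spec, random_rates(np.random.default_rng(3), kind))
        assert gen.is_irreducible()

    @pytest.mark.parametrize("kind", ["IP", "DP"])
    def test_level_transitions_are_tridiagonal(self, kind):
        """QBD property: a reaction changes the phosphorylated count by <= 1."""
        spec = ModelSpec(kind=kind, n_R=30, n_L=8)
        gen = build_generator(spec, random_rates(np.random.default_rng(5), kind))
        coo = gen.matrix.tocoo()
        lv = gen.space.levels
        jumps = np.abs(lv[coo.row] - lv[coo.col])
        assert jumps.max() <= 1

    def test_dp_without_phosphorylation_rate_rejected(self):
        with pytest.raises(ValueError):
            build_generator(ModelSpec(kind="DP", n_R=10, n_L=3),
                            KineticRates(1e-3, 1e-3, 1e-3, 1e-3, 0.0, 0.0))


class TestGeneratorDerivative:
    @pytest.mark.parametrize("kind", ["IP", "DP"])
    def test_rate_weighted_patterns_reassemble_generator(self, kind):
        rng = np.random.default_rng(11)
        spec = ModelSpec(kind=kind, n_R=25, n_L=7)
        rates = random_rates(rng, kind)
        gen = build_generator(spec, rates)
        names = RATE_NAMES_DP[:4] if kind == "IP" else RATE_NAMES_DP
        total = sum(getattr(rates, n) * generator_derivative(spec, n, gen.space)
                    for n in names)
        assert abs(gen.matrix - total).max() <= 1e-14

    def test_pattern_matches_finite_difference(self, kin):
        spec = ModelSpec(kind="DP", n_R=30, n_L=5)
        h = 1e-6
        for name in RATE_NAMES_DP:
            B = generator_derivative(spec, name)
            bumped = kin.replace(**{name: getattr(kin, name) + h})
            fd = (build_generator(spec, bumped).matrix
                  - build_generator(spec, kin).matrix) / h
            assert abs(fd - B).max() <= 1e-8 * max(1.0, abs(B).max())

    def test_unknown_rate_name_rejected(self):
        spec = ModelSpec(kind="IP", n_R=10, n_L=3)
        with pytest.raises(KeyError):
            generator_derivative(spec, "gamma_plus")   # IP has no gamma
        with pytest.raises(KeyError):
            generator_derivative(spec, "not_a_rate")
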