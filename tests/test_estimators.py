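import math

import numpy as np
import pytest

from finitek import (
    ClusterModel,
    CountsSeries,
    ReactionSpec,
    block_error,
    closed_form_K,
    cycle_closure,
    delta_G,
    elementary_K,
    enumerate_mechanisms,
    exact_moment,
    fluctuation_relation_check,
    partition_fluctuation_equality,
    path_K,
    prob_ratio_K,
    relative_fluctuation,
    sample_states,
    series_moment,
    transfer_K_direct,
    transfer_K_ratio,
    transfer_K_uncorrelated,
    uncorrelated_K,
)


def generic_model(n, volume=23.0, c_std=0.7):
    """Oracle with deliberately non-factorial b so K_m are all distinct."""
    b = [1.0] + [math.factorial(m) * 1.3**m / (1 + 0.1 * m) for m in range(2, n + 1)]
    return ClusterModel(n, volume, b, c_std=c_std)


class TestSeriesMoment:
    def test_empty_spec(self, sampled_series_n4):
        est = series_moment(sampled_series_n4, {})
        assert est.value == 1.0 and est.stderr == 0.0

    def test_falling_factorial_zeroes_single_count(self):
        s = CountsSeries(np.array([[1, 0, 1, 0]]), volume=5.0, n_total=4)
        assert series_moment(s, {1: 2}).value == 0.0

    def test_matches_exact_moments(self, factorial_model_n4, sampled_series_n4):
        for spec in ({1: 1}, {2: 1}, {1: 2}, {1: 1, 3: 1}, {2: 2}, {1: 4}):
            exact = exact_moment(factorial_model_n4, spec)
            est = series_moment(sampled_series_n4, spec)
            assert abs(est.value - exact) < 3 * est.stderr


class TestElementaryK:
    def test_two_particle_oracle(self, two_particle_model):
        assert elementary_K(two_particle_model, (1, 1)).value == pytest.approx(1.0)

    def test_concerted_trimer_factorial_b(self):
        m = ClusterModel(3, 10.0, [1.0, 2.0, 6.0], c_std=1.0)
        assert elementary_K(m, (1, 1, 1)).value == pytest.approx(1.0, rel=1e-12)

    def test_identity_reaction(self, factorial_model_n4):
        # single reactant: <c_1> c_std^0 / <c_1> = 1 by construction
        assert elementary_K(factorial_model_n4, (1,)).value == pytest.approx(1.0)

    def test_oversized_product_rejected(self, factorial_model_n4):
        with pytest.raises(ValueError):
            elementary_K(factorial_model_n4, (2, 3))

    def test_unobserved_species_flagged(self):
        s = CountsSeries(np.array([[0, 2], [0, 2]] * 5), volume=5.0, n_total=4)
        k = elementary_K(s, (1, 1))
        assert not k.defined and math.isnan(k.value)


class TestPathIndependence:
    """Every mechanism yields the same K_m value: the state-function property."""

    @pytest.mark.parametrize("n", range(2, 13))
    def test_all_mechanisms_match_closed_form(self, n):
        mechs = enumerate_mechanisms(min(n, 6))
        m_target = min(n, 6)
        for volume in (3.0, 11.0, 60.0, 300.0, 2500.0):
            model = generic_model(n, volume=volume)
            ref = closed_form_K(model, m_target)
            for path in mechs:
                k = path_K(model, path)
                assert k.value == pytest.approx(ref, rel=1e-10), k.label

    def test_mechanism_enumeration_includes_all_orders(self):
        mechs = enumerate_mechanisms(4)
        labels = {tuple(r.reactants for r in p) for p in mechs}
        assert ((1, 1), (1, 2), (1, 3)) in labels      # gradual additions
        assert ((1, 1), (1, 1), (2, 2)) in labels      # dimer-of-dimers
        assert ((1, 1), (1, 1, 2)) in labels           # mixed order
        assert ((1, 1, 1), (1, 3)) in labels           # three-body first
        assert ((1, 1, 1, 1),) in labels               # concerted four-body
        assert len(enumerate_mechanisms(4, max_order=2)) == 2

    def test_size_invariance_of_two_body_constants(self):
        # correlated two-body constants are identical across N_total at fixed b
        vals = {}
        for n in range(4, 13):
            model = generic_model(n, volume=17.0)
            for r in ((1, 1), (1, 2), (1, 3), (2, 2)):
                vals.setdefault(r, []).append(elementary_K(model, r).value)
        for r, vs in vals.items():
            assert np.ptp(vs) < 1e-12 * abs(vs[0]), r

    def test_non_telescoping_path_rejected(self, factorial_model_n4):
        with pytest.raises(ValueError):
            path_K(factorial_model_n4, [(1, 1), (1, 1)])


class TestUncorrelatedK:
    def test_two_particle_bias_formula(self):
        # K'_2 / K_2 = (1 + b_2/V)/2 exactly for N_total = 2
        for volume, b2 in ((10.0, 2.0), (50.0, 3.0), (1e4, 2.0), (1e7, 5.0)):
            model = ClusterModel(2, volume, [1.0, b2], c_std=1.0)
            ratio = uncorrelated_K(model, 2).value / closed_form_K(model, 2)
            assert ratio == pytest.approx((1 + b2 / volume) / 2, rel=1e-10)

    def test_large_volume_limit_is_half(self):
        model = ClusterModel(2, 1e9, [1.0, 2.0], c_std=1.0)
        ratio = uncorrelated_K(model, 2).value / closed_form_K(model, 2)
        assert ratio == pytest.approx(0.5, rel=1e-6)

    def test_varies_with_volume_unlike_K(self):
        vals_k, vals_kp = [], []
        for volume in (5.0, 20.0, 100.0):
            model = generic_model(4, volume=volume)
            vals_k.append(elementary_K(model, (1, 1, 1, 1)).value)
            vals_kp.append(uncorrelated_K(model, 4).value)
        assert np.ptp(vals_k) < 1e-10 * abs(vals_k[0])
        assert np.ptp(vals_kp) > 0.1 * abs(vals_kp[0])

    def test_fully_aggregated_series_undefined(self):
        s = CountsSeries(np.array([[0, 0, 0, 1]] * 10), volume=5.0, n_total=4)
        assert not uncorrelated_K(s, 4).defined


class TestTransferReactions:
    RXN13 = ReactionSpec((1, 3), (2, 2))
    RXN14 = ReactionSpec((1, 4), (2, 3))

    def test_factorial_oracle_values(self, factorial_model_n4):
        assert transfer_K_direct(factorial_model_n4, self.RXN13).value == pytest.approx(
            1.0, rel=1e-12
        )
        m5 = ClusterModel(5, 10.0, [math.factorial(k) for k in range(1, 6)], c_std=1.0)
        assert transfer_K_direct(m5, self.RXN14).value == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("rxn", [RXN13, RXN14])
    def test_direct_equals_ratio_on_oracle(self, rxn, generic_model_n8):
        kd = transfer_K_direct(generic_model_n8, rxn)
        kr = transfer_K_ratio(generic_model_n8, rxn)
        assert kd.value == pytest.approx(kr.value, rel=1e-12)

    def test_direct_equals_ratio_within_error_on_samples(self, generic_model_n8):
        s = sample_states(generic_model_n8, 100_000, seed=23)
        kd = transfer_K_direct(s, self.RXN13)
        kr = transfer_K_ratio(s, self.RXN13)
        joint = math.hypot(kd.stderr, kr.stderr)
        assert abs(kd.value - kr.value) < 3 * joint

    def test_uncorrelated_transfer_is_biased(self):
        model = generic_model(4, volume=10.0)
        kd = transfer_K_direct(model, self.RXN13).value
        kp = transfer_K_uncorrelated(model, self.RXN13).value
        assert kp != pytest.approx(kd, rel=1e-6)

    def test_transfer_bias_smaller_than_association_bias(self):
        # partial cancellation: correlations on both sides of a transfer
        model = generic_model(4, volume=10.0)
        trans_bias = abs(
            math.log(
                transfer_K_uncorrelated(model, self.RXN13).value
                / transfer_K_direct(model, self.RXN13).value
            )
        )
        assoc_bias = abs(
            math.log(uncorrelated_K(model, 4).value / closed_form_K(model, 4))
        )
        assert trans_bias < assoc_bias

    def test_uncorrelated_ratio_approaches_one_in_bulk(self):
        # large N at fixed concentration: correlations vanish
        n = 30
        b = [1.0] + [math.factorial(m) * 0.5**m for m in range(2, n + 1)]
        model = ClusterModel(n, 1500.0, b, c_std=1.0)
        ratio = (
            transfer_K_uncorrelated(model, self.RXN13).value
            / transfer_K_direct(model, self.RXN13).value
        )
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_self_inverse_reaction(self, generic_model_n8):
        rxn = ReactionSpec((1, 3), (1, 3))
        assert transfer_K_direct(generic_model_n8, rxn).value == pytest.approx(1.0)
        assert transfer_K_uncorrelated(generic_model_n8, rxn).value == pytest.approx(1.0)

    def test_ratio_rejects_foreign_stoichiometry(self, generic_model_n8):
        with pytest.raises(ValueError):
            transfer_K_ratio(generic_model_n8, ReactionSpec((2, 4), (3, 3)))


class TestProbRatioK:
    def test_two_particle_oracle(self, two_particle_model):
        # f_dimer/f_monomer * (c_std V)/2 = (1/6)/(5/6) * 10/2 = 1
        assert prob_ratio_K(two_particle_model).value == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_equals_concerted_form_frame_by_frame(self, n):
        model = generic_model(n, volume=8.0)
        s = sample_states(model, 5000, seed=n)
        kp = prob_ratio_K(s)
        kc = elementary_K(s, tuple([1] * n))
        assert kp.value == pytest.approx(kc.value, rel=1e-12)

    def test_never_clustered_series(self):
        s = CountsSeries(np.array([[2, 1, 0, 0]] * 50), volume=5.0, n_total=4)
        k = prob_ratio_K(s)
        assert math.isnan(k.value) and math.isnan(k.stderr) and not k.defined


class TestRelativeFluctuations:
    def test_constant_expression(self, sampled_series_n4):
        ell = relative_fluctuation(sampled_series_n4, lambda c: np.ones(len(c)), {1: 1})
        assert ell.value == pytest.approx(0.0, abs=1e-12)

    def test_independent_iid_columns(self):
        rng = np.random.default_rng(0)
        # two independent systems concatenated: counts of size-1 and size-3
        # clusters vary independently frame to frame
        n1 = rng.integers(0, 3, size=40_000)
        n3 = rng.integers(0, 3, size=40_000)
        counts = np.zeros((40_000, 15), dtype=int)
        counts[:, 0] = n1
        counts[:, 2] = n3
        counts[:, 14] = 0
        # pad with a large inert cluster to conserve particles
        filler = 15 - (n1 + 3 * n3)
        assert filler.min() >= 1
        for i, f in enumerate(filler):
            counts[i, f - 1] += 1
        s = CountsSeries(counts, volume=5.0, n_total=15)
        ell = relative_fluctuation(s, {1: 1}, {3: 1})
        assert abs(ell.value) < 3 * max(ell.stderr, 1e-4)

    def test_oracle_vs_sampled(self, two_particle_model):
        exact = relative_fluctuation(
            two_particle_model, lambda c: c[:, 0], lambda c: c[:, 0]
        )
        s = sample_states(two_particle_model, 100_000, seed=4)
        samp = relative_fluctuation(s, lambda c: c[:, 0], lambda c: c[:, 0])
        assert exact.stderr == 0.0
        assert abs(samp.value - exact.value) < 3 * samp.stderr


class TestFluctuationRelation:
    @pytest.mark.parametrize("i,j", [(1, 1), (1, 2), (1, 3), (2, 2), (2, 3), (1, 7)])
    def test_exact_identity_on_oracle(self, generic_model_n8, i, j):
        K = elementary_K(generic_model_n8, (i, j))
        lhs, rhs = fluctuation_relation_check(generic_model_n8, i, j, K)
        assert rhs == pytest.approx(lhs, rel=1e-12, abs=1e-15)

    def test_two_particle_mean_dimer_count(self, two_particle_model):
        lhs, _ = fluctuation_relation_check(
            two_particle_model, 1, 1, elementary_K(two_particle_model, (1, 1))
        )
        assert lhs == pytest.approx(1.0 / 6.0)

    def test_sampled_consistency(self, generic_model_n8):
        s = sample_states(generic_model_n8, 100_000, seed=31)
        K = elementary_K(s, (1, 3))
        lhs, rhs = fluctuation_relation_check(s, 1, 3, K)
        scale = abs(lhs) * (3 * K.stderr / max(K.value, 1e-300) + 0.05)
        assert abs(lhs - rhs) < max(scale, 1e-3)


class TestPartitionFluctuationEquality:
    def test_exact_on_n8_oracle(self, generic_model_n8):
        l1, l2 = partition_fluctuation_equality(generic_model_n8, 1, 3, 2, 2)
        assert l1.value == pytest.approx(l2.value, rel=1e-10)

    def test_degenerate_partition(self, generic_model_n8):
        l1, l2 = partition_fluctuation_equality(generic_model_n8, 2, 2, 2, 2)
        assert l1.value == l2.value

    def test_sampled_agreement(self, generic_model_n8):
        s = sample_states(generic_model_n8, 200_000, seed=13)
        l1, l2 = partition_fluctuation_equality(s, 1, 3, 2, 2)
        joint = math.hypot(l1.stderr, l2.stderr)
        assert abs(l1.value - l2.value) < 3 * joint

    def test_mismatched_partition_rejected(self, generic_model_n8):
        with pytest.raises(ValueError):
            partition_fluctuation_equality(generic_model_n8, 1, 3, 2, 3)


class TestDeltaG:
    def test_unit_constant(self):
        from finitek import KEstimate

        assert delta_G(KEstimate(1.0, 0.0, True, "", 0), 300.0).value == 0.0

    def test_natural_log_scale(self):
        from finitek import KEstimate

        dg = delta_G(KEstimate(math.e, 0.0, True, "", 0), 300.0)
        assert dg.value == pytest.approx(-2.4943, abs=2e-4)
        assert dg.stderr == 0.0

    def test_error_propagation(self):
        from finitek import KEstimate

        dg = delta_G(KEstimate(2.0, 0.2, True, "", 0), 300.0)
        assert dg.stderr == pytest.approx(0.0083144626 * 300 * 0.1)

    def test_nonpositive_rejected(self):
        from finitek import KEstimate

        with pytest.raises(ValueError):
            delta_G(KEstimate(0.0, 0.0, True, "", 0), 300.0)


class TestCycleClosure:
    CYCLE = [(1, (1, 2)), (1, (1, 3)), (-1, (1, 1)), (-1, (2, 2))]

    def test_zero_on_oracle(self, generic_model_n8):
        cc = cycle_closure(generic_model_n8, self.CYCLE, 300.0)
        assert abs(cc.value) < 1e-10

    def test_orientation_flips_sign(self):
        model = generic_model(4, volume=9.0)
        fwd = cycle_closure(model, self.CYCLE, 300.0)
        rev = cycle_closure(model, [(-s, r) for s, r in self.CYCLE], 300.0)
        assert rev.value == pytest.approx(-fwd.value, abs=1e-12)

    def test_non_closing_cycle_rejected(self, generic_model_n8):
        with pytest.raises(ValueError):
            cycle_closure(generic_model_n8, [(1, (1, 1)), (1, (1, 2))], 300.0)


class TestBlockError:
    def test_constant_series(self):
        s = CountsSeries(np.array([[2, 1]] * 100), volume=5.0, n_total=4)
        assert block_error(s, lambda sub: float(sub.counts[:, 0].mean())) == 0.0

    def test_clt_scaling(self, generic_model_n8):
        lengths = [2_000, 8_000, 32_000, 128_000]
        errs = []
        for n in lengths:
            s = sample_states(generic_model_n8, n, seed=5)
            errs.append(block_error(s, lambda sub: float(sub.counts[:, 0].mean())))
        slope = np.polyfit(np.log(lengths), np.log(errs), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)

    def test_too_many_blocks_rejected(self):
        s = CountsSeries(np.array([[2, 1]] * 30), volume=5.0, n_total=4)
        with pytest.raises(ValueError):
            block_error(s, lambda sub: 1.0, n_blocks=20)
        with pytest.raises(ValueError):
            block_error(s, lambda sub: 1.0, n_blocks=1)


class TestStatisticalConsistency:
    def test_estimators_converge_to_oracle_values(self):
        """Across seeds, sampled estimates sit within 3 stderr of exact values."""
        model = generic_model(6, volume=12.0)
        targets = {
            "K[1+1]": lambda d: elementary_K(d, (1, 1)),
            "K[1+2]": lambda d: elementary_K(d, (1, 2)),
            "K6path": lambda d: path_K(d, [(1, 1), (1, 2), (1, 3), (1, 4), (1, 5)]),
            "Ktrans": lambda d: transfer_K_direct(d, ReactionSpec((1, 3), (2, 2))),
        }
        exact = {name: fn(model).value for name, fn in targets.items()}
        total, within = 0, 0
        for seed in range(20):
            s = sample_states(model, 40_000, seed=100 + seed)
            for name, fn in targets.items():
                k = fn(s)
                if not k.defined:
                    continue
                total += 1
                if abs(k.value - exact[name]) < 3 * k.stderr:
                    within += 1
        assert total >= 70
        assert within / total >= 0.95

    def test_values_invariant_under_frame_permutation(self, generic_model_n8):
        s = sample_states(generic_model_n8, 50_000, seed=8)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(s))
        s2 = CountsSeries(s.counts[perm], s.volume, s.n_total, s.c_std)
        for fn in (
            lambda d: elementary_K(d, (1, 1)).value,
            lambda d: uncorrelated_K(d, 4).value,
            lambda d: transfer_K_direct(d, ReactionSpec((1, 3), (2, 2))).value,
        ):
            assert fn(s) == pytest.approx(fn(s2), rel=1e-12)
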