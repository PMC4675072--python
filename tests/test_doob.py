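"""The h-transform: exact conditioned laws, inverses, and first passage.

The independent oracle for the discrete transform is a path-length
recursion: the probability of absorbing in the target within L steps is
computed by first-step iteration alone (no linear solve, no transform
formula), and the conditional one-step law follows from truncated path
mass.  Agreement to 1e-6 at a truncation capturing all but 1e-9 of the
conditional mass checks the whole transform pipeline.
"""

import numpy as np
import pytest

from condchain import (
    AbsorptionProfile,
    absorption_probabilities,
    condition_continuous,
    condition_discrete,
    debias,
    first_passage_condition,
    make_atb_chain,
    make_drunkard_walk,
)
from condchain.testing import random_ctmc, random_discrete_chain


class TestConditionDiscrete:
    def test_walk_conditioned_on_bar(self, drunkard):
        cond = condition_discrete(drunkard, "16")
        i = cond.spec.index
        assert cond.spec.kernel[i["2"], i["3"]] == pytest.approx(0.75, abs=1e-12)
        # a left step from 1 absorbs at home, impossible in a bar-selected path
        assert cond.spec.kernel[i["1"], i["2"]] == pytest.approx(1.0, abs=1e-12)
        assert cond.spec.kernel[i["15"], i["16"]] == pytest.approx(8 / 15, abs=1e-12)
        # home has absorption probability 0: outside the support
        assert "0" not in cond.support

    def test_closed_form_rightward_probability(self, drunkard):
        """Conditioned on the bar, q_right at position i is (i+1)/(2i)."""
        cond = condition_discrete(drunkard, "16")
        i = cond.spec.index
        for pos in range(1, 16):
            got = cond.spec.kernel[i[str(pos)], i[str(pos + 1)]]
            assert got == pytest.approx((pos + 1) / (2 * pos), abs=1e-12)

    def test_bias_direction_and_monotone_decay(self, drunkard):
        cond = condition_discrete(drunkard, "16")
        i = cond.spec.index
        rights = np.array(
            [cond.spec.kernel[i[str(p)], i[str(p + 1)]] for p in range(1, 16)]
        )
        assert np.all(rights > 0.5)
        assert np.all(np.diff(rights) < 0)  # decays toward 0.5 with i

    def test_full_absorbing_set_is_identity(self, drunkard):
        cond = condition_discrete(drunkard, {"0", "16"})
        assert cond.support == drunkard.state_labels
        np.testing.assert_allclose(cond.spec.kernel, drunkard.kernel, atol=1e-12)

    def test_mirror_symmetry(self, drunkard):
        """Home-conditioned rightward prob at i equals bar-conditioned
        leftward prob at 16 - i."""
        bar = condition_discrete(drunkard, "16")
        home = condition_discrete(drunkard, "0")

        def q(cond, frm, to):
            # a transition into a dropped (zero-probability) state has law 0
            if frm not in cond.spec.index or to not in cond.spec.index:
                return 0.0
            return cond.spec.kernel[cond.spec.index[frm], cond.spec.index[to]]

        for pos in range(1, 16):
            mirror = 16 - pos
            home_right = q(home, str(pos), str(pos + 1))
            bar_left = q(bar, str(mirror), str(mirror - 1))
            assert home_right == pytest.approx(bar_left, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_rows_normalize_on_random_chains(self, seed):
        spec = random_discrete_chain(seed, n_transient=6, n_absorbing=3)
        cond = condition_discrete(spec, sorted(spec.absorbing)[0])
        amask = cond.spec.absorbing_mask
        rows = cond.spec.kernel[~amask].sum(axis=1)
        np.testing.assert_allclose(rows, 1.0, rtol=0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_mixture_recomposes_true_kernel(self, seed):
        """Law of total probability: sum_k pi^k * qhat^(k) = q."""
        spec = random_discrete_chain(seed, n_transient=5, n_absorbing=2)
        n = spec.n_states
        recomposed = np.zeros((n, n))
        idx = spec.index
        for k in sorted(spec.absorbing):
            prof = absorption_probabilities(spec, k)
            cond = condition_discrete(spec, k)
            ci = cond.spec.index
            for frm in cond.support:
                if frm in cond.spec.absorbing:
                    continue
                for to in cond.support:
                    recomposed[idx[frm], idx[to]] += (
                        prof.values[idx[frm]]
                        * cond.spec.kernel[ci[frm], ci[to]]
                    )
        amask = spec.absorbing_mask
        np.testing.assert_allclose(
            recomposed[~amask], spec.kernel[~amask], rtol=0, atol=1e-9
        )

    def test_zero_probability_state_dropped(self):
        """A transient state that cannot reach the target leaves the support."""
        from condchain import ChainSpec

        # s0 -> a0 only; s1 -> a0 or a1
        kern = np.array(
            [
                [0.0, 0.0, 1.0, 0.0],
                [0.0, 0.0, 0.5, 0.5],
                [0.0, 0.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        spec = ChainSpec(("s0", "s1", "a0", "a1"), "discrete", kern, frozenset({"a0", "a1"}))
        cond = condition_discrete(spec, "a1")
        assert cond.support == ("s1", "a1")
        assert cond.spec.kernel[0, 1] == 1.0


class TestConditionContinuous:
    def test_ctmc_example_rates(self, ctmc4):
        cond = condition_continuous(ctmc4, "p")
        assert cond.support == ("1", "2", "p")
        i = cond.spec.index
        assert cond.spec.kernel[i["1"], i["2"]] == pytest.approx(2.0, abs=1e-12)
        assert cond.spec.kernel[i["2"], i["1"]] == pytest.approx(0.5, abs=1e-12)
        assert cond.spec.kernel[i["2"], i["p"]] == pytest.approx(2.5, abs=1e-12)
        assert "g" not in cond.support

    def test_exit_rates_conserved_on_example(self, ctmc4):
        cond = condition_continuous(ctmc4, "p")
        exits = cond.spec.kernel.sum(axis=1)
        np.testing.assert_allclose(exits[:2], [2.0, 3.0], atol=1e-12)

    def test_full_absorbing_set_is_identity(self, ctmc4):
        cond = condition_continuous(ctmc4, {"g", "p"})
        np.testing.assert_allclose(cond.spec.kernel, ctmc4.kernel, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_exit_rate_conservation_random(self, seed):
        """Conditioning reshapes rates but conserves each state's exit rate,
        so sojourn times carry no trace of the selection."""
        spec = random_ctmc(seed)
        target = sorted(spec.absorbing)[0]
        cond = condition_continuous(spec, target)
        idx = spec.index
        orig_exit = spec.kernel.sum(axis=1)
        ci = cond.spec.index
        for lab in cond.support:
            if lab in cond.spec.absorbing:
                continue
            got = cond.spec.kernel[ci[lab]].sum()
            assert got == pytest.approx(orig_exit[idx[lab]], abs=1e-9)


class TestFirstPassage:
    def test_closed_form(self, atb):
        """Conditioned T->B rate equals the total exit rate of T."""
        cond = first_passage_condition(atb, "A", "B")
        i = cond.spec.index
        assert cond.spec.kernel[i["T"], i["B"]] == pytest.approx(3.0, abs=1e-12)
        # the A->T rate is unbiased: pi is equal at A and T
        assert cond.spec.kernel[i["A"], i["T"]] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_estimated_rate_always_exceeds_true(self, seed):
        rng = np.random.default_rng(seed)
        w = {k: float(rng.uniform(0.05, 5.0)) for k in ("w_at", "w_ta", "w_tb", "w_bt")}
        spec = make_atb_chain(w)
        cond = first_passage_condition(spec, "A", "B")
        i = cond.spec.index
        hat = cond.spec.kernel[i["T"], i["B"]]
        assert hat > w["w_tb"]
        assert hat == pytest.approx(w["w_ta"] + w["w_tb"], abs=1e-9)

    def test_vanishing_rejection_limit(self):
        """With almost no returns to A there is almost no bias."""
        spec = make_atb_chain({"w_at": 1.0, "w_ta": 1e-3, "w_tb": 1.0, "w_bt": 1.0})
        cond = first_passage_condition(spec, "A", "B")
        i = cond.spec.index
        hat = cond.spec.kernel[i["T"], i["B"]]
        assert hat == pytest.approx(1.0, rel=2e-3)

    def test_unreachable_goal_raises(self):
        from condchain import ChainSpec

        kern = np.zeros((3, 3))
        kern[0, 1] = 1.0  # A -> T only; B unreachable
        spec = ChainSpec(("A", "T", "B"), "continuous", kern, frozenset())
        with pytest.raises(ValueError, match="unreachable"):
            first_passage_condition(spec, "A", "B")


class TestDebias:
    def test_round_trip_discrete(self, drunkard):
        prof = absorption_probabilities(drunkard, "16")
        cond = condition_discrete(drunkard, "16")
        rec = recovered = debias(cond, prof)
        idx = drunkard.index
        ri = recovered.index
        for frm in cond.support:
            if frm in cond.spec.absorbing:
                continue
            for to in cond.support:
                assert rec.kernel[ri[frm], ri[to]] == pytest.approx(
                    drunkard.kernel[idx[frm], idx[to]], abs=1e-9
                )

    def test_round_trip_continuous(self, ctmc4):
        prof = absorption_probabilities(ctmc4, "p")
        cond = condition_continuous(ctmc4, "p")
        rec = debias(cond, prof)
        idx = ctmc4.index
        ri = rec.index
        for frm in ("1", "2"):
            for to in cond.support:
                assert rec.kernel[ri[frm], ri[to]] == pytest.approx(
                    ctmc4.kernel[idx[frm], idx[to]], abs=1e-9
                )

    def test_wrong_profile_gives_wrong_kernel(self, drunkard):
        """De-biasing with a flat profile returns the still-biased kernel:
        q_23 stays 0.75 instead of the physical 0.5."""
        cond = condition_discrete(drunkard, "16")
        flat = AbsorptionProfile(
            frozenset({"16"}), np.full(17, 0.5), cond.base_fingerprint
        )
        rec = debias(cond, flat)
        ri = rec.index
        assert abs(rec.kernel[ri["2"], ri["3"]] - 0.5) > 0.1

    def test_fingerprint_mismatch_raises(self, drunkard):
        cond = condition_discrete(drunkard, "16")
        other = make_drunkard_walk(5, 0.5)
        prof = absorption_probabilities(other, "6")
        with pytest.raises(ValueError, match="fingerprint"):
            debias(cond, prof)


class TestPathEnumerationOracle:
    def test_conditional_one_step_law(self):
        """Truncated path-mass recursion reproduces the transform to 1e-6.

        f(i, t) = P(absorbed at target within t steps | X_0 = i) is built
        by pure first-step iteration; the conditional one-step law is then
        q_ij f(j, L) / f(i, L+1) — no linear algebra, no transform.
        """
        spec = random_discrete_chain(3, n_transient=2, n_absorbing=2)
        target = sorted(spec.absorbing)[0]
        idx = spec.index
        t_idx = idx[target]
        n = spec.n_states
        Q = spec.kernel

        f = np.zeros(n)
        f[t_idx] = 1.0
        # iterate until all but 1e-9 of the conditional mass is captured
        for _ in range(10_000):
            f_next = Q @ f
            f_next[t_idx] = 1.0
            for a in spec.absorbing:
                if a != target:
                    f_next[idx[a]] = 0.0
            if np.max(np.abs(f_next - f)) < 1e-12:
                f = f_next
                break
            f = f_next

        cond = condition_discrete(spec, target)
        ci = cond.spec.index
        for frm in cond.support:
            if frm in cond.spec.absorbing:
                continue
            i = idx[frm]
            den = float(Q[i] @ f)
            for to in cond.support:
                j = idx[to]
                oracle = Q[i, j] * f[j] / den
                got = cond.spec.kernel[ci[frm], ci[to]]
                assert got == pytest.approx(oracle, abs=1e-6)
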