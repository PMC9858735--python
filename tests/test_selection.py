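import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import liverweight as lw
from liverweight.selection import CandidateCV, InnerCVResult
from conftest import make_cohort


class TestEnumerate:
    def test_six_variables_give_21_candidates(self):
        cands = lw.enumerate_candidates()
        assert len(cands) == 21  # C(6,1) + C(6,2)
        assert sum(c.n_vars == 1 for c in cands) == 6
        assert sum(c.n_vars == 2 for c in cands) == 15

    def test_single_variable(self):
        assert [c.name for c in lw.enumerate_candidates(["bw"], max_vars=2)] == ["bw"]

    def test_two_variables_exhaustive(self):
        names = [c.name for c in lw.enumerate_candidates(["bw", "age"], max_vars=2)]
        assert names == ["bw", "age", "bw+age"]

    def test_deterministic_priority_order(self):
        cands = lw.enumerate_candidates()
        assert [c.name for c in cands[:6]] == [
            "bw", "bsa_dubois", "bsa_mosteller", "bh", "age", "sex"
        ]
        assert cands[6].name == "bw+bsa_dubois"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lw.enumerate_candidates([])

    def test_candidate_spec_invariants(self):
        spec = lw.CandidateSpec(("age", "bw"))
        assert spec.predictors == ("bw", "age")  # canonical priority order
        with pytest.raises(ValueError):
            lw.CandidateSpec(("bw", "bw"))
        with pytest.raises(ValueError):
            lw.CandidateSpec(("bw", "age", "bh"))


def _mk_result(entries, threshold=0.05):
    per = {
        lw.CandidateSpec(tuple(preds)): CandidateCV(r, 0.0, True, 100)
        for preds, r in entries
    }
    return InnerCVResult(per_candidate=per, threshold=threshold)


class TestParsimonyRule:
    def test_bivariable_needs_more_than_the_surcharge(self):
        # 191 * 1.05 = 200.55 > 200 -> univariable retained
        res = _mk_result([(["bw"], 200.0), (["bw", "age"], 191.0)])
        assert lw.apply_parsimony_rule(res).name == "bw"

    def test_bivariable_wins_below_cutoff(self):
        res = _mk_result([(["bw"], 200.0), (["bw", "age"], 189.0)])
        assert lw.apply_parsimony_rule(res).name == "bw+age"

    def test_exact_five_pct_reduction_accepts_complex(self):
        res = _mk_result([(["bw"], 200.0), (["bw", "age"], 190.0)])
        assert lw.apply_parsimony_rule(res).name == "bw+age"

    def test_single_candidate(self):
        res = _mk_result([(["bh"], 250.0)])
        assert lw.apply_parsimony_rule(res).name == "bh"

    def test_cost_tie_goes_to_simpler_then_priority(self):
        res = _mk_result([(["bw"], 210.0), (["bh"], 210.0), (["bw", "bh"], 200.0)])
        # bivariable cost 210 ties both univariable costs -> simpler wins, bw first
        assert lw.apply_parsimony_rule(res).name == "bw"

    def test_invalid_candidates_ignored(self):
        per = {
            lw.CandidateSpec(("bw",)): CandidateCV(float("nan"), float("nan"), False, 0),
            lw.CandidateSpec(("bh",)): CandidateCV(220.0, 1.0, True, 100),
        }
        assert lw.apply_parsimony_rule(InnerCVResult(per)).name == "bh"
        with pytest.raises(ValueError):
            lw.apply_parsimony_rule(InnerCVResult({}))

    @given(
        rmses=st.lists(st.floats(min_value=1.0, max_value=1000.0), min_size=21,
                       max_size=21),
    )
    def test_cost_argmin_equals_literal_band_rule(self, rmses):
        """The cost-function argmin agrees with the direct reading of the rule:
        the best bivariable displaces the best univariable only when even
        after the 5% surcharge it still beats it."""
        cands = lw.enumerate_candidates()
        res = InnerCVResult({c: CandidateCV(r, 0.0, True, 100)
                             for c, r in zip(cands, rmses)})
        winner = lw.apply_parsimony_rule(res)

        # independent literal implementation
        uni = [(r, c) for c, r in zip(cands, rmses) if c.n_vars == 1]
        bi = [(r, c) for c, r in zip(cands, rmses) if c.n_vars == 2]
        best_uni = min(uni, key=lambda t: (t[0], t[1].priority_key()))
        best_bi = min(bi, key=lambda t: (t[0], t[1].priority_key()))
        expected = best_bi[1] if best_bi[0] * 1.05 < best_uni[0] else best_uni[1]
        assert winner == expected


class TestInnerCV:
    def test_noiseless_model_has_zero_cv_rmse(self):
        rng = np.random.default_rng(0)
        bw = rng.uniform(40, 90, 60)
        cohort = make_cohort(bw=bw, y=2.0 * bw)
        res = lw.run_inner_cv(cohort, [lw.CandidateSpec(("bw",))],
                              lw.CVConfig(n_folds=5, n_repeats=2, seed=1))
        assert res.per_candidate[lw.CandidateSpec(("bw",))].mean_rmse < 1e-8

    def test_every_record_held_out_once_per_repeat(self, bw_cohort):
        from liverweight.selection import (_candidate_columns, _cv_fold_errors,
                                           _design_with_intercept, _validity_mask)

        Z, y = _design_with_intercept(bw_cohort)
        cands = [lw.CandidateSpec(("bw",))]
        cols = _candidate_columns(cands)
        valid = _validity_mask(Z, cols)
        n_folds, n_repeats = 10, 3
        sse, cnt = _cv_fold_errors(Z, y, cols, valid, n_folds, n_repeats,
                                   np.random.default_rng(0))
        counts = cnt.reshape(1, n_repeats, n_folds)
        assert np.all(counts.sum(axis=2) == len(bw_cohort))  # exhaustive
        assert np.all(counts > 0)  # disjoint, non-empty folds

    def test_leave_one_out_single_repeat_is_seed_invariant(self):
        rng = np.random.default_rng(3)
        bw = rng.uniform(40, 90, 12)
        cohort = make_cohort(bw=bw, bh=rng.uniform(150, 190, 12),
                             age=rng.uniform(20, 70, 12),
                             y=14.8 * bw + 439.2 + rng.normal(0, 50, 12))
        cfg = lambda s: lw.CVConfig(n_folds=12, n_repeats=1, seed=s)
        cands = lw.enumerate_candidates(["bw", "bh", "age"])
        r1 = lw.run_inner_cv(cohort, cands, cfg(1))
        r2 = lw.run_inner_cv(cohort, cands, cfg(99))
        for c in cands:
            assert r1.per_candidate[c].mean_rmse == r2.per_candidate[c].mean_rmse

    def test_rank_deficient_candidate_flagged_not_dropped(self):
        cohort = make_cohort(bw=np.linspace(40, 90, 30), sex=["male"] * 30)
        cands = [lw.CandidateSpec(("bw",)), lw.CandidateSpec(("sex",))]
        res = lw.run_inner_cv(cohort, cands, lw.CVConfig(n_folds=5, n_repeats=1, seed=0))
        assert not res.per_candidate[lw.CandidateSpec(("sex",))].valid
        assert res.per_candidate[lw.CandidateSpec(("bw",))].valid
        assert lw.apply_parsimony_rule(res).name == "bw"

    def test_noise_predictor_does_not_help_on_average(self):
        """Sign test over 50 seeds: adding a pure-noise predictor to the true
        model cannot lower the mean held-out RMSE on average."""
        wins = 0
        true_c, nested_c = lw.CandidateSpec(("bw",)), lw.CandidateSpec(("bw", "age"))
        for seed in range(50):
            cohort = lw.scenario("bw_truth", n=80, seed=1000 + seed)
            res = lw.run_inner_cv(cohort, [true_c, nested_c],
                                  lw.CVConfig(n_folds=5, n_repeats=2, seed=seed))
            if res.per_candidate[nested_c].mean_rmse >= res.per_candidate[true_c].mean_rmse:
                wins += 1
        assert wins > 25  # one-sided sign test, p < 0.5 under the null of no harm

    def test_cohort_smaller_than_folds_rejected(self):
        cohort = make_cohort(bw=np.linspace(40, 90, 5))
        with pytest.raises(ValueError, match="folds"):
            lw.run_inner_cv(cohort, [lw.CandidateSpec(("bw",))], lw.CVConfig(seed=0))


class TestVoting:
    def test_single_cycle(self, bw_cohort):
        sel = lw.vote_selection(bw_cohort, lw.enumerate_candidates(),
                                lw.CVConfig(seed=4), n_cycles=1)
        assert sum(sel.votes.values()) == 1
        assert sel.winner == sel.cycle_winners[0]

    def test_votes_sum_to_cycles(self, bw_cohort):
        sel = lw.vote_selection(bw_cohort, lw.enumerate_candidates(),
                                lw.CVConfig(seed=4), n_cycles=20)
        assert sum(sel.votes.values()) == 20
        assert sel.votes[sel.winner] == max(sel.votes.values())

    def test_exact_bivariable_truth_sweeps_votes(self):
        rng = np.random.default_rng(5)
        bw = rng.uniform(40, 90, 60)
        bh = rng.uniform(150, 190, 60)
        cohort = make_cohort(bw=bw, bh=bh, y=bw + bh)
        cands = [lw.CandidateSpec(("bw",)), lw.CandidateSpec(("bh",)),
                 lw.CandidateSpec(("bw", "bh"))]
        sel = lw.vote_selection(cohort, cands, lw.CVConfig(n_folds=5, seed=0),
                                n_cycles=10)
        assert sel.votes == {lw.CandidateSpec(("bw", "bh")): 10}

    def test_bw_truth_plurality_winner_over_seeds(self):
        """Simulation oracle: on cohorts generated from the body-weight truth,
        {bw} wins the vote in the clear majority of generator seeds."""
        winners = []
        for seed in range(20):
            cohort = lw.scenario("bw_truth", seed=2000 + seed)
            sel = lw.vote_selection(cohort, lw.enumerate_candidates(),
                                    lw.CVConfig(seed=seed), n_cycles=25)
            winners.append(sel.winner.name)
        assert sum(w == "bw" for w in winners) >= 15

    def test_reproducibility_bit_exact(self, bw_cohort):
        cfg = lw.CVConfig(seed=11)
        a = lw.vote_selection(bw_cohort, lw.enumerate_candidates(), cfg, n_cycles=10)
        b = lw.vote_selection(bw_cohort, lw.enumerate_candidates(), cfg, n_cycles=10)
        assert a.votes == b.votes
        assert a.winner == b.winner
        assert a.cycle_winners == b.cycle_winners

    def test_subset_smaller_than_folds_rejected(self):
        cohort = make_cohort(bw=np.linspace(40, 90, 10))
        with pytest.raises(ValueError, match="subset"):
            lw.vote_selection(cohort, [lw.CandidateSpec(("bw",))],
                              lw.CVConfig(n_folds=10, seed=0), subset_fraction=0.5)


class TestFitFinal:
    def test_equals_direct_fit(self, bw_cohort):
        winner = lw.CandidateSpec(("bw",))
        assert lw.fit_final(bw_cohort, winner) == lw.fit_ols(bw_cohort, ("bw",))

    def test_exact_line(self):
        cohort = make_cohort(bw=[1, 2, 3, 4], y=[2, 4, 6, 8])
        m = lw.fit_final(cohort, lw.CandidateSpec(("bw",)))
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert m.coefficients["bw"] == pytest.approx(2.0)
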