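import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

import varcallxt as vx
from varcallxt import evaluation, io_tables


class TestDirichletOC:
    def test_all_pathogenic_called(self):
        # 21 known pathogenic, all called: sensitivity 95.6%, 2.2% elsewhere
        counts = vx.CallCounts(evaluation.KNOWN_PATHOGENIC, 0, 0, 21)
        oc = vx.dirichlet_oc(counts)
        assert oc["called_pathogenic"] == pytest.approx(95.6, abs=0.05)
        assert oc["no_call"] == pytest.approx(2.2, abs=0.05)
        assert oc["called_benign"] == pytest.approx(2.2, abs=0.05)

    def test_benign_with_one_no_call(self):
        # 42 known benign, 41 called benign, 1 no-call
        counts = vx.CallCounts(evaluation.KNOWN_BENIGN, 41, 1, 0)
        oc = vx.dirichlet_oc(counts)
        assert oc["called_benign"] == pytest.approx(95.4, abs=0.05)
        assert oc["no_call"] == pytest.approx(3.4, abs=0.05)
        assert oc["called_pathogenic"] == pytest.approx(1.1, abs=0.05)

    def test_zero_counts_give_prior_mean(self):
        oc = vx.dirichlet_oc(vx.CallCounts(evaluation.KNOWN_BENIGN, 0, 0, 0))
        for v in oc.values():
            assert v == pytest.approx(100 / 3)

    @given(st.tuples(st.integers(0, 200), st.integers(0, 200),
                     st.integers(0, 200)))
    @settings(deadline=None, max_examples=100)
    def test_means_sum_to_one(self, counts):
        cc = vx.CallCounts(evaluation.KNOWN_BENIGN, *counts)
        assert sum(vx.dirichlet_oc(cc).values()) == pytest.approx(100.0)


class TestDirichletHDR:
    def test_monotone_marginal_boundary_attached(self):
        # Beta(21.5, 1) marginal: lower bound is the closed form 0.05^(1/21.5)
        counts = vx.CallCounts(evaluation.KNOWN_PATHOGENIC, 0, 0, 21)
        lo, hi = vx.dirichlet_hdr(counts, "called_pathogenic", 0.95)
        assert hi == 1.0
        assert lo == pytest.approx(0.05 ** (1 / 21.5), abs=1e-9)
        assert round(100 * lo) == 87

    def test_symmetric_beta_symmetric_interval(self):
        lo, hi = vx.beta_hdr(2.0, 2.0, 0.95)
        assert lo == pytest.approx(1 - hi, abs=1e-6)

    def test_mass_and_minimality_by_grid_search(self):
        a, b = 41.5, 2.0
        lo, hi = vx.beta_hdr(a, b, 0.95)
        dist = beta_dist(a, b)
        assert dist.cdf(hi) - dist.cdf(lo) == pytest.approx(0.95, abs=1e-6)
        # no equal-mass interval over a dense grid of left endpoints is
        # narrower
        grid = np.linspace(0, float(dist.ppf(0.05)), 10_000)
        widths = dist.ppf(dist.cdf(grid) + 0.95) - grid
        assert hi - lo <= np.nanmin(widths) + 1e-7

    def test_interior_interval_contains_posterior_mean(self):
        counts = vx.CallCounts(evaluation.KNOWN_BENIGN, 41, 1, 0)
        for category in evaluation.CATEGORIES:
            a, b = evaluation._beta_marginal(counts, category)
            lo, hi = vx.dirichlet_hdr(counts, category, 0.95)
            if a > 1 and b > 1:
                assert lo <= a / (a + b) <= hi

    def test_reproduces_reported_specificity_interval(self):
        # 41 of 42 benign called benign -> 95.4 (89.3, 99.9)
        counts = vx.CallCounts(evaluation.KNOWN_BENIGN, 41, 1, 0)
        lo, hi = vx.dirichlet_hdr(counts, "called_benign", 0.95)
        assert 100 * lo == pytest.approx(89.3, abs=0.05)
        assert 100 * hi == pytest.approx(99.9, abs=0.05)

    def test_decreasing_density_attaches_to_zero(self):
        lo, hi = vx.beta_hdr(0.5, 10.0, 0.95)
        assert lo == 0.0
        assert hi == pytest.approx(float(beta_dist(0.5, 10.0).ppf(0.95)))


class TestRawAccuracyAndBrier:
    def test_reported_accuracies(self):
        b1 = vx.CallCounts(evaluation.KNOWN_BENIGN, 41, 1, 0)
        p1 = vx.CallCounts(evaluation.KNOWN_PATHOGENIC, 0, 0, 21)
        assert vx.raw_accuracy(b1, p1) == pytest.approx(98.4, abs=0.05)
        b2 = vx.CallCounts(evaluation.KNOWN_BENIGN, 22, 0, 0)
        p2 = vx.CallCounts(evaluation.KNOWN_PATHOGENIC, 0, 1, 10)
        assert vx.raw_accuracy(b2, p2) == pytest.approx(97.0, abs=0.05)

    def test_all_correct_is_100(self):
        b = vx.CallCounts(evaluation.KNOWN_BENIGN, 5, 0, 0)
        p = vx.CallCounts(evaluation.KNOWN_PATHOGENIC, 0, 0, 5)
        assert vx.raw_accuracy(b, p) == 100.0

    def test_brier_perfect_zero(self):
        assert vx.scaled_brier([0.0, 1.0], [0, 1]) == 0.0

    def test_brier_prevalence_predictor_is_one(self):
        labels = [0, 0, 1, 1, 1]
        pbar = np.mean(labels)
        assert vx.scaled_brier([pbar] * 5, labels) == pytest.approx(1.0)

    def test_brier_hand_arithmetic(self):
        assert vx.scaled_brier([0.9, 0.2], [1, 0]) == pytest.approx(0.1)

    def test_brier_anticalibrated_exceeds_one(self):
        assert vx.scaled_brier([0.9, 0.1], [0, 1]) > 1.0

    def test_brier_order_invariant_and_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        probs = rng.random(50)
        labels = rng.integers(0, 2, 50)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        a = vx.scaled_brier(probs, labels)
        perm = rng.permutation(50)
        assert vx.scaled_brier(probs[perm], labels[perm]) == pytest.approx(a)
        pbar = labels.mean()
        brute = np.mean((probs - labels) ** 2) / np.mean((pbar - labels) ** 2)
        assert a == pytest.approx(brute, rel=1e-12)

    def test_brier_degenerate_labels_warn(self):
        with pytest.warns(UserWarning, match="unscaled"):
            out = vx.scaled_brier([0.2, 0.1], [0, 0])
        assert out == pytest.approx(np.mean([0.04, 0.01]))


def _strong_two_variant_tables():
    rng = np.random.default_rng(7)
    rows = []
    for b in range(40):
        rows.append(("known_b", f"x{b}", 0.0 + 0.05 * rng.normal(),
                     io_tables.BENIGN))
        rows.append(("known_p", f"x{b}", -5.0 + 0.05 * rng.normal(),
                     io_tables.PATHOGENIC))
        rows.append(("filler_b", f"x{b}", 0.0 + 0.05 * rng.normal(),
                     io_tables.BENIGN))
        rows.append(("filler_p", f"x{b}", -5.0 + 0.05 * rng.normal(),
                     io_tables.PATHOGENIC))
    return pd.DataFrame(rows, columns=["variant_id", "batch_id",
                                       "mean_log_ratio", "label"])


class TestLovo:
    def _cfg(self, **kw):
        base = dict(evidence_set=("function",), n_iter=1500, n_burn=700,
                    thin=1, n_chains=2, seed=19)
        base.update(kw)
        return vx.ModelConfig(**base)

    def test_separation_limit_all_correct(self):
        bm = _strong_two_variant_tables()
        counts, probs = vx.lovo_evaluate(bm, None, self._cfg())
        assert counts[evaluation.KNOWN_BENIGN].n_called_benign == 2
        assert counts[evaluation.KNOWN_PATHOGENIC].n_called_pathogenic == 2
        assert not probs["skipped"].any()

    def test_family_only_zero_bf_all_no_call(self):
        ev = pd.DataFrame({
            "variant_id": ["a", "b", "c", "d"],
            "family_log_bf": [0.0] * 4,
            "label": [io_tables.BENIGN, io_tables.BENIGN,
                      io_tables.PATHOGENIC, io_tables.PATHOGENIC],
        })
        cfg = self._cfg(evidence_set=("family",), n_iter=4000, n_burn=1000)
        counts, probs = vx.lovo_evaluate(None, ev, cfg)
        assert counts[evaluation.KNOWN_BENIGN].n_no_call == 2
        assert counts[evaluation.KNOWN_PATHOGENIC].n_no_call == 2

    def test_planted_misclassification_detected(self):
        # one known benign variant given a pathogenic-level functional
        # signal; ten variants per class keep the mixture anchored despite
        # the contaminated fold
        rng = np.random.default_rng(7)
        rows = []
        for b in range(40):
            for i in range(10):
                rows.append((f"ben{i}", f"x{b}", 0.0 + 0.05 * rng.normal(),
                             io_tables.BENIGN))
                rows.append((f"pat{i}", f"x{b}", -6.0 + 0.05 * rng.normal(),
                             io_tables.PATHOGENIC))
        bm = pd.DataFrame(rows, columns=["variant_id", "batch_id",
                                         "mean_log_ratio", "label"])
        bm.loc[bm["variant_id"] == "ben0", "mean_log_ratio"] -= 6.0
        counts, probs = vx.lovo_evaluate(bm, None, self._cfg(seed=23))
        by_id = probs.set_index("variant_id")
        assert by_id.loc["ben0", "call"] == "called_pathogenic"
        others = by_id.drop("ben0")
        expected = {io_tables.BENIGN: "called_benign",
                    io_tables.PATHOGENIC: "called_pathogenic"}
        for vid, row in others.iterrows():
            assert row["call"] == expected[row["label"]]

    def test_last_labeled_variant_fold_skipped(self):
        bm = _strong_two_variant_tables()
        bm = bm[bm["variant_id"] != "filler_p"]
        with pytest.warns(UserWarning, match="skipping"):
            counts, probs = vx.lovo_evaluate(bm, None, self._cfg())
        assert probs.set_index("variant_id").loc["known_p", "skipped"]

    def test_tallies_match_elementwise_classify(self):
        bm = _strong_two_variant_tables()
        cfg = self._cfg()
        counts, probs = vx.lovo_evaluate(bm, None, cfg)
        ok = probs[~probs["skipped"]]
        recount = evaluation.tally_calls(ok, cfg)
        for cond in counts:
            assert counts[cond] == recount[cond]


class TestOddsShift:
    def _summary(self, probs, labels):
        clipped = np.clip(probs, 1e-6, 1 - 1e-6)
        return pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(len(probs))],
            "prob_pathogenic": probs,
            "log_odds": np.log(clipped / (1 - clipped)),
            "call": [vx.classify(p, vx.ModelConfig()) for p in probs],
            "label": labels,
        })

    def test_identical_summaries_or_one(self):
        s = self._summary([0.2, 0.8], [io_tables.BENIGN, io_tables.PATHOGENIC])
        rep = vx.odds_shift_report(s, s)
        np.testing.assert_allclose(rep["odds_ratio"], 1.0)
        assert not rep["changed"].any()

    def test_probability_move_gives_expected_or(self):
        a = self._summary([0.5], [io_tables.UNLABELED])
        b = self._summary([0.9], [io_tables.UNLABELED])
        rep = vx.odds_shift_report(a, b)
        assert rep["odds_ratio"].iloc[0] == pytest.approx(9.0, rel=1e-6)

    def test_uniform_log_bf_gives_uniform_or(self):
        # additivity of combine_log_odds: adding log(2) to every variant's
        # log-odds doubles every odds ratio
        rng = np.random.default_rng(5)
        probs = rng.uniform(0.1, 0.9, 10)
        a = self._summary(probs, [io_tables.UNLABELED] * 10)
        b = a.copy()
        b["log_odds"] = [vx.combine_log_odds(x, np.log(2))
                         for x in a["log_odds"]]
        rep = vx.odds_shift_report(a, b)
        np.testing.assert_allclose(rep["odds_ratio"], 2.0, rtol=1e-9)

    def test_variant_mismatch_lists_difference(self):
        a = self._summary([0.5], [io_tables.UNLABELED])
        b = self._summary([0.5, 0.6],
                          [io_tables.UNLABELED, io_tables.UNLABELED])
        with pytest.raises(ValueError, match="v1"):
            vx.odds_shift_report(a, b)
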