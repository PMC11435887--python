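"""Donor-ASV engraftment: set exclusion, rates, summaries, and oracle checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fmtkit.engraftment import (
    EngraftmentError,
    EngraftmentResult,
    PresenceProfile,
    build_presence,
    candidate_donor_set,
    engraftment_rate,
    summarize_engraftment,
)
from fmtkit.feature_table import AsvTable, SampleMetadata, remove_rare_asvs


def profile(owner, context, asvs):
    return PresenceProfile(owner=owner, context=context, present_asvs=frozenset(asvs))


def brute_force_rate(donor_asvs, pre_asvs, post_asvs):
    """Independent oracle: exhaustive membership loops, no set algebra."""
    candidates = []
    for a in donor_asvs:
        shared = False
        for b in pre_asvs:
            if a == b:
                shared = True
        if not shared:
            candidates.append(a)
    engrafted = []
    for a in candidates:
        for b in post_asvs:
            if a == b:
                engrafted.append(a)
                break
    return candidates, engrafted, 100.0 * len(engrafted) / len(candidates)


class TestBuildPresence:
    def make_table_meta(self):
        counts = pd.DataFrame(
            {"a": [3, 0, 1], "b": [0, 1, 0], "c": [0, 0, 2]},
            index=["d1_treatment", "d1_post_treatment", "d1_endoscopy"],
        )
        meta = SampleMetadata(pd.DataFrame([
            {"sample_id": "d1_treatment", "dog_id": "d1", "group": "FMT", "visit": "treatment"},
            {"sample_id": "d1_post_treatment", "dog_id": "d1", "group": "FMT", "visit": "post_treatment"},
            {"sample_id": "d1_endoscopy", "dog_id": "d1", "group": "FMT", "visit": "endoscopy"},
        ]))
        return AsvTable(counts), meta

    def test_post_fmt_pools_treatment_and_post_treatment(self):
        table, meta = self.make_table_meta()
        prof = build_presence(table, meta, "d1", "post_fmt")
        assert prof.present_asvs == {"a", "b"}

    def test_pre_fmt_uses_endoscopy(self):
        table, meta = self.make_table_meta()
        prof = build_presence(table, meta, "d1", "pre_fmt")
        assert prof.present_asvs == {"a", "c"}

    def test_missing_context_sample_is_error(self):
        table, meta = self.make_table_meta()
        with pytest.raises(EngraftmentError, match="d2.*pre_fmt"):
            build_presence(table, meta, "d2", "pre_fmt")

    def test_baseline_override_for_dog_without_endoscopy(self):
        counts = pd.DataFrame({"a": [1]}, index=["d3_inclusion"])
        meta = SampleMetadata(pd.DataFrame([
            {"sample_id": "d3_inclusion", "dog_id": "d3", "group": "FMT", "visit": "inclusion"},
        ]))
        table = AsvTable(counts)
        with pytest.raises(EngraftmentError):
            build_presence(table, meta, "d3", "pre_fmt")
        prof = build_presence(table, meta, "d3", "pre_fmt", baseline_visit="inclusion")
        assert prof.present_asvs == {"a"}

    def test_empty_counts_give_empty_set(self):
        counts = pd.DataFrame({"a": [0], "b": [0]}, index=["d1_endoscopy"])
        meta = SampleMetadata(pd.DataFrame([
            {"sample_id": "d1_endoscopy", "dog_id": "d1", "group": "FMT", "visit": "endoscopy"},
        ]))
        prof = build_presence(AsvTable(counts), meta, "d1", "pre_fmt")
        assert prof.present_asvs == frozenset()


class TestRates:
    def test_candidate_set_excludes_shared(self):
        donor = profile("donor", "donor", "abcde")
        pre = profile("d1", "pre_fmt", "a")
        assert candidate_donor_set(donor, pre) == set("bcde")
        assert candidate_donor_set(donor, profile("d1", "pre_fmt", "xyz")) == set("abcde")
        assert candidate_donor_set(donor, profile("d1", "pre_fmt", "abcdefg")) == set()

    def test_worked_example_rate_50(self):
        donor = profile("donor", "donor", "abcde")
        pre = profile("d1", "pre_fmt", "a")
        post = profile("d1", "post_fmt", ["b", "c", "x"])
        res = engraftment_rate(donor, pre, post)
        assert res.candidate_donor_asvs == set("bcde")
        assert res.engrafted_asvs == {"b", "c"}
        assert res.rate_percent == 50.0

    def test_rate_bounds(self):
        donor = profile("donor", "donor", "abc")
        pre = profile("d1", "pre_fmt", [])
        assert engraftment_rate(donor, pre, profile("d1", "post_fmt", "xyz")).rate_percent == 0.0
        assert engraftment_rate(donor, pre, profile("d1", "post_fmt", "abcxyz")).rate_percent == 100.0

    def test_zero_denominator_advises_exclusion(self):
        donor = profile("donor", "donor", "ab")
        pre = profile("d1", "pre_fmt", "ab")
        with pytest.raises(EngraftmentError, match="exclude"):
            engraftment_rate(donor, pre, profile("d1", "post_fmt", "ab"))

    def test_engrafted_must_be_subset(self):
        with pytest.raises(EngraftmentError, match="subset"):
            EngraftmentResult("d1", frozenset("ab"), frozenset("abc"))

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(123)
        universe = [f"asv{i}" for i in range(50)]
        checked = 0
        for _ in range(1200):
            donor_asvs = set(rng.choice(universe, size=rng.integers(1, 40), replace=False))
            pre_asvs = set(rng.choice(universe, size=rng.integers(0, 40), replace=False))
            post_asvs = set(rng.choice(universe, size=rng.integers(0, 40), replace=False))
            if donor_asvs <= pre_asvs:
                continue  # zero denominator, contract error path
            cand, engrafted, rate = brute_force_rate(donor_asvs, pre_asvs, post_asvs)
            res = engraftment_rate(
                profile("donor", "donor", donor_asvs),
                profile("d", "pre_fmt", pre_asvs),
                profile("d", "post_fmt", post_asvs),
            )
            assert res.candidate_donor_asvs == set(cand)
            assert res.engrafted_asvs == set(engrafted)
            assert res.rate_percent == rate  # bit-exact
            checked += 1
        assert checked >= 1000

    def test_monotonicity_in_post_profile(self):
        rng = np.random.default_rng(5)
        donor = profile("donor", "donor", [f"a{i}" for i in range(20)])
        pre = profile("d", "pre_fmt", [f"a{i}" for i in range(5)])
        post = set(rng.choice([f"a{i}" for i in range(20)], size=8, replace=False))
        base = engraftment_rate(donor, pre, profile("d", "post_fmt", post)).rate_percent
        grown = engraftment_rate(
            donor, pre, profile("d", "post_fmt", post | {"a19"})
        ).rate_percent
        assert grown >= base
        # adding a donor∩pre (shared) ASV to post never changes the rate
        shared = engraftment_rate(
            donor, pre, profile("d", "post_fmt", post | {"a0"})
        ).rate_percent
        assert shared == base

    def test_rate_invariant_under_asv_relabeling(self):
        rng = np.random.default_rng(9)
        names = [f"x{i}" for i in range(30)]
        donor_asvs = set(names[:20])
        pre_asvs = set(names[5:12])
        post_asvs = set(rng.choice(names, size=15, replace=False))
        mapping = dict(zip(names, rng.permutation(names)))
        r1 = engraftment_rate(
            profile("donor", "donor", donor_asvs),
            profile("d", "pre_fmt", pre_asvs),
            profile("d", "post_fmt", post_asvs),
        ).rate_percent
        r2 = engraftment_rate(
            profile("donor", "donor", {mapping[a] for a in donor_asvs}),
            profile("d", "pre_fmt", {mapping[a] for a in pre_asvs}),
            profile("d", "post_fmt", {mapping[a] for a in post_asvs}),
        ).rate_percent
        assert r1 == r2


class TestSummary:
    def test_hand_summary(self):
        results = [
            EngraftmentResult(f"d{i}", frozenset(f"a{j}" for j in range(10)),
                              frozenset(f"a{j}" for j in range(k)))
            for i, k in enumerate([1, 3, 5])
        ]
        s = summarize_engraftment(results)
        assert s.mean_percent == 30.0
        assert s.median_percent == 30.0
        assert (s.min_percent, s.max_percent) == (10.0, 50.0)
        assert s.asv_frequency["a0"] == 3
        assert s.asv_frequency["a4"] == 1

    def test_single_result_degenerate(self):
        r = EngraftmentResult("d1", frozenset("abcd"), frozenset("ab"))
        s = summarize_engraftment([r])
        assert s.mean_percent == s.median_percent == s.min_percent == s.max_percent == 50.0

    def test_median_midpoint_for_even_counts(self):
        results = [
            EngraftmentResult(f"d{i}", frozenset("abcde"), frozenset(list("abcde")[:k]))
            for i, k in enumerate([1, 2, 3, 5])
        ]
        s = summarize_engraftment(results)
        assert s.median_percent == 50.0  # midpoint of 40 and 60

    def test_empty_list_is_error(self):
        with pytest.raises(EngraftmentError):
            summarize_engraftment([])


class TestGroundTruthRecovery:
    def test_mean_rate_within_binomial_interval_of_transfer_probability(self, trial_sim):
        """End-to-end: simulated trial, measured mean engraftment consistent
        with the configured per-ASV transfer probability."""
        table = remove_rare_asvs(trial_sim["table"])
        meta = trial_sim["metadata"]
        donor = build_presence(table, meta, "donor", "donor")
        n_trials = n_hits = 0
        rates = []
        for dog in meta.dogs_in_group("FMT"):
            pre = build_presence(table, meta, dog, "pre_fmt")
            post = build_presence(table, meta, dog, "post_fmt")
            res = engraftment_rate(donor, pre, post)
            n_trials += len(res.candidate_donor_asvs)
            n_hits += len(res.engrafted_asvs)
            rates.append(res.rate_percent)
        p = trial_sim["ground_truth"]["engraft_prob"]
        lo, hi = stats.binom.interval(0.95, n_trials, p)
        mean_rate = np.mean(rates)
        assert 100.0 * lo / n_trials <= mean_rate <= 100.0 * hi / n_trials

    def test_recovers_exact_transferred_sets_when_detection_guaranteed(self):
        from fmtkit.synthetic import TrialSimConfig, simulate_trial

        cfg = TrialSimConfig(seed=11, transfer_floor_reads=50.0, n_fmt=4, n_placebo=2,
                             n_healthy=2)
        sim = simulate_trial(cfg)
        table = remove_rare_asvs(sim["table"])
        meta = sim["metadata"]
        donor = build_presence(table, meta, "donor", "donor")
        for dog, truth in sim["ground_truth"]["transferred"].items():
            pre = build_presence(table, meta, dog, "pre_fmt")
            post = build_presence(table, meta, dog, "post_fmt")
            res = engraftment_rate(donor, pre, post)
            # truth restricted to ASVs detectable in the donor sample
            expected = set(truth) & res.candidate_donor_asvs
            assert res.engrafted_asvs == expected
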