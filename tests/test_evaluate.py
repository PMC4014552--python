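"""Signature evaluation: normalization, risk grouping, robustness tools."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from survwalk import (Signature, SurvwalkError, evaluate_signature,
                      kmeans_risk_groups, merge_and_normalize,
                      nearest_centroid_classify, optimize_topn,
                      perturb_partition, recurrence_ratio, shuffle_and_split,
                      zscore_columns, zscore_rows)
from survwalk.synthetic import PlantedTruth, generate_cohort


def _clinical(index, events, days=None):
    n = len(index)
    return pd.DataFrame(
        {"survival_days": days if days is not None else np.arange(100, 100 + n),
         "event": events, "grade": "IV", "age": 50, "gender": "F"},
        index=pd.Index(index, name="sample_id"))


def _blob_data(rng, n_per_blob=20, n_feat=4, sep=8.0):
    """Two well-separated sample blobs; returns matrix and blob labels."""
    a = rng.standard_normal((n_feat, n_per_blob)) - sep / 2
    b = rng.standard_normal((n_feat, n_per_blob)) + sep / 2
    cols = [f"S{i:03d}" for i in range(2 * n_per_blob)]
    X = pd.DataFrame(np.hstack([a, b]), columns=cols,
                     index=[f"f{j}" for j in range(n_feat)])
    labels = np.array([0] * n_per_blob + [1] * n_per_blob)
    return X, labels


class TestNormalization:
    def test_row_zscore_identity(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"], columns=list("abc"))
        z = zscore_rows(df)
        assert z.to_numpy()[0] == pytest.approx([-1.22474487, 0.0, 1.22474487])

    def test_standardized_matrix_unchanged_by_row_step(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((5, 50)))
        z = zscore_rows(df)
        assert zscore_rows(z).to_numpy() == pytest.approx(z.to_numpy(), abs=1e-9)

    def test_row_moments_after_row_step(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(5, 3, (10, 30)))
        z = zscore_rows(df)
        assert z.mean(axis=1).to_numpy() == pytest.approx(np.zeros(10), abs=1e-12)
        assert z.std(axis=1, ddof=0).to_numpy() == pytest.approx(np.ones(10))

    def test_merge_restricts_and_drops_constant(self):
        rng = np.random.default_rng(2)
        cols = [f"S{i}" for i in range(12)]
        mrna = pd.DataFrame(rng.standard_normal((4, 12)),
                            index=["g1", "g2", "g3", "gflat"], columns=cols)
        mrna.loc["gflat"] = 7.0
        mirna = pd.DataFrame(rng.standard_normal((2, 12)),
                             index=["m1", "m2"], columns=cols)
        sig = Signature("s", mirnas=frozenset(["m1"]),
                        genes=frozenset(["g1", "gflat"]))
        merged = merge_and_normalize(mirna, mrna, sig)
        # the constant row is dropped; the rest of the signature survives
        assert sorted(merged.index) == ["g1", "m1"]
        assert list(merged.columns) == cols

    def test_normalization_happens_before_restriction(self):
        # the signature rows must match the full-profile normalization,
        # not a re-normalization of the restricted matrix
        rng = np.random.default_rng(12)
        cols = [f"S{i}" for i in range(20)]
        mrna = pd.DataFrame(rng.standard_normal((6, 20)),
                            index=[f"g{i}" for i in range(6)], columns=cols)
        mirna = pd.DataFrame(rng.standard_normal((3, 20)),
                             index=[f"m{i}" for i in range(3)], columns=cols)
        full = zscore_columns(zscore_rows(pd.concat([mirna, mrna])))
        sig = Signature("s", genes=frozenset(["g0", "g1"]))
        merged = merge_and_normalize(mirna, mrna, sig)
        assert merged.to_numpy() == pytest.approx(
            full.loc[["g0", "g1"]].to_numpy())

    def test_missing_signature_feature_rejected(self):
        cols = ["S1", "S2"]
        mrna = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=cols)
        mirna = pd.DataFrame([[1.0, 2.0]], index=["m1"], columns=cols)
        with pytest.raises(SurvwalkError, match="absent"):
            merge_and_normalize(mirna, mrna,
                                Signature("s", genes=frozenset(["gX"])))


class TestKmeansRiskGroups:
    def test_high_risk_is_deadlier_blob(self):
        rng = np.random.default_rng(3)
        X, blob = _blob_data(rng)
        events = np.where(blob == 0, rng.random(len(blob)) < 0.9,
                          rng.random(len(blob)) < 0.1).astype(int)
        clin = _clinical(X.columns, events)
        risk = kmeans_risk_groups(X, clin, seed=0)
        assert (risk[blob == 0] == "high").all()
        assert (risk[blob == 1] == "low").all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        X, blob = _blob_data(rng, sep=2.0)
        clin = _clinical(X.columns, (blob == 0).astype(int))
        a = kmeans_risk_groups(X, clin, seed=5)
        b = kmeans_risk_groups(X, clin, seed=5)
        assert a.equals(b)

    def test_recovers_planted_groups(self):
        agreements = []
        for rep in range(10):
            rng = np.random.default_rng(50 + rep)
            X, blob = _blob_data(rng, sep=4.0)
            events = (blob == 0).astype(int)
            clin = _clinical(X.columns, events)
            risk = kmeans_risk_groups(X, clin, seed=rep)
            got = (risk == "high").to_numpy()
            agreements.append(max(np.mean(got == (blob == 0)),
                                  np.mean(got == (blob == 1))))
        assert np.mean(agreements) >= 0.9

    def test_degenerate_input_rejected(self):
        X = pd.DataFrame(np.ones((3, 10)), columns=[f"S{i}" for i in range(10)])
        clin = _clinical(X.columns, [1] * 10)
        with pytest.raises(SurvwalkError, match="identical"):
            kmeans_risk_groups(X, clin)


class TestNearestCentroid:
    def test_separated_blobs_match_direct_kmeans(self):
        rng = np.random.default_rng(6)
        X, blob = _blob_data(rng, sep=10.0)
        events = (blob == 0).astype(int)
        clin = _clinical(X.columns, events)
        loo = nearest_centroid_classify(X, clin, seed=0)
        direct = kmeans_risk_groups(X, clin, seed=0)
        assert loo.equals(direct)

    def test_sample_at_centroid_joins_its_group(self):
        rng = np.random.default_rng(7)
        X, blob = _blob_data(rng, sep=10.0)
        # place one sample exactly at the empirical mean of blob 0
        X.iloc[:, 0] = X.iloc[:, 1:20].mean(axis=1)
        clin = _clinical(X.columns, (blob == 0).astype(int))
        loo = nearest_centroid_classify(X, clin, seed=0)
        assert loo.iloc[0] == loo.iloc[1]

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((2, 4)),
                         columns=list("abcd"))
        with pytest.raises(SurvwalkError, match=">= 5"):
            nearest_centroid_classify(X, _clinical(list("abcd"), [1, 0, 1, 0]))


class TestEvaluateSignature:
    def test_identical_inputs_identical_result(self, small_cohort):
        mrna, mirna, clinical, truth = small_cohort
        sig = Signature("planted", mirnas=frozenset(truth.planted_mirnas),
                        genes=frozenset(truth.planted_genes))
        a = evaluate_signature(mirna, mrna, clinical, sig, seed=1)
        b = evaluate_signature(mirna.copy(), mrna.copy(), clinical.copy(),
                               sig, seed=1)
        assert a.logrank_p == b.logrank_p
        assert a.risk_labels.equals(b.risk_labels)

    def test_null_signature_pvalues_uniform(self):
        """With no survival signal the evaluation p-value is U(0,1)."""
        null = PlantedTruth(effect_size=0.0)
        ps = []
        for rep in range(200):
            mrna, mirna, clin = generate_cohort(60, 20, 10, null, seed=5000 + rep)
            sig = Signature("null", mirnas=frozenset(null.planted_mirnas),
                            genes=frozenset(null.planted_genes))
            ps.append(evaluate_signature(mirna, mrna, clin, sig,
                                         seed=rep).logrank_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_signature_has_power(self):
        """A planted prognostic signature reaches p < 0.05 in >=90% of runs."""
        hits = 0
        for rep in range(50):
            truth = PlantedTruth()
            mrna, mirna, clin = generate_cohort(160, 20, 10, truth,
                                                seed=7000 + rep)
            sig = Signature("planted", mirnas=frozenset(truth.planted_mirnas),
                            genes=frozenset(truth.planted_genes))
            res = evaluate_signature(mirna, mrna, clin, sig, seed=rep)
            hits += res.logrank_p < 0.05
        assert hits / 50 >= 0.9

    def test_grade_subset_supported(self, small_cohort):
        mrna, mirna, clinical, truth = small_cohort
        sig = Signature("planted", genes=frozenset(truth.planted_genes))
        subset = clinical.index[clinical["grade"].isin(["III", "IV"])].tolist()
        res = evaluate_signature(mirna, mrna, clinical, sig, seed=0,
                                 samples=subset)
        assert set(res.risk_labels.index) <= set(subset)

    def test_small_subset_rejected(self, small_cohort):
        mrna, mirna, clinical, truth = small_cohort
        sig = Signature("planted", genes=frozenset(truth.planted_genes))
        with pytest.raises(SurvwalkError, match=">= 10"):
            evaluate_signature(mirna, mrna, clinical, sig,
                               samples=list(clinical.index[:5]))


class TestOptimizeTopn:
    def test_range_arithmetic(self, small_cohort):
        mrna, mirna, clinical, _ = small_cohort
        ranked = list(mrna.index[:30])
        best_n, curve = optimize_topn(ranked, mirna, mrna, clinical,
                                      n_range=(2, 25), seed=0)
        assert len(curve) == 24
        assert 2 <= best_n <= 25
        assert curve.loc[best_n, "p_value"] == curve["p_value"].min()

    def test_truncation_warning(self, small_cohort):
        mrna, mirna, clinical, _ = small_cohort
        ranked = list(mrna.index[:5])
        _, curve = optimize_topn(ranked, mirna, mrna, clinical, n_range=(2, 25))
        assert list(curve.index) == [2, 3, 4, 5]

    def test_null_candidates_dilute_a_dominant_pair(self):
        """Padding a prognostic pair with null genes degrades the signature.

        The p-vs-n curve is stochastic, so the argmin itself is noisy; the
        stable property is that the pure pair beats the fully diluted
        signature in most replicates and by orders of magnitude on average.
        """
        from survwalk import screen_features

        wins, log_gaps = 0, []
        reps = 20
        for rep in range(reps):
            truth = PlantedTruth(planted_genes=("G0001", "G0002"),
                                 planted_seed_genes=("G0001", "G0002"),
                                 effect_size=1.0)
            mrna, mirna, clin = generate_cohort(160, 30, 5, truth, seed=8000 + rep)
            sc = screen_features(mrna, clin, alpha=1.0)
            ranked = list(sc.sort_values("p_value").index)
            _, curve = optimize_topn(ranked, mirna, mrna, clin,
                                     n_range=(2, 25), seed=rep)
            p2, p25 = curve.loc[2, "p_value"], curve.loc[25, "p_value"]
            wins += p2 < p25
            log_gaps.append(np.log10(max(p25, 1e-300)) - np.log10(max(p2, 1e-300)))
        assert wins / reps >= 0.7
        assert np.mean(log_gaps) > 1.0  # >= 10x better on average

    def test_ties_resolve_to_smallest_n(self):
        # identical candidate rows -> identical evaluations for every n
        rng = np.random.default_rng(13)
        cols = [f"S{i:03d}" for i in range(40)]
        base = rng.standard_normal(40)
        mrna = pd.DataFrame([base + rng.normal(0, 1e-9, 40) for _ in range(6)],
                            index=[f"g{i}" for i in range(6)], columns=cols)
        mirna = pd.DataFrame(rng.standard_normal((2, 40)),
                             index=["m1", "m2"], columns=cols)
        clin = _clinical(cols, rng.integers(0, 2, 40))
        best_n, curve = optimize_topn(list(mrna.index), mirna, mrna, clin,
                                      n_range=(2, 6), seed=0)
        assert curve["p_value"].nunique() == 1
        assert best_n == 2


class TestRecurrenceRatio:
    def test_identity_and_disjoint(self):
        assert recurrence_ratio({"a", "b"}, {"a", "b"}) == 1.0
        assert recurrence_ratio({"a", "b"}, {"c"}) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            orig = set(rng.choice(50, rng.integers(1, 20), replace=False))
            rerun = set(rng.choice(50, rng.integers(0, 20), replace=False))
            assert recurrence_ratio(orig, rerun) == len(orig & rerun) / len(orig)

    def test_empty_original_rejected(self):
        with pytest.raises(SurvwalkError):
            recurrence_ratio(set(), {"a"})

    @given(st.sets(st.integers(0, 30), min_size=1),
           st.sets(st.integers(0, 30)), st.integers(31, 60))
    def test_monotone_in_intersection(self, orig, rerun, extra):
        base = recurrence_ratio(orig, rerun)
        more = rerun | {next(iter(orig))}
        assert recurrence_ratio(orig, more) >= base
        assert recurrence_ratio(orig, rerun | {extra}) == base


class TestPartitions:
    def test_half_split_of_160(self):
        samples = [f"S{i}" for i in range(160)]
        splits = shuffle_and_split(samples, n_repeats=5, seed=0)
        for train, test in splits:
            assert len(train) == 80 and len(test) == 80
            assert set(train) | set(test) == set(samples)
            assert set(train) & set(test) == set()

    def test_deterministic_stream(self):
        samples = [f"S{i}" for i in range(20)]
        assert shuffle_and_split(samples, 10, seed=3) == \
            shuffle_and_split(samples, 10, seed=3)

    def test_perturb_swaps_n_samples(self):
        train = [f"A{i}" for i in range(10)]
        test = [f"B{i}" for i in range(10)]
        new_train, new_test = perturb_partition(train, test, n_swap=3, seed=0)
        assert len(new_train) == len(new_test) == 10
        assert len(set(new_train) & set(test)) == 3
        assert len(set(new_test) & set(train)) == 3
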