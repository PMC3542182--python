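import logging

import numpy as np
import pandas as pd
import pytest

from crmscan.classify import (
    BolassoResult,
    EnhancerSet,
    FeatureMatrix,
    bolasso,
    build_features,
    fit_lasso_once,
    hit_density,
    loocv_auc,
    score_enhancer,
    select_final,
    standardize,
    unstandardize,
)
from crmscan.motifs import ConsensusMotif, scan_consensus
from crmscan.seqio import SequenceRecord

from conftest import random_dna


def toy_matrix(rng, n=40, p=10, signal_col=0, effect=2.0):
    """Labels +/-1 with one informative density-like column."""
    y = np.array([+1] * (n // 2) + [-1] * (n - n // 2))
    X = rng.normal(0, 1, (n, p))
    X[:, signal_col] += effect * (y > 0)
    values = pd.DataFrame(X, index=[f"e{i}" for i in range(n)],
                          columns=[f"m{j}" for j in range(p)])
    return FeatureMatrix(values), y


class TestEnhancerSet:
    def test_valid_labels_required(self):
        rec = SequenceRecord("a", "ACGT")
        with pytest.raises(ValueError):
            EnhancerSet([(rec, 0)])
        with pytest.raises(ValueError):
            EnhancerSet([(rec, 1), (rec, 1)])  # one class only


class TestBuildFeatures:
    def make_set(self, rng, n=6):
        records = []
        for i in range(n):
            rec = SequenceRecord(f"e{i}", random_dna(rng, 500))
            records.append((rec, +1 if i < n // 2 else -1))
        return EnhancerSet(records)

    def test_single_cell_matches_hit_density(self):
        rng = np.random.default_rng(0)
        enh = self.make_set(rng, n=2)
        motif = ConsensusMotif("CEE", "ATTKCC")
        fm = build_features(enh, consensi=[motif])
        rec = enh.sequences[0]
        expected = hit_density(scan_consensus(rec, motif), len(rec))
        assert fm.values.loc[rec.id, "CEE"] == pytest.approx(expected)

    def test_absent_motif_column_retained_as_zero(self):
        rng = np.random.default_rng(1)
        enh = self.make_set(rng)
        fm = build_features(enh, consensi=[ConsensusMotif("never", "ACGTACGTACGT")])
        assert (fm.values["never"] == 0).all()

    def test_duplicate_ids_rejected(self):
        rng = np.random.default_rng(2)
        enh = self.make_set(rng)
        dup = [ConsensusMotif("m", "ACGTAA"), ConsensusMotif("m", "TTGACA")]
        with pytest.raises(ValueError):
            build_features(enh, consensi=dup)

    def test_matrix_matches_cellwise_oracle(self):
        rng = np.random.default_rng(3)
        enh = self.make_set(rng, n=10)
        motifs = [ConsensusMotif(f"m{i}", random_dna(rng, 5)) for i in range(3)]
        fm = build_features(enh, consensi=motifs)
        for rec in enh.sequences:
            for m in motifs:
                expected = hit_density(scan_consensus(rec, m), len(rec))
                assert fm.values.loc[rec.id, m.id] == pytest.approx(expected)


class TestStandardize:
    def test_population_zscores(self):
        fm = FeatureMatrix(pd.DataFrame({"a": [1.0, 2.0, 3.0]}, index=list("xyz")))
        z = standardize(fm)
        assert np.allclose(z.values["a"], [-1.22474487, 0, 1.22474487])
        assert z.values["a"].mean() == pytest.approx(0, abs=1e-9)
        assert z.values["a"].var(ddof=0) == pytest.approx(1, abs=1e-6)

    def test_constant_column_dropped_with_warning(self, caplog):
        fm = FeatureMatrix(pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]}))
        with caplog.at_level(logging.WARNING):
            z = standardize(fm)
        assert list(z.values.columns) == ["a"]
        assert any("constant" in r.message for r in caplog.records)

    def test_roundtrip(self):
        rng = np.random.default_rng(4)
        fm = FeatureMatrix(pd.DataFrame(rng.normal(2, 3, (8, 4)), columns=list("abcd")))
        back = unstandardize(standardize(fm))
        assert np.allclose(back.values, fm.values)

    def test_all_constant_rejected(self):
        fm = FeatureMatrix(pd.DataFrame({"a": [1.0, 1.0]}))
        with pytest.raises(ValueError):
            standardize(fm)


class TestFitLassoOnce:
    def test_separating_feature_selected_with_positive_sign(self):
        rng = np.random.default_rng(5)
        fm, y = toy_matrix(rng, n=50, p=8, effect=3.0)
        z = standardize(fm)
        fit = fit_lasso_once(z.values.to_numpy(), y, seed=1)
        assert fit.coefficients[0] > 0

    def test_permuted_labels_select_little(self):
        rng = np.random.default_rng(6)
        fm, y = toy_matrix(rng, n=50, p=8, effect=0.0)
        z = standardize(fm)
        n_selected = [
            int(fit_lasso_once(z.values.to_numpy(), rng.permutation(y), seed=s).selected.sum())
            for s in range(5)
        ]
        assert np.mean(n_selected) < 4

    def test_max_features_zero_gives_intercept_only(self):
        rng = np.random.default_rng(7)
        fm, y = toy_matrix(rng)
        fit = fit_lasso_once(fm.values.to_numpy(), y, max_features=0)
        assert not fit.selected.any()
        assert fit.intercept == pytest.approx(y.mean())

    def test_feature_cap_enforced(self):
        rng = np.random.default_rng(8)
        fm, y = toy_matrix(rng, n=40, p=20, effect=1.0)
        z = standardize(fm)
        fit = fit_lasso_once(z.values.to_numpy(), y, max_features=3, seed=2)
        assert fit.selected.sum() <= 3


class TestBolasso:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        fm, y = toy_matrix(rng, n=30, p=6)
        z = standardize(fm)
        a = bolasso(z, y, n_bootstrap=30, seed=11)
        b = bolasso(z, y, n_bootstrap=30, seed=11)
        assert a.selection_freq == b.selection_freq

    def test_planted_feature_dominates(self):
        # one clearly discriminative feature among 30 noise features, 61 rows
        rng = np.random.default_rng(10)
        fm, y = toy_matrix(rng, n=61, p=31, effect=2.5)
        z = standardize(fm)
        res = bolasso(z, y, n_bootstrap=100, seed=3)
        assert res.selection_freq["m0"] >= 0.95
        noise_max = max(v for k, v in res.selection_freq.items() if k != "m0")
        assert res.selection_freq["m0"] >= noise_max

    def test_requires_standardized_matrix(self):
        rng = np.random.default_rng(11)
        fm, y = toy_matrix(rng)
        with pytest.raises(ValueError):
            bolasso(fm, y, n_bootstrap=5)

    def test_threshold_sets_are_nested(self):
        rng = np.random.default_rng(12)
        fm, y = toy_matrix(rng, n=40, p=10, effect=1.5)
        z = standardize(fm)
        res = bolasso(z, y, n_bootstrap=50, seed=5)
        sets = {
            t: {m for m, f in res.selection_freq.items() if f >= t}
            for t in (0.9, 0.7, 0.5, 0.3)
        }
        assert sets[0.9] <= sets[0.7] <= sets[0.5] <= sets[0.3]


class TestSelectFinal:
    def scripted(self, aucs_by_nfeat):
        def fake_auc(fm, y, feats):
            return aucs_by_nfeat[len(feats)]
        return fake_auc

    def make_result(self, freqs):
        return BolassoResult(100, freqs, seed=0)

    def test_stops_when_auc_stops_improving(self):
        rng = np.random.default_rng(13)
        fm, y = toy_matrix(rng, n=20, p=8)
        z = standardize(fm)
        # distinct feature sets appear at 0.95, 0.90, 0.65, 0.50; AUC improves
        # down to the 0.65 set then goes flat
        freqs = {"m0": 0.96, "m1": 0.9, "m2": 0.65, "m3": 0.5}
        freqs.update({f"m{i}": 0.0 for i in range(4, 8)})
        auc = self.scripted({1: 0.7, 2: 0.8, 3: 0.9, 4: 0.9})
        clf = select_final(self.make_result(freqs), z, y, auc_fn=auc)
        assert clf.confidence_threshold == pytest.approx(0.65)
        assert set(clf.motifs) == {"m0", "m1", "m2"}
        assert clf.loocv_auc == pytest.approx(0.9)

    def test_single_confident_feature_stops_at_start(self):
        rng = np.random.default_rng(14)
        fm, y = toy_matrix(rng, n=20, p=8)
        z = standardize(fm)
        freqs = {f"m{i}": 0.0 for i in range(8)}
        freqs["m0"] = 0.96
        freqs["m1"] = 0.3
        auc = self.scripted({1: 0.9, 2: 0.85})
        clf = select_final(self.make_result(freqs), z, y, auc_fn=auc)
        assert clf.confidence_threshold == pytest.approx(0.95)
        assert clf.motifs == ["m0"]

    def test_empty_bolasso_gives_none(self):
        rng = np.random.default_rng(15)
        fm, y = toy_matrix(rng, n=20, p=4)
        z = standardize(fm)
        freqs = {m: 0.0 for m in z.motif_ids}
        assert select_final(self.make_result(freqs), z, y) is None

    def test_recovers_planted_signal_end_to_end(self):
        rng = np.random.default_rng(16)
        fm, y = toy_matrix(rng, n=61, p=20, effect=2.5)
        z = standardize(fm)
        res = bolasso(z, y, n_bootstrap=100, seed=6)
        clf = select_final(res, z, y)
        assert clf is not None
        assert "m0" in clf.motifs
        assert clf.coefficients["m0"] > 0
        assert clf.loocv_auc > 0.9


def oracle_auc(y, decisions):
    """O(n^2) Mann-Whitney pair counting with half-credit ties."""
    pos = decisions[y > 0]
    neg = decisions[y < 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestLoocvAuc:
    def test_perfectly_separable_feature(self):
        rng = np.random.default_rng(17)
        fm, y = toy_matrix(rng, n=30, p=3, effect=50.0)
        z = standardize(fm)
        assert loocv_auc(z, y, ["m0"]) == 1.0

    def test_matches_pair_counting_oracle(self):
        # recompute the held-out decisions independently, then compare AUCs
        rng = np.random.default_rng(18)
        fm, y = toy_matrix(rng, n=24, p=4, effect=1.0)
        z = standardize(fm)
        X = z.values[["m0", "m1"]].to_numpy()
        decisions = np.empty(len(y))
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            A = np.column_stack([np.ones(keep.sum()), X[keep]])
            beta, *_ = np.linalg.lstsq(A, y[keep].astype(float), rcond=None)
            decisions[i] = beta[0] + X[i] @ beta[1:] - y[keep].mean()
        assert loocv_auc(z, y, ["m0", "m1"]) == pytest.approx(oracle_auc(y, decisions), abs=1e-12)

    def test_permutation_null_is_centered(self):
        rng = np.random.default_rng(19)
        fm, y = toy_matrix(rng, n=61, p=10, effect=0.0)
        z = standardize(fm)
        aucs = [loocv_auc(z, rng.permutation(y), ["m0", "m1", "m2"]) for _ in range(200)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(20)
        fm, _ = toy_matrix(rng, n=10, p=2)
        with pytest.raises(ValueError):
            loocv_auc(fm, np.ones(10), ["m0"])


class TestScoring:
    def make_clf(self):
        rng = np.random.default_rng(21)
        fm, y = toy_matrix(rng, n=30, p=5, effect=2.0)
        z = standardize(fm)
        res = bolasso(z, y, n_bootstrap=50, seed=7)
        return select_final(res, z, y), z, y

    def test_zero_row_scores_intercept(self):
        clf, z, _ = self.make_clf()
        row = {m: 0.0 for m in clf.motifs}
        assert score_enhancer(clf, row) == pytest.approx(clf.intercept)

    def test_training_row_matches_in_sample_decision(self):
        clf, z, y = self.make_clf()
        X = z.values[clf.motifs].to_numpy()
        coefs = np.array([clf.coefficients[m] for m in clf.motifs])
        expected = clf.intercept + X[0] @ coefs
        assert score_enhancer(clf, z.values.iloc[0]) == pytest.approx(expected)

    def test_linearity_in_positive_coefficient(self):
        clf, z, _ = self.make_clf()
        positives = [m for m, c in clf.coefficients.items() if c > 0]
        assert positives
        row = {m: 0.0 for m in clf.motifs}
        low = score_enhancer(clf, row)
        row[positives[0]] = 2.0
        assert score_enhancer(clf, row) > low

    def test_missing_feature_rejected(self):
        clf, _, _ = self.make_clf()
        with pytest.raises(ValueError):
            score_enhancer(clf, {})
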