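import numpy as np
import pandas as pd
import pytest
from scipy import stats

import imrescore as ir
from imrescore import synthetic as syn
from imrescore.io import IonMobilityValue, Psm, parse_peptidoform
from imrescore.rescoring import (
    RescoreConfig,
    assemble_features,
    calibrate_ccs,
    ccs_features,
    compare_runs,
    entrapment_analysis,
    feature_weight_report,
    rollup,
    semi_supervised_rescore,
    tdc_qvalues,
)


def brute_force_qvalues(scores, decoys):
    """Independent oracle: enumerate every threshold explicitly."""
    scores = np.asarray(scores, float)
    decoys = np.asarray(decoys, bool)
    q = np.empty(len(scores))
    thresholds = np.unique(scores)
    fdr_at = {}
    for t in thresholds:
        above = scores >= t
        d = int((above & decoys).sum())
        targets = int((above & ~decoys).sum())
        fdr_at[t] = min((d + 1) / max(targets, 1), 1.0)
    for i, s in enumerate(scores):
        q[i] = min(fdr_at[t] for t in thresholds if t <= s)
    return q


class TestTdcQvalues:
    def test_hand_enumerated_example(self):
        # descending scores [10 T, 9 T, 8 D, 7 T, 6 D]
        qt = tdc_qvalues([10, 9, 8, 7, 6],
                         [False, False, True, False, True])
        np.testing.assert_allclose(qt.q_values[:2], 0.5)
        assert qt.q_values[3] == pytest.approx(2 / 3)

    def test_no_decoys_one_over_t_pattern(self):
        qt = tdc_qvalues([5, 4, 3, 2], [False] * 4)
        np.testing.assert_allclose(qt.q_values, [1 / 4] * 4)
        # running minimum makes every q the floor 1/#targets

    def test_matches_bruteforce_on_random_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(2, 120))
            scores = rng.choice(rng.normal(size=max(n // 2, 2)), size=n)
            decoys = rng.random(n) < 0.5
            if decoys.all():
                decoys[0] = False
            qt = tdc_qvalues(scores, decoys)
            np.testing.assert_allclose(
                qt.q_values, brute_force_qvalues(scores, decoys), atol=1e-12
            )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=150)
        decoys = rng.random(150) < 0.5
        qt = tdc_qvalues(scores, decoys)
        perm = rng.permutation(150)
        qt_p = tdc_qvalues(scores[perm], decoys[perm])
        np.testing.assert_allclose(qt.q_values[perm], qt_p.q_values)

    def test_monotone_in_score(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=200)
        decoys = rng.random(200) < 0.4
        qt = tdc_qvalues(scores, decoys)
        order = np.argsort(-scores)
        assert np.all(np.diff(qt.q_values[order]) >= -1e-12)

    def test_all_decoys_warns(self):
        with pytest.warns(UserWarning):
            qt = tdc_qvalues([3, 2], [True, True])
        np.testing.assert_allclose(qt.q_values, 1.0)


class TestRollup:
    def _psm(self, sid, pep, score, decoy=False, proteins=("P1",), rank=1):
        return Psm(sid, parse_peptidoform(pep), score, is_decoy=decoy,
                   proteins=proteins, rank=rank)

    def test_peptide_keeps_best_psm(self):
        psms = [
            self._psm("s1", "ACDK/2", 1.0),
            self._psm("s2", "ACDK/3", 3.0),
            self._psm("s3", "ACDK/2", 2.0, rank=2),
        ]
        ids, scores, dec = rollup(psms, [p.score for p in psms], "peptide")
        assert len(ids) == 1 and scores[0] == 3.0  # charge-agnostic key

    def test_peptide_charge_aware_switch(self):
        psms = [self._psm("s1", "ACDK/2", 1.0), self._psm("s2", "ACDK/3", 3.0)]
        ids, _, _ = rollup(psms, [1.0, 3.0], "peptide",
                           charge_aware_peptides=True)
        assert len(ids) == 2

    def test_picked_protein_competition(self):
        psms = [
            self._psm("s1", "ACDK/2", 5.0, False, ("P12345",)),
            self._psm("s2", "KDCAK/2", 7.0, True, ("rev_P12345",)),
        ]
        ids, scores, dec = rollup(psms, [5.0, 7.0], "protein")
        assert ids == ["rev_P12345"] and dec[0] and scores[0] == 7.0

    def test_unique_keys_identity(self):
        psms = [self._psm(f"s{i}", f"ACD{aa}K/2", float(i))
                for i, aa in enumerate("EFGH")]
        ids, scores, _ = rollup(psms, [p.score for p in psms], "peptide")
        assert len(ids) == 4

    def test_protein_level_skips_orphans(self):
        psms = [self._psm("s1", "ACDK/2", 5.0, proteins=())]
        with pytest.warns(UserWarning):
            ids, _, _ = rollup(psms, [5.0], "protein")
        assert ids == []


class TestCalibration:
    def _psms_with_ccs(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        peps = syn.generate_peptides(n, (8, 14), modification_alphabet=(),
                                     seed=seed)
        coeffs = syn.CcsCoefficients()
        psms, obs = [], []
        for i, p in enumerate(peps):
            ccs = coeffs.truth(p)
            decoy = i % 3 == 2
            score = rng.normal(5.0 if not decoy else 0.0, 1.0)
            psms.append(Psm(f"s{i}", p, score,
                            ion_mobility=IonMobilityValue("ccs", ccs),
                            is_decoy=decoy))
            obs.append(ccs)
        return psms, np.array(obs)

    def test_identity_when_predictions_match(self):
        psms, obs = self._psms_with_ccs()
        cal = calibrate_ccs(psms, obs)
        assert cal.slope == pytest.approx(1.0, abs=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)

    def test_pure_offset(self):
        psms, obs = self._psms_with_ccs()
        cal = calibrate_ccs(psms, obs - 5.0)
        assert cal.slope == pytest.approx(1.0, abs=1e-9)
        assert cal.intercept == pytest.approx(5.0, abs=1e-6)

    def test_drift_recovery_with_noise(self):
        psms, obs = self._psms_with_ccs(n=600, seed=3)
        rng = np.random.default_rng(9)
        pred = (obs + 8.0) / 1.03 + rng.normal(0, 1.0, len(obs))
        cal = calibrate_ccs(psms, pred)
        assert cal.slope == pytest.approx(1.03, abs=0.02)
        assert cal.intercept == pytest.approx(-8.0, abs=2.5)

    def test_too_few_pairs_identity_with_warning(self):
        psms, obs = self._psms_with_ccs(n=12)
        with pytest.warns(UserWarning):
            cal = calibrate_ccs(psms[:6], obs[:6])
        assert (cal.slope, cal.intercept) == (1.0, 0.0)


class TestCcsFeatures:
    def test_arithmetic(self):
        psm = Psm("s", parse_peptidoform("ACDK/2"), 1.0,
                  ion_mobility=IonMobilityValue("ccs", 300.0))
        f = ccs_features(psm, 303.0)
        assert f["ccs_abs_error"] == pytest.approx(3.0)
        assert f["ccs_perc_error"] == pytest.approx(1.0)

    def test_zero_error_and_scale_invariance(self):
        psm = Psm("s", parse_peptidoform("ACDK/2"), 1.0,
                  ion_mobility=IonMobilityValue("ccs", 250.0))
        f = ccs_features(psm, 250.0)
        assert f["ccs_abs_error"] == 0.0 and f["ccs_perc_error"] == 0.0
        for c in (2.0, 10.0):
            psm_c = Psm("s", psm.peptidoform, 1.0,
                        ion_mobility=IonMobilityValue("ccs", 250.0 * c))
            assert ccs_features(psm_c, 260.0 * c)["ccs_perc_error"] == (
                pytest.approx(ccs_features(psm, 260.0)["ccs_perc_error"])
            )

    def test_missing_mobility_explicit(self):
        psm = Psm("s", parse_peptidoform("ACDK/2"), 1.0)
        f = ccs_features(psm, 300.0)
        assert all(np.isnan(v) for v in f.values())


class TestAssembleFeatures:
    def test_predictor_free_is_search_block_only(self, small_benchmark):
        psms, spectra, _ = small_benchmark
        feats, kept = assemble_features(list(psms)[:30])
        assert list(feats.columns) == ["search_score"]
        assert len(kept) == 30

    def test_row_conservation(self, small_benchmark):
        psms, spectra, _ = small_benchmark
        subset = list(psms)[:40]
        spectra_missing = dict(list(spectra.items()))
        for p in subset[:5]:
            spectra_missing.pop(p.spectrum_id)
        feats, kept = assemble_features(
            subset, spectra_missing, syn.LawIntensityPredictor()
        )
        assert len(feats) + feats.attrs["dropped"] == len(subset)
        assert feats.attrs["dropped"] == 5

    def test_perfect_predictor_unity_pcc_for_correct(self):
        p = parse_peptidoform("ACDEFGHIK/2")
        sp = syn.simulate_spectrum(p, noise_sigma=0.0, n_noise_peaks=0,
                                   seed=0, identifier="x")
        psm = Psm("x", p, 1.0)
        feats, _ = assemble_features([psm], {"x": sp},
                                     syn.LawIntensityPredictor())
        assert feats["spectrum_pcc"][0] == pytest.approx(1.0, abs=1e-9)


class TestSemiSupervised:
    def test_search_score_only_preserves_order(self, small_benchmark):
        psms, _, _ = small_benchmark
        kept = list(psms)
        feats = pd.DataFrame({"search_score": [p.score for p in kept]})
        decoys = [p.is_decoy for p in kept]
        scores, _ = semi_supervised_rescore(feats, decoys,
                                            RescoreConfig(seed=0))
        # fold-wise decoy normalization merges fold scores through affine
        # maps estimated from finite decoy samples, so cross-fold ordering
        # is preserved only up to that sampling noise
        rho = stats.spearmanr([p.score for p in kept], scores).statistic
        assert rho > 0.995

    def test_determinism(self, small_benchmark):
        psms, spectra, _ = small_benchmark
        feats, kept = assemble_features(
            list(psms), spectra, syn.LawIntensityPredictor(),
            syn.TruthCcsPredictor(),
        )
        decoys = [p.is_decoy for p in kept]
        s1, w1 = semi_supervised_rescore(feats, decoys, RescoreConfig(seed=5))
        s2, w2 = semi_supervised_rescore(feats, decoys, RescoreConfig(seed=5))
        np.testing.assert_array_equal(s1, s2)
        pd.testing.assert_series_equal(w1, w2)

    def test_informative_features_gain_identifications(self, small_benchmark):
        psms, spectra, _ = small_benchmark
        feats, kept = assemble_features(
            list(psms), spectra, syn.LawIntensityPredictor(),
            syn.TruthCcsPredictor(),
        )
        decoys = np.array([p.is_decoy for p in kept])
        scores, _ = semi_supervised_rescore(feats, decoys,
                                            RescoreConfig(seed=1))
        q = 0.05  # small benchmark: the +1 correction dominates below this
        before = tdc_qvalues([p.score for p in kept], decoys).n_accepted(q)
        after = tdc_qvalues(scores, decoys).n_accepted(q)
        assert after > before

    def test_no_decoys_rejected(self):
        feats = pd.DataFrame({"search_score": [1.0, 2.0]})
        with pytest.raises(ValueError):
            semi_supervised_rescore(feats, [False, False])


class TestReports:
    def test_compare_runs_set_identities(self):
        before = tdc_qvalues([5, 4, 3, 1], [False, False, False, True],
                             ["a", "b", "c", "d"])
        after = tdc_qvalues([1, 4, 5, 3], [True, False, False, False],
                            ["a", "b", "c", "d"])
        (rep,) = compare_runs(before, after, (0.5,))
        assert rep.gained | rep.shared == {
            i for i, acc in zip(after.identifiers, after.accepted(0.5)) if acc
        }
        assert len(rep.gained) - len(rep.lost) == rep.n_after - rep.n_before

    def test_identical_tables_no_changes(self):
        qt = tdc_qvalues([5, 4, 3], [False, False, True], ["a", "b", "c"])
        (rep,) = compare_runs(qt, qt, (0.5,))
        assert rep.gained == set() and rep.lost == set()

    def test_entrapment_percentages(self):
        n = 600
        scores = np.linspace(10, 1, n)
        decoys = np.zeros(n, bool)
        decoys[500:] = True
        qt = tdc_qvalues(scores, decoys)
        flags = np.zeros(n, bool)
        flags[:5] = True  # 5 entrapment hits among accepted
        rep = entrapment_analysis(qt, flags, db_size_ratio=2.0, threshold=0.01)
        assert rep["raw_percent"] == pytest.approx(
            100 * 5 / rep["n_accepted"]
        )
        assert rep["normalized_percent"] == pytest.approx(
            rep["raw_percent"] / 2.0
        )

    def test_entrapment_zero_accepted(self):
        qt = tdc_qvalues([1.0, 0.9], [False, True])
        rep = entrapment_analysis(qt, [False, False], 1.0, threshold=1e-6)
        assert rep["n_accepted"] == 0 and rep["raw_percent"] == 0.0

    def test_feature_weight_report_blocks(self):
        w = pd.Series({"spectrum_pcc": 2.0, "search_score": 1.0,
                       "ccs_abs_error": 0.5, "unrelated": 0.1})
        rep = feature_weight_report(w)
        assert list(rep["feature"])[:2] == ["spectrum_pcc", "search_score"]
        assert rep.loc[rep["feature"] == "spectrum_pcc", "block"].item() == "spectrum"
        assert rep.loc[rep["feature"] == "unrelated", "block"].item() == "other"
        np.testing.assert_allclose(sorted(rep["abs_weight"]),
                                   sorted(w.abs().values))
        summary = rep.attrs["block_summary"]
        assert summary.index[0] == "spectrum"
        assert summary["ccs"] == pytest.approx(0.5)
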