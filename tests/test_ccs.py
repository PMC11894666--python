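import numpy as np
import pytest

import imrescore as ir
from imrescore import synthetic as syn
from imrescore.ccs import (
    CcsConfig,
    CcsRecord,
    GLOBAL_FEATURE_NAMES,
    align_datasets,
    ccs_to_one_over_k0,
    collapse_isomers,
    encode_peptide,
    global_features,
    loo_amino_acid_harness,
    loo_modification_harness,
    merge_datasets,
    one_over_k0_to_ccs,
    predict_ccs,
    train_ccs_model,
)
from imrescore.io import Modification, Peptidoform, parse_peptidoform

FAST = CcsConfig(seed=2)
GIDX = {name: i for i, name in enumerate(GLOBAL_FEATURE_NAMES)}


def _shift_records(delta=12.0, sigma=1.0, n=800, frac=0.3, seed=5):
    """Peptides where a fraction carry a synthetic modification whose
    composition induces a CCS shift of `delta` under the linear truth."""
    name, mass, comp = syn.modification_with_shift(delta)
    rng = np.random.default_rng(seed)
    peps = syn.generate_peptides(n, (8, 30), modification_alphabet=(),
                                 seed=seed + 1)
    out = []
    for p in peps:
        if rng.random() < frac:
            pos = int(rng.integers(1, len(p.sequence) + 1))
            mod = Modification(pos, name, mass, tuple(sorted(comp.items())))
            out.append(Peptidoform(p.sequence, (mod,), p.charge))
        else:
            out.append(p)
    return syn.simulate_ccs(out, noise_sigma=sigma, seed=seed + 2), name


class TestEncoding:
    def test_global_frequencies(self):
        g = global_features(parse_peptidoform("HKWDE/2"))
        assert g[GIDX["freq_his"]] == pytest.approx(0.2)
        assert g[GIDX["freq_bulky"]] == pytest.approx(0.2)
        assert g[GIDX["freq_acidic"]] == pytest.approx(0.4)
        assert g[GIDX["freq_kr"]] == pytest.approx(0.2)
        assert g[GIDX["charge"]] == 2

    def test_diamino_composition(self):
        enc = encode_peptide(parse_peptidoform("AGKR/2"))
        # first diamino row = A + G = C5 H8 N2 O2
        np.testing.assert_allclose(enc.path2[0, :5], [5, 8, 2, 2, 0])

    def test_ignored_modification_equals_unmodified(self):
        mod = parse_peptidoform("AC[+57.02146]DKLM/2")
        plain = parse_peptidoform("ACDKLM/2")
        e_ign = encode_peptide(mod, ignore_modification="carbamidomethyl")
        e_plain = encode_peptide(plain)
        for path in ("path1", "path2", "path3", "path4"):
            np.testing.assert_array_equal(
                getattr(e_ign, path), getattr(e_plain, path)
            )

    def test_encoding_is_pure(self):
        p = parse_peptidoform("ACDEFM[+15.99491]K/3")
        a, b = encode_peptide(p), encode_peptide(p)
        for path in ("path1", "path2", "path3", "path4"):
            assert getattr(a, path).tobytes() == getattr(b, path).tobytes()

    def test_padding_marker_and_length_cap(self):
        enc = encode_peptide(parse_peptidoform("ACDK/2"), max_length=10)
        assert enc.path1[4:, 6].all() and not enc.path1[:4, 6].any()
        with pytest.raises(ValueError):
            encode_peptide(parse_peptidoform("ACDK/2"), max_length=3)

    def test_glycine_substitution(self):
        sub = encode_peptide(parse_peptidoform("WADK/2"), substitute={"W": "G"})
        ref = encode_peptide(parse_peptidoform("GADK/2"))
        np.testing.assert_array_equal(sub.path1, ref.path1)
        np.testing.assert_array_equal(sub.path3, ref.path3)
        np.testing.assert_array_equal(sub.path4, ref.path4)


@pytest.fixture(scope="module")
def linear_records():
    peps = syn.generate_peptides(800, (8, 30), seed=3)
    return syn.simulate_ccs(peps, noise_sigma=0.0, seed=4)


class TestTraining:
    def test_noiseless_recovery(self, linear_records):
        model = train_ccs_model(linear_records, FAST)
        assert model.log["test_mae"] <= 0.5

    def test_determinism(self, linear_records):
        m1 = train_ccs_model(linear_records[:400], FAST)
        m2 = train_ccs_model(linear_records[:400], FAST)
        peps = [r.peptidoform for r in linear_records[400:420]]
        np.testing.assert_array_equal(predict_ccs(m1, peps),
                                      predict_ccs(m2, peps))

    def test_empty_validation_rejected(self, linear_records):
        cfg = CcsConfig(validation_fraction=0.0)
        with pytest.raises(ValueError, match="validation"):
            train_ccs_model(linear_records[:100], cfg)

    def test_predictions_positive_finite_and_duplicated(self, linear_records):
        model = train_ccs_model(linear_records, FAST)
        peps = [r.peptidoform for r in linear_records[:50]]
        out = predict_ccs(model, peps + peps)
        assert np.all(np.isfinite(out)) and np.all(out > 0)
        np.testing.assert_array_equal(out[:50], out[50:])

    def test_charge_sensitivity(self, linear_records):
        model = train_ccs_model(linear_records, FAST)
        p2 = parse_peptidoform("ACDEFGHIKLMNPK/2")
        p3 = parse_peptidoform("ACDEFGHIKLMNPK/3")
        (a,), (b,) = predict_ccs(model, [p2]), predict_ccs(model, [p3])
        assert abs(a - b) > 1.0  # truth moves 26 A^2 per charge

    def test_unencodable_peptide_yields_nan(self, linear_records):
        model = train_ccs_model(linear_records[:200], FAST)
        long = Peptidoform("A" * 61, (), 2)
        with pytest.warns(UserWarning):
            out = predict_ccs(model, [linear_records[0].peptidoform, long])
        assert np.isfinite(out[0]) and np.isnan(out[1])

    def test_convolutional_backend_trains_and_is_deterministic(self):
        peps = syn.generate_peptides(300, (8, 20), seed=9)
        records = syn.simulate_ccs(peps, noise_sigma=0.0, seed=10)
        cfg = CcsConfig(
            backend="four_path_convolutional", epochs=8, patience=4,
            train_fraction=0.8, validation_fraction=0.1, seed=1,
        )
        m1 = train_ccs_model(records, cfg)
        m2 = train_ccs_model(records, cfg)
        assert m1.log["epochs_run"] >= 1
        assert np.isfinite(m1.log["best_val_mse"])
        test_peps = [r.peptidoform for r in records[:10]]
        np.testing.assert_array_equal(predict_ccs(m1, test_peps),
                                      predict_ccs(m2, test_peps))


class TestAlignment:
    def _records(self, values, source, peps=None):
        peps = peps or syn.generate_peptides(len(values), (8, 12),
                                             modification_alphabet=(), seed=1)
        return [CcsRecord(p, v, source) for p, v in zip(peps, values)], peps

    def test_exact_linear_data(self):
        other_vals = list(np.linspace(100, 400, 12))
        ref_vals = [2 * v + 1 for v in other_vals]
        other, peps = self._records(other_vals, "o")
        ref, _ = self._records(ref_vals, "r", peps)
        al = align_datasets(ref, other)
        assert al.slope == pytest.approx(2.0, abs=1e-9)
        assert al.intercept == pytest.approx(1.0, abs=1e-7)
        assert al.n_overlap == 12

    def test_identity_alignment(self):
        vals = list(np.linspace(300, 600, 20))
        a, peps = self._records(vals, "a")
        b, _ = self._records(vals, "b", peps)
        al = align_datasets(a, b)
        assert al.slope == pytest.approx(1.0, abs=1e-12)
        assert al.intercept == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_overlap_reports_count(self):
        a, peps = self._records([300.0] * 5, "a")
        b, _ = self._records([301.0] * 5, "b", peps)
        with pytest.raises(ValueError, match="5"):
            align_datasets(a, b)

    def test_noisy_drift_recovery(self):
        peps = syn.generate_peptides(500, (8, 25), seed=6)
        ref = syn.simulate_ccs(peps, noise_sigma=1.0, seed=7, source="ref")
        other = syn.simulate_ccs(peps, noise_sigma=1.0, seed=8,
                                 drift=(1.02, -3.0), source="d2")
        al = align_datasets(ref, other)
        # reference = a*other + b with other = 1.02*true - 3
        assert al.slope == pytest.approx(1 / 1.02, abs=0.01)
        assert al.intercept == pytest.approx(3 / 1.02, abs=1.0)


class TestMergeAndIsomers:
    def test_overlap_mean_and_union(self):
        peps = syn.generate_peptides(4, (8, 12), modification_alphabet=(),
                                     seed=2)
        ref = [CcsRecord(peps[0], 300.0, "r"), CcsRecord(peps[1], 410.0, "r")]
        other = [CcsRecord(peps[0], 302.0, "o"), CcsRecord(peps[2], 350.0, "o")]
        from imrescore.ccs import AlignmentModel

        merged = merge_datasets(ref, other, AlignmentModel(1.0, 0.0, 10))
        by_key = {r.peptidoform.key(): r.ccs for r in merged}
        assert by_key[peps[0].key()] == pytest.approx(301.0)
        assert by_key[peps[1].key()] == 410.0
        assert by_key[peps[2].key()] == 350.0
        assert len(merged) == len(by_key)

    def test_self_merge_is_identity(self):
        peps = syn.generate_peptides(30, (8, 12), seed=3)
        recs = syn.simulate_ccs(peps, seed=4)
        al = align_datasets(recs, recs)
        merged = merge_datasets(recs, recs, al)
        assert al.slope == pytest.approx(1.0, abs=1e-12)
        assert sorted(r.ccs for r in merged) == pytest.approx(
            sorted(r.ccs for r in recs)
        )

    def test_isomer_collapse(self):
        seq = "ACDKR"
        m1 = Modification(2, "dimethyl_sym", 28.0313)
        m2 = Modification(2, "dimethyl_asym", 28.0313)
        a = CcsRecord(Peptidoform(seq, (m1,), 2), 410.0)
        b = CcsRecord(Peptidoform(seq, (m2,), 2), 414.0)
        other = CcsRecord(Peptidoform("ACDEK", (), 2), 350.0)
        out = collapse_isomers([a, b, other])
        assert len(out) == 2
        assert out[0].ccs == pytest.approx(412.0)
        assert out[1].ccs == 350.0

    def test_no_isomers_unchanged(self):
        peps = syn.generate_peptides(10, (8, 12), modification_alphabet=(),
                                     seed=5)
        recs = syn.simulate_ccs(peps, seed=6)
        assert collapse_isomers(recs) == recs


class TestLeaveOneOutHarnesses:
    def test_modification_shift_recovered(self):
        records, name = _shift_records(delta=12.0)
        rep = loo_modification_harness(records, name, FAST)
        assert rep["mae_ignored"] == pytest.approx(12.0, rel=0.25)
        assert rep["mae_encoded"] < 0.5 * rep["mae_ignored"]
        assert rep["n_carriers"] > 0

    def test_zero_shift_null_case(self):
        records, name = _shift_records(delta=0.0)
        rep = loo_modification_harness(records, name, FAST)
        assert abs(rep["mae_encoded"] - rep["mae_ignored"]) < 0.3

    def test_no_carriers_rejected(self):
        peps = syn.generate_peptides(100, (8, 12), modification_alphabet=(),
                                     seed=1)
        recs = syn.simulate_ccs(peps, seed=2)
        with pytest.raises(ValueError, match="carry"):
            loo_modification_harness(recs, "phospho", FAST)

    def test_amino_acid_substitution_hurts_for_non_glycine_like(self):
        peps = syn.generate_peptides(1200, (8, 25), modification_alphabet=(),
                                     seed=12)
        recs = syn.simulate_ccs(peps, noise_sigma=1.0, seed=13)
        rep = loo_amino_acid_harness(recs, "W", FAST)
        # tryptophan's composition differs strongly from glycine's
        assert rep["mae_encoded"] < rep["mae_substituted"]
        assert rep["n_train"] > 0 and rep["n_carriers"] > 0

    def test_glycine_is_not_a_target(self):
        with pytest.raises(ValueError):
            loo_amino_acid_harness([], "G", FAST)


class TestIonMobilityConversion:
    def test_inverse_functions_roundtrip(self):
        ccs = one_over_k0_to_ccs(1.1, 2, 1500.0)
        back = ccs_to_one_over_k0(ccs, 2, 1500.0)
        assert back == pytest.approx(1.1, rel=1e-12)

    def test_against_independent_constant_derivation(self):
        # oracle: Mason-Schamp assembled from scipy.constants
        from scipy import constants as sc

        points = [(1.0, 1, 800.0), (0.8, 2, 1200.0), (1.3, 2, 1800.0),
                  (0.95, 3, 2400.0), (1.6, 1, 600.0)]
        for inv_k0, z, m in points:
            mu = m * 28.00615 / (m + 28.00615) * sc.atomic_mass
            n0 = sc.physical_constants["Loschmidt constant (273.15 K, 101.325 kPa)"][0]
            omega = (
                (3 / 16)
                * np.sqrt(2 * np.pi / (mu * sc.k * 305.0))
                * z * sc.e / (n0 * (1e-4 / inv_k0))
            ) * 1e20
            assert one_over_k0_to_ccs(inv_k0, z, m) == pytest.approx(
                omega, rel=1e-6
            )

    def test_scaling_with_charge(self):
        assert one_over_k0_to_ccs(1.0, 2, 1500.0) > one_over_k0_to_ccs(
            1.0, 1, 1500.0
        )
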