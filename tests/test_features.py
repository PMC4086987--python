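"""ICA basis fitting, pseudo-inverse projection and feature assembly."""

import numpy as np
import pytest

from bbbdetect import features, synthetic
from bbbdetect.features import (ICABasis, assemble_ica, assemble_morph,
                                fit_ica_basis, ica_project, select_basis_beats)
from bbbdetect.preprocess import Beat


def _beat_from_wave(wave_a, wave_b=None, label="NORM", record_id="r", r_index=0):
    wave_b = wave_a if wave_b is None else wave_b
    return Beat(wave_a, wave_b, 0.8, label, record_id, r_index)


def _stub_beats(record_sizes):
    """record_sizes: {record_id: {label: n}} -> cheap beats, temporal order."""
    rng = np.random.default_rng(0)
    beats = []
    for rid, by_label in record_sizes.items():
        idx = 0
        for label, n in by_label.items():
            for _ in range(n):
                beats.append(_beat_from_wave(rng.standard_normal(200),
                                             label=label, record_id=rid,
                                             r_index=idx))
                idx += 400
    return beats


class TestSelectBasisBeats:
    def test_study_structure_yields_620(self):
        sizes = {f"n{i:02d}": {"NORM": 12} for i in range(18)}
        sizes.update({f"l{i}": {"LBBB": 110} for i in range(2)})
        sizes.update({f"r{i}": {"RBBB": 90} for i in range(3)})
        picked = select_basis_beats(_stub_beats(sizes))
        assert len(picked) == 620
        counts = {lab: sum(b.label == lab for b in picked)
                  for lab in ("NORM", "LBBB", "RBBB")}
        assert counts == {"NORM": 180, "LBBB": 200, "RBBB": 240}

    def test_selection_is_first_k_in_temporal_order(self):
        beats = _stub_beats({"a": {"NORM": 5}})
        picked = select_basis_beats(beats, plan={"NORM": 3})
        assert [b.r_index for b in picked] == [0, 400, 800]
        # deterministic
        again = select_basis_beats(list(reversed(beats)), plan={"NORM": 3})
        assert [b.r_index for b in again] == [0, 400, 800]

    def test_shortfall_names_record(self):
        beats = _stub_beats({"a": {"LBBB": 4}})
        with pytest.raises(ValueError, match="record a.*shortfall 6"):
            select_basis_beats(beats, plan={"LBBB": 10})


class TestFitICA:
    def test_source_recovery_known_mixing(self):
        # 200 mixtures of 3 super-Gaussian (Laplace) activations of fixed
        # source waveforms: recovered basis rows match the waveforms
        rng = np.random.default_rng(11)
        t = np.linspace(0, 1, 200)
        sources = np.stack([np.sin(2 * np.pi * 3 * t),
                            np.sign(np.sin(2 * np.pi * 5 * t)),
                            ((t * 7) % 1) - 0.5])
        acts = rng.laplace(size=(200, 3))
        beats = [_beat_from_wave(w) for w in acts @ sources]
        basis = fit_ica_basis(beats, "A", n_components=3, seed=0)
        corr = np.corrcoef(np.vstack([basis.components, sources]))[:3, 3:]
        matched = np.argmax(np.abs(corr), axis=1)
        assert sorted(matched) == [0, 1, 2]  # one distinct source each
        assert np.all(np.abs(corr[np.arange(3), matched]) > 0.95)

    def test_bit_reproducible_under_seed(self, small_dataset):
        beats = small_dataset[0][:80]
        b1 = fit_ica_basis(beats, "A", n_components=5, seed=42)
        b2 = fit_ica_basis(beats, "A", n_components=5, seed=42)
        assert np.array_equal(b1.components, b2.components)

    def test_too_few_beats(self, small_dataset):
        with pytest.raises(ValueError, match="need >="):
            fit_ica_basis(small_dataset[0][:4], "A", n_components=10)


class TestProjection:
    def test_basis_rows_map_to_standard_basis(self, small_dataset):
        basis = fit_ica_basis(small_dataset[0][:80], "A", n_components=4, seed=1)
        for i in range(4):
            f = ica_project(basis.components[i], basis)
            expected = np.zeros(4)
            expected[i] = 1.0
            assert np.allclose(f, expected, atol=1e-8)

    def test_hand_computed_two_component_pinv(self):
        # orthogonal rows: pinv is row-wise transpose over squared norms
        comps = np.array([[1.0, 0, 0, 0], [0, 2.0, 0, 0]])
        basis = ICABasis("A", comps, np.linalg.pinv(comps), 0, 2)
        f = np.array([3.0, 4.0, 0, 0]) @ basis.pinv_components
        assert np.allclose(f, [3.0, 2.0])  # 4 / 2**2 * 2 = 2 by hand

    def test_zero_segment(self, small_dataset):
        basis = fit_ica_basis(small_dataset[0][:80], "A", n_components=3, seed=1)
        assert np.allclose(ica_project(np.zeros(200), basis), 0.0)

    def test_linearity(self, small_dataset):
        basis = fit_ica_basis(small_dataset[0][:80], "A", n_components=3, seed=1)
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 200))
        lhs = ica_project(2.5 * x - 1.5 * y, basis)
        rhs = 2.5 * ica_project(x, basis) - 1.5 * ica_project(y, basis)
        assert np.allclose(lhs, rhs)

    def test_dimension_mismatch(self, small_dataset):
        basis = fit_ica_basis(small_dataset[0][:80], "A", n_components=3, seed=1)
        with pytest.raises(ValueError, match="length"):
            ica_project(np.zeros(100), basis)

    def test_reconstruction_improves_with_basis_size(self, small_dataset):
        beats = small_dataset[0][:120]
        X = np.stack([b.lead_a for b in beats])
        resid = {}
        for k in (5, 30):
            basis = fit_ica_basis(beats, "A", n_components=k, seed=2)
            F = X @ basis.pinv_components
            resid[k] = np.linalg.norm(F @ basis.components - X)
        assert resid[30] < resid[5]


class TestAssemble:
    def test_morph_401(self, one_beat):
        fv = assemble_morph(one_beat)
        assert fv.kind == features.MORPH and fv.values.shape == (401,)
        assert fv.values[-1] == one_beat.rr_s
        assert np.array_equal(fv.values[:200], one_beat.lead_a)

    def test_morph_single_lead_201(self, one_beat):
        assert assemble_morph(one_beat, "B").values.shape == (201,)

    def test_ica_lengths(self, one_beat, small_dataset):
        beats = small_dataset[0][:80]
        ba = fit_ica_basis(beats, "A", n_components=6, seed=1)
        bb = fit_ica_basis(beats, "B", n_components=6, seed=2)
        assert assemble_ica(one_beat, ba, bb).values.shape == (13,)
        assert assemble_ica(one_beat, basis_a=ba, lead_config="A").values.shape == (7,)

    def test_lead_a_features_independent_of_lead_b_basis(self, one_beat,
                                                         small_dataset):
        beats = small_dataset[0][:80]
        ba = fit_ica_basis(beats, "A", n_components=5, seed=1)
        bb1 = fit_ica_basis(beats, "B", n_components=5, seed=2)
        bb2 = fit_ica_basis(beats, "B", n_components=5, seed=3)
        v1 = assemble_ica(one_beat, ba, bb1).values
        v2 = assemble_ica(one_beat, ba, bb2).values
        assert np.array_equal(v1[:5], v2[:5])

    def test_basis_lead_mismatch(self, one_beat, small_dataset):
        ba = fit_ica_basis(small_dataset[0][:80], "A", n_components=3, seed=1)
        with pytest.raises(ValueError, match="lead"):
            assemble_ica(one_beat, basis_a=ba, basis_b=ba)


def test_basis_save_load_round_trip(tmp_path, small_dataset):
    basis = fit_ica_basis(small_dataset[0][:80], "A", n_components=4, seed=9)
    path = str(tmp_path / "basis.json")
    basis.save(path)
    back = ICABasis.load(path)
    assert back.lead == "A" and back.fit_seed == 9
    assert np.allclose(back.components, basis.components)
    assert np.allclose(back.pinv_components, basis.pinv_components, atol=1e-10)
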