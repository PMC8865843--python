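"""Generator contracts: library structure, recordings, ratings."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from hapticode import perception as pc
from hapticode import synthetic as syn


class TestMaterialLibrary:
    def test_canonical_library_has_81_materials_in_7_categories(self):
        mats = syn.make_material_library(seed=0)
        assert len(mats) == 81
        counts = pd.Series([m.category_id for m in mats]).value_counts()
        assert sorted(counts) == [11, 11, 11, 12, 12, 12, 12]
        assert len({m.material_id for m in mats}) == 81

    def test_minimal_two_category_library_has_distinct_envelopes(self):
        mats = syn.make_material_library(2, [1, 1], seed=1)
        assert len(mats) == 2
        r = np.corrcoef(mats[0].spectral_envelope, mats[1].spectral_envelope)[0, 1]
        assert r < 0.8

    def test_same_seed_reproduces_library_field_for_field(self):
        a = syn.make_material_library(3, [2, 2, 2], seed=5)
        b = syn.make_material_library(3, [2, 2, 2], seed=5)
        for ma, mb in zip(a, b):
            assert ma.material_id == mb.material_id
            assert ma.category_id == mb.category_id
            np.testing.assert_array_equal(ma.spectral_envelope, mb.spectral_envelope)
            np.testing.assert_array_equal(ma.sample_jitter, mb.sample_jitter)

    @pytest.mark.parametrize("counts", [[0, 2], [-1, 2, 2]])
    def test_non_positive_counts_rejected(self, counts):
        with pytest.raises(ValueError):
            syn.make_material_library(len(counts), counts, seed=0)

    def test_envelopes_non_negative(self, small_library):
        for m in small_library:
            assert (m.spectral_envelope >= 0).all()


def _narrow_material(center_hz: float) -> syn.MaterialSpec:
    env = np.exp(-0.5 * ((syn.FREQ_GRID - center_hz) / 3.0) ** 2)
    return syn.MaterialSpec("probe", 0, env, np.ones_like(env))


class TestRecordings:
    def test_duration_times_rate_samples(self):
        mat = _narrow_material(100.0)
        part = syn.ParticipantSpec(0, 1.0, 0.0)
        rec = syn.synth_recording(mat, part, duration_s=10.0, rate_hz=3200.0, seed=0)
        assert rec.samples.shape == (32000,)

    def test_speed_factor_scales_spectral_peak(self):
        mat = _narrow_material(100.0)
        fast = syn.ParticipantSpec(1, 2.0, 0.0)
        rec = syn.synth_recording(mat, fast, duration_s=5.0, rate_hz=3200.0, seed=2,
                                  drift_amplitude=0.0, hf_noise_amplitude=0.0)
        f, p = sps.welch(rec.samples, fs=3200.0, nperseg=4096)
        assert abs(f[np.argmax(p)] - 200.0) < 15.0

    def test_zero_envelope_and_noise_gives_silent_trace(self):
        env = np.zeros_like(syn.FREQ_GRID)
        mat = syn.MaterialSpec("null", 0, env, np.ones_like(env))
        part = syn.ParticipantSpec(0, 1.0, 0.0)
        rec = syn.synth_recording(mat, part, duration_s=1.0, rate_hz=3200.0, seed=0,
                                  drift_amplitude=0.0, hf_noise_amplitude=0.0)
        assert np.all(rec.samples == 0.0)

    def test_sub_nyquist_rate_rejected(self):
        mat = _narrow_material(400.0)
        part = syn.ParticipantSpec(0, 1.0, 0.0)
        with pytest.raises(ValueError, match="Nyquist"):
            syn.synth_recording(mat, part, duration_s=1.0, rate_hz=700.0, seed=0)

    def test_same_seed_reproduces_recording(self):
        mat = _narrow_material(150.0)
        part = syn.ParticipantSpec(0, 1.1, 0.0)
        a = syn.synth_recording(mat, part, duration_s=1.0, rate_hz=3200.0, seed=9)
        b = syn.synth_recording(mat, part, duration_s=1.0, rate_hz=3200.0, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_within_category_spectra_more_similar_than_between(self, small_library,
                                                               participants):
        recs = syn.synth_dataset(small_library, participants[:1], duration_s=1.0,
                                 rate_hz=3200.0, seed=13)
        spectra, cats = [], []
        for rec in recs:
            f, p = sps.welch(rec.samples, fs=3200.0, nperseg=2048)
            spectra.append(np.log(p + 1e-12))
            cats.append(rec.category_id)
        spectra = np.array(spectra)
        cats = np.array(cats)
        corr = np.corrcoef(spectra)
        within, between = [], []
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                (within if cats[i] == cats[j] else between).append(corr[i, j])
        assert np.mean(within) > np.mean(between)


class TestRatings:
    def test_one_row_per_participant_material_pair(self, small_library):
        parts = syn.make_participants(11, seed=0)
        mats = syn.make_material_library(seed=1)
        table = syn.synth_ratings(mats, parts, seed=2)
        pairs = table.descriptors.drop_duplicates(["participant_id", "material_id"])
        assert len(pairs) == 891
        assert len(table.descriptors) == 891 * 7
        assert set(table.descriptors["descriptor"]) == set(pc.DESCRIPTORS)

    def test_noiseless_ratings_peak_at_true_category_for_every_participant(
        self, small_library
    ):
        parts = syn.make_participants(3, seed=0, rating_noise_sd=0.0)
        table = syn.synth_ratings(small_library, parts, seed=1, confusion=0.0)
        truth = syn.ground_truth_labels(small_library)
        top = (
            table.categories.sort_values("category_id")
            .groupby(["participant_id", "material_id"])
            .apply(lambda g: g.loc[g["similarity"].idxmax(), "category_id"],
                   include_groups=False)
        )
        for (pid, mid), label in top.items():
            assert label == truth[mid]

    def test_full_confusion_drives_labels_to_chance(self):
        mats = syn.make_material_library(7, [3] * 7, seed=3)
        parts = syn.make_participants(5, seed=4)
        truth = syn.ground_truth_labels(mats)
        hits, total = 0, 0
        for seed in range(12):
            table = syn.synth_ratings(mats, parts, seed=seed, confusion=1.0)
            labels = pc.assign_perceptual_labels(table)
            hits += int((labels.sort_index().values == truth.values).sum())
            total += len(truth)
        assert abs(hits / total - 1 / 7) < 0.07

    def test_empty_inputs_rejected(self, small_library, participants):
        with pytest.raises(ValueError):
            syn.synth_ratings([], participants, seed=0)
        with pytest.raises(ValueError):
            syn.synth_ratings(small_library, [], seed=0)


class TestRoundTrips:
    def test_recordings_round_trip(self, tmp_path, small_library, participants):
        recs = syn.synth_dataset(small_library[:3], participants[:1], duration_s=0.2,
                                 rate_hz=3200.0, seed=5)
        manifest = syn.write_recordings(recs, tmp_path)
        back = syn.read_recordings(manifest)
        assert len(back) == len(recs)
        np.testing.assert_allclose(back[0].samples, recs[0].samples)
        assert back[0].material_id == recs[0].material_id

    def test_ratings_round_trip(self, tmp_path, small_library, participants):
        table = syn.synth_ratings(small_library, participants, seed=6)
        d, c = syn.write_ratings(table, tmp_path)
        back = syn.read_ratings(d, c)
        pd.testing.assert_frame_equal(back.descriptors, table.descriptors)
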