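"""Rating analyses: z-transform, rating PCA, perceptual distances, labels."""

import numpy as np
import pandas as pd
import pytest

from hapticode import perception as pc
from hapticode.latent import DistanceMatrix


def _table(desc_rows, cat_rows=None):
    desc = pd.DataFrame(desc_rows, columns=["participant_id", "material_id",
                                            "descriptor", "value"])
    if cat_rows is None:
        cat_rows = [(0, "m0", 0, 1.0)]
    cat = pd.DataFrame(cat_rows, columns=["participant_id", "material_id",
                                          "category_id", "similarity"])
    return pc.RatingTable(descriptors=desc, categories=cat)


class TestZTransform:
    def test_three_point_slice_matches_population_formula(self):
        rows = [(0, f"m{i}", "roughness", v) for i, v in enumerate([1.0, 2.0, 3.0])]
        z = pc.z_transform(_table(rows))
        got = z.descriptors["value"].tolist()
        np.testing.assert_allclose(got, [-1.224744871, 0.0, 1.224744871])

    def test_idempotent_and_zero_mean(self):
        rng = np.random.default_rng(0)
        rows = [(0, f"m{i}", d, rng.normal()) for i in range(5)
                for d in ("roughness", "hardness")]
        once = pc.z_transform(_table(rows))
        twice = pc.z_transform(once)
        np.testing.assert_allclose(once.descriptors["value"], twice.descriptors["value"],
                                   atol=1e-12)
        means = once.descriptors.groupby(["participant_id", "descriptor"])["value"].mean()
        np.testing.assert_allclose(means, 0.0, atol=1e-12)

    def test_constant_slice_names_offender(self):
        rows = [(3, f"m{i}", "friction", 2.0) for i in range(4)]
        with pytest.raises(ValueError, match="participant 3.*friction"):
            pc.z_transform(_table(rows))


class TestRatingsPCA:
    def _full_table(self, values):
        """values: materials x 7 array -> one participant's ratings."""
        rows = [(0, f"m{i:02d}", d, values[i, j])
                for i in range(values.shape[0]) for j, d in enumerate(pc.DESCRIPTORS)]
        return _table(rows)

    def test_rank_two_ratings_need_two_components(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((12, 2)) @ rng.standard_normal((2, 7))
        scores, evr = pc.ratings_pca(self._full_table(values))
        assert evr[:2].sum() == pytest.approx(1.0)
        assert scores.shape == (12, 7)

    def test_variance_ratios_sum_to_one(self):
        values = np.random.default_rng(2).standard_normal((10, 7))
        _, evr = pc.ratings_pca(self._full_table(values))
        assert evr.sum() == pytest.approx(1.0)


def _category_table(profiles, cats):
    """Build a z-ready rating table from per-material 7-vectors."""
    rows = []
    for (mid, vec) in profiles.items():
        for d, v in zip(pc.DESCRIPTORS, vec):
            rows.append((0, mid, d, v))
    cat_rows = [(0, mid, 0, 1.0) for mid in profiles]
    table = _table(rows, cat_rows)
    table.z_transformed = True  # hand-built profiles already on a common scale
    return table, pd.Series(cats)


class TestPerceptualDistances:
    def test_identical_profiles_give_zero_distance(self):
        v = np.array([1.0, -1.0, 0.5, 0.2, -0.3, 0.8, -0.6])
        profiles = {"a": v, "b": v, "c": v, "d": v}
        cats = {"a": 0, "b": 0, "c": 1, "d": 1}
        table, cs = _category_table(profiles, cats)
        dm = pc.perceptual_distance_matrix(table, material_categories=cs)
        np.testing.assert_allclose(dm.values, 0.0, atol=1e-12)

    def test_anticorrelated_categories_hit_both_endpoint_forms(self):
        v = np.array([1.0, -0.5, 0.3, -0.2, 0.7, -0.9, 0.1])
        profiles = {"a": v, "b": v, "c": -v, "d": -v}
        cats = {"a": 0, "b": 0, "c": 1, "d": 1}
        table, cs = _category_table(profiles, cats)
        printed = pc.perceptual_distance_matrix(table, material_categories=cs)
        assert printed.values[0, 1] == pytest.approx(4.0)  # delta = 2(1 - (-1))
        sqrt_form = pc.perceptual_distance_matrix(table, material_categories=cs,
                                                  sqrt_variant=True)
        assert sqrt_form.values[0, 1] == pytest.approx(2.0)

    def test_three_material_toy_matches_brute_force(self):
        rng = np.random.default_rng(3)
        profiles = {m: rng.standard_normal(7) for m in ("a", "b", "c")}
        cats = {"a": 0, "b": 1, "c": 1}
        table, cs = _category_table(profiles, cats)
        dm = pc.perceptual_distance_matrix(table, material_categories=cs)
        rho_ab = np.corrcoef(profiles["a"], profiles["b"])[0, 1]
        rho_ac = np.corrcoef(profiles["a"], profiles["c"])[0, 1]
        rho_bc = np.corrcoef(profiles["b"], profiles["c"])[0, 1]
        assert dm.values[0, 1] == pytest.approx(2 * (1 - np.mean([rho_ab, rho_ac])))
        assert dm.values[1, 1] == pytest.approx(2 * (1 - rho_bc))

    def test_delta_strictly_decreases_with_rho(self):
        deltas = [2 * (1 - rho) for rho in np.linspace(-1, 1, 9)]
        assert all(d1 > d2 for d1, d2 in zip(deltas, deltas[1:]))

    def test_unstandardized_table_rejected(self):
        rows = [(0, "a", d, 1.0 * i) for i, d in enumerate(pc.DESCRIPTORS)]
        with pytest.raises(ValueError, match="z-transform"):
            pc.perceptual_distance_matrix(_table(rows))


def _label_table(labels_by_participant):
    """labels_by_participant: {pid: {mid: winning_category}} with 3 categories."""
    rows = []
    for pid, by_mat in labels_by_participant.items():
        for mid, win in by_mat.items():
            for cat in range(3):
                rows.append((pid, mid, cat, 1.0 if cat == win else 0.0))
    cat = pd.DataFrame(rows, columns=["participant_id", "material_id",
                                      "category_id", "similarity"])
    desc = pd.DataFrame([(0, "m0", "roughness", 0.0)],
                        columns=["participant_id", "material_id", "descriptor", "value"])
    return pc.RatingTable(descriptors=desc, categories=cat)


class TestLabels:
    def test_unanimous_vote(self):
        table = _label_table({p: {"m0": 2} for p in range(5)})
        assert pc.assign_perceptual_labels(table)["m0"] == 2

    def test_six_versus_five_majority(self):
        votes = {p: {"m0": 1} for p in range(6)}
        votes.update({p: {"m0": 2} for p in range(6, 11)})
        assert pc.assign_perceptual_labels(_label_table(votes))["m0"] == 1

    def test_tie_breaks_to_lowest_category(self):
        votes = {0: {"m0": 2}, 1: {"m0": 1}}
        assert pc.assign_perceptual_labels(_label_table(votes))["m0"] == 1

    def test_argmax_tie_breaks_to_lowest_category(self):
        rows = [(0, "m0", 0, 0.7), (0, "m0", 1, 0.7), (0, "m0", 2, 0.1)]
        cat = pd.DataFrame(rows, columns=["participant_id", "material_id",
                                          "category_id", "similarity"])
        desc = pd.DataFrame([(0, "m0", "roughness", 0.0)],
                            columns=["participant_id", "material_id", "descriptor",
                                     "value"])
        table = pc.RatingTable(descriptors=desc, categories=cat)
        assert pc.assign_perceptual_labels(table)["m0"] == 0


class TestAgreement:
    def test_identical_participants_agree_fully(self):
        votes = {p: {"m0": 1, "m1": 2, "m2": 0} for p in range(4)}
        assert pc.agreement_level(_label_table(votes)) == pytest.approx(100.0)

    def test_two_participants_predict_each_other(self):
        votes = {0: {"m0": 1, "m1": 2}, 1: {"m0": 1, "m1": 0}}
        # m0 agrees for both directions, m1 for neither -> 50%
        assert pc.agreement_level(_label_table(votes)) == pytest.approx(50.0)

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            pc.agreement_level(_label_table({0: {"m0": 1}}))

    def test_random_labels_sit_near_chance(self):
        rng = np.random.default_rng(4)
        accs = []
        for _ in range(30):
            votes = {p: {f"m{i}": int(rng.integers(0, 3)) for i in range(20)}
                     for p in range(5)}
            accs.append(pc.agreement_level(_label_table(votes)))
        assert abs(np.mean(accs) - 100 / 3) < 6.0
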