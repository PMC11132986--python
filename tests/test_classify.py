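"""Organelle classifier: SVM first assignment, α-mixing, change calling."""

import numpy as np
import pandas as pd
import pytest

from spatmap.classify import (
    call_localization_changes,
    change_summary,
    estimate_second_localization,
    marker_accuracy,
    predict_first,
    train_classifier,
)
from spatmap.config import RunConfig
from spatmap.pcp import (
    concatenate_replicates,
    filter_reproducible,
    merge_replicates,
    organelle_median_profiles,
    protein_median_profiles,
    scale_profiles,
)
from spatmap.synthetic import FractionationSimSpec, organelle_archetype, simulate_fractionation
from spatmap.tables import MarkerTable, TableFormatError


@pytest.fixture(scope="module")
def trained(small_fractionation_module):
    spec, (tables, markers, truth) = small_fractionation_module
    pset = merge_replicates([scale_profiles(t) for t in tables])
    features = concatenate_replicates(pset)
    cfg = RunConfig(seed=0)
    model = train_classifier(features, markers, cfg)
    return spec, tables, markers, truth, pset, features, model


@pytest.fixture(scope="module")
def small_fractionation_module():
    spec = FractionationSimSpec(
        seed=11,
        organelles=(
            ("LipidDroplet", 2.0, 1.5),
            ("ER", 9.0, 1.8),
            ("Mitochondrion", 16.0, 1.8),
            ("Cytosol", 22.0, 2.0),
        ),
        markers_per_organelle=15,
        n_single=40,
        n_dual=20,
        noise_sd=0.0,
        n_replicates=2,
    )
    return spec, simulate_fractionation(spec)


class TestTrainPredict:
    def test_markers_classified_perfectly_when_separable(self, trained):
        _, _, markers, _, _, features, model = trained
        pred = predict_first(model, features.loc[markers.assignments.index])
        assert (pred.set_index("protein_id")["first_organelle"] == markers.assignments).all()

    def test_conflicting_duplicate_marker_labels_rejected(self):
        with pytest.raises(TableFormatError, match="duplicate"):
            MarkerTable(
                pd.Series(["ER", "Golgi"], index=pd.Index(["p1", "p1"], name="protein_id"))
            )

    def test_training_is_deterministic(self, trained):
        _, _, markers, _, _, features, model = trained
        model2 = train_classifier(features, markers, RunConfig(seed=0))
        p1 = predict_first(model, features)
        p2 = predict_first(model2, features)
        pd.testing.assert_frame_equal(p1, p2)

    def test_feature_signature_mismatch_rejected(self, trained):
        _, _, _, _, _, features, model = trained
        with pytest.raises(ValueError, match="signature"):
            predict_first(model, features.iloc[:, :-1])

    def test_small_compartment_error_names_it(self, trained):
        _, _, markers, _, _, features, _ = trained
        few = MarkerTable(
            markers.assignments[
                list(markers.assignments.index[markers.assignments != "ER"])
                + markers.members("ER")[:2]
            ],
            markers.vocabulary,
        )
        with pytest.raises(ValueError, match="ER"):
            train_classifier(features, few, RunConfig(seed=0))

    def test_empty_feature_set_gives_empty_output(self, trained):
        _, _, _, _, _, features, model = trained
        assert len(predict_first(model, features.iloc[:0])) == 0

    def test_noiseless_singles_match_ground_truth(self, trained):
        _, _, _, truth, _, features, model = trained
        singles = truth.index[truth["kind"] == "single"]
        pred = predict_first(model, features.loc[singles]).set_index("protein_id")
        assert (pred["first_organelle"] == truth.loc[singles, "organelle1"]).all()


class TestMarkerAccuracy:
    def test_perfectly_separable_gives_accuracy_one(self, trained):
        _, _, markers, _, _, features, _ = trained
        report = marker_accuracy(features, markers, RunConfig(seed=0))
        assert report.mean_accuracy == 1.0
        assert (report.per_compartment == 1.0).all()

    def test_confusion_row_sums_equal_marker_counts(self, trained):
        _, _, markers, _, _, features, _ = trained
        report = marker_accuracy(features, markers, RunConfig(seed=0))
        counts = markers.assignments.value_counts()
        for comp in report.confusion.index:
            assert report.confusion.loc[comp].sum() == counts[comp]

    def test_mean_is_unweighted_mean_of_per_class(self, trained):
        _, _, markers, _, _, features, _ = trained
        report = marker_accuracy(features, markers, RunConfig(seed=0))
        assert report.mean_accuracy == pytest.approx(report.per_compartment.mean())

    def test_identical_archetypes_split_roughly_evenly(self):
        spec = FractionationSimSpec(
            seed=3,
            organelles=(("Endosome", 10.0, 1.5), ("Lysosome", 10.0, 1.5), ("Cytosol", 20.0, 2.0)),
            markers_per_organelle=40,
            n_single=0,
            n_dual=0,
            noise_sd=0.05,
        )
        tables, markers, _ = simulate_fractionation(spec)
        pset = filter_reproducible(merge_replicates([scale_profiles(t) for t in tables]))
        report = marker_accuracy(concatenate_replicates(pset), markers, RunConfig(seed=3))
        assert abs(report.per_compartment["Endosome"] - 0.5) <= 0.15
        assert abs(report.per_compartment["Lysosome"] - 0.5) <= 0.15


@pytest.fixture(scope="module")
def org_profiles():
    n = 25
    return pd.DataFrame(
        {
            "Mitochondrion": organelle_archetype(6.0, 1.8, n),
            "ER": organelle_archetype(14.0, 1.8, n),
            "Cytosol": organelle_archetype(21.0, 2.0, n),
        }
    ).T


class TestSecondLocalization:

    def test_pure_first_profile_is_single_specific(self, org_profiles):
        second, alpha, r = estimate_second_localization(
            org_profiles.loc["Mitochondrion"].to_numpy(), "Mitochondrion", org_profiles
        )
        assert second is None and alpha == 0.0
        assert r == pytest.approx(1.0)

    def test_planted_half_mixture_recovered(self, org_profiles):
        profile = 0.5 * org_profiles.loc["Mitochondrion"] + 0.5 * org_profiles.loc["ER"]
        second, alpha, r = estimate_second_localization(
            profile.to_numpy(), "Mitochondrion", org_profiles
        )
        assert (second, alpha) == ("ER", 0.5)
        assert r == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha_true", [0.05, 0.15, 0.35, 0.65, 0.95])
    def test_grid_alpha_recovered_exactly_without_noise(self, org_profiles, alpha_true):
        profile = (1 - alpha_true) * org_profiles.loc["ER"] + alpha_true * org_profiles.loc["Cytosol"]
        second, alpha, _ = estimate_second_localization(profile.to_numpy(), "ER", org_profiles)
        assert second == "Cytosol"
        assert abs(alpha - alpha_true) <= 0.025

    def test_affine_rescaling_of_profile_changes_nothing(self, org_profiles):
        profile = 0.7 * org_profiles.loc["ER"] + 0.3 * org_profiles.loc["Mitochondrion"]
        base = estimate_second_localization(profile.to_numpy(), "ER", org_profiles)
        scaled = estimate_second_localization(2.5 * profile.to_numpy() + 7.0, "ER", org_profiles)
        assert base[0] == scaled[0] and base[1] == scaled[1]
        assert base[2] == pytest.approx(scaled[2])

    def test_needs_two_compartments(self, org_profiles):
        with pytest.raises(ValueError, match="2 compartments"):
            estimate_second_localization(
                org_profiles.loc["ER"].to_numpy(), "ER", org_profiles.loc[["ER"]]
            )

    def test_pipeline_alpha_recovery_on_synthetic_duals(self, trained):
        spec, _, markers, truth, pset, _, _ = trained
        org = organelle_median_profiles(pset, markers)
        med = protein_median_profiles(pset)
        duals = truth.index[truth["kind"] == "dual"]
        for pid in duals:
            o1, o2, a = truth.loc[pid, ["organelle1", "organelle2", "true_alpha"]]
            second, ahat, _ = estimate_second_localization(med.loc[pid].to_numpy(), o1, org)
            assert second == o2
            assert abs(ahat - a) <= 0.025


class TestLocalizationChanges:
    @staticmethod
    def _map(rows):
        return pd.DataFrame(
            [
                {
                    "protein_id": pid,
                    "first_organelle": org,
                    "confidence": conf,
                    "high_confidence": conf >= 0.5,
                    "second_organelle": "",
                    "alpha": np.nan,
                    "best_mix_correlation": np.nan,
                }
                for pid, org, conf in rows
            ]
        )

    def test_same_assignment_is_unchanged(self):
        a = self._map([("P1", "Mitochondrion", 0.9)])
        changes = call_localization_changes(a, a.copy())
        assert not changes["changed"].any()

    def test_high_confidence_change_detected(self):
        a = self._map([("P1", "Cytosol", 0.9), ("P2", "ER", 0.4)])
        b = self._map([("P1", "Mitochondrion", 0.8), ("P2", "Golgi", 0.9)])
        changes = call_localization_changes(a, b).set_index("protein_id")
        assert changes.loc["P1", "high_confidence_change"]
        assert changes.loc["P2", "changed"] and not changes.loc["P2", "high_confidence_change"]
        assert change_summary(changes.reset_index())["n_high_confidence_changed"] == 1

    def test_empty_intersection_rejected(self):
        a = self._map([("P1", "ER", 0.9)])
        b = self._map([("P2", "ER", 0.9)])
        with pytest.raises(ValueError, match="shared"):
            call_localization_changes(a, b)

    def test_planted_relocalizations_recovered_at_zero_noise(self):
        spec = FractionationSimSpec(seed=21, noise_sd=0.0, n_single=150, n_dual=0, n_replicates=2)
        tables_a, markers, truth = simulate_fractionation(spec)
        labels = [o[0] for o in spec.organelles]
        singles = truth.index[truth["kind"] == "single"][:5]
        reassign = {
            pid: labels[(labels.index(truth.loc[pid, "organelle1"]) + 1) % len(labels)]
            for pid in singles
        }
        tables_b, _, _ = simulate_fractionation(spec, reassign=reassign)
        cfg = RunConfig(seed=21)
        maps = []
        for tables in (tables_a, tables_b):
            pset = merge_replicates([scale_profiles(t) for t in tables])
            features = concatenate_replicates(pset)
            model = train_classifier(features, markers, cfg)
            maps.append(predict_first(model, features))
        changes = call_localization_changes(*maps)
        called = set(changes.loc[changes["high_confidence_change"], "protein_id"])
        assert called == set(singles)
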