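import numpy as np
import pandas as pd
import pytest

import leukotype as lt
from leukotype.ranking import PANEL_SIZE

SMALL_C = tuple(2.0 ** np.arange(-3, 8, 2))
SMALL_GAMMA = tuple(2.0 ** np.arange(-9, 1, 2))


def _separable_profiles(panel, n_per_class=20, seed=0):
    """Two classes whose rank profiles are trivially separable."""
    rng = np.random.default_rng(seed)
    cols, labels = {}, {}
    for k, subtype in enumerate(["T-ALL", "ETV6-RUNX1"]):
        base = np.arange(1, PANEL_SIZE + 1, dtype=float)
        if k == 1:
            base = base[::-1].copy()
        for i in range(n_per_class):
            sid = f"C{k}_{i:02d}"
            v = base + rng.normal(0, 0.01, PANEL_SIZE)
            cols[sid] = lt.rank_sample(v)
            labels[sid] = subtype
    frame = pd.DataFrame(cols, index=list(panel.genes))
    return lt.RankProfiles(panel, frame), lt.SampleLabels(labels)


@pytest.fixture(scope="module")
def separable(panel_module):
    return _separable_profiles(panel_module)


@pytest.fixture(scope="module")
def panel_module():
    return lt.default_panel()[1]


class TestTrain:
    def test_separable_classes_reach_perfect_cv(self, separable):
        profiles, labels = separable
        model, report = lt.train(
            profiles, labels, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA, seed=1
        )
        assert report.best_accuracy == 1.0
        preds = lt.predict(model, profiles)
        assert all(preds[s] == labels[s] for s in preds)

    def test_same_seed_gives_identical_report(self, separable):
        profiles, labels = separable
        _, r1 = lt.train(profiles, labels, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA, seed=5)
        _, r2 = lt.train(profiles, labels, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA, seed=5)
        pd.testing.assert_frame_equal(r1.grid, r2.grid)
        assert (r1.best_C, r1.best_gamma, r1.best_accuracy) == (
            r2.best_C,
            r2.best_gamma,
            r2.best_accuracy,
        )

    def test_cv_invariant_to_sample_order(self, separable):
        profiles, labels = separable
        shuffled = profiles.subset(list(reversed(profiles.sample_ids)))
        _, r1 = lt.train(profiles, labels, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA, seed=2)
        _, r2 = lt.train(shuffled, labels, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA, seed=2)
        pd.testing.assert_frame_equal(r1.grid, r2.grid)

    def test_tiny_class_reduces_folds_with_warning(self, panel_module):
        profiles, labels = _separable_profiles(panel_module, n_per_class=4)
        with pytest.warns(UserWarning, match="folds"):
            _, report = lt.train(
                profiles, labels, c_grid=SMALL_C[:1], gamma_grid=SMALL_GAMMA[:1], folds=10
            )
        assert report.folds == 4

    def test_single_class_rejected(self, panel_module):
        profiles, labels = _separable_profiles(panel_module, n_per_class=6)
        one_class = lt.SampleLabels({s: "T-ALL" for s in profiles.sample_ids})
        with pytest.raises(lt.ValidationError, match="two subtype classes"):
            lt.train(profiles, one_class, c_grid=SMALL_C[:1], gamma_grid=SMALL_GAMMA[:1])

    def test_tie_break_prefers_smallest_c_then_gamma(self, separable):
        # the separable problem yields CV accuracy 1.0 at many grid points;
        # the winner must be the smallest C, then the smallest gamma, among them
        profiles, labels = separable
        _, report = lt.train(
            profiles, labels, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA, seed=3
        )
        ties = report.grid[report.grid["cv_accuracy"] == report.best_accuracy]
        expected = ties.sort_values(["C", "gamma"]).iloc[0]
        assert report.best_C == expected["C"]
        assert report.best_gamma == expected["gamma"]

    def test_gamma_is_explicit_number_not_data_scaled(self, separable):
        profiles, labels = separable
        model, report = lt.train(
            profiles, labels, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA, seed=1
        )
        assert isinstance(model.svc.gamma, float)
        assert model.svc.gamma == model.gamma == report.best_gamma
        assert model.gamma in SMALL_GAMMA


class TestPredict:
    def test_single_equals_batch(self, separable):
        profiles, labels = separable
        model, _ = lt.train(
            profiles, labels, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA, seed=1
        )
        batch = lt.predict(model, profiles)
        sid = profiles.sample_ids[0]
        alone = lt.predict(model, profiles.subset([sid]))
        assert alone[sid] == batch[sid]

    def test_panel_mismatch_raises(self, separable, panel_module):
        profiles, labels = separable
        model, _ = lt.train(
            profiles, labels, c_grid=SMALL_C[:1], gamma_grid=SMALL_GAMMA[:1], seed=1
        )
        genes = list(panel_module.genes)
        genes[0], genes[1] = genes[1], genes[0]
        other = lt.RankProfiles(
            lt.MarkerPanel(tuple(genes)),
            profiles.ranks.set_axis(genes, axis=0),
        )
        with pytest.raises(lt.DimensionError):
            lt.predict(model, other)

    def test_monotone_platform_distortion_leaves_predictions_identical(self, panel_module):
        # exact cross-platform contract: same latent ranks => same labels
        cfg = lt.SimulationConfig(
            n_per_subtype={s: 6 for s in lt.SUBTYPES}, seed=21
        )
        ma, mb, labels = lt.simulate_paired_platforms(lt.without_dropout(cfg))
        pa = lt.rank_matrix(ma, panel_module)
        pb = lt.rank_matrix(mb, panel_module)
        model, _ = lt.train(pa, labels, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA, seed=21)
        assert lt.predict(model, pa) == lt.predict(model, pb)


class TestPersistence:
    def test_save_load_round_trip(self, separable, tmp_path):
        profiles, labels = separable
        model, report = lt.train(
            profiles, labels, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA, seed=1
        )
        path = tmp_path / "model.joblib"
        lt.save_model(model, path)
        back = lt.load_model(path)
        assert lt.predict(back, profiles) == lt.predict(model, profiles)
        assert back.panel.genes == model.panel.genes
        assert (back.C, back.gamma) == (report.best_C, report.best_gamma)
        assert back.seed == model.seed

    def test_truncated_file_is_load_error(self, separable, tmp_path):
        profiles, labels = separable
        model, _ = lt.train(
            profiles, labels, c_grid=SMALL_C[:1], gamma_grid=SMALL_GAMMA[:1], seed=1
        )
        path = tmp_path / "model.joblib"
        lt.save_model(model, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(lt.ModelLoadError):
            lt.load_model(path)

    def test_wrong_payload_is_load_error(self, tmp_path):
        import joblib

        path = tmp_path / "junk.joblib"
        joblib.dump({"something": "else"}, path)
        with pytest.raises(lt.ModelLoadError, match="not a leukotype model"):
            lt.load_model(path)
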