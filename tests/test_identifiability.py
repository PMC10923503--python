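import numpy as np
import pytest

from idnet.errors import DataError, ParameterError
from idnet.identifiability import (
    band_profile,
    best_score,
    correlation_baseline,
    correlation_from_bank,
    identifiability_matrix,
    score_pair,
)
from idnet.models import default_specs
from idnet.preprocess import PairDataset, Recording, build_segment_bank
from idnet.synth import generate_group


def _noise_pair_dataset(rng, n_slots=30, length=200, duplicated=False):
    a = rng.standard_normal((n_slots, length))
    b = a.copy() if duplicated else rng.standard_normal((n_slots, length))
    return PairDataset(a, b, "a", "b", [("s0", "all")] * n_slots)


class TestScorePair:
    def test_duplicated_channel_scores_at_chance(self):
        ds = _noise_pair_dataset(np.random.default_rng(0), duplicated=True)
        specs = default_specs(200, models=("knn_fallback",))
        means, _ = score_pair(ds, specs, n_iterations=10, seed=0)
        n_eval = 10 * 2 * (ds.n_slots - ds.n_slots // 2)
        assert abs(means["knn_fallback"] - 0.5) <= 1.96 * np.sqrt(0.25 / n_eval)

    def test_score_table_has_n_iterations_rows_per_model(self):
        ds = _noise_pair_dataset(np.random.default_rng(1))
        specs = default_specs(200, models=("knn_fallback",))
        _, table = score_pair(ds, specs, n_iterations=7, seed=0)
        counts = table.groupby("model").size()
        assert (counts == 7).all()

    def test_too_few_segments_is_a_data_error_naming_the_pair(self):
        ds = _noise_pair_dataset(np.random.default_rng(2), n_slots=2)
        with pytest.raises(DataError, match=r"\(a, b\)"):
            score_pair(ds, default_specs(200, models=("knn_fallback",)), 5)

    def test_same_seed_reproduces_scores_exactly(self):
        ds = _noise_pair_dataset(np.random.default_rng(3))
        specs = default_specs(200, models=("knn_fallback",))
        m1, t1 = score_pair(ds, specs, n_iterations=5, seed=9)
        m2, t2 = score_pair(ds, specs, n_iterations=5, seed=9)
        assert m1 == m2
        assert t1["score"].tolist() == t2["score"].tolist()


class TestBestScore:
    def test_maximum_wins(self):
        assert best_score({"fcn": 0.62, "resnet": 0.71, "cnn": 0.9}) == (0.9, "cnn")

    def test_single_model_is_identity(self):
        assert best_score({"resnet": 0.8}) == (0.8, "resnet")

    def test_exact_tie_broken_by_registry_order(self):
        assert best_score({"resnet": 0.8, "fcn": 0.8}) == (0.8, "fcn")

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            best_score({})


@pytest.fixture(scope="module")
def matrix():
    from idnet.synth import SynthConfig

    cfg = SynthConfig(
        n_channels=4, n_subjects=2, n_groups=1, sampling_rate=250.0,
        duration=30.0, noise_sd=0.3, seed=13,
    )
    recs, _ = generate_group(cfg, 0)
    return identifiability_matrix(
        recs,
        specs=default_specs(500, models=("knn_fallback",)),
        length=500,
        n_iterations=5,
        seed=3,
    )


class TestIdentifiabilityMatrix:
    def test_four_channels_give_six_pair_scores(self, matrix):
        off = ~np.eye(4, dtype=bool)
        assert np.isfinite(matrix.scores[off]).all()
        assert np.isnan(np.diag(matrix.scores)).all()
        assert len(matrix.pair_frame()) == 6

    def test_matrix_is_symmetric_with_matching_best_models(self, matrix):
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_array_equal(matrix.scores[off], matrix.scores.T[off])
        assert (matrix.best_model[off] == matrix.best_model.T[off]).all()

    def test_best_model_is_from_the_spec_list(self, matrix):
        off = ~np.eye(4, dtype=bool)
        assert set(matrix.best_model[off]) == {"knn_fallback"}


class TestCorrelationBaseline:
    def test_channel_with_itself_is_one(self):
        rng = np.random.default_rng(4)
        rec = Recording(
            data=np.tile(rng.standard_normal(1000), (2, 1)),
            sampling_rate=100.0,
            channel_labels=["a", "b"],
        )
        m = correlation_baseline([rec], length=250)
        assert m.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_noise_matches_null_expectation(self):
        # E|r| under independence ~ sqrt(2 / (pi (L-1)))
        rng = np.random.default_rng(5)
        L = 200
        rec = Recording(
            data=rng.standard_normal((2, L * 400)),
            sampling_rate=100.0,
            channel_labels=["a", "b"],
        )
        m = correlation_baseline([rec], length=L)
        expected = np.sqrt(2.0 / (np.pi * (L - 1)))
        assert m.loc["a", "b"] == pytest.approx(expected, rel=0.15)

    def test_zero_variance_segments_are_excluded(self, caplog):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((2, 1000))
        data[0, :250] = 0.0  # first segment flat on channel a
        rec = Recording(data=data, sampling_rate=100.0, channel_labels=["a", "b"])
        bank = build_segment_bank([rec], length=250)
        with caplog.at_level("WARNING"):
            m = correlation_from_bank(bank)
        assert "zero-variance" in caplog.text
        assert np.isfinite(m[0, 1])


@pytest.fixture(scope="module")
def recordings(two_tone_config):
    recs, _ = generate_group(two_tone_config, 0)
    return recs


class TestBandProfile:
    def test_single_band_equals_plain_run(self, recordings):
        specs = default_specs(500, models=("knn_fallback",))
        table, medians = band_profile(
            recordings, bands=["broadband"], specs=specs, length=500,
            n_iterations=4, seed=2,
        )
        plain = identifiability_matrix(
            recordings, specs=specs, length=500, n_iterations=4, seed=2,
        )
        assert medians["broadband"] == pytest.approx(
            float(plain.pair_frame()["score"].median())
        )

    def test_medians_lie_in_unit_interval(self, recordings):
        _, medians = band_profile(
            recordings,
            bands=["broadband", "alpha"],
            specs=default_specs(500, models=("knn_fallback",)),
            length=500,
            n_iterations=3,
            seed=2,
        )
        assert all(0.0 <= v <= 1.0 for v in medians.values())
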