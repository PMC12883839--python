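import numpy as np
import pytest

from leafwp import (
    CGANConfig,
    SpectraSet,
    augment_training_set,
    fidelity_sam,
    generate_conditioned_spectra,
    resample_condition_grid,
    train_cgan,
)
from leafwp.spectral_core import WavelengthGrid, max_abs_normalize


TINY = CGANConfig(epochs=20, batch_size=16, n_synthetic=25)


@pytest.fixture(scope="module")
def train_split(default_dataset):
    norm = max_abs_normalize(default_dataset.spectra, axis=-1)
    return SpectraSet(grid=default_dataset.grid, spectra=norm[:120], psi=default_dataset.psi[:120])


@pytest.fixture(scope="module")
def tiny_bundle(train_split):
    return train_cgan(train_split, TINY)


class TestConditionGrid:
    def test_even_grid_with_endpoints(self):
        np.testing.assert_allclose(
            resample_condition_grid(5, -1.0, 0.0), [-1.0, -0.75, -0.5, -0.25, 0.0]
        )

    def test_default_count_matches_augmentation_size(self):
        assert CGANConfig().n_synthetic == 500
        grid = resample_condition_grid(500, -2.2, -0.2)
        assert grid.size == 500
        assert grid[0] == -2.2 and grid[-1] == -0.2

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            resample_condition_grid(10, -0.1, -0.5)


class TestTraining:
    def test_seeded_determinism(self, train_split):
        a = train_cgan(train_split, TINY)
        b = train_cgan(train_split, TINY)
        for pa, pb in zip(a.generator.state_arrays(), b.generator.state_arrays()):
            np.testing.assert_array_equal(pa, pb)

    def test_loss_traces_finite_every_epoch(self, tiny_bundle):
        assert len(tiny_bundle.disc_loss_trace) == TINY.epochs
        assert np.all(np.isfinite(tiny_bundle.disc_loss_trace))
        assert np.all(np.isfinite(tiny_bundle.gen_loss_trace))

    def test_unlabeled_set_rejected(self, train_split):
        unlabeled = SpectraSet(grid=train_split.grid, spectra=train_split.spectra)
        with pytest.raises(ValueError, match="label"):
            train_cgan(unlabeled, TINY)

    def test_oversized_batch_rejected(self, train_split):
        with pytest.raises(ValueError, match="batch"):
            train_cgan(train_split, CGANConfig(batch_size=4096))


class TestGeneration:
    def test_row_count_and_provenance_and_labels(self, tiny_bundle):
        psi = resample_condition_grid(40, -2.0, -0.2)
        gen = generate_conditioned_spectra(tiny_bundle, psi, seed=0)
        assert gen.n_samples == 40
        assert set(gen.provenance) == {"cgan_generated"}
        np.testing.assert_array_equal(gen.psi, psi)
        assert gen.spectra.min() >= 0.0

    def test_reproducible_given_noise_seed(self, tiny_bundle):
        psi = resample_condition_grid(10, -2.0, -0.2)
        a = generate_conditioned_spectra(tiny_bundle, psi, seed=5)
        b = generate_conditioned_spectra(tiny_bundle, psi, seed=5)
        np.testing.assert_array_equal(a.spectra, b.spectra)

    def test_condition_changes_output_for_same_noise(self, tiny_bundle):
        a = generate_conditioned_spectra(tiny_bundle, np.array([-0.3, -0.3]), seed=1)
        b = generate_conditioned_spectra(tiny_bundle, np.array([-2.3, -2.3]), seed=1)
        assert not np.allclose(a.spectra, b.spectra)

    def test_untrained_bundle_rejected(self, train_split):
        from leafwp.cgan_augment import _init_bundle

        raw = _init_bundle(train_split, TINY)
        with pytest.raises(ValueError, match="untrained"):
            generate_conditioned_spectra(raw, np.array([-1.0, -2.0]))


class TestFidelityAndAugmentation:
    def test_identical_sets_have_zero_angle(self, train_split):
        assert fidelity_sam(train_split, train_split) == pytest.approx(0.0, abs=1e-6)

    def test_scaled_mean_spectra_have_zero_angle(self, train_split):
        scaled = SpectraSet(
            grid=train_split.grid, spectra=0.37 * train_split.spectra, psi=train_split.psi
        )
        assert fidelity_sam(train_split, scaled) == pytest.approx(0.0, abs=1e-6)

    def test_toy_quarter_angle(self):
        grid = WavelengthGrid(np.array([400.0, 500.0, 600.0]))
        a = SpectraSet(grid=grid, spectra=np.array([[1.0, 0.0, 0.0]] * 2))
        b = SpectraSet(grid=grid, spectra=np.array([[1.0, 1.0, 0.0]] * 3))
        assert fidelity_sam(a, b) == pytest.approx(np.pi / 4)

    def test_augmented_row_count_and_purity(self, train_split, tiny_bundle):
        before = train_split.spectra.copy()
        aug = augment_training_set(train_split, tiny_bundle, n_synthetic=25)
        assert aug.n_samples == train_split.n_samples + 25
        assert aug.provenance[-1] == "cgan_generated"
        assert aug.provenance[0] == "measured"
        np.testing.assert_array_equal(train_split.spectra, before)  # pure function

    def test_zero_synthetic_is_identity(self, train_split, tiny_bundle):
        aug = augment_training_set(train_split, tiny_bundle, n_synthetic=0)
        assert aug is train_split
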