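"""Model construction, image pipeline and training-loop contracts."""

import numpy as np
import pytest

from phototrait.cnn import (
    BackboneUnavailableError,
    TraitModelConfig,
    augment_image,
    build_model,
    preprocess_image,
    train,
)
from phototrait.datasets import (
    DatasetSplit,
    fit_split_normalizers,
    link_and_sample,
    make_split,
)
from phototrait.pipeline import build_trait_dataset
from phototrait.synthetic import SyntheticSpec, generate_corpus


def cfg(**kw):
    kw.setdefault("image_size", 64)
    kw.setdefault("seed", 0)
    return TraitModelConfig(**kw)


class TestBuildModel:
    def test_image_only_output_shape(self, rng):
        net = build_model(cfg())
        batch = rng.uniform(0, 1, size=(20, 64, 64, 3))
        assert net.forward(batch).shape == (20, 1)

    def test_mixed_accepts_six_rejects_five(self, rng):
        net = build_model(cfg(mixed_data=True))
        batch = rng.uniform(0, 1, size=(4, 64, 64, 3))
        assert net.forward(batch, rng.uniform(0, 1, size=(4, 6))).shape == (4, 1)
        with pytest.raises(ValueError):
            net.forward(batch, rng.uniform(0, 1, size=(4, 5)))

    def test_mixed_fusion_input_width(self):
        net = build_model(cfg(mixed_data=True))
        # 4 image + 4 climate features enter the fusion stack
        assert net.fusion.layers[0].W.shape[0] == 8
        # climate branch is 64 -> 32 -> 4, final layer linear
        widths = [l.W.shape[1] for l in net.clim_branch.layers if hasattr(l, "W")]
        assert widths == [64, 32, 4]

    def test_unknown_backbone_lists_options(self):
        with pytest.raises(ValueError, match="tiny_test_cnn"):
            build_model(cfg(backbone="resnet50"))

    def test_unavailable_backbone_raises_informatively(self):
        with pytest.raises(BackboneUnavailableError, match="framework"):
            build_model(cfg(backbone="xception"))

    def test_seeded_build_reproducible(self, rng):
        batch = rng.uniform(0, 1, size=(3, 64, 64, 3))
        a = build_model(cfg(seed=7)).forward(batch)
        b = build_model(cfg(seed=7)).forward(batch)
        np.testing.assert_array_equal(a, b)

    def test_zero_climate_makes_permutation_irrelevant(self, rng):
        """With the climate input frozen at zeros, permuting it changes nothing."""
        net = build_model(cfg(mixed_data=True))
        batch = rng.uniform(0, 1, size=(6, 64, 64, 3))
        zeros = np.zeros((6, 6))
        a = net.forward(batch, zeros)
        b = net.forward(batch, zeros[rng.permutation(6)])
        np.testing.assert_array_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TraitModelConfig(image_size=16)
        with pytest.raises(ValueError):
            TraitModelConfig(batch_size=0)
        with pytest.raises(ValueError):
            TraitModelConfig(lr=0.0)


class TestAugmentImage:
    def test_identity_configuration(self, rng):
        img = rng.uniform(0, 1, size=(32, 32, 3))
        out = augment_image(img, hflip=False, vflip=False, contrast=1.0,
                            saturation=1.0, brightness=1.0)
        np.testing.assert_array_equal(out, img)

    def test_output_stays_in_unit_interval(self, rng):
        img = rng.uniform(0, 1, size=(16, 16, 3))
        for _ in range(1000):
            out = augment_image(img, rng)
            assert out.min() >= 0.0 and out.max() <= 1.0
            assert out.shape == img.shape

    def test_horizontal_flip_involution(self, rng):
        img = rng.uniform(0, 1, size=(8, 8, 3))
        once = augment_image(img, hflip=True, vflip=False, contrast=1.0,
                             saturation=1.0, brightness=1.0)
        twice = augment_image(once, hflip=True, vflip=False, contrast=1.0,
                              saturation=1.0, brightness=1.0)
        np.testing.assert_array_equal(twice, img)

    def test_brightness_scales_channels(self, rng):
        img = np.full((4, 4, 3), 0.5)
        out = augment_image(img, hflip=False, vflip=False, contrast=1.0,
                            saturation=1.0, brightness=1.1)
        np.testing.assert_allclose(out, 0.55)


class TestPreprocessImage:
    def test_landscape_center_crop(self, rng):
        img = (rng.uniform(0, 1, size=(60, 96, 3)) * 255).astype(np.uint8)
        out = preprocess_image(img, 48)
        assert out.shape == (48, 48, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_square_input_geometry_unchanged(self, rng):
        img = (rng.uniform(0, 1, size=(64, 64, 3)) * 255).astype(np.uint8)
        out = preprocess_image(img, 64)
        np.testing.assert_allclose(out, img / 255.0, atol=1e-6)

    def test_uniform_gray_stays_uniform(self):
        img = np.full((100, 80, 3), 0.5)
        out = preprocess_image(img, 64)
        assert out.shape == (64, 64, 3)
        assert np.allclose(out, out[0, 0, 0], atol=1 / 255)

    def test_upsampling_warns(self):
        img = np.full((40, 40, 3), 0.5)
        with pytest.warns(RuntimeWarning, match="upsampling"):
            preprocess_image(img, 64)

    def test_unreadable_file_named(self, tmp_path):
        bad = tmp_path / "broken.png"
        bad.write_text("not an image")
        with pytest.raises(OSError, match="broken.png"):
            preprocess_image(bad, 64)


@pytest.fixture(scope="module")
def trained_setup(tmp_path_factory):
    """A small informative corpus with its split and preloaded images."""
    spec = SyntheticSpec(n_species=20, images_per_species=(2, 4), seed=21,
                         c_area=2.0, c_green=0.3, sigma_noise=0.02)
    corpus = generate_corpus(spec, tmp_path_factory.mktemp("cnn_corpus"))
    split, tparams, bparams = build_trait_dataset(
        corpus.trait_csv, corpus.occurrence_csv, corpus.climate_dir, seed=2
    )
    return corpus, split, tparams, bparams


class TestTrain:
    def test_zero_epochs_is_noop(self, trained_setup):
        corpus, split, tparams, _ = trained_setup
        net = build_model(cfg(max_epochs=0))
        before = net.get_weights()
        history = train(net, split, cfg(max_epochs=0), tparams, images=corpus.images)
        assert history.n_epochs == 0
        for a, b in zip(net.get_weights(), before):
            np.testing.assert_array_equal(a, b)

    def test_training_reduces_mae(self, trained_setup):
        """The trained (best-epoch) model beats the initialized one on the train set."""
        from phototrait.datasets import normalized_targets

        corpus, split, tparams, _ = trained_setup
        c = cfg(max_epochs=8, seed=3)
        net = build_model(c)
        imgs = np.stack([corpus.images[o.record_id] for o in split.train])
        targets = normalized_targets(split.train, tparams)
        mae_init = float(np.mean(np.abs(net.predict(imgs) - targets)))
        history = train(net, split, c, tparams, images=corpus.images)
        mae_final = float(np.mean(np.abs(net.predict(imgs) - targets)))
        assert history.n_epochs > 0
        assert mae_final < mae_init

    def test_seeded_training_deterministic(self, trained_setup):
        corpus, split, tparams, _ = trained_setup
        histories = []
        for _ in range(2):
            net = build_model(cfg(max_epochs=1, seed=5))
            h = train(net, split, cfg(max_epochs=1, seed=5), tparams, images=corpus.images)
            histories.append(h.train_mae[0])
        assert histories[0] == pytest.approx(histories[1], abs=1e-6)

    def test_empty_validation_rejected(self, trained_setup):
        corpus, split, tparams, _ = trained_setup
        bad = DatasetSplit(train=split.train, validation=[], test=split.test, seed=0)
        with pytest.raises(ValueError, match="validation"):
            train(build_model(cfg()), bad, cfg(), tparams, images=corpus.images)

    def test_plasticity_with_zero_sd_matches_baseline(self, tmp_path):
        """With every species SD zero, the augmented stream is bit-identical."""
        spec = SyntheticSpec(n_species=18, images_per_species=(2, 3), seed=31,
                             trait_records_per_species=1)  # single record -> sd 0
        corpus = generate_corpus(spec, tmp_path / "c")
        split, tparams, _ = build_trait_dataset(
            corpus.trait_csv, corpus.occurrence_csv, None, seed=4
        )
        assert all(o.trait_sd == 0 for o in split.train)
        weights = []
        for plast in (False, True):
            net = build_model(cfg(max_epochs=2, seed=6))
            train(net, split, cfg(max_epochs=2, seed=6), tparams,
                  plasticity=plast, images=corpus.images)
            weights.append(net.get_weights())
        for a, b in zip(*weights):
            np.testing.assert_array_equal(a, b)
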