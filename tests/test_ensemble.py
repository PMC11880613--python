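"""Feature-level fusion ensemble: structure, routing, freezing."""

import numpy as np
import pytest

from xaimri.ensemble import (
    EnsembleConfig,
    EnsembleNet,
    build_ensemble,
    ensemble_forward,
    load_ensemble_checkpoint,
    save_ensemble_checkpoint,
    strip_output_layer,
)
from xaimri.errors import StructuralError, ValidationError
from xaimri.train import TrainConfig, train
from xaimri.unet import UNetConfig, build_unet, stack_modalities

TINY = UNetConfig(in_channels=2, n_classes=4, depth_levels=2, base_filters=4, dropout_rate=0.0)


@pytest.fixture()
def bases():
    return build_unet(TINY, seed=1), build_unet(TINY, seed=2)


@pytest.fixture()
def ensemble(bases):
    return build_ensemble((bases[0], ("T2", "T1ce")), (bases[1], ("T1ce", "FLAIR")))


class TestStripOutputLayer:
    def test_extractor_matches_captured_penultimate_activations(self, bases, rng):
        model = bases[0]
        x = rng.normal(size=(1, 2, 8, 8, 8)).astype(np.float32)
        model.request_capture(["dec0.conv2"])
        model.forward(x)
        captured = model.activations["dec0.conv2"]
        model.clear_capture()
        feats = strip_output_layer(model)(x)
        assert np.array_equal(feats, captured)

    def test_extractor_channel_count_and_spatial_shape(self, bases, rng):
        extractor = strip_output_layer(bases[0])
        assert extractor.out_channels == bases[0].penultimate_channels == 4
        x = rng.normal(size=(1, 2, 8, 8, 8)).astype(np.float32)
        assert extractor(x).shape == (1, 4, 8, 8, 8)

    def test_model_without_output_layer_is_structural_error(self):
        with pytest.raises(StructuralError):
            strip_output_layer(object())


class TestBuildEnsemble:
    def test_concat_width_and_fusion_channels(self, ensemble):
        assert ensemble.fusion_conv.in_channels == 8  # 4 + 4 penultimate channels
        assert ensemble.fusion_channels == 16
        assert ensemble.fusion_conv.k == 3
        assert ensemble.out_conv.k == 1

    def test_union_modalities_share_t1ce(self, ensemble):
        assert ensemble.union_modalities == ["T2", "T1ce", "FLAIR"]
        assert ensemble.routing == {"base_a": (0, 1), "base_b": (1, 2)}
        assert ensemble.in_channels == 3

    def test_duplicated_base_gives_identical_branches(self, bases, rng):
        model = bases[0]
        ens = build_ensemble((model, ("T2", "T1ce")), (model, ("T2", "T1ce")))
        x = rng.normal(size=(1, 2, 8, 8, 8)).astype(np.float32)
        fa = ens.extractor_a(ens._route(x, "base_a"))
        fb = ens.extractor_b(ens._route(x, "base_b"))
        assert np.array_equal(fa, fb)

    def test_mismatched_bases_rejected(self, bases):
        other = build_unet(
            UNetConfig(in_channels=2, n_classes=3, depth_levels=2, base_filters=4), seed=0
        )
        with pytest.raises(StructuralError, match="n_classes"):
            build_ensemble((bases[0], ("T2", "T1ce")), (other, ("T1ce", "FLAIR")))
        with pytest.raises(ValidationError, match="exactly 2"):
            build_ensemble((bases[0], ("T2",)), (bases[1], ("T1ce", "FLAIR")))

    def test_frozen_trainable_parameters_are_head_only(self, ensemble):
        head = ensemble.fusion_conv.parameters() + ensemble.out_conv.parameters()
        expected = sum(p.value.size for p in head)
        assert sum(p.value.size for p in ensemble.trainable_parameters()) == expected
        # closed form: fusion conv (16·8·27+16) + output head (4·16+4)
        assert expected == (16 * 8 * 27 + 16) + (4 * 16 + 4)


class TestEnsembleForward:
    def test_softmax_normalization_on_random_input(self, ensemble, rng):
        x = rng.normal(size=(2, 3, 8, 8, 8)).astype(np.float32)
        probs = ensemble.forward(x)
        assert probs.shape == (2, 4, 8, 8, 8)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_single_sample_convenience_wrapper(self, ensemble, rng):
        x = rng.normal(size=(3, 8, 8, 8)).astype(np.float32)
        probs = ensemble_forward(ensemble, x)
        assert probs.shape == (4, 8, 8, 8)

    def test_wrong_channel_count_cites_union_order(self, ensemble, rng):
        with pytest.raises(ValidationError, match="T2.*T1ce.*FLAIR"):
            ensemble.forward(rng.normal(size=(1, 2, 8, 8, 8)).astype(np.float32))

    def test_routing_invariance_under_channel_permutation(self, bases, rng):
        """Permuting the union order together with the routing table
        leaves the output unchanged, element for element."""
        ens_a = build_ensemble((bases[0], ("T2", "T1ce")), (bases[1], ("T1ce", "FLAIR")))
        ens_b = build_ensemble((bases[1], ("T1ce", "FLAIR")), (bases[0], ("T2", "T1ce")))
        # ens_b's union order is (T1ce, FLAIR, T2); its head weights differ,
        # so align them with ens_a's before comparing
        ens_b.fusion_conv.weight.value = np.concatenate(
            [ens_a.fusion_conv.weight.value[:, 4:], ens_a.fusion_conv.weight.value[:, :4]],
            axis=1,
        )
        ens_b.fusion_conv.bias.value = ens_a.fusion_conv.bias.value.copy()
        ens_b.out_conv.weight.value = ens_a.out_conv.weight.value.copy()
        ens_b.out_conv.bias.value = ens_a.out_conv.bias.value.copy()
        x = rng.normal(size=(1, 3, 8, 8, 8)).astype(np.float32)  # T2, T1ce, FLAIR
        perm = [ens_a.union_modalities.index(m) for m in ens_b.union_modalities]
        out_a = ens_a.forward(x)
        out_b = ens_b.forward(x[:, perm])
        assert np.allclose(out_a, out_b, atol=1e-6)


class TestFusionTraining:
    def test_frozen_bases_are_bit_identical_after_training(self, preprocessed_cohort):
        base_a = build_unet(TINY, seed=1)
        base_b = build_unet(TINY, seed=2)
        ens = build_ensemble((base_a, ("T2", "T1ce")), (base_b, ("T1ce", "FLAIR")))
        samples = [
            (stack_modalities(p, ens.union_modalities), p.mask.astype(np.int64))
            for p in preprocessed_cohort
        ]
        snap_a = [w.copy() for w in base_a.get_weights()]
        snap_b = [w.copy() for w in base_b.get_weights()]
        fusion_before = ens.fusion_conv.weight.value.copy()
        train(ens, samples[:2], samples[2:3],
              TrainConfig(batch_size=2, max_epochs=1, learning_rate=3e-3, seed=0))
        assert all(np.array_equal(a, b) for a, b in zip(snap_a, base_a.get_weights()))
        assert all(np.array_equal(a, b) for a, b in zip(snap_b, base_b.get_weights()))
        assert not np.array_equal(fusion_before, ens.fusion_conv.weight.value)

    def test_finetuned_bases_do_change(self, preprocessed_cohort):
        base_a = build_unet(TINY, seed=1)
        base_b = build_unet(TINY, seed=2)
        ens = build_ensemble(
            (base_a, ("T2", "T1ce")), (base_b, ("T1ce", "FLAIR")),
            EnsembleConfig(freeze_base=False),
        )
        samples = [
            (stack_modalities(p, ens.union_modalities), p.mask.astype(np.int64))
            for p in preprocessed_cohort
        ]
        snap_a = [w.copy() for w in base_a.get_weights()]
        train(ens, samples[:2], samples[2:3],
              TrainConfig(batch_size=2, max_epochs=1, learning_rate=3e-3, seed=0))
        assert any(not np.array_equal(a, b) for a, b in zip(snap_a, base_a.get_weights()))


class TestEnsembleCheckpoint:
    def test_round_trip_preserves_outputs_and_routing(self, ensemble, tmp_path, rng):
        x = rng.normal(size=(1, 3, 8, 8, 8)).astype(np.float32)
        before = ensemble.forward(x)
        path = save_ensemble_checkpoint(ensemble, tmp_path / "ens.npz")
        loaded, sidecar = load_ensemble_checkpoint(path)
        assert np.array_equal(loaded.forward(x), before)
        assert sidecar["union_modalities"] == ["T2", "T1ce", "FLAIR"]
        assert sidecar["routing"] == {"base_a": [0, 1], "base_b": [1, 2]}
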