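"""Pairing, splitting, and the two-stage training loop."""

import dataclasses

import numpy as np
import pytest

from endorestore import (ConfigurationError, DegradationSpec, ModelConfig,
                         NoiseSpec, ParameterError, build_model,
                         make_motion_kernel, make_pairs, restore, train_stage)
from endorestore.phantom import PhantomConfig, generate_dataset
from endorestore.training import TrainConfig, derive_pair_seed, restore_batch

GRID3 = [
    DegradationSpec(noise=NoiseSpec(family="gaussian", sigma=25.0)),
    DegradationSpec(kernel=make_motion_kernel(5, 45.0)),
    DegradationSpec(noise=NoiseSpec(family="speckle", variance=0.04)),
]


@pytest.fixture(scope="module")
def small_manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("frames")
    return generate_dataset(10, PhantomConfig(seed=0, height=32, width=32), out)


def test_pair_cardinality(small_manifest):
    data = make_pairs(small_manifest, GRID3, seed=0)
    assert len(data) == 30
    for p in data.pairs:
        assert p.clean.shape == p.degraded.shape == (32, 32, 3)


def test_split_is_deterministic_and_frame_disjoint(small_manifest):
    a = make_pairs(small_manifest, GRID3, seed=4)
    b = make_pairs(small_manifest, GRID3, seed=4)
    assert [p.split for p in a.pairs] == [p.split for p in b.pairs]
    by_frame = {}
    for p in a.pairs:
        by_frame.setdefault(p.frame_index, set()).add(p.split)
    assert all(len(s) == 1 for s in by_frame.values())


def test_split_fractions_near_70_15_15(tmp_path):
    manifest = generate_dataset(200, PhantomConfig(seed=1, height=16, width=16),
                                tmp_path / "f")
    grid = [DegradationSpec(noise=NoiseSpec(family="gaussian", sigma=20.0)),
            DegradationSpec(kernel=make_motion_kernel(3, 0.0)),
            DegradationSpec(),
            DegradationSpec(noise=NoiseSpec(family="poisson", peak=100.0)),
            DegradationSpec(noise=NoiseSpec(family="salt_pepper", amount=0.05))]
    data = make_pairs(manifest, grid, seed=0)
    assert len(data) == 1000
    frac = {s: sum(p.split == s for p in data.pairs) / 1000
            for s in ("train", "val", "test")}
    assert abs(frac["train"] - 0.70) <= 0.02
    assert abs(frac["val"] - 0.15) <= 0.02
    assert abs(frac["test"] - 0.15) <= 0.02


def test_empty_inputs_rejected(small_manifest):
    with pytest.raises(ParameterError):
        make_pairs(small_manifest, [], seed=0)
    empty = dataclasses.replace(small_manifest, records=[])
    with pytest.raises(ParameterError):
        make_pairs(empty, GRID3, seed=0)


def test_pair_seeds_stable_and_bounded():
    s1 = derive_pair_seed(3, 5, 2)
    assert s1 == derive_pair_seed(3, 5, 2)
    assert 0 <= s1 < 2 ** 31
    assert derive_pair_seed(3, 5, 2) != derive_pair_seed(3, 6, 2)


def test_zero_epochs_leaves_model_unchanged(small_manifest):
    data = make_pairs(small_manifest, GRID3, seed=0)
    model = build_model(ModelConfig(depth=1, base_channels=2), seed=0)
    before = [p.data.copy() for p in model.parameters()]
    model, log = train_stage(model, data, TrainConfig(
        stage="coarse", epochs=0, patch_size=32, seed=0))
    assert log.records == []
    for p, b in zip(model.parameters(), before):
        np.testing.assert_array_equal(p.data, b)


def test_fine_before_coarse_rejected(small_manifest):
    data = make_pairs(small_manifest, GRID3, seed=0)
    model = build_model(ModelConfig(depth=1, base_channels=2), seed=0)
    with pytest.raises(ConfigurationError):
        train_stage(model, data, TrainConfig(stage="fine", epochs=1,
                                             patch_size=32, seed=0))


def test_fine_stage_requires_edge_weight():
    from endorestore import LossWeights
    with pytest.raises(ConfigurationError):
        TrainConfig(stage="fine", loss_weights=LossWeights(1, 1, 1, 0))


def test_fine_stage_without_blur_pairs_rejected(small_manifest):
    blurless = [DegradationSpec(noise=NoiseSpec(family="gaussian", sigma=25.0))]
    data = make_pairs(small_manifest, blurless, seed=0)
    model = build_model(ModelConfig(depth=1, base_channels=2), seed=0)
    model.stage = "coarse"
    with pytest.raises(ConfigurationError):
        train_stage(model, data, TrainConfig(stage="fine", epochs=1,
                                             patch_size=32, seed=0))


def test_training_reduces_loss_and_is_reproducible(small_manifest):
    data = make_pairs(small_manifest, GRID3, seed=0)
    cfg = TrainConfig(stage="coarse", epochs=2, batch_size=2, patch_size=32,
                      seed=7)

    def run():
        model = build_model(ModelConfig(depth=1, base_channels=4), seed=7)
        return train_stage(model, data, cfg)

    m1, log1 = run()
    m2, log2 = run()
    assert log1.records == log2.records
    for p, q in zip(m1.parameters(), m2.parameters()):
        np.testing.assert_array_equal(p.data, q.data)
    assert m1.stage == "coarse"
    assert [r["epoch"] for r in log1.records] == [0, 1]
    assert log1.records[-1]["total"] <= log1.records[0]["total"]


def test_restore_batch_roundtrip(tmp_path, small_manifest):
    model = build_model(ModelConfig(depth=1, base_channels=2), seed=0)
    model.stage = "coarse"
    ckpt = tmp_path / "m.npz"
    model.save(ckpt)
    out1 = tmp_path / "out1"
    out2 = tmp_path / "out2"
    m1 = restore_batch(ckpt, small_manifest.root, out1)
    m2 = restore_batch(ckpt, small_manifest.root, out2)
    names = sorted(r.file for r in m1.records)
    assert names == sorted(r.file for r in small_manifest.records)
    for name in names:
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


def test_restore_batch_missing_checkpoint(tmp_path, small_manifest):
    with pytest.raises(IOError):
        restore_batch(tmp_path / "missing.npz", small_manifest.root,
                      tmp_path / "o")
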