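"""Quantification model: architecture, training behavior, inference."""

import dataclasses

import numpy as np
import pytest

from cmxrf import datasets, model
from cmxrf.model import ModelConfig, QuantPrediction, aggregate_predictions


SMALL = ModelConfig(
    conv_channels=(4, 8),
    pool_after=(0, 1),
    feature_shape=(10, 37),
    mlp_widths=(32,),
    epochs=3,
    learning_rate=1e-3,
    seed=5,
)


@pytest.fixture(scope="module")
def tiny_data():
    ds = datasets.generate_dataset(48, seed=50)
    val = datasets.generate_dataset(12, seed=51)
    return ds, val


def test_forward_pass_emits_55_entries(tiny_data):
    ds, _ = tiny_data
    m = model.build_model(SMALL)
    out = m.forward_scaled(ds.X[:1].astype(np.float64))
    assert out.shape == (1, 55)


def test_same_seed_bitwise_identical_init():
    a = model.build_model(SMALL)
    b = model.build_model(SMALL)
    for pa, pb in zip(a.net.params, b.net.params):
        np.testing.assert_array_equal(pa, pb)


def test_parameter_count_formula():
    """Doubling the first MLP width changes the count analytically."""
    base = model.build_model(SMALL)
    wider = model.build_model(dataclasses.replace(SMALL, mlp_widths=(64,)))
    n_in = 8 * 10 * 37 + 2 * 150  # conv features + sum-spectrum shortcuts
    expected_delta = (n_in + 1) * 32 + (64 - 32) * 55  # extra hidden + output fan-in
    assert wider.n_parameters() - base.n_parameters() == expected_delta


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        ModelConfig(n_outputs=54)
    with pytest.raises(ValueError):
        # grid mismatch between model and generator
        model.build_model(dataclasses.replace(SMALL, input_shape=(40, 100)))


def test_tiny_dataset_memorization(tiny_data):
    """Memorization sanity: training on two profiles drives the training
    MSE to a vanishing fraction of its initial value.  (A one-profile
    set is degenerate here: per-feature standardization of a single
    sample collapses inputs and targets to exact zeros.)"""
    ds, _ = tiny_data
    two = datasets.ProfileDataset(
        ds.X[:2], ds.Y[:2], ds.elements, ds.depth_grid, ds.energy_grid, ds.config
    )
    cfg = dataclasses.replace(
        SMALL, epochs=300, learning_rate=1e-2, poisson_augmentation=False, batch_size=2
    )
    m = model.build_model(cfg)
    log = model.train(m, two, val_dataset=two)
    assert log[-1]["train_mse"] < 1e-4 * log[0]["train_mse"]


def test_validation_loss_improves(tiny_data):
    ds, val = tiny_data
    cfg = dataclasses.replace(SMALL, epochs=8)
    m = model.build_model(cfg)
    log = model.train(m, ds, val)
    assert min(e["val_mse"] for e in log[1:]) < log[0]["val_mse"]


def test_noise_augmentation_helps_on_noisy_validation(tiny_data):
    """At matched epochs and seed, training with Poisson augmentation
    yields a lower validation loss on noisy profiles than without.

    Exposure is scaled down so shot noise is a dominant effect."""
    ds, val = tiny_data
    scale = 0.02

    def scaled(d):
        return datasets.ProfileDataset(
            d.X * scale, d.Y, d.elements, d.depth_grid, d.energy_grid, d.config
        )

    ds_s, val_s = scaled(ds), scaled(val)
    cfg = dataclasses.replace(SMALL, epochs=8)
    with_aug = model.build_model(cfg)
    model.train(with_aug, ds_s, val_s)
    without = model.build_model(dataclasses.replace(cfg, poisson_augmentation=False))
    model.train(without, ds_s, val_s)

    rng = np.random.default_rng(123)
    noisy = rng.poisson(val_s.X.astype(np.float64)).astype(np.float64)
    t_aug = with_aug.scaler.scale(val.Y)
    mse_aug = float(np.mean((with_aug.forward_scaled(noisy) - t_aug) ** 2))
    t_plain = without.scaler.scale(val.Y)
    mse_plain = float(np.mean((without.forward_scaled(noisy) - t_plain) ** 2))
    assert mse_aug < mse_plain


def test_divergence_aborts(tiny_data):
    ds, val = tiny_data
    cfg = dataclasses.replace(SMALL, learning_rate=1e6, epochs=50)
    m = model.build_model(cfg)
    with pytest.raises(RuntimeError, match="diverged"):
        model.train(m, ds, val)


@pytest.fixture(scope="module")
def trained(tiny_data):
    ds, val = tiny_data
    m = model.build_model(SMALL)
    model.train(m, ds, val)
    return m


def test_predict_output_structure(trained, tiny_data):
    ds, _ = tiny_data
    pred = model.predict(trained, ds.X[0])
    assert isinstance(pred, QuantPrediction)
    assert pred.concentrations.shape == (53,)
    assert np.all(pred.concentrations >= 0)
    assert len(pred.as_vector()) == 55


def test_inference_deterministic(trained, tiny_data):
    ds, _ = tiny_data
    a = model.predict(trained, ds.X[0])
    b = model.predict(trained, ds.X[0])
    np.testing.assert_array_equal(a.as_vector(), b.as_vector())


def test_batch_predict_equals_single_predicts(trained, tiny_data):
    ds, _ = tiny_data
    batch = model.predict(trained, ds.X[:5])
    singles = [model.predict(trained, ds.X[i]) for i in range(5)]
    for pb, ps in zip(batch, singles):
        np.testing.assert_allclose(pb.as_vector(), ps.as_vector(), rtol=1e-6)


def test_predict_on_depth_profile_object(trained):
    """A full-resolution DepthProfile is binned onto the training grid."""
    from cmxrf import confocal, forward
    from cmxrf.samples import Composition

    comp = Composition({26: 0.03, 19: 0.01}, 2.0)
    spec = forward.simulate_mxrf(comp)
    prof = confocal.transform(spec, comp, x0=60.0)
    pred = model.predict(trained, prof)
    assert len(pred.as_vector()) == 55


def test_predict_rejects_untrained_model():
    m = model.build_model(SMALL)
    with pytest.raises(RuntimeError):
        model.predict(m, np.zeros((40, 300)))


def test_predict_rejects_grid_mismatch(trained):
    with pytest.raises(ValueError):
        model.predict(trained, np.zeros((40, 100)))


def test_checkpoint_roundtrip_bitwise(trained, tiny_data, tmp_path):
    ds, _ = tiny_data
    path = tmp_path / "model.npz"
    trained.save(path)
    back = model.QuantModel.load(path)
    a = model.predict(trained, ds.X[0])
    b = model.predict(back, ds.X[0])
    np.testing.assert_array_equal(a.as_vector(), b.as_vector())
    assert back.config == trained.config
    assert back.training_log == trained.training_log


def test_aggregate_predictions_mean():
    single = QuantPrediction(np.full(53, 0.1), 2.0, 60.0)
    agg = aggregate_predictions([single])
    np.testing.assert_array_equal(agg.as_vector(), single.as_vector())

    a = QuantPrediction(np.full(53, 0.1), 2.0, 60.0)
    b = QuantPrediction(np.full(53, 0.3), 3.0, 70.0)
    agg = aggregate_predictions([a, b])
    assert agg.concentrations[0] == pytest.approx(0.2)
    assert agg.density == pytest.approx(2.5)

    rng = np.random.default_rng(0)
    preds = [
        QuantPrediction(rng.random(53), float(rng.random()) + 1, float(rng.random()))
        for _ in range(100)
    ]
    mat = np.stack([p.as_vector() for p in preds])
    np.testing.assert_allclose(
        aggregate_predictions(preds).as_vector(), mat.mean(axis=0), rtol=1e-12
    )

    with pytest.raises(ValueError):
        aggregate_predictions([])
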