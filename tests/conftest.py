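import numpy as np
import pytest

from sparus.acquisition import PlaneWaveSequence, make_linear_array
from sparus.beamform import ImageGrid
from sparus.phantoms import make_paired_dataset


@pytest.fixture(scope="session")
def dense_array():
    return make_linear_array(128, 70e-6, 28e6, 0.6)


@pytest.fixture(scope="session")
def clean_sequence():
    # 250 MHz keeps the full -6 dB pulse band below Nyquist (the 62.5 MHz
    # DAQ rate undersamples a 28 MHz / 60% probe and aliases the band edge)
    return PlaneWaveSequence(sampling_rate=250e6)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small paired dataset shared by phantom/io/restoration tests."""
    return make_paired_dataset(8, [2, 8], seed=11, image_size=64)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def acceptance_run():
    """Desk-scale analog of the paper's training experiment.

    200-pair pool (80/20 train/val) of 128x128 factor-8 sparse/dense pairs
    plus 50 held-out test pairs; a small RUNet trained for 8 epochs.
    Session-scoped because it takes several minutes.
    """
    from sparus.metrics import mse, psnr, ssim
    from sparus.restoration import RUNetConfig, build_runet, predict, train

    data = make_paired_dataset(200, [8], seed=7, image_size=128, n_test=50)
    cfg = RUNetConfig(
        depth=2,
        base_channels=8,
        epochs=8,
        batch_size=8,
        learning_rate=5e-4,
        loss_weights={"pixel": 1.0, "perceptual": 0.1},
        seed=7,
    )
    model = build_runet(cfg)
    train(model, data.pairs(8, data.split["train"]), data.pairs(8, data.split["val"]))

    rows = []
    for i in data.split["test"]:
        gt = data.dense_images[i].pixels
        sp = data.sparse_images[8][i]
        pr = predict(model, sp).pixels
        rows.append(
            {
                "ssim_in": ssim(gt, sp.pixels),
                "ssim_pred": ssim(gt, pr),
                "mse_in": mse(gt, sp.pixels),
                "mse_pred": mse(gt, pr),
                "psnr_in": psnr(gt, sp.pixels),
                "psnr_pred": psnr(gt, pr),
            }
        )
    return {"data": data, "model": model, "test_metrics": rows}
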