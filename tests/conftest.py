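import numpy as np
import pytest

import eegfatigue as ef


@pytest.fixture(scope="session")
def montage():
    return ef.standard_montage()


@pytest.fixture(scope="session")
def profiles():
    return ef.default_profiles()


@pytest.fixture(scope="session")
def small_epoch(profiles):
    """One preprocessed fatigue epoch (32 x 12000 at 200 Hz)."""
    rec = ef.generate_recording(profiles["fatigue"], duration=60, fs=500,
                                seed=42)
    return ef.preprocess_recording(rec)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_toy_images(n_per_class: int, size: int = 24, seed: int = 0,
                    classes=("normal", "fatigue")):
    """Linearly separable images: class 0 bright on the left half,
    class 1 bright on the right half, plus mild noise."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    half = size // 2
    for label_index, label in enumerate(classes):
        for _ in range(n_per_class):
            img = 0.1 * rng.random((size, size, 3))
            if label_index == 0:
                img[:, :half, :] += 0.8
            else:
                img[:, half:, :] += 0.8
            images.append(img)
            labels.append(label)
    order = rng.permutation(len(images))
    return (np.asarray(images, dtype=np.float32)[order],
            np.asarray(labels)[order])
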