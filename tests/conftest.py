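import numpy as np
import pytest

import rimtrack as rt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_roi():
    """84x84 tissue ROI inside a 96x96 frame."""
    mask = np.zeros((96, 96), dtype=bool)
    mask[6:90, 6:90] = True
    return rt.RegionOfInterest(mask)


@pytest.fixture
def noiseless_scene(default_roi):
    """One noiseless scene at the plin2-like peak: exact intensities."""
    params = rt.SceneParams(
        image_size=(96, 96),
        seed=7,
        read_noise_sd=0.0,
        photon_noise=False,
        protein_scale_sd=0.0,
    )
    schedule = rt.protein_schedule("plin2_like")
    dye, protein, truth = rt.make_droplet_scene(
        params, schedule, time_hr=12.0, roi=default_roi
    )
    return params, dye, protein, truth, default_roi


@pytest.fixture(scope="session")
def trained_model():
    """Pixel classifier trained on three default-noise scenes."""
    rng = np.random.default_rng(42)
    images, label_maps = [], []
    schedule = rt.protein_schedule("plin2_like")
    for k in range(3):
        params = rt.SceneParams(seed=100 + k)
        dye, _, truth = rt.make_droplet_scene(params, schedule, time_hr=6.0)
        labels = np.zeros(dye.pixels.shape, dtype=np.uint8)
        for region, value in ((truth.droplet_mask, 2), (~truth.droplet_mask, 1)):
            coords = np.argwhere(region)
            sel = coords[rng.choice(len(coords), size=400, replace=False)]
            labels[sel[:, 0], sel[:, 1]] = value
        images.append(dye)
        label_maps.append(labels)
    return rt.train_pixel_classifier(images, label_maps, seed=0)
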