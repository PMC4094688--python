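import numpy as np
import pytest
from scipy import ndimage

from lvecho.phantom import PhantomConfig, generate_sequence
from lvecho.segmentation import SegmentationSpec


@pytest.fixture(scope="session")
def seq5_128():
    """5 ml-default phantom sequence on a 128-px raster (shared, read-only)."""
    cfg = PhantomConfig.for_dose("5", rng_seed=1, image_height=128, image_width=128)
    return generate_sequence(cfg)


@pytest.fixture(scope="session")
def noiseless_seq_128():
    """Noiseless, homogeneous 5 ml phantom on a 128-px raster."""
    cfg = PhantomConfig.for_dose(
        "5", rng_seed=1, image_height=128, image_width=128,
        speckle_looks=None, inhomogeneity=0.0,
    )
    return generate_sequence(cfg)


def spec_for(seq, n_iterations=800, **overrides):
    """Segmentation spec seeded at the truth centroid with truth-area estimate."""
    truth = seq.truth_mask
    return SegmentationSpec(
        seed_center=tuple(ndimage.center_of_mass(truth)),
        expected_area=float(truth.sum()),
        av_plane=seq.av_plane,
        n_iterations=n_iterations,
        **overrides,
    )


def disc_image(shape=(96, 96), center=(48, 48), radius=28, inside=0.9, outside=0.1):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    disc = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 < radius**2
    img = np.full(shape, outside)
    img[disc] = inside
    return img, disc
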