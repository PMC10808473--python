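import numpy as np
import pytest

from pfahet import density, synth


@pytest.fixture(scope="session")
def tissue_03():
    """One rendered tissue field with a planted 30% nodule fraction."""
    return synth.gen_tissue_image(synth.SynthTissueSpec(nodule_fraction=0.3, seed=7))


@pytest.fixture(scope="session")
def tissue_03_detected(tissue_03):
    """Detected nuclei + density map + compartments for the shared field."""
    img = density.TissueImage(
        tissue_03.image, tissue_03.scale_um_per_px, ki67=tissue_03.ki67
    )
    nuclei = density.detect_nuclei(img)
    dmap = density.density_map(nuclei, img.extent_um)
    cmask = density.classify_compartments(dmap)
    return img, nuclei, dmap, cmask


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
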