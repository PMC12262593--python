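import numpy as np
import pytest

import chromdom as cd

#: analysis parameters matched to the 256x256-pixel synthetic field of view
#: (the nucleus size gate scales with image area; the shift search window
#: just needs to cover the generator's systematic offset)
SMALL_FIELD_CONFIG = dict(min_nucleus_px=5000, max_shift=6, alignment_max_slides=3)


@pytest.fixture(scope="session")
def ed_stack():
    """One estrogen-deprived-like synthetic stack plus ground truth."""
    return cd.generate_stack(cd.ed_like_spec(), grid_shape=(10, 256, 256), seed=11)


@pytest.fixture(scope="session")
def ed_analysis(ed_stack):
    """Full pipeline result on the shared ED-like stack."""
    stack, _ = ed_stack
    return cd.analyze_stack(stack, cd.RunConfig(**SMALL_FIELD_CONFIG))


def ball_voxels(radius: int, center=None) -> np.ndarray:
    """Integer voxel coordinates of a digitized ball."""
    r = int(np.ceil(radius))
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    inside = zz**2 + yy**2 + xx**2 <= radius**2
    coords = np.argwhere(inside)
    if center is not None:
        coords = coords - r + np.asarray(center)
    return coords


def capsule_voxels(radius: float, half_len: float, axis=(0, 0, 1)) -> np.ndarray:
    """Voxel coordinates of a digitized capsule along ``axis``."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    ext = int(np.ceil(radius + half_len)) + 1
    zz, yy, xx = np.mgrid[-ext : ext + 1, -ext : ext + 1, -ext : ext + 1]
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    t = np.clip(pts @ axis, -half_len, half_len)
    d2 = ((pts - t[..., None] * axis) ** 2).sum(axis=-1)
    return np.argwhere(d2 <= radius**2)
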