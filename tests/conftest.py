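import numpy as np
import pytest

from cdseg.backbone import tiny_backbone
from cdseg.imaging_io import PreprocessConfig
from cdseg.phantom_gen import PhantomConfig, generate_phantom
from cdseg.segmentation_model import ModelConfig, SegmentationModel


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def phantom(phantom_config):
    """One default phantom volume with ground-truth mask."""
    return generate_phantom(phantom_config, seed=11)


@pytest.fixture(scope="session")
def small_backbone():
    """Tiny frozen extractor used throughout the tests (stride 8, 32 channels)."""
    return tiny_backbone(seed=5, channels=32, stride=8)


@pytest.fixture(scope="session")
def preprocess_config():
    return PreprocessConfig(
        target_slice_size=(64, 64), intensity_window=None, normalization="zscore"
    )


@pytest.fixture()
def small_model(small_backbone):
    cfg = ModelConfig(head_channels=16, decoder_channels=(16, 8, 8, 8, 8), dropout_rate=0.0)
    return SegmentationModel(small_backbone, cfg, seed=2)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (four nested loops / all-pairs), kept free
# of the package's vectorized implementations.
# ---------------------------------------------------------------------------


def cosine_map_oracle(fx, fy, eps=1e-8):
    C, H, W = fx.shape
    _, I, J = fy.shape
    out = np.zeros((H, W, I, J))
    for h in range(H):
        for w in range(W):
            for i in range(I):
                for j in range(J):
                    a, b = fx[:, h, w], fy[:, i, j]
                    out[h, w, i, j] = float(
                        np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b) + eps)
                    )
    return out


def center_oracle(x):
    out = np.empty_like(x)
    H, W, I, J = x.shape
    for h in range(H):
        for w in range(W):
            out[h, w] = x[h, w] - x[h, w].mean()
    return out


def correspondence_loss_oracle(fx, fy, hx, hy, b, eps=1e-8):
    s = center_oracle(cosine_map_oracle(fx, fy, eps))
    xc = cosine_map_oracle(hx, hy, eps)
    total, count = 0.0, 0
    H, W, I, J = s.shape
    for h in range(H):
        for w in range(W):
            for i in range(I):
                for j in range(J):
                    total += (s[h, w, i, j] - b) * max(xc[h, w, i, j], 0.0)
                    count += 1
    return -total / count


def surface_voxels_oracle(mask):
    """Foreground voxels with a background 6-neighbor, by explicit looping."""
    coords = []
    zz, yy, xx = mask.shape
    for z in range(zz):
        for y in range(yy):
            for x in range(xx):
                if not mask[z, y, x]:
                    continue
                for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    nz, ny, nx = z + dz, y + dy, x + dx
                    if not (0 <= nz < zz and 0 <= ny < yy and 0 <= nx < xx) or not mask[nz, ny, nx]:
                        coords.append((z, y, x))
                        break
    return np.array(coords, dtype=float)


def surface_distance_oracle(pred, ref, spacing):
    """All-pairs ASSD/MSSD between surface voxel sets, in mm."""
    sp = surface_voxels_oracle(pred) * np.asarray(spacing)
    sr = surface_voxels_oracle(ref) * np.asarray(spacing)
    d = np.sqrt(((sp[:, None, :] - sr[None, :, :]) ** 2).sum(-1))
    d_pr = d.min(axis=1)
    d_rp = d.min(axis=0)
    assd = 0.5 * (d_pr.mean() + d_rp.mean())
    mssd = max(d_pr.max(), d_rp.max())
    return assd, mssd
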