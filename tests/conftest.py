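import numpy as np
import pytest

from dyespec import (
    CalibrationConfig,
    builtin_dye_library,
    default_grid,
    default_illumination,
    default_layout,
)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def noiseless_illum(grid):
    return default_illumination(grid, noise_sd=0.0)


@pytest.fixture(scope="session")
def library():
    return builtin_dye_library()


@pytest.fixture(scope="session")
def cal_cfg():
    return CalibrationConfig()


def glcm_metrics_bruteforce(img, mask=None):
    """Independent oracle: exhaustive double-loop horizontal pair enumeration."""
    img = np.asarray(img)
    rows, cols = img.shape
    pairs = []
    for r in range(rows):
        for c in range(cols - 1):
            if mask is None or (mask[r, c] and mask[r, c + 1]):
                pairs.append((int(img[r, c]), int(img[r, c + 1])))
    n = len(pairs)
    contrast = sum((i - j) ** 2 for i, j in pairs) / n
    homogeneity = sum(1.0 / (1 + abs(i - j)) for i, j in pairs) / n
    return contrast, homogeneity, n


def diff_histogram_bruteforce(img):
    """Independent oracle: multiset of |left - right| over all horizontal pairs."""
    img = np.asarray(img).astype(int)
    out = {}
    for r in range(img.shape[0]):
        for c in range(img.shape[1] - 1):
            d = abs(img[r, c] - img[r, c + 1])
            out[d] = out.get(d, 0) + 1
    return out
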