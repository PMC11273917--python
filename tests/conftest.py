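import numpy as np
import pytest

from pfstain import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def palette():
    return sd.StainPalette()


@pytest.fixture(scope="session")
def small_set():
    """A small unpaired 64x64 training set with ground-truth labels."""
    return sd.make_unpaired_training_set(30, 30, 0.5, seed=7, patch_size=64)


def flood_fill_area(mask: np.ndarray, connectivity: int) -> int:
    """Independent largest-component oracle: BFS flood fill."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    best = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            queue = [(r0, c0)]
            seen[r0, c0] = True
            area = 0
            while queue:
                r, c = queue.pop()
                area += 1
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            best = max(best, area)
    return best
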