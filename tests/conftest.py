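import numpy as np
import pytest

import focusctu as f


@pytest.fixture(scope="session")
def small_phantom():
    """Reference small-scale phantom (no gaps, two lesions, known misalignment)."""
    return f.generate_phantom(f.default_spec("small"))


@pytest.fixture(scope="session")
def gapped_phantom():
    """Phantom with a single 15 mm unopacified gap in the left ureter."""
    spec = f.random_spec(seed=11, n_gaps=1, gap_length_range=(15.0, 15.0))
    return f.generate_phantom(spec)


def flood_fill_components(mask: np.ndarray) -> np.ndarray:
    """Independent connected-component oracle: breadth-first flood fill
    under 26-connectivity, written without scipy labeling."""
    from collections import deque

    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nz < mask.shape[2]
                    and mask[nx, ny, nz]
                    and not labels[nx, ny, nz]
                ):
                    labels[nx, ny, nz] = current
                    queue.append((nx, ny, nz))
    return labels


def single_component_contains(mask: np.ndarray, *seeds: np.ndarray) -> bool:
    """True iff every seed mask intersects one and the same flood-fill component."""
    labels = flood_fill_components(mask)
    ids = set()
    for seed in seeds:
        hit = np.unique(labels[np.asarray(seed, dtype=bool) & (labels > 0)])
        if len(hit) == 0:
            return False
        ids.update(hit.tolist())
    return len(ids) == 1 and labels.max() == 1
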