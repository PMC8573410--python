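import numpy as np
import pytest

from chiasmseg.phantom import PhantomParams, make_phantom
from chiasmseg.volgrid import BinaryMask, Volume


@pytest.fixture(scope="session")
def clean_phantom():
    """One noise-free, blur-free phantom shared across tests."""
    return make_phantom(PhantomParams(seed=11, noise_sd=0.0, blur_sd=0.0))


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomParams(seed=11))


def random_mask(rng: np.random.Generator, shape=(8, 8, 8), p=0.3) -> BinaryMask:
    return BinaryMask((rng.random(shape) < p).astype(np.uint8))


def flood_fill_components(arr: np.ndarray, connectivity: int) -> list[set[int]]:
    """Brute-force connected components by explicit flood fill.

    Independent of scipy labelling: neighbours are enumerated from the
    connectivity definition (6: faces, 18: +edges, 26: +corners).
    """
    shape = arr.shape
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if (connectivity == 6 and order > 1) or (
                    connectivity == 18 and order > 2
                ):
                    continue
                offsets.append((dz, dy, dx))
    seen = np.zeros(shape, dtype=bool)
    comps = []
    coords = np.argwhere(arr > 0)
    for start in map(tuple, coords):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = set()
        while stack:
            v = stack.pop()
            comp.add(int(np.ravel_multi_index(v, shape)))
            for off in offsets:
                nb = tuple(v[i] + off[i] for i in range(3))
                if all(0 <= nb[i] < shape[i] for i in range(3)) and arr[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(comp)
    return comps
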