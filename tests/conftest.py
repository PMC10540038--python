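import numpy as np
import pytest

import pvsquant as pq


@pytest.fixture(scope="session")
def tube_phantom():
    """64^3 phantom with 12 random tubes at the reference noise level."""
    spec = pq.PhantomSpec(shape=(64, 64, 64), seed=11)
    rng = np.random.default_rng(11)
    spec.tubes = pq.synthetic.random_tubes(12, spec, rng)
    vol, truth = pq.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def segmented_phantom(tube_phantom):
    """The tube phantom pushed through ROI + denoise + Frangi + IQR."""
    _, vol, truth = tube_phantom
    roi, wmh = pq.build_pvs_roi(truth.tissue_labels)
    den = pq.denoise_nlm(vol)
    vmap = pq.frangi_vesselness(den, roi, pq.FrangiParams())
    svmap = pq.iqr_standardize(vmap, roi)
    return truth, roi, wmh, vmap, svmap


def flood_fill_label(field: np.ndarray, connectivity: int = 26,
                     min_size: int = 1):
    """Brute-force BFS connected-component oracle.

    Returns (component list as sets of index triples, retained voxel count)
    after dropping components smaller than min_size.
    """
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    field = np.asarray(field, dtype=bool)
    seen = np.zeros_like(field, dtype=bool)
    comps = []
    nx, ny, nz = field.shape
    for idx in np.argwhere(field):
        start = tuple(idx)
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = {start}
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if (0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz
                        and field[p] and not seen[p]):
                    seen[p] = True
                    comp.add(p)
                    stack.append(p)
        comps.append(comp)
    kept = [c for c in comps if len(c) >= min_size]
    return kept, sum(len(c) for c in kept)
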