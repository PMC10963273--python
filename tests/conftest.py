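import numpy as np
import pytest

import fosmap as fm


@pytest.fixture
def flat_volume():
    """5x5x5 constant background of 100 with a single 25%-excess center peak."""
    data = np.full((5, 5, 5), 100.0)
    data[2, 2, 2] = 125.0
    return fm.Volume3D(data)


@pytest.fixture(scope="session")
def small_snrnaseq():
    """One seeded simulated snRNA-seq dataset shared across tests."""
    spec = fm.SnRnaSimSpec(n_genes=200, n_cells=1200, n_clusters=4, seed=11)
    adata, effects = fm.generate_snrnaseq(spec)
    return spec, adata, effects


def brute_force_detect(volume, mask, threshold_fraction=0.20, mode="each-neighbor"):
    """Literal triple-loop 26-neighbor reference detector (test oracle)."""
    data = np.asarray(volume, dtype=float)
    out = np.zeros(data.shape, dtype=bool)
    Z, Y, X = data.shape
    factor = 1.0 + threshold_fraction
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                neighbors = []
                interior = True
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if not (0 <= zz < Z and 0 <= yy < Y and 0 <= xx < X):
                                interior = False
                                break
                            if not mask[zz, yy, xx]:
                                interior = False
                                break
                            neighbors.append(data[zz, yy, xx])
                        if not interior:
                            break
                    if not interior:
                        break
                if not interior or not mask[z, y, x]:
                    continue
                v = data[z, y, x]
                if mode == "each-neighbor":
                    out[z, y, x] = all(v >= factor * u and v > u for u in neighbors)
                else:
                    m = sum(neighbors) / 26.0
                    out[z, y, x] = v >= factor * m and v > m
    return out


def brute_force_components(mask, connectivity=26):
    """Flood-fill connected components of a boolean grid (test oracle)."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                manhattan = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offsets.append((dz, dy, dx))
    seen = np.zeros(mask.shape, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for dz, dy, dx in offsets:
                u = (v[0] + dz, v[1] + dy, v[2] + dx)
                if all(0 <= u[i] < mask.shape[i] for i in range(3)) and mask[u] and not seen[u]:
                    seen[u] = True
                    stack.append(u)
        components.append(frozenset(comp))
    return components
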