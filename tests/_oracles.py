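"""Independent brute-force oracles used by the unit and acceptance tests.

Every function here recomputes a quantity by direct enumeration, staying
deliberately naive and separate from the library implementations it checks.
"""

import itertools

import numpy as np


def entropy_oracle(img: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel histogram entropy by explicit neighbourhood construction."""
    half = window // 2
    padded = np.pad(img, half, mode="symmetric")
    out = np.zeros(img.shape, dtype=np.float64)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            patch = padded[y:y + window, x:x + window].ravel()
            counts = np.bincount(patch, minlength=256)
            p = counts[counts > 0] / patch.size
            out[y, x] = -(p * np.log2(p)).sum()
    return out


def otsu_oracle(values: np.ndarray):
    """Exhaustive 256-threshold scan of the between-class-variance objective."""
    values = np.asarray(values).ravel().astype(np.float64)
    best_t, best_score = None, -1.0
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / values.size
        w1 = hi.size / values.size
        score = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if score > best_score + 1e-12:
            best_score, best_t = score, t
    return best_t


def energy_oracle(labels: np.ndarray, unary: np.ndarray, offsets,
                  weight_fn) -> float:
    """Term-by-term energy enumeration with explicit python loops.

    ``weight_fn(i_idx, j_idx, dist)`` returns the differing-label weight for
    a voxel pair given their (z, y, x) indices.
    """
    nz, ny, nx = labels.shape
    e = 0.0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                e += unary[z, y, x, labels[z, y, x]]
    for (dz, dy, dx), dist in offsets:
        for z in range(nz - dz):
            for y in range(ny - dy):
                for x in range(nx - dx):
                    i = (z, y, x)
                    j = (z + dz, y + dy, x + dx)
                    if labels[i] != labels[j]:
                        e += weight_fn(i, j, dist)
    return e


def exhaustive_min_energy(unary_flat: np.ndarray, edges) -> float:
    """Global minimum over all 3^n labellings of a small lattice.

    ``unary_flat`` is (n, 3); ``edges`` is a list of (i, j, w) with flat
    voxel indices.
    """
    n = unary_flat.shape[0]
    labellings = np.array(list(itertools.product(range(3), repeat=n)))
    e = unary_flat[np.arange(n)[None, :], labellings].sum(axis=1)
    for i, j, w in edges:
        e = e + w * (labellings[:, i] != labellings[:, j])
    return float(e.min())


def min_cut_oracle(cap: np.ndarray, source: int, sink: int) -> float:
    """Minimum s-t cut by enumerating every internal node partition."""
    n = cap.shape[0]
    internal = [v for v in range(n) if v not in (source, sink)]
    best = np.inf
    for bits in itertools.product([0, 1], repeat=len(internal)):
        side = np.zeros(n, dtype=bool)
        side[source] = True
        for v, b in zip(internal, bits):
            side[v] = bool(b)
        value = cap[np.ix_(side, ~side)].sum()
        best = min(best, value)
    return float(best)


def contact_oracle(labels: np.ndarray) -> int:
    """Brute-force tumour/CAF adjacency scan (both endpoints counted)."""
    nz, ny, nx = labels.shape
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
               (0, 0, -1)]
    count = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                lab = labels[z, y, x]
                if lab not in (1, 2):
                    continue
                other = 2 if lab == 1 else 1
                for dz, dy, dx in offsets:
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx \
                            and labels[zz, yy, xx] == other:
                        count += 1
                        break
    return count
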