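"""Shared test utilities, including independent oracles.

The flood oracle here deliberately re-implements marker-controlled flooding
with a linear-scan frontier (no heap): the same (altitude, insertion order)
semantics reached through a different data structure, so agreement with the
package's implementation is a meaningful cross-check.
"""

from __future__ import annotations

import numpy as np


def flood_oracle(
    flood: np.ndarray, seeds: np.ndarray, mask: np.ndarray, connectivity: int = 26
) -> np.ndarray:
    """Brute-force priority flood: frontier kept as a list, min() per step."""
    flood = np.asarray(flood, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    nz, ny, nx = flood.shape
    if connectivity == 6:
        offsets = [(-1, 0, 0), (0, -1, 0), (0, 0, -1), (0, 0, 1), (0, 1, 0), (1, 0, 0)]
    else:
        offsets = sorted(
            (dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        )
    labels = np.zeros_like(flood, dtype=np.int64)
    frontier: list[tuple[float, int, int, int, int, int]] = []
    counter = 0
    coords = np.argwhere(seeds > 0)
    if len(coords):
        ids = seeds[coords[:, 0], coords[:, 1], coords[:, 2]]
        order = np.argsort(ids, kind="stable")
        for (z, y, x), sid in zip(coords[order], ids[order]):
            if not mask[z, y, x]:
                continue
            labels[z, y, x] = sid
            frontier.append((flood[z, y, x], counter, int(sid), int(z), int(y), int(x)))
            counter += 1
    while frontier:
        entry = min(frontier)
        frontier.remove(entry)
        _, _, sid, z, y, x = entry
        for dz, dy, dx in offsets:
            zn, yn, xn = z + dz, y + dy, x + dx
            if 0 <= zn < nz and 0 <= yn < ny and 0 <= xn < nx:
                if mask[zn, yn, xn] and labels[zn, yn, xn] == 0:
                    labels[zn, yn, xn] = sid
                    frontier.append((flood[zn, yn, xn], counter, sid, zn, yn, xn))
                    counter += 1
    return labels


def random_flood_instance(rng: np.random.Generator, max_dim: int = 20):
    """A random (flood, seeds, mask) triple with abundant altitude ties."""
    dims = tuple(int(rng.integers(4, max_dim + 1)) for _ in range(3))
    flood = rng.integers(0, 5, size=dims).astype(float)
    mask = rng.random(dims) < 0.65
    n_seeds = int(rng.integers(1, 6))
    seeds = np.zeros(dims, dtype=np.int64)
    for sid in range(1, n_seeds + 1):
        z, y, x = (int(rng.integers(0, d)) for d in dims)
        seeds[z, y, x] = sid
    return flood, seeds, mask


def direct_conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Naive same-padding cross-correlation; oracle for the FFT convolution."""
    n, c, D, H, W = x.shape
    f, _, k, _, _ = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    y = np.zeros((n, f, D, H, W))
    for ni in range(n):
        for fi in range(f):
            for z in range(D):
                for yy in range(H):
                    for xx in range(W):
                        y[ni, fi, z, yy, xx] = (
                            xp[ni, :, z:z + k, yy:yy + k, xx:xx + k] * w[fi]
                        ).sum() + b[fi]
    return y


def huang_objective_bruteforce(image: np.ndarray, nbins: int = 256):
    """Direct evaluation of the fuzzy-entropy criterion at every threshold.

    Independent of the vectorized implementation: loops over thresholds and
    histogram bins, recomputing class means from scratch.
    """
    img = np.asarray(image, dtype=float).ravel()
    lo, hi = img.min(), img.max()
    hist, edges = np.histogram(img, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    C = hi - lo
    best_t, best_val = None, np.inf
    for t in range(nbins):
        w0 = hist[: t + 1].sum()
        w1 = hist[t + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * centers[: t + 1]).sum() / w0
        mu1 = (hist[t + 1:] * centers[t + 1:]).sum() / w1
        total = 0.0
        for g in range(nbins):
            mu = mu0 if g <= t else mu1
            u = 1.0 / (1.0 + abs(centers[g] - mu) / C)
            u = min(max(u, 1e-12), 1 - 1e-12)
            total += hist[g] * (-u * np.log(u) - (1 - u) * np.log(1 - u))
        if total < best_val:
            best_val, best_t = total, t
    return float(edges[best_t + 1]), best_val


def percentile_bootstrap_ci_oracle(values, n_boot, seed):
    """Second implementation of the percentile bootstrap CI of the median."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    medians = []
    for _ in range(n_boot):
        sample = values[rng.integers(0, len(values), size=len(values))]
        medians.append(np.median(sample))
    return float(np.percentile(medians, 2.5)), float(np.percentile(medians, 97.5))
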