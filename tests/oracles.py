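"""Independent brute-force oracles used to verify the library.

Everything here is deliberately naive (nested loops, iterate-to-stability,
exhaustive search) and shares no code with the package internals.
"""

from collections import deque

import numpy as np


def iterated_support(offsets, lam):
    """Support of the lam-fold iterated structuring element: all sums of
    lam offsets (lam = 0 gives just the origin)."""
    support = {(0, 0, 0)}
    for _ in range(lam):
        support = {tuple(np.add(s, o)) for s in support for o in offsets}
    return sorted(support)


def brute_min_filter(f, offsets, lam):
    """Erosion oracle: voxelwise min of f over the in-domain iterated
    support."""
    f = np.asarray(f)
    support = iterated_support(offsets, lam)
    out = np.empty_like(f)
    for p in np.ndindex(f.shape):
        vals = []
        for off in support:
            q = tuple(np.add(p, off[-f.ndim:]))
            if all(0 <= c < s for c, s in zip(q, f.shape)):
                vals.append(f[q])
        out[p] = min(vals)
    return out


def brute_max_filter(f, offsets, lam):
    """Dilation oracle: voxelwise max over the reflected iterated support."""
    f = np.asarray(f)
    reflected = [tuple(-np.asarray(o)) for o in offsets]
    support = iterated_support(reflected, lam)
    out = np.empty_like(f)
    for p in np.ndindex(f.shape):
        vals = []
        for off in support:
            q = tuple(np.add(p, off[-f.ndim:]))
            if all(0 <= c < s for c, s in zip(q, f.shape)):
                vals.append(f[q])
        out[p] = max(vals)
    return out


def iterate_reconstruction(marker, reference, offsets, max_iter=100_000):
    """Geodesic reconstruction by dilation oracle: dilate the marker one unit
    step along the offset graph, clamp by the reference, repeat until stable.
    """
    g = np.asarray(marker).astype(np.int64)
    ref = np.asarray(reference).astype(np.int64)
    for _ in range(max_iter):
        d = brute_max_filter(g, offsets, 1)
        nxt = np.minimum(ref, np.maximum(g, d))
        if np.array_equal(nxt, g):
            return nxt.astype(np.uint8)
        g = nxt
    raise RuntimeError("reconstruction oracle did not converge")


def flood_fill_maxima(f, offsets):
    """Regional maxima oracle: flood-fill every flat zone and keep those with
    no strictly brighter neighbour. Returns a set of frozensets of voxel
    coordinates."""
    f = np.asarray(f)
    nd = f.ndim
    offs = [tuple(o[-nd:]) for o in offsets]
    offs = [o for o in offs if any(o)]
    visited = np.zeros(f.shape, bool)
    maxima = set()
    for start in np.ndindex(f.shape):
        if visited[start]:
            continue
        level = f[start]
        comp = []
        queue = deque([start])
        visited[start] = True
        is_max = True
        while queue:
            p = queue.popleft()
            comp.append(p)
            for off in offs:
                q = tuple(np.add(p, off))
                if any(c < 0 or c >= s for c, s in zip(q, f.shape)):
                    continue
                if f[q] == level:
                    if not visited[q]:
                        visited[q] = True
                        queue.append(q)
                elif f[q] > level:
                    is_max = False
        if is_max:
            maxima.add(frozenset(comp))
    return maxima


def leveling_step_oracle(f, g, alpha, offsets):
    """One lower-leveling step computed by explicit voxel loops:
    f ^ [g v (delta_1(g) - alpha)] with the subtraction clamped at 0."""
    f = np.asarray(f).astype(np.int64)
    g = np.asarray(g).astype(np.int64)
    nd = f.ndim
    offs = [tuple(-np.asarray(o)[-nd:]) for o in offsets]
    out = np.empty_like(f)
    for p in np.ndindex(f.shape):
        best = 0
        for off in offs:
            q = tuple(np.add(p, off))
            if all(0 <= c < s for c, s in zip(q, f.shape)):
                best = max(best, g[q])
        prop = max(best - alpha, 0)
        out[p] = min(f[p], max(g[p], prop))
    return out.astype(np.uint8)


def otsu_exhaustive(values):
    """Otsu oracle: try every split t in 0..254 of the 256-bin histogram and
    return the lowest t maximising the between-class variance."""
    hist = np.bincount(np.asarray(values).ravel(), minlength=256)
    total = hist.sum()
    best_t, best_var = None, -1.0
    levels = np.arange(256)
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            var = 0.0
        else:
            mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
            mu1 = (hist[t + 1:] * levels[t + 1:]).sum() / w1
            var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var = var
            best_t = t
    return best_t
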