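"""Independent brute-force oracles.

Deliberately naive reimplementations (double loops, full enumeration) used
only to cross-check the package's optimised code paths; they share no code
with the implementation.
"""

import itertools
import math

import numpy as np


def brute_force_ball_opening(raster: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening by a ball structuring element, per-pixel double loop.

    Edge handling replicates 'nearest' padding: out-of-bounds neighbours take
    the nearest edge pixel's value.
    """
    img = np.asarray(raster, dtype=float)
    h, w = img.shape
    r_int = int(math.floor(radius))
    offsets = []
    for dy in range(-r_int, r_int + 1):
        for dx in range(-r_int, r_int + 1):
            if dx * dx + dy * dy <= radius * radius:
                b = math.sqrt(radius * radius - dx * dx - dy * dy) - radius
                offsets.append((dy, dx, b))

    def clamp(v, lo, hi):
        return max(lo, min(hi, v))

    eroded = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            eroded[y, x] = min(
                img[clamp(y + dy, 0, h - 1), clamp(x + dx, 0, w - 1)] - b
                for dy, dx, b in offsets)
    opened = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            opened[y, x] = max(
                eroded[clamp(y - dy, 0, h - 1), clamp(x - dx, 0, w - 1)] + b
                for dy, dx, b in offsets)
    return opened


def exhaustive_otsu(raster: np.ndarray):
    """Best 256-bin threshold by direct scan over every candidate split.

    Returns (bin_index, threshold_value): the lowest bin index maximising the
    between-class variance computed directly from the two classes.
    """
    img = np.asarray(raster, dtype=float).ravel()
    vmin, vmax = img.min(), img.max()
    hist, edges = np.histogram(img, bins=256, range=(vmin, vmax))
    centers = np.arange(256)
    best_k, best_var = None, -1.0
    total = hist.sum()
    for k in range(255):
        n0 = hist[:k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[:k + 1] * centers[:k + 1]).sum() / n0
        mu1 = (hist[k + 1:] * centers[k + 1:]).sum() / n1
        var = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_k = var, k
    return best_k, float(edges[best_k + 1])


def flood_fill_label(mask: np.ndarray, connectivity: int):
    """Connected-component labelling by breadth-first flood fill."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for y in range(h):
        for x in range(w):
            if m[y, x] and labels[y, x] == 0:
                current += 1
                stack = [(y, x)]
                labels[y, x] = current
                while stack:
                    cy, cx = stack.pop()
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and m[ny, nx] and labels[ny, nx] == 0:
                            labels[ny, nx] = current
                            stack.append((ny, nx))
    return labels, current


def component_stats(labels: np.ndarray, n: int):
    """(area, centroid) per flood-fill component, centroids at pixel centres."""
    stats = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        stats.append((len(ys), (xs.mean() + 0.5, ys.mean() + 0.5)))
    return stats


def winding_number_inside(point, poly, tol=1e-9) -> bool:
    """Point-in-polygon by winding number; boundary counts as inside."""
    px, py = float(point[0]), float(point[1])
    p = np.asarray(poly, dtype=float)
    n = len(p)
    # boundary check
    for i in range(n):
        x1, y1 = p[i]
        x2, y2 = p[(i + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            continue
        t = ((px - x1) * dx + (py - y1) * dy) / seg2
        cross = (px - x1) * dy - (py - y1) * dx
        if abs(cross) <= tol * math.sqrt(seg2) and -tol <= t <= 1 + tol:
            return True
    winding = 0.0
    for i in range(n):
        v1 = p[i] - (px, py)
        v2 = p[(i + 1) % n] - (px, py)
        ang = math.atan2(v1[0] * v2[1] - v1[1] * v2[0], v1 @ v2)
        winding += ang
    return abs(winding) > math.pi  # ~2*pi inside, ~0 outside


def permutation_ranksum_p(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating every group assignment,
    computing midranks by sorting from scratch."""
    a = list(map(float, a))
    b = list(map(float, b))
    combined = a + b
    n, n_a = len(combined), len(a)
    # midranks
    order = sorted(range(n), key=lambda i: combined[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and combined[order[j + 1]] == combined[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    w_obs = sum(ranks[:n_a])
    mu = n_a * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), n_a):
        total += 1
        if abs(sum(ranks[i] for i in combo) - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def stepup_bh(pvalues):
    """Textbook BH step-up, computed per element from the definition:
    padj_i = min over {j : p_j >= p_i} of (m * p_j / rank_j), capped at 1."""
    p = list(map(float, pvalues))
    m = len(p)
    srt = sorted(p)
    out = []
    for pi in p:
        candidates = []
        for j, pj in enumerate(srt, start=1):
            if pj >= pi:
                candidates.append(m * pj / j)
        out.append(min(1.0, min(candidates)))
    return out
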