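"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written in the most naive way possible
(explicit loops, per-step recomputation from scratch) and shares no code
with the package implementation.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------- FCM

def naive_fcm(X, c, m, tol, max_iter, U0):
    """Loop-based fuzzy C-means from a given initial membership matrix.

    Returns (final objective, list of per-iteration objectives, final U).
    """
    X = [float(v) for v in X]
    n = len(X)
    U = [list(map(float, row)) for row in U0]
    trace = []
    prev = float("inf")
    for _ in range(max_iter):
        centers = []
        for i in range(c):
            num = sum((U[j][i] ** m) * X[j] for j in range(n))
            den = sum(U[j][i] ** m for j in range(n))
            centers.append(num / den)
        newU = []
        for j in range(n):
            d = [abs(centers[i] - X[j]) for i in range(c)]
            if any(v == 0 for v in d):
                row = [0.0] * c
                row[d.index(0.0)] = 1.0
            else:
                row = []
                for i in range(c):
                    s = sum((d[i] / d[k]) ** (2.0 / (m - 1.0)) for k in range(c))
                    row.append(1.0 / s)
            newU.append(row)
        U = newU
        J = sum(
            (U[j][i] ** m) * (centers[i] - X[j]) ** 2
            for i in range(c)
            for j in range(n)
        )
        trace.append(J)
        if J < tol or abs(prev - J) < tol:
            break
        prev = J
    return trace[-1], trace, np.asarray(U)


def naive_objective(U, centers, X, m):
    """Triple-loop evaluation of the FCM objective."""
    n, c = len(X), len(centers)
    return sum(
        (float(U[j][i]) ** m) * (float(centers[i]) - float(X[j])) ** 2
        for i in range(c)
        for j in range(n)
    )


def naive_centroids(U, X, m):
    """Double-loop membership-weighted centroids."""
    n = len(X)
    c = len(U[0])
    out = []
    for i in range(c):
        num = sum((float(U[j][i]) ** m) * float(X[j]) for j in range(n))
        den = sum(float(U[j][i]) ** m for j in range(n))
        out.append(num / den)
    return np.asarray(out)


# ------------------------------------------------- region growing

def naive_region_grow(img, seeds, maxdis, domain=None):
    """Exhaustive best-first region growing; mean recomputed from scratch.

    Scans every frontier pixel at every step; keeps one persistent frontier
    across seed restarts.  Returns (region set, list of batch means after
    each acceptance).
    """
    h, w = len(img), len(img[0])
    if domain is None:
        domain = [[True] * w for _ in range(h)]
    region = []
    region_set = set()
    frontier = set()
    means = []

    def mean():
        return sum(img[r][c] for r, c in region) / len(region)

    def add(r, c):
        region.append((r, c))
        region_set.add((r, c))
        frontier.discard((r, c))
        means.append(mean())
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and domain[rr][cc] and (rr, cc) not in region_set:
                frontier.add((rr, cc))

    for seed in seeds:
        if tuple(seed) not in region_set:
            add(*seed)
        while frontier:
            m = mean()
            best = None
            for (r, c) in sorted(frontier):
                d = abs(img[r][c] - m)
                if best is None or d < best[0]:
                    best = (d, r, c)
            if best[0] > maxdis:
                break
            add(best[1], best[2])
    return region_set, means


# ------------------------------------------------------ morphology

def disk_offsets(radius):
    out = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr * dr + dc * dc <= radius * radius:
                out.append((dr, dc))
    return out


def naive_erosion(mask, offsets):
    """Out-of-bounds counts as foreground (border-ignore convention)."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def naive_dilation(mask, offsets):
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            for dr, dc in offsets:
                rr, cc = r - dr, c - dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    out[r, c] = True
                    break
    return out


def naive_opening(mask, radius):
    off = disk_offsets(radius)
    return naive_dilation(naive_erosion(mask, off), off)


def naive_closing(mask, radius):
    off = disk_offsets(radius)
    return naive_erosion(naive_dilation(mask, off), off)


def naive_largest_component(mask):
    """Largest 4-connected component by breadth-first search."""
    h, w = mask.shape
    seen = np.zeros_like(mask)
    best = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = [(r0, c0)]
                seen[r0, c0] = True
                queue = [(r0, c0)]
                while queue:
                    r, c = queue.pop()
                    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            comp.append((rr, cc))
                            queue.append((rr, cc))
                if len(comp) > len(best):
                    best = comp
    out = np.zeros_like(mask)
    for r, c in best:
        out[r, c] = True
    return out


def naive_fill_holes(mask):
    """Background connected to the border stays; enclosed background fills."""
    h, w = mask.shape
    outside = np.zeros_like(mask)
    queue = []
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.pop()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not outside[rr, cc]:
                outside[rr, cc] = True
                queue.append((rr, cc))
    return mask | ~outside


# -------------------------------------------------- rasterization

def point_in_polygon_evenodd(r, c, vertices):
    """Classic even-odd ray-casting test for a single point."""
    inside = False
    n = len(vertices)
    for i in range(n):
        y1, x1 = vertices[i]
        y2, x2 = vertices[(i + 1) % n]
        if (y1 > r) != (y2 > r):
            x_at = x1 + (r - y1) * (x2 - x1) / (y2 - y1)
            if c < x_at:
                inside = not inside
    return inside


# ---------------------------------------------- split-plot ANOVA

def balanced_split_plot(df, dv, between, within, subject):
    """Classical sums-of-squares split-plot ANOVA for equal group sizes.

    Returns dict of (ss, df, F) per effect, computed directly from cell and
    marginal means (textbook decomposition; valid for balanced designs).
    """
    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    k = df[within].nunique()
    genders = sorted(df[between].unique())
    levels = sorted(df[within].unique())
    subjects = sorted(df[subject].unique())
    n_s = len(subjects)

    subj_mean = df.groupby(subject)[dv].mean()
    g_of_subj = df.groupby(subject)[between].first()
    g_mean = df.groupby(between)[dv].mean()
    l_mean = df.groupby(within)[dv].mean()
    cell = df.groupby([between, within])[dv].mean()
    n_per_g = {g: (g_of_subj == g).sum() for g in genders}

    ss_between_subj = k * sum((subj_mean[s] - grand) ** 2 for s in subjects)
    ss_g = k * sum(n_per_g[g] * (g_mean[g] - grand) ** 2 for g in genders)
    ss_e1 = ss_between_subj - ss_g
    ss_l = n_s * sum((l_mean[le] - grand) ** 2 for le in levels)
    ss_i = sum(
        n_per_g[g] * (cell[(g, le)] - g_mean[g] - l_mean[le] + grand) ** 2
        for g in genders
        for le in levels
    )
    ss_tot = ((y - grand) ** 2).sum()
    ss_e2 = ss_tot - ss_between_subj - ss_l - ss_i

    df_g = len(genders) - 1
    df_e1 = n_s - len(genders)
    df_l = k - 1
    df_i = df_g * df_l
    df_e2 = df_e1 * df_l
    return {
        between: (ss_g, df_g, (ss_g / df_g) / (ss_e1 / df_e1)),
        f"subject({between})": (ss_e1, df_e1, None),
        within: (ss_l, df_l, (ss_l / df_l) / (ss_e2 / df_e2)),
        f"{between}:{within}": (ss_i, df_i, (ss_i / df_i) / (ss_e2 / df_e2)),
        "residual": (ss_e2, df_e2, None),
    }
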