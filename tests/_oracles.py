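"""Independent brute-force reference implementations used as oracles.

Everything here is written as plain double loops over trial pairs using
np.corrcoef, with its own sphere enumeration and cluster bookkeeping, so
it shares no code path with the package implementation it checks.
"""

import itertools

import numpy as np
from scipy import ndimage, stats

CLIP = 1.0 - 1e-7


def bf_z(x, y):
    """Fisher z of the Pearson correlation of two voxel vectors."""
    r = np.corrcoef(x, y)[0, 1]
    return np.arctanh(np.clip(r, -CLIP, CLIP))


def bf_sphere(radius_mm, voxel_mm):
    """All lattice offsets within the sphere, by exhaustive enumeration."""
    out = []
    m = int(np.ceil(radius_mm / voxel_mm)) + 1
    for d in itertools.product(range(-m, m + 1), repeat=3):
        if (np.array(d) ** 2).sum() * voxel_mm**2 <= radius_mm**2 + 1e-9:
            out.append(d)
    return sorted(out)


def bf_neighbors(center, grid_shape, mask_flat, radius_mm, voxel_mm):
    nbrs = []
    for d in bf_sphere(radius_mm, voxel_mm):
        p = tuple(np.array(center) + np.array(d))
        if all(0 <= p[i] < grid_shape[i] for i in range(3)):
            flat = np.ravel_multi_index(p, grid_shape)
            if mask_flat[flat]:
                nbrs.append(flat)
    return nbrs


def bf_item_metrics(patterns_td1, patterns_td2):
    """(within_item, between_item) means over a voxel subset.

    Row i of the two matrices is the same object's TD1 / TD2 pattern.
    """
    n = patterns_td1.shape[0]
    within = [bf_z(patterns_td1[i], patterns_td2[i]) for i in range(n)]
    between = [bf_z(patterns_td1[i], patterns_td2[j])
               for i in range(n) for j in range(n) if i != j]
    return np.mean(within), np.mean(between)


def bf_category_metrics(patterns_obj, runs_obj, patterns_scn):
    """(within_category, between_category) means; object pairs must come
    from different runs."""
    n = patterns_obj.shape[0]
    within = [bf_z(patterns_obj[i], patterns_obj[j])
              for i in range(n) for j in range(n)
              if i != j and runs_obj[i] != runs_obj[j]]
    between = [bf_z(patterns_obj[i], patterns_scn[j])
               for i in range(n) for j in range(patterns_scn.shape[0])]
    return np.mean(within), np.mean(between)


def bf_scene_contrast(patterns, runs, scene_of):
    """within-scene minus between-scene mean z over object pairs from
    different runs (one phase)."""
    n = patterns.shape[0]
    w, b = [], []
    for i in range(n):
        for j in range(n):
            if i == j or runs[i] == runs[j]:
                continue
            z = bf_z(patterns[i], patterns[j])
            (w if scene_of[i] == scene_of[j] else b).append(z)
    return np.mean(w) - np.mean(b)


def bf_trialwise_item(patterns_td1, patterns_td2):
    n = patterns_td1.shape[0]
    vals = []
    for i in range(n):
        within = bf_z(patterns_td1[i], patterns_td2[i])
        between = np.mean([bf_z(patterns_td1[i], patterns_td2[j])
                           for j in range(n) if j != i])
        vals.append(within - between)
    return np.array(vals)


def bf_trialwise_category(patterns_obj, runs, patterns_scn):
    n = patterns_obj.shape[0]
    vals = []
    for i in range(n):
        partners = [bf_z(patterns_obj[i], patterns_obj[j])
                    for j in range(n) if j != i and runs[i] != runs[j]]
        scenes = [bf_z(patterns_obj[i], patterns_scn[s])
                  for s in range(patterns_scn.shape[0])]
        vals.append(np.mean(partners) - np.mean(scenes))
    return np.array(vals)


def bf_exhaustive_signflip_null(diffs, grid_shape, alpha, connectivity=26):
    """Exhaustive sign-flip null of the max |cluster mass| for a paired
    design: all 2^n sign patterns, one-sample t per voxel, threshold at
    two-sided alpha, 3D components, mass = sum of t."""
    n = diffs.shape[0]
    t_crit = stats.t.ppf(1 - alpha / 2, n - 1)
    structure = (np.ones((3, 3, 3)) if connectivity == 26
                 else ndimage.generate_binary_structure(3, 1))
    out = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        d = diffs * np.array(signs)[:, None]
        m = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = m / (sd / np.sqrt(n))
        t = np.where(np.isfinite(t), t, 0.0).reshape(grid_shape)
        best = 0.0
        for sign in (1, -1):
            lab, k = ndimage.label(sign * t > t_crit, structure=structure)
            for c in range(1, k + 1):
                mass = abs(t[lab == c].sum())
                best = max(best, mass)
        out.append(best)
    return np.array(out)
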