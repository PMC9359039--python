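"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions (exhaustive loops, all-pairs
distances, direct objective minimisation) and shares no code path with the
package, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# surface metrics


def brute_surface_points(voxels: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)):
    """Border-voxel centres by explicit 6-neighbour scan (out-of-grid = false)."""
    nz, ny, nx = voxels.shape
    pts = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not voxels[z, y, x]:
                    continue
                border = False
                for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx) \
                            or not voxels[zz, yy, xx]:
                        border = True
                        break
                if border:
                    pts.append([origin[0] + z * spacing[0],
                                origin[1] + y * spacing[1],
                                origin[2] + x * spacing[2]])
    return np.asarray(pts, dtype=float).reshape(-1, 3)


def brute_directed(x_pts: np.ndarray, y_pts: np.ndarray) -> np.ndarray:
    """All-pairs nearest distances from each x point to the y set."""
    diff = x_pts[:, None, :] - y_pts[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)


def brute_metrics(vox_a, vox_b, spacing, taus=(1, 2, 3, 4, 5, 7, 10)):
    """All 11 metrics from first principles on one grid."""
    na, nb = int(vox_a.sum()), int(vox_b.sum())
    dsc = 2.0 * int((vox_a & vox_b).sum()) / (na + nb)
    X = brute_surface_points(vox_a, spacing)
    Y = brute_surface_points(vox_b, spacing)
    d_xy = brute_directed(X, Y)
    d_yx = brute_directed(Y, X)
    out = {
        "dsc": dsc,
        "hd_100": max(d_xy.max(), d_yx.max()),
        "hd_95": max(np.percentile(d_xy, 95.0), np.percentile(d_yx, 95.0)),
        "msd": np.concatenate([d_xy, d_yx]).mean(),
    }
    for tau in taus:
        out[f"sdsc_{tau}"] = ((d_xy <= tau).sum() + (d_yx <= tau).sum()) \
            / (len(X) + len(Y))
    return out


def random_mask_pair(rng: np.random.Generator, max_side: int = 20):
    """A random pair of non-empty blobby masks on a shared anisotropic grid."""
    shape = tuple(int(rng.integers(6, max_side + 1)) for _ in range(3))
    spacing = tuple(float(rng.uniform(0.5, 3.0)) for _ in range(3))
    masks = []
    for _ in range(2):
        vox = np.zeros(shape, dtype=bool)
        for _ in range(int(rng.integers(1, 4))):  # union of random boxes
            lo = [int(rng.integers(0, s - 1)) for s in shape]
            hi = [int(rng.integers(lo[i] + 1, shape[i] + 1)) for i in range(3)]
            vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        # random sprinkle of single voxels
        n_extra = int(rng.integers(0, 5))
        for _ in range(n_extra):
            idx = tuple(int(rng.integers(0, s)) for s in shape)
            vox[idx] = True
        masks.append(vox)
    return masks[0], masks[1], spacing


# ---------------------------------------------------------------------------
# classifier oracles


def hinge_threshold(values, labels, C):
    """1-D soft-margin SVM threshold by direct primal minimisation.

    Standardises the values (as the package contract states), minimises
    0.5 w^2 + C * sum(hinge) over (w, b) with Nelder-Mead from several
    starts (the objective is convex), and maps the boundary back to metric
    units.
    """
    v = np.asarray(values, dtype=float)
    mu, sd = v.mean(), v.std()
    x = (v - mu) / sd
    y = np.where(np.asarray(labels) == "unacceptable", 1.0, -1.0)

    def obj(p):
        w, b = p
        return 0.5 * w * w + C * np.maximum(0.0, 1.0 - y * (w * x + b)).sum()

    best = None
    for w0 in (-2.0, -0.5, 0.5, 2.0):
        for b0 in (-1.0, 0.0, 1.0):
            r = minimize(obj, [w0, b0], method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12,
                                  "maxiter": 20000, "maxfev": 20000})
            if best is None or r.fun < best.fun:
                best = r
    w, b = best.x
    return mu - b * sd / w


def pair_counting_auc(values, labels, flag_if_below=True):
    """AUC as the Mann-Whitney concordant-pair fraction (ties count 1/2)."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    score = -v if flag_if_below else v
    pos = score[y == "unacceptable"]
    neg = score[y == "acceptable"]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                conc += 1
            elif p == n:
                conc += 0.5
    return conc / total


def sweep_operating_point(values, labels, target, flag_if_below=True):
    """Best (specificity, then sensitivity) with sensitivity >= target, by
    brute force over every threshold placed just beside each value and
    beyond the range."""
    v = np.asarray(values, dtype=float)
    y = (np.asarray(labels) == "unacceptable").astype(int)
    eps = 1e-9 * max(1.0, np.abs(v).max())
    cands = np.concatenate([v - eps, v + eps,
                            [v.min() - 1.0, v.max() + 1.0]])
    best = None
    for t in cands:
        pred = (v < t).astype(int) if flag_if_below else (v > t).astype(int)
        sens = pred[y == 1].mean()
        spec = 1.0 - pred[y == 0].mean()
        acc = (pred == y).mean()
        if sens >= target and (best is None or (spec, sens) > best[:2]):
            best = (spec, sens, acc)
    return best  # (specificity, sensitivity, accuracy)
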