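"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's fitting code paths: the line oracle is
a spectral decomposition of the centered scatter, and the circle/ellipse
oracles are nested grid searches with successive refinement around the best
grid point, with the radius (circle) solved in closed form per grid point.
"""

import numpy as np


def spectral_line_direction(points):
    """TLS line direction via eigen-decomposition of the scatter matrix."""
    pts = np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    evals, evecs = np.linalg.eigh(centered.T @ centered)
    return evecs[:, np.argmax(evals)]


def circle_objective(points, center, normal, radius):
    d = points - center
    w = d @ normal
    q = np.sqrt(np.maximum(np.einsum("ij,ij->i", d, d) - w**2, 0.0))
    return float(np.sum((q - radius) ** 2 + w**2))


def grid_circle_objective(points, refinements=3):
    """Best sum of squared 3D point-to-circle distances found by grid search.

    Grid over center (3) and normal tilt (2); the optimal radius per grid
    point is the mean in-plane distance (closed form).  Refines the grid
    around the best point ``refinements`` times.
    """
    pts = np.asarray(points, float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    n0 = vt[2]
    t1, t2 = vt[0], vt[1]

    c_best = centroid.copy()
    uv_best = np.zeros(2)
    c_step, uv_step = 0.12, 0.05
    c_range, uv_range = 0.6, 0.25
    best_obj = np.inf
    for level in range(refinements + 1):
        c_off = np.arange(-c_range, c_range + 1e-12, c_step)
        centers = (c_best[None, :]
                   + np.stack(np.meshgrid(c_off, c_off, c_off, indexing="ij"),
                              axis=-1).reshape(-1, 3))
        uv_off = np.arange(-uv_range, uv_range + 1e-12, uv_step)
        d = pts[None, :, :] - centers[:, None, :]
        dd = np.einsum("cij,cij->ci", d, d)
        for du in uv_off:
            for dv in uv_off:
                u, v = uv_best[0] + du, uv_best[1] + dv
                n = n0 + u * t1 + v * t2
                n = n / np.linalg.norm(n)
                w = d @ n
                q = np.sqrt(np.maximum(dd - w**2, 0.0))
                r = q.mean(axis=1)
                obj = np.sum((q - r[:, None]) ** 2 + w**2, axis=1)
                i = int(np.argmin(obj))
                if obj[i] < best_obj:
                    best_obj = float(obj[i])
                    new_c = centers[i]
                    new_uv = np.array([u, v])
        c_best, uv_best = new_c, new_uv
        c_range, uv_range = 2.0 * c_step, 2.0 * uv_step
        c_step /= 5.0
        uv_step /= 5.0
    return best_obj


def ellipse_objective_2d(xy, cx, cy, a, b):
    dx = xy[:, 0] - cx
    dy = xy[:, 1] - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    boundary = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    return float(np.sum((r - boundary) ** 2))


def grid_ellipse_objective(xy, refinements=3):
    """Best sum of squared radial deviations of an axis-aligned ellipse.

    Grid over center (2) and radii (2), refined around the best point.
    """
    xy = np.asarray(xy, float)
    c0 = xy.mean(axis=0)
    centered = xy - c0
    a0 = np.sqrt(2.0) * centered[:, 0].std()
    b0 = np.sqrt(2.0) * centered[:, 1].std()
    best = np.array([c0[0], c0[1], a0, b0])
    step, rng = 0.1, 0.5
    best_obj = np.inf
    for level in range(refinements + 1):
        off = np.arange(-rng, rng + 1e-12, step)
        grids = [best[i] + off for i in range(4)]
        CX, CY, A, B = np.meshgrid(*grids, indexing="ij")
        params = np.stack([CX, CY, np.maximum(A, 0.05), np.maximum(B, 0.05)],
                          axis=-1).reshape(-1, 4)
        dx = xy[None, :, 0] - params[:, None, 0]
        dy = xy[None, :, 1] - params[:, None, 1]
        r = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        a = params[:, None, 2]
        b = params[:, None, 3]
        boundary = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        obj = np.sum((r - boundary) ** 2, axis=1)
        i = int(np.argmin(obj))
        if obj[i] < best_obj:
            best_obj = float(obj[i])
            best = params[i]
        rng = 2.0 * step
        step /= 5.0
    return best_obj


def two_sample_t_closed_form(x, y):
    """Pooled-variance two-sample t statistic and df, straight from the formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    return t, nx + ny - 2


def random_rigid_transform(rng):
    """Uniform random rotation (QR of a Gaussian matrix) plus a translation."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-50.0, 50.0, 3)
    return Q, t
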