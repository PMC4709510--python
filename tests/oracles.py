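"""Independent brute-force/high-precision oracles used by the tests.

These deliberately avoid the library's own code paths: the occlusal-plane
oracle is an exhaustive 2-parameter grid search, the projected-distance
oracle constructs the two coronal planes explicitly, and the angle oracle
evaluates the arccos at extended precision.
"""

import numpy as np


def grid_search_occlusal(points: np.ndarray, msp_normal: np.ndarray,
                         n_theta: int = 7200) -> float:
    """Minimum sum of squared point-plane residuals over all planes whose
    normal is perpendicular to ``msp_normal``, by brute-force sweep of the
    normal direction (the offset is optimal in closed form: the mean)."""
    n = msp_normal / np.linalg.norm(msp_normal)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(n @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - (seed @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    thetas = np.linspace(0.0, np.pi, n_theta, endpoint=False)
    normals = np.outer(np.cos(thetas), u) + np.outer(np.sin(thetas), v)
    proj = points @ normals.T                      # (n_pts, n_theta)
    resid = ((proj - proj.mean(axis=0)) ** 2).sum(axis=0)
    return float(resid.min())


def plane_construction_ap_distance(pa: np.ndarray, pb: np.ndarray,
                                   ap_axis: np.ndarray) -> float:
    """Distance between the two coronal planes (normal = ap axis) passing
    through the two landmarks: |signed distance of pb from the plane
    through pa|."""
    ap = ap_axis / np.linalg.norm(ap_axis)
    return abs(float((pb - pa) @ ap))


def angle_extended_precision(p, v, q) -> float:
    """Interior angle at v in degrees, evaluated in extended precision."""
    p, v, q = (np.asarray(x, dtype=np.longdouble) for x in (p, v, q))
    u1, u2 = p - v, q - v
    c = (u1 @ u2) / np.sqrt((u1 @ u1) * (u2 @ u2))
    c = min(max(c, np.longdouble(-1.0)), np.longdouble(1.0))
    return float(np.degrees(np.arccos(c)))


def random_rigid(rng: np.random.Generator):
    """A uniform random proper rotation and a translation."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    t = rng.uniform(-50.0, 50.0, size=3)
    return q, t
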