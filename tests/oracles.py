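"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's simulation and estimation code paths:
fields are simulated by dense covariance factorization, variograms and
indices by direct loops over pairs and definitions.
"""

import numpy as np


def dense_cov_matrix(model, points):
    """Joint (2n x 2n) covariance matrix in variable-major order, built from
    the model's semivariance (covariance = total sill - semivariance)."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    total = model.total_sill
    K = np.empty((2 * n, 2 * n))
    for i in range(n):
        for j in range(n):
            g = model.semivariance((points[i] - points[j])[None, :])[0]
            c = total - g
            for a in range(2):
                for b in range(2):
                    K[a * n + i, b * n + j] = c[a, b]
    return K


def dense_gaussian_cosimulation(model, points, n_real, rng):
    """Unconditional Gaussian cofields by Cholesky of the dense covariance."""
    n = np.asarray(points).shape[0]
    K = dense_cov_matrix(model, points)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(2 * n))
    out = np.empty((n_real, n, 2))
    for r in range(n_real):
        z = L @ rng.standard_normal(2 * n)
        out[r] = z.reshape(2, n).T
    return out


def dense_conditional_cosimulation(model, points, data_idx, data_vals, n_real, rng):
    """Conditional Gaussian cosimulation from the joint-normal conditional
    distribution (mean + Cholesky of the conditional covariance)."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    K = dense_cov_matrix(model, points)
    didx = np.concatenate([np.asarray(data_idx), n + np.asarray(data_idx)])
    free = np.setdiff1d(np.arange(2 * n), didx)
    Kdd = K[np.ix_(didx, didx)]
    Kfd = K[np.ix_(free, didx)]
    Kff = K[np.ix_(free, free)]
    d = np.asarray(data_vals, dtype=float).T.ravel()
    solve = np.linalg.solve(Kdd, d)
    mu = Kfd @ solve
    cov = Kff - Kfd @ np.linalg.solve(Kdd, Kfd.T)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(free.size))
    out = np.empty((n_real, n, 2))
    flat = np.empty(2 * n)
    for r in range(n_real):
        flat[didx] = d
        flat[free] = mu + L @ rng.standard_normal(free.size)
        out[r] = flat.reshape(2, n).T
    return out


def brute_variogram(xy, za, zb, azimuth_deg, lag_centres, lag_tol, ang_tol):
    """Direct double-loop implementation of the directional estimator."""
    xy = np.asarray(xy, float)
    n = len(xy)
    u = np.array([np.sin(np.deg2rad(azimuth_deg)), np.cos(np.deg2rad(azimuth_deg))])
    sums = np.zeros(len(lag_centres))
    counts = np.zeros(len(lag_centres), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            h = xy[j] - xy[i]
            d = np.hypot(*h)
            if d == 0:
                continue
            if abs(h @ u) / d < np.cos(np.deg2rad(ang_tol)) - 1e-12:
                continue
            for k, c in enumerate(lag_centres):
                if abs(d - c) <= lag_tol + 1e-12:
                    sums[k] += 0.5 * (za[j] - za[i]) * (zb[j] - zb[i])
                    counts[k] += 1
                    break
    gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return gamma, counts
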