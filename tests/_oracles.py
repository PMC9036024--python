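"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's vectorized code paths: texture
matrices are built by exhaustive voxel-pair / run enumeration, texture
features by literal scalar-loop formulas, Kaplan-Meier by explicit risk
sets, and the PLS direction by dense grid search on the unit sphere.
"""

import math

import numpy as np


def brute_glcm(levels, mask, offset, n_bins, symmetric=True):
    """Exhaustive co-occurrence counting over all voxel pairs."""
    P = np.zeros((n_bins, n_bins))
    shape = mask.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        j = tuple(a + b for a, b in zip(idx, offset))
        if all(0 <= c < s for c, s in zip(j, shape)) and mask[j]:
            P[levels[idx] - 1, levels[j] - 1] += 1
    if symmetric:
        P = P + P.T
    return P


def brute_rlm(levels, mask, direction, n_bins):
    """Exhaustive maximal-run enumeration along one direction."""
    shape = mask.shape
    runs = []
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        prev = tuple(a - b for a, b in zip(idx, direction))
        if (
            all(0 <= c < s for c, s in zip(prev, shape))
            and mask[prev]
            and levels[prev] == levels[idx]
        ):
            continue  # not a run start
        length, cur = 1, idx
        while True:
            nxt = tuple(a + b for a, b in zip(cur, direction))
            if (
                all(0 <= c < s for c, s in zip(nxt, shape))
                and mask[nxt]
                and levels[nxt] == levels[cur]
            ):
                length += 1
                cur = nxt
            else:
                break
        runs.append((levels[idx], length))
    R = np.zeros((n_bins, max(l for _, l in runs)))
    for g, l in runs:
        R[g - 1, l - 1] += 1
    return R


def _log2(x):
    return math.log2(x)


def oracle_glcm_features(P):
    """GLCM features via literal scalar loops on a count matrix."""
    n = P.shape[0]
    total = P.sum()
    p = P / total
    px = [sum(p[i][j] for j in range(n)) for i in range(n)]
    py = [sum(p[i][j] for i in range(n)) for j in range(n)]
    ux = sum((i + 1) * px[i] for i in range(n))
    uy = sum((j + 1) * py[j] for j in range(n))
    sx = math.sqrt(sum((i + 1 - ux) ** 2 * px[i] for i in range(n)))
    sy = math.sqrt(sum((j + 1 - uy) ** 2 * py[j] for j in range(n)))
    psum = {}
    pdiff = {}
    for i in range(n):
        for j in range(n):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i][j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i][j]
    da = sum(k * v for k, v in pdiff.items())
    hxy = -sum(v * _log2(v) for row in p for v in row if v > 0)
    hx = -sum(v * _log2(v) for v in px if v > 0)
    hy = -sum(v * _log2(v) for v in py if v > 0)
    hxy1 = -sum(
        p[i][j] * _log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if p[i][j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * _log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if px[i] * py[j] > 0
    )
    denom = max(hx, hy)
    out = {
        "glcm_autocorrelation": sum(
            (i + 1) * (j + 1) * p[i][j] for i in range(n) for j in range(n)
        ),
        "glcm_joint_average": ux,
        "glcm_cluster_prominence": sum(
            (i + j + 2 - ux - uy) ** 4 * p[i][j] for i in range(n) for j in range(n)
        ),
        "glcm_cluster_shade": sum(
            (i + j + 2 - ux - uy) ** 3 * p[i][j] for i in range(n) for j in range(n)
        ),
        "glcm_cluster_tendency": sum(
            (i + j + 2 - ux - uy) ** 2 * p[i][j] for i in range(n) for j in range(n)
        ),
        "glcm_contrast": sum(
            (i - j) ** 2 * p[i][j] for i in range(n) for j in range(n)
        ),
        "glcm_correlation": (
            (
                sum((i + 1) * (j + 1) * p[i][j] for i in range(n) for j in range(n))
                - ux * uy
            )
            / (sx * sy)
            if sx * sy > 0
            else 1.0
        ),
        "glcm_difference_average": da,
        "glcm_difference_entropy": -sum(
            v * _log2(v) for v in pdiff.values() if v > 0
        ),
        "glcm_difference_variance": sum(
            (k - da) ** 2 * v for k, v in pdiff.items()
        ),
        "glcm_joint_energy": sum(v**2 for row in p for v in row),
        "glcm_joint_entropy": hxy,
        "glcm_imc1": (hxy - hxy1) / denom if denom > 0 else 0.0,
        "glcm_imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "glcm_inverse_difference": sum(
            p[i][j] / (1 + abs(i - j)) for i in range(n) for j in range(n)
        ),
        "glcm_inverse_difference_normalized": sum(
            p[i][j] / (1 + abs(i - j) / n) for i in range(n) for j in range(n)
        ),
        "glcm_inverse_difference_moment": sum(
            p[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)
        ),
        "glcm_inverse_difference_moment_normalized": sum(
            p[i][j] / (1 + (i - j) ** 2 / n**2) for i in range(n) for j in range(n)
        ),
        "glcm_inverse_variance": sum(
            p[i][j] / (i - j) ** 2 for i in range(n) for j in range(n) if i != j
        ),
        "glcm_maximum_probability": max(v for row in p for v in row),
        "glcm_sum_entropy": -sum(v * _log2(v) for v in psum.values() if v > 0),
        "glcm_sum_of_squares": sum(
            (i + 1 - ux) ** 2 * p[i][j] for i in range(n) for j in range(n)
        ),
    }
    return out


def oracle_glrlm_features(R, n_voxels):
    """GLRLM features via literal scalar loops on a run-count matrix."""
    ng, nl = R.shape
    nr = R.sum()
    out = {
        "glrlm_short_run_emphasis": sum(
            R[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(nl)
        )
        / nr,
        "glrlm_long_run_emphasis": sum(
            R[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(nl)
        )
        / nr,
        "glrlm_gray_level_nonuniformity": sum(
            sum(R[i][j] for j in range(nl)) ** 2 for i in range(ng)
        )
        / nr,
        "glrlm_run_length_nonuniformity": sum(
            sum(R[i][j] for i in range(ng)) ** 2 for j in range(nl)
        )
        / nr,
        "glrlm_run_percentage": nr / n_voxels,
        "glrlm_low_gray_level_run_emphasis": sum(
            R[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(nl)
        )
        / nr,
        "glrlm_high_gray_level_run_emphasis": sum(
            R[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(nl)
        )
        / nr,
        "glrlm_short_run_low_gray_level_emphasis": sum(
            R[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
            for i in range(ng)
            for j in range(nl)
        )
        / nr,
        "glrlm_short_run_high_gray_level_emphasis": sum(
            R[i][j] * (i + 1) ** 2 / (j + 1) ** 2
            for i in range(ng)
            for j in range(nl)
        )
        / nr,
        "glrlm_long_run_low_gray_level_emphasis": sum(
            R[i][j] * (j + 1) ** 2 / (i + 1) ** 2
            for i in range(ng)
            for j in range(nl)
        )
        / nr,
        "glrlm_long_run_high_gray_level_emphasis": sum(
            R[i][j] * (i + 1) ** 2 * (j + 1) ** 2
            for i in range(ng)
            for j in range(nl)
        )
        / nr,
    }
    return out


def km_hand(times, events):
    """Kaplan-Meier by explicit risk sets: list of (time, survival)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    s = 1.0
    curve = [(0.0, 1.0)]
    for t in sorted(set(times[events])):
        n = (times >= t).sum()
        d = ((times == t) & events).sum()
        s *= 1.0 - d / n
        curve.append((t, s))
    return curve


def pls_grid_search(X, y, n_theta=400, n_phi=800):
    """Dense unit-sphere search for the 3-gene covariance-maximizing direction.

    X must be standardized (3 columns) and y centered.  Returns the best
    direction and its |covariance| with y.
    """
    theta = np.linspace(0, np.pi, n_theta)
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    W = np.stack(
        [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1
    ).reshape(-1, 3)
    cov = np.abs(W @ (X.T @ y))
    best = np.argmax(cov)
    return W[best], cov[best]
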