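"""Independent brute-force oracles for the geometry engine.

Everything here is coded from first principles (hand-built rotation
matrices, explicit argmax scans, spherical winding numbers, Monte-Carlo
surface integration) and deliberately shares no code with
``hipmorph.measure`` or ``hipmorph.frame``.
"""

import numpy as np


def rot_x_anterior(phi_deg: float) -> np.ndarray:
    """Rotation about the x-axis tipping +z toward +y for positive phi."""
    c, s = np.cos(np.deg2rad(phi_deg)), np.sin(np.deg2rad(phi_deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])


def lcea_closed_form(theta_deg: float, phi_deg: float) -> float:
    """Axisymmetric-cup LCEA under APP tilt: arctan(tan(theta)/cos(phi))."""
    th, ph = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    return float(np.degrees(np.arctan2(np.tan(th), np.cos(ph))))


def acea_closed_form(theta_deg: float, phi_deg: float, fp_deg: float = 65.0) -> float:
    """Axisymmetric-cup ACEA under APP tilt, from the explicit argmax over
    rim azimuth of the false-profile direction score."""
    th, ph, fp = map(np.deg2rad, (theta_deg, phi_deg, fp_deg))
    C, S = np.cos(fp), np.sin(fp)
    amp = np.hypot(C, S * np.cos(ph))
    sin_psi = S * np.cos(ph) / amp
    u_comp = np.sin(th) * amp + np.cos(th) * np.sin(ph) * S
    z_comp = -np.sin(th) * sin_psi * np.sin(ph) + np.cos(th) * np.cos(ph)
    return float(np.degrees(np.arctan2(u_comp, z_comp)))


def brute_lcea(rim_points, center, side_sign: float, phi_deg: float) -> float:
    """Exhaustive LCEA: rotate the rim about the x-line through the head
    center, scan all points for the most lateral one, angle from vertical."""
    P = (np.asarray(rim_points, float) - center) @ rot_x_anterior(phi_deg).T
    lat = side_sign * P[:, 0]
    e = P[np.argmax(lat)]
    return float(np.degrees(np.arctan2(side_sign * e[0], e[2])))


def brute_acea(rim_points, center, side_sign: float, phi_deg: float, fp_deg: float = 65.0) -> float:
    P = (np.asarray(rim_points, float) - center) @ rot_x_anterior(phi_deg).T
    fp = np.deg2rad(fp_deg)
    u = np.array([side_sign * np.cos(fp), np.sin(fp), 0.0])
    e = P[np.argmax(P @ u)]
    return float(np.degrees(np.arctan2(e @ u, e[2])))


def spherical_winding_inside(directions: np.ndarray, rim_dirs: np.ndarray) -> np.ndarray:
    """For each query direction, whether it lies inside the closed rim
    curve on the unit sphere (winding number of the rim's azimuths in the
    query point's tangent plane is +/-1)."""
    inside = np.empty(len(directions), dtype=bool)
    closed = np.vstack([rim_dirs, rim_dirs[:1]])
    for i, d in enumerate(directions):
        ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        t1 = ref - (ref @ d) * d
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(d, t1)
        az = np.arctan2(closed @ t2, closed @ t1)
        dpsi = np.diff(az)
        dpsi = (dpsi + np.pi) % (2 * np.pi) - np.pi
        inside[i] = abs(dpsi.sum()) > np.pi
    return inside


def mc_coverage(rim_points, center, radius, rng, n_samples: int = 60000) -> float:
    """Monte-Carlo horizontal-projection coverage of the superior
    hemisphere: projected area = integral of the vertical direction
    cosine over the covered superior surface, over pi r^2."""
    v = rng.standard_normal((n_samples, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    upper = v[:, 2] > 0
    rim_dirs = (np.asarray(rim_points, float) - center) / radius
    rim_dirs /= np.linalg.norm(rim_dirs, axis=1, keepdims=True)
    inside = np.zeros(n_samples, dtype=bool)
    inside[upper] = spherical_winding_inside(v[upper], rim_dirs)
    # projected area = 4 pi r^2 * E[cos * 1_covered&upper]; denominator pi r^2
    return float(4.0 * np.mean(np.where(inside & upper, v[:, 2], 0.0)))


def icc_2_1_mean_squares(M: np.ndarray) -> float:
    """From-scratch ICC(2,1) via explicit two-way ANOVA sums of squares."""
    M = np.asarray(M, float)
    n, k = M.shape
    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((M - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def pooled_t(a, b):
    """Textbook pooled-variance two-sample t statistic and df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), n1 + n2 - 2
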