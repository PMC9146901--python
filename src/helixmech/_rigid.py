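"""Low-level rotation helpers shared by geometry and the optimizer.

All functions work in radians on raw ndarrays; the public modules convert
from the degree/angstrom units used everywhere else.
"""
from __future__ import annotations

import numpy as np

_EPS = 1e-12


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix [v]x, broadcasting over leading axes."""
    v = np.asarray(v, dtype=float)
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


def rotation_z(angle):
    """Rz(angle); broadcasts over leading axes of ``angle``."""
    angle = np.asarray(angle, dtype=float)
    c, s = np.cos(angle), np.sin(angle)
    out = np.zeros(angle.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def rodrigues(v: np.ndarray) -> np.ndarray:
    """exp([v]x) for rotation vectors v, broadcasting over leading axes."""
    v = np.asarray(v, dtype=float)
    theta = np.linalg.norm(v, axis=-1)
    K = skew(v)
    K2 = K @ K
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(theta > _EPS, np.sin(theta) / np.where(theta > _EPS, theta, 1.0), 1.0)
        b = np.where(
            theta > _EPS,
            (1.0 - np.cos(theta)) / np.where(theta > _EPS, theta**2, 1.0),
            0.5,
        )
    eye = np.broadcast_to(np.eye(3), K.shape)
    return eye + a[..., None, None] * K + b[..., None, None] * K2


def rodrigues_jacobian(v: np.ndarray) -> np.ndarray:
    """d exp([v]x) / d v_i (Gallego & Yezzi closed form).

    Returns shape (..., 3, 3, 3): leading batch axes, then derivative index i,
    then the 3x3 matrix dR/dv_i.
    """
    v = np.asarray(v, dtype=float)
    R = rodrigues(v)
    n2 = np.sum(v * v, axis=-1)
    small = n2 < 1e-16
    out = np.empty(v.shape[:-1] + (3, 3, 3))
    eye = np.eye(3)
    ImR = eye - R
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1.0
        # v x ((I - R) e_i)
        w = np.cross(np.broadcast_to(v, ImR[..., 0].shape), ImR[..., i], axis=-1)
        num = v[..., i, None, None] * skew(v) + skew(w)
        with np.errstate(invalid="ignore", divide="ignore"):
            dR = (num / np.where(small, 1.0, n2)[..., None, None]) @ R
        dR = np.where(small[..., None, None], skew(e), dR)
        out[..., i, :, :] = dR
    return out
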