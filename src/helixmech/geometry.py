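"""Rigid-body geometry of DNA base-pair steps.

A base-pair step is parameterized by six rigid-body coordinates: three
rotations (tilt, roll, twist, in degrees) and three translations (shift,
slide, rise, in angstroms).  The convention is the mid-step-frame scheme
used by 3DNA/CEHS: the relative rotation between the two base-pair frames
decomposes as

    A = Rz(omega/2 - phi) . Ry(Gamma) . Rz(omega/2 + phi)
      = Rz(omega/2) . exp([tilt, roll, 0]x) . Rz(omega/2)

with Gamma = sqrt(tilt^2 + roll^2) the bending magnitude and
phi = atan2(tilt, roll) its phase, and the translations are the components
of the origin-to-origin vector expressed in the mid-step frame

    Rm = R1 . Rz(omega/2) . exp([tilt/2, roll/2, 0]x).

The leading strand runs 5'->3'; the base-pair normal (local z) points along
the chain; twist is a right-handed rotation about the mid-frame z axis.
Reading a step on the complementary strand flips the signs of tilt and
shift and leaves roll, twist, slide, rise unchanged — a property used as
the internal consistency check on the convention.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._rigid import rodrigues, rotation_z

__all__ = [
    "StepParameters",
    "BasePairFrame",
    "ChainPath",
    "params_to_transform",
    "transform_to_params",
    "build_chain",
    "principal_axes",
    "steps_to_transforms",
    "accumulate_frames",
    "PARAM_NAMES",
]

PARAM_NAMES = ("tilt", "roll", "twist", "shift", "slide", "rise")

_DEG = np.pi / 180.0


class InvalidParameterError(ValueError):
    """A step parameter is non-finite or out of range."""


class InvalidFrameError(ValueError):
    """A base-pair frame is not a proper orthonormal rotation."""


@dataclass(frozen=True)
class StepParameters:
    """Six rigid-body parameters of one base-pair step.

    Angles in degrees (wrapped to (-180, 180]), translations in angstroms.
    """

    tilt: float
    roll: float
    twist: float
    shift: float
    slide: float
    rise: float

    def __post_init__(self):
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError(f"non-finite step parameters: {arr}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.tilt, self.roll, self.twist, self.shift, self.slide, self.rise]
        )

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "StepParameters":
        a = np.asarray(arr, dtype=float)
        if a.shape != (6,):
            raise InvalidParameterError(f"expected 6 parameters, got shape {a.shape}")
        return cls(*a)


@dataclass(frozen=True)
class BasePairFrame:
    """Origin (angstroms) and right-handed orthonormal axes of one base pair.

    ``axes`` columns are the local x (minor-groove direction), y (long
    base-pair axis) and z (normal, pointing 5'->3' along the chain).
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        R = np.asarray(self.axes, dtype=float).reshape(3, 3)
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", R)
        if not np.all(np.isfinite(o)) or not np.all(np.isfinite(R)):
            raise InvalidFrameError("non-finite frame")
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-8:
            raise InvalidFrameError("frame axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidFrameError("frame axes are left-handed")

    @classmethod
    def identity(cls) -> "BasePairFrame":
        return cls(np.zeros(3), np.eye(3))


@dataclass
class ChainPath:
    """Global base-pair frames of a chain plus its leading-strand sequence."""

    origins: np.ndarray  # (n, 3)
    axes: np.ndarray  # (n, 3, 3)
    sequence: str
    closed: bool = False

    def __post_init__(self):
        self.origins = np.asarray(self.origins, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        n = len(self.sequence)
        if self.origins.shape != (n, 3) or self.axes.shape != (n, 3, 3):
            raise ValueError(
                f"frame count {self.origins.shape[0]} != sequence length {n}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def frame(self, i: int) -> BasePairFrame:
        return BasePairFrame(self.origins[i], self.axes[i])

    def to_xyz_table(self) -> str:
        lines = ["# base origin_x origin_y origin_z"]
        for b, o in zip(self.sequence, self.origins):
            lines.append(f"{b} {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}")
        return "\n".join(lines) + "\n"

    def to_pdb(self) -> str:
        """Minimal PDB: one pseudo-atom per bp origin, axes as REMARK records."""
        lines = []
        for i, R in enumerate(self.axes):
            flat = " ".join(f"{x:8.5f}" for x in R.ravel())
            lines.append(f"REMARK 290 FRAME {i + 1:5d} {flat}")
        for i, (b, o) in enumerate(zip(self.sequence, self.origins)):
            lines.append(
                f"ATOM  {i + 1:5d}  CA  D{b}  A{i + 1:4d}    "
                f"{o[0]:8.3f}{o[1]:8.3f}{o[2]:8.3f}  1.00  0.00           C"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# parameter <-> transform
# ---------------------------------------------------------------------------

def _compose(params_deg: np.ndarray):
    """Vectorized (A, m): relative rotation and frame-1 displacement.

    params_deg: (..., 6).  frame2 = (R1 @ A, o1 + R1 @ m).
    """
    p = np.asarray(params_deg, dtype=float)
    tilt, roll, twist = (p[..., i] * _DEG for i in range(3))
    d = p[..., 3:6]
    half = rotation_z(twist / 2.0)
    v = np.stack([tilt, roll, np.zeros_like(tilt)], axis=-1)
    A = half @ rodrigues(v) @ half
    mid = half @ rodrigues(v / 2.0)
    m = np.einsum("...ij,...j->...i", mid, d)
    return A, m, mid


def steps_to_transforms(params_deg: np.ndarray):
    """Relative rotations A (n,3,3) and displacements m (n,3) for n steps."""
    A, m, _ = _compose(np.atleast_2d(params_deg))
    return A, m


def params_to_transform(p: StepParameters | Iterable[float]):
    """Rotation and displacement taking base-pair frame i to frame i+1.

    Returns (A, m) such that ``axes2 = axes1 @ A`` and
    ``origin2 = origin1 + axes1 @ m``.
    """
    arr = p.as_array() if isinstance(p, StepParameters) else np.asarray(p, float)
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("non-finite step parameters")
    A, m, _ = _compose(arr)
    return A, m


def _wrap_deg(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def transform_to_params(f1: BasePairFrame, f2: BasePairFrame) -> StepParameters:
    """Invert :func:`params_to_transform` for a pair of base-pair frames."""
    R1, R2 = f1.axes, f2.axes
    A = R1.T @ R2
    # zyz Euler decomposition A = Rz(a) Ry(beta) Rz(c); the bend angle comes
    # from atan2 rather than arccos, which loses half the digits near zero
    sb = np.hypot(np.hypot(A[0, 2], A[1, 2]), np.hypot(A[2, 0], A[2, 1]) ) / np.sqrt(2.0)
    beta = np.arctan2(sb, A[2, 2])
    if sb > 1e-12:
        a = np.arctan2(A[1, 2], A[0, 2])
        c = np.arctan2(A[2, 1], -A[2, 0])
    else:
        # pure twist (or 180 deg bend, outside the physical range)
        a = np.arctan2(A[1, 0], A[0, 0]) / 2.0
        c = a
    omega = a + c
    phi = (c - a) / 2.0
    # a and c are each reduced mod 2pi; if their sum left (-pi, pi], the
    # phase is off by pi and the bend components change sign with the wrap
    if omega > np.pi:
        omega -= 2.0 * np.pi
        phi += np.pi
    elif omega <= -np.pi:
        omega += 2.0 * np.pi
        phi += np.pi
    tilt = beta * np.sin(phi)
    roll = beta * np.cos(phi)
    half = rotation_z(omega / 2.0)
    mid = R1 @ half @ rodrigues(np.array([tilt / 2.0, roll / 2.0, 0.0]))
    d = mid.T @ (f2.origin - f1.origin)
    return StepParameters(
        _wrap_deg(tilt / _DEG),
        _wrap_deg(roll / _DEG),
        _wrap_deg(omega / _DEG),
        d[0],
        d[1],
        d[2],
    )


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

def accumulate_frames(params_deg: np.ndarray, anchor: BasePairFrame):
    """Frames 0..n obtained by composing n steps from the anchor.

    Returns (origins (n+1,3), axes (n+1,3,3)); frame 0 is the anchor.
    """
    params_deg = np.atleast_2d(np.asarray(params_deg, dtype=float))
    n = params_deg.shape[0]
    A, m = steps_to_transforms(params_deg)
    origins = np.empty((n + 1, 3))
    axes = np.empty((n + 1, 3, 3))
    origins[0] = anchor.origin
    axes[0] = anchor.axes
    for i in range(n):
        origins[i + 1] = origins[i] + axes[i] @ m[i]
        axes[i + 1] = axes[i] @ A[i]
    return origins, axes


def build_chain(
    seq: str,
    steps: Sequence[StepParameters] | np.ndarray,
    anchor: BasePairFrame | None = None,
    closed: bool | None = None,
) -> ChainPath:
    """Accumulate step transforms from the anchor into a global chain path.

    Open chains take ``len(steps) == len(seq) - 1``; closed chains take
    ``len(steps) == len(seq)`` (the last step returns to base pair 1 and is
    a closure constraint, not a stored frame).
    """
    if anchor is None:
        anchor = BasePairFrame.identity()
    arr = np.asarray(
        [s.as_array() if isinstance(s, StepParameters) else s for s in steps],
        dtype=float,
    )
    if arr.size == 0:
        if len(seq) != 1:
            raise ValueError("zero steps require a single-base sequence")
        return ChainPath(anchor.origin[None, :], anchor.axes[None, :, :], seq, False)
    n = len(seq)
    if closed is None:
        closed = arr.shape[0] == n
    expected = n if closed else n - 1
    if arr.shape[0] != expected:
        raise ValueError(
            f"sequence of {n} bp needs {expected} steps "
            f"({'closed' if closed else 'open'}), got {arr.shape[0]}"
        )
    origins, axes = accumulate_frames(arr, anchor)
    return ChainPath(origins[:n], axes[:n], seq, closed)


def principal_axes(path: ChainPath):
    """Principal axes and extents of the bp-origin cloud.

    Returns (axes (3,3) rows = unit vectors, extents (3,) = sqrt of the
    second-moment eigenvalues, sorted descending).  Collinear input earns a
    warning but still returns tie-broken axes.
    """
    import warnings

    pts = path.origins
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 origins")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    if vals[1] < 1e-12 * max(vals[0], 1.0):
        warnings.warn("collinear origins: principal axes are degenerate")
    return vecs.T, np.sqrt(vals)
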