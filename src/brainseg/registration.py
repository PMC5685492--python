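"""Prototype selection (NCC) and 12-DOF affine registration maximizing MI.

The training database lives in a common (atlas) space.  A test subject is
matched against it with the normalized cross-correlation coefficient, and the
best-matching subjects become the reference prototypes.  The test subject is
then co-aligned to a prototype with a 12-degree-of-freedom affine transform
(3 translations, 3 rotations, 3 scales, 3 shears) found by maximizing the
joint-histogram mutual information over a coarse-to-fine pyramid with a
derivative-free (Powell) optimizer.

Transform convention: the transform maps *test* (moving) voxel coordinates
into the atlas (fixed) domain; parameters compose as T . R . Sh . S about the
volume centre.  ``resample`` pulls the moving image back onto the fixed
lattice through the inverse matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .phantom import SubjectPair
from .volume_io import LabelMap, Volume, VolumeError, check_same_lattice


class RegistrationError(RuntimeError):
    pass


@dataclass
class AffineTransform12:
    """12-parameter affine in voxel coordinates: translation, rotation (rad,
    extrinsic x-y-z), per-axis scale, and shears (xy, xz, yz), composed as
    T . R . Sh . S about ``center``."""

    translation: np.ndarray
    rotation: np.ndarray
    scale: np.ndarray
    shear: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        for name in ("translation", "rotation", "scale", "shear", "center"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.scale <= 0):
            raise RegistrationError(f"scales must be positive, got {self.scale}")

    @classmethod
    def identity(cls, shape) -> "AffineTransform12":
        center = np.array([(n - 1) / 2.0 for n in shape])
        return cls(np.zeros(3), np.zeros(3), np.ones(3), np.zeros(3), center)

    @classmethod
    def from_params(cls, params, center) -> "AffineTransform12":
        p = np.asarray(params, dtype=float)
        return cls(p[0:3], p[3:6], p[6:9], p[9:12], np.asarray(center, dtype=float))

    def params(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation, self.scale, self.shear])

    def matrix(self) -> np.ndarray:
        rot = Rotation.from_euler("xyz", self.rotation).as_matrix()
        sh = np.eye(3)
        sh[0, 1], sh[0, 2], sh[1, 2] = self.shear
        a = rot @ sh @ np.diag(self.scale)
        m = np.eye(4)
        m[:3, :3] = a
        m[:3, 3] = self.translation + self.center - a @ self.center
        return m

    @classmethod
    def from_matrix(cls, m, center) -> "AffineTransform12":
        m = np.asarray(m, dtype=float)
        a = m[:3, :3]
        det = np.linalg.det(a)
        if abs(det) < 1e-8:
            raise RegistrationError(f"affine matrix is singular (det={det:.2e})")
        if det < 0:
            raise RegistrationError("reflections are not representable (det < 0)")
        q, r = np.linalg.qr(a)
        d = np.sign(np.diag(r))
        d[d == 0] = 1.0
        q, r = q * d, (r.T * d).T
        rotation = Rotation.from_matrix(q).as_euler("xyz")
        scale = np.diag(r).copy()
        shear = np.array([r[0, 1] / scale[1], r[0, 2] / scale[2], r[1, 2] / scale[2]])
        center = np.asarray(center, dtype=float)
        translation = m[:3, 3] - center + a @ center
        return cls(translation, rotation, scale, shear, center)

    def to_json(self) -> str:
        return json.dumps(
            {
                "translation": self.translation.tolist(),
                "rotation": self.rotation.tolist(),
                "scale": self.scale.tolist(),
                "shear": self.shear.tolist(),
                "center": self.center.tolist(),
                "matrix": self.matrix().tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "AffineTransform12":
        d = json.loads(s)
        return cls(d["translation"], d["rotation"], d["scale"], d["shear"], d["center"])


def ncc(a: Volume, b: Volume) -> float:
    """Pearson correlation of intensities over voxels nonzero in either volume."""
    check_same_lattice(a, b)
    mask = (a.values > 0) | (b.values > 0)
    av = a.values[mask].astype(float)
    bv = b.values[mask].astype(float)
    av -= av.mean()
    bv -= bv.mean()
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0 or nb == 0:
        raise RegistrationError("zero variance on the evaluation mask")
    return float(np.dot(av, bv) / (na * nb))


@dataclass
class PrototypeMatch:
    subject: SubjectPair
    score: float
    index: int


def select_prototypes(
    test: Volume, training: list[SubjectPair], k: int
) -> list[PrototypeMatch]:
    """Rank training subjects by descending NCC with the test volume; stable ties."""
    if not training:
        raise RegistrationError("empty training set")
    if k > len(training):
        raise RegistrationError(f"k={k} exceeds training set size {len(training)}")
    scores = np.array([ncc(test, s.grey) for s in training])
    order = np.argsort(-scores, kind="stable")
    return [PrototypeMatch(training[i], float(scores[i]), int(i)) for i in order[:k]]


@dataclass
class RegistrationOptions:
    bins: int = 64
    levels: int = 3
    max_iters: int = 4  # Powell direction-set iterations per pyramid level
    xtol: float = 1e-3
    smooth: bool = True


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """Histogram-based MI (nats) between two equally-shaped arrays."""
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _downsample(vals: np.ndarray, factor: int, smooth: bool) -> np.ndarray:
    if factor == 1:
        return vals.astype(float)
    v = vals.astype(float)
    if smooth:
        v = gaussian_filter(v, sigma=factor / 2.0)
    return v[::factor, ::factor, ::factor]


_PARAM_UNITS = np.concatenate([np.ones(3), np.full(3, 0.02), np.full(3, 0.02), np.full(3, 0.02)])
_PARAM_REF = np.concatenate([np.zeros(3), np.zeros(3), np.ones(3), np.zeros(3)])


def _warp_level(moving_l, matrix_full, factor):
    d = np.diag([1.0 / factor] * 3 + [1.0])
    m_level = d @ matrix_full @ np.linalg.inv(d)
    inv = np.linalg.inv(m_level)
    return affine_transform(
        moving_l, inv[:3, :3], offset=inv[:3, 3], order=1, mode="constant", cval=0.0
    )


def affine_register_mi(
    moving: Volume, fixed: Volume, opts: RegistrationOptions | None = None
) -> AffineTransform12:
    """Find the 12-DOF transform mapping ``moving`` into ``fixed``'s domain by
    maximizing mutual information over a multi-resolution pyramid.

    Deterministic given inputs and options.  The returned transform never has
    lower full-resolution MI than the identity (identity is kept on failure to
    improve)."""
    opts = opts or RegistrationOptions()
    center = np.array([(n - 1) / 2.0 for n in moving.shape])
    x = np.zeros(12)  # optimizer works in scaled offsets from the identity
    factors = [2 ** (opts.levels - 1 - i) for i in range(opts.levels)]
    fixed_levels = {f: _downsample(fixed.values, f, opts.smooth) for f in factors}
    moving_levels = {f: _downsample(moving.values, f, opts.smooth) for f in factors}

    def make_objective(f):
        fx = fixed_levels[f]
        mv = moving_levels[f]

        def neg_mi(xv):
            params = _PARAM_REF + xv * _PARAM_UNITS
            if np.any(params[6:9] <= 0.1):
                return 1e6
            t = AffineTransform12.from_params(params, center)
            warped = _warp_level(mv, t.matrix(), f)
            val = -mutual_information(fx, warped, opts.bins)
            if not np.isfinite(val):
                raise RegistrationError(
                    f"non-finite MI objective at params {params.tolist()}"
                )
            return val

        return neg_mi

    for f in factors:
        obj = make_objective(f)
        res = minimize(
            obj,
            x,
            method="Powell",
            options={"maxiter": opts.max_iters, "xtol": opts.xtol, "ftol": 1e-6},
        )
        x = res.x
    # keep the better of (optimum, identity) at full resolution
    final = AffineTransform12.from_params(_PARAM_REF + x * _PARAM_UNITS, center)
    mi_final = mutual_information(
        fixed.values.astype(float), _warp_level(moving.values, final.matrix(), 1), opts.bins
    )
    mi_id = mutual_information(
        fixed.values.astype(float), moving.values.astype(float), opts.bins
    )
    if mi_final < mi_id:
        return AffineTransform12.identity(moving.shape)
    return final


def resample(image, t: AffineTransform12, target_shape=None, mode: str | None = None):
    """Pull an image back onto the target lattice through ``t``.

    Volumes use trilinear interpolation, label maps nearest-neighbour;
    requesting trilinear on a label map is an error.  Out-of-field voxels
    become 0/background.
    """
    is_labels = isinstance(image, LabelMap)
    if mode is None:
        mode = "nearest" if is_labels else "trilinear"
    if is_labels and mode == "trilinear":
        raise VolumeError("trilinear interpolation is invalid for label maps")
    if mode not in ("trilinear", "nearest"):
        raise VolumeError(f"unknown resampling mode {mode!r}")
    order = 0 if mode == "nearest" else 1
    target_shape = target_shape or image.shape
    inv = np.linalg.inv(t.matrix())
    out = affine_transform(
        image.values.astype(float),
        inv[:3, :3],
        offset=inv[:3, 3],
        output_shape=tuple(target_shape),
        order=order,
        mode="constant",
        cval=0.0,
    )
    if is_labels:
        return image.with_values(np.rint(out).astype(image.values.dtype))
    vals = np.clip(np.rint(out), 0, image.Q - 1).astype(image.values.dtype)
    return image.with_values(vals)
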