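"""Adaptive, appearance-guided voxel-wise shape prior.

The prior P_sp(m) is a spatially variant independent random field: each voxel
carries an empirical probability vector over the labels, and the prior of a
whole map is the product of its voxels' probabilities (so log-priors add).

The "adaptive" part conditions the prior on the test subject's appearance:
for every brain voxel v, its position is mapped into the atlas domain by the
affine transform T, a small cube C is centred there, and across *all* training
subjects (with intensities pre-equalized to the test subject) the voxels
inside C whose grey level falls within +-tau of g_v are collected.  The prior
probability of label l at v is the fraction of collected voxels carrying l.
If no voxel matches, the cube grows and the search repeats up to a maximum
size; if there is still no match, the prior falls back to the label
frequencies of all voxels in the maximal cube regardless of intensity (and to
a pure background prior for voxels that map entirely outside the atlas).

The construction is deterministic: no random numbers are involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import SubjectPair
from .registration import AffineTransform12
from .volume_io import N_LABELS, Volume, VolumeError

EPS = 1e-10  # shared log floor for prior and likelihood


class ShapePriorError(ValueError):
    pass


@dataclass
class PriorSearchParams:
    """tau: intensity tolerance (grey levels); cube sizes odd, grown by
    cube_step per axis up to cube_max."""

    tau: int = 10
    cube_init: int = 3
    cube_step: int = 2
    cube_max: int = 11

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ShapePriorError("tau must be >= 0")
        for name in ("cube_init", "cube_max"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ShapePriorError(f"{name} must be odd and >= 1, got {v}")
        if self.cube_init > self.cube_max:
            raise ShapePriorError("cube_init must not exceed cube_max")
        if self.cube_step <= 0 or self.cube_step % 2 == 1:
            raise ShapePriorError("cube_step must be a positive even increment")


@dataclass
class ShapePriorField:
    """Per-voxel probabilities over the labels, shape (X, Y, Z, L+1)."""

    probs: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 4 or self.probs.shape[3] != N_LABELS:
            raise ShapePriorError(
                f"prior field must have shape (X, Y, Z, {N_LABELS}), got {self.probs.shape}"
            )
        sums = self.probs.sum(axis=3)
        if np.any(self.probs < 0) or np.max(np.abs(sums - 1.0)) > 1e-9:
            raise ShapePriorError("per-voxel probabilities must be >= 0 and sum to 1")

    @property
    def shape(self):
        return self.probs.shape[:3]

    def argmax_labels(self) -> np.ndarray:
        return np.argmax(self.probs, axis=3).astype(np.int16)


def _cube_offsets(size: int) -> np.ndarray:
    h = size // 2
    r = np.arange(-h, h + 1)
    return np.stack(np.meshgrid(r, r, r, indexing="ij"), axis=-1).reshape(-1, 3)


def build_adaptive_prior(
    test: Volume,
    prototypes: list[SubjectPair],
    transform: AffineTransform12 | None = None,
    params: PriorSearchParams | None = None,
) -> ShapePriorField:
    """Build the adaptive shape prior for ``test`` from equalized prototypes.

    ``prototypes`` are the co-aligned training subjects whose grey volumes
    have already been histogram-matched to the test subject;  ``transform``
    maps test voxel coordinates into the atlas domain (identity if None).
    """
    if not prototypes:
        raise ShapePriorError("empty prototype list")
    params = params or PriorSearchParams()
    shape = test.shape
    if transform is None:
        transform = AffineTransform12.identity(shape)
    mat = transform.matrix()
    if abs(np.linalg.det(mat[:3, :3])) < 1e-8:
        raise ShapePriorError("transform is not invertible")

    brain = test.values > 0
    vx, vy, vz = np.nonzero(brain)
    g_v = test.values[brain].astype(np.int64)
    n = g_v.size
    pts = np.stack([vx, vy, vz]).astype(float)
    mapped = mat[:3, :3] @ pts + mat[:3, 3:4]
    mapped = np.rint(mapped).astype(np.int64)  # cube centres in the atlas domain

    proto_grey = [p.grey.values.astype(np.int64) for p in prototypes]
    proto_lab = [p.labels.values.astype(np.int64) for p in prototypes]
    ashape = proto_grey[0].shape

    counts = np.zeros((n, N_LABELS), dtype=np.int64)  # intensity-matched labels
    allcounts = np.zeros((n, N_LABELS), dtype=np.int64)  # every in-cube voxel
    active = np.arange(n)

    sizes = list(range(params.cube_init, params.cube_max + 1, params.cube_step))
    prev = 0
    for size in sizes:
        offsets = _cube_offsets(size)
        # only the shell of offsets new at this size
        shell = offsets[np.abs(offsets).max(axis=1) > prev // 2] if prev else offsets
        prev = size
        if active.size == 0:
            break
        na = active.size
        cx, cy, cz = (mapped[i, active] for i in range(3))
        ga = g_v[active]
        c_match = np.zeros((na, N_LABELS), dtype=np.int64)
        c_all = np.zeros((na, N_LABELS), dtype=np.int64)
        for grey, lab in zip(proto_grey, proto_lab):
            for dx, dy, dz in shell:
                px, py, pz = cx + dx, cy + dy, cz + dz
                inb = (
                    (px >= 0)
                    & (py >= 0)
                    & (pz >= 0)
                    & (px < ashape[0])
                    & (py < ashape[1])
                    & (pz < ashape[2])
                )
                if not inb.any():
                    continue
                ii = np.nonzero(inb)[0]
                pl = lab[px[ii], py[ii], pz[ii]]
                pg = grey[px[ii], py[ii], pz[ii]]
                c_all += np.bincount(
                    ii * N_LABELS + pl, minlength=na * N_LABELS
                ).reshape(na, N_LABELS)
                match = np.abs(pg - ga[ii]) <= params.tau
                if match.any():
                    c_match += np.bincount(
                        ii[match] * N_LABELS + pl[match], minlength=na * N_LABELS
                    ).reshape(na, N_LABELS)
        counts[active] += c_match
        allcounts[active] += c_all
        # voxels with at least one intensity match are frozen at this cube size
        active = active[c_match.sum(axis=1) == 0]

    probs = np.zeros((*shape, N_LABELS), dtype=np.float64)
    probs[..., 0] = 1.0  # background voxels: p(background) = 1
    flat_probs = np.zeros((n, N_LABELS), dtype=np.float64)

    tot = counts.sum(axis=1)
    matched = tot > 0
    flat_probs[matched] = counts[matched] / tot[matched, None]
    # fallback: label frequencies of all voxels in the maximal cube
    atot = allcounts.sum(axis=1)
    fb = ~matched & (atot > 0)
    flat_probs[fb] = allcounts[fb] / atot[fb, None]
    # voxels mapped entirely outside the atlas: pure background prior
    none = ~matched & (atot == 0)
    flat_probs[none, 0] = 1.0

    probs[vx, vy, vz] = flat_probs
    return ShapePriorField(probs, test.spacing, test.affine.copy())


def log_prior(field: ShapePriorField, voxel, label: int) -> float:
    """log p_sp at one voxel with the shared floor: log(max(p, 1e-10))."""
    x, y, z = voxel
    return float(np.log(max(field.probs[x, y, z, label], EPS)))


def log_prior_field(field: ShapePriorField) -> np.ndarray:
    """Floored elementwise log of the whole field, shape (X, Y, Z, L+1)."""
    return np.log(np.maximum(field.probs, EPS))
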