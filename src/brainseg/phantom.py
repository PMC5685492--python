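"""Synthetic 3-D brain phantoms with known ground truth.

The phantom is a nested-ellipsoid caricature of an axial brain: an outer CSF
shell, a GM cortical shell, a WM core and a central CSF-filled ventricle.  It
is deliberately simple — no cortical folding, no partial-volume voxels — but it
reproduces the features the segmentation model actually consumes: nested
tissue geometry, per-class overlapping intensity distributions (including a
low-contrast "isointense infant" regime where GM and WM nearly coincide),
optional smooth multiplicative bias, additive noise, and small affine+elastic
inter-subject variation for training databases.

Two presets instantiate the two contrast regimes:

* ``adult``  — class means (CSF, GM, WM) = (60, 110, 170), sigma 12;
* ``infant`` — class means (90, 110, 130), sigma 15 (GM/WM histograms overlap
  heavily, as in 6-month-old T1 scans where WM is unmyelinated).

Rendering is a pure function of (spec, seed): the same spec always yields a
bit-identical subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .volume_io import BACKGROUND, CSF, GM, WM, LabelMap, Volume


class PhantomConfigError(ValueError):
    """Raised when a phantom spec violates its geometric or intensity contract."""


@dataclass(frozen=True)
class EllipsoidGeometry:
    """Semi-axes (voxels) of the four nested shells, inside out.

    A voxel at offset ``d`` from the grid centre belongs to the innermost
    ellipsoid that contains it; strict nesting is required:
    ventricle < wm < gm < csf < grid half-extent.
    """

    ventricle: tuple[float, float, float]
    wm: tuple[float, float, float]
    gm: tuple[float, float, float]
    csf: tuple[float, float, float]

    def validate(self, grid_shape: tuple[int, int, int]) -> None:
        names = ("ventricle", "wm", "gm", "csf")
        radii = [self.ventricle, self.wm, self.gm, self.csf]
        for inner_name, outer_name, rin, rout in zip(names, names[1:], radii, radii[1:]):
            if not all(a < b for a, b in zip(rin, rout)):
                raise PhantomConfigError(
                    f"shell nesting violated: {inner_name} radii {rin} must be "
                    f"strictly inside {outer_name} radii {rout}"
                )
        half = tuple((n - 1) / 2.0 for n in grid_shape)
        if not all(r < h for r, h in zip(self.csf, half)):
            raise PhantomConfigError(
                f"outer csf radii {self.csf} must fit inside the grid half-extent {half}"
            )

    def min_gap(self) -> float:
        """Smallest inter-shell gap over shells and axes (voxels)."""
        radii = [self.ventricle, self.wm, self.gm, self.csf]
        return min(
            b - a for rin, rout in zip(radii, radii[1:]) for a, b in zip(rin, rout)
        )


def default_geometry(grid_shape: tuple[int, int, int]) -> EllipsoidGeometry:
    """Geometry scaled to the grid: shells at 18/56/75/88% of the half-extent."""
    half = np.array([(n - 1) / 2.0 for n in grid_shape])
    mk = lambda f: tuple(np.round(f * half, 2))
    return EllipsoidGeometry(ventricle=mk(0.18), wm=mk(0.56), gm=mk(0.75), csf=mk(0.88))


@dataclass
class PhantomSpec:
    """Full description of one synthetic subject.

    ``class_intensity`` maps tissue label -> (mean, sigma) on the grey scale
    ``0..Q-1``; ``noise_sigma`` is an extra global additive noise on top of the
    per-class sigma.  ``bias_amplitude`` is the fractional amplitude of a
    degree-2 polynomial multiplicative bias field (0 disables it).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    geometry: EllipsoidGeometry | None = None
    class_intensity: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {CSF: (60.0, 12.0), GM: (110.0, 12.0), WM: (170.0, 12.0)}
    )
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    noise_model: str = "gaussian"  # or "rician"
    Q: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry is None:
            self.geometry = default_geometry(self.grid_shape)
        self.geometry.validate(self.grid_shape)
        if self.Q < 2:
            raise PhantomConfigError("Q must be >= 2")
        if self.noise_sigma < 0:
            raise PhantomConfigError("noise_sigma must be >= 0")
        for lab, (mean, sig) in self.class_intensity.items():
            if not 0 <= mean <= self.Q - 1:
                raise PhantomConfigError(
                    f"class {lab} mean {mean} outside grey range [0, {self.Q - 1}]"
                )
            if sig < 0:
                raise PhantomConfigError(f"class {lab} sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise PhantomConfigError(f"unknown noise model {self.noise_model!r}")


@dataclass
class SubjectPair:
    """A grey volume with its ground-truth label map and generation provenance."""

    grey: Volume
    labels: LabelMap
    provenance: dict = field(default_factory=dict)


def adult_spec(grid_shape=(64, 64, 64), seed: int = 0, **kw) -> PhantomSpec:
    """High-contrast regime: well-separated CSF/GM/WM modes."""
    return PhantomSpec(
        grid_shape=grid_shape,
        class_intensity={CSF: (60.0, 12.0), GM: (110.0, 12.0), WM: (170.0, 12.0)},
        seed=seed,
        **kw,
    )


def infant_spec(grid_shape=(64, 64, 64), seed: int = 0, **kw) -> PhantomSpec:
    """Isointense regime: GM/WM means 20 grey levels apart with sigma 15."""
    return PhantomSpec(
        grid_shape=grid_shape,
        class_intensity={CSF: (90.0, 15.0), GM: (110.0, 15.0), WM: (130.0, 15.0)},
        seed=seed,
        **kw,
    )


PRESETS = {"adult": adult_spec, "infant": infant_spec}


def _shell_labels(spec: PhantomSpec) -> np.ndarray:
    geo = spec.geometry
    center = [(n - 1) / 2.0 for n in spec.grid_shape]
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in spec.grid_shape], indexing="ij")

    def inside(radii):
        return sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)) <= 1.0

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[inside(geo.csf)] = CSF
    labels[inside(geo.gm)] = GM
    labels[inside(geo.wm)] = WM
    labels[inside(geo.ventricle)] = CSF
    return labels


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth degree-2 polynomial multiplicative field, mean 1 over the grid."""
    coords = [
        2.0 * np.arange(n, dtype=float) / max(n - 1, 1) - 1.0 for n in spec.grid_shape
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    basis = [x, y, z, x * y, x * z, y * z, x * x, y * y, z * z]
    coef = rng.normal(size=len(basis))
    poly = sum(c * b for c, b in zip(coef, basis))
    peak = np.abs(poly).max()
    if peak > 0:
        poly = poly / peak
    fld = 1.0 + spec.bias_amplitude * poly
    return fld / fld.mean()


def _render(spec: PhantomSpec, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mean_lut = np.zeros(4)
    sigma_lut = np.zeros(4)
    for lab, (mean, sig) in spec.class_intensity.items():
        mean_lut[lab], sigma_lut[lab] = mean, sig
    signal = mean_lut[labels]
    brain = labels != BACKGROUND
    noise_sd = np.where(brain, np.hypot(sigma_lut[labels], spec.noise_sigma), 0.0)
    if spec.noise_model == "rician":
        n1 = rng.normal(size=labels.shape) * noise_sd
        n2 = rng.normal(size=labels.shape) * noise_sd
        grey = np.hypot(signal + n1, n2)
    else:
        grey = signal + rng.normal(size=labels.shape) * noise_sd
    if spec.bias_amplitude != 0.0:
        grey = grey * _bias_field(spec, rng)
    grey = np.rint(np.clip(grey, 1, spec.Q - 1)).astype(np.int16)
    grey[~brain] = 0  # background renders exactly 0 so mask == (grey > 0)
    return grey


def generate_phantom(spec: PhantomSpec) -> SubjectPair:
    """Render one subject deterministically from its spec."""
    rng = np.random.default_rng(spec.seed)
    labels = _shell_labels(spec)
    grey = _render(spec, labels, rng)
    return SubjectPair(
        grey=Volume(grey, spec.spacing, Q=spec.Q),
        labels=LabelMap(labels, spec.spacing),
        provenance={"seed": spec.seed, "kind": "base"},
    )


@dataclass(frozen=True)
class Perturbation:
    """Bounds of the random inter-subject variation applied to training subjects.

    Each subject draws an affine within these bounds (rotation in degrees,
    scale as fractional deviation from 1, translation and shear in voxels)
    composed with a smooth random displacement field (Gaussian-smoothed white
    noise with kernel ``elastic_sigma``, rescaled so the largest displacement
    equals ``elastic_magnitude`` voxels).
    """

    rotation_deg: float = 4.0
    scale_dev: float = 0.03
    translation: float = 2.0
    shear: float = 0.01
    elastic_sigma: float = 8.0
    elastic_magnitude: float = 1.0

    def scaled(self, f: float) -> "Perturbation":
        return Perturbation(
            self.rotation_deg * f,
            self.scale_dev * f,
            self.translation * f,
            self.shear * f,
            self.elastic_sigma,
            self.elastic_magnitude * f,
        )


def _random_affine(p: Perturbation, rng: np.random.Generator, shape) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler(
        "xyz", rng.uniform(-p.rotation_deg, p.rotation_deg, 3), degrees=True
    ).as_matrix()
    scale = np.diag(1.0 + rng.uniform(-p.scale_dev, p.scale_dev, 3))
    shear = np.eye(3)
    shear[0, 1], shear[0, 2], shear[1, 2] = rng.uniform(-p.shear, p.shear, 3)
    a = rot @ shear @ scale
    t = rng.uniform(-p.translation, p.translation, 3)
    center = np.array([(n - 1) / 2.0 for n in shape])
    mat = np.eye(4)
    mat[:3, :3] = a
    mat[:3, 3] = center + t - a @ center
    return mat


def _warp_labels(
    labels: np.ndarray, mat: np.ndarray, disp: np.ndarray | None
) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in labels.shape], indexing="ij")
    pts = np.stack([g.ravel() for g in grids])
    coords = mat[:3, :3] @ pts + mat[:3, 3:4]
    if disp is not None:
        coords = coords + disp.reshape(3, -1)
    out = map_coordinates(labels, coords, order=0, mode="constant", cval=BACKGROUND)
    return out.reshape(labels.shape).astype(np.int16)


def generate_training_set(
    spec: PhantomSpec,
    n_subjects: int,
    perturbation: Perturbation = Perturbation(),
) -> list[SubjectPair]:
    """Generate a training database of perturbed, independently rendered subjects.

    Each subject's ground-truth labels are the base shell partition warped by
    its own small affine composed with a smooth displacement field
    (nearest-neighbour interpolation keeps labels categorical), then re-rendered
    with an independent noise draw.
    """
    if n_subjects < 1:
        raise PhantomConfigError("n_subjects must be >= 1")
    min_gap = spec.geometry.min_gap()
    if perturbation.elastic_magnitude >= min_gap / 2.0:
        raise PhantomConfigError(
            f"elastic magnitude {perturbation.elastic_magnitude} voxels can break "
            f"shell nesting (minimum inter-shell gap is {min_gap:.2f} voxels)"
        )
    base_labels = _shell_labels(spec)
    subjects = []
    for i in range(n_subjects):
        rng = np.random.default_rng([spec.seed, 1000 + i])
        identity = (
            perturbation.rotation_deg == 0
            and perturbation.scale_dev == 0
            and perturbation.translation == 0
            and perturbation.shear == 0
            and perturbation.elastic_magnitude == 0
        )
        if identity:
            labels = base_labels.copy()
        else:
            mat = _random_affine(perturbation, rng, spec.grid_shape)
            disp = None
            if perturbation.elastic_magnitude > 0:
                disp = rng.normal(size=(3, *spec.grid_shape))
                disp = np.stack(
                    [gaussian_filter(d, perturbation.elastic_sigma) for d in disp]
                )
                peak = np.abs(disp).max()
                if peak > 0:
                    disp *= perturbation.elastic_magnitude / peak
            labels = _warp_labels(base_labels, mat, disp)
        grey = _render(spec, labels, rng)
        subjects.append(
            SubjectPair(
                grey=Volume(grey, spec.spacing, Q=spec.Q),
                labels=LabelMap(labels, spec.spacing),
                provenance={
                    "seed": [spec.seed, 1000 + i],
                    "index": i,
                    "perturbation": perturbation,
                },
            )
        )
    return subjects


def generate_test_subject(
    spec: PhantomSpec, perturbation: Perturbation = Perturbation()
) -> SubjectPair:
    """A held-out subject: perturbed like a training subject but with its own seed."""
    min_gap = spec.geometry.min_gap()
    if perturbation.elastic_magnitude >= min_gap / 2.0:
        raise PhantomConfigError(
            f"elastic magnitude {perturbation.elastic_magnitude} voxels can break "
            f"shell nesting (minimum inter-shell gap is {min_gap:.2f} voxels)"
        )
    rng = np.random.default_rng([spec.seed, 7])
    base_labels = _shell_labels(spec)
    identity = perturbation == Perturbation(0, 0, 0, 0, perturbation.elastic_sigma, 0)
    if identity:
        labels = base_labels
    else:
        mat = _random_affine(perturbation, rng, spec.grid_shape)
        disp = None
        if perturbation.elastic_magnitude > 0:
            disp = rng.normal(size=(3, *spec.grid_shape))
            disp = np.stack([gaussian_filter(d, perturbation.elastic_sigma) for d in disp])
            peak = np.abs(disp).max()
            if peak > 0:
                disp *= perturbation.elastic_magnitude / peak
        labels = _warp_labels(base_labels, mat, disp)
    grey = _render(spec, labels, rng)
    return SubjectPair(
        grey=Volume(grey, spec.spacing, Q=spec.Q),
        labels=LabelMap(labels, spec.spacing),
        provenance={"seed": [spec.seed, 7], "kind": "test"},
    )


def expected_shell_volumes(spec: PhantomSpec) -> dict[int, float]:
    """Closed-form ellipsoid voxel counts per tissue label (continuum limit)."""
    geo = spec.geometry
    vol = lambda r: 4.0 / 3.0 * np.pi * r[0] * r[1] * r[2]
    v_vent, v_wm, v_gm, v_csf = (vol(r) for r in (geo.ventricle, geo.wm, geo.gm, geo.csf))
    return {
        CSF: (v_csf - v_gm) + v_vent,
        GM: v_gm - v_wm,
        WM: v_wm - v_vent,
    }
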