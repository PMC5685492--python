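"""End-to-end segmentation: joint shape/intensity/spatial model with ICM.

The joint model of a grey volume g and its label map m is

    P(g, m) = P(g|m) . P_sp(m) . P_V(m)

with P(g|m) the LCDG per-class conditional densities, P_sp the adaptive shape
prior and P_V the higher-order MGRF.  Segmentation of one subject proceeds
per reference prototype (the top-k NCC-ranked training subjects, default 3):

1. GGMRF smoothing of the test volume;
2. affine co-alignment of the test subject to the prototype (MI);
3. adaptive shape prior from the equalized training database;
4. LCDG fit of the smoothed volume's brain histogram (4 dominant modes) and
   partition into 3 tissue-class densities;
5. initial map: voxel-wise argmax of log-likelihood + log-prior;
6. analytic Gibbs potentials estimated once from the initial map;
7. ICM sweeps maximizing log P(g|m) + log P_sp(m) + log P_V(m) voxel by
   voxel (raster order, in-place), a coordinate ascent whose objective is
   non-decreasing by construction;

and the k candidate label maps are fused by per-voxel majority voting, ties
resolved by prototype rank.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from ._kernels import icm_sweep
from .lcdg import ClassDensities, LCDGFitOptions, empirical_density, fit_lcdg, partition_classes
from .mgrf import (
    CliqueFamily,
    PotentialTable,
    enumerate_families,
    estimate_potentials,
    pack_for_kernel,
    total_energy,
)
from .phantom import SubjectPair
from .preprocess import GGMRFParams, equalize_to_reference, ggmrf_smooth
from .registration import (
    AffineTransform12,
    RegistrationOptions,
    affine_register_mi,
    select_prototypes,
)
from .shape_prior import EPS, PriorSearchParams, ShapePriorField, build_adaptive_prior, log_prior_field
from .volume_io import LabelMap, TISSUE_LABELS, Volume, VolumeError, check_same_lattice

logger = logging.getLogger(__name__)


class SegmentationError(RuntimeError):
    pass


@dataclass
class ICMOptions:
    max_sweeps: int = 10
    stop_fraction: float = 1e-4
    reestimate_potentials: bool = False


@dataclass
class SegmenterParams:
    """Every tunable of the pipeline, with the package defaults."""

    k_prototypes: int = 3
    mgrf_order: int = 4
    skip_ggmrf: bool = False
    ggmrf: GGMRFParams = field(default_factory=GGMRFParams)
    prior: PriorSearchParams = field(default_factory=PriorSearchParams)
    lcdg_k: int = 4
    lcdg: LCDGFitOptions = field(default_factory=LCDGFitOptions)
    registration: RegistrationOptions = field(default_factory=RegistrationOptions)
    icm: ICMOptions = field(default_factory=ICMOptions)
    assume_aligned: bool = False  # skip MI registration (identity transform)


@dataclass
class SegmentationResult:
    labels: LabelMap
    energy_trace: list[float]
    changed_fraction: list[float]
    provenance: dict = field(default_factory=dict)


def _class_loglik(classes: ClassDensities, g: Volume) -> np.ndarray:
    """Log p(g_p | l) per voxel and tissue label, floored at log(1e-10).

    Tissue classes are mean-ordered; class i maps to label i+1 (CSF<GM<WM
    on T1 intensity ordering)."""
    out = np.full((*g.shape, 4), np.log(EPS))
    for i in range(classes.n_classes):
        out[..., i + 1] = np.log(np.maximum(classes.densities[i][g.values], EPS))
    return out


def initial_map(prior: ShapePriorField, classes: ClassDensities, g: Volume) -> LabelMap:
    """Voxel-wise MAP classification from intensity likelihood and shape prior.

    Ties break toward the label with the larger prior, then the smaller code;
    background voxels stay 0."""
    if prior.shape != g.shape:
        raise VolumeError(f"lattice mismatch: prior {prior.shape} vs volume {g.shape}")
    ll = _class_loglik(classes, g)
    lp = log_prior_field(prior)
    score = ll + lp
    brain = g.values > 0
    out = np.zeros(g.shape, dtype=np.int16)
    best_label = np.full(g.shape, TISSUE_LABELS[0], dtype=np.int16)
    best_score = score[..., TISSUE_LABELS[0]].copy()
    best_prior = prior.probs[..., TISSUE_LABELS[0]].copy()
    for lab in TISSUE_LABELS[1:]:
        s = score[..., lab]
        p = prior.probs[..., lab]
        better = (s > best_score) | ((s == best_score) & (p > best_prior))
        best_label[better] = lab
        best_score = np.where(better, s, best_score)
        best_prior = np.where(better, p, best_prior)
    out[brain] = best_label[brain]
    return LabelMap(out, g.spacing, g.affine.copy())


def _objective(
    m: np.ndarray,
    lp: np.ndarray,
    labels_template: LabelMap,
    table: PotentialTable,
    families: list[CliqueFamily],
) -> float:
    brain = m > 0
    x, y, z = np.nonzero(brain)
    data = float(lp[x, y, z, m[brain]].sum())
    gibbs = total_energy(labels_template.with_values(m.astype(np.int16)), table, families)
    return data + gibbs


def icm_refine(
    g: Volume,
    m0: LabelMap,
    prior: ShapePriorField,
    classes: ClassDensities,
    table: PotentialTable,
    families: list[CliqueFamily],
    opts: ICMOptions | None = None,
) -> SegmentationResult:
    """Iterated conditional modes on the joint model, starting from ``m0``.

    Raster-order sweeps with in-place updates; a voxel is relabelled only on
    strict improvement of its conditional objective, so the global objective
    J(m) = sum_p [log p(g_p|m_p) + log p_sp(m_p)] + E_V(m) is non-decreasing
    sweep to sweep.  Stops when the fraction of changed voxels falls below
    ``stop_fraction`` or after ``max_sweeps``.
    """
    opts = opts or ICMOptions()
    check_same_lattice(g, m0)
    lp = _class_loglik(classes, g) + log_prior_field(prior)
    m = m0.values.astype(np.int64)
    n_brain = int((m > 0).sum())
    if n_brain == 0:
        return SegmentationResult(m0.copy(), [0.0], [0.0])
    packed = pack_for_kernel(table, families)
    j0 = _objective(m, lp, m0, table, families)
    if not np.isfinite(j0):
        raise SegmentationError(f"non-finite initial objective {j0}")
    energy_trace = [j0]
    changed_fraction: list[float] = []
    for sweep in range(opts.max_sweeps):
        if opts.reestimate_potentials and sweep > 0:
            table = estimate_potentials(m0.with_values(m.astype(np.int16)), families)
            packed = pack_for_kernel(table, families)
        changed = icm_sweep(m, lp, *packed)
        frac = changed / n_brain
        changed_fraction.append(frac)
        j = _objective(m, lp, m0, table, families)
        if not np.isfinite(j):
            raise SegmentationError(f"non-finite objective at sweep {sweep}")
        energy_trace.append(j)
        logger.info("ICM sweep %d: changed %.5f%%, J=%.2f", sweep + 1, 100 * frac, j)
        if frac < opts.stop_fraction:
            break
    labels = m0.with_values(m.astype(np.int16))
    return SegmentationResult(labels, energy_trace, changed_fraction)


def majority_vote(
    candidates: list[LabelMap], ranks: list[int] | None = None
) -> LabelMap:
    """Per-voxel modal label; ties go to the best-ranked candidate's vote.

    ``ranks`` lists candidate indices from best to worst prototype NCC rank
    (default: the given order)."""
    if not candidates:
        raise SegmentationError("no candidate segmentations to fuse")
    for c in candidates[1:]:
        check_same_lattice(candidates[0], c)
    if ranks is None:
        ranks = list(range(len(candidates)))
    stack = np.stack([c.values for c in candidates])  # (n, X, Y, Z)
    counts = np.stack([(stack == lab).sum(axis=0) for lab in range(4)])  # (4, X, Y, Z)
    top = counts.max(axis=0)
    modal = counts.argmax(axis=0).astype(np.int16)
    n_top = (counts == top).sum(axis=0)
    tied = n_top > 1
    if tied.any():
        unresolved = tied.copy()
        for idx in ranks:
            vote = candidates[idx].values
            ok = unresolved & (np.take_along_axis(counts, vote[None].astype(np.int64), axis=0)[0] == top)
            modal[ok] = vote[ok]
            unresolved &= ~ok
            if not unresolved.any():
                break
    return candidates[0].with_values(modal)


def segment_with_prototype(
    test: Volume,
    training: list[SubjectPair],
    prototype: SubjectPair,
    params: SegmenterParams | None = None,
    _shared: dict | None = None,
) -> SegmentationResult:
    """Run the single-prototype pipeline: equalize, register, prior, LCDG,
    initial map, analytic potentials, ICM."""
    params = params or SegmenterParams()
    stage = "preprocess"
    try:
        shared = _shared if _shared is not None else {}
        if "smoothed" not in shared:
            shared["smoothed"] = (
                test if params.skip_ggmrf else ggmrf_smooth(test, params.ggmrf)
            )
        smoothed = shared["smoothed"]

        stage = "lcdg"
        if "classes" not in shared:
            f_emp = empirical_density(smoothed)
            model = fit_lcdg(f_emp, K=params.lcdg_k, opts=params.lcdg)
            shared["lcdg_model"] = model
            shared["classes"] = partition_classes(model, n_classes=len(TISSUE_LABELS))
        classes = shared["classes"]

        stage = "registration"
        if params.assume_aligned:
            transform = AffineTransform12.identity(test.shape)
        else:
            transform = affine_register_mi(smoothed, prototype.grey, params.registration)

        stage = "equalize"
        if "equalized" not in shared:
            shared["equalized"] = [
                SubjectPair(equalize_to_reference(s.grey, smoothed), s.labels, s.provenance)
                for s in training
            ]
        equalized = shared["equalized"]

        stage = "shape_prior"
        prior = build_adaptive_prior(smoothed, equalized, transform, params.prior)

        stage = "initial_map"
        m0 = initial_map(prior, classes, smoothed)

        stage = "potentials"
        families = enumerate_families(params.mgrf_order)
        table = estimate_potentials(m0, families)

        stage = "icm"
        result = icm_refine(smoothed, m0, prior, classes, table, families, params.icm)
        result.provenance.update(
            {
                "prototype": prototype.provenance,
                "transform": transform.to_json(),
                "potentials": table.to_json(),
                "mgrf_order": params.mgrf_order,
            }
        )
        return result
    except Exception as err:
        raise SegmentationError(f"stage {stage!r} failed: {err}") from err


def segment_subject(
    test: Volume,
    training: list[SubjectPair],
    params: SegmenterParams | None = None,
    return_candidates: bool = False,
):
    """Full multi-prototype segmentation with majority-vote fusion."""
    params = params or SegmenterParams()
    t0 = time.time()
    smoothed = test if params.skip_ggmrf else ggmrf_smooth(test, params.ggmrf)
    matches = select_prototypes(smoothed, training, params.k_prototypes)
    shared: dict = {"smoothed": smoothed}
    results = []
    for match in matches:
        logger.info("segmenting with prototype %d (ncc=%.4f)", match.index, match.score)
        results.append(
            segment_with_prototype(test, training, match.subject, params, _shared=shared)
        )
    fused = majority_vote([r.labels for r in results])
    logger.info("segmentation finished in %.1f s", time.time() - t0)
    if return_candidates:
        return fused, results, matches
    return fused


def compare_mgrf_orders(
    test: Volume,
    training: list[SubjectPair],
    params: SegmenterParams | None = None,
    orders: tuple[int, ...] = (2, 4),
) -> dict[int, LabelMap]:
    """Paired comparison of MGRF orders sharing every stage up to the initial map.

    For each prototype the smoothing, registration, equalization, shape prior,
    LCDG fit and initial map are computed once; only the potential estimation
    and ICM refinement differ between the orders."""
    params = params or SegmenterParams()
    smoothed = test if params.skip_ggmrf else ggmrf_smooth(test, params.ggmrf)
    matches = select_prototypes(smoothed, training, params.k_prototypes)
    f_emp = empirical_density(smoothed)
    model = fit_lcdg(f_emp, K=params.lcdg_k, opts=params.lcdg)
    classes = partition_classes(model, n_classes=len(TISSUE_LABELS))
    equalized = [
        SubjectPair(equalize_to_reference(s.grey, smoothed), s.labels, s.provenance)
        for s in training
    ]
    per_order: dict[int, list[LabelMap]] = {o: [] for o in orders}
    for match in matches:
        if params.assume_aligned:
            transform = AffineTransform12.identity(test.shape)
        else:
            transform = affine_register_mi(smoothed, match.subject.grey, params.registration)
        prior = build_adaptive_prior(smoothed, equalized, transform, params.prior)
        m0 = initial_map(prior, classes, smoothed)
        for order in orders:
            families = enumerate_families(order)
            table = estimate_potentials(m0, families)
            res = icm_refine(smoothed, m0, prior, classes, table, families, params.icm)
            per_order[order].append(res.labels)
    return {o: majority_vote(cands) for o, cands in per_order.items()}
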