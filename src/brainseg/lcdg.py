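"""First-order intensity model: linear combination of discrete Gaussians (LCDG).

The empirical grey-level density of the brain voxels is approximated by a
signed mixture

    P(q) = sum_k w_p:k psi(q | theta_p:k)  -  sum_j w_n:j psi(q | theta_n:j)

of *discrete* Gaussians (a continuous Gaussian integrated over unit grey-level
bins, with the two edge bins absorbing the tails so each component sums to 1
exactly).  All weights are non-negative and satisfy the signed constraint
sum(w_pos) - sum(w_neg) = 1.  A small number of dominant positive components
carry the tissue modes; subordinate positive/negative components absorb the
deviations of the empirical density from the dominant mixture.

Fitting is a three-phase procedure:

1. conventional (histogram-weighted) EM for the K dominant positive DGs;
2. the signed deviation (empirical minus dominant mixture) is split into its
   positive and negative parts and each part's normalized magnitude is
   approximated by a small DG mixture — the subordinate components;
3. joint refinement of all components by EM modified for signed weights under
   the unit signed-sum constraint, with a guarded acceptance rule: a step is
   kept only if the sup-distance between model and empirical density does not
   increase, so the recorded refinement trace is monotone.

The fitted mixture is then partitioned into per-class conditional densities
p(q|l): thresholds sit at the minima of the mixed density between consecutive
dominant means, and each subordinate component joins the class of the nearest
dominant mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr  # standard normal CDF, high precision

from .volume_io import Volume

logger = logging.getLogger(__name__)

_TINY = 1e-12


class LCDGError(ValueError):
    pass


@dataclass
class DGComponent:
    """One discrete Gaussian: mean, std, non-negative weight and a sign."""

    mu: float
    sigma: float
    w: float
    sign: int = 1  # +1 positive, -1 negative

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise LCDGError(f"sigma must be > 0, got {self.sigma}")
        if self.w < 0:
            raise LCDGError(f"weights are magnitudes and must be >= 0, got {self.w}")
        if self.sign not in (1, -1):
            raise LCDGError("sign must be +1 or -1")

    def pdf(self, Q: int) -> np.ndarray:
        return dg_pdf(self.mu, self.sigma, Q)


def dg_pdf(mu: float, sigma: float, Q: int) -> np.ndarray:
    """Discrete Gaussian over {0..Q-1}: bin-integrated normal, tail-absorbing.

    psi(q) = Phi((q+0.5-mu)/sigma) - Phi((q-0.5-mu)/sigma) for interior q,
    with psi(0) and psi(Q-1) integrating to -inf / +inf, so sum_q psi = 1.
    """
    if sigma <= 0:
        raise LCDGError(f"sigma must be > 0, got {sigma}")
    edges = (np.arange(Q - 1) + 0.5 - mu) / sigma
    cdf = ndtr(edges)
    return np.diff(np.concatenate([[0.0], cdf, [1.0]]))


def empirical_density(g: Volume, mask: np.ndarray | None = None) -> np.ndarray:
    """Normalized grey-level histogram of the masked voxels."""
    if mask is None:
        mask = g.values > 0
    vals = g.values[mask]
    if vals.size == 0:
        raise LCDGError("empty mask")
    hist = np.bincount(vals.ravel(), minlength=g.Q).astype(float)
    return hist / hist.sum()


@dataclass
class LCDGModel:
    """Signed DG mixture: K dominant positive components (means ascending),
    plus positive and negative subordinates."""

    dominant: list[DGComponent]
    sub_pos: list[DGComponent] = field(default_factory=list)
    sub_neg: list[DGComponent] = field(default_factory=list)
    Q: int = 256

    def __post_init__(self) -> None:
        self.dominant = sorted(self.dominant, key=lambda c: c.mu)
        for c in self.dominant + self.sub_pos:
            if c.sign != 1:
                raise LCDGError("dominant/positive-subordinate components must have sign +1")
        for c in self.sub_neg:
            if c.sign != -1:
                raise LCDGError("negative subordinates must have sign -1")

    @property
    def components(self) -> list[DGComponent]:
        return self.dominant + self.sub_pos + self.sub_neg

    def signed_weight_sum(self) -> float:
        return sum(c.w for c in self.dominant + self.sub_pos) - sum(
            c.w for c in self.sub_neg
        )

    def raw_density(self) -> np.ndarray:
        p = np.zeros(self.Q)
        for c in self.components:
            p += c.sign * c.w * c.pdf(self.Q)
        return p

    def density(self) -> np.ndarray:
        """Total mixture density clipped at 0 (the signed sum can dip below)."""
        return np.clip(self.raw_density(), 0.0, None)

    def to_json(self) -> str:
        enc = lambda cs: [[c.mu, c.sigma, c.w, c.sign] for c in cs]
        return json.dumps(
            {
                "Q": self.Q,
                "dominant": enc(self.dominant),
                "sub_pos": enc(self.sub_pos),
                "sub_neg": enc(self.sub_neg),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "LCDGModel":
        d = json.loads(s)
        dec = lambda rows, sign: [DGComponent(m, sg, w, sign) for m, sg, w, _ in rows]
        return cls(
            dominant=dec(d["dominant"], 1),
            sub_pos=dec(d["sub_pos"], 1),
            sub_neg=dec(d["sub_neg"], -1),
            Q=d["Q"],
        )


@dataclass
class LCDGFitOptions:
    max_subordinate: int = 4  # cap per sign
    min_weight: float = 1e-3
    tol: float = 1e-4  # sup-norm density change stopping rule
    max_iters: int = 100
    em_iters_phase1: int = 200
    # grey levels are integer-quantized, so a component std below one bin
    # width is not identifiable; floor sigma at the quantization step
    sigma_floor: float = 1.0
    merge_duplicates: bool = True  # collapse redundant same-mode dominant splits


def _weighted_em(
    f: np.ndarray, k: int, n_iters: int, sigma_floor: float, Q: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram-weighted EM for a k-component positive DG mixture.

    Deterministic: means initialize at the density's quantile positions.
    Returns (w, mu, sigma)."""
    q = np.arange(Q, dtype=float)
    cdf = np.cumsum(f)
    targets = (np.arange(k) + 0.5) / k
    mu = np.array([q[np.searchsorted(cdf, t)] for t in targets], dtype=float)
    total_var = float(np.sum(f * q**2) - np.sum(f * q) ** 2)
    sigma = np.full(k, max(np.sqrt(max(total_var, 1.0)) / k, sigma_floor))
    w = np.full(k, 1.0 / k)
    for _ in range(n_iters):
        comp = np.stack([dg_pdf(m, s, Q) for m, s in zip(mu, sigma)])  # (k, Q)
        num = w[:, None] * comp
        den = num.sum(axis=0)
        resp = num / np.maximum(den, _TINY)  # (k, Q)
        mass = resp @ f
        new_w = np.maximum(mass, _TINY)
        new_mu = (resp * q) @ f / new_w
        new_sigma = np.sqrt(np.maximum((resp * (q - new_mu[:, None]) ** 2 @ f) / new_w, 0.0))
        new_sigma = np.maximum(new_sigma, sigma_floor)
        shift = np.max(np.abs(new_mu - mu))
        w, mu, sigma = new_w / new_w.sum(), new_mu, new_sigma
        if shift < 1e-6:
            break
    return w, mu, sigma


def _fit_part(
    part: np.ndarray, max_comps: int, opts: LCDGFitOptions, Q: int
) -> list[tuple[float, float, float]]:
    """Approximate a non-negative deviation part by a small DG mixture.

    Returns (w, mu, sigma) triples scaled by the part's total mass."""
    mass = float(part.sum())
    if mass <= opts.min_weight or max_comps == 0:
        return []
    norm = part / mass
    # one component per local maximum of the part, capped
    interior = norm[1:-1]
    peaks = np.nonzero((interior > norm[:-2]) & (interior >= norm[2:]) & (interior > 0))[0]
    k = int(np.clip(len(peaks), 1, max_comps))
    w, mu, sigma = _weighted_em(norm, k, 100, opts.sigma_floor, Q)
    return [(mass * wi, mi, si) for wi, mi, si in zip(w, mu, sigma) if mass * wi >= opts.min_weight]


def _model_arrays(model: LCDGModel):
    comps = model.components
    w = np.array([c.w for c in comps])
    mu = np.array([c.mu for c in comps])
    sigma = np.array([c.sigma for c in comps])
    sign = np.array([c.sign for c in comps], dtype=float)
    return w, mu, sigma, sign


def _refine_signed(
    f: np.ndarray, model: LCDGModel, opts: LCDGFitOptions
) -> tuple[LCDGModel, list[float]]:
    """Phase 3: modified EM with signed weights under sum(w+) - sum(w-) = 1.

    Steps are accepted only while the model-vs-empirical sup-distance does not
    increase, so the returned trace is monotone non-increasing."""
    Q = model.Q
    q = np.arange(Q, dtype=float)
    w, mu, sigma, sign = _model_arrays(model)
    n_dom = len(model.dominant)

    def density(w_, mu_, s_):
        comp = np.stack([dg_pdf(m, s, Q) for m, s in zip(mu_, s_)])
        return (sign * w_) @ comp, comp

    cur_p, comp = density(w, mu, sigma)
    trace = [float(np.max(np.abs(cur_p - f)))]
    for _ in range(opts.max_iters):
        p_clip = np.maximum(cur_p, _TINY)
        gamma = (sign[:, None] * w[:, None] * comp) / p_clip  # signed responsibilities
        signed_mass = gamma @ f
        new_w = sign * signed_mass  # magnitude, may go negative for a dead component
        new_w = np.maximum(new_w, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            new_mu = np.where(
                np.abs(signed_mass) > 1e-8, (gamma * q) @ f / signed_mass, mu
            )
            var = np.where(
                np.abs(signed_mass) > 1e-8,
                ((gamma * (q - new_mu[:, None]) ** 2) @ f) / signed_mass,
                sigma**2,
            )
        bad = ~np.isfinite(new_mu) | ~np.isfinite(var) | (var <= opts.sigma_floor**2)
        new_mu = np.where(bad, mu, np.clip(new_mu, 0, Q - 1))
        new_sigma = np.where(bad, sigma, np.sqrt(np.maximum(var, opts.sigma_floor**2)))
        s = float(np.sum(sign * new_w))
        if s <= 0.5:  # degenerate step; keep the current model
            break
        new_w = new_w / s
        new_p, new_comp = density(new_w, new_mu, new_sigma)
        sup = float(np.max(np.abs(new_p - f)))
        if sup > trace[-1] + _TINY:
            break  # guarded acceptance: never worsen the fit
        delta = float(np.max(np.abs(new_p - cur_p)))
        w, mu, sigma, comp, cur_p = new_w, new_mu, new_sigma, new_comp, new_p
        trace.append(sup)
        if delta < opts.tol:
            break

    comps = [
        DGComponent(float(m), float(s), float(wi), int(sg))
        for m, s, wi, sg in zip(mu, sigma, w, sign)
    ]
    refined = LCDGModel(
        dominant=comps[:n_dom],
        sub_pos=[c for c in comps[n_dom:] if c.sign == 1],
        sub_neg=[c for c in comps[n_dom:] if c.sign == -1],
        Q=Q,
    )
    return refined, trace


def _moment_merge(a: DGComponent, b: DGComponent) -> DGComponent:
    """Single DG with the first two moments of the weighted pair."""
    w = a.w + b.w
    mu = (a.mu * a.w + b.mu * b.w) / max(w, _TINY)
    second = (a.w * (a.sigma**2 + a.mu**2) + b.w * (b.sigma**2 + b.mu**2)) / max(w, _TINY)
    return DGComponent(mu, float(np.sqrt(max(second - mu**2, 0.25))), w, 1)


def _merge_duplicates(model: LCDGModel, f_emp: np.ndarray) -> LCDGModel:
    """Collapse dominant pairs that EM split across a single mode.

    An adjacent pair is merged only if replacing it with one moment-matched DG
    does not worsen the sup-distance to the empirical density, so genuinely
    distinct class modes — even heavily overlapping ones — are kept apart
    while redundant same-mode splits collapse."""
    dominant = list(model.dominant)
    changed = True
    while changed and len(dominant) > 1:
        changed = False
        cur = LCDGModel(dominant, model.sub_pos, model.sub_neg, model.Q)
        cur_sup = float(np.max(np.abs(cur.raw_density() - f_emp)))
        for i in range(len(dominant) - 1):
            trial = dominant[:i] + [_moment_merge(dominant[i], dominant[i + 1])] + dominant[i + 2 :]
            cand = LCDGModel(trial, model.sub_pos, model.sub_neg, model.Q)
            if float(np.max(np.abs(cand.raw_density() - f_emp))) <= cur_sup + 1e-9:
                dominant = trial
                changed = True
                break
    return LCDGModel(dominant, model.sub_pos, model.sub_neg, model.Q)


def _normalize_constraint(model: LCDGModel) -> LCDGModel:
    s = model.signed_weight_sum()
    if s <= 0:
        raise LCDGError("signed weight sum collapsed to <= 0")
    scale = 1.0 / s
    fix = lambda cs: [DGComponent(c.mu, c.sigma, c.w * scale, c.sign) for c in cs]
    return LCDGModel(fix(model.dominant), fix(model.sub_pos), fix(model.sub_neg), model.Q)


def fit_lcdg(
    f_emp: np.ndarray,
    K: int = 4,
    opts: LCDGFitOptions | None = None,
    return_trace: bool = False,
):
    """Fit an LCDG with K dominant modes to a normalized empirical density."""
    opts = opts or LCDGFitOptions()
    f_emp = np.asarray(f_emp, dtype=float)
    Q = f_emp.size
    if K < 2:
        raise LCDGError("K must be >= 2")
    if abs(f_emp.sum() - 1.0) > 1e-6 or np.any(f_emp < 0):
        raise LCDGError("f_emp must be a normalized density")
    if np.count_nonzero(f_emp) < K:
        raise LCDGError(
            f"K={K} exceeds the {np.count_nonzero(f_emp)} distinct grey levels in support"
        )

    # phase 1: dominant positive mixture
    w, mu, sigma = _weighted_em(f_emp, K, opts.em_iters_phase1, opts.sigma_floor, Q)
    dominant = [DGComponent(float(m), float(s), float(wi)) for wi, m, s in zip(w, mu, sigma)]
    model = LCDGModel(dominant, [], [], Q)

    # phase 2: subordinate components from the signed deviation
    deviation = f_emp - model.raw_density()
    sub_pos = [
        DGComponent(m, s, wi, 1)
        for wi, m, s in _fit_part(np.clip(deviation, 0, None), opts.max_subordinate, opts, Q)
    ]
    sub_neg = [
        DGComponent(m, s, wi, -1)
        for wi, m, s in _fit_part(np.clip(-deviation, 0, None), opts.max_subordinate, opts, Q)
    ]
    model = _normalize_constraint(LCDGModel(dominant, sub_pos, sub_neg, Q))

    # phase 3: joint signed refinement
    model, trace = _refine_signed(f_emp, model, opts)

    # finalization: prune feather-weight subordinates, merge duplicate modes
    model = LCDGModel(
        model.dominant,
        [c for c in model.sub_pos if c.w >= opts.min_weight],
        [c for c in model.sub_neg if c.w >= opts.min_weight],
        Q,
    )
    if opts.merge_duplicates:
        model = _merge_duplicates(model, f_emp)
    model = _normalize_constraint(model)
    return (model, trace) if return_trace else model


@dataclass
class ClassDensities:
    """Per-class conditional densities p(q|l) with priors and mode thresholds.

    Classes are ordered by ascending dominant mean; ``densities[i]`` is the
    normalized density of class i and ``thresholds`` the grey levels separating
    consecutive classes (strictly increasing)."""

    densities: np.ndarray  # (n_classes, Q)
    priors: np.ndarray  # (n_classes,)
    thresholds: list[int]

    def __post_init__(self) -> None:
        sums = self.densities.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > 1e-6:
            raise LCDGError("class densities must each sum to 1")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise LCDGError("thresholds must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return self.densities.shape[0]


def partition_classes(model: LCDGModel, n_classes: int = 3) -> ClassDensities:
    """Split the fitted mixture into per-class conditional densities.

    Dominant modes are grouped into ``n_classes`` groups by repeatedly merging
    the adjacent pair with the smallest mean gap; thresholds are the minima of
    the mixed density between consecutive group means; subordinates join the
    group with the nearest dominant mean.
    """
    doms = model.dominant
    if n_classes > len(doms):
        raise LCDGError(f"n_classes={n_classes} exceeds {len(doms)} dominant modes")
    mus = [c.mu for c in doms]
    if len(set(np.round(mus, 9))) < len(mus):
        raise LCDGError("dominant means are not separated")
    # group consecutive dominant modes: merge smallest adjacent gaps first
    groups = [[i] for i in range(len(doms))]
    while len(groups) > n_classes:
        gaps = [
            doms[g2[0]].mu - doms[g1[-1]].mu for g1, g2 in zip(groups, groups[1:])
        ]
        j = int(np.argmin(gaps))
        groups[j] = groups[j] + groups[j + 1]
        del groups[j + 1]

    def group_mean(g):
        wsum = sum(doms[i].w for i in g)
        return sum(doms[i].mu * doms[i].w for i in g) / max(wsum, _TINY)

    centers = [group_mean(g) for g in groups]
    mixed = model.density()
    thresholds = []
    for g1, g2 in zip(groups, groups[1:]):
        lo = int(np.ceil(doms[g1[-1]].mu))
        hi = int(np.floor(doms[g2[0]].mu))
        if hi <= lo:
            hi = lo + 1
        seg = mixed[lo : hi + 1]
        thresholds.append(lo + int(np.argmin(seg)))

    # assign subordinates to the group whose dominant mean is nearest
    assign: list[list[DGComponent]] = [
        [doms[i] for i in g] for g in groups
    ]
    dom_mus = np.array(mus)
    dom_group = np.zeros(len(doms), dtype=int)
    for gi, g in enumerate(groups):
        for i in g:
            dom_group[i] = gi
    for c in model.sub_pos + model.sub_neg:
        nearest_dom = int(np.argmin(np.abs(dom_mus - c.mu)))
        assign[dom_group[nearest_dom]].append(c)

    densities = np.zeros((n_classes, model.Q))
    priors = np.zeros(n_classes)
    for gi, comps in enumerate(assign):
        sub = np.zeros(model.Q)
        for c in comps:
            sub += c.sign * c.w * c.pdf(model.Q)
        priors[gi] = sum(c.sign * c.w for c in comps)
        sub = np.clip(sub, 0.0, None)
        total = sub.sum()
        if total <= 0:
            raise LCDGError(f"class {gi} density vanished after clipping")
        densities[gi] = sub / total
    priors = np.clip(priors, _TINY, None)
    priors = priors / priors.sum()
    return ClassDensities(densities, priors, thresholds)
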