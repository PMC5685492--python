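"""Higher-order Markov-Gibbs random field model of label maps.

The unconditional spatial model P_V(m) is a Gibbs distribution

    P_V(m) = (1/Z_V) exp( sum_a sum_{c in C_a} V_a(labels of c) )

over translation-invariant clique families built on the 26-neighbourhood:

* 3 pairwise families, grouped by neighbour distance {1, sqrt2, sqrt3}
  (3 + 6 + 4 undirected offset classes pooled per family);
* 13 triple families of collinear triples {p - d, p, p + d}, one per unique
  26-neighbourhood direction d;
* 3 quad families of planar 2x2 squares (xy, xz, yz planes).

For symmetry, a potential depends only on the equality pattern of the labels
in the clique.  The maximum-likelihood potentials are approximated
analytically from the configuration frequencies F of a single map m0 (the
initial voxel-wise classification):

    V2:eq  = -V2:ne  = 4 (F_eq  - 1/2)
    V3:eq3 = -V3:eq2 = (16/3) (F_eq3 - 1/4)
    V4:eq4 = lam (F_eq4 - 1/8),  V4:eq3 = lam (F_eq3 - 1/2),
    V4:eq2 = lam (F_eq2 - 3/8) = -(V4:eq4 + V4:eq3)

with the shared factor lam pooled over the quad families:

    lam = sum_a [(F_eq4-1/8)^2 + (F_eq3-1/2)^2 + (F_eq2-3/8)^2]
        / sum_a [7/64 (F_eq4-1/8)^2 + 1/4 (F_eq3-1/2)^2 + 15/64 (F_eq2-3/8)^2]

Cliques touching background (label 0) are excluded, so the statistics are
brain-only.  The partition function Z_V is never needed: inference (ICM) uses
only energy differences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
import numpy as np

from .volume_io import LabelMap

logger = logging.getLogger(__name__)


class MGRFError(ValueError):
    pass


@dataclass(frozen=True)
class CliqueFamily:
    """A translation-invariant family of order-s cliques.

    ``shapes`` is a tuple of clique shapes pooled into this family; each shape
    lists the s-1 offsets of the clique's members relative to its anchor voxel
    (the anchor itself is implicit at offset (0,0,0)).  Anchoring each clique
    at its lexicographically smallest member counts it exactly once over the
    lattice; cliques crossing the boundary are dropped.
    """

    id: str
    order: int
    shapes: tuple[tuple[tuple[int, int, int], ...], ...]
    tag: str = ""


# the 13 unique 26-neighbourhood directions (one per +/- pair)
DIRECTIONS_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_PAIR_GROUPS = {
    "pair_d1": [d for d in DIRECTIONS_13 if sum(abs(c) for c in d) == 1],
    "pair_d2": [d for d in DIRECTIONS_13 if sum(abs(c) for c in d) == 2],
    "pair_d3": [d for d in DIRECTIONS_13 if sum(abs(c) for c in d) == 3],
}

_QUAD_PLANES = {"quad_xy": (0, 1), "quad_xz": (0, 2), "quad_yz": (1, 2)}


def enumerate_families(max_order: int = 4) -> list[CliqueFamily]:
    """The clique families of the model; ``max_order=2`` keeps pairwise only."""
    if max_order not in (2, 3, 4):
        raise MGRFError("max_order must be 2, 3 or 4")
    fams = [
        CliqueFamily(fid, 2, tuple((d,) for d in dirs), tag=f"pairwise distance class {fid[-1]}")
        for fid, dirs in _PAIR_GROUPS.items()
    ]
    if max_order >= 3:
        for d in DIRECTIONS_13:
            name = "triple_" + "".join(f"{c:+d}" for c in d)
            two_d = tuple(2 * c for c in d)
            fams.append(
                CliqueFamily(name, 3, ((d, two_d),), tag=f"collinear triple along {d}")
            )
    if max_order >= 4:
        for fid, (i, j) in _QUAD_PLANES.items():
            e1 = tuple(1 if k == i else 0 for k in range(3))
            e2 = tuple(1 if k == j else 0 for k in range(3))
            e12 = tuple(a + b for a, b in zip(e1, e2))
            fams.append(CliqueFamily(fid, 4, ((e1, e2, e12),), tag=f"2x2 square in {fid[-2:]}"))
    return fams


def _shape_views(m: np.ndarray, shape) -> list[np.ndarray] | None:
    """Aligned array views of a clique shape's members over all valid anchors."""
    offsets = [(0, 0, 0), *shape]
    lo = [max(0, -min(o[i] for o in offsets)) for i in range(3)]
    hi = [m.shape[i] - max(0, max(o[i] for o in offsets)) for i in range(3)]
    if any(h <= l for l, h in zip(lo, hi)):
        return None
    views = []
    for o in offsets:
        sl = tuple(slice(l + o[i], h + o[i]) for i, (l, h) in enumerate(zip(lo, hi)))
        views.append(m[sl])
    return views


def clique_count(family: CliqueFamily, grid_shape, brain_mask=None) -> int:
    """Number of in-bounds cliques of a family (optionally brain-only)."""
    dummy = np.zeros(grid_shape, dtype=np.int8)
    total = 0
    for shape in family.shapes:
        views = _shape_views(dummy, shape)
        if views is None:
            continue
        if brain_mask is None:
            total += views[0].size
        else:
            mviews = _shape_views(brain_mask, shape)
            valid = np.ones(mviews[0].shape, dtype=bool)
            for v in mviews:
                valid &= v
            total += int(valid.sum())
    return total


def _family_class_counts(
    m: np.ndarray, family: CliqueFamily, brain_only: bool
) -> np.ndarray:
    """Raw configuration-class counts for one family.

    order 2 -> [n_eq, n_ne]; order 3 -> [n_eq3, n_eq2];
    order 4 -> [n_eq4, n_eq3, n_eq2]."""
    n_classes = {2: 2, 3: 2, 4: 3}[family.order]
    counts = np.zeros(n_classes, dtype=np.int64)
    for shape in family.shapes:
        views = _shape_views(m, shape)
        if views is None:
            continue
        valid = np.ones(views[0].shape, dtype=bool)
        if brain_only:
            for v in views:
                valid &= v != 0
        if family.order == 2:
            eq = (views[0] == views[1]) & valid
            counts[0] += int(eq.sum())
            counts[1] += int(valid.sum()) - int(eq.sum())
        elif family.order == 3:
            eq = (views[0] == views[1]) & (views[1] == views[2]) & valid
            counts[0] += int(eq.sum())
            counts[1] += int(valid.sum()) - int(eq.sum())
        else:
            npairs = np.zeros(views[0].shape, dtype=np.int8)
            for i in range(4):
                for j in range(i + 1, 4):
                    npairs += views[i] == views[j]
            counts[0] += int(((npairs == 6) & valid).sum())
            counts[1] += int(((npairs == 3) & valid).sum())
            counts[2] += int(valid.sum()) - int(((npairs == 6) & valid).sum()) - int(
                ((npairs == 3) & valid).sum()
            )
    return counts


@dataclass
class ConfigFrequencies:
    """Relative configuration-class frequencies per family, plus clique counts."""

    freqs: dict[str, np.ndarray]
    counts: dict[str, int]
    orders: dict[str, int]


def config_frequencies(
    m: LabelMap, families: list[CliqueFamily], brain_only: bool = True
) -> ConfigFrequencies:
    """Equality-pattern frequencies of every family on a label map."""
    vals = m.values
    freqs, counts, orders = {}, {}, {}
    for fam in families:
        c = _family_class_counts(vals, fam, brain_only)
        total = int(c.sum())
        if total == 0:
            raise MGRFError(f"family {fam.id} has zero in-bounds cliques")
        freqs[fam.id] = c / total
        counts[fam.id] = total
        orders[fam.id] = fam.order
    return ConfigFrequencies(freqs, counts, orders)


@dataclass
class PotentialTable:
    """Analytic Gibbs potentials per family and the shared quad factor lam.

    ``v2[fam]`` is V2:eq (V2:ne = -V2:eq); ``v3[fam]`` is V3:eq3
    (V3:eq2 = -V3:eq3); ``v4[fam]`` is (V4:eq4, V4:eq3, V4:eq2) with
    V4:eq2 = -(V4:eq4 + V4:eq3)."""

    v2: dict[str, float]
    v3: dict[str, float]
    v4: dict[str, tuple[float, float, float]]
    lambda_star: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "v2": self.v2,
                "v3": self.v3,
                "v4": {k: list(v) for k, v in self.v4.items()},
                "lambda_star": self.lambda_star,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "PotentialTable":
        d = json.loads(s)
        return cls(d["v2"], d["v3"], {k: tuple(v) for k, v in d["v4"].items()}, d["lambda_star"])

    @classmethod
    def zeros(cls, families: list[CliqueFamily]) -> "PotentialTable":
        return cls(
            {f.id: 0.0 for f in families if f.order == 2},
            {f.id: 0.0 for f in families if f.order == 3},
            {f.id: (0.0, 0.0, 0.0) for f in families if f.order == 4},
            0.0,
        )


_QUAD_REF = np.array([1.0 / 8.0, 1.0 / 2.0, 3.0 / 8.0])
_QUAD_DENOM_W = np.array([7.0 / 64.0, 1.0 / 4.0, 15.0 / 64.0])


def estimate_potentials(
    m0: LabelMap, families: list[CliqueFamily], brain_only: bool = True
) -> PotentialTable:
    """Analytic ML potential estimates from the initial map's statistics."""
    fr = config_frequencies(m0, families, brain_only)
    v2, v3, v4 = {}, {}, {}
    quad_devs = {}
    for fam in families:
        f = fr.freqs[fam.id]
        if fam.order == 2:
            v2[fam.id] = 4.0 * (f[0] - 0.5)
        elif fam.order == 3:
            v3[fam.id] = (16.0 / 3.0) * (f[0] - 0.25)
        else:
            quad_devs[fam.id] = f - _QUAD_REF
    lam = 0.0
    if quad_devs:
        num = sum(float(np.sum(d**2)) for d in quad_devs.values())
        den = sum(float(np.sum(_QUAD_DENOM_W * d**2)) for d in quad_devs.values())
        if den == 0.0:
            logger.warning(
                "all quad frequencies at reference values; lambda* set to 0"
            )
            lam = 0.0
        else:
            lam = num / den
        for fid, d in quad_devs.items():
            v4[fid] = (lam * d[0], lam * d[1], lam * d[2])
    return PotentialTable(v2, v3, v4, lam)


def _clique_potential(labels, fam: CliqueFamily, table: PotentialTable) -> float:
    if fam.order == 2:
        v = table.v2[fam.id]
        return v if labels[0] == labels[1] else -v
    if fam.order == 3:
        v = table.v3[fam.id]
        return v if labels[0] == labels[1] == labels[2] else -v
    npairs = sum(
        labels[i] == labels[j] for i in range(4) for j in range(i + 1, 4)
    )
    v4 = table.v4[fam.id]
    if npairs == 6:
        return v4[0]
    if npairs == 3:
        return v4[1]
    return v4[2]


def local_energy(
    m: LabelMap,
    p: tuple[int, int, int],
    label: int,
    table: PotentialTable,
    families: list[CliqueFamily],
    brain_only: bool = True,
) -> float:
    """Sum of potentials over every clique containing voxel ``p``, with m_p
    temporarily set to ``label``.  Pure function; reference implementation for
    the compiled ICM kernel."""
    vals = m.values
    shape = vals.shape
    if not all(0 <= c < s for c, s in zip(p, shape)):
        raise MGRFError(f"voxel {p} outside lattice {shape}")

    def get(pos):
        return label if pos == p else int(vals[pos])

    e = 0.0
    for fam in families:
        for cshape in fam.shapes:
            offsets = [(0, 0, 0), *cshape]
            # anchors for which the clique contains p
            for o in offsets:
                anchor = (p[0] - o[0], p[1] - o[1], p[2] - o[2])
                members = [
                    (anchor[0] + oo[0], anchor[1] + oo[1], anchor[2] + oo[2])
                    for oo in offsets
                ]
                in_bounds = all(
                    0 <= mm[i] < shape[i] for mm in members for i in range(3)
                )
                if not in_bounds:
                    continue
                labels = [get(mm) for mm in members]
                if brain_only and any(l == 0 for l in labels):
                    continue
                e += _clique_potential(labels, fam, table)
    return e


def total_energy(
    m: LabelMap,
    table: PotentialTable,
    families: list[CliqueFamily],
    brain_only: bool = True,
) -> float:
    """Unnormalized Gibbs log-probability: sum of V over all cliques."""
    e = 0.0
    for fam in families:
        c = _family_class_counts(m.values, fam, brain_only).astype(float)
        if fam.order == 2:
            v = table.v2[fam.id]
            e += c[0] * v - c[1] * v
        elif fam.order == 3:
            v = table.v3[fam.id]
            e += c[0] * v - c[1] * v
        else:
            v4 = table.v4[fam.id]
            e += c[0] * v4[0] + c[1] * v4[1] + c[2] * v4[2]
    return e


def pack_for_kernel(table: PotentialTable, families: list[CliqueFamily]):
    """Flatten a potential table into the arrays the ICM kernel consumes."""
    off2_list, v2_list = [], []
    for fam in families:
        if fam.order != 2:
            continue
        for (d,) in fam.shapes:
            for s in (1, -1):
                off2_list.append((s * d[0], s * d[1], s * d[2]))
                v2_list.append(table.v2[fam.id])
    dir3_list, v3_list = [], []
    for fam in families:
        if fam.order != 3:
            continue
        d = fam.shapes[0][0]
        dir3_list.append(d)
        v3_list.append(table.v3[fam.id])
    e1_list, e2_list, v4_list = [], [], []
    for fam in families:
        if fam.order != 4:
            continue
        e1, e2, _ = fam.shapes[0]
        e1_list.append(e1)
        e2_list.append(e2)
        v4_list.append(table.v4[fam.id])
    as_arr = lambda lst, dt, w: (
        np.asarray(lst, dtype=dt).reshape(len(lst), w) if lst else np.zeros((0, w), dtype=dt)
    )
    return (
        as_arr(off2_list, np.int64, 3),
        np.asarray(v2_list, dtype=np.float64) if v2_list else np.zeros(0),
        as_arr(dir3_list, np.int64, 3),
        np.asarray(v3_list, dtype=np.float64) if v3_list else np.zeros(0),
        as_arr(e1_list, np.int64, 3),
        as_arr(e2_list, np.int64, 3),
        as_arr(v4_list, np.float64, 3),
    )
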