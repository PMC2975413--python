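"""Fuzzy c-means merging of oversegments into core segments.

Merging is confined to an ROI: a connected foreground blob and the
watershed segments inside it.  Each member segment contributes a
feature vector (mean intensity, intensity variance, distance from its
centroid to the blob centroid), scaled by the feature weights — default
(0.25, 0.25, 1.0), the centre distance weighted highest because only
adjacent segments may merge.  Fuzzy c-means with one cluster per core
segment, centres initialised at the core features, assigns every
oversegment the label of the core whose cluster gives it maximal
membership; an adjacency repair step falls back to the next-best
*adjacent* core when the winner's territory does not touch the
oversegment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import LabelMap
from .region_metrics import CORE, OVERSEGMENT, SegmentRecord
from .thresholding import BinaryMask

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (0.25, 0.25, 1.0)  # mean intensity, intensity variance, centre distance
DEFAULT_M = 2.0
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class MergeGroup:
    """One connected foreground blob (ROI) and the segments inside it."""

    component_id: int
    member_labels: tuple[int, ...]
    core_labels: tuple[int, ...]
    roi_center: tuple[float, float]


@dataclass(frozen=True)
class FCMResult:
    """Converged fuzzy c-means state."""

    memberships: np.ndarray  # (n, c), rows sum to 1
    centers: np.ndarray  # (c, p)
    objective_trace: np.ndarray
    n_iter: int
    converged: bool


def build_merge_groups(
    labels: LabelMap, mask: BinaryMask, records: list[SegmentRecord]
) -> list[MergeGroup]:
    """One group per 8-connected foreground component, with its members."""
    comp, n_comp = ndimage.label(mask.mask, structure=_EIGHT)
    by_label = {r.label: r for r in records}
    groups = []
    for k in range(1, n_comp + 1):
        sel = comp == k
        members = np.unique(labels.labels[sel])
        members = tuple(int(m) for m in members if m > 0)
        cores = tuple(m for m in members if by_label[m].classification == CORE)
        rr, cc = np.nonzero(sel)
        groups.append(
            MergeGroup(
                component_id=k,
                member_labels=members,
                core_labels=cores,
                roi_center=(float(rr.mean()), float(cc.mean())),
            )
        )
    return groups


def extract_features(
    group: MergeGroup,
    records: list[SegmentRecord],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    use_centroid_coords: bool = False,
) -> np.ndarray:
    """Weighted feature vectors for the group's member segments, in order.

    Weights scale the raw coordinates, so plain Euclidean distance in
    feature space realises the weighted metric.  With
    ``use_centroid_coords`` the scalar ROI-centre distance is replaced
    by the two centroid offsets from the ROI centre (same weight on
    both), which disambiguates cores lying at equal distances on
    opposite sides of the ROI centre.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or (w <= 0).any():
        raise ValueError("exactly three positive feature weights required")
    by_label = {r.label: r for r in records}
    feats = []
    for m in group.member_labels:
        r = by_label[m]
        drow = r.centroid[0] - group.roi_center[0]
        dcol = r.centroid[1] - group.roi_center[1]
        if use_centroid_coords:
            feats.append(
                [w[0] * r.mean_intensity, w[1] * r.intensity_variance, w[2] * drow, w[2] * dcol]
            )
        else:
            dist = float(np.hypot(drow, dcol))
            feats.append([w[0] * r.mean_intensity, w[1] * r.intensity_variance, w[2] * dist])
    return np.asarray(feats, dtype=float)


def fcm(
    data: np.ndarray,
    init_centers: np.ndarray,
    m: float = DEFAULT_M,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FCMResult:
    """Fuzzy c-means minimising J = sum_ik u_ik^m * d(x_k, v_i)^2.

    Alternates the membership update u_ik ∝ d(x_k, v_i)^(-2/(m-1))
    (rows normalised to 1) with the centre update
    v_i = sum_k u_ik^m x_k / sum_k u_ik^m, until the largest centre
    shift drops below ``tol``.  A datum coinciding with a centre gets
    crisp membership 1 there (0 at the rest).
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    v = np.atleast_2d(np.asarray(init_centers, dtype=float)).copy()
    n, p = x.shape
    c = v.shape[0]
    if c < 1:
        raise ValueError("need at least one cluster")
    if n < c:
        raise ValueError("need at least as many data points as clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    trace = []
    converged = False
    n_iter = 0
    u = _memberships(x, v, m)
    for n_iter in range(1, max_iter + 1):
        um = u**m
        v_new = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = np.abs(v_new - v).max()
        v = v_new
        u = _memberships(x, v, m)
        d2 = ((x[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
        trace.append(float((u.T**m * d2.T).sum()))
        if shift < tol:
            converged = True
            break
    return FCMResult(
        memberships=u,
        centers=v,
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
    )


def _memberships(x: np.ndarray, v: np.ndarray, m: float) -> np.ndarray:
    d2 = ((x[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)  # (n, c)
    u = np.zeros_like(d2)
    zero = d2 <= 0
    coincident = zero.any(axis=1)
    if coincident.any():
        # singularity rule: crisp membership at the (first) coinciding centre
        first = zero[coincident].argmax(axis=1)
        u[np.nonzero(coincident)[0], first] = 1.0
    reg = ~coincident
    if reg.any():
        w = d2[reg] ** (-1.0 / (m - 1.0))
        u[reg] = w / w.sum(axis=1, keepdims=True)
    return u


def merge_oversegments(
    labels: LabelMap,
    groups: list[MergeGroup],
    records: list[SegmentRecord],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    m: float = DEFAULT_M,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    use_centroid_coords: bool = False,
) -> LabelMap:
    """Absorb every identified oversegment into a core segment.

    Per group with at least one core and one oversegment, fuzzy c-means
    runs with c = number of cores, centres initialised at the core
    features (cluster i keeps its identity with core i throughout).
    Oversegments adopt the winning core's label subject to 8-adjacency
    with the core's growing territory; a group with oversegments but no
    core is left unmerged with a warning.  The result is compacted.
    """
    by_label = {r.label: r for r in records}
    out = labels.labels.copy()
    for g in groups:
        overs = [l for l in g.member_labels if by_label[l].classification == OVERSEGMENT]
        if not overs:
            continue
        if not g.core_labels:
            logger.warning(
                "ROI %d has %d oversegment(s) but no core segment; left unmerged",
                g.component_id,
                len(overs),
            )
            continue
        feats = extract_features(g, records, weights, use_centroid_coords)
        idx = {l: i for i, l in enumerate(g.member_labels)}
        centers = feats[[idx[l] for l in g.core_labels]]
        res = fcm(feats, centers, m=m, tol=tol, max_iter=max_iter)
        # membership of each oversegment in each core's cluster
        pref = {
            l: [g.core_labels[j] for j in np.argsort(-res.memberships[idx[l]], kind="stable")]
            for l in overs
        }
        territory = {core: out == core for core in g.core_labels}
        remaining = list(overs)
        while remaining:
            progressed = False
            for l in list(remaining):
                seg = labels.labels == l
                touching = ndimage.binary_dilation(seg, structure=_EIGHT)
                for core in pref[l]:
                    if (touching & territory[core]).any():
                        out[seg] = core
                        territory[core] |= seg
                        remaining.remove(l)
                        progressed = True
                        logger.info("merged oversegment %d into core %d", l, core)
                        break
                if progressed:
                    break
            if not progressed:
                # no remaining oversegment touches any core territory yet
                # (cannot happen in a connected blob, but stay safe):
                l = remaining.pop(0)
                core = pref[l][0]
                out[labels.labels == l] = core
                territory[core] |= labels.labels == l
                logger.warning("forced merge of detached oversegment %d into core %d", l, core)
    return LabelMap(out).compact()
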