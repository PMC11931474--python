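"""Synapse definition by pre/post punctum overlap, input gating, receptor assignment.

A synapse is any pair of presynaptic and postsynaptic puncta whose masks
share at least one pixel; the pair distance is measured between the two
intensity maxima.  Synapses are optionally gated by vesicular transporter
(VGLUT1/VGLUT2) signal overlapping the presynaptic punctum, and receptor
puncta are classified as postsynaptic or presynaptic by overlap, with ties
resolved by the shorter maxima distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .detect import PunctaSet
from .image import ChannelImage

logger = logging.getLogger(__name__)

__all__ = [
    "SynapsePair", "ReceptorAssignment", "SynapseTable", "Metric",
    "DistanceHistogram", "pair_synapses", "gate_synapses_by_vglut",
    "assign_receptor_puncta", "distance_histogram",
    "summarize_synapse_metrics", "homer_only_vglut_analysis",
]

POSTSYNAPTIC = "postsynaptic"
PRESYNAPTIC = "presynaptic"
UNASSIGNED = "unassigned"


@dataclass
class SynapsePair:
    pre_id: int
    post_id: int
    distance_nm: float
    input_label: str = "none"          # "VGLUT1" | "VGLUT2" | "none"
    pre_multi: bool = False            # pre punctum overlaps > 1 post
    post_multi: bool = False           # post punctum overlaps > 1 pre
    vglut_overlap_px: int = 0          # pixels supporting the input label


@dataclass
class ReceptorAssignment:
    receptor_id: int
    compartment: str                   # postsynaptic | presynaptic | unassigned
    synapse_index: int | None          # index into SynapseTable.pairs
    distance_to_marker_nm: float | None


@dataclass
class SynapseTable:
    """Paired puncta plus receptor assignments for one FOV."""

    pairs: list[SynapsePair]
    pre_set: PunctaSet
    post_set: PunctaSet
    assignments: list[ReceptorAssignment] = field(default_factory=list)
    receptor_set: PunctaSet | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def synaptic_pre_ids(self) -> set[int]:
        return {p.pre_id for p in self.pairs}

    def synaptic_post_ids(self) -> set[int]:
        return {p.post_id for p in self.pairs}


@dataclass
class Metric:
    """A ratio metric with its numerator and denominator kept explicit.

    ``value`` is ``None`` (undefined) when the denominator is zero —
    never silently 0.
    """

    value: float | None
    numerator: float
    denominator: float

    @classmethod
    def ratio(cls, num: float, den: float, scale: float = 100.0) -> "Metric":
        if den == 0:
            return cls(None, num, den)
        return cls(scale * num / den, num, den)


def _overlap_pairs(lab_a: np.ndarray, lab_b: np.ndarray) -> dict[tuple[int, int], int]:
    """Map (label_a, label_b) -> shared pixel count, labels > 0 only."""
    both = (lab_a > 0) & (lab_b > 0)
    if not both.any():
        return {}
    pairs = np.column_stack([lab_a[both], lab_b[both]])
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return {(int(a), int(b)): int(c) for (a, b), c in zip(uniq, counts)}


def pair_synapses(pre: PunctaSet, post: PunctaSet) -> SynapseTable:
    """Pair every pre/post punctum whose masks share >= 1 pixel.

    Multiplicity flags record puncta participating in more than one pair
    (a quality metric: well-separated synapses rarely share markers).
    """
    if pre.shape != post.shape or pre.pixel_size_nm != post.pixel_size_nm:
        raise ValueError("pre and post channels must share FOV geometry "
                         "and pixel size")
    overlap = _overlap_pairs(pre.label_image(), post.label_image())
    pre_by_id = {p.id: p for p in pre.puncta}
    post_by_id = {p.id: p for p in post.puncta}
    pre_count: dict[int, int] = {}
    post_count: dict[int, int] = {}
    for (a, b) in overlap:
        pre_count[a] = pre_count.get(a, 0) + 1
        post_count[b] = post_count.get(b, 0) + 1
    pairs = []
    for (a, b) in sorted(overlap):
        pa, pb = pre_by_id[a], post_by_id[b]
        dist = math.dist(pa.max_pos_nm, pb.max_pos_nm)
        pairs.append(SynapsePair(
            pre_id=a, post_id=b, distance_nm=dist,
            pre_multi=pre_count[a] > 1, post_multi=post_count[b] > 1,
        ))
    return SynapseTable(pairs, pre, post)


def gate_synapses_by_vglut(table: SynapseTable, vglut: ChannelImage,
                           vglut_threshold: float, label: str) -> SynapseTable:
    """Label pairs whose presynaptic mask touches suprathreshold VGLUT signal.

    The gate is a single-pixel criterion: at least one pixel of the
    presynaptic punctum with VGLUT intensity >= threshold.  A pair already
    carrying a different input label keeps whichever label has the larger
    pixel overlap (conflicts are logged; distinct transporters mark
    non-overlapping terminal populations, so conflicts indicate artifacts).
    """
    if vglut_threshold <= 0:
        raise ValueError("vglut_threshold must be > 0")
    if vglut.shape != table.pre_set.shape:
        raise ValueError("VGLUT image shape does not match FOV")
    supra = vglut.pixels >= vglut_threshold
    pre_by_id = {p.id: p for p in table.pre_set.puncta}
    conflicts = 0
    for pair in table.pairs:
        mask = pre_by_id[pair.pre_id].mask
        n_over = int(supra[mask[:, 0], mask[:, 1]].sum())
        if n_over == 0:
            continue
        if pair.input_label not in ("none", label):
            conflicts += 1
            if n_over <= pair.vglut_overlap_px:
                continue
        pair.input_label = label
        pair.vglut_overlap_px = n_over
    if conflicts:
        logger.warning("gate_synapses_by_vglut: %d pairs matched both VGLUT "
                       "labels; kept the larger overlap", conflicts)
    return table


def assign_receptor_puncta(receptors: PunctaSet, table: SynapseTable,
                           pre: PunctaSet, post: PunctaSet
                           ) -> list[ReceptorAssignment]:
    """Classify receptor puncta as postsynaptic, presynaptic, or unassigned.

    A receptor overlapping the postsynaptic punctum of a synapse is
    postsynaptic; one overlapping only the presynaptic punctum is
    presynaptic; overlapping both compartments resolves to the punctum
    whose maximum is nearest to the receptor maximum.  A receptor touching
    several synapses' markers goes to the nearest marker maximum.
    """
    if receptors.shape != pre.shape:
        raise ValueError("receptor channel shape does not match FOV")
    syn_pre = table.synaptic_pre_ids()
    syn_post = table.synaptic_post_ids()
    pre_pairs: dict[int, list[int]] = {}
    post_pairs: dict[int, list[int]] = {}
    for i, pair in enumerate(table.pairs):
        pre_pairs.setdefault(pair.pre_id, []).append(i)
        post_pairs.setdefault(pair.post_id, []).append(i)

    rec_lab = receptors.label_image()
    over_pre = _overlap_pairs(rec_lab, pre.label_image())
    over_post = _overlap_pairs(rec_lab, post.label_image())
    pre_by_id = {p.id: p for p in pre.puncta}
    post_by_id = {p.id: p for p in post.puncta}

    cand_pre: dict[int, list[int]] = {}
    for (r, a) in over_pre:
        if a in syn_pre:
            cand_pre.setdefault(r, []).append(a)
    cand_post: dict[int, list[int]] = {}
    for (r, b) in over_post:
        if b in syn_post:
            cand_post.setdefault(r, []).append(b)

    out = []
    for rec in receptors.puncta:
        rx, ry = rec.max_pos_nm
        posts = cand_post.get(rec.id, [])
        pres = cand_pre.get(rec.id, [])
        best_post = min(
            ((math.dist((rx, ry), post_by_id[b].max_pos_nm), b) for b in posts),
            default=None)
        best_pre = min(
            ((math.dist((rx, ry), pre_by_id[a].max_pos_nm), a) for a in pres),
            default=None)
        if best_post is not None and (best_pre is None
                                      or best_post[0] <= best_pre[0]):
            dist, marker = best_post
            syn_idx = min(post_pairs[marker],
                          key=lambda i: table.pairs[i].distance_nm)
            out.append(ReceptorAssignment(rec.id, POSTSYNAPTIC, syn_idx, dist))
        elif best_pre is not None:
            dist, marker = best_pre
            syn_idx = min(pre_pairs[marker],
                          key=lambda i: table.pairs[i].distance_nm)
            out.append(ReceptorAssignment(rec.id, PRESYNAPTIC, syn_idx, dist))
        else:
            out.append(ReceptorAssignment(rec.id, UNASSIGNED, None, None))
    table.assignments = out
    table.receptor_set = receptors
    return out


@dataclass
class DistanceHistogram:
    bin_edges_nm: np.ndarray
    frequencies: np.ndarray   # sum to 1
    median_nm: float
    iqr_nm: float
    n: int


def distance_histogram(values, bin_width_nm: float) -> DistanceHistogram:
    """Normalized frequency distribution of distances plus median and IQR.

    Median and IQR come from the raw values, not the binned ones.
    """
    if bin_width_nm <= 0:
        raise ValueError("bin_width_nm must be > 0")
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("distance_histogram: empty input")
    top = max(bin_width_nm, math.ceil(values.max() / bin_width_nm)
              * bin_width_nm)
    edges = np.arange(0.0, top + bin_width_nm / 2, bin_width_nm)
    counts, edges = np.histogram(values, bins=edges)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return DistanceHistogram(edges, counts / values.size, float(med),
                             float(q3 - q1), int(values.size))


def _mask_hits_labels(ps_mask: np.ndarray, lab: np.ndarray) -> set[int]:
    vals = lab[ps_mask[:, 0], ps_mask[:, 1]]
    return set(int(v) for v in np.unique(vals) if v > 0)


def summarize_synapse_metrics(table: SynapseTable,
                              receptors: PunctaSet | None = None
                              ) -> dict[str, Metric]:
    """Per-FOV colocalization metrics with explicit denominators.

    Percentages: synaptic fractions of each marker channel, input-type
    composition, receptor compartment fractions, receptor-positive synapse
    fractions (overall and per input), and puncta densities per 25 μm².
    A synapse counts as receptor-positive postsynaptically when its
    postsynaptic punctum shares a pixel with any receptor punctum, and
    presynaptically when its presynaptic punctum overlaps a receptor that
    touches no synaptic postsynaptic punctum.
    """
    if receptors is None:
        receptors = table.receptor_set
    pre, post = table.pre_set, table.post_set
    n_pairs = table.n_pairs
    m: dict[str, Metric] = {}

    m["pct_pre_synaptic"] = Metric.ratio(len(table.synaptic_pre_ids()),
                                         len(pre))
    m["pct_post_synaptic"] = Metric.ratio(len(table.synaptic_post_ids()),
                                          len(post))
    n_v1 = sum(p.input_label == "VGLUT1" for p in table.pairs)
    n_v2 = sum(p.input_label == "VGLUT2" for p in table.pairs)
    m["pct_synapses_vglut1"] = Metric.ratio(n_v1, n_pairs)
    m["pct_synapses_vglut2"] = Metric.ratio(n_v2, n_pairs)

    post_multi = {p.post_id for p in table.pairs if p.post_multi}
    m["pct_synaptic_post_multi_pre"] = Metric.ratio(
        len(post_multi), len(table.synaptic_post_ids()))

    area = pre.fov_area_um2
    m["pre_puncta_per_25um2"] = Metric(25.0 * len(pre) / area, len(pre), area)
    m["post_puncta_per_25um2"] = Metric(25.0 * len(post) / area, len(post),
                                        area)

    if receptors is not None:
        m["receptor_puncta_per_25um2"] = Metric(
            25.0 * len(receptors) / area, len(receptors), area)
        assigns = table.assignments
        n_rec = len(receptors)
        n_post_rec = sum(a.compartment == POSTSYNAPTIC for a in assigns)
        n_pre_rec = sum(a.compartment == PRESYNAPTIC for a in assigns)
        m["pct_receptor_postsynaptic"] = Metric.ratio(n_post_rec, n_rec)
        m["pct_receptor_presynaptic"] = Metric.ratio(n_pre_rec, n_rec)

        rec_lab = receptors.label_image()
        post_by_id = {p.id: p for p in post.puncta}
        pre_by_id = {p.id: p for p in pre.puncta}
        # receptors overlapping any synaptic post punctum
        syn_post_ids = table.synaptic_post_ids()
        post_lab = post.label_image()
        rec_touch_syn_post = set()
        for rec in receptors.puncta:
            hit = _mask_hits_labels(rec.mask, post_lab)
            if hit & syn_post_ids:
                rec_touch_syn_post.add(rec.id)

        def pair_post_positive(pair) -> bool:
            return bool(_mask_hits_labels(post_by_id[pair.post_id].mask,
                                          rec_lab))

        def pair_pre_positive(pair) -> bool:
            hits = _mask_hits_labels(pre_by_id[pair.pre_id].mask, rec_lab)
            return any(r not in rec_touch_syn_post for r in hits)

        post_pos = [pair_post_positive(p) for p in table.pairs]
        pre_pos = [pair_pre_positive(p) for p in table.pairs]
        m["pct_synapses_receptor_postsynaptic"] = Metric.ratio(
            sum(post_pos), n_pairs)
        m["pct_synapses_receptor_presynaptic"] = Metric.ratio(
            sum(pre_pos), n_pairs)
        for label in ("VGLUT1", "VGLUT2"):
            sel = [i for i, p in enumerate(table.pairs)
                   if p.input_label == label]
            m[f"pct_{label.lower()}_synapses_receptor_postsynaptic"] = \
                Metric.ratio(sum(post_pos[i] for i in sel), len(sel))
            m[f"pct_{label.lower()}_synapses_receptor_presynaptic"] = \
                Metric.ratio(sum(pre_pos[i] for i in sel), len(sel))
            # receptor-positive fraction of VGLUT-labeled postsynaptic puncta
            post_ids = {table.pairs[i].post_id for i in sel}
            n_hit = sum(
                1 for b in post_ids
                if _mask_hits_labels(post_by_id[b].mask, rec_lab))
            m[f"pct_{label.lower()}_post_puncta_receptor_positive"] = \
                Metric.ratio(n_hit, len(post_ids))
    return m


def homer_only_vglut_analysis(post: PunctaSet, vglut: ChannelImage,
                              receptors: PunctaSet, vglut_threshold: float
                              ) -> dict[str, Metric]:
    """Three-channel variant: input-gate postsynaptic puncta directly.

    Without a presynaptic channel, postsynaptic puncta overlapping
    suprathreshold VGLUT signal by >= 1 pixel are treated as input-labeled,
    and the receptor-positive percentage is computed among them.  Designed
    to track the four-channel pipeline when pre and post markers sit inside
    the same terminal's VGLUT footprint.
    """
    if vglut_threshold <= 0:
        raise ValueError("vglut_threshold must be > 0")
    if vglut.shape != post.shape:
        raise ValueError("VGLUT image shape does not match FOV")
    supra = vglut.pixels >= vglut_threshold
    rec_lab = receptors.label_image()
    labeled = [p for p in post.puncta
               if supra[p.mask[:, 0], p.mask[:, 1]].any()]
    n_hit = sum(1 for p in labeled if _mask_hits_labels(p.mask, rec_lab))
    return {
        "pct_post_vglut_positive": Metric.ratio(len(labeled), len(post)),
        "pct_vglut_post_receptor_positive": Metric.ratio(n_hit, len(labeled)),
    }
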