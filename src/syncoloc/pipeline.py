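"""Per-FOV orchestration, per-mouse aggregation, and Welch group comparison.

The unit of acquisition is a field of view (FOV); three FOVs are imaged
per animal and averaged so that the mouse, not the FOV, is the unit of
analysis.  Group comparisons use Welch's t-test (unequal variances are the
norm in these data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detect import DetectionParams, PunctaSet, detect_puncta
from .image import ChannelImage
from .interaction import InteractionFit, interaction_strength_for_channels
from .pairing import (DistanceHistogram, Metric, SynapseTable,
                      assign_receptor_puncta, distance_histogram,
                      gate_synapses_by_vglut, pair_synapses,
                      summarize_synapse_metrics)
from .synthetic import SynthConfig, rotate_channel_control

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig", "FOVResult", "MouseSummary", "GroupComparison",
    "run_fov_analysis", "aggregate_by_mouse", "compare_groups",
    "default_detection_params",
]


@dataclass
class AnalysisConfig:
    """All thresholds and settings for one batch of FOVs."""

    detection: dict[str, DetectionParams]
    vglut_thresholds: dict[str, float] = field(default_factory=dict)
    bin_width_nm: float = 27.0
    run_interaction: bool = True
    interaction_n_runs: int = 1000
    interaction_alpha: float = 0.05
    interaction_run_mc: bool = False
    rotate_control: str | None = None     # channel rotated 90 deg as control
    seed: int = 0


def default_detection_params(config: SynthConfig,
                             channel: str) -> DetectionParams:
    """Detection thresholds matched to the simulator's imaging model.

    The intensity floor sits 3% of the mean spot amplitude plus three
    noise SDs above background; the prominence tolerance separates
    juxtaposed spots while rejecting noise peaks.  All channels use the
    0.02 μm² minimum area: simulated spots are PSF-limited (~0.04 μm² at
    these thresholds), so the 0.05 μm² floor used for real receptor
    puncta — which carry intrinsic size — would reject them wholesale.
    """
    min_area = 0.02
    return DetectionParams(
        min_intensity=config.background + 0.03 * config.amplitude_mean
        + 3 * config.noise_sd,
        max_intensity=float("inf"),
        noise_tolerance=0.02 * config.amplitude_mean + 3 * config.noise_sd,
        median_radius=2,
        min_area_um2=min_area,
        max_area_um2=5.0,
    )


@dataclass
class FOVResult:
    fov_id: str
    mouse_id: str
    metrics: dict[str, Metric]
    fits: dict[str, InteractionFit] = field(default_factory=dict)
    histograms: dict[str, DistanceHistogram] = field(default_factory=dict)
    table: SynapseTable | None = None
    puncta: dict[str, PunctaSet] = field(default_factory=dict)


def run_fov_analysis(images: dict[str, ChannelImage], config: AnalysisConfig,
                     fov_id: str = "fov", mouse_id: str = "mouse"
                     ) -> FOVResult:
    """Detect -> pair -> gate -> assign -> summarize -> interaction.

    ``images`` must contain ``pre`` and ``post`` channels; ``receptor``,
    ``vglut1`` and ``vglut2`` are optional.  With ``rotate_control`` set,
    the named channel is rotated 90 degrees before analysis and the
    interaction fits are flagged as controls.
    """
    for required in ("pre", "post"):
        if required not in images:
            raise ValueError(f"missing required channel '{required}'")
    pixel_sizes = {im.pixel_size_nm for im in images.values()}
    if len(pixel_sizes) != 1:
        raise ValueError("all channels must share one pixel size")
    images = dict(images)
    if config.rotate_control:
        name = config.rotate_control
        if name not in images:
            raise ValueError(f"rotate_control channel '{name}' not present")
        images[name] = rotate_channel_control(images[name], 1)

    puncta: dict[str, PunctaSet] = {}
    for name in ("pre", "post", "receptor"):
        if name not in images:
            continue
        params = config.detection.get(name)
        if params is None:
            raise ValueError(f"no detection parameters for channel '{name}'")
        try:
            puncta[name] = detect_puncta(images[name], params)
        except Exception as exc:
            raise RuntimeError(f"detection failed on channel '{name}': "
                               f"{exc}") from exc
        logger.info("%s/%s: %d puncta in channel %s", mouse_id, fov_id,
                    len(puncta[name]), name)

    table = pair_synapses(puncta["pre"], puncta["post"])
    for vname, label in (("vglut1", "VGLUT1"), ("vglut2", "VGLUT2")):
        if vname in images:
            thr = config.vglut_thresholds.get(vname)
            if thr is None:
                raise ValueError(f"no threshold configured for '{vname}'")
            gate_synapses_by_vglut(table, images[vname], thr, label)
    if "receptor" in puncta:
        assign_receptor_puncta(puncta["receptor"], table, puncta["pre"],
                               puncta["post"])

    metrics = summarize_synapse_metrics(table, puncta.get("receptor"))

    histograms: dict[str, DistanceHistogram] = {}
    pair_d = [p.distance_nm for p in table.pairs]
    if pair_d:
        histograms["pre_post"] = distance_histogram(pair_d,
                                                    config.bin_width_nm)
    rec_d = [a.distance_to_marker_nm for a in table.assignments
             if a.compartment == "postsynaptic"]
    if rec_d:
        histograms["receptor_post"] = distance_histogram(
            rec_d, config.bin_width_nm)

    fits: dict[str, InteractionFit] = {}
    if config.run_interaction:
        specs = [("pre_post", puncta["pre"], puncta["post"])]
        if "receptor" in puncta:
            specs.append(("post_receptor", puncta["post"],
                          puncta["receptor"]))
        for key, ref, tgt in specs:
            try:
                fit = interaction_strength_for_channels(
                    ref, tgt, n_runs=config.interaction_n_runs,
                    alpha=config.interaction_alpha, seed=config.seed,
                    run_mc=config.interaction_run_mc)
            except ValueError as exc:
                logger.warning("%s/%s: interaction fit skipped for %s (%s)",
                               mouse_id, fov_id, key, exc)
                continue
            fit.is_control = bool(config.rotate_control)
            fits[key] = fit

    return FOVResult(fov_id, mouse_id, metrics, fits, histograms, table,
                     puncta)


@dataclass
class MouseSummary:
    mouse_id: str
    means: dict[str, float | None]
    n_fov: int
    n_per_metric: dict[str, int]


def aggregate_by_mouse(results: list[FOVResult]) -> list[MouseSummary]:
    """Unweighted per-metric mean over each mouse's FOVs.

    Undefined (zero-denominator) metrics are skipped per FOV; the number
    of contributing FOVs is recorded per metric, and a metric undefined in
    every FOV stays ``None``.  Fitted interaction strengths are averaged
    alongside under ``epsilon_<pair>`` keys.
    """
    by_mouse: dict[str, list[FOVResult]] = {}
    for r in results:
        by_mouse.setdefault(r.mouse_id, []).append(r)
    summaries = []
    for mouse_id, fovs in by_mouse.items():
        values: dict[str, list[float]] = {}
        for r in fovs:
            for name, metric in r.metrics.items():
                if metric.value is not None:
                    values.setdefault(name, []).append(metric.value)
            for key, fit in r.fits.items():
                values.setdefault(f"epsilon_{key}", []).append(fit.epsilon)
        means = {k: float(np.mean(v)) for k, v in values.items()}
        n_per = {k: len(v) for k, v in values.items()}
        if len({len(v) for v in values.values()} | {len(fovs)}) > 1:
            logger.info("mouse %s: metrics averaged over differing FOV "
                        "counts %s", mouse_id, n_per)
        summaries.append(MouseSummary(mouse_id, means, len(fovs), n_per))
    return summaries


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    t_statistic: float
    df: float | None
    p_value: float | None
    mean_difference: float
    ci95: tuple[float, float] | None
    degenerate: bool = False


def compare_groups(a, b, labels: tuple[str, str] = ("a", "b")
                   ) -> GroupComparison:
    """Welch's two-sided t-test on per-mouse values.

    t = (m1 - m2) / sqrt(s1²/n1 + s2²/n2) with Welch–Satterthwaite degrees
    of freedom; the 95% CI of the mean difference uses the same df.  Two
    zero-variance groups are reported as degenerate rather than erroring.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("compare_groups needs n >= 2 per group")
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    n1, n2 = a.size, b.size
    diff = float(m1 - m2)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return GroupComparison(labels, (float(m1), float(m2)),
                               (0.0, 0.0), (n1, n2),
                               t_statistic=0.0, df=None,
                               p_value=1.0 if diff == 0 else None,
                               mean_difference=diff, ci95=None,
                               degenerate=True)
    t = diff / math.sqrt(se2)
    # Welch–Satterthwaite via the scale-free weights w_i = (v_i/n_i)/se2,
    # immune to underflow for tiny variances
    w1 = (v1 / n1) / se2
    w2 = (v2 / n2) / se2
    df = 1.0 / (w1 ** 2 / (n1 - 1) + w2 ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    half = tcrit * math.sqrt(se2)
    return GroupComparison(labels, (float(m1), float(m2)),
                           (float(math.sqrt(v1)), float(math.sqrt(v2))),
                           (n1, n2), t_statistic=float(t), df=float(df),
                           p_value=float(p), mean_difference=diff,
                           ci95=(diff - half, diff + half))
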