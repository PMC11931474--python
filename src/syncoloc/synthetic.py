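"""Ground-truthed synthetic fields of synaptic puncta.

The generator emulates the statistical structure the colocalization
analysis assumes: presynaptic and postsynaptic puncta at realistic
densities with a configurable fraction of pre puncta paired to a
postsynaptic partner at a sub-resolution radial offset (right-skewed,
parameterized by median and IQR), receptor puncta attached to synapses
with configurable compartment probabilities, large sparse VGLUT2 terminal
discs versus small per-synapse VGLUT1 discs, and an imaging forward model
(isotropic Gaussian PSF, additive read noise).  It also draws pure point
patterns from a known Hernquist-potential Gibbs model for validating the
interaction fitter against ground truth.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage, stats
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .image import ChannelImage
from .interaction import hernquist_potential

__all__ = [
    "SynthConfig", "GroundTruth", "generate_synapse_field", "render_channel",
    "render_field", "generate_gibbs_pair_pattern", "rotate_channel_control",
    "rotate_points", "gamma_from_median_iqr",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic field of view.

    Densities are puncta per μm²; offsets and radii are nm.  Defaults are
    calibrated to super-resolution spinning-disk imaging of thalamic
    synapses: 27 nm pixels, ~120 nm lateral resolution (Gaussian PSF sigma
    120/2.355 ≈ 51 nm), a 193 nm (IQR 31) pre/post maxima offset, 42% of
    presynaptic puncta paired, receptor puncta at 51%/7% of synapses
    post-/presynaptically at a 161 nm (IQR 55) offset from the
    postsynaptic marker, and 49%/6% of synapses gated to the VGLUT1/VGLUT2
    input classes.
    """

    fov_shape: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 27.0
    density_pre: float = 0.5
    density_post: float = 0.6
    density_receptor: float = 0.6
    paired_fraction_pre: float = 0.42
    offset_median_nm: float = 193.0
    offset_iqr_nm: float = 31.0
    receptor_post_prob: float = 0.51
    receptor_pre_prob: float = 0.07
    receptor_offset_median_nm: float = 161.0
    receptor_offset_iqr_nm: float = 55.0
    vglut1_fraction: float = 0.49
    vglut2_fraction: float = 0.06
    vglut1_terminal_radius_nm: float = 250.0
    vglut2_terminal_radius_nm: float = 1000.0
    psf_sigma_nm: float = 51.0
    amplitude_mean: float = 1000.0
    amplitude_cv: float = 0.3
    background: float = 100.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        def bad(name, msg):
            raise ValueError(f"SynthConfig.{name}: {msg}")

        for name in ("density_pre", "density_post", "density_receptor"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                bad(name, "density must be a positive finite number")
        for name in ("paired_fraction_pre", "receptor_post_prob",
                     "receptor_pre_prob", "vglut1_fraction",
                     "vglut2_fraction"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0 <= v <= 1):
                bad(name, "must lie in [0, 1]")
        if self.vglut1_fraction + self.vglut2_fraction > 1:
            bad("vglut1_fraction", "vglut1_fraction + vglut2_fraction "
                "must be <= 1")
        for name in ("pixel_size_nm", "psf_sigma_nm", "offset_median_nm",
                     "offset_iqr_nm", "receptor_offset_median_nm",
                     "receptor_offset_iqr_nm", "amplitude_mean",
                     "vglut1_terminal_radius_nm", "vglut2_terminal_radius_nm"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                bad(name, "must be a positive finite number")
        for name in ("amplitude_cv", "background", "noise_sd"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                bad(name, "must be a non-negative finite number")
        if len(self.fov_shape) != 2 or min(self.fov_shape) < 8:
            bad("fov_shape", "must be (rows, cols) with both >= 8")

    @property
    def fov_size_nm(self) -> tuple[float, float]:
        return (self.fov_shape[0] * self.pixel_size_nm,
                self.fov_shape[1] * self.pixel_size_nm)

    @property
    def fov_area_um2(self) -> float:
        h, w = self.fov_size_nm
        return h * w / 1e6

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fov_shape"] = list(self.fov_shape)
        return d


def gamma_from_median_iqr(median: float, iqr: float):
    """Gamma distribution (frozen) with the requested median and IQR.

    The gamma family gives positive support and right skew with exactly
    two free parameters; the shape is solved from the scale-free
    IQR/median ratio, then the scale fixes the median.
    """
    if median <= 0 or iqr <= 0:
        raise ValueError("median and iqr must be > 0")
    ratio = iqr / median

    def f(log_k):
        k = math.exp(log_k)
        q1, q2, q3 = stats.gamma.ppf([0.25, 0.5, 0.75], k)
        return (q3 - q1) / q2 - ratio

    log_k = brentq(f, math.log(1e-3), math.log(1e9), xtol=1e-10)
    k = math.exp(log_k)
    scale = median / stats.gamma.ppf(0.5, k)
    return stats.gamma(k, scale=scale)


@dataclass
class GroundTruth:
    """Simulator truth tables for one field of view.

    Point coordinates are (x, y) in nm with per-point amplitudes;
    ``pairing`` rows are (pre_index, post_index, offset_nm);
    ``receptor_assignment`` rows are (receptor_index, synapse_index,
    compartment) with compartment in {"post", "pre", "none"} (synapse
    index -1 for unattached receptors); ``input_labels[s]`` is the input
    class of synapse ``s``.  Synapse ``s`` is ``pairing[s]``.
    """

    config: SynthConfig
    points: dict[str, np.ndarray]
    amplitudes: dict[str, np.ndarray]
    pairing: list[tuple[int, int, float]]
    receptor_assignment: list[tuple[int, int, str]]
    input_labels: list[str]
    vglut_masks: dict[str, np.ndarray]

    @property
    def n_synapses(self) -> int:
        return len(self.pairing)

    def validate(self) -> None:
        h, w = self.config.fov_size_nm
        for ch, pts in self.points.items():
            if pts.size and not ((pts[:, 0] >= 0).all()
                                 and (pts[:, 0] <= w).all()
                                 and (pts[:, 1] >= 0).all()
                                 and (pts[:, 1] <= h).all()):
                raise AssertionError(f"{ch}: coordinates outside FOV")
        n_pre = self.points["pre"].shape[0]
        n_post = self.points["post"].shape[0]
        for (i, j, _) in self.pairing:
            if not (0 <= i < n_pre and 0 <= j < n_post):
                raise AssertionError("pairing references missing points")
        rec_ids = [r for (r, _, _) in self.receptor_assignment]
        if len(rec_ids) != len(set(rec_ids)):
            raise AssertionError("duplicate receptor in assignment table")
        if len(self.input_labels) != self.n_synapses:
            raise AssertionError("input label per synapse required")


def _uniform_in_fov(rng, n, fov_size_nm):
    h, w = fov_size_nm
    return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])


def _offset_point(rng, origin, dist, fov_size_nm, max_tries=200):
    """Place a point at a fixed radial distance, rejecting out-of-FOV draws."""
    h, w = fov_size_nm
    for _ in range(max_tries):
        theta = rng.uniform(0, 2 * math.pi)
        p = (origin[0] + dist * math.cos(theta),
             origin[1] + dist * math.sin(theta))
        if 0 <= p[0] <= w and 0 <= p[1] <= h:
            return np.array(p)
    return np.clip(np.asarray(origin), [0, 0], [w, h])


def _amplitudes(rng, n, mean, cv):
    if cv == 0:
        return np.full(n, float(mean))
    sig2 = math.log1p(cv ** 2)
    mu = math.log(mean) - sig2 / 2
    return rng.lognormal(mu, math.sqrt(sig2), n)


def generate_synapse_field(config: SynthConfig) -> GroundTruth:
    """Draw one ground-truthed field of pre/post/receptor puncta.

    Counts are Poisson at the configured densities; paired postsynaptic
    partners sit at gamma-distributed radial offsets matching the
    configured median/IQR; receptors attach to synapses per the
    compartment probabilities with leftover receptors placed uniformly
    (extrasynaptic); synapses are gated to VGLUT input classes by the
    configured fractions, with VGLUT terminal discs drawn into binary
    masks.
    """
    rng = np.random.default_rng(config.seed)
    fov = config.fov_size_nm
    area = config.fov_area_um2

    n_pre = int(rng.poisson(config.density_pre * area))
    pre = _uniform_in_fov(rng, n_pre, fov)
    paired = rng.random(n_pre) < config.paired_fraction_pre

    offset_dist = gamma_from_median_iqr(config.offset_median_nm,
                                        config.offset_iqr_nm)
    pairing: list[tuple[int, int, float]] = []
    post_pts: list[np.ndarray] = []
    for i in np.nonzero(paired)[0]:
        r = float(offset_dist.rvs(random_state=rng))
        post_pts.append(_offset_point(rng, pre[i], r, fov))
        pairing.append((int(i), len(post_pts) - 1, r))

    n_post_total = int(rng.poisson(config.density_post * area))
    n_extra_post = max(0, n_post_total - len(post_pts))
    extra_post = _uniform_in_fov(rng, n_extra_post, fov)
    parts = []
    if post_pts:
        parts.append(np.asarray(post_pts))
    if n_extra_post:
        parts.append(extra_post)
    post = np.vstack(parts) if parts else np.empty((0, 2))

    # input class per synapse
    u = rng.random(len(pairing))
    input_labels = np.where(
        u < config.vglut1_fraction, "VGLUT1",
        np.where(u < config.vglut1_fraction + config.vglut2_fraction,
                 "VGLUT2", "none")).tolist()

    # receptor puncta: attached first, then extrasynaptic fill
    rec_offset = gamma_from_median_iqr(config.receptor_offset_median_nm,
                                       config.receptor_offset_iqr_nm)
    rec_pts: list[np.ndarray] = []
    assignment: list[tuple[int, int, str]] = []
    for s, (i, j, _) in enumerate(pairing):
        if rng.random() < config.receptor_post_prob:
            r = float(rec_offset.rvs(random_state=rng))
            rec_pts.append(_offset_point(rng, post[j], r, fov))
            assignment.append((len(rec_pts) - 1, s, "post"))
        if rng.random() < config.receptor_pre_prob:
            r = float(rec_offset.rvs(random_state=rng))
            rec_pts.append(_offset_point(rng, pre[i], r, fov))
            assignment.append((len(rec_pts) - 1, s, "pre"))
    n_rec_total = int(rng.poisson(config.density_receptor * area))
    n_extra_rec = max(0, n_rec_total - len(rec_pts))
    for _ in range(n_extra_rec):
        rec_pts.append(_uniform_in_fov(rng, 1, fov)[0])
        assignment.append((len(rec_pts) - 1, -1, "none"))
    receptor = np.vstack(rec_pts) if rec_pts else np.empty((0, 2))

    masks = {
        "vglut1": np.zeros(config.fov_shape, dtype=bool),
        "vglut2": np.zeros(config.fov_shape, dtype=bool),
    }
    radii = {"VGLUT1": config.vglut1_terminal_radius_nm,
             "VGLUT2": config.vglut2_terminal_radius_nm}
    rows, cols = config.fov_shape
    yy = (np.arange(rows) + 0.0) * config.pixel_size_nm
    xx = (np.arange(cols) + 0.0) * config.pixel_size_nm
    for s, label in enumerate(input_labels):
        if label == "none":
            continue
        cx, cy = pre[pairing[s][0]]
        r = radii[label]
        rsel = np.abs(yy - cy) <= r
        csel = np.abs(xx - cx) <= r
        sub = ((xx[None, csel] - cx) ** 2
               + (yy[rsel, None] - cy) ** 2) <= r ** 2
        m = masks[label.lower()]
        m[np.ix_(rsel, csel)] |= sub

    amps = {
        "pre": _amplitudes(rng, pre.shape[0], config.amplitude_mean,
                           config.amplitude_cv),
        "post": _amplitudes(rng, post.shape[0], config.amplitude_mean,
                            config.amplitude_cv),
        "receptor": _amplitudes(rng, receptor.shape[0],
                                config.amplitude_mean, config.amplitude_cv),
    }
    gt = GroundTruth(config=config,
                     points={"pre": pre, "post": post, "receptor": receptor},
                     amplitudes=amps, pairing=pairing,
                     receptor_assignment=assignment,
                     input_labels=input_labels, vglut_masks=masks)
    gt.validate()
    return gt


def render_channel(points: np.ndarray, amplitudes: np.ndarray,
                   config: SynthConfig, seed: int | None = None,
                   channel_label: str = "") -> ChannelImage:
    """Forward-image a point set: Gaussian PSF spots + background + noise.

    ``image = background + sum_i A_i * exp(-r_i^2 / (2 sigma^2)) + N(0, noise_sd)``
    evaluated at pixel centers, clipped at zero.  Deterministic given
    ``seed`` (defaults to the config seed).
    """
    if config.psf_sigma_nm < config.pixel_size_nm / 4:
        warnings.warn("psf_sigma_nm < pixel_size/4: PSF is undersampled",
                      stacklevel=2)
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    amplitudes = np.asarray(amplitudes, dtype=float).reshape(-1)
    h, w = config.fov_size_nm
    if points.size and (points[:, 0].min() < 0 or points[:, 0].max() > w
                        or points[:, 1].min() < 0 or points[:, 1].max() > h):
        raise ValueError("points outside the FOV")
    rows, cols = config.fov_shape
    img = np.zeros((rows, cols))
    px = config.pixel_size_nm
    sig_px = config.psf_sigma_nm / px
    win = int(math.ceil(5 * sig_px)) + 1
    for (x, y), a in zip(points, amplitudes):
        c0 = max(int(x / px) - win, 0)
        c1 = min(int(x / px) + win + 1, cols)
        r0 = max(int(y / px) - win, 0)
        r1 = min(int(y / px) + win + 1, rows)
        cc = np.arange(c0, c1) * px
        rr = np.arange(r0, r1) * px
        img[r0:r1, c0:c1] += a * np.exp(
            -((cc[None, :] - x) ** 2 + (rr[:, None] - y) ** 2)
            / (2 * config.psf_sigma_nm ** 2))
    img += config.background
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        img += rng.normal(0, config.noise_sd, img.shape)
    return ChannelImage(np.clip(img, 0, None), px, channel_label)


def render_field(gt: GroundTruth) -> dict[str, ChannelImage]:
    """Render every channel of a ground-truth field.

    Point channels get Gaussian spots; VGLUT channels are their terminal
    masks imaged at the mean amplitude through the same PSF.  Per-channel
    noise seeds are spawned deterministically from the config seed.
    """
    config = gt.config
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(8)
    out: dict[str, ChannelImage] = {}
    for k, name in enumerate(("pre", "post", "receptor")):
        out[name] = render_channel(gt.points[name], gt.amplitudes[name],
                                   config, seed=int(seeds[k]),
                                   channel_label=name)
    px = config.pixel_size_nm
    for k, name in enumerate(("vglut1", "vglut2"), start=3):
        base = gt.vglut_masks[name].astype(float) * config.amplitude_mean
        base = ndimage.gaussian_filter(base, config.psf_sigma_nm / px)
        base += config.background
        if config.noise_sd > 0:
            rng = np.random.default_rng(int(seeds[k]))
            base += rng.normal(0, config.noise_sd, base.shape)
        out[name] = ChannelImage(np.clip(base, 0, None), px, name)
    return out


def generate_gibbs_pair_pattern(n_ref: int, n_target: int, epsilon: float,
                                sigma_nm: float,
                                fov_size_nm: tuple[float, float],
                                seed: int | None = 0,
                                min_acceptance: float = 1e-4
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Draw a (reference, target) point pair from the Hernquist Gibbs model.

    Targets are uniform; reference points are rejection-sampled with
    acceptance weight exp(-phi(dNN(x, targets))) normalized by its maximum
    over the field, so the reference NN-distance density is exactly
    p(d) * exp(-phi(d)) / Z.  Deterministic given seed.
    """
    if n_ref <= 0 or n_target <= 0:
        raise ValueError("n_ref and n_target must be > 0")
    if sigma_nm <= 0:
        raise ValueError("sigma_nm must be > 0")
    rng = np.random.default_rng(seed)
    target = _uniform_in_fov(rng, n_target, fov_size_nm)
    tree = cKDTree(target)
    h, w = fov_size_nm
    dmax = math.hypot(h, w)
    log_m = max(-hernquist_potential(0.0, epsilon, sigma_nm),
                -hernquist_potential(dmax, epsilon, sigma_nm))

    accepted: list[np.ndarray] = []
    n_proposed = 0
    batch = max(4 * n_ref, 1000)
    while len(accepted) < n_ref:
        pts = _uniform_in_fov(rng, batch, fov_size_nm)
        d, _ = tree.query(pts, k=1)
        logw = -hernquist_potential(d, epsilon, sigma_nm) - log_m
        keep = rng.random(batch) < np.exp(logw)
        accepted.extend(pts[keep])
        n_proposed += batch
        if n_proposed >= 1e4 and (len(accepted) / n_proposed) < min_acceptance:
            raise RuntimeError(
                "rejection sampler acceptance rate below "
                f"{min_acceptance:g}; use a smaller |epsilon|")
    reference = np.vstack(accepted[:n_ref])
    return reference, target


def rotate_points(points: np.ndarray, fov_size_nm: tuple[float, float],
                  quarter_turns: int) -> np.ndarray:
    """Rigid 90-degree rotations of point coordinates about the FOV center.

    One quarter turn maps (x, y) -> (y, W - x) in a W x W field; a
    non-square field only admits even turn counts.
    """
    h, w = fov_size_nm
    quarter_turns = quarter_turns % 4
    if quarter_turns % 2 == 1 and not math.isclose(h, w):
        raise ValueError("odd quarter-turn rotation requires a square FOV "
                         "(crop to the central square first)")
    pts = np.asarray(points, dtype=float).reshape(-1, 2).copy()
    if quarter_turns == 1:
        pts = np.column_stack([pts[:, 1], w - pts[:, 0]])
    elif quarter_turns == 2:
        pts = np.column_stack([w - pts[:, 0], h - pts[:, 1]])
    elif quarter_turns == 3:
        pts = np.column_stack([h - pts[:, 1], pts[:, 0]])
    return pts


def rotate_channel_control(obj, quarter_turns: int,
                           fov_size_nm: tuple[float, float] | None = None):
    """Rotate an image or a point set by multiples of 90 degrees.

    This produces the standard independence control: one channel rotated
    against the others destroys true pairings while preserving each
    channel's internal statistics.  Non-square images are cropped to the
    central square before odd rotations.
    """
    if isinstance(obj, ChannelImage):
        a = obj.pixels
        if quarter_turns % 2 == 1 and a.shape[0] != a.shape[1]:
            n = min(a.shape)
            r0 = (a.shape[0] - n) // 2
            c0 = (a.shape[1] - n) // 2
            a = a[r0:r0 + n, c0:c0 + n]
        return obj.copy_with(np.rot90(a, quarter_turns).copy())
    if fov_size_nm is None:
        raise ValueError("fov_size_nm is required to rotate raw points")
    return rotate_points(obj, fov_size_nm, quarter_turns)
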