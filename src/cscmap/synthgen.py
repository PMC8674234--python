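"""Ground-truthed synthetic scenes, movies, and tables.

Every generator emulates the statistical structure one analysis stage
assumes — a minority sensor-positive population over a control
background, distance-dependent CSC placement around doorway circles,
two-speed persistent random walks, oscillatory edge traces,
contact-triggered first-order reporter kinetics, colocalized puncta
fields, lesion-size-dependent stem fractions, and single-hit
limiting-dilution take tables — and returns a machine-readable truth
table alongside the rendered pixels, so every downstream estimate is
checkable by parameter recovery.

Rendering conventions: single 2-D plane per frame, default 0.5 µm/px,
8-bit-range intensities, additive Gaussian noise, cells drawn as 12 µm
diameter soft-edged disks. All randomness flows through one seeded
`numpy.random.Generator`; identical seed and configuration give
bit-identical output. The seed is echoed in the output metadata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import spatial
from .containers import ChannelStack, MovieTruth, RegionMask, SceneTruth

__all__ = [
    "CELL_DIAMETER_UM",
    "SceneConfig",
    "ReporterKinetics",
    "DilutionDesign",
    "EdgeTrace",
    "generate_tissue_scene",
    "generate_timelapse",
    "generate_kymograph",
    "generate_puncta_scene",
    "generate_dilution_table",
    "generate_metastasis_section",
]

CELL_DIAMETER_UM = 12.0  # single tumor cell diameter used throughout
_CELL_R = CELL_DIAMETER_UM / 2.0
_MAC_R = 8.0  # macrophage blob radius, µm


# ------------------------------------------------------------------ config

@dataclass
class SceneConfig:
    """Parameters of a synthetic tumor-tissue scene.

    ``enrichment_profile`` maps contour bins (aligned with
    :func:`cscmap.spatial.bin_labels` at ``bin_width``/``cap``) to the
    CSC probability of cells falling in that bin; when ``None``, every
    cell is CSC with ``csc_fraction_baseline``.
    """

    field_size: tuple[float, float] = (1000.0, 1000.0)  # µm (width, height)
    pixel_size: float = 0.5  # µm/px
    n_cells: int = 1000
    csc_fraction_baseline: float = 0.02
    tmem_sites: Sequence[tuple[float, float, float]] = ()  # (x, y, diameter µm)
    vessel_segments: Sequence[Sequence[tuple[float, float]]] = ()
    enrichment_profile: Optional[Sequence[float]] = None
    bin_width: float = 40.0
    cap: float = 300.0
    macrophage_coverage: float = 0.0
    contact_fraction_by_class: dict = field(default_factory=dict)
    sensor_background: tuple[float, float] = (20.0, 5.0)  # mean, sd
    sensor_positive: tuple[float, float] = (120.0, 15.0)
    n_control: int = 2000
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("csc_fraction_baseline", "macrophage_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for cls, p in self.contact_fraction_by_class.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"contact fraction for {cls!r} outside [0, 1]")
        w, h = self.field_size
        for x, y, diam in self.tmem_sites:
            r = diam / 2.0
            if not (0 <= x - r and x + r <= w and 0 <= y - r and y + r <= h):
                raise ValueError(
                    f"doorway circle at ({x}, {y}) d={diam} extends outside "
                    f"the {w}x{h} µm field"
                )
        if self.enrichment_profile is not None:
            prof = np.asarray(self.enrichment_profile, dtype=float)
            k = spatial.n_bins(self.bin_width, self.cap)
            if prof.shape != (k,):
                raise ValueError(
                    f"enrichment_profile must have {k} entries "
                    f"(one per contour bin), got {prof.shape}"
                )
            if np.any(prof < 0) or np.any(prof > 1):
                raise ValueError("CSC probability outside [0, 1] in profile")

    def echo(self) -> dict:
        d = asdict(self)
        d["tmem_sites"] = [tuple(s) for s in self.tmem_sites]
        if d["enrichment_profile"] is not None:
            d["enrichment_profile"] = list(np.asarray(d["enrichment_profile"], float))
        return d


@dataclass(frozen=True)
class ReporterKinetics:
    """First-order kinetics of the destabilized stemness reporter.

    The fluorescent protein is destabilized with a 1–2 h half-life so
    the sensor tracks acquisition and loss of the stem state with
    kinetic resolution; production switches on at macrophage contact
    and the noiseless signal follows
    ``baseline + (P/k)(1 - exp(-k (t - t0)))`` with ``k = ln2 / half_life``.
    """

    half_life_h: float = 1.5
    production_rate: float = 100.0  # intensity units / hour
    baseline_mean: float = 20.0
    baseline_sd: float = 5.0
    contact_time_h: float = 0.0

    def __post_init__(self) -> None:
        if not 1.0 <= self.half_life_h <= 2.0:
            raise ValueError("reporter half-life must be within 1-2 h")
        if self.production_rate < 0:
            raise ValueError("production_rate must be >= 0")

    @property
    def k_per_h(self) -> float:
        return math.log(2.0) / self.half_life_h

    def signal(self, t_h: np.ndarray, t0_h: float = 0.0) -> np.ndarray:
        """Noiseless reporter rise above baseline at times ``t_h`` (hours)."""
        t = np.asarray(t_h, dtype=float)
        dt = np.maximum(0.0, t - t0_h)
        k = self.k_per_h
        return (self.production_rate / k) * (1.0 - np.exp(-k * dt))

    def crossing_time_h(self, level: float) -> float:
        """Time after onset at which the noiseless curve reaches ``level``."""
        k = self.k_per_h
        x = 1.0 - level * k / self.production_rate
        if x <= 0:
            return float("inf")
        return -math.log(x) / k


@dataclass(frozen=True)
class DilutionDesign:
    """Doses and replication of a limiting-dilution experiment."""

    doses: tuple[float, ...] = (100.0, 1000.0, 10000.0)
    n_injections_per_dose: int = 6
    frequency_pos: float = 1.0 / 1000.0
    frequency_neg: float = 1.0 / 7800.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be > 0")
        if self.n_injections_per_dose <= 0:
            raise ValueError("n_injections_per_dose must be > 0")
        for f in (self.frequency_pos, self.frequency_neg):
            if not 0.0 <= f <= 1.0:
                raise ValueError("frequencies must be in [0, 1]")


# --------------------------------------------------------------- rendering

def _soft_disk(img: np.ndarray, x_px: float, y_px: float, r_px: float,
               amplitude: float) -> None:
    """Additively draw an anti-aliased disk (sub-pixel center)."""
    h, w = img.shape
    lo_r = max(0, int(math.floor(y_px - r_px - 2)))
    hi_r = min(h, int(math.ceil(y_px + r_px + 2)) + 1)
    lo_c = max(0, int(math.floor(x_px - r_px - 2)))
    hi_c = min(w, int(math.ceil(x_px + r_px + 2)) + 1)
    if lo_r >= hi_r or lo_c >= hi_c:
        return
    rr = np.arange(lo_r, hi_r)[:, None]
    cc = np.arange(lo_c, hi_c)[None, :]
    d = np.sqrt((rr - y_px) ** 2 + (cc - x_px) ** 2)
    img[lo_r:hi_r, lo_c:hi_c] += amplitude * np.clip(r_px - d + 0.5, 0.0, 1.0)


def _gaussian_spot(img: np.ndarray, x_px: float, y_px: float, sigma_px: float,
                   amplitude: float) -> None:
    h, w = img.shape
    ext = int(math.ceil(4 * sigma_px)) + 1
    lo_r = max(0, int(y_px) - ext)
    hi_r = min(h, int(y_px) + ext + 1)
    lo_c = max(0, int(x_px) - ext)
    hi_c = min(w, int(x_px) + ext + 1)
    if lo_r >= hi_r or lo_c >= hi_c:
        return
    rr = np.arange(lo_r, hi_r)[:, None]
    cc = np.arange(lo_c, hi_c)[None, :]
    img[lo_r:hi_r, lo_c:hi_c] += amplitude * np.exp(
        -((rr - y_px) ** 2 + (cc - x_px) ** 2) / (2 * sigma_px**2)
    )


def _disk_mask(shape: tuple[int, int], x_px: float, y_px: float,
               r_px: float) -> tuple[slice, slice, np.ndarray]:
    h, w = shape
    lo_r = max(0, int(math.floor(y_px - r_px - 1)))
    hi_r = min(h, int(math.ceil(y_px + r_px + 1)) + 1)
    lo_c = max(0, int(math.floor(x_px - r_px - 1)))
    hi_c = min(w, int(math.ceil(x_px + r_px + 1)) + 1)
    rr = np.arange(lo_r, hi_r)[:, None]
    cc = np.arange(lo_c, hi_c)[None, :]
    return slice(lo_r, hi_r), slice(lo_c, hi_c), (
        (rr - y_px) ** 2 + (cc - x_px) ** 2 <= r_px**2
    )


def _finish(img: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, 255.0).astype(np.float32)


# ------------------------------------------------------------ tissue scene

def _sites_frame(tmem_sites) -> pd.DataFrame:
    return pd.DataFrame(
        [{"x_um": x, "y_um": y, "diameter_um": d, "kind": "tmem"}
         for x, y, d in tmem_sites]
    )


def generate_tissue_scene(
    config: SceneConfig, render: bool = True
) -> tuple[Optional[ChannelStack], SceneTruth]:
    """Generate a multi-channel still scene with paired ground truth.

    CSC labels are Bernoulli draws whose probability depends on the
    contour bin of the cell's distance to the nearest doorway circle
    (``config.enrichment_profile``), or is flat at
    ``csc_fraction_baseline`` when no profile is given. Sensor
    intensities come from a low control-construct distribution for
    non-CSCs and a shifted distribution for CSCs. If
    ``contact_fraction_by_class`` is set, the stated fraction of each
    class is placed in direct contact with a macrophage blob; remaining
    macrophage coverage is placed clear of all non-contacted cells.

    Placement, labels, intensities and rendering draw from independent
    child streams of the seed, so scenes with the same seed share cell
    positions even when label parameters differ.
    """
    place_rng, label_rng, intens_rng, mac_rng, noise_rng = (
        np.random.default_rng(config.seed).spawn(5)
    )
    w, h = config.field_size
    xy = np.column_stack(
        [place_rng.uniform(0, w, config.n_cells),
         place_rng.uniform(0, h, config.n_cells)]
    )

    # --- class labels ---------------------------------------------------
    if len(config.tmem_sites) > 0:
        sites = _sites_frame(config.tmem_sites)
        dist = spatial.distance_to_nearest_doorway(xy, sites)
    else:
        sites = None
        dist = np.full(config.n_cells, np.inf)
    if config.enrichment_profile is not None:
        if sites is None:
            raise ValueError("enrichment_profile requires at least one doorway")
        prof = np.asarray(config.enrichment_profile, dtype=float)
        p = prof[spatial.assign_bins(dist, config.bin_width, config.cap)]
    else:
        p = np.full(config.n_cells, config.csc_fraction_baseline)
    is_csc = label_rng.random(config.n_cells) < p
    cls = np.where(is_csc, "CSC", "nonCSC")

    # --- sensor intensities --------------------------------------------
    bg_mu, bg_sd = config.sensor_background
    pos_mu, pos_sd = config.sensor_positive
    sensor = np.where(
        is_csc,
        intens_rng.normal(pos_mu, pos_sd, config.n_cells),
        intens_rng.normal(bg_mu, bg_sd, config.n_cells),
    )
    control = intens_rng.normal(bg_mu, bg_sd, config.n_control)

    # --- macrophage mask and contact flags ------------------------------
    shape_px = (int(round(h / config.pixel_size)), int(round(w / config.pixel_size)))
    mac = np.zeros(shape_px, dtype=bool)
    contact = np.zeros(config.n_cells, dtype=bool)
    for c, frac in config.contact_fraction_by_class.items():
        members = np.flatnonzero(cls == c)
        contact[members] = mac_rng.random(len(members)) < frac
    clear_um = 1.5  # min gap between macrophage and non-contacted cell edges
    noncontact_xy = xy[~contact]

    def _blob_ok(bx: float, by: float) -> bool:
        if len(noncontact_xy) == 0:
            return True
        d = np.sqrt(((noncontact_xy - (bx, by)) ** 2).sum(axis=1))
        return bool(np.all(d > _MAC_R + _CELL_R + clear_um))

    def _stamp(bx: float, by: float) -> None:
        sl_r, sl_c, m = _disk_mask(
            shape_px, bx / config.pixel_size, by / config.pixel_size,
            _MAC_R / config.pixel_size,
        )
        mac[sl_r, sl_c] |= m

    n_unplaceable = 0
    for i in np.flatnonzero(contact):
        # place a blob overlapping the cell boundary by ~1 µm
        for _ in range(500):
            theta = mac_rng.uniform(0, 2 * np.pi)
            r = _CELL_R + _MAC_R - 1.0
            bx = xy[i, 0] + r * math.cos(theta)
            by = xy[i, 1] + r * math.sin(theta)
            if 0 <= bx <= w and 0 <= by <= h and _blob_ok(bx, by):
                _stamp(bx, by)
                break
        else:
            # crowded neighborhood: no contact-safe placement; record the
            # cell as not contacted so the truth matches the rendered mask
            contact[i] = False
            noncontact_xy = xy[~contact]
            n_unplaceable += 1
    target_px = config.macrophage_coverage * mac.size
    attempts = 0
    while mac.sum() < target_px and attempts < 20000:
        attempts += 1
        bx, by = mac_rng.uniform(0, w), mac_rng.uniform(0, h)
        if _blob_ok(bx, by):
            _stamp(bx, by)

    # --- vessel mask ----------------------------------------------------
    vessel = np.zeros(shape_px, dtype=bool)
    for poly in config.vessel_segments:
        pts = np.asarray(poly, dtype=float) / config.pixel_size
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            n = int(max(abs(x1 - x0), abs(y1 - y0))) * 2 + 2
            for t in np.linspace(0, 1, n):
                sl_r, sl_c, m = _disk_mask(
                    shape_px, x0 + t * (x1 - x0), y0 + t * (y1 - y0),
                    4.0 / config.pixel_size,
                )
                vessel[sl_r, sl_c] |= m

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(config.n_cells),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "cls": cls,
            "sensor_intensity": sensor,
            "contact": contact,
            "distance_um": dist,
        }
    )
    truth = SceneTruth(
        cells=cells,
        config={**config.echo(), "generator": "generate_tissue_scene",
                "n_contacts_unplaceable": n_unplaceable},
        masks={
            "macrophage": RegionMask(mac, config.pixel_size, "macrophage"),
            "vessel": RegionMask(vessel, config.pixel_size, "vessel"),
        },
        sites=sites,
        control_intensities=control,
    )

    stack = None
    if render:
        px = config.pixel_size
        nuclei = np.zeros(shape_px)
        volume = np.zeros(shape_px)
        sensor_ch = np.zeros(shape_px)
        for i in range(config.n_cells):
            xp, yp = xy[i, 0] / px, xy[i, 1] / px
            _soft_disk(nuclei, xp, yp, 4.0 / px, 180.0)
            _soft_disk(volume, xp, yp, _CELL_R / px, 150.0)
            _soft_disk(sensor_ch, xp, yp, _CELL_R / px, float(sensor[i]))
        channels = {
            "nuclei": _finish(nuclei, noise_rng, config.noise_sd),
            "volume": _finish(volume, noise_rng, config.noise_sd),
            "sensor": _finish(sensor_ch, noise_rng, config.noise_sd),
            "macrophage": _finish(mac * 180.0, noise_rng, config.noise_sd),
            "vessel": _finish(vessel * 150.0, noise_rng, config.noise_sd),
        }
        stack = ChannelStack(channels, px, metadata={"seed": config.seed})
    return stack, truth


# ---------------------------------------------------------------- movies

def generate_timelapse(
    config: SceneConfig,
    kinetics: ReporterKinetics,
    speeds: dict[str, float],
    drift_um_per_min: Union[float, tuple[float, float]] = 0.0,
    duration_min: float = 60.0,
    frame_interval_min: float = 2.0,
    seed: Optional[int] = None,
    *,
    persistence_min: float = 10.0,
    localization_jitter_um: float = 0.0,
    conversion_prob_contacted: float = 1.0,
    conversion_prob_uncontacted: float = 0.0,
    margin_um: float = 80.0,
    render: bool = True,
) -> tuple[Optional[ChannelStack], MovieTruth]:
    """Generate a time-lapse movie with per-frame ground truth.

    Cells follow persistent random walks with constant per-cell speed
    (so the truth mean speed equals the configured class speed exactly)
    and heading decorrelation time ``persistence_min``. A global drift
    is added to all observed positions. Non-CSC cells flagged as
    contacted (per ``config.contact_fraction_by_class``) convert with
    probability ``conversion_prob_contacted`` and switch reporter
    production on at the contact frame with first-order decay
    ``k = ln2 / half_life``; uncontacted cells convert spontaneously
    with ``conversion_prob_uncontacted`` at a random frame.
    """
    if frame_interval_min <= 0:
        raise ValueError("frame_interval must be > 0")
    if duration_min < 2 * frame_interval_min:
        raise ValueError("duration must cover at least 2 frame intervals")
    if seed is None:
        seed = config.seed
    rng_pos, rng_evt, rng_int, rng_noise = np.random.default_rng(seed).spawn(4)

    n_frames = int(math.floor(duration_min / frame_interval_min)) + 1
    t_min = np.arange(n_frames) * frame_interval_min
    w, h = config.field_size
    n = config.n_cells
    n_csc = int(round(n * config.csc_fraction_baseline))
    cls = np.array(["CSC"] * n_csc + ["nonCSC"] * (n - n_csc))
    speed = np.array([speeds.get(c, 0.0) for c in cls], dtype=float)

    # persistent random walk with reflecting field margins
    x = rng_pos.uniform(margin_um, w - margin_um, n)
    y = rng_pos.uniform(margin_um, h - margin_um, n)
    theta = rng_pos.uniform(0, 2 * np.pi, n)
    sigma_theta = math.sqrt(2.0 * frame_interval_min / persistence_min)
    xs = np.empty((n_frames, n))
    ys = np.empty((n_frames, n))
    xs[0], ys[0] = x, y
    step = speed * frame_interval_min
    for f in range(1, n_frames):
        theta = theta + rng_pos.normal(0.0, sigma_theta, n)
        x = x + step * np.cos(theta)
        y = y + step * np.sin(theta)
        # reflect off the field border (rare with an adequate margin)
        flip_x = (x < 0) | (x > w)
        flip_y = (y < 0) | (y > h)
        x = np.where(x < 0, -x, np.where(x > w, 2 * w - x, x))
        y = np.where(y < 0, -y, np.where(y > h, 2 * h - y, y))
        theta = np.where(flip_x, np.pi - theta, theta)
        theta = np.where(flip_y, -theta, theta)
        xs[f], ys[f] = x, y

    if np.isscalar(drift_um_per_min):
        mag = float(drift_um_per_min)
        ang = rng_pos.uniform(0, 2 * np.pi)
        drift_v = np.array([mag * math.cos(ang), mag * math.sin(ang)])
    else:
        drift_v = np.asarray(drift_um_per_min, dtype=float)
    drift_cum = np.outer(t_min, drift_v)  # (T, 2)

    # --- contact and conversion events ----------------------------------
    contacted = np.zeros(n, dtype=bool)
    frac = config.contact_fraction_by_class.get("nonCSC", 0.0)
    non_idx = np.flatnonzero(cls == "nonCSC")
    contacted[non_idx] = rng_evt.random(len(non_idx)) < frac
    lo = 3  # guarantee pre-contact frames for induction normalization
    hi = max(lo + 1, n_frames // 2)
    contact_frame = np.full(n, -1)
    contact_frame[contacted] = rng_evt.integers(lo, hi, contacted.sum())
    converted = np.zeros(n, dtype=bool)
    conversion_frame = np.full(n, -1)
    for i in non_idx:
        if contacted[i]:
            if rng_evt.random() < conversion_prob_contacted:
                converted[i] = True
                conversion_frame[i] = contact_frame[i]
        elif rng_evt.random() < conversion_prob_uncontacted:
            converted[i] = True
            conversion_frame[i] = rng_evt.integers(lo, hi)

    # --- reporter intensity ---------------------------------------------
    pos_mu, pos_sd = config.sensor_positive
    sensor = rng_int.normal(kinetics.baseline_mean, kinetics.baseline_sd,
                            (n_frames, n))
    for i in range(n):
        if cls[i] == "CSC":
            sensor[:, i] += pos_mu - kinetics.baseline_mean
        elif converted[i]:
            t0_h = conversion_frame[i] * frame_interval_min / 60.0
            sensor[:, i] += kinetics.signal(t_min / 60.0, t0_h)
    np.clip(sensor, 0.0, None, out=sensor)

    jitter = (
        rng_noise.normal(0.0, localization_jitter_um, (n_frames, n, 2))
        if localization_jitter_um > 0
        else np.zeros((n_frames, n, 2))
    )
    x_obs = xs + drift_cum[:, None, 0] + jitter[:, :, 0]
    y_obs = ys + drift_cum[:, None, 1] + jitter[:, :, 1]

    frames_col = np.repeat(np.arange(n_frames), n)
    tracks = pd.DataFrame(
        {
            "cell_id": np.tile(np.arange(n), n_frames),
            "frame": frames_col,
            "t_min": frames_col * frame_interval_min,
            "x_um": xs.ravel(),
            "y_um": ys.ravel(),
            "x_obs": x_obs.ravel(),
            "y_obs": y_obs.ravel(),
            "sensor_intensity": sensor.ravel(),
        }
    )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "cls": cls,
            "speed_truth": speed,
            "contacted": contacted,
            "contact_frame": contact_frame,
            "converted": converted,
            "conversion_frame": conversion_frame,
        }
    )
    cfg = {
        **config.echo(),
        "generator": "generate_timelapse",
        "seed": seed,
        "speeds": dict(speeds),
        "drift_um_per_min": list(drift_v),
        "duration_min": duration_min,
        "frame_interval_min": frame_interval_min,
        "persistence_min": persistence_min,
        "localization_jitter_um": localization_jitter_um,
        "conversion_prob_contacted": conversion_prob_contacted,
        "conversion_prob_uncontacted": conversion_prob_uncontacted,
    }
    truth = MovieTruth(tracks, cells, drift_cum, frame_interval_min, cfg)

    stack = None
    if render:
        px = config.pixel_size
        shape_px = (int(round(h / px)), int(round(w / px)))
        vol = np.zeros((n_frames, *shape_px), dtype=np.float32)
        sen = np.zeros((n_frames, *shape_px), dtype=np.float32)
        for f in range(n_frames):
            vf = np.zeros(shape_px)
            sf = np.zeros(shape_px)
            for i in range(n):
                xp, yp = x_obs[f, i] / px, y_obs[f, i] / px
                _soft_disk(vf, xp, yp, _CELL_R / px, 150.0)
                _soft_disk(sf, xp, yp, _CELL_R / px, float(sensor[f, i]))
            vol[f] = _finish(vf, rng_noise, config.noise_sd)
            sen[f] = _finish(sf, rng_noise, config.noise_sd)
        stack = ChannelStack(
            {"volume": vol, "sensor": sen},
            px,
            frame_interval=frame_interval_min,
            metadata={"seed": seed},
        )
    return stack, truth


# ------------------------------------------------------------- kymograph

@dataclass
class EdgeTrace:
    """A membrane edge-position trace with its planted periodicity."""

    t_min: np.ndarray
    position_um: np.ndarray
    sampling_min: float
    period_truth_min: float
    amplitude_um: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_min": self.t_min, "position_um": self.position_um})


def generate_kymograph(
    period_min: float = 10.0,
    amplitude_um: float = 2.0,
    duration_min: float = 60.0,
    sampling_min: float = 1.0,
    noise_sd_um: float = 0.0,
    seed: int = 0,
) -> EdgeTrace:
    """Sinusoid-plus-noise edge-position trace (protrusion oscillations)."""
    if sampling_min <= 0 or period_min <= 0:
        raise ValueError("sampling and period must be > 0")
    if sampling_min >= period_min / 2.0:
        raise ValueError(
            f"sampling {sampling_min} min violates Nyquist for a "
            f"{period_min} min period"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min, sampling_min)
    pos = amplitude_um * np.sin(2 * np.pi * t / period_min)
    if noise_sd_um > 0:
        pos = pos + rng.normal(0.0, noise_sd_um, t.shape)
    return EdgeTrace(t, pos, sampling_min, period_min, amplitude_um)


# ----------------------------------------------------------- puncta scene

def generate_puncta_scene(
    n_cells: int = 50,
    stem_fraction: float = 0.2,
    puncta_per_stem_area: float = 0.02,  # spots / µm²
    puncta_per_nonstem_area: float = 0.004,
    coloc_fraction: float = 0.8,
    degradation_fraction_by_class: Optional[dict] = None,
    seed: int = 0,
    *,
    field_size: tuple[float, float] = (300.0, 300.0),
    pixel_size: float = 0.5,
    roi_diameter_um: float = 36.0,
    coloc_offset_um: float = 0.15,
    spot_sigma_um: float = 0.25,
    noise_sd: float = 2.0,
    render: bool = True,
) -> tuple[Optional[ChannelStack], SceneTruth]:
    """Puncta field with planted colocalized pairs and degradation areas.

    Cortactin (A) spots are Poisson-placed at the stated densities in
    stem-cell ROIs (``roi_diameter_um`` disks around stem cells) and in
    the non-stem remainder; a ``coloc_fraction`` of A spots receive a
    Tks5 (B) partner within ``coloc_offset_um`` of their center, and
    unpaired B spots are added at the complementary rate. Degradation
    (cleaved collagen) is planted per-pixel at the per-class fractions.
    """
    for name, v in (("stem_fraction", stem_fraction),
                    ("coloc_fraction", coloc_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    degradation_fraction_by_class = degradation_fraction_by_class or {}
    for c, f in degradation_fraction_by_class.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"degradation fraction for {c!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    w, h = field_size
    shape_px = (int(round(h / pixel_size)), int(round(w / pixel_size)))

    xy = np.column_stack([rng.uniform(0, w, n_cells), rng.uniform(0, h, n_cells)])
    is_stem = rng.random(n_cells) < stem_fraction

    stem_mask = np.zeros(shape_px, dtype=bool)
    roi_r = roi_diameter_um / 2.0
    for i in np.flatnonzero(is_stem):
        sl_r, sl_c, m = _disk_mask(
            shape_px, xy[i, 0] / pixel_size, xy[i, 1] / pixel_size,
            roi_r / pixel_size,
        )
        stem_mask[sl_r, sl_c] |= m
    nonstem_mask = ~stem_mask
    areas = {
        "stem": stem_mask.sum() * pixel_size**2,
        "nonstem": nonstem_mask.sum() * pixel_size**2,
    }

    def _sample_in(mask: np.ndarray, count: int) -> np.ndarray:
        rows, cols = np.nonzero(mask)
        if len(rows) == 0 or count == 0:
            return np.empty((0, 2))
        pick = rng.integers(0, len(rows), count)
        sub = rng.uniform(-0.5, 0.5, (count, 2))
        return np.column_stack(
            [(cols[pick] + sub[:, 0]) * pixel_size,
             (rows[pick] + sub[:, 1]) * pixel_size]
        )

    records = []
    pair_id = 0
    for region, mask, dens in (
        ("stem", stem_mask, puncta_per_stem_area),
        ("nonstem", nonstem_mask, puncta_per_nonstem_area),
    ):
        n_a = rng.poisson(dens * areas[region])
        a_xy = _sample_in(mask, n_a)
        paired = rng.random(n_a) < coloc_fraction
        n_lone_b = rng.poisson((1.0 - coloc_fraction) * dens * areas[region])
        b_lone = _sample_in(mask, n_lone_b)
        for j in range(n_a):
            pid = -1
            if paired[j]:
                pid = pair_id
                pair_id += 1
            records.append(
                dict(x_um=a_xy[j, 0], y_um=a_xy[j, 1], channel="cortactin",
                     region=region, pair_id=pid)
            )
            if paired[j]:
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, coloc_offset_um)
                records.append(
                    dict(x_um=a_xy[j, 0] + rad * math.cos(ang),
                         y_um=a_xy[j, 1] + rad * math.sin(ang),
                         channel="tks5", region=region, pair_id=pid)
                )
        for b in b_lone:
            records.append(
                dict(x_um=b[0], y_um=b[1], channel="tks5",
                     region=region, pair_id=-1)
            )
    puncta = pd.DataFrame(
        records, columns=["x_um", "y_um", "channel", "region", "pair_id"]
    )

    merged_warning = False
    for ch in ("cortactin", "tks5"):
        pts = puncta.loc[puncta.channel == ch, ["x_um", "y_um"]].to_numpy()
        if len(pts) > 1:
            from scipy.spatial import cKDTree

            d, _ = cKDTree(pts).query(pts, k=2)
            if np.any(d[:, 1] < 4 * spot_sigma_um):
                merged_warning = True
    if merged_warning:
        warnings.warn(
            "puncta density high enough that some spots overlap beyond the "
            "stated tolerance; detection counts may undershoot the truth",
            stacklevel=2,
        )

    # degradation: planted per-pixel positive fractions per class region
    degr = np.zeros(shape_px, dtype=bool)
    for region, mask in (("stem", stem_mask), ("nonstem", nonstem_mask)):
        f = degradation_fraction_by_class.get(region, 0.0)
        if f > 0:
            degr |= mask & (rng.random(shape_px) < f)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "cls": np.where(is_stem, "CSC", "nonCSC"),
            "sensor_intensity": np.where(is_stem, 120.0, 20.0),
        }
    )
    truth = SceneTruth(
        cells=cells,
        config={
            "generator": "generate_puncta_scene",
            "seed": seed,
            "stem_fraction": stem_fraction,
            "coloc_fraction": coloc_fraction,
            "densities": {"stem": puncta_per_stem_area,
                          "nonstem": puncta_per_nonstem_area},
            "degradation_fraction_by_class": dict(degradation_fraction_by_class),
            "field_size": field_size,
            "pixel_size": pixel_size,
            "roi_diameter_um": roi_diameter_um,
            "merged_warning": merged_warning,
        },
        masks={
            "stem_area": RegionMask(stem_mask, pixel_size, "stem_area"),
            "degradation": RegionMask(degr, pixel_size, "degradation"),
        },
        puncta=puncta,
    )

    stack = None
    if render:
        volume = np.zeros(shape_px)
        flag = np.zeros(shape_px)
        cort = np.zeros(shape_px)
        tks5 = np.zeros(shape_px)
        for i in range(n_cells):
            xp, yp = xy[i, 0] / pixel_size, xy[i, 1] / pixel_size
            _soft_disk(volume, xp, yp, _CELL_R / pixel_size, 120.0)
            if is_stem[i]:
                _soft_disk(flag, xp, yp, _CELL_R / pixel_size, 150.0)
        for _, p in puncta.iterrows():
            target = cort if p.channel == "cortactin" else tks5
            _gaussian_spot(
                target, p.x_um / pixel_size, p.y_um / pixel_size,
                spot_sigma_um / pixel_size, 200.0,
            )
        channels = {
            "volume": _finish(volume, rng, noise_sd),
            "flag": _finish(flag, rng, noise_sd),
            "cortactin": _finish(cort, rng, noise_sd),
            "tks5": _finish(tks5, rng, noise_sd),
            "cleaved_collagen": _finish(degr * 200.0, rng, noise_sd),
        }
        stack = ChannelStack(channels, pixel_size, metadata={"seed": seed})
    return stack, truth


# --------------------------------------------------------------- dilution

def generate_dilution_table(
    design: DilutionDesign, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate tumor-take tables for the positive and negative arms.

    Each injection takes with the single-hit probability
    ``p = 1 - exp(-f * dose)``. Returns ``(table_pos, table_neg)`` with
    columns ``dose, n_injections, n_tumors``.
    """
    rng = np.random.default_rng(seed)

    def one_arm(f: float) -> pd.DataFrame:
        doses = np.asarray(design.doses, dtype=float)
        p = 1.0 - np.exp(-f * doses)
        takes = rng.binomial(design.n_injections_per_dose, p)
        return pd.DataFrame(
            {
                "dose": doses,
                "n_injections": design.n_injections_per_dose,
                "n_tumors": takes,
            }
        )

    return one_arm(design.frequency_pos), one_arm(design.frequency_neg)


# ------------------------------------------------------ metastasis section

_LESION_CLASSES = ("small", "medium", "large")
_DEFAULT_CELL_RANGES = {"small": (1, 10), "medium": (11, 300), "large": (301, 600)}


def generate_metastasis_section(
    lesion_count_by_class: dict[str, int],
    stem_fraction_by_class: dict[str, float],
    seed: int = 0,
    *,
    field_size: tuple[float, float] = (3000.0, 3000.0),
    pixel_size: float = 1.0,
    cells_per_lesion: Optional[dict] = None,
    cell_spacing_um: float = 10.0,
    min_separation_um: float = 120.0,
    max_retries: int = 500,
    sensor_background: tuple[float, float] = (20.0, 5.0),
    sensor_positive: tuple[float, float] = (120.0, 15.0),
    n_control: int = 2000,
    noise_sd: float = 2.0,
    render: bool = True,
) -> tuple[Optional[ChannelStack], SceneTruth]:
    """Lung-section style scene of spatially separated metastatic lesions.

    Lesions come in size classes (small ≤ 10 cells, medium 11–300,
    large > 300); each cell is sensor-positive with the per-class stem
    fraction. Lesion footprints are disks placed with at least
    ``min_separation_um`` between boundaries so that downstream
    clustering recovers the planted lesions exactly.
    """
    bad = set(lesion_count_by_class) - set(_LESION_CLASSES)
    if bad:
        raise ValueError(f"unknown lesion classes {sorted(bad)}; "
                         f"expected keys from {_LESION_CLASSES}")
    for c, f in stem_fraction_by_class.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"stem fraction for {c!r} outside [0, 1]")
    cells_per_lesion = {**_DEFAULT_CELL_RANGES, **(cells_per_lesion or {})}
    rng = np.random.default_rng(seed)
    w, h = field_size

    lesions = []  # (class, n_cells, x, y, radius)
    placed = []
    for c in _LESION_CLASSES:
        for _ in range(lesion_count_by_class.get(c, 0)):
            spec_n = cells_per_lesion[c]
            n_in = (int(spec_n) if np.isscalar(spec_n)
                    else int(rng.integers(spec_n[0], spec_n[1] + 1)))
            radius = max(
                _CELL_R, math.sqrt(n_in * cell_spacing_um**2 / math.pi)
            )
            for _ in range(max_retries):
                cx = rng.uniform(radius, w - radius)
                cy = rng.uniform(radius, h - radius)
                if all(
                    math.hypot(cx - px_, cy - py_) >= r_ + radius + min_separation_um
                    for px_, py_, r_ in placed
                ):
                    placed.append((cx, cy, radius))
                    lesions.append((c, n_in, cx, cy, radius))
                    break
            else:
                raise RuntimeError(
                    "could not place non-overlapping lesions; enlarge the field"
                )

    rows = []
    cell_id = 0
    for lesion_id, (c, n_in, cx, cy, radius) in enumerate(lesions):
        frac = stem_fraction_by_class.get(c, 0.0)
        rr = radius * np.sqrt(rng.random(n_in))
        aa = rng.uniform(0, 2 * np.pi, n_in)
        stem = rng.random(n_in) < frac
        for j in range(n_in):
            rows.append(
                dict(
                    cell_id=cell_id,
                    x_um=cx + rr[j] * math.cos(aa[j]),
                    y_um=cy + rr[j] * math.sin(aa[j]),
                    cls="CSC" if stem[j] else "nonCSC",
                    lesion_id=lesion_id,
                    lesion_class=c,
                )
            )
            cell_id += 1
    cells = pd.DataFrame(
        rows, columns=["cell_id", "x_um", "y_um", "cls", "lesion_id",
                       "lesion_class"]
    )
    bg_mu, bg_sd = sensor_background
    pos_mu, pos_sd = sensor_positive
    is_csc = (cells.cls == "CSC").to_numpy()
    cells["sensor_intensity"] = np.where(
        is_csc,
        rng.normal(pos_mu, pos_sd, len(cells)),
        rng.normal(bg_mu, bg_sd, len(cells)),
    )
    control = rng.normal(bg_mu, bg_sd, n_control)

    lesion_table = pd.DataFrame(
        [
            dict(lesion_id=i, lesion_class=c, n_cells=n_in, x_um=cx, y_um=cy,
                 radius_um=r)
            for i, (c, n_in, cx, cy, r) in enumerate(lesions)
        ],
        columns=["lesion_id", "lesion_class", "n_cells", "x_um", "y_um",
                 "radius_um"],
    )
    truth = SceneTruth(
        cells=cells,
        config={
            "generator": "generate_metastasis_section",
            "seed": seed,
            "lesion_count_by_class": dict(lesion_count_by_class),
            "stem_fraction_by_class": dict(stem_fraction_by_class),
            "field_size": field_size,
            "pixel_size": pixel_size,
        },
        sites=lesion_table,
        control_intensities=control,
    )

    stack = None
    if render:
        shape_px = (int(round(h / pixel_size)), int(round(w / pixel_size)))
        nuclei = np.zeros(shape_px)
        volume = np.zeros(shape_px)
        sensor_ch = np.zeros(shape_px)
        for _, cell in cells.iterrows():
            xp, yp = cell.x_um / pixel_size, cell.y_um / pixel_size
            _soft_disk(nuclei, xp, yp, 4.0 / pixel_size, 180.0)
            _soft_disk(volume, xp, yp, _CELL_R / pixel_size, 150.0)
            _soft_disk(sensor_ch, xp, yp, _CELL_R / pixel_size,
                       float(cell.sensor_intensity))
        channels = {
            "nuclei": _finish(nuclei, rng, noise_sd),
            "volume": _finish(volume, rng, noise_sd),
            "sensor": _finish(sensor_ch, rng, noise_sd),
        }
        stack = ChannelStack(channels, pixel_size, metadata={"seed": seed})
    return stack, truth
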