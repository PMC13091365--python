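"""Synthetic study-data generators with recorded ground truth.

Every input the analysis pipeline consumes can be generated here at desk
scale: tubular vascular phantoms, raw optoacoustic raster scans (bandlimited
bipolar pulses from absorbing voxels, per-B-scan vertical motion, additive
noise), two-distance diffuse reflectance spectra, fluorescence hypoxia
sections and two-group longitudinal cohorts.  Generators are deterministic
per seed and always return the ground truth used to produce the data, so
each downstream stage can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.signal import butter, fftconvolve, sosfiltfilt

from . import dosrecon
from .hypoxia import FluorescenceSection

__all__ = [
    "CohortDesign",
    "LongitudinalDataset",
    "MotionProfile",
    "RawScan",
    "ScanConfig",
    "SectionTruth",
    "VesselPhantom",
    "generate_hypoxia_section",
    "generate_vessel_tree",
    "load_rawscan",
    "save_rawscan",
    "simulate_cohort",
    "simulate_dos_spectrum",
    "simulate_motion_profile",
    "simulate_oa_scan",
    "tube_phantom",
]


# ---------------------------------------------------------------------------
# Vascular phantoms
# ---------------------------------------------------------------------------

@dataclass
class VesselPhantom:
    """Rasterized tubular absorber phantom.

    ``absorption_map`` is indexed [x][y][z] (x = fast scan axis, y = slow
    axis, z = depth) with isotropic ``voxel_size`` in um.  ``centerlines``
    is a list of (points_mm (k,3), radius_um) tuples recording the ground
    truth geometry; ``true_volume_fraction`` is the exact percentage of
    voxels inside any vessel.
    """

    absorption_map: NDArray[np.float64]
    voxel_size: float
    centerlines: list[tuple[NDArray[np.float64], float]]
    true_volume_fraction: float
    domain_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if np.any(self.absorption_map < 0):
            raise ValueError("absorption map must be nonnegative")
        if not (0.0 <= self.true_volume_fraction <= 100.0):
            raise ValueError("true_volume_fraction must be a percentage")

    @property
    def mask(self) -> NDArray[np.bool_]:
        return self.absorption_map > 0

    @classmethod
    def from_centerlines(
        cls,
        domain_size_mm: tuple[float, float, float],
        voxel_size_um: float,
        polylines: list[tuple[NDArray, float]],
        absorption: float = 1.0,
    ) -> "VesselPhantom":
        """Rasterize polyline centerlines (points in mm, radius in um)."""
        shape = tuple(
            int(round(d * 1000.0 / voxel_size_um)) for d in domain_size_mm
        )
        vol = np.zeros(shape, dtype=float)
        for points_mm, radius_um in polylines:
            _stamp_tube(vol, np.asarray(points_mm, float), radius_um, voxel_size_um)
        vvf = 100.0 * np.count_nonzero(vol) / vol.size
        return cls(
            absorption_map=vol * absorption,
            voxel_size=voxel_size_um,
            centerlines=[(np.asarray(p, float), float(r)) for p, r in polylines],
            true_volume_fraction=vvf,
            domain_size=tuple(domain_size_mm),
        )


def _sphere_offsets(radius_vox: float) -> NDArray[np.int64]:
    r_int = int(np.floor(radius_vox))
    ax = np.arange(-r_int, r_int + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius_vox**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def _stamp_tube(
    vol: NDArray, points_mm: NDArray, radius_um: float, voxel_um: float
) -> None:
    """Mark all voxels whose center lies within radius of the polyline."""
    radius_vox = radius_um / voxel_um
    offsets = _sphere_offsets(radius_vox)
    pts_vox = points_mm * 1000.0 / voxel_um  # voxel-center registration below
    centers = []
    for p0, p1 in zip(pts_vox[:-1], pts_vox[1:]):
        seg = p1 - p0
        length = np.linalg.norm(seg)
        n_sub = max(2, int(np.ceil(length / 0.4)))
        t = np.linspace(0.0, 1.0, n_sub)
        centers.append(p0[None] + t[:, None] * seg[None])
    if not centers:
        centers = [pts_vox]
    pts = np.concatenate(centers, axis=0)
    # voxel index of center (i) covers coordinate (i + 0.5) * voxel
    idx = np.floor(pts - 0.5).astype(int) + offsets[:, None, :].reshape(-1, 1, 3)
    idx = idx.reshape(-1, 3)
    valid = np.all((idx >= 0) & (idx < np.array(vol.shape)), axis=1)
    idx = idx[valid]
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0


def tube_phantom(
    domain_size_mm: tuple[float, float, float],
    start_mm: tuple[float, float, float],
    end_mm: tuple[float, float, float],
    diameter_um: float,
    voxel_size_um: float = 20.0,
) -> VesselPhantom:
    """Single straight tube; the workhorse fixture for recovery tests."""
    pts = np.array([start_mm, end_mm], dtype=float)
    return VesselPhantom.from_centerlines(
        domain_size_mm, voxel_size_um, [(pts, diameter_um / 2.0)]
    )


def parallel_tube_phantom(
    n_tubes: int,
    diameter_um: float = 80.0,
    domain_size_mm: tuple[float, float, float] = (1.28, 1.28, 1.28),
    depth_range_mm: tuple[float, float] = (0.46, 0.70),
    lateral_range_mm: tuple[float, float] = (0.34, 0.94),
    voxel_size_um: float = 20.0,
    seed: int = 0,
    grid: tuple[int, int] = (4, 3),
) -> VesselPhantom:
    """Slow-axis-parallel straight tubes on a jittered (x, z) grid.

    The canonical recovery fixture: tubes crossing the full slow-axis
    extent at constant depth present identical point-like cross-sections to
    every B-scan, keeping the imaging point-spread identical for each tube
    (grid placement guarantees lateral separation).  Deterministic per seed.
    """
    if n_tubes > grid[0] * grid[1]:
        raise ValueError("more tubes requested than grid cells")
    rng = np.random.default_rng(seed)
    xs = np.linspace(*lateral_range_mm, grid[0])
    zs = np.linspace(*depth_range_mm, grid[1])
    cells = [(x, z) for x in xs for z in zs]
    order = rng.permutation(len(cells))[:n_tubes]
    jx = 0.3 * (xs[1] - xs[0]) if grid[0] > 1 else 0.04
    jz = 0.3 * (zs[1] - zs[0]) if grid[1] > 1 else 0.03
    polys = []
    for k in order:
        x, z = cells[k]
        x += rng.uniform(-jx, jx)
        z += rng.uniform(-jz, jz)
        pts = np.array([[x, 0.0, z], [x, domain_size_mm[1], z]])
        polys.append((pts, diameter_um / 2.0))
    return VesselPhantom.from_centerlines(domain_size_mm, voxel_size_um, polys)


def generate_vessel_tree(
    domain_size_mm: tuple[float, float, float] = (1.28, 1.28, 1.28),
    n_seeds: int = 4,
    diameter_range_um: tuple[float, float] = (40.0, 140.0),
    branching_params: dict | None = None,
    voxel_size_um: float = 20.0,
    seed: int = 0,
) -> VesselPhantom:
    """Random tortuous vessel tree rasterized onto the voxel grid.

    Each seed spawns a persistent random-walk centerline with a per-vessel
    radius drawn from ``diameter_range_um``; child branches split off with
    probability ``branch_prob`` per step at ~0.8x the parent radius.
    Deterministic per seed.
    """
    lo_d, hi_d = diameter_range_um
    if lo_d < 2 * voxel_size_um:
        raise ValueError("smallest diameter must span at least two voxels")
    if hi_d / 1000.0 > min(domain_size_mm):
        raise ValueError("largest requested diameter does not fit in the domain")
    bp = {"branch_prob": 0.03, "step_mm": 0.08, "jitter": 0.35, "max_steps": 200}
    bp.update(branching_params or {})
    rng = np.random.default_rng(seed)
    sx, sy, sz = domain_size_mm
    polylines: list[tuple[NDArray, float]] = []
    stack: list[tuple[NDArray, NDArray, float]] = []
    for _ in range(n_seeds):
        origin = np.array(
            [rng.uniform(0.1 * sx, 0.9 * sx),
             rng.uniform(0.1 * sy, 0.9 * sy),
             rng.uniform(0.25 * sz, 0.75 * sz)]
        )
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(theta), np.sin(theta), rng.uniform(-0.2, 0.2)])
        radius = rng.uniform(lo_d, hi_d) / 2.0
        stack.append((origin, direction, radius))
    margin = np.array([0.0, 0.0, 0.0])
    hi = np.array(domain_size_mm)
    while stack:
        pos, direction, radius = stack.pop()
        direction = direction / np.linalg.norm(direction)
        pts = [pos.copy()]
        for _ in range(bp["max_steps"]):
            direction = direction + bp["jitter"] * rng.standard_normal(3) * np.array(
                [1.0, 1.0, 0.5]
            )
            direction /= np.linalg.norm(direction)
            nxt = pts[-1] + bp["step_mm"] * direction
            if np.any(nxt < margin) or np.any(nxt > hi):
                break
            pts.append(nxt)
            if radius > lo_d / 2.0 * 1.25 and rng.uniform() < bp["branch_prob"]:
                child_dir = direction + 0.8 * rng.standard_normal(3)
                stack.append((nxt.copy(), child_dir, radius * 0.8))
        if len(pts) >= 2:
            polylines.append((np.array(pts), radius))
    if not polylines:
        empty = VesselPhantom(
            absorption_map=np.zeros(
                tuple(int(round(d * 1000 / voxel_size_um)) for d in domain_size_mm)
            ),
            voxel_size=voxel_size_um,
            centerlines=[],
            true_volume_fraction=0.0,
            domain_size=tuple(domain_size_mm),
        )
        return empty
    return VesselPhantom.from_centerlines(domain_size_mm, voxel_size_um, polylines)


# ---------------------------------------------------------------------------
# Raw optoacoustic scans
# ---------------------------------------------------------------------------

@dataclass
class ScanConfig:
    """Acquisition geometry and electronics of the raster scanner.

    The focused detector is modeled as a virtual point receiver at its focus
    raster-scanned in the plane z = 0 above the volume (depth positive
    downward).
    """

    sampling_rate: float = 2.0e8
    scan_step: float = 20.0
    field_of_view: tuple[float, float, float] = (1.28, 1.28, 1.92)
    sound_speed_true: float = 1505.0
    detector_band: tuple[float, float] = (1.0e6, 3.0e7)
    pulse_energy: float = 0.3
    beam_diameter: float = 5.5
    n_time_samples: int = 512

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2.0 * self.detector_band[1]:
            raise ValueError("sampling rate must exceed twice the upper band edge")
        if self.scan_step <= 0:
            raise ValueError("scan step must be positive")
        if not (1400.0 <= self.sound_speed_true <= 1650.0):
            raise ValueError("sound speed outside plausible tissue range")
        if self.n_time_samples < 16:
            raise ValueError("need at least 16 time samples")

    @property
    def record_depth_mm(self) -> float:
        """Maximum depth reachable within the record window, mm."""
        return self.sound_speed_true * self.n_time_samples / self.sampling_rate * 1e3


@dataclass
class MotionProfile:
    """Per-B-scan vertical (depth) displacement along the slow axis, um."""

    shifts: NDArray[np.float64]
    increment_bound: float = np.inf

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 1 or not np.all(np.isfinite(self.shifts)):
            raise ValueError("shifts must be a finite 1D array")

    @classmethod
    def zero(cls, n_bscans: int) -> "MotionProfile":
        return cls(np.zeros(n_bscans), increment_bound=0.0)


def simulate_motion_profile(
    n_bscans: int,
    max_shift: float = 100.0,
    smoothness: float = 8.0,
    seed: int = 0,
) -> MotionProfile:
    """Smooth bounded random walk of vertical shifts.

    Construction guarantees |shift| <= max_shift and per-B-scan increments
    bounded by max_shift/smoothness (clipping is 1-Lipschitz, so the final
    amplitude clip cannot enlarge increments).
    """
    if max_shift < 0:
        raise ValueError("max_shift must be nonnegative")
    rng = np.random.default_rng(seed)
    if max_shift == 0 or n_bscans == 0:
        return MotionProfile.zero(n_bscans)
    inc_bound = max_shift / smoothness
    raw = gaussian_filter1d(rng.standard_normal(n_bscans), sigma=smoothness / 2.0)
    inc = np.diff(raw, prepend=0.0)
    scale = np.max(np.abs(inc))
    inc = inc / scale * inc_bound if scale > 0 else inc
    prof = np.clip(np.cumsum(inc), -max_shift, max_shift)
    return MotionProfile(prof, increment_bound=inc_bound)


@dataclass
class RawScan:
    """Stack of time-resolved A-scans [slow axis][fast axis][time] + truth."""

    ascans: NDArray[np.float64]
    config: ScanConfig
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ascans.ndim != 3:
            raise ValueError("ascans must be a 3D array [slow][fast][time]")
        if self.ascans.shape[2] != self.config.n_time_samples:
            raise ValueError("time axis inconsistent with config.n_time_samples")
        if not np.all(np.isfinite(self.ascans)):
            raise ValueError("A-scans contain non-finite values")


def _oa_pulse_kernel(config: ScanConfig, n_kernel: int = 257) -> NDArray:
    """Band-limited bipolar (N-shaped) source pulse seen by the detector.

    Time-derivative of a Gaussian, then band-passed over the detector band.
    The Gaussian width is set so the pulse's -20 dB spectral band matches the
    detector band (a derivative-of-Gaussian peaking at f_p has its -20 dB
    upper edge near 2.5 f_p); absolute amplitude is arbitrary.
    """
    fs = config.sampling_rate
    t = (np.arange(n_kernel) - n_kernel // 2) / fs
    f_peak = config.detector_band[1] / 2.5
    sigma_t = 1.0 / (2.0 * np.pi * f_peak)
    pulse = -t / sigma_t**2 * np.exp(-0.5 * (t / sigma_t) ** 2)
    nyq = fs / 2.0
    lo = config.detector_band[0] / nyq
    hi = min(config.detector_band[1] / nyq, 0.99)
    sos = butter(2, [lo, hi], btype="bandpass", output="sos")
    pulse = sosfiltfilt(sos, pulse)
    peak = np.max(np.abs(pulse))
    return pulse / peak if peak > 0 else pulse


def simulate_oa_scan(
    phantom: VesselPhantom,
    config: ScanConfig | None = None,
    motion: MotionProfile | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RawScan:
    """Forward-model a raster scan of the phantom.

    Each absorbing voxel emits the band-limited bipolar pulse with 1/r
    spherical spreading, arriving at the virtual point detector after
    delay r / c; per-B-scan motion displaces the whole object in depth;
    Gaussian noise of ``noise_sd`` is added last.
    """
    config = config or ScanConfig(sound_speed_true=1505.0)
    if abs(phantom.voxel_size - config.scan_step) > 1e-9:
        raise ValueError("phantom voxel size must equal the scan step")
    nx, ny, nz = phantom.absorption_map.shape
    c_um_s = config.sound_speed_true * 1e6  # um per second
    depth_um = nz * phantom.voxel_size
    max_range_um = np.sqrt(
        depth_um**2
        + (nx * phantom.voxel_size) ** 2
        + (ny * phantom.voxel_size) ** 2
    )
    t_record = config.n_time_samples / config.sampling_rate
    if max_range_um / c_um_s > t_record:
        raise ValueError(
            "phantom deeper than the record window: "
            f"max range {max_range_um * 1e-3:.2f} mm exceeds "
            f"c*T = {c_um_s * t_record * 1e-3:.2f} mm"
        )
    if motion is None:
        motion = MotionProfile.zero(ny)
    if motion.shifts.size != ny:
        raise ValueError("motion profile length must equal the B-scan count")

    v = phantom.voxel_size
    src_idx = np.argwhere(phantom.absorption_map > 0)
    weights_amp = phantom.absorption_map[
        src_idx[:, 0], src_idx[:, 1], src_idx[:, 2]
    ]
    ascans = np.zeros((ny, nx, config.n_time_samples), dtype=float)
    if src_idx.size:
        sx = (src_idx[:, 0] + 0.5) * v
        sy = (src_idx[:, 1] + 0.5) * v
        sz = (src_idx[:, 2] + 0.5) * v
        det_x = (np.arange(nx) + 0.5) * v
        fs = config.sampling_rate
        n_t = config.n_time_samples
        for j in range(ny):
            det_y = (j + 0.5) * v
            z_eff = sz + motion.shifts[j]
            lat2 = (sy - det_y) ** 2 + z_eff**2
            dist = np.sqrt((sx[:, None] - det_x[None, :]) ** 2 + lat2[:, None])
            amp = weights_amp[:, None] / np.maximum(dist, v)
            samp = dist / c_um_s * fs
            i0 = np.floor(samp).astype(int)
            frac = samp - i0
            ok = (i0 >= 0) & (i0 < n_t - 1)
            cols = np.broadcast_to(np.arange(nx), dist.shape)
            np.add.at(
                ascans[j], (cols[ok], i0[ok]), (amp * (1.0 - frac))[ok]
            )
            np.add.at(ascans[j], (cols[ok], i0[ok] + 1), (amp * frac)[ok])
        kernel = _oa_pulse_kernel(config)
        ascans = fftconvolve(ascans, kernel[None, None, :], mode="same")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ascans = ascans + rng.normal(0.0, noise_sd, ascans.shape)
    truth = {
        "phantom": phantom,
        "motion": motion,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return RawScan(ascans=ascans, config=config, truth=truth)


def save_rawscan(path: str | Path, raw: RawScan) -> None:
    """Write a RawScan to HDF5 (/ascans, /config attrs, /truth)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("ascans", data=raw.ascans, compression="gzip")
        cfg = fh.create_group("config")
        for k, val in vars(raw.config).items():
            cfg.attrs[k] = val
        tr = fh.create_group("truth")
        motion = raw.truth.get("motion")
        if motion is not None:
            tr.create_dataset("motion_shifts", data=motion.shifts)
        phantom = raw.truth.get("phantom")
        if phantom is not None:
            tr.create_dataset("absorption_map", data=phantom.absorption_map,
                              compression="gzip")
            tr.attrs["voxel_size"] = phantom.voxel_size
            tr.attrs["true_volume_fraction"] = phantom.true_volume_fraction
            tr.attrs["domain_size"] = phantom.domain_size
        tr.attrs["noise_sd"] = raw.truth.get("noise_sd", 0.0)
        tr.attrs["seed"] = raw.truth.get("seed", 0)


def load_rawscan(path: str | Path) -> RawScan:
    with h5py.File(path, "r") as fh:
        ascans = fh["ascans"][...]
        cfg_attrs = dict(fh["config"].attrs)
        cfg_attrs["field_of_view"] = tuple(cfg_attrs["field_of_view"])
        cfg_attrs["detector_band"] = tuple(cfg_attrs["detector_band"])
        config = ScanConfig(**{k: cfg_attrs[k] for k in cfg_attrs})
        truth: dict = {}
        tr = fh["truth"]
        if "motion_shifts" in tr:
            truth["motion"] = MotionProfile(tr["motion_shifts"][...])
        if "absorption_map" in tr:
            amap = tr["absorption_map"][...]
            truth["phantom"] = VesselPhantom(
                absorption_map=amap,
                voxel_size=float(tr.attrs["voxel_size"]),
                centerlines=[],
                true_volume_fraction=float(tr.attrs["true_volume_fraction"]),
                domain_size=tuple(tr.attrs["domain_size"]),
            )
        truth["noise_sd"] = float(tr.attrs.get("noise_sd", 0.0))
        truth["seed"] = int(tr.attrs.get("seed", 0))
    return RawScan(ascans=ascans, config=config, truth=truth)


# ---------------------------------------------------------------------------
# Longitudinal cohorts
# ---------------------------------------------------------------------------

#: Group-mean StO2 trajectories over the measurement days: controls decline
#: monotonically as the tumor outgrows its supply; treated animals show the
#: transient oxygenation rise peaking mid-course before returning to the
#: control trend.
DEFAULT_STO2_TRAJECTORIES = {
    "control": (0.65, 0.58, 0.52, 0.48, 0.46),
    "treated": (0.65, 0.59, 0.70, 0.50, 0.46),
}
DEFAULT_THB_TRAJECTORIES_UM = {
    "control": (60.0, 64.0, 68.0, 71.0, 73.0),
    "treated": (60.0, 61.0, 59.0, 57.0, 55.0),
}


@dataclass
class CohortDesign:
    """Two-group longitudinal study design and its generative parameters.

    Defaults emulate the study conditions: n = 6 per group measured on days
    9/16/23/30/37 of tumor growth; exponential control growth of 20-fold
    over the 28-day window; antiangiogenic growth suppression (rate
    multiplier 1 - suppression) taking effect after a one-week latency,
    sized to a 30-fold endpoint separation; lognormal inter-animal volume
    noise of CV 0.35.
    """

    n_per_group: int = 6
    measurement_days: tuple[int, ...] = (9, 16, 23, 30, 37)
    growth_rate_control: float = float(np.log(20.0) / 28.0)
    treatment_growth_suppression: float = 1.513
    effect_onset_day: float = 16.0
    baseline_volume_mm3: float = 40.0
    sto2_trajectories: dict = field(
        default_factory=lambda: {
            k: tuple(v) for k, v in DEFAULT_STO2_TRAJECTORIES.items()
        }
    )
    thb_trajectories: dict = field(
        default_factory=lambda: {
            k: tuple(v) for k, v in DEFAULT_THB_TRAJECTORIES_UM.items()
        }
    )
    noise_cv: float = 0.35
    sto2_noise_sd: float = 0.05
    thb_noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 animals per group")
        days = np.asarray(self.measurement_days)
        if np.any(np.diff(days) <= 0):
            raise ValueError("measurement days must be strictly increasing")
        if self.noise_cv < 0 or self.sto2_noise_sd < 0 or self.thb_noise_cv < 0:
            raise ValueError("noise levels must be nonnegative")


@dataclass
class LongitudinalDataset:
    """Tidy per-animal measurements plus the generating design and truth."""

    data: pd.DataFrame
    design: CohortDesign
    truth: dict = field(default_factory=dict)


def _median_volume(design: CohortDesign, group: str, day: float) -> float:
    k = design.growth_rate_control
    t0 = design.measurement_days[0]
    if group == "treated":
        onset = max(design.effect_onset_day, t0)
        k_t = k * (1.0 - design.treatment_growth_suppression)
        pre = min(day, onset) - t0
        post = max(0.0, day - onset)
        return design.baseline_volume_mm3 * np.exp(k * pre + k_t * post)
    return design.baseline_volume_mm3 * np.exp(k * (day - t0))


def simulate_cohort(design: CohortDesign | None = None) -> LongitudinalDataset:
    """Generate the two-group longitudinal dataset (volume, StO2, tHb, HbO2, HHb).

    Volumes follow exponential growth with multiplicative lognormal noise
    (the treated group's rate is scaled by 1 - suppression from the onset
    day); StO2 and tHb follow the configured per-group trends with additive
    and multiplicative noise respectively; HbO2/HHb derive from the noisy
    StO2 and tHb.  Deterministic per design.seed.
    """
    design = design or CohortDesign()
    rng = np.random.default_rng(design.seed)
    days = design.measurement_days
    sigma_ln = np.sqrt(np.log(1.0 + design.noise_cv**2))
    rows = []
    for group in ("control", "treated"):
        sto2_traj = np.asarray(design.sto2_trajectories[group], dtype=float)
        thb_traj = np.asarray(design.thb_trajectories[group], dtype=float)
        if sto2_traj.size != len(days) or thb_traj.size != len(days):
            raise ValueError("trajectory length must match measurement days")
        for a in range(design.n_per_group):
            animal = f"{group[0]}{a + 1:02d}"
            for di, day in enumerate(days):
                vol = _median_volume(design, group, day) * np.exp(
                    sigma_ln * rng.standard_normal()
                )
                sto2 = np.clip(
                    sto2_traj[di] + design.sto2_noise_sd * rng.standard_normal(),
                    0.01,
                    0.99,
                )
                thb = thb_traj[di] * max(
                    0.05, 1.0 + design.thb_noise_cv * rng.standard_normal()
                )
                values = {
                    "volume": vol,
                    "sto2": sto2,
                    "thb": thb,
                    "hbo2": sto2 * thb,
                    "hhb": (1.0 - sto2) * thb,
                }
                units = {
                    "volume": "mm3",
                    "sto2": "fraction",
                    "thb": "uM",
                    "hbo2": "uM",
                    "hhb": "uM",
                }
                for var, val in values.items():
                    rows.append(
                        {
                            "animal_id": animal,
                            "group": group,
                            "day": day,
                            "variable": var,
                            "value": float(val),
                            "units": units[var],
                        }
                    )
    truth = {
        "median_volume": {
            g: [_median_volume(design, g, d) for d in days]
            for g in ("control", "treated")
        },
        "sto2_mean": {g: design.sto2_trajectories[g] for g in ("control", "treated")},
        "thb_mean": {g: design.thb_trajectories[g] for g in ("control", "treated")},
    }
    return LongitudinalDataset(pd.DataFrame(rows), design, truth)


# ---------------------------------------------------------------------------
# Hypoxia sections
# ---------------------------------------------------------------------------

@dataclass
class SectionTruth:
    """Ground truth of a generated hypoxia section."""

    positive_mask: NDArray[np.bool_]
    necrosis_mask: NDArray[np.bool_]
    tissue_mask: NDArray[np.bool_]
    intensity_params: tuple[float, float, float, float]
    true_rhf: float


def _blob_mask(
    field_shape: tuple[int, int],
    region: NDArray[np.bool_],
    n_target: int,
    rng: np.random.Generator,
    blob_scale: float,
) -> NDArray[np.bool_]:
    """Connected random blobs covering exactly ``n_target`` pixels of region."""
    if n_target == 0:
        return np.zeros(field_shape, dtype=bool)
    noise = gaussian_filter(rng.standard_normal(field_shape), blob_scale)
    vals = noise[region]
    if n_target > vals.size:
        raise ValueError("requested coverage exceeds the available region")
    cut = np.sort(vals)[-n_target]
    return region & (noise >= cut)


def generate_hypoxia_section(
    shape: tuple[int, int] = (256, 256),
    true_rhf: float = 10.0,
    necrosis_fraction: float = 0.0,
    intensity_params: tuple[float, float, float, float] = (0.2, 0.05, 0.8, 0.05),
    seed: int = 0,
    pixel_size: float = 10.0,
    blob_scale: float = 8.0,
) -> tuple[FluorescenceSection, SectionTruth]:
    """Synthetic stained cryosection with exact positive-area bookkeeping.

    Marker-positive pixels form connected blobs (thresholded smooth random
    field) covering ``true_rhf`` percent of viable tissue; necrosis blobs are
    drawn first and excluded from the viable denominator.
    ``intensity_params`` = (background mean, background SD, positive mean,
    positive SD).
    """
    if not (0.0 <= true_rhf <= 100.0):
        raise ValueError("true_rhf must be in [0, 100]")
    if not (0.0 <= necrosis_fraction < 100.0):
        raise ValueError("necrosis_fraction must be in [0, 100)")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    tissue = (
        ((yy - ny / 2.0) / (0.45 * ny)) ** 2 + ((xx - nx / 2.0) / (0.45 * nx)) ** 2
    ) <= 1.0
    n_necro = int(round(necrosis_fraction / 100.0 * tissue.sum()))
    necrosis = _blob_mask(shape, tissue, n_necro, rng, blob_scale)
    viable = tissue & ~necrosis
    n_pos = int(round(true_rhf / 100.0 * viable.sum()))
    positive = _blob_mask(shape, viable, n_pos, rng, blob_scale)
    rhf_exact = 100.0 * positive.sum() / viable.sum() if viable.sum() else 0.0

    bg_mean, bg_sd, pos_mean, pos_sd = intensity_params
    img = bg_mean + bg_sd * rng.standard_normal(shape)
    img[positive] = pos_mean + pos_sd * rng.standard_normal(int(positive.sum()))
    img[~tissue] = np.abs(0.02 + 0.01 * rng.standard_normal((~tissue).sum()))
    img = np.clip(img, 0.0, None)
    section = FluorescenceSection(
        intensity=img,
        tissue_mask=tissue,
        necrosis_mask=necrosis,
        pixel_size=pixel_size,
    )
    truth = SectionTruth(
        positive_mask=positive,
        necrosis_mask=necrosis,
        tissue_mask=tissue,
        intensity_params=intensity_params,
        true_rhf=float(rhf_exact),
    )
    return section, truth


# ---------------------------------------------------------------------------
# DOS spectra (forward model lives in dosrecon; noise added here)
# ---------------------------------------------------------------------------

def simulate_dos_spectrum(
    params: dosrecon.TissueParams,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelengths: NDArray | None = None,
    distances: tuple[float, ...] = dosrecon.DEFAULT_DISTANCES_MM,
    table: dosrecon.ExtinctionTable | None = None,
) -> dosrecon.ReflectanceSpectra:
    """Model spectra with multiplicative (1 + eps) Gaussian noise."""
    clean = dosrecon.forward_spectra(params, table, wavelengths, distances)
    if noise_sd <= 0:
        return clean
    rng = np.random.default_rng(seed)
    noisy = clean.r * (1.0 + noise_sd * rng.standard_normal(clean.r.shape))
    noisy = np.clip(noisy, 1e-30, None)
    return dosrecon.ReflectanceSpectra(clean.wavelengths, clean.distances, noisy)
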