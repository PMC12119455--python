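"""Synthetic phantom cohorts for the DRG quantitative-MRI pipeline.

Generates, per subject, a 3D ground-truth scene (four ellipsoidal DRGs at
levels L5/S1 x sides L/R, a tubular CSF reference, background tissue, and a
smooth B1 field), simulates the multi-echo spin-echo acquisition through the
EPG-CPMG forward model with Rician magnitude noise, and perturbs masks to
emulate independent raters.  Cohorts reproduce the study's group structure —
28 healthy controls (HC), 12 NF1 without pain (NF1n), 8 NF1 with pain
(NF1p) — with per-group feature distributions calibrated to the published
group medians and interquartile ranges.

Calibration model
-----------------
Each subject's feature (volume, T2, PD) on the mean-of-L5/S1 scale is drawn
log-normal with ``exp(mu)`` equal to the target group median — the log-normal
median is preserved under exponentiation, so the calibrated quantity is exact
in the degenerate (sigma -> 0) limit — and sigma solved from the target IQR
via ``sigma = asinh(IQR / (2 median)) / z_75``.  The subject value is split
into L5/S1 by fixed level factors derived from the published per-level
medians (so the level contrast is reproduced), and into left/right by a
symmetric arithmetic jitter that leaves the level mean unchanged.  Volume
draws are truncated symmetrically in log-space to what the phantom grid can
hold; symmetric truncation leaves the median untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .epg import epg_cpmg_batch
from .features import LEVELS, LabelInfo, RoiMask
from .relaxometry import MultiEchoSeries

__all__ = [
    "AcquisitionProtocol",
    "GroundTruthScene",
    "SubjectSpec",
    "GroupParams",
    "FeatureParams",
    "CohortConfig",
    "sigma_from_iqr",
    "default_cohort_config",
    "sample_cohort",
    "make_scene",
    "simulate_multiecho",
    "make_rater_masks",
    "DRG_LABELS",
    "CSF_LABEL",
    "TISSUE_LABEL",
]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal

# label layout of generated scenes
DRG_LABELS = {("L5", "L"): 1, ("L5", "R"): 2, ("S1", "L"): 3, ("S1", "R"): 4}
CSF_LABEL = 5
TISSUE_LABEL = 6

# fixed compartment constants (ms / a.u.); see the methods note
CSF_T2 = 2000.0
CSF_T1 = 4000.0
TISSUE_T1 = 1000.0
TISSUE_T2 = 70.0
TISSUE_M0 = 0.7
CSF_M0 = 1.0


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-echo spin-echo protocol: echo train length, echo spacing (ms),
    repetition time (ms), voxel spacing (mm) and grid size.  Echo time of
    echo k (1-based) is ``k * delta_te``."""

    n_echoes: int = 10
    delta_te: float = 15.0
    tr: float = 4800.0
    voxel_spacing: Tuple[float, float, float] = (1.5, 1.5, 1.8)
    grid_shape: Tuple[int, int, int] = (64, 64, 16)

    def __post_init__(self):
        if self.n_echoes < 2:
            raise ValueError("n_echoes must be >= 2")
        if self.delta_te <= 0:
            raise ValueError("delta_te must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must be positive")

    @property
    def echo_times(self) -> Tuple[float, ...]:
        return tuple(self.delta_te * k for k in range(1, self.n_echoes + 1))

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.voxel_spacing
        return sx * sy * sz


@dataclass
class GroundTruthScene:
    """Voxel-wise ground truth: T2/T1 (ms), M0 (a.u.), B1 (dimensionless)
    maps plus the labelled truth mask."""

    t2_map: np.ndarray
    m0_map: np.ndarray
    t1_map: np.ndarray
    b1_map: np.ndarray
    mask: RoiMask
    spec: "SubjectSpec"
    protocol: AcquisitionProtocol


@dataclass(frozen=True)
class SubjectSpec:
    """Ground-truth feature values for one subject.

    ``drg_volume``/``drg_t2``/``drg_pd`` map (level, side) to the per-DRG
    truth; PD is the M0 ratio against CSF, so the scene assigns
    ``m0_DRG = pd * m0_CSF``.
    """

    subject_id: str
    group: str  # HC, NF1n or NF1p
    sex: str  # F or M
    age: float
    height: float  # cm
    weight: float  # kg
    drg_volume: Dict[Tuple[str, str], float]  # mm^3
    drg_t2: Dict[Tuple[str, str], float]  # ms
    drg_pd: Dict[Tuple[str, str], float]  # a.u.
    noise_sigma: float
    seed: int

    def __post_init__(self):
        # "NF1" is the pooled patient group (used when the pain split is
        # not part of the question)
        if self.group not in ("HC", "NF1", "NF1n", "NF1p"):
            raise ValueError(f"unknown group {self.group!r}")
        if any(v <= 0 for v in self.drg_volume.values()):
            raise ValueError("DRG volumes must be positive")
        if any(not (0 < p <= 1.5) for p in self.drg_pd.values()):
            raise ValueError("PD must lie in (0, 1.5]")


@dataclass(frozen=True)
class FeatureParams:
    """Log-normal parameters for one feature on the mean-of-levels scale."""

    median: float  # exp(mu)
    sigma: float  # log-scale SD
    level_factors: Tuple[float, float] = (1.0, 1.0)  # (L5, S1), mean 1

    def __post_init__(self):
        if self.median <= 0:
            raise ValueError("median must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class GroupParams:
    n: int
    volume: FeatureParams
    t2: FeatureParams
    pd: FeatureParams
    n_female: int
    age_median: float
    age_iqr: float
    height_median: float
    height_iqr: float
    weight_median: float
    weight_iqr: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to draw a reproducible cohort."""

    groups: Dict[str, GroupParams]
    seed: int = 0
    noise_sigma: float = 0.01  # a.u., per channel, relative to CSF M0 = 1
    side_jitter: float = 0.03  # SD of the symmetric left/right split
    volume_bounds: Tuple[float, float] = (120.0, 4800.0)  # mean-of-levels, mm^3
    b1_range: Tuple[float, float] = (0.8, 1.1)

    def scaled(self, factor: float) -> "CohortConfig":
        """Copy with every feature sigma (and the side jitter) multiplied by
        ``factor``; factor 0 gives the degenerate, median-exact cohort."""
        groups = {
            name: replace(
                g,
                volume=replace(g.volume, sigma=g.volume.sigma * factor),
                t2=replace(g.t2, sigma=g.t2.sigma * factor),
                pd=replace(g.pd, sigma=g.pd.sigma * factor),
            )
            for name, g in self.groups.items()
        }
        return replace(self, groups=groups, side_jitter=self.side_jitter * factor)


def sigma_from_iqr(median: float, iqr: float) -> float:
    """Log-normal sigma whose distribution has the given median and IQR.

    For LogNormal(mu, sigma): IQR = exp(mu) * 2 sinh(z75 * sigma), so
    ``sigma = asinh(IQR / (2 median)) / z75``.
    """
    if median <= 0 or iqr < 0:
        raise ValueError("median must be positive and IQR non-negative")
    return math.asinh(iqr / (2.0 * median)) / _Z75


def _level_factors(m_l5: float, m_s1: float) -> Tuple[float, float]:
    s = m_l5 + m_s1
    return (2.0 * m_l5 / s, 2.0 * m_s1 / s)


def _fp(median, iqr, m_l5, m_s1) -> FeatureParams:
    return FeatureParams(median=median, sigma=sigma_from_iqr(median, iqr),
                         level_factors=_level_factors(m_l5, m_s1))


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The published cohort: 28 HC / 12 NF1n / 8 NF1p with per-group feature
    distributions calibrated to the reported medians and IQRs (mean-of-levels
    rows; level factors from the per-level medians)."""
    groups = {
        "HC": GroupParams(
            n=28,
            volume=_fp(628.4, 243.1, 456.4, 777.1),
            t2=_fp(96.2, 16.6, 95.4, 93.5),
            pd=_fp(0.833, 0.103, 0.824, 0.836),
            n_female=14, age_median=40.5, age_iqr=26.5,
            height_median=174.0, height_iqr=5.5,
            weight_median=71.5, weight_iqr=19.0,
        ),
        "NF1n": GroupParams(
            n=12,
            volume=_fp(1557.9, 936.8, 1345.7, 1842.9),
            t2=_fp(110.3, 25.2, 105.3, 104.9),
            pd=_fp(0.859, 0.102, 0.883, 0.843),
            n_female=6, age_median=31.0, age_iqr=10.5,
            height_median=170.0, height_iqr=5.8,
            weight_median=67.5, weight_iqr=12.8,
        ),
        "NF1p": GroupParams(
            n=8,
            volume=_fp(2894.9, 4411.1, 1869.2, 3884.1),
            t2=_fp(125.7, 20.8, 111.9, 136.6),
            pd=_fp(0.932, 0.037, 0.879, 0.985),
            n_female=3, age_median=33.0, age_iqr=24.8,
            height_median=175.5, height_iqr=11.5,
            weight_median=72.5, weight_iqr=19.8,
        ),
    }
    return CohortConfig(groups=groups, seed=seed)


def _draw_lognormal(rng, median, sigma, log_bound: Optional[float] = None) -> float:
    """One log-normal draw; optional symmetric truncation of the log deviate
    (preserves the median)."""
    z = rng.standard_normal()
    d = sigma * z
    if log_bound is not None and sigma > 0:
        while abs(d) > log_bound:
            d = sigma * rng.standard_normal()
    return median * math.exp(d)


def sample_cohort(config: CohortConfig) -> List[SubjectSpec]:
    """Draw the full cohort deterministically from the master seed."""
    specs: List[SubjectSpec] = []
    ss = np.random.SeedSequence(config.seed)
    v_lo, v_hi = config.volume_bounds
    counter = 0
    for group, gp in config.groups.items():
        children = ss.spawn(gp.n + 1)  # one spare stream per group
        for i in range(gp.n):
            rng = np.random.default_rng(children[i])
            counter += 1
            sid = f"{group}{i + 1:02d}"
            sex = "F" if i < gp.n_female else "M"
            age = max(18.0, gp.age_median + gp.age_iqr / (2 * _Z75) * rng.standard_normal())
            height = gp.height_median + gp.height_iqr / (2 * _Z75) * rng.standard_normal()
            weight = max(40.0, gp.weight_median + gp.weight_iqr / (2 * _Z75) * rng.standard_normal())

            log_bound = None
            if gp.volume.sigma > 0:
                if not (v_lo < gp.volume.median < v_hi):
                    raise ValueError("volume_bounds must bracket the group median")
                log_bound = min(math.log(v_hi / gp.volume.median),
                                math.log(gp.volume.median / v_lo))
            vol_m = _draw_lognormal(rng, gp.volume.median, gp.volume.sigma, log_bound)
            t2_m = _draw_lognormal(rng, gp.t2.median, gp.t2.sigma)
            pd_m = min(1.5, _draw_lognormal(rng, gp.pd.median, gp.pd.sigma))

            vols: Dict[Tuple[str, str], float] = {}
            t2s: Dict[Tuple[str, str], float] = {}
            pds: Dict[Tuple[str, str], float] = {}
            for mean_val, factors, store, clip_hi in (
                (vol_m, gp.volume.level_factors, vols, None),
                (t2_m, gp.t2.level_factors, t2s, None),
                (pd_m, gp.pd.level_factors, pds, 1.5),
            ):
                for level, f in zip(LEVELS, factors):
                    v = mean_val * f
                    eps = np.clip(config.side_jitter * rng.standard_normal(), -0.2, 0.2)
                    left, right = v * (1 + eps), v * (1 - eps)
                    if clip_hi is not None:
                        left, right = min(left, clip_hi), min(right, clip_hi)
                    store[(level, "L")] = left
                    store[(level, "R")] = right

            subj_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
            specs.append(SubjectSpec(
                subject_id=sid, group=group, sex=sex, age=float(age),
                height=float(height), weight=float(weight),
                drg_volume=vols, drg_t2=t2s, drg_pd=pds,
                noise_sigma=config.noise_sigma, seed=subj_seed))
    return specs


def _voxelize_ellipsoid(grid_shape, spacing, center_mm, semi_axes_mm, n_target):
    """The ``n_target`` voxels closest to the centre in the ellipsoidal norm.

    This makes the voxelised volume ``n_target * voxel_volume``, i.e. within
    half a voxel volume of any requested volume, and yields a connected,
    ellipsoid-shaped blob.  Deterministic (stable sort, ties by index).
    """
    nx, ny, nz = grid_shape
    sx, sy, sz = spacing
    # bounding box in voxel units, padded by one voxel
    ext = [semi_axes_mm[i] / spacing[i] + 1.5 for i in range(3)]
    c_vox = [center_mm[i] / spacing[i] for i in range(3)]
    lo = [max(0, int(math.floor(c_vox[i] - ext[i]))) for i in range(3)]
    hi = [min(grid_shape[i], int(math.ceil(c_vox[i] + ext[i])) + 1) for i in range(3)]
    xs = (np.arange(lo[0], hi[0]) + 0.5) * sx
    ys = (np.arange(lo[1], hi[1]) + 0.5) * sy
    zs = (np.arange(lo[2], hi[2]) + 0.5) * sz
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    r2 = (((gx - center_mm[0]) / semi_axes_mm[0]) ** 2
          + ((gy - center_mm[1]) / semi_axes_mm[1]) ** 2
          + ((gz - center_mm[2]) / semi_axes_mm[2]) ** 2)
    flat = r2.ravel()
    if n_target > flat.size:
        raise ValueError("requested volume does not fit inside the grid window")
    order = np.argsort(flat, kind="stable")[:n_target]
    sel = np.zeros(flat.shape, dtype=bool).reshape(r2.shape)
    sel.ravel()[order] = True
    mask = np.zeros(grid_shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sel
    return mask


def make_scene(spec: SubjectSpec, protocol: AcquisitionProtocol,
               b1_range: Tuple[float, float] = (0.8, 1.1),
               rng: Optional[np.random.Generator] = None,
               max_retries: int = 10) -> GroundTruthScene:
    """Build the ground-truth scene for one subject.

    Four ellipsoidal DRGs are placed in the four in-plane quadrants (levels
    along y, sides along x) around the central slice, with random axis ratio
    in [1, 2.5] and small positional jitter; a CSF tube runs along y through
    the grid centre so it intersects the slices of every DRG.  M0 is assigned
    so that ``m0_DRG / m0_CSF`` equals the spec PD exactly; B1 is a smooth
    quadratic field rescaled into ``b1_range``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    nx, ny, nz = protocol.grid_shape
    sx, sy, sz = protocol.voxel_spacing
    vv = protocol.voxel_volume
    for key, vol in spec.drg_volume.items():
        if vol < 8 * vv:
            raise ValueError(
                f"requested DRG volume {vol:.1f} mm^3 for {key} is below the "
                f"minimum of 8 voxel volumes ({8 * vv:.1f} mm^3) at this spacing")

    fov = (nx * sx, ny * sy, nz * sz)
    z_c = fov[2] / 2.0
    csf_radius_mm = 3.0

    labels = np.zeros(protocol.grid_shape, dtype=np.int16)
    # CSF tube along y at the grid centre (x), central slice (z)
    xs = (np.arange(nx) + 0.5) * sx
    zs = (np.arange(nz) + 0.5) * sz
    gx, gz = np.meshgrid(xs, zs, indexing="ij")
    tube = ((gx - fov[0] / 2) ** 2 + (gz - z_c) ** 2) <= csf_radius_mm ** 2
    csf = np.repeat(tube[:, None, :], ny, axis=1)
    labels[csf] = CSF_LABEL

    quadrant = {
        ("L5", "L"): (0.28, 0.28), ("L5", "R"): (0.72, 0.28),
        ("S1", "L"): (0.28, 0.72), ("S1", "R"): (0.72, 0.72),
    }
    z_half_max = (nz * sz) / 2.0 - sz
    for key in DRG_LABELS:
        vol = spec.drg_volume[key]
        n_target = int(round(vol / vv))
        placed = False
        for attempt in range(max_retries):
            ratio = rng.uniform(1.0, 2.5)
            # long axis along y; z semi-axis capped to the slab
            c = (3.0 * vol / (4.0 * math.pi * ratio)) ** (1.0 / 3.0)
            az = min(c, z_half_max)
            ax = math.sqrt(3.0 * vol / (4.0 * math.pi * az * ratio))
            ay = ratio * ax
            fx, fy = quadrant[key]
            jitter = rng.uniform(-2.0, 2.0, size=2) * (1.0 - attempt / max_retries)
            center = (fx * fov[0] + jitter[0] * sx,
                      fy * fov[1] + jitter[1] * sy, z_c)
            try:
                m = _voxelize_ellipsoid(protocol.grid_shape, protocol.voxel_spacing,
                                        center, (ax, ay, az), n_target)
            except ValueError:
                continue
            if not (m & (labels > 0)).any():
                labels[m] = DRG_LABELS[key]
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place DRG {key} (volume {vol:.0f} mm^3) without "
                f"overlap after {max_retries} attempts; use a larger grid")

    labels[labels == 0] = TISSUE_LABEL
    label_table = {lab: LabelInfo("DRG", level=lv, side=sd)
                   for (lv, sd), lab in DRG_LABELS.items()}
    label_table[CSF_LABEL] = LabelInfo("CSF")
    label_table[TISSUE_LABEL] = LabelInfo("tissue")
    mask = RoiMask(labels=labels, spacing=protocol.voxel_spacing,
                   label_table=label_table)

    t2 = np.full(protocol.grid_shape, TISSUE_T2)
    t1 = np.full(protocol.grid_shape, TISSUE_T1)
    m0 = np.full(protocol.grid_shape, TISSUE_M0)
    t2[labels == CSF_LABEL] = CSF_T2
    t1[labels == CSF_LABEL] = CSF_T1
    m0[labels == CSF_LABEL] = CSF_M0
    for key, lab in DRG_LABELS.items():
        t2[labels == lab] = spec.drg_t2[key]
        m0[labels == lab] = spec.drg_pd[key] * CSF_M0

    # smooth quadratic B1 field rescaled exactly into b1_range
    xn = np.linspace(-1, 1, nx)[:, None, None]
    yn = np.linspace(-1, 1, ny)[None, :, None]
    zn = np.linspace(-1, 1, nz)[None, None, :]
    coef = rng.uniform(-1, 1, size=6)
    b1 = (coef[0] * xn + coef[1] * yn + coef[2] * zn
          + coef[3] * xn * xn + coef[4] * yn * yn + coef[5] * xn * yn)
    lo, hi = b1_range
    bmin, bmax = b1.min(), b1.max()
    if bmax - bmin < 1e-12:
        b1 = np.full(protocol.grid_shape, (lo + hi) / 2.0)
    else:
        b1 = lo + (b1 - bmin) * (hi - lo) / (bmax - bmin)

    return GroundTruthScene(t2_map=t2, m0_map=m0, t1_map=t1, b1_map=b1,
                            mask=mask, spec=spec, protocol=protocol)


def simulate_multiecho(scene: GroundTruthScene, protocol: AcquisitionProtocol,
                       noise_sigma: float, seed: Optional[int] = None) -> MultiEchoSeries:
    """Simulate the multi-echo acquisition of a scene.

    Noise-free echo trains come from the EPG-CPMG forward model at each
    voxel's (T2, T1, M0, B1); Rician noise is then applied per echo:
    ``out = |signal + n1 + i n2|`` with independent Gaussian channels of SD
    ``noise_sigma``.  With ``noise_sigma = 0`` the output is the exact
    noise-free series (no RNG consumed), and for a fixed seed the noisy
    series is bit-reproducible.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if scene.t2_map.shape != protocol.grid_shape:
        raise ValueError("scene grid does not match protocol grid")
    shape = protocol.grid_shape
    echoes = epg_cpmg_batch(scene.t2_map.ravel(), scene.t1_map.ravel(),
                            scene.b1_map.ravel(), protocol.n_echoes,
                            protocol.delta_te)
    signal = (echoes * scene.m0_map.ravel()[None, :]).T.reshape(
        shape + (protocol.n_echoes,))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, noise_sigma, signal.shape)
        n2 = rng.normal(0.0, noise_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
    return MultiEchoSeries(data=signal, echo_times=protocol.echo_times,
                           voxel_spacing=protocol.voxel_spacing)


def make_rater_masks(mask: RoiMask, n_raters: int = 2, perturbation: float = 0.1,
                     seed: Optional[int] = None) -> List[RoiMask]:
    """Emulate independent raters by toggling boundary voxels of each DRG.

    Each rater's mask is the truth with boundary voxels (the inner surface
    and the free outer shell) independently toggled with probability
    ``perturbation``; the largest connected component is kept so every rater
    mask stays connected and non-empty.  Rater 1 with perturbation 0 equals
    the truth exactly.
    """
    if n_raters < 2:
        raise ValueError("n_raters must be >= 2")
    if not (0 <= perturbation < 1):
        raise ValueError("perturbation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    struct = ndimage.generate_binary_structure(3, 1)
    out: List[RoiMask] = []
    free = (mask.labels == 0) | (mask.labels == TISSUE_LABEL)
    for r in range(n_raters):
        labels = mask.labels.copy()
        for lab in mask.drg_labels():
            sel = mask.labels == lab
            if perturbation > 0:
                inner = sel & ~ndimage.binary_erosion(sel, structure=struct)
                outer = ndimage.binary_dilation(sel, structure=struct) & free
                toggled = sel.copy()
                toggled[inner & (rng.random(labels.shape) < perturbation)] = False
                toggled[outer & (rng.random(labels.shape) < perturbation)] = True
                cc, n_cc = ndimage.label(toggled, structure=struct)
                if n_cc > 1:
                    sizes = ndimage.sum_labels(np.ones_like(cc), cc, range(1, n_cc + 1))
                    toggled = cc == (1 + int(np.argmax(sizes)))
                if not toggled.any():
                    toggled = sel
                labels[sel & ~toggled] = TISSUE_LABEL
                labels[toggled & ~sel & free] = lab
        table = {lab: LabelInfo(info.structure, info.level, info.side,
                                rater_id=f"rater{r + 1}")
                 for lab, info in mask.label_table.items()}
        out.append(RoiMask(labels=labels, spacing=mask.spacing, label_table=table))
    return out
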