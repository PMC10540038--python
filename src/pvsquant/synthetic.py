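"""Synthetic phantoms and cohorts with known ground truth.

Two families of generators:

* **Image phantoms** — T2-like volumes containing bright tubular PVS of
  known geometry inside a white-matter "brain" ellipsoid, optionally with a
  CSF-bright ventricle, WMH blobs, a smooth multiplicative bias field, and
  Rician noise. The exact voxelized PVS mask and tissue labels are returned
  as ground truth, so segmentation accuracy can be scored without any real
  data.
* **Longitudinal cohorts** — two-arm, two-timepoint tables with participant
  and site random intercepts, a group-by-time effect on the PVS volume
  fraction (percentage points over the follow-up interval), demographic and
  imaging covariates, per-class antihypertensive exposure fractions, and
  achieved systolic blood pressure.

All generators are pure functions of (spec, seed). Phantom tubes are
voxelized by center-inclusion: a voxel belongs to a tube iff its center
lies within the tube radius of the axis segment, which makes the analytic
cylinder volume an oracle for the voxel count.

The generators do not attempt realistic MR physics (no k-space, no partial
volume beyond voxelization) — they exercise the pipeline's contracts, not
scanner behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError
from .measures import MED_CLASSES, SBPSeries
from .volume import LabelVolume, RoiMask, TISSUE_CODES, Volume


# ---------------------------------------------------------------------------
# Scene primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tube:
    """Capsule: all points within radius_mm of the segment a-b (mm coords)."""

    a: tuple[float, float, float]
    b: tuple[float, float, float]
    radius_mm: float
    intensity: float = 160.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ParameterError("tube radius must be > 0")
        if self.intensity < 0:
            raise ParameterError("tube intensity must be >= 0")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.b, self.a)))

    @property
    def analytic_volume_mm3(self) -> float:
        """Cylinder part only (pi r^2 L); end caps are not counted."""
        return float(np.pi * self.radius_mm ** 2 * self.length_mm)


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]


@dataclass
class PhantomSpec:
    """Scene description for a T2-like PVS phantom."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tubes: list[Tube] = field(default_factory=list)
    brain: Ellipsoid | None = None          # default: centered, 90% extent
    ventricle: Ellipsoid | None = None
    wmh_blobs: list[tuple[tuple[float, float, float], float]] = field(
        default_factory=list)
    # T2-like intensity levels on a raw-scanner-like scale; white matter is
    # wrapped in a gray-matter shell so the analysis-region boundary has
    # tissue-tissue (not tissue-air) contrast, as in a real brain
    tissue_intensity: float = 1000.0
    gm_intensity: float = 1150.0
    csf_intensity: float = 2000.0
    wmh_intensity: float = 1500.0
    pvs_intensity: float = 2000.0           # PVS are CSF-filled: CSF-bright
    wm_shell_fraction: float = 0.88         # WM ellipsoid / brain ellipsoid
    bias_field: np.ndarray | None = None    # 10 polynomial coefficients
    noise_sigma: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if min(self.tissue_intensity, self.csf_intensity,
               self.wmh_intensity) < 0:
            raise ParameterError("intensities must be >= 0")


@dataclass
class GroundTruth:
    """Exact masks and volumes of a generated phantom."""

    pvs_mask: RoiMask
    tissue_labels: LabelVolume
    roi_mask: RoiMask
    per_tube_volume_mm3: np.ndarray
    total_pvs_volume_mm3: float


def _voxel_centers_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return axes


def _ellipsoid_mask(shape, spacing, ell: Ellipsoid) -> np.ndarray:
    ax = _voxel_centers_mm(shape, spacing)
    g = np.meshgrid(*ax, indexing="ij", sparse=True)
    q = sum(((gi - c) / a) ** 2
            for gi, c, a in zip(g, ell.center, ell.semi_axes))
    return q <= 1.0


def _tube_mask(shape, spacing, tube: Tube) -> np.ndarray:
    """Center-inclusion voxelization of a capsule, on a bounding sub-box."""
    a = np.asarray(tube.a, dtype=float)
    b = np.asarray(tube.b, dtype=float)
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    for p in (a, b):
        if np.any(p - tube.radius_mm < 0) or np.any(
                p + tube.radius_mm > np.asarray(extent)):
            raise GeometryError(f"tube {tube} extends outside the grid")
    lo = np.minimum(a, b) - tube.radius_mm
    hi = np.maximum(a, b) + tube.radius_mm
    i_lo = [max(0, int(np.floor(l / s))) for l, s in zip(lo, spacing)]
    i_hi = [min(n - 1, int(np.ceil(h / s))) for h, n, s
            in zip(hi, shape, spacing)]
    sub = [np.arange(il, ih + 1) * s
           for il, ih, s in zip(i_lo, i_hi, spacing)]
    g = np.meshgrid(*sub, indexing="ij")
    p = np.stack(g, axis=-1)                       # (..., 3) voxel centers
    d = b - a
    dd = float(d @ d)
    if dd == 0:
        dist = np.linalg.norm(p - a, axis=-1)
    else:
        t = np.clip(((p - a) @ d) / dd, 0.0, 1.0)
        closest = a + t[..., None] * d
        dist = np.linalg.norm(p - closest, axis=-1)
    mask = np.zeros(shape, dtype=bool)
    mask[i_lo[0]:i_hi[0] + 1, i_lo[1]:i_hi[1] + 1,
         i_lo[2]:i_hi[2] + 1] = dist <= tube.radius_mm + 1e-12
    return mask


def _polynomial_bias(shape, spacing, coeffs: np.ndarray) -> np.ndarray:
    """Low-order polynomial field in normalized [-1, 1] coordinates.

    Terms: 1, x, y, z, x^2, y^2, z^2, xy, xz, yz.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (10,):
        raise ParameterError("bias_field needs 10 polynomial coefficients")
    ax = [np.linspace(-1, 1, n) for n in shape]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    terms = [np.ones(shape), x, y, z, x * x, y * y, z * z,
             x * y, x * z, y * z]
    return sum(c * t for c, t in zip(coeffs, terms))


def add_rician_noise(vol: Volume, sigma: float, seed: int) -> Volume:
    """Replace each voxel x by sqrt((x + n1)^2 + n2^2), n1, n2 ~ N(0, sigma).

    This is the magnitude-MRI noise model the non-local-means denoiser
    assumes; for x = 0 the output is Rayleigh with mean sigma * sqrt(pi/2).
    """
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if sigma == 0:
        return Volume(vol.data.copy(), affine=vol.affine)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, vol.shape)
    n2 = rng.normal(0.0, sigma, vol.shape)
    out = np.sqrt((vol.data + n1) ** 2 + n2 ** 2)
    return Volume(out.astype(np.float32), affine=vol.affine)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Render a phantom and its exact ground truth.

    Deterministic given spec.seed. Tissue labels: white matter fills the
    brain ellipsoid; ventricle voxels are labeled ventricle; WMH blobs are
    labeled wmh. PVS tubes remain white matter in the label map (they are
    sub-voxel anatomy, not a tissue class) and are returned as pvs_mask.
    """
    shape, spacing = tuple(spec.shape), tuple(spec.spacing)
    brain = spec.brain or Ellipsoid(
        center=tuple(0.5 * (n - 1) * s for n, s in zip(shape, spacing)),
        semi_axes=tuple(0.45 * (n - 1) * s for n, s in zip(shape, spacing)),
    )
    labels = np.zeros(shape, dtype=np.int16)
    brain_mask = _ellipsoid_mask(shape, spacing, brain)
    wm_ell = Ellipsoid(brain.center,
                       tuple(spec.wm_shell_fraction * a
                             for a in brain.semi_axes))
    wm_mask = _ellipsoid_mask(shape, spacing, wm_ell)
    labels[brain_mask] = TISSUE_CODES["gray_matter"]
    labels[wm_mask & brain_mask] = TISSUE_CODES["white_matter"]
    if spec.ventricle is not None:
        vent = _ellipsoid_mask(shape, spacing, spec.ventricle) & brain_mask
        labels[vent] = TISSUE_CODES["ventricle"]
    for center, radius in spec.wmh_blobs:
        blob = _ellipsoid_mask(shape, spacing,
                               Ellipsoid(center, (radius,) * 3))
        labels[blob & (labels == TISSUE_CODES["white_matter"])] = \
            TISSUE_CODES["wmh"]

    img = np.zeros(shape, dtype=np.float64)
    img[labels == TISSUE_CODES["gray_matter"]] = spec.gm_intensity
    img[labels == TISSUE_CODES["white_matter"]] = spec.tissue_intensity
    img[labels == TISSUE_CODES["wmh"]] = spec.wmh_intensity
    img[labels == TISSUE_CODES["ventricle"]] = spec.csf_intensity

    pvs = np.zeros(shape, dtype=bool)
    per_tube = np.zeros(len(spec.tubes), dtype=float)
    voxvol = float(np.prod(spacing))
    wm = labels == TISSUE_CODES["white_matter"]
    for k, tube in enumerate(spec.tubes):
        m = _tube_mask(shape, spacing, tube) & wm
        per_tube[k] = m.sum() * voxvol
        img[m] = tube.intensity
        pvs |= m

    if spec.bias_field is not None:
        img *= _polynomial_bias(shape, spacing, spec.bias_field)

    aff = np.diag(list(spacing) + [1.0])
    vol = Volume(img.astype(np.float32), affine=aff)
    if spec.noise_sigma > 0:
        vol = add_rician_noise(vol, spec.noise_sigma, spec.seed)

    lab = LabelVolume(labels, affine=aff)
    truth = GroundTruth(
        pvs_mask=RoiMask(pvs, affine=aff),
        tissue_labels=lab,
        roi_mask=lab.mask_for("white_matter", "basal_ganglia"),
        per_tube_volume_mm3=per_tube,
        total_pvs_volume_mm3=float(pvs.sum() * voxvol),
    )
    return vol, truth


def random_tubes(n: int, spec: PhantomSpec, rng: np.random.Generator,
                 radius_mm: tuple[float, float] = (0.6, 1.2),
                 length_mm: tuple[float, float] = (8.0, 24.0),
                 intensity: float | None = None) -> list[Tube]:
    """Draw n tubes with random orientation inside the white-matter ellipsoid."""
    shape, spacing = spec.shape, spec.spacing
    brain = spec.brain or Ellipsoid(
        center=tuple(0.5 * (n_ - 1) * s for n_, s in zip(shape, spacing)),
        semi_axes=tuple(0.45 * (n_ - 1) * s for n_, s in zip(shape, spacing)),
    )
    if intensity is None:
        intensity = spec.pvs_intensity
    c = np.asarray(brain.center)
    sa = spec.wm_shell_fraction * np.asarray(brain.semi_axes)
    tubes: list[Tube] = []
    while len(tubes) < n:
        r = rng.uniform(*radius_mm)
        L = rng.uniform(*length_mm)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        mid = c + rng.uniform(-0.55, 0.55, size=3) * sa
        a = mid - 0.5 * L * u
        b = mid + 0.5 * L * u
        # both endpoints (with radius margin) inside the brain ellipsoid
        ok = all(np.sum(((p - c) / (sa - r)) ** 2) <= 1.0
                 for p in (a, b) if np.all(sa - r > 0))
        if ok:
            tubes.append(Tube(tuple(a), tuple(b), r, intensity))
    return tubes


# ---------------------------------------------------------------------------
# Longitudinal cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """True data-generating process for a two-arm, two-timepoint cohort.

    Fixed effects are in percentage points of PVS volume fraction; covariate
    contributions are centered at their population means so ``intercept`` is
    the population baseline mean. ``group_time`` is the headline
    group-by-time interaction over the whole follow-up interval.
    """

    n_per_arm: int = 200
    n_sites: int = 7
    followup_years: float = 3.9
    intercept: float = 1.23
    time: float = 0.0017
    group: float = -0.0021
    group_time: float = -0.029
    coef_age: float = 0.004
    coef_male: float = 0.081
    coef_black: float = -0.065
    coef_cvd: float = 0.067
    coef_ckd: float = -0.021
    coef_baseline_sbp: float = 0.00025
    coef_logwmh: float = -1.05
    sd_participant: float = 0.25
    sd_site: float = 0.05
    sd_residual: float = 0.08
    # achieved-SBP model: per-arm (mean, between-participant SD), visit SD
    sbp_intensive: tuple[float, float] = (120.0, 8.0)
    sbp_standard: tuple[float, float] = (136.0, 7.0)
    sbp_visit_sd: float = 9.0
    # per-class Beta(a, b) exposure distributions and optional class-by-time
    # effects (percentage points at full exposure)
    med_beta: dict = field(default_factory=lambda: {
        "acei_arb": (3.0, 1.3), "beta_blocker": (1.2, 2.2),
        "ccb": (1.6, 2.4), "diuretic": (2.4, 1.6)})
    med_time_effects: dict = field(default_factory=lambda: {
        c: 0.0 for c in MED_CLASSES})
    # nuisance covariate margins (cohort-like defaults)
    mean_age: float = 68.0
    sd_age: float = 8.0
    p_male: float = 0.6
    p_black: float = 0.32
    p_cvd: float = 0.20
    p_ckd: float = 0.28
    mean_baseline_sbp: float = 138.0
    sd_baseline_sbp: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ParameterError("n_per_arm must be >= 2")
        if min(self.sd_participant, self.sd_site, self.sd_residual) < 0:
            raise ParameterError("random-effect SDs must be >= 0")
        if self.n_sites < 1:
            raise ParameterError("need at least one site")


def simulate_sbp_series(arm: int, n_visits: int, followup_days: float,
                        spec: CohortSpec, seed: int) -> SBPSeries:
    """Simulate a per-participant SBP series around the arm target."""
    if n_visits < 2:
        raise ParameterError("need >= 2 visits")
    if followup_days <= 0:
        raise ParameterError("followup_days must be > 0")
    rng = np.random.default_rng(seed)
    mean, between_sd = (spec.sbp_intensive if arm == 1 else spec.sbp_standard)
    target = mean + rng.normal(0.0, between_sd) if between_sd > 0 else mean
    days = np.linspace(0.0, followup_days, n_visits)
    vals = target + (rng.normal(0.0, spec.sbp_visit_sd, n_visits)
                     if spec.sbp_visit_sd > 0 else 0.0)
    return SBPSeries(days=days, sbp=np.maximum(vals, 1.0))


def simulate_visual_ratings(true_fractions, noise_sd: float, seed: int,
                            fraction_at_max: float = 2.5) -> np.ndarray:
    """Map volume fractions (%) to ordinal 0-8 visual PVS scores.

    A monotone latent score 8 * f / fraction_at_max gets Gaussian rater
    noise, is rounded and clipped to [0, 8] (basal ganglia/insula 0-4 plus
    centrum semiovale 0-4 in the visual scale this emulates).
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    f = np.asarray(true_fractions, dtype=float)
    if np.any(f < 0):
        raise ParameterError("fractions must be >= 0")
    latent = 8.0 * f / fraction_at_max
    if noise_sd > 0:
        latent = latent + np.random.default_rng(seed).normal(
            0.0, noise_sd, f.shape)
    return np.clip(np.rint(latent), 0, 8).astype(int)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a long-format two-timepoint cohort table.

    outcome = intercept + time*t + group*g + group_time*g*t
              + centered covariate effects + medication-by-time effects
              + site intercept + participant intercept + residual.

    Participants are nested in sites; arm assignment is 1:1 within the
    cohort. Returns one row per participant-visit.
    """
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_arm
    arm = np.repeat([0, 1], spec.n_per_arm)
    site = rng.integers(0, spec.n_sites, size=n)
    site_eff = rng.normal(0.0, spec.sd_site, spec.n_sites)
    part_eff = rng.normal(0.0, spec.sd_participant, n)

    age = rng.normal(spec.mean_age, spec.sd_age, n)
    male = (rng.random(n) < spec.p_male).astype(int)
    black = (rng.random(n) < spec.p_black).astype(int)
    cvd = (rng.random(n) < spec.p_cvd).astype(int)
    ckd = (rng.random(n) < spec.p_ckd).astype(int)
    bsbp = rng.normal(spec.mean_baseline_sbp, spec.sd_baseline_sbp, n)
    ticv = rng.normal(1400.0, 130.0, n)
    wmh_vol = np.exp(rng.normal(np.log(3.0), 0.8, n))
    logwmh0 = np.log1p(wmh_vol / ticv)
    mean_logwmh = float(np.log1p(3.0 * np.exp(0.32) / 1400.0))
    bpf = np.clip(rng.normal(0.82, 0.04, n), 0.6, 0.95)
    tbv0 = bpf * ticv

    exposures = {c: (rng.beta(*spec.med_beta[c], size=n)
                     if spec.med_beta.get(c) is not None
                     else np.zeros(n)) for c in MED_CLASSES}

    followup_days = spec.followup_years * 365.25
    achieved = np.empty(n)
    for i in range(n):
        s = simulate_sbp_series(int(arm[i]), 10, followup_days, spec,
                                seed=int(rng.integers(0, 2 ** 31 - 1)))
        achieved[i] = np.trapezoid(s.sbp, s.days) / (s.days[-1] - s.days[0])

    # longitudinal drift of adjustment covariates
    dlogwmh = rng.normal(0.05, 0.03, n) * np.log1p(wmh_vol / ticv) * 10
    dtbv = rng.normal(-28.0, 8.0, n)

    rows = []
    for t in (0, 1):
        logwmh = logwmh0 + t * dlogwmh
        tbv = tbv0 + t * dtbv
        lp = (spec.intercept
              + spec.time * t
              + spec.group * arm
              + spec.group_time * arm * t
              + spec.coef_age * (age - spec.mean_age)
              + spec.coef_male * (male - spec.p_male)
              + spec.coef_black * (black - spec.p_black)
              + spec.coef_cvd * (cvd - spec.p_cvd)
              + spec.coef_ckd * (ckd - spec.p_ckd)
              + spec.coef_baseline_sbp * (bsbp - spec.mean_baseline_sbp)
              + spec.coef_logwmh * (logwmh0 - mean_logwmh))
        for c in MED_CLASSES:
            lp = lp + spec.med_time_effects.get(c, 0.0) * exposures[c] * t
        resid = (rng.normal(0.0, spec.sd_residual, n)
                 if spec.sd_residual > 0 else 0.0)
        outcome = lp + site_eff[site] + part_eff + resid
        roi_cm3 = 0.32 * ticv            # analyzed WM+BG tissue volume
        rows.append(pd.DataFrame({
            "participant": np.arange(n),
            "site": site,
            "arm": arm,
            "timepoint": t,
            "pvs_volume_fraction": outcome,
            "pvs_volume_cm3": outcome / 100.0 * roi_cm3,
            "age": age, "male": male, "black": black,
            "cvd": cvd, "ckd": ckd,
            "baseline_sbp": bsbp,
            "logwmh": logwmh,
            "tbv": tbv, "ticv": ticv,
            "achieved_sbp": achieved,
            **{f"exp_{c}": exposures[c] for c in MED_CLASSES},
        }))
    df = pd.concat(rows, ignore_index=True)
    return df.sort_values(["participant", "timepoint"]).reset_index(drop=True)
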