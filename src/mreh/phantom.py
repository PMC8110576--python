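"""Synthetic viscoelastic liver phantoms and multifrequency shear-wave fields.

This module generates everything the rest of the pipeline consumes, so the
whole analysis is testable without patient data:

* ground-truth shear-wave-speed (SWS, m/s) and fluidity (phi, rad) volumes
  with liver and vessel masks, in two disease archetypes — focal stiffening
  with controllable spatial heterogeneity (PSC-like) and smooth diffuse
  stiffening (viral-hepatitis-like);
* time-resolved 3-component displacement fields at the six drive
  frequencies, synthesized as superpositions of damped plane shear waves
  whose local phase speed equals the ground-truth SWS and whose attenuation
  encodes the ground-truth fluidity via alpha = k * tan(phi / 2);
* whole cohorts of (phantom, wave field, clinical record) triples with
  group-specific stiffness, heterogeneity and laboratory distributions.

All randomness is driven by explicit integer seeds; identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "GroundTruthMaps",
    "WaveField",
    "CohortSpec",
    "GroupSpec",
    "make_phantom",
    "synthesize_wavefield",
    "draw_cohort_parameters",
    "simulate_cohort",
]

#: default drive frequencies (Hz) of the multifrequency acquisition
DEFAULT_FREQUENCIES_HZ = (35.0, 40.0, 45.0, 50.0, 55.0, 60.0)

#: speed assigned inside vessel lumina (m/s); below the 1 m/s VOI threshold
VESSEL_SWS_MPS = 0.5
#: fluidity assigned inside vessel lumina (rad)
VESSEL_PHI_RAD = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic liver phantom.

    Defaults mirror the emulated acquisition: 9 axial slices on a 78 x 100
    in-plane matrix, 3 x 3 mm in-plane and 5 mm through-plane voxels, eight
    time offsets per vibration period and drive frequencies 35-60 Hz.
    ``voxel_size_mm`` is ordered (row, column, slice).
    """

    grid_shape: tuple[int, int, int] = (9, 78, 100)  # (slices, rows, cols)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 5.0)  # (row, col, slice)
    frequencies_hz: tuple[float, ...] = DEFAULT_FREQUENCIES_HZ
    n_offsets: int = 8
    archetype: str = "heterogeneous_focal"
    background_sws_mps: float = 1.7
    lesion_fraction: float = 0.25
    lesion_contrast: float = 0.5
    target_cv_percent: float | None = None
    phi_background_rad: float = 0.49
    vessel_count: int = 4
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be 3 positive reals")
        if not self.frequencies_hz or any(f <= 0 for f in self.frequencies_hz):
            raise ValueError("frequencies_hz must be positive")
        if self.n_offsets < 3:
            raise ValueError("need at least 3 time offsets per period")
        if self.archetype not in ("heterogeneous_focal", "homogeneous_diffuse"):
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.background_sws_mps <= 0:
            raise ValueError("background_sws_mps must be positive")
        if not (0.0 <= self.lesion_fraction <= 1.0):
            raise ValueError("lesion_fraction must lie in [0, 1]")
        if self.lesion_contrast <= -1.0:
            raise ValueError("lesion_contrast must be > -1")
        if self.target_cv_percent is not None and self.target_cv_percent < 0:
            raise ValueError("target_cv_percent must be nonnegative")
        if not (0.0 <= self.phi_background_rad < math.pi / 2):
            raise ValueError("phi_background_rad must lie in [0, pi/2)")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class GroundTruthMaps:
    """Voxelwise ground truth: SWS (m/s), fluidity (rad), liver/vessel masks."""

    sws_true_mps: np.ndarray
    phi_true_rad: np.ndarray
    liver_mask: np.ndarray
    vessel_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    @property
    def parenchyma_mask(self) -> np.ndarray:
        """Liver voxels excluding vessel lumina."""
        return self.liver_mask & ~self.vessel_mask

    def parenchymal_cv_percent(self) -> float:
        """Spatial coefficient of variation of true SWS over liver \\ vessels."""
        vals = self.sws_true_mps[self.parenchyma_mask]
        return 100.0 * float(np.std(vals, ddof=1) / np.mean(vals))


@dataclass
class WaveField:
    """Time-resolved displacement, indexed (component, frequency, slice, row, col, offset)."""

    displacement: np.ndarray
    frequencies_hz: tuple[float, ...]
    voxel_size_mm: tuple[float, float, float]
    n_offsets: int

    def __post_init__(self) -> None:
        if self.displacement.ndim != 6 or self.displacement.shape[0] != 3:
            raise ValueError(
                "displacement must be (3, n_freq, slices, rows, cols, n_offsets)"
            )


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Simply-connected ellipsoidal liver surrogate, roughly 600 cm^3 at defaults."""
    ns, nr, nc = shape
    zz, rr, cc = np.meshgrid(
        np.arange(ns), np.arange(nr), np.arange(nc), indexing="ij"
    )
    center = ((ns - 1) / 2.0, (nr - 1) / 2.0, (nc - 1) / 2.0)
    # semi-axes leave a margin so waves can enter from outside the organ
    semi = (max(0.45 * ns, 0.75), 0.33 * nr, 0.35 * nc)
    d2 = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((rr - center[1]) / semi[1]) ** 2
        + ((cc - center[2]) / semi[2]) ** 2
    )
    return d2 <= 1.0


def _vessel_mask(
    liver: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    count: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Tubular low-speed structures: straight cylinders through the liver."""
    mask = np.zeros_like(liver, dtype=bool)
    if count == 0:
        return mask
    ns, nr, nc = liver.shape
    spacing = np.array([voxel_size_mm[2], voxel_size_mm[0], voxel_size_mm[1]])
    coords = np.stack(
        np.meshgrid(np.arange(ns), np.arange(nr), np.arange(nc), indexing="ij"),
        axis=-1,
    ).astype(float) * spacing  # physical mm, (slice,row,col) order

    center_idx = np.array(ndimage.center_of_mass(liver))
    for _ in range(count):
        # anchor near the hilum (liver centroid, jittered), random orientation
        anchor = (center_idx + rng.normal(0.0, [0.8, 6.0, 6.0])) * spacing
        direction = rng.normal(size=3)
        direction[0] *= 0.3  # vessels run mostly in-plane on axial slices
        direction /= np.linalg.norm(direction)
        radius_mm = rng.uniform(4.0, 6.0)
        rel = coords - anchor
        along = rel @ direction
        perp2 = np.einsum("...i,...i->...", rel, rel) - along**2
        mask |= perp2 <= radius_mm**2
    return mask & liver


def _lesion_pattern(
    liver: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    lesion_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth-edged focal blobs (Gaussian-blurred spherical indicator), in [0, 1]."""
    if lesion_fraction == 0.0:
        return np.zeros(liver.shape, dtype=float)
    ns, nr, nc = liver.shape
    spacing = np.array([voxel_size_mm[2], voxel_size_mm[0], voxel_size_mm[1]])
    coords = np.stack(
        np.meshgrid(np.arange(ns), np.arange(nr), np.arange(nc), indexing="ij"),
        axis=-1,
    ).astype(float) * spacing

    liver_idx = np.argwhere(liver)
    target_vox = lesion_fraction * liver.sum()
    indicator = np.zeros(liver.shape, dtype=bool)
    # place spheres until coverage reaches the requested liver fraction
    for _ in range(200):
        if indicator.sum() >= target_vox:
            break
        c = liver_idx[rng.integers(len(liver_idx))] * spacing
        # segmental-to-lobar scale (liver segments span ~60-100 mm), above
        # the shear wavelength so the imposed heterogeneity is within the
        # method's spatial resolution
        radius_mm = rng.uniform(30.0, 60.0)
        d2 = np.einsum("...i,...i->...", coords - c, coords - c)
        indicator |= d2 <= radius_mm**2
    # smooth edges: ~6 mm Gaussian apron so the inversion can track the lesion
    sigma_vox = 6.0 / spacing
    pattern = ndimage.gaussian_filter(indicator.astype(float), sigma=sigma_vox)
    return np.clip(pattern, 0.0, 1.0)


def _diffuse_pattern(
    liver: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth Gaussian random texture (correlation length ~35 mm), min-max in [0, 1]."""
    spacing = np.array([voxel_size_mm[2], voxel_size_mm[0], voxel_size_mm[1]])
    noise = rng.standard_normal(liver.shape)
    pattern = ndimage.gaussian_filter(noise, sigma=35.0 / spacing)
    lo, hi = pattern.min(), pattern.max()
    if hi - lo < 1e-12:
        return np.zeros_like(pattern)
    return (pattern - lo) / (hi - lo)


def make_phantom(spec: PhantomSpec) -> GroundTruthMaps:
    """Build ground-truth SWS/fluidity maps for one subject.

    The liver is an ellipsoid; ``heterogeneous_focal`` superimposes smooth
    focal stiffening covering about ``lesion_fraction`` of the organ, while
    ``homogeneous_diffuse`` uses a smooth low-contrast texture. When
    ``target_cv_percent`` is set, the parenchymal field is affinely rescaled
    so that its spatial mean equals ``background_sws_mps`` and its
    coefficient of variation over liver-minus-vessels equals the target
    exactly. Vessels are tubes of 0.5 m/s inside the liver.

    Raises
    ------
    ValueError
        If the heterogeneity target is infeasible for the generated pattern
        (e.g. ``lesion_fraction == 0`` with a nonzero target, or a target so
        large the speed field would become nonpositive).
    """
    rng = np.random.default_rng(spec.seed)
    liver = _ellipsoid_mask(spec.grid_shape)
    vessels = _vessel_mask(liver, spec.voxel_size_mm, spec.vessel_count, rng)
    parenchyma = liver & ~vessels

    if spec.archetype == "heterogeneous_focal":
        pattern = _lesion_pattern(
            liver, spec.voxel_size_mm, spec.lesion_fraction, rng
        )
    else:
        pattern = _diffuse_pattern(liver, spec.voxel_size_mm, rng)

    c0 = spec.background_sws_mps
    # heterogeneity lives inside the liver; surrounding tissue is uniform
    pattern = pattern * liver
    if spec.target_cv_percent is None:
        sws = c0 * (1.0 + spec.lesion_contrast * pattern)
    elif spec.target_cv_percent == 0.0:
        sws = np.full(spec.grid_shape, c0)
    else:
        p = pattern[parenchyma]
        mu, sd = float(np.mean(p)), float(np.std(p, ddof=1))
        if sd < 1e-9:
            raise ValueError(
                "infeasible heterogeneity target: pattern has no spatial "
                "variation (increase lesion_fraction or vessel-free volume)"
            )
        t = spec.target_cv_percent / 100.0
        z = np.where(liver, (pattern - mu) / sd, 0.0)  # standardized over parenchyma
        sws = c0 * (1.0 + t * z)
        if sws[parenchyma].min() <= 0.05:
            raise ValueError(
                "infeasible heterogeneity target: requested CV drives the "
                "speed field nonpositive"
            )

    phi = np.full(spec.grid_shape, spec.phi_background_rad)
    sws = sws.copy()
    sws[vessels] = VESSEL_SWS_MPS
    phi[vessels] = VESSEL_PHI_RAD

    return GroundTruthMaps(
        sws_true_mps=sws,
        phi_true_rad=phi,
        liver_mask=liver,
        vessel_mask=vessels,
        voxel_size_mm=spec.voxel_size_mm,
    )


# ---------------------------------------------------------------------------
# wave synthesis
# ---------------------------------------------------------------------------


def _solve_eikonal(
    slowness: np.ndarray,
    seed_mask: np.ndarray,
    step_m: float,
    tol: float = 1e-9,
    max_iter: int = 1024,
) -> np.ndarray:
    """First-arrival travel time T with |grad T| = slowness, per slice.

    Vectorized Jacobi iteration of the Godunov upwind discretization of the
    2D eikonal equation (slices are independent; the slice axis is batched).
    T = 0 on ``seed_mask``. Plane-wave solutions are exact for this scheme
    at any propagation angle, so homogeneous-medium fields satisfy the
    closed-form oracle to machine precision.
    """
    big = 1e30
    T = np.where(seed_mask, 0.0, big)
    f = slowness * step_m

    def shifted_min(a: np.ndarray, axis: int) -> np.ndarray:
        lo = np.full_like(a, big)
        hi = np.full_like(a, big)
        sl_lo = [slice(None)] * a.ndim
        sl_hi = [slice(None)] * a.ndim
        sl_lo[axis] = slice(1, None)
        sl_hi[axis] = slice(None, -1)
        lo[tuple(sl_lo)] = a[tuple(sl_hi)]
        hi[tuple(sl_hi)] = a[tuple(sl_lo)]
        return np.minimum(lo, hi)

    for it in range(max_iter):
        a = shifted_min(T, axis=1)
        b = shifted_min(T, axis=2)
        lo = np.minimum(a, b)
        diff = np.abs(a - b)
        # 1D update when the front arrives mostly along one axis,
        # 2D quadratic update otherwise
        t_1d = lo + f
        with np.errstate(invalid="ignore"):
            t_2d = 0.5 * (a + b + np.sqrt(np.maximum(2 * f**2 - diff**2, 0.0)))
        t = np.where(diff >= f, t_1d, t_2d)
        T_new = np.where(seed_mask, 0.0, np.minimum(T, t))
        if it % 8 == 7:
            change = np.max(np.abs(T_new - T)[T_new < big])
            T = T_new
            if change < tol:
                break
        else:
            T = T_new
    return T


def _source_arc_mask(
    shape: tuple[int, int, int], angle_deg: float, arc_half_deg: float = 45.0
) -> np.ndarray:
    """Boundary-ring pixels centered at ``angle_deg`` (the driver position)."""
    ns, nr, nc = shape
    ring = np.zeros((nr, nc), dtype=bool)
    ring[0, :] = ring[-1, :] = True
    ring[:, 0] = ring[:, -1] = True
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    ang = np.degrees(np.arctan2(rr - (nr - 1) / 2.0, cc - (nc - 1) / 2.0))
    delta = (ang - angle_deg + 180.0) % 360.0 - 180.0
    arc = ring & (np.abs(delta) <= arc_half_deg)
    return np.broadcast_to(arc, (ns, nr, nc)).copy()


def _body_mask(shape: tuple[int, int, int], margin_vox: int = 2) -> np.ndarray:
    """Phantom body: an in-plane ellipse nearly filling the field of view.

    Waves propagate through the whole body (liver plus surrounding tissue at
    background speed), so the liver sees no artificial truncation edge.
    """
    ns, nr, nc = shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    d2 = (
        ((rr - (nr - 1) / 2.0) / (nr / 2.0 - margin_vox)) ** 2
        + ((cc - (nc - 1) / 2.0) / (nc / 2.0 - margin_vox)) ** 2
    )
    return np.broadcast_to(d2 <= 1.0, (ns, nr, nc)).copy()


def _body_taper(body: np.ndarray, width_vox: float = 3.0) -> np.ndarray:
    """Smooth amplitude window supported on the body (1 in the interior)."""
    dist = ndimage.distance_transform_edt(body)
    return np.clip(dist / width_vox, 0.0, 1.0)


def synthesize_wavefield(
    gt: GroundTruthMaps,
    spec: PhantomSpec,
    n_sources: int = 12,
    amplitude: float = 1.0,
) -> WaveField:
    """Superpose damped shear waves launched from ``n_sources`` boundary arcs.

    Each source is an arc of the field-of-view boundary (emulating a surface
    driver); its wave front obeys the eikonal equation, so the local phase
    gradient magnitude equals the local wave number k(x) = 2*pi*f / c(x)
    everywhere — geometric-optics propagation with refraction but without
    diffraction. The accumulated log-amplitude is the path integral of
    alpha(x) = k(x) * tan(phi(x) / 2), the plane-wave attenuation implied by
    fluidity phi. Both travel-time fields are computed once per source and
    scaled by 2*pi*f for every drive frequency. Offsets sample
    u(x, t) = Re[U(x) e^{-i 2 pi f t}] at ``spec.n_offsets`` uniform phases
    of one period; Gaussian noise with standard deviation ``noise_sigma``
    times the mean in-body amplitude is added when requested. Displacement
    is zero outside the phantom body.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    if not gt.liver_mask.any():
        raise ValueError("empty liver mask")
    if abs(spec.voxel_size_mm[0] - spec.voxel_size_mm[1]) > 1e-9:
        raise ValueError("wave synthesis requires square in-plane voxels")

    rng = np.random.default_rng(spec.seed + 1)  # independent of phantom draw
    step_m = spec.voxel_size_mm[0] * 1e-3
    slowness = 1.0 / gt.sws_true_mps
    loss = np.tan(gt.phi_true_rad / 2.0) / gt.sws_true_mps

    # evenly spread driver positions around the boundary, with seeded jitter
    base = rng.uniform(0.0, 360.0)
    angles = base + 360.0 * np.arange(n_sources) / n_sources
    angles += rng.uniform(-10.0, 10.0, size=n_sources)

    body = _body_mask(spec.grid_shape)
    taper = _body_taper(body)
    freqs = np.asarray(spec.frequencies_hz, dtype=float)
    n_freq = len(freqs)
    ns, nr, nc = spec.grid_shape
    n_off = spec.n_offsets

    # complex harmonic amplitude per (component, frequency); sources are
    # distributed round-robin over the three field components — each
    # component of the measured motion is dominated by a different subset of
    # propagation directions, which keeps the per-component directional
    # spectra sparse (as polarization does for real shear waves)
    U = np.zeros((3, n_freq, ns, nr, nc), dtype=np.complex128)
    for s_idx, angle in enumerate(angles):
        seed_mask = _source_arc_mask(spec.grid_shape, angle)
        # phase and log-amplitude per Hz: 2*pi*T and 2*pi*B with
        # |grad T| = 1/c and |grad B| = tan(phi/2)/c along the same fronts
        phase_per_hz = 2.0 * np.pi * _solve_eikonal(slowness, seed_mask, step_m)
        decay_per_hz = 2.0 * np.pi * _solve_eikonal(loss, seed_mask, step_m)
        src_phase = rng.uniform(0.0, 2.0 * np.pi)
        comp = (2 + s_idx) % 3  # first source drives the through-plane (z) motion
        for f_idx, f in enumerate(freqs):
            field = np.exp(1j * (f * phase_per_hz + src_phase) - f * decay_per_hz)
            U[comp, f_idx] += field
    U *= amplitude * taper[None, None]

    offsets = np.arange(n_off) / n_off  # fractions of one period
    # u(t_j) = Re[U e^{-i 2 pi f t_j}], with f t_j = j / n_off for every f
    phase_fac = np.exp(-2j * np.pi * offsets)
    disp = np.real(U[..., None] * phase_fac)

    if spec.noise_sigma > 0:
        mean_amp = float(np.mean(np.abs(disp[:, :, body, :])))
        noise = rng.normal(0.0, spec.noise_sigma * mean_amp, size=disp.shape)
        disp = disp + noise * body[None, None, :, :, :, None]

    return WaveField(
        displacement=disp.astype(np.float32),
        frequencies_hz=tuple(freqs),
        voxel_size_mm=spec.voxel_size_mm,
        n_offsets=n_off,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Per-group distributions of MRE truth and clinical covariates.

    MRE defaults follow the cohort summary of the study this package
    emulates (group mean +/- SD); laboratory values use moment-matched
    lognormals so they stay positive.
    """

    archetype: str = "heterogeneous_focal"
    sws_mean: float = 1.70
    sws_sd: float = 0.28
    cv_mean: float = 21.0
    cv_sd: float = 5.0
    age_mean: float = 41.0
    age_sd: float = 14.0
    ast_mean: float = 64.0
    ast_sd: float = 56.0
    bilirubin_mean: float = 1.64
    bilirubin_sd: float = 3.11
    albumin_mean: float = 3.9
    albumin_sd: float = 0.5
    platelets_median: float = 220.0
    platelets_sigma: float = 0.35  # lognormal shape
    variceal_p: float = 0.10


PSC_GROUP = GroupSpec()
VIRAL_GROUP = GroupSpec(
    archetype="homogeneous_diffuse",
    sws_mean=1.84,
    sws_sd=0.38,
    cv_mean=18.0,
    cv_sd=3.0,
    age_mean=50.0,
    age_sd=14.0,
    ast_mean=83.0,
    ast_sd=99.0,
    bilirubin_mean=1.03,
    bilirubin_sd=0.63,
    platelets_median=180.0,
    variceal_p=0.04,
)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation settings."""

    psc: GroupSpec = field(default_factory=lambda: PSC_GROUP)
    viral: GroupSpec = field(default_factory=lambda: VIRAL_GROUP)
    ast_uln_u_per_l: float = 40.0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)


def _lognormal_from_moments(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and SD."""
    var = sd**2
    sigma2 = math.log(1.0 + var / mean**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def _truncnorm(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int,
) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def draw_cohort_parameters(
    n_psc: int,
    n_viral: int,
    cohort_spec: CohortSpec | None = None,
    seed: int = 0,
) -> "pd.DataFrame":
    """Draw per-subject ground-truth MRE parameters and clinical covariates.

    Returns one row per subject: id, group, archetype, background SWS,
    target CV, and the laboratory values the biological scores need. This is
    the sampling layer of :func:`simulate_cohort`, usable on its own for
    statistics-level experiments that do not need wave physics.
    """
    import pandas as pd

    if n_psc < 1 or n_viral < 1:
        raise ValueError("empty group: both group sizes must be >= 1")
    spec = cohort_spec or CohortSpec()
    rng = np.random.default_rng(seed)

    rows = []
    for label, n, g in (("PSC", n_psc, spec.psc), ("viral", n_viral, spec.viral)):
        sws = _truncnorm(rng, g.sws_mean, g.sws_sd, 1.15, 3.2, n)
        cv = _truncnorm(rng, g.cv_mean, g.cv_sd, 3.0, 45.0, n)
        age = _truncnorm(rng, g.age_mean, g.age_sd, 18.0, 90.0, n)
        ast = _lognormal_from_moments(rng, g.ast_mean, g.ast_sd, n)
        bili = _lognormal_from_moments(rng, g.bilirubin_mean, g.bilirubin_sd, n)
        alb = _truncnorm(rng, g.albumin_mean, g.albumin_sd, 2.0, 5.5, n)
        plate = g.platelets_median * rng.lognormal(0.0, g.platelets_sigma, size=n)
        varice = rng.uniform(size=n) < g.variceal_p
        for i in range(n):
            rows.append(
                {
                    "group": label,
                    "archetype": g.archetype,
                    "background_sws_mps": float(sws[i]),
                    "target_cv_percent": float(cv[i]),
                    "age_years": float(age[i]),
                    "ast_u_per_l": float(ast[i]),
                    "ast_uln_u_per_l": spec.ast_uln_u_per_l,
                    "platelets_1e9_per_l": float(plate[i]),
                    "bilirubin_mg_per_dl": float(bili[i]),
                    "albumin_g_per_dl": float(alb[i]),
                    "variceal_bleeding": bool(varice[i]),
                }
            )
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", [f"S{i:03d}" for i in range(len(df))])
    return df


def simulate_cohort(
    n_psc: int,
    n_viral: int,
    cohort_spec: CohortSpec | None = None,
    seed: int = 0,
    n_sources: int = 12,
):
    """Simulate a full cohort: phantom truth, wave field and clinical record.

    Returns a list of ``(GroundTruthMaps, WaveField, record)`` triples where
    ``record`` is a plain dict of the subject's clinical covariates and
    group label. Fully deterministic for fixed arguments.
    """
    spec = cohort_spec or CohortSpec()
    params = draw_cohort_parameters(n_psc, n_viral, spec, seed=seed)
    out = []
    for i, row in params.iterrows():
        subj_spec = replace(
            spec.phantom,
            archetype=row["archetype"],
            background_sws_mps=row["background_sws_mps"],
            target_cv_percent=row["target_cv_percent"],
            seed=int(np.random.default_rng(seed + 1000 + i).integers(2**31 - 1)),
        )
        gt = make_phantom(subj_spec)
        wf = synthesize_wavefield(gt, subj_spec, n_sources=n_sources)
        record = {
            k: row[k]
            for k in (
                "subject_id",
                "group",
                "age_years",
                "ast_u_per_l",
                "ast_uln_u_per_l",
                "platelets_1e9_per_l",
                "bilirubin_mg_per_dl",
                "albumin_g_per_dl",
                "variceal_bleeding",
            )
        }
        out.append((gt, wf, record))
    return out
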