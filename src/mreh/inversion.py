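"""Tomoelastography-style multifrequency inversion.

Reconstructs shear-wave-speed (SWS) and fluidity maps from time-resolved
multifrequency displacement fields in four stages:

1. temporal harmonic extraction (DFT over the time offsets at the drive
   frequency);
2. directional decomposition of each slice's 2D spatial spectrum into
   angular sectors with raised-cosine windows plus a radial band-pass, so
   each sector contains waves travelling in one direction;
3. per-direction plane-wave phase-gradient wave-number estimation,
   SWS = 2*pi*f / |grad(phase)|, with the filtered wave amplitude as the
   reliability weight;
4. amplitude-weighted compounding over all directions, field components and
   drive frequencies (12 x 3 x 6 = 216 maps per slice at defaults), and an
   algebraic Helmholtz estimate of the fluidity phi = arg(-rho w^2 u / lap u)
   aggregated over components and frequencies.

Units: wave numbers in rad/m, speeds in m/s, fluidity in rad clipped to
[0, pi/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase

from .phantom import WaveField

__all__ = [
    "HarmonicField",
    "Elastogram",
    "InversionSettings",
    "extract_harmonic",
    "directional_filter_bank",
    "phase_gradient_sws",
    "compound_sws",
    "estimate_fluidity",
    "invert_subject",
]

#: soft-tissue density assumed by the fluidity estimator (kg/m^3)
TISSUE_DENSITY_KG_M3 = 1000.0


@dataclass
class HarmonicField:
    """Complex displacement per (component, frequency, slice, row, col)."""

    u: np.ndarray
    frequencies_hz: tuple[float, ...]
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.u.ndim != 5 or self.u.shape[0] != 3:
            raise ValueError("u must be (3, n_freq, slices, rows, cols)")
        if self.u.shape[1] != len(self.frequencies_hz):
            raise ValueError("frequency axis mismatch")


@dataclass
class Elastogram:
    """Reconstructed SWS (m/s) and fluidity (rad) maps plus provenance."""

    sws_mps: np.ndarray
    phi_rad: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    n_compounded: int  # directions x components x frequencies per slice
    valid_mask: np.ndarray | None = None


@dataclass(frozen=True)
class InversionSettings:
    """Tunable parameters of the inversion.

    ``c_lowcut_mps`` sets the radial low cut k >= 2*pi*f / c_lowcut (speeds
    above it are treated as compression-wave leakage); the high cut defaults
    to the in-plane Nyquist wave number. ``amplitude_floor`` is the fraction
    of the strongest filtered amplitude (per component and frequency) below
    which a voxel's directional estimate is discarded, mirroring the
    exclusion of poorly excited regions.
    """

    n_directions: int = 12
    #: radial low cut expressed as a speed: k >= 2*pi*f / c_lowcut. Set above
    #: the fastest plausible shear speed (focal cirrhotic tissue approaches
    #: 3 m/s) so stiff-lesion wave numbers are kept; residual bulk-wave
    #: leakage sits at far lower k and is still rejected.
    c_lowcut_mps: float = 5.0
    k_highcut: float | None = None  # rad/m; None -> in-plane Nyquist
    #: half-width of the angular windows in sector spacings; 3 keeps
    #: counter-propagating waves separated (the window vanishes at +/-90
    #: degrees) while minimizing the spatial smoothing the angular
    #: restriction imposes on the filtered fields
    angular_width_factor: int = 3
    amplitude_floor: float = 0.05
    sws_max_mps: float = 5.0
    smooth_sigma_vox: float = 0.6  # pre-gradient Gaussian smoothing
    weight_power: float = 2.0  # compound weights = amplitude ** weight_power
    #: amplitude normalization before directional filtering: the field is
    #: divided by (|u| + eps * max|u|) so strong viscous decay does not smear
    #: the spatial spectrum; the original amplitude still sets the weights
    normalize_eps: float = 0.05


def extract_harmonic(wf: WaveField) -> HarmonicField:
    """Complex amplitude of the drive-frequency fundamental at each voxel.

    With offsets sampling one period uniformly, the positive-frequency DFT
    bin scaled by 2/N maps u(t) = A cos(2 pi f t + theta) to A e^{i theta}.
    """
    n = wf.n_offsets
    if n < 3:
        raise ValueError("need at least 3 uniform offsets per period")
    disp = wf.displacement.astype(np.float64)
    j = np.arange(n)
    kernel = np.exp(-2j * np.pi * j / n)
    u = (2.0 / n) * np.tensordot(disp, kernel, axes=([-1], [0]))
    return HarmonicField(
        u=u, frequencies_hz=wf.frequencies_hz, voxel_size_mm=wf.voxel_size_mm
    )


def _k_grids(shape_2d: tuple[int, int], spacing_m: tuple[float, float]):
    """Angular wave-number grids (rad/m) for a 2D FFT of an image slice."""
    kr = 2.0 * np.pi * np.fft.fftfreq(shape_2d[0], d=spacing_m[0])
    kc = 2.0 * np.pi * np.fft.fftfreq(shape_2d[1], d=spacing_m[1])
    return np.meshgrid(kr, kc, indexing="ij")


def directional_filter_bank(
    field: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    n_directions: int,
    k_lowcut: float,
    k_highcut: float,
    width_factor: int = 1,
) -> np.ndarray:
    """Split a complex field into ``n_directions`` angular k-space sectors.

    Parameters
    ----------
    field
        Complex array (..., rows, cols); the FFT is taken over the last two
        axes (each leading index, e.g. slice, is filtered independently).
    k_lowcut, k_highcut
        Radial band (rad/m), low edge excluded below, high edge above. The
        angular windows are raised cosines (cos^2) that sum to one at every
        angle, so with the radial band fully open the directional fields sum
        back to the input exactly.
    width_factor
        Integer widening of the angular windows (half-width in units of the
        sector spacing). Wider windows trade angular selectivity for better
        spatial resolution of the filtered fields; the partition-of-unity
        property is preserved for any integer value.

    Returns
    -------
    np.ndarray with a new leading direction axis, shape (n_directions, ...).
    """
    if n_directions < 4:
        raise ValueError("need at least 4 filter directions")
    if not (0.0 <= k_lowcut < k_highcut):
        raise ValueError("require 0 <= k_lowcut < k_highcut")
    rows, cols = field.shape[-2:]
    spacing_m = (voxel_size_mm[0] * 1e-3, voxel_size_mm[1] * 1e-3)
    kr, kc = _k_grids((rows, cols), spacing_m)
    k_mag = np.hypot(kr, kc)
    if k_lowcut > 0 and k_lowcut > k_mag.max():
        raise ValueError("grid too small for requested wave-number band")
    theta = np.arctan2(kc, kr)
    radial = (k_mag >= k_lowcut) & (k_mag <= k_highcut)

    spectrum = np.fft.fft2(field, axes=(-2, -1))
    # raised-cosine windows of half-width ``width_factor`` sector spacings;
    # for integer width_factor they sum to width_factor at every angle, so
    # dividing by it keeps the bank a partition of unity
    half_width = width_factor * 2.0 * np.pi / n_directions
    out = np.empty((n_directions,) + field.shape, dtype=np.complex128)
    for d in range(n_directions):
        center = 2.0 * np.pi * d / n_directions - np.pi
        delta = np.angle(np.exp(1j * (theta - center)))  # wrapped difference
        win = np.where(
            np.abs(delta) < half_width,
            np.cos(np.pi * delta / (2.0 * half_width)) ** 2 / width_factor,
            0.0,
        )
        out[d] = np.fft.ifft2(spectrum * (win * radial), axes=(-2, -1))
    return out


def phase_gradient_sws(
    directional_field: np.ndarray,
    frequency_hz: float,
    voxel_size_mm: tuple[float, float, float],
    amplitude_floor: float = 0.05,
    floor_reference: float | None = None,
    sws_max_mps: float = 5.0,
    smooth_sigma_vox: float = 0.6,
):
    """Plane-wave phase-gradient speed estimate for one directional field.

    The phase of each slice is unwrapped (2D quality-guided unwrapping),
    differentiated by central differences scaled by the physical voxel size,
    and converted to speed as SWS = 2*pi*f / |grad(phase)|. Voxels whose
    filtered amplitude falls below ``amplitude_floor`` times the reference
    amplitude (per-field maximum by default), or whose implied speed exceeds
    ``sws_max_mps``, are flagged invalid.

    Returns ``(sws, amplitude, valid)`` arrays of the field's shape.
    """
    f3 = np.asarray(directional_field)
    if f3.ndim == 2:
        f3 = f3[None]
    if not np.any(f3):
        raise ValueError("all-zero directional field")
    amp = np.abs(f3)
    if smooth_sigma_vox > 0:
        sm = ndimage.gaussian_filter
        f3 = sm(f3.real, (0, smooth_sigma_vox, smooth_sigma_vox)) + 1j * sm(
            f3.imag, (0, smooth_sigma_vox, smooth_sigma_vox)
        )
    ref = float(np.max(amp)) if floor_reference is None else floor_reference
    valid = amp >= amplitude_floor * ref

    dr = voxel_size_mm[0] * 1e-3
    dc = voxel_size_mm[1] * 1e-3
    sws = np.zeros(f3.shape, dtype=np.float64)
    for s in range(f3.shape[0]):
        if not valid[s].any():
            continue
        phase = unwrap_phase(np.angle(f3[s]))
        gr, gc = np.gradient(phase, dr, dc)
        gmag = np.hypot(gr, gc)
        with np.errstate(divide="ignore"):
            c = 2.0 * np.pi * frequency_hz / gmag
        ok = np.isfinite(c) & (c <= sws_max_mps)
        sws[s][ok] = c[ok]
        valid[s] &= ok
    if directional_field.ndim == 2:
        return sws[0], amp[0], valid[0]
    return sws, amp, valid


def compound_sws(
    sws_maps: np.ndarray, amplitude_maps: np.ndarray, valid_masks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude-weighted average of per-direction/component/frequency maps.

    ``sws_maps``, ``amplitude_maps`` and ``valid_masks`` are stacked along a
    leading contribution axis. Voxels with no valid contribution are set to
    zero and flagged in the returned validity mask.
    """
    sws_maps = np.asarray(sws_maps, dtype=np.float64)
    w = np.asarray(amplitude_maps, dtype=np.float64) * np.asarray(valid_masks)
    if sws_maps.shape != w.shape:
        raise ValueError("shape mismatch among compounded maps")
    wsum = w.sum(axis=0)
    num = (sws_maps * w).sum(axis=0)
    ok = wsum > 0
    out = np.zeros_like(wsum)
    out[ok] = num[ok] / wsum[ok]
    return out, ok


def estimate_fluidity(
    h: HarmonicField,
    smooth_sigma_vox: float = 1.0,
    density_kg_m3: float = TISSUE_DENSITY_KG_M3,
) -> np.ndarray:
    """Fluidity map phi = arg G* from an algebraic Helmholtz inversion.

    For a plane wave u ~ e^{i k* x} the complex squared wave number is
    k*^2 = -lap(u)/u and the complex shear modulus G* = rho w^2 / k*^2, so
    phi = |arg(-lap u / u)| independently of frequency. The per-voxel phase
    of k*^2 is aggregated over the 3 components and all frequencies by
    energy-weighted (|u|^2) averaging of its unit phasor, then clipped to
    [0, pi/2). The discrete Laplacian rescales k*^2 by a real factor only,
    leaving the phase unbiased.
    """
    dr = h.voxel_size_mm[0] * 1e-3
    dc = h.voxel_size_mm[1] * 1e-3
    acc = np.zeros(h.u.shape[2:], dtype=np.complex128)
    wacc = np.zeros(h.u.shape[2:], dtype=np.float64)
    sm = ndimage.gaussian_filter
    any_signal = False
    for comp in range(3):
        for f_idx in range(len(h.frequencies_hz)):
            u = h.u[comp, f_idx]
            if not np.any(u):
                continue
            any_signal = True
            if smooth_sigma_vox > 0:
                u = sm(u.real, (0, smooth_sigma_vox, smooth_sigma_vox)) + 1j * sm(
                    u.imag, (0, smooth_sigma_vox, smooth_sigma_vox)
                )
            # in-plane 5-point Laplacian with physical spacing
            lap = (
                (np.roll(u, 1, axis=1) + np.roll(u, -1, axis=1) - 2 * u) / dr**2
                + (np.roll(u, 1, axis=2) + np.roll(u, -1, axis=2) - 2 * u) / dc**2
            )
            ksq = -lap * np.conj(u)  # phase of k*^2, |u|^2-weighted
            mag = np.abs(ksq)
            nz = mag > 0
            w = np.abs(u) ** 2
            acc[nz] += w[nz] * ksq[nz] / mag[nz]
            wacc += w
    if not any_signal or not (wacc > 0).any():
        raise ValueError("all-zero harmonic field: fluidity undefined")
    phi = np.abs(np.angle(acc))
    phi[wacc == 0] = 0.0
    return np.clip(phi, 0.0, math.pi / 2 - 1e-6)


def invert_subject(
    wf: WaveField, settings: InversionSettings | None = None
) -> Elastogram:
    """Full inversion: harmonic extraction, directional filtering,
    phase-gradient speed estimation, amplitude-weighted compounding and
    Helmholtz fluidity estimation.

    Deterministic for fixed input; the provenance counter records the number
    of compounded images per slice (directions x components x frequencies).
    """
    st = settings or InversionSettings()
    h = extract_harmonic(wf)
    n_freq = len(h.frequencies_hz)
    shape = h.u.shape[2:]
    spacing_m = min(wf.voxel_size_mm[0], wf.voxel_size_mm[1]) * 1e-3
    k_nyq = np.pi / spacing_m
    k_high = st.k_highcut if st.k_highcut is not None else k_nyq

    num = np.zeros(shape)
    den = np.zeros(shape)
    for f_idx, f in enumerate(h.frequencies_hz):
        k_low = 2.0 * np.pi * f / st.c_lowcut_mps
        for comp in range(3):
            u = h.u[comp, f_idx]
            if not np.any(u):
                continue
            amp_u = np.abs(u)
            if st.normalize_eps > 0:
                u = u / (amp_u + st.normalize_eps * float(amp_u.max()))
            dirs = directional_filter_bank(
                u, wf.voxel_size_mm, st.n_directions, k_low, k_high,
                width_factor=st.angular_width_factor,
            )
            floor_ref = float(np.max(np.abs(dirs)))
            for d in range(st.n_directions):
                if not np.any(dirs[d]):
                    continue
                sws_d, amp_d, ok_d = phase_gradient_sws(
                    dirs[d],
                    f,
                    wf.voxel_size_mm,
                    amplitude_floor=st.amplitude_floor,
                    floor_reference=floor_ref,
                    sws_max_mps=st.sws_max_mps,
                    smooth_sigma_vox=st.smooth_sigma_vox,
                )
                w = amp_d**st.weight_power * ok_d
                num += sws_d * w
                den += w

    ok = den > 0
    sws = np.zeros(shape)
    sws[ok] = num[ok] / den[ok]
    phi = estimate_fluidity(h)
    phi = np.where(ok, phi, 0.0)
    return Elastogram(
        sws_mps=sws,
        phi_rad=phi,
        voxel_size_mm=wf.voxel_size_mm,
        n_compounded=st.n_directions * 3 * n_freq,
        valid_mask=ok,
    )
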