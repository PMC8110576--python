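"""Volume-of-interest statistics and fibrosis staging.

The analysis VOI is the liver mask with major vessels and poorly excited
regions excluded by an inclusive lower shear-wave-speed threshold of
1.0 m/s. Per-subject heterogeneity is quantified by the coefficient of
variation CV = 100 * SD / mean of the voxel values inside the VOI (sample
SD, N-1 denominator). Mean SWS is mapped to ordinal fibrosis stages F0-F4
by fixed inclusive cutoffs:

    F1 (any fibrosis)      >= 1.52 m/s
    F2 (moderate fibrosis) >= 1.55 m/s
    F3 (severe fibrosis)   >= 1.67 m/s
    F4 (cirrhosis)         >= 1.72 m/s
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inversion import Elastogram

__all__ = [
    "VOI_SWS_THRESHOLD_MPS",
    "STAGE_CUTOFFS_MPS",
    "VoiMask",
    "SubjectStats",
    "build_voi",
    "summarize_map",
    "stage_fibrosis",
    "stage_label",
    "mean_stage",
    "subject_stats",
]

#: inclusive lower SWS bound for VOI membership (m/s)
VOI_SWS_THRESHOLD_MPS = 1.0

#: stage -> minimum mean SWS (m/s); inclusive (>=) thresholds
STAGE_CUTOFFS_MPS: dict[int, float] = {1: 1.52, 2: 1.55, 3: 1.67, 4: 1.72}


@dataclass
class VoiMask:
    """Boolean analysis mask with its voxel count and physical volume."""

    mask: np.ndarray
    voxel_count: int
    volume_cm3: float


@dataclass
class SubjectStats:
    """Per-subject VOI summary of the SWS and fluidity maps."""

    sws_mean_mps: float
    sws_sd_mps: float
    sws_cv_percent: float
    phi_mean_rad: float
    phi_sd_rad: float
    phi_cv_percent: float
    fibrosis_stage: int
    voi_volume_cm3: float


def build_voi(
    e: Elastogram,
    liver_mask: np.ndarray,
    threshold_mps: float = VOI_SWS_THRESHOLD_MPS,
) -> VoiMask:
    """Liver voxels with SWS >= threshold (inclusive at exactly 1.0 m/s)."""
    liver_mask = np.asarray(liver_mask, dtype=bool)
    if liver_mask.shape != e.sws_mps.shape:
        raise ValueError("liver mask does not match the map grid")
    mask = liver_mask & (e.sws_mps >= threshold_mps)
    if not mask.any():
        raise ValueError("empty VOI after SWS thresholding")
    voxel_cm3 = float(np.prod(e.voxel_size_mm)) / 1000.0
    count = int(mask.sum())
    return VoiMask(mask=mask, voxel_count=count, volume_cm3=count * voxel_cm3)


def summarize_map(map_values: np.ndarray, voi: VoiMask) -> tuple[float, float, float]:
    """Mean, sample SD (N-1) and CV (%) of a map inside the VOI.

    Raises ``ValueError`` when the VOI mean is nonpositive (CV undefined).
    """
    vals = np.asarray(map_values, dtype=np.float64)[voi.mask]
    if vals.size == 0:
        raise ValueError("empty VOI")
    mean = float(np.mean(vals))
    if mean <= 0:
        raise ValueError("CV undefined: VOI mean is nonpositive")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return mean, sd, 100.0 * sd / mean


def stage_fibrosis(
    sws_mean_mps: float, cutoffs: dict[int, float] | None = None
) -> int:
    """Fibrosis stage 0-4: highest stage whose cutoff is <= mean SWS."""
    if sws_mean_mps <= 0:
        raise ValueError("mean SWS must be positive")
    table = STAGE_CUTOFFS_MPS if cutoffs is None else cutoffs
    stage = 0
    for s in sorted(table):
        if sws_mean_mps >= table[s]:
            stage = s
    return stage


def stage_label(stage: int) -> str:
    """Ordinal stage as the conventional 'F0'..'F4' string."""
    if not 0 <= stage <= 4:
        raise ValueError("stage must be in 0..4")
    return f"F{stage}"


def mean_stage(stages) -> float:
    """Arithmetic mean of a nonempty list of integer stages 0-4."""
    stages = list(stages)
    if not stages:
        raise ValueError("empty stage list")
    if any(not 0 <= int(s) <= 4 for s in stages):
        raise ValueError("stages must be integers in 0..4")
    return float(np.mean(stages))


def subject_stats(
    e: Elastogram,
    liver_mask: np.ndarray,
    cutoffs: dict[int, float] | None = None,
    threshold_mps: float = VOI_SWS_THRESHOLD_MPS,
) -> SubjectStats:
    """VOI construction + map summaries + staging for one subject."""
    voi = build_voi(e, liver_mask, threshold_mps=threshold_mps)
    sws_mean, sws_sd, sws_cv = summarize_map(e.sws_mps, voi)
    phi_mean, phi_sd, phi_cv = summarize_map(e.phi_rad, voi)
    return SubjectStats(
        sws_mean_mps=sws_mean,
        sws_sd_mps=sws_sd,
        sws_cv_percent=sws_cv,
        phi_mean_rad=phi_mean,
        phi_sd_rad=phi_sd,
        phi_cv_percent=phi_cv,
        fibrosis_stage=stage_fibrosis(sws_mean, cutoffs),
        voi_volume_cm3=voi.volume_cm3,
    )
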