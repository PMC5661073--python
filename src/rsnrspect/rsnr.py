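"""The RSNR statistic: automatic LV segmentation and stress/rest SNR ratio.

For each acquisition the left ventricle is segmented by registering the
subject volume to the sex-matched template and warping the template's LV
mask back through the inverse transformation. The signal-to-noise ratio is
the mean divided by the sample standard deviation of the in-mask voxel
intensities; RSNR is SNR_stress / SNR_rest, with rest and stress segmented
independently (patient pose can differ between the two acquisitions). A
subject is called positive for triple-vessel disease when RSNR falls below
the decision cutoff (0.94 by default); the boundary value itself is negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .registration import (
    RegistrationConfig,
    apply_transform,
    estimate_normalization,
    invert_transform,
)
from .templates import TemplateSet
from .volumes import MaskVolume, Volume3D

__all__ = [
    "SnrResult",
    "RsnrRecord",
    "segment_lv",
    "compute_snr",
    "compute_rsnr",
    "run_pipeline",
    "classify_tvd",
    "DEFAULT_RSNR_CUTOFF",
]

DEFAULT_RSNR_CUTOFF = 0.94


class DegenerateVoiError(ValueError):
    """The VOI has zero intensity variance, so the SNR is undefined."""


@dataclass(frozen=True)
class SnrResult:
    """Mean, sample SD (n-1 denominator) and their ratio over a VOI."""

    mean: float
    sd: float
    snr: float
    n_voxels: int


@dataclass
class RsnrRecord:
    """Full RSNR provenance for one subject: both SNRs and both masks."""

    snr_rest: SnrResult
    snr_stress: SnrResult
    rsnr: float
    mask_rest: MaskVolume
    mask_stress: MaskVolume


def segment_lv(
    subject_volume: Volume3D,
    templates: TemplateSet,
    config: RegistrationConfig | None = None,
) -> MaskVolume:
    """Segment the LV myocardium of a subject volume via the template.

    The subject is spatially normalized to the template; the template LV
    mask is then carried back onto the subject grid through the inverse
    transformation. An empty warped mask signals a registration failure.
    """
    t = estimate_normalization(moving=subject_volume, fixed=templates.template, config=config)
    mask = apply_transform(templates.lv_mask, invert_transform(t), target=subject_volume.grid)
    if mask.n_voxels == 0:
        raise RuntimeError("segmentation produced an empty LV mask (registration failure)")
    return mask


def compute_snr(volume: Volume3D, mask: MaskVolume) -> SnrResult:
    """SNR = mean / sample SD of the voxel intensities inside the mask."""
    if mask.values.shape != volume.values.shape:
        raise ValueError("mask and volume must share a grid")
    vals = volume.values[mask.as_bool()]
    if vals.size < 2:
        raise ValueError(f"VOI needs at least 2 voxels, has {vals.size}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        raise DegenerateVoiError("constant VOI: SD is zero, SNR undefined")
    return SnrResult(mean=mean, sd=sd, snr=mean / sd, n_voxels=int(vals.size))


def compute_rsnr(rest: SnrResult, stress: SnrResult) -> float:
    """RSNR = SNR_stress / SNR_rest."""
    return stress.snr / rest.snr


def run_pipeline(
    rest: Volume3D,
    stress: Volume3D,
    templates: TemplateSet,
    sex: str | None = None,
    config: RegistrationConfig | None = None,
) -> RsnrRecord:
    """Segment rest and stress independently and compute both SNRs and RSNR.

    ``sex``, when given, must match the template set's sex. Fully
    deterministic for fixed inputs; no per-subject manual parameters.
    Failures are re-raised tagged with the acquisition that caused them.
    """
    if sex is not None and sex != templates.sex:
        raise ValueError(f"subject sex {sex!r} does not match template sex {templates.sex!r}")
    results = {}
    masks = {}
    for name, vol in (("rest", rest), ("stress", stress)):
        try:
            masks[name] = segment_lv(vol, templates, config=config)
            results[name] = compute_snr(vol, masks[name])
        except Exception as exc:  # noqa: BLE001 - tag acquisition, re-raise
            raise RuntimeError(f"RSNR pipeline failed on the {name} acquisition: {exc}") from exc
    return RsnrRecord(
        snr_rest=results["rest"],
        snr_stress=results["stress"],
        rsnr=compute_rsnr(results["rest"], results["stress"]),
        mask_rest=masks["rest"],
        mask_stress=masks["stress"],
    )


def classify_tvd(rsnr: float, cutoff: float = DEFAULT_RSNR_CUTOFF) -> str:
    """Binary TVD call: ``"positive"`` iff rsnr < cutoff (strict inequality).

    A value exactly at the cutoff is negative.
    """
    if rsnr <= 0:
        raise ValueError("RSNR must be positive")
    return "positive" if rsnr < cutoff else "negative"
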