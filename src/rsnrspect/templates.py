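"""Sex-specific template construction and LV mask delineation.

A template is the voxelwise average of normal rest studies after each has
been spatially normalized to one chosen reference subject. The LV mask is
delineated on the template by Otsu thresholding of the intensity histogram
(computed over voxels above a small floor so the empty background does not
dominate), keeping only the largest 26-connected component.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .registration import RegistrationConfig, apply_transform, estimate_normalization
from .volumes import MaskVolume, Volume3D, read_mask, read_volume, write_mask, write_volume

__all__ = [
    "TemplateSet",
    "otsu_threshold",
    "build_template",
    "delineate_template_mask",
    "make_template_set",
]


def otsu_threshold(values, n_bins: int = 256) -> float:
    """Histogram threshold maximizing the between-class variance.

    The sample is binned into ``n_bins`` equal-width bins; the returned
    threshold is the bin boundary t maximizing
    ``sigma_b^2(t) = w0 * w1 * (mu0 - mu1)^2`` where class 0 is the sample
    below t and class 1 the sample at or above t. When several boundaries
    tie for the maximum (the criterion is exactly flat across empty
    histogram gaps between well-separated modes) the midmost maximizing
    boundary is returned, so a clean bimodal sample is split near the middle
    of the gap. Raises ``ValueError`` on a constant sample.
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size < 2:
        raise ValueError("need at least 2 samples for a threshold")
    if n_bins < 2:
        raise ValueError("need at least 2 histogram bins")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise ValueError("constant sample has no Otsu threshold")
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    counts = counts.astype(float)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(counts)[:-1]  # mass strictly below each interior boundary
    w1 = total - w0
    s0 = np.cumsum(counts * centers)[:-1]
    s1 = counts @ centers - s0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, s0 / w0, 0.0)
        mu1 = np.where(w1 > 0, s1 / w1, 0.0)
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    # maximizer set with a relative tolerance: the plateau values agree only
    # up to floating-point summation order
    top = np.flatnonzero(sigma_b >= sigma_b.max() * (1.0 - 1e-12))
    best = int(round(top.mean()))
    return float(edges[1:-1][best])


def build_template(
    volumes: list[Volume3D],
    reference_index: int = 0,
    config: RegistrationConfig | None = None,
) -> Volume3D:
    """Average ``volumes`` on the grid of the reference subject.

    Every non-reference volume is spatially normalized to the reference and
    resampled onto its grid; the template is the voxelwise mean of the
    reference plus all normalized volumes. A normalization failure is
    re-raised with the offending subject index.
    """
    if len(volumes) < 2:
        raise ValueError("template construction needs at least 2 volumes")
    if not 0 <= reference_index < len(volumes):
        raise ValueError(f"reference index {reference_index} out of range")
    ref = volumes[reference_index]
    for i, v in enumerate(volumes):
        if v.dims != ref.dims or v.spacing != ref.spacing:
            raise ValueError(f"volume {i} is not on the shared acquisition grid")
    acc = ref.values.copy()
    for i, v in enumerate(volumes):
        if i == reference_index:
            continue
        try:
            t = estimate_normalization(moving=v, fixed=ref, config=config)
            warped = apply_transform(v, t, target=ref.grid)
        except Exception as exc:  # noqa: BLE001 - annotate subject, re-raise
            raise RuntimeError(f"spatial normalization failed for subject {i}: {exc}") from exc
        acc += warped.values
    return Volume3D(acc / len(volumes), ref.grid)


def delineate_template_mask(
    template: Volume3D, n_bins: int = 256, floor_fraction: float = 0.01
) -> MaskVolume:
    """Otsu-threshold the template and keep the largest 26-connected component.

    The histogram is built from voxels above ``floor_fraction`` of the
    maximum so that empty background does not dominate the threshold.
    """
    vals = template.values
    floor = floor_fraction * float(vals.max())
    sample = vals[vals > floor]
    if sample.size < 2 or float(np.ptp(sample)) == 0.0:
        raise ValueError("template is constant above the histogram floor")
    thr = otsu_threshold(sample, n_bins=n_bins)
    binary = vals > thr
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        raise ValueError("no voxels above the Otsu threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return MaskVolume((labels == keep).astype(np.uint8), template.grid)


@dataclass
class TemplateSet:
    """A sex-specific template image with its delineated LV mask."""

    sex: str
    template: Volume3D
    lv_mask: MaskVolume
    n_subjects: int

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.lv_mask.n_voxels == 0:
            raise ValueError("template LV mask is empty")
        if np.any(self.template.values < 0):
            raise ValueError("template intensities must be nonnegative")

    def save(self, directory: str | os.PathLike) -> None:
        """Write template + mask as NIfTI with a JSON sidecar."""
        os.makedirs(directory, exist_ok=True)
        d = str(directory)
        write_volume(self.template, os.path.join(d, f"template_{self.sex}.nii.gz"))
        write_mask(self.lv_mask, os.path.join(d, f"mask_{self.sex}.nii.gz"))
        with open(os.path.join(d, f"template_{self.sex}.json"), "w") as fh:
            json.dump({"sex": self.sex, "n_subjects": self.n_subjects}, fh, indent=2)

    @classmethod
    def load(cls, directory: str | os.PathLike, sex: str) -> "TemplateSet":
        d = str(directory)
        with open(os.path.join(d, f"template_{sex}.json")) as fh:
            meta = json.load(fh)
        return cls(
            sex=sex,
            template=read_volume(os.path.join(d, f"template_{sex}.nii.gz")),
            lv_mask=read_mask(os.path.join(d, f"mask_{sex}.nii.gz")),
            n_subjects=int(meta["n_subjects"]),
        )


def make_template_set(
    volumes: list[Volume3D],
    sex: str,
    reference_index: int = 0,
    config: RegistrationConfig | None = None,
) -> TemplateSet:
    """Build the template for one sex and delineate its LV mask."""
    template = build_template(volumes, reference_index=reference_index, config=config)
    mask = delineate_template_mask(template)
    return TemplateSet(sex=sex, template=template, lv_mask=mask, n_subjects=len(volumes))
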