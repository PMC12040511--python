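"""ROI quantification: per-muscle and whole-calf measures from FF maps.

Given a fat-fraction map (percent, 0-100) and an integer label map on
the same pixel grid, this module extracts for each muscle ROI the mean
fat fraction, cross-sectional area (CSA = pixel count x pixel area) and
remaining muscle area (RMA = CSA x (100 - FF)/100, a contractile-tissue
proxy), and aggregates them into a whole-calf summary whose FF is the
CSA-weighted average over all included muscles of both sides.

Muscles with gross imaging artifact are excluded whole (never pixelwise)
from the summary: in synthetic mode a muscle is flagged when the
artifact mask covers more than 5 % of its ROI; in real-data mode the
flag comes from the user's QC table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .muscles import LABELS

logger = logging.getLogger(__name__)

#: whole-muscle exclusion when artifact covers more than this ROI fraction
ARTIFACT_EXCLUSION_FRACTION = 0.05


@dataclass(frozen=True)
class MuscleMeasure:
    """Quantitative measures for one muscle ROI at one visit."""

    muscle: str
    side: str
    ff_mean: float          # %
    csa: float              # mm^2
    rma: float              # mm^2
    n_pixels: int
    artifact_excluded: bool = False
    n_nan_pixels: int = 0

    @property
    def missing(self) -> bool:
        return self.n_pixels == 0 or not np.isfinite(self.ff_mean)

    @property
    def included(self) -> bool:
        return not (self.missing or self.artifact_excluded)


@dataclass(frozen=True)
class CalfSummary:
    """Whole-calf summary over included muscles of both sides."""

    ff_weighted: float      # CSA-weighted mean FF, %
    csa_total: float        # mm^2
    rma_total: float        # mm^2 (summed per muscle, not re-derived)
    n_muscles_used: int

    @property
    def missing(self) -> bool:
        return self.n_muscles_used == 0


def remaining_muscle_area(csa: float, ff: float) -> float:
    """Remaining muscle area, RMA = CSA x (100 - FF) / 100.

    ``csa`` may be in any area unit (mm^2 internally, cm^2 in report
    tables); the result carries the same unit.
    """
    if not 0.0 <= ff <= 100.0:
        raise ValueError("fat fraction must lie in [0, 100]")
    if csa < 0:
        raise ValueError("CSA must be non-negative")
    return csa * (100.0 - ff) / 100.0


def measure_muscle(ff_map, label_map, label: int,
                   pixel_area_mm2: float = 1.0,
                   artifact_mask=None) -> MuscleMeasure:
    """Extract one muscle's measures from a whole-muscle ROI.

    The ROI is every pixel of ``label_map`` equal to ``label``.  NaN
    pixels within the ROI are excluded from the FF mean but still
    counted in the CSA (they are segmented tissue with a failed fit);
    their number is recorded and logged.  An empty ROI yields a
    missing-measure result rather than an exception.
    """
    ff_map = np.asarray(ff_map, dtype=float)
    label_map = np.asarray(label_map)
    if ff_map.shape != label_map.shape:
        raise ValueError("ff_map and label_map must share one pixel grid")
    if label not in LABELS:
        raise ValueError(f"unknown muscle label {label}")
    side, muscle = LABELS[label]

    roi = label_map == label
    n_pixels = int(roi.sum())
    if n_pixels == 0:
        logger.warning("label %d (%s %s): empty ROI", label, side, muscle)
        return MuscleMeasure(muscle, side, float("nan"), 0.0, float("nan"), 0)

    vals = ff_map[roi]
    nan_mask = ~np.isfinite(vals)
    n_nan = int(nan_mask.sum())
    if n_nan:
        logger.info("label %d (%s %s): %d/%d NaN pixels excluded from mean",
                    label, side, muscle, n_nan, n_pixels)
        vals = vals[~nan_mask]
    if vals.size == 0:
        return MuscleMeasure(muscle, side, float("nan"),
                             n_pixels * pixel_area_mm2, float("nan"),
                             n_pixels, n_nan_pixels=n_nan)

    ff_mean = float(vals.mean())
    csa = n_pixels * pixel_area_mm2
    excluded = False
    if artifact_mask is not None:
        overlap = float(np.asarray(artifact_mask, bool)[roi].mean())
        excluded = overlap > ARTIFACT_EXCLUSION_FRACTION
        if excluded:
            logger.info("label %d (%s %s): excluded, artifact covers %.1f%% "
                        "of ROI", label, side, muscle, 100 * overlap)
    return MuscleMeasure(muscle, side, ff_mean, csa,
                         remaining_muscle_area(csa, ff_mean), n_pixels,
                         artifact_excluded=excluded, n_nan_pixels=n_nan)


def quantify_image(ff_map, label_map, pixel_area_mm2: float = 1.0,
                   artifact_mask=None) -> list[MuscleMeasure]:
    """Measure all 12 muscle ROIs of one visit image."""
    return [measure_muscle(ff_map, label_map, lab, pixel_area_mm2,
                           artifact_mask) for lab in sorted(LABELS)]


def calf_summary(measures) -> CalfSummary:
    """CSA-weighted whole-calf summary over included muscles.

    Artifact-excluded and missing muscles are removed from both the
    numerator and denominator of the weighted FF.  The total RMA is the
    sum of per-muscle RMAs -- deliberately NOT ``csa_total x (100 -
    ff_weighted)/100``, which differs whenever FF varies across muscles
    (the two agree only for a uniform calf).
    """
    used = [m for m in measures if m.included]
    if not used:
        return CalfSummary(float("nan"), float("nan"), float("nan"), 0)
    csa_total = sum(m.csa for m in used)
    ff_weighted = sum(m.ff_mean * m.csa for m in used) / csa_total
    rma_total = sum(m.rma for m in used)
    return CalfSummary(float(ff_weighted), float(csa_total),
                       float(rma_total), len(used))


def load_nifti_pair(ff_path, label_path, artifact_path=None):
    """Load a single-slice FF/label NIfTI pair onto a shared 2-D grid.

    Returns ``(ff_map, label_map, artifact_mask_or_None, pixel_area_mm2)``.
    """
    import nibabel as nib

    ff_img = nib.load(str(ff_path))
    lab_img = nib.load(str(label_path))
    ff = np.squeeze(np.asarray(ff_img.dataobj, dtype=float))
    lab = np.squeeze(np.asarray(lab_img.dataobj)).astype(int)
    if ff.shape != lab.shape:
        raise ValueError("FF and label maps must share one pixel grid")
    zooms = ff_img.header.get_zooms()[:2]
    pixel_area = float(zooms[0]) * float(zooms[1])
    artifact = None
    if artifact_path is not None:
        artifact = np.squeeze(
            np.asarray(nib.load(str(artifact_path)).dataobj)).astype(bool)
    return ff, lab, artifact, pixel_area
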