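"""Functional lung segmentation from SPECT activity.

Functional lung is defined by a relative threshold: the lung voxels whose
tracer activity reaches a stated fraction (default 30%) of the maximum
activity found *within the lung mask*. The complement within the lung is
non-functional lung. The same rule serves both perfusion (Q) and ventilation
(V) SPECT; because the threshold is relative, the segmentation is invariant
to any positive rescaling of the counts.

The reference maximum is taken inside the lung mask rather than over the
whole field of view, so that injection-site or airway hot spots outside the
lung cannot depress the functional region. A robust reference (percentile of
in-lung activity) is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import BinaryMask, ImageGrid, mask_volume, require_alignment, validate_alignment

MODALITIES = ("perfusion", "ventilation")


@dataclass(frozen=True)
class FunctionalMask:
    """A functional-lung segmentation result.

    Attributes
    ----------
    mask
        Binary functional region; a subset of ``lung``.
    modality
        ``"perfusion"`` or ``"ventilation"``.
    threshold_fraction
        Fraction of ``reference_max`` a voxel must reach for inclusion.
    reference_max
        Activity value used as the 100% reference (max within lung by
        default).
    lung
        The anatomical lung mask the segmentation was restricted to.
    """

    mask: BinaryMask
    modality: str
    threshold_fraction: float
    reference_max: float
    lung: BinaryMask

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.reference_max <= 0:
            raise ValueError("reference_max must be positive")
        require_alignment(self.mask, self.lung, "functional mask and lung")
        if np.any(self.mask.values & ~self.lung.values):
            raise ValueError("functional mask extends outside the lung mask")


def segment_functional(
    activity: ImageGrid,
    lung: BinaryMask,
    threshold_fraction: float = 0.30,
    modality: str = "perfusion",
    inclusive: bool = True,
    reference_percentile: float | None = None,
) -> FunctionalMask:
    """Segment functional lung at a fraction of the in-lung maximum activity.

    Parameters
    ----------
    activity
        SPECT activity grid, aligned with ``lung``.
    lung
        Anatomical lung mask; must be non-empty.
    threshold_fraction
        In (0, 1]; default 0.30.
    inclusive
        If True (default), a voxel at exactly the threshold is functional
        (``activity >= t * reference``); if False the comparison is strict.
    reference_percentile
        If given (e.g. 99.0), use that percentile of in-lung activity as the
        reference instead of the strict maximum.
    """
    require_alignment(activity, lung, "activity and lung")
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError(f"threshold_fraction must be in (0, 1], got {threshold_fraction}")
    if lung.voxel_count == 0:
        raise ValueError("lung mask is empty")
    in_lung = activity.values[lung.values]
    if reference_percentile is None:
        ref = float(in_lung.max())
    else:
        if not 0.0 < reference_percentile <= 100.0:
            raise ValueError("reference_percentile must be in (0, 100]")
        ref = float(np.percentile(in_lung, reference_percentile))
    if ref <= 0:
        raise ValueError(
            f"no functional reference: maximum {modality} activity within lung is {ref}"
        )
    cut = threshold_fraction * ref
    keep = activity.values >= cut if inclusive else activity.values > cut
    out = BinaryMask(keep & lung.values, spacing=lung.spacing, origin=lung.origin)
    return FunctionalMask(
        mask=out,
        modality=modality,
        threshold_fraction=float(threshold_fraction),
        reference_max=ref,
        lung=lung,
    )


def mismatch_report(q_func: FunctionalMask, v_func: FunctionalMask) -> dict:
    """Quantify V/Q mismatch between two functional masks of the same lung.

    Returns matched (Q∩V), perfusion-only (Q∖V) and ventilation-only (V∖Q)
    volumes in cm^3 plus each as a fraction of the anatomical lung volume.
    Ventilation-only defects with preserved perfusion (``q_only``) are the
    COPD-typical mismatch pattern.
    """
    require_alignment(q_func.mask, v_func.mask, "Q and V functional masks")
    if not validate_alignment(q_func.lung, v_func.lung) or not np.array_equal(
        q_func.lung.values, v_func.lung.values
    ):
        raise ValueError("functional masks derive from different lung masks")
    q, v = q_func.mask.values, v_func.mask.values
    geom = dict(spacing=q_func.mask.spacing, origin=q_func.mask.origin)
    matched = BinaryMask(q & v, **geom)
    q_only = BinaryMask(q & ~v, **geom)
    v_only = BinaryMask(v & ~q, **geom)
    lung_vol = mask_volume(q_func.lung)
    out = {
        "matched_volume_cm3": mask_volume(matched),
        "q_only_volume_cm3": mask_volume(q_only),
        "v_only_volume_cm3": mask_volume(v_only),
    }
    out.update(
        {
            "matched_fraction": out["matched_volume_cm3"] / lung_vol,
            "q_only_fraction": out["q_only_volume_cm3"] / lung_vol,
            "v_only_fraction": out["v_only_volume_cm3"] / lung_vol,
        }
    )
    return out
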