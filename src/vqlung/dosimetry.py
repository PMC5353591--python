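"""Dose–volume metrics over anatomical and functional lung.

The six per-patient quantities of interest are the anatomical V20 and mean
lung dose (MLD) over the whole lung mask, and their functional counterparts
Q-V20 / Q-MLD / V-V20 / V-MLD computed over the perfusion- and
ventilation-functional masks. Vx is the percentage of a region's volume
receiving at least x Gy (default x = 20); MLD is the arithmetic mean dose
over the region. Relative volume is by voxel count — within one grid every
voxel has the same volume — and the denominator of a functional Vx is the
functional region itself, so a functional DVH starts at 100% like the
anatomical one.

The Vx dose comparison defaults to ``>= x`` (standard cumulative-DVH and
treatment-planning-system convention); a strict ``>`` mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import BinaryMask, ImageGrid, require_alignment, validate_alignment
from .segmentation import FunctionalMask


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose–volume histogram for one region.

    ``volume_pct[i]`` is the percentage of the region receiving at least
    ``bin_edges[i]`` Gy; the curve is non-increasing and starts at 100%.
    """

    bin_edges: np.ndarray
    volume_pct: np.ndarray
    mask_label: str = "lung"

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        pct = np.asarray(self.volume_pct, dtype=float)
        if edges.ndim != 1 or edges.shape != pct.shape:
            raise ValueError("bin_edges and volume_pct must be 1D arrays of equal length")
        if edges[0] != 0 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must ascend from 0")
        if np.any(np.diff(pct) > 1e-12):
            raise ValueError("cumulative volume must be non-increasing")
        if pct[0] != 100.0 or np.any(pct < 0) or np.any(pct > 100):
            raise ValueError("volume_pct must start at 100 and lie in [0, 100]")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "volume_pct", pct)

    def value_at(self, dose_gy: float) -> float:
        """Curve value at an arbitrary dose.

        Exact at edges; between edges the next (higher) edge's value is used —
        a lower bound on the receiving fraction — and 0 beyond the top edge.
        """
        if dose_gy < 0:
            raise ValueError("dose must be non-negative")
        if dose_gy > self.bin_edges[-1]:
            return 0.0
        idx = int(np.searchsorted(self.bin_edges, dose_gy, side="left"))
        return float(self.volume_pct[idx])


@dataclass(frozen=True)
class MetricRecord:
    """The six dosimetric metrics for one patient (%, Gy)."""

    V20: float
    MLD: float
    Q_V20: float
    Q_MLD: float
    V_V20: float
    V_MLD: float
    provenance: dict = field(default_factory=dict, compare=False)

    METRIC_NAMES = ("V20", "MLD", "Q_V20", "Q_MLD", "V_V20", "V_MLD")

    def __post_init__(self):
        for name in ("V20", "Q_V20", "V_V20"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]%")
        for name in ("MLD", "Q_MLD", "V_MLD"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 Gy")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.METRIC_NAMES}


def _masked_dose(dose: ImageGrid, mask: BinaryMask, what: str) -> np.ndarray:
    require_alignment(dose, mask, f"dose and {what}")
    if mask.voxel_count == 0:
        raise ValueError(f"{what} is empty")
    return dose.values[mask.values]


def cumulative_dvh(
    dose: ImageGrid, mask: BinaryMask, bin_width: float = 0.1, mask_label: str = "lung"
) -> DVHCurve:
    """Cumulative DVH with edges 0, w, 2w, ... up to ceil(max/w)*w inclusive."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = _masked_dose(dose, mask, f"mask '{mask_label}'")
    n_bins = max(1, math.ceil(d.max() / bin_width - 1e-12))
    edges = np.arange(n_bins + 1) * bin_width
    # count of voxels with dose >= edge: sorted search is exact for floats
    ds = np.sort(d)
    counts = d.size - np.searchsorted(ds, edges, side="left")
    pct = 100.0 * counts / d.size
    return DVHCurve(bin_edges=edges, volume_pct=pct, mask_label=mask_label)


def mean_dose(dose: ImageGrid, mask: BinaryMask) -> float:
    """Arithmetic mean dose (Gy) over the mask voxels."""
    return float(_masked_dose(dose, mask, "mask").mean())


def vx(dose: ImageGrid, mask: BinaryMask, x: float = 20.0, inclusive: bool = True) -> float:
    """Percent of mask volume receiving >= x Gy (or > x with ``inclusive=False``)."""
    if x < 0:
        raise ValueError("x must be >= 0 Gy")
    d = _masked_dose(dose, mask, "mask")
    hit = d >= x if inclusive else d > x
    return 100.0 * float(np.count_nonzero(hit)) / d.size


def compute_metrics(
    dose: ImageGrid,
    lung: BinaryMask,
    q_func: FunctionalMask,
    v_func: FunctionalMask,
    x: float = 20.0,
    inclusive: bool = True,
    provenance: dict | None = None,
) -> MetricRecord:
    """The six-metric record for one patient.

    Functional Vx uses the functional mask as its own denominator. Empty
    functional masks are rejected with the modality named.
    """
    require_alignment(dose, lung, "dose and lung")
    for fm in (q_func, v_func):
        require_alignment(dose, fm.mask, f"dose and {fm.modality} functional mask")
        if not validate_alignment(fm.lung, lung) or not np.array_equal(
            fm.lung.values, lung.values
        ):
            raise ValueError(f"{fm.modality} functional mask derives from a different lung mask")
        if fm.mask.voxel_count == 0:
            raise ValueError(f"{fm.modality} functional mask is empty")
    return MetricRecord(
        V20=vx(dose, lung, x, inclusive),
        MLD=mean_dose(dose, lung),
        Q_V20=vx(dose, q_func.mask, x, inclusive),
        Q_MLD=mean_dose(dose, q_func.mask),
        V_V20=vx(dose, v_func.mask, x, inclusive),
        V_MLD=mean_dose(dose, v_func.mask),
        provenance=provenance or {},
    )


def activity_weighted_metrics(
    dose: ImageGrid,
    activity: ImageGrid,
    lung: BinaryMask,
    x: float = 20.0,
    inclusive: bool = True,
) -> dict:
    """Activity-weighted alternative to the binary-mask metrics.

    fMLD = sum(activity * dose) / sum(activity) over the lung;
    fVx = 100 * sum(activity where dose >= x) / sum(activity). With uniform
    activity these reduce exactly to ``mean_dose`` and ``vx``. Non-default
    mode: the binary 30%-of-max functional region is the primary definition.
    """
    require_alignment(dose, lung, "dose and lung")
    require_alignment(activity, lung, "activity and lung")
    if lung.voxel_count == 0:
        raise ValueError("lung mask is empty")
    a = activity.values[lung.values]
    d = dose.values[lung.values]
    total = a.sum()
    if total <= 0:
        raise ValueError("total activity within lung is zero")
    hit = d >= x if inclusive else d > x
    return {
        "fMLD": float((a * d).sum() / total),
        "fVx": 100.0 * float(a[hit].sum() / total),
    }


def dvh_to_dataframe(curve: DVHCurve):
    """DVH as a DataFrame with columns dose_gy, volume_pct, mask_label."""
    import pandas as pd

    return pd.DataFrame(
        {
            "dose_gy": curve.bin_edges,
            "volume_pct": curve.volume_pct,
            "mask_label": curve.mask_label,
        }
    )
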