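"""Virtual MRI: threshold masks and circle-equivalent radii.

MRI does not show tumor cells directly.  The package mimics the clinical
readouts with density thresholds:

* T1Gd-enhancing region — total cell density (c + h + n + v) at or above
  80% of the carrying capacity, where contrast leaks through tumor-induced
  neovasculature;
* bulk-tumor region — abnormal cells (normoxic + hypoxic + necrotic, the
  vasculature excluded) at or above 16% of the carrying capacity, i.e. a
  density five-fold lower than the T1Gd threshold;
* edema (T2/FLAIR-like) region — edematous fluid at or above 50% of the
  capillary fluid level.

All thresholds are closed (>=).  Region sizes are summarized as the radius
of the circle with the same area; no connected-component filtering is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import StateFields


class ImagingError(ValueError):
    """Invalid imaging configuration or incomplete trajectory."""


@dataclass(frozen=True)
class ImagingThresholds:
    """Density fractions defining the three virtual-imaging regions."""

    t1gd_fraction: float = 0.80
    tumor_fraction: float = 0.16
    edema_fraction: float = 0.50

    def __post_init__(self) -> None:
        for name in ("t1gd_fraction", "tumor_fraction", "edema_fraction"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ImagingError(f"{name} must be in (0, 1], got {value}")


def t1gd_mask(state: StateFields, params=None,
              thresholds: ImagingThresholds | None = None) -> np.ndarray:
    """Voxels whose total cell density (all four cellular species) reaches
    the T1Gd fraction of the carrying capacity."""
    thresholds = thresholds or ImagingThresholds()
    total = state.c + state.h + state.n + state.v
    return total >= thresholds.t1gd_fraction


def tumor_extent_mask(state: StateFields, params=None,
                      thresholds: ImagingThresholds | None = None) -> np.ndarray:
    """Voxels whose abnormal-cell density (normoxic + hypoxic + necrotic;
    vasculature excluded) reaches the bulk-tumor fraction."""
    thresholds = thresholds or ImagingThresholds()
    return (state.c + state.h + state.n) >= thresholds.tumor_fraction


def edema_mask(state: StateFields, params=None,
               thresholds: ImagingThresholds | None = None) -> np.ndarray:
    """Voxels whose edematous-fluid fraction (of the capillary level l_v)
    reaches the edema fraction.  The fluid field is stored normalized to
    l_v, so the comparison is direct."""
    thresholds = thresholds or ImagingThresholds()
    l_v = getattr(params, "l_v", 1.0) if params is not None else 1.0
    return state.l / l_v >= thresholds.edema_fraction


def equivalent_radius(mask: np.ndarray, spacing: float,
                      mode: str = "circle",
                      slab_thickness_mm: float | None = None) -> float:
    """Radius (mm) of the circle whose area equals the mask's area.

    The paper-style "spherically symmetric equivalent radius" on a 2D slice
    is read as the circle-equivalent radius sqrt(area / pi).  A
    sphere-equivalent alternative requires an explicit slab thickness:
    ``mode='sphere'`` with ``slab_thickness_mm`` returns
    (3 * area * thickness / (4 pi)) ** (1/3).
    """
    area = float(np.count_nonzero(mask)) * spacing**2
    if mode == "circle":
        return float(np.sqrt(area / np.pi))
    if mode == "sphere":
        if slab_thickness_mm is None or slab_thickness_mm <= 0:
            raise ImagingError(
                "sphere-equivalent radius needs a positive slab_thickness_mm")
        return float((3.0 * area * slab_thickness_mm / (4.0 * np.pi)) ** (1.0 / 3.0))
    raise ImagingError(f"unknown equivalent-radius mode {mode!r}")


def radius_series(trajectory, check_nesting: bool = True) -> pd.DataFrame:
    """Per-day table (day, r_t1gd_mm, r_tumor_mm, r_edema_mm, treatment_on)
    from a simulated trajectory.

    Verifies the nesting invariant r_tumor >= r_t1gd (the 16% region
    contains the 80% region up to the vasculature's contribution).
    """
    if not trajectory.records:
        raise ImagingError("trajectory has no observer records")
    needed = {"day", "r_t1gd_mm", "r_tumor_mm", "r_edema_mm", "treatment_on"}
    missing = needed - set(trajectory.records[0])
    if missing:
        raise ImagingError(f"trajectory records missing {sorted(missing)}")
    columns = ["day", "r_t1gd_mm", "r_tumor_mm", "r_edema_mm", "treatment_on"]
    df = pd.DataFrame(trajectory.records)[columns]
    if not np.all(np.diff(df["day"].to_numpy()) > 0):
        raise ImagingError("trajectory days are not strictly increasing")
    if check_nesting and np.any(df["r_tumor_mm"] < df["r_t1gd_mm"] - 1e-9):
        raise ImagingError("nesting violated: r_tumor < r_t1gd")
    return df
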