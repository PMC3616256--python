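"""Tissue-label domains: synthetic brain phantom, label-image IO, invasion field.

Coordinate convention (used everywhere in the package): 0-based voxel indices
``(ix, iy)``; the center of voxel ``(ix, iy)`` sits at physical position
``origin + (ix + 0.5, iy + 0.5) * spacing`` in mm.  Label arrays are indexed
``labels[ix, iy]``.

Glioma cells invade white matter faster than gray matter and are excluded
from cerebral spinal fluid (CSF), so the invasion rate ``D(x)`` is piecewise
constant over the labels: ``D_w`` in white matter, ``D_g`` in gray matter,
zero in CSF and outside the brain.  The solver goes further and removes
CSF/OUTSIDE voxels from the unknown set entirely, so neither cells nor fluid
can ever occupy them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

OUTSIDE = 0
WHITE = 1
GRAY = 2
CSF = 3

#: Default integer coding for label images.
DEFAULT_LABEL_MAPPING: dict[str, int] = {
    "OUTSIDE": OUTSIDE, "WHITE": WHITE, "GRAY": GRAY, "CSF": CSF,
}

LABEL_NAMES = {v: k for k, v in DEFAULT_LABEL_MAPPING.items()}


class GeometryError(ValueError):
    """Invalid domain geometry (sizing, labels, file format)."""


@dataclass
class TissueMap:
    """A labelled 2D grid of brain tissue.

    Attributes
    ----------
    labels : (nx, ny) int array with values in {OUTSIDE, WHITE, GRAY, CSF}
    spacing : voxel edge length in mm
    origin : physical coordinate (mm) of the *corner* of voxel (0, 0); the
        voxel center is at origin + spacing/2.
    """

    labels: np.ndarray
    spacing: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise GeometryError(
                f"labels must be 2D, got {self.labels.ndim}D")
        if self.spacing <= 0:
            raise GeometryError(f"spacing must be > 0, got {self.spacing}")
        bad = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if bad:
            raise GeometryError(f"unknown label value(s): {sorted(bad)}")

    @property
    def nx(self) -> int:
        return self.labels.shape[0]

    @property
    def ny(self) -> int:
        return self.labels.shape[1]

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical size (mm) of the grid."""
        return (self.nx * self.spacing, self.ny * self.spacing)

    @property
    def mask(self) -> np.ndarray:
        """Simulation mask: gray + white matter.  CSF/OUTSIDE never hold
        cells or fluid."""
        return (self.labels == WHITE) | (self.labels == GRAY)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical center coordinates (mm) as broadcastable (nx,1), (1,ny)."""
        x = self.origin[0] + (np.arange(self.nx) + 0.5) * self.spacing
        y = self.origin[1] + (np.arange(self.ny) + 0.5) * self.spacing
        return x[:, None], y[None, :]

    def voxel_at(self, x: float, y: float) -> tuple[int, int]:
        """Index of the voxel containing physical point (x, y) mm."""
        ix = int(np.floor((x - self.origin[0]) / self.spacing))
        iy = int(np.floor((y - self.origin[1]) / self.spacing))
        if not (0 <= ix < self.nx and 0 <= iy < self.ny):
            raise GeometryError(f"point ({x}, {y}) mm outside the grid")
        return ix, iy

    def inscribed_radius_mm(self) -> float:
        """Radius of the largest disc of brain tissue centered on the
        mask's centroid; used to stop runs before boundary artifacts."""
        from scipy.ndimage import distance_transform_edt

        dist = distance_transform_edt(self.mask, sampling=self.spacing)
        return float(dist.max())


def generate_phantom(
    nx: int = 147,
    ny: int = 185,
    spacing: float = 1.0,
    with_ventricles: bool = True,
    seed: int = 0,
    rim_wobble_mm: float = 0.0,
) -> TissueMap:
    """Build the synthetic axial-slice brain phantom.

    An elliptical brain with a gray-matter cortical rim, white-matter
    interior, and (optionally) two elliptical CSF ventricles, standing in
    for an atlas-derived slice.  The default 147 x 185 voxel grid at 1 mm
    spacing spans [0, 147] mm x [0, 185] mm.  The shape is fixed and
    versioned; ``seed`` only drives the optional cortical-rim wobble
    (``rim_wobble_mm > 0``), so the default phantom is identical for every
    seed.

    Raises
    ------
    GeometryError
        If the grid is too small to contain the rim structure.
    """
    if nx < 16 or ny < 16:
        raise GeometryError(f"grid {nx}x{ny} too small; need at least 16x16")
    if spacing <= 0:
        raise GeometryError(f"spacing must be > 0, got {spacing}")

    Lx, Ly = nx * spacing, ny * spacing
    cx, cy = Lx / 2.0, Ly / 2.0
    # Outer (pial) ellipse and white-matter ellipse; rim >= 2 voxels thick.
    a_out, b_out = 0.42 * Lx, 0.46 * Ly
    rim = max(2.0 * spacing, 0.04 * min(Lx, Ly))
    a_in, b_in = a_out - rim, b_out - rim
    if a_in <= 2 * spacing or b_in <= 2 * spacing:
        raise GeometryError(
            f"grid {nx}x{ny} at {spacing} mm cannot hold the cortical rim")

    x, y = TissueMap(np.zeros((nx, ny), dtype=np.int8), spacing).voxel_centers()
    dx, dy = x - cx, y - cy

    theta = np.arctan2(dy / b_out, dx / a_out)
    if rim_wobble_mm > 0.0:
        rng = np.random.default_rng(seed)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        wobble = rim_wobble_mm * sum(
            np.sin((k + 3) * theta + phases[k]) for k in range(3)) / 3.0
    else:
        wobble = 0.0

    r_out = np.sqrt((dx / a_out) ** 2 + (dy / b_out) ** 2)
    r_in = np.sqrt((dx / a_in) ** 2 + (dy / b_in) ** 2)
    scale = 1.0 + wobble / min(a_out, b_out)

    labels = np.full((nx, ny), OUTSIDE, dtype=np.int8)
    labels[r_out <= scale] = GRAY
    labels[r_in <= scale] = WHITE

    if with_ventricles:
        va, vb = 0.04 * Lx, 0.085 * Ly
        for sign in (-1.0, 1.0):
            vx, vy = cx + sign * 0.09 * Lx, cy
            inside = ((dx - sign * 0.09 * Lx) / va) ** 2 + ((dy) / vb) ** 2 <= 1.0
            labels[inside & (labels == WHITE)] = CSF
        if not np.any(labels == CSF):
            raise GeometryError(
                f"grid {nx}x{ny} at {spacing} mm too coarse for ventricles")

    return TissueMap(labels=labels, spacing=spacing)


def invasion_field(tissue: TissueMap, D_w: float, D_g: float,
                   strict: bool = False) -> np.ndarray:
    """Piecewise-constant invasion rate: D_w on white, D_g on gray, 0 on
    CSF/OUTSIDE.  Units follow the inputs (typically mm^2/year).

    White-matter invasion exceeds gray-matter invasion (myelinated tracts);
    ``D_w <= D_g`` warns, or raises when ``strict``.
    """
    if D_w <= 0 or D_g <= 0:
        raise GeometryError(f"invasion rates must be > 0 (D_w={D_w}, D_g={D_g})")
    if D_w <= D_g:
        msg = f"expected D_w > D_g, got D_w={D_w} <= D_g={D_g}"
        if strict:
            raise GeometryError(msg)
        warnings.warn(msg, stacklevel=2)
    D = np.zeros(tissue.labels.shape, dtype=float)
    D[tissue.labels == WHITE] = D_w
    D[tissue.labels == GRAY] = D_g
    return D


# ------------------------------------------------------------------- file IO

def write_tissue_labels(tissue: TissueMap, path: str | Path) -> None:
    """Write a label image: NIfTI (.nii/.nii.gz) or plain-text grid (.txt).

    The text dialect holds one grid row per line (``iy`` fixed per line,
    ``ix`` varying), integer labels separated by spaces.
    """
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        import nibabel as nib

        affine = np.diag([tissue.spacing, tissue.spacing, 1.0, 1.0])
        img = nib.Nifti1Image(tissue.labels.astype(np.int16), affine)
        nib.save(img, str(path))
    else:
        header = f"# spacing_mm={tissue.spacing!r}\n"
        rows = "\n".join(
            " ".join(str(int(v)) for v in tissue.labels[:, iy])
            for iy in range(tissue.ny))
        path.write_text(header + rows + "\n")


def read_tissue_labels(
    path: str | Path,
    label_mapping: dict[str, int] | None = None,
    spacing: float | None = None,
) -> TissueMap:
    """Read a label image written by :func:`write_tissue_labels` (or any
    2D integer NIfTI / text grid).

    ``label_mapping`` maps category names (OUTSIDE/WHITE/GRAY/CSF) to the
    integers used in the file; every integer present must be mapped.
    Spacing comes from file metadata when present, else from ``spacing``.
    """
    path = Path(path)
    mapping = dict(label_mapping or DEFAULT_LABEL_MAPPING)
    unknown_names = set(mapping) - set(DEFAULT_LABEL_MAPPING)
    if unknown_names:
        raise GeometryError(f"unknown label categories: {sorted(unknown_names)}")

    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise GeometryError(f"expected a 2D label image, got {data.ndim}D")
        file_spacing = float(img.header.get_zooms()[0])
        spacing = file_spacing if file_spacing > 0 else spacing
    else:
        lines = path.read_text().splitlines()
        body = []
        for line in lines:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                # file metadata takes precedence over the config fallback
                if "spacing_mm=" in line:
                    spacing = float(line.split("spacing_mm=")[1])
                continue
            body.append([int(tok) for tok in line.split()])
        if not body:
            raise GeometryError(f"empty label file: {path}")
        data = np.array(body).T  # lines are iy-rows

    if spacing is None:
        spacing = 1.0

    inverse = {v: DEFAULT_LABEL_MAPPING[k] for k, v in mapping.items()}
    values = np.unique(data)
    unmapped = [int(v) for v in values if int(v) not in inverse]
    if unmapped:
        raise GeometryError(
            f"label value(s) {unmapped} in {path.name} have no mapping")
    labels = np.zeros(data.shape, dtype=np.int8)
    for file_value, internal in inverse.items():
        labels[data == file_value] = internal
    return TissueMap(labels=labels, spacing=float(spacing))
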