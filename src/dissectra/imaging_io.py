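"""Image, mesh and table I/O for the dissection-analysis pipeline.

Volumes are exchanged as single-image NIfTI-1 files, surfaces as STL
(ASCII or binary), and the published 16-case measurement tables ship with
the package as CSV fixtures.  World coordinates are millimetres with a
right-handed axis-aligned grid whose origin sits at the volume corner;
conversions to cm/cm³ happen only at reporting boundaries.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "ImageVolume",
    "LumenLabelMap",
    "SurfaceMesh",
    "CohortTable",
    "read_volume",
    "write_volume",
    "read_stl",
    "write_stl",
    "load_paper_tables",
]

STAGES = ("pre", "post", "fu")


@dataclass
class ImageVolume:
    """A 3D scalar grid in Hounsfield-like units.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities.
    spacing_mm : tuple of float
        Strictly positive voxel edge lengths (dx, dy, dz) in mm.
    origin_mm : tuple of float
        World position of the corner of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel: the product of the (possibly anisotropic) spacings."""
        return float(np.prod(self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (mm) of all voxel centers, shape ``(*shape, 3)``."""
        axes = [
            self.origin_mm[i] + (np.arange(self.data.shape[i]) + 0.5) * self.spacing_mm[i]
            for i in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)


@dataclass
class SurfaceMesh:
    """A triangle surface in world mm: ``vertices`` (n, 3) and ``faces`` (m, 3)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def open_edge_count(self) -> int:
        """Number of edges not shared by exactly two faces (0 for a watertight mesh)."""
        edges = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.sum(counts != 2))

    @property
    def watertight(self) -> bool:
        return self.open_edge_count() == 0


@dataclass
class LumenLabelMap:
    """Per-voxel lumen labels on the same grid as an :class:`ImageVolume`.

    Label values: 0 background, 1 true lumen (TL), 2 false lumen (FL),
    3 intimal flap.
    """

    BACKGROUND = 0
    TL = 1
    FL = 2
    FLAP = 3

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must be integer-valued")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def mask(self, *labels: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        return np.isin(self.data, labels)

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.data.astype(np.int16), self.spacing_mm, self.origin_mm)


# ---------------------------------------------------------------------------
# NIfTI volumes

def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` as a single-image NIfTI-1 file.

    The affine is diagonal (axis-aligned grid); the translation places voxel
    (0,0,0)'s *center* at ``origin + spacing/2`` so that corner-origin world
    coordinates round-trip exactly.
    """
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    affine[:3, 3] = np.asarray(vol.origin_mm) + 0.5 * np.asarray(vol.spacing_mm)
    img = nib.Nifti1Image(np.asarray(vol.data), affine)
    zooms = vol.spacing_mm
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ImageVolume:
    """Read a single-image NIfTI-1 volume written by :func:`write_volume`.

    Raises
    ------
    ValueError
        If the image is not 3D or uses an off-diagonal (rotated/sheared) affine,
        which this corner-origin dialect does not represent.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"unsupported NIfTI: expected a single 3D image, got shape {data.shape}")
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError("unsupported NIfTI: non-axis-aligned affine")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError("unsupported NIfTI: non-positive or flipped voxel spacing")
    origin = affine[:3, 3] - 0.5 * spacing
    return ImageVolume(data=data, spacing_mm=tuple(spacing), origin_mm=tuple(origin))


# ---------------------------------------------------------------------------
# STL surfaces

def write_stl(mesh: SurfaceMesh, path: str | Path, ascii: bool = False) -> None:
    """Write a triangle mesh as binary (default) or ASCII STL."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    file_type = "stl_ascii" if ascii else "stl"
    data = trimesh.exchange.export.export_mesh(tm, None, file_type=file_type)
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)


def read_stl(path: str | Path) -> SurfaceMesh:
    """Read an STL file (ASCII or binary), deduplicating vertices within 1e-6 mm.

    Triangle winding is preserved as stored in the file.
    """
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # corrupt facet count, truncated file, ...
        raise ValueError(f"cannot parse STL file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"STL file {path} contains no triangles")
    tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# Cohort tables

@dataclass
class CohortTable:
    """The 16-case measurement tables in long form.

    ``data`` has one row per (case_id, stage) with columns ``tl_vol_cm3``,
    ``fl_vol_cm3``, ``tl_pmc_cm``, ``fli`` (as printed), ``fli_recomputed``
    (FL/TL from the printed volumes, full precision), ``total_vol_cm3`` and
    ``followup_months``.  Case 6 has no preoperative scan; its pre-stage
    measurement fields are NaN.
    """

    data: pd.DataFrame = field(repr=False)

    def rows(self, stage: str | None = None, dropna: str | None = None) -> pd.DataFrame:
        out = self.data
        if stage is not None:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
            out = out[out["stage"] == stage]
        if dropna is not None:
            out = out[out[dropna].notna()]
        return out

    def value(self, case_id: int, stage: str, column: str) -> float:
        row = self.data[(self.data["case_id"] == case_id) & (self.data["stage"] == stage)]
        if row.empty:
            raise KeyError(f"no row for case {case_id} stage {stage!r}")
        return float(row.iloc[0][column])

    def audit(self, atol: float = 0.01) -> pd.DataFrame:
        """Internal-consistency audit of the printed tables.

        For every row where all relevant values are printed, checks that the
        total aortic volume equals TL + FL within ``atol`` cm³ and the printed
        FLI equals FL/TL within ``atol``.  Returns the per-row audit frame and
        raises ``AssertionError`` on any violation.
        """
        d = self.data.copy()
        have_vols = d["tl_vol_cm3"].notna() & d["fl_vol_cm3"].notna()
        d["sum_check"] = np.where(
            have_vols & d["total_vol_cm3"].notna(),
            np.abs(d["tl_vol_cm3"] + d["fl_vol_cm3"] - d["total_vol_cm3"]),
            np.nan,
        )
        d["fli_check"] = np.where(
            have_vols & d["fli"].notna(),
            np.abs(d["fl_vol_cm3"] / d["tl_vol_cm3"] - d["fli"]),
            np.nan,
        )
        bad = d[(d["sum_check"] > atol) | (d["fli_check"] > atol)]
        if not bad.empty:
            raise AssertionError(f"cohort table inconsistent rows:\n{bad}")
        return d


def _fixture_path(name: str) -> Path:
    return Path(str(importlib.resources.files("dissectra") / "data" / name))


def load_paper_tables() -> CohortTable:
    """Load the packaged 16-case tables (48 rows: 16 cases × pre/post/fu).

    The published FLI column is kept as printed; ``fli_recomputed`` carries
    FL/TL from the printed volumes at full precision, since whether the source
    rounded before or after the division is not documented.
    """
    t1 = pd.read_csv(_fixture_path("table1.csv"))
    t2 = pd.read_csv(_fixture_path("table2.csv"))
    merged = t2.merge(t1, on=["case_id", "stage"], how="outer")
    merged["stage"] = pd.Categorical(merged["stage"], categories=list(STAGES), ordered=True)
    merged = merged.sort_values(["case_id", "stage"]).reset_index(drop=True)
    merged["fli_recomputed"] = merged["fl_vol_cm3"] / merged["tl_vol_cm3"]
    return CohortTable(data=merged)
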