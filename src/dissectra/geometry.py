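"""Geometric read-outs of a segmented dissection.

Implements the measurement protocol: lumen volumes by voxel counting, a
centerline from the ridge of the interior distance transform, cross-sections
orthogonal to the centerline tangent, the plane of maximum compression (PMC)
as the section with the smallest true-lumen equivalent diameter within the
dissected extent, and the false lumen index FLI = FL volume / TL volume.

"Diameter" is the equivalent-circle diameter 2*sqrt(A/pi) of the sectional
TL area; sections are sampled on a sub-voxel in-plane grid at one quarter of
the voxel pitch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage
from scipy.spatial import cKDTree
from skimage.graph import MCP_Geometric, route_through_array

from .imaging_io import LumenLabelMap

__all__ = [
    "Centerline",
    "CrossSection",
    "CaseMeasurement",
    "voxel_volume",
    "extract_centerline",
    "cross_sections",
    "find_pmc",
    "fli",
    "measure_case",
]


# ---------------------------------------------------------------------------
# volumes

def voxel_volume(labels: LumenLabelMap, label: int) -> float:
    """Volume of one label in cm³: voxel count times the voxel volume.

    The voxel volume is the product of the (possibly anisotropic) spacings.
    """
    valid = {LumenLabelMap.TL, LumenLabelMap.FL, LumenLabelMap.FLAP, LumenLabelMap.BACKGROUND}
    if label not in valid:
        raise ValueError(f"unknown label {label}; expected one of {sorted(valid)}")
    count = int(np.count_nonzero(labels.data == label))
    return count * labels.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# centerline

@dataclass
class Centerline:
    """Ordered centerline samples: points (mm), arc length s (mm), unit tangents."""

    points: np.ndarray
    s_mm: np.ndarray
    tangents: np.ndarray
    step_mm: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.s_mm) <= 0):
            raise ValueError("arc length must be strictly increasing")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("tangents must be unit vectors")

    @property
    def length_mm(self) -> float:
        return float(self.s_mm[-1] - self.s_mm[0])

    def reversed(self) -> "Centerline":
        pts = self.points[::-1].copy()
        s = self.s_mm[-1] - self.s_mm[::-1]
        return Centerline(pts, s, -self.tangents[::-1], self.step_mm)


def extract_centerline(
    aorta_mask: np.ndarray,
    spacing_mm=(1.0, 1.0, 1.0),
    origin_mm=(0.0, 0.0, 0.0),
    step_mm: float = 1.0,
    smoothing_mm: float = 2.0,
) -> Centerline:
    """Trace the lumen centerline as the ridge of the interior distance map.

    The two endpoints are found by a double sweep of geodesic distances
    (farthest voxel from an arbitrary start, then farthest from that), a
    minimum-cost path between them is routed with cost ``1/(dt + h/2)^3`` so
    it hugs the maximal-thickness ridge, and the voxel path is spline-smoothed
    and resampled at ``step_mm``.  The output is a simple path (no branches)
    ordered so that the endpoint with the smaller z (then x, then y) comes
    first — the proximal/inlet convention of the phantom geometry.

    Raises
    ------
    ValueError
        If the mask is empty or has more than one connected component.
    """
    mask = np.asarray(aorta_mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot extract a centerline from an empty mask")
    _, ncomp = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 3))
    if ncomp != 1:
        raise ValueError(f"mask must be a single connected component, found {ncomp}")

    spacing = np.asarray(spacing_mm, dtype=float)
    h = float(spacing.min())
    dt = ndimage.distance_transform_edt(mask, sampling=spacing)

    def farthest_from(seed):
        mcp = MCP_Geometric(np.where(mask, 1.0, np.inf), sampling=tuple(spacing))
        dist, _ = mcp.find_costs([seed])
        dist[~mask] = -np.inf
        return np.unravel_index(np.nanargmax(np.where(np.isfinite(dist), dist, -np.inf)), dist.shape)

    def recenter_on_cap(e):
        # a farthest-sweep endpoint lands in a cap corner; if it lies on or
        # near a volume face (an obliquely cut vessel end stops a slice or
        # two short of it), move it to the deepest point of its 2D cap so
        # the traced path leaves the cap along the vessel axis
        for ax in range(3):
            for idx in (0, mask.shape[ax] - 1):
                if min(abs(e[ax] - idx), abs(int(e[ax]) - idx)) > 2:
                    continue
                face = np.take(mask, idx, axis=ax)
                if not face.any():
                    continue
                lab2, _ = ndimage.label(face)
                e2d = np.array([c for i, c in enumerate(e) if i != ax])
                comp_id = lab2[tuple(e2d)]
                if comp_id == 0:
                    pts2 = np.argwhere(face)
                    comp_id = lab2[tuple(pts2[np.argmin(np.linalg.norm(pts2 - e2d, axis=1))])]
                cap = lab2 == comp_id
                d2 = ndimage.distance_transform_edt(cap)
                jk = np.unravel_index(np.argmax(d2), d2.shape)
                out = list(jk)
                out.insert(ax, idx)
                return tuple(int(i) for i in out)
        return e

    start = tuple(np.argwhere(mask)[0])
    e1 = recenter_on_cap(farthest_from(start))
    e2 = recenter_on_cap(farthest_from(e1))

    ridge_cost = (1.0 / (dt + 0.5 * h)) ** 3
    ridge_cost[~mask] = np.inf
    path_idx, _ = route_through_array(ridge_cost, e1, e2, fully_connected=True, geometric=True)
    pts = np.asarray(origin_mm) + (np.asarray(path_idx, dtype=float) + 0.5) * spacing

    # proximal-first ordering: compare endpoints lexicographically on (z, x, y)
    k0, k1 = (pts[0][2], pts[0][0], pts[0][1]), (pts[-1][2], pts[-1][0], pts[-1][1])
    if k1 < k0:
        pts = pts[::-1]

    # smooth the voxel-jagged path and resample at a uniform arc-length step
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    keep = np.concatenate([[True], seg > 1e-9])
    pts, u = pts[keep], u[keep]
    tck, _ = interpolate.splprep(pts.T, u=u / u[-1], s=len(pts) * smoothing_mm**2)
    dense_t = np.linspace(0.0, 1.0, max(4 * len(pts), 200))
    dense = np.asarray(interpolate.splev(dense_t, tck)).T
    dseg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    ds = np.concatenate([[0.0], np.cumsum(dseg)])
    n_out = max(int(np.floor(ds[-1] / step_mm)) + 1, 2)
    s_out = np.linspace(0.0, ds[-1], n_out)
    t_of_s = np.interp(s_out, ds, dense_t)
    out_pts = np.asarray(interpolate.splev(t_of_s, tck)).T
    deriv = np.asarray(interpolate.splev(t_of_s, tck, der=1)).T
    tangents = deriv / np.linalg.norm(deriv, axis=1, keepdims=True)
    return Centerline(out_pts, s_out, tangents, step_mm=float(s_out[1] - s_out[0]))


# ---------------------------------------------------------------------------
# cross sections

@dataclass
class CrossSection:
    """One orthogonal section: plane pose and TL/FL pixel-counted areas (mm²)."""

    s_mm: float
    origin_mm: np.ndarray
    normal: np.ndarray
    tl_area_mm2: float
    fl_area_mm2: float

    @property
    def tl_equiv_diameter_cm(self) -> float:
        """Diameter of the circle with the TL's sectional area, in cm."""
        return 2.0 * np.sqrt(self.tl_area_mm2 / np.pi) / 10.0


def _plane_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(tangent[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n1 = np.cross(ref, tangent)
    n1 /= np.linalg.norm(n1)
    return n1, np.cross(tangent, n1)


def cross_sections(
    labels: LumenLabelMap,
    centerline: Centerline,
    step_mm: float = 2.0,
    extent_mm: float | None = None,
) -> list[CrossSection]:
    """Measure TL/FL areas on planes orthogonal to the centerline.

    Sections are taken every ``step_mm`` of arc length.  Each label's binary
    indicator is sampled with trilinear interpolation on an in-plane grid at
    one quarter of the smallest voxel pitch and counted above 0.5; areas are
    pixel count times pixel area.  ``extent_mm`` (half-width of the section
    window) defaults to the maximum distance of any labeled voxel from the
    centerline plus two voxels.
    """
    if step_mm <= 0:
        raise ValueError("section step must be positive")
    spacing = np.asarray(labels.spacing_mm)
    origin = np.asarray(labels.origin_mm)
    data = labels.data

    if extent_mm is None:
        labeled = np.argwhere(data > 0)
        if labeled.size:
            world = origin + (labeled + 0.5) * spacing
            tree = cKDTree(centerline.points)
            d, _ = tree.query(world, workers=-1)
            extent_mm = float(d.max() + 2.0 * spacing.max())
        else:
            extent_mm = float(10.0 * spacing.max())

    pitch = float(spacing.min()) / 4.0
    ax = np.arange(-extent_mm, extent_mm + pitch / 2, pitch)
    px, py = np.meshgrid(ax, ax, indexing="ij")
    pixel_area = pitch * pitch

    tl_ind = (data == LumenLabelMap.TL).astype(np.float32)
    fl_ind = (data == LumenLabelMap.FL).astype(np.float32)

    s_samples = np.arange(centerline.s_mm[0], centerline.s_mm[-1] + 1e-9, step_mm)
    sections: list[CrossSection] = []
    for s in s_samples:
        c = np.array([np.interp(s, centerline.s_mm, centerline.points[:, i]) for i in range(3)])
        t = np.array([np.interp(s, centerline.s_mm, centerline.tangents[:, i]) for i in range(3)])
        t /= np.linalg.norm(t)
        n1, n2 = _plane_basis(t)
        pts = c + px[..., None] * n1 + py[..., None] * n2
        idx = ((pts - origin) / spacing - 0.5).reshape(-1, 3).T
        tl_vals = ndimage.map_coordinates(tl_ind, idx, order=1, mode="constant", cval=0.0)
        fl_vals = ndimage.map_coordinates(fl_ind, idx, order=1, mode="constant", cval=0.0)
        sections.append(
            CrossSection(
                s_mm=float(s),
                origin_mm=c,
                normal=t,
                tl_area_mm2=float(np.count_nonzero(tl_vals >= 0.5) * pixel_area),
                fl_area_mm2=float(np.count_nonzero(fl_vals >= 0.5) * pixel_area),
            )
        )
    return sections


def find_pmc(
    sections: list[CrossSection],
    dissected_extent_only: bool = True,
    smooth_window: int = 3,
) -> tuple[float, float]:
    """Locate the plane of maximum compression.

    Returns ``(s_mm, tl_equiv_diameter_cm)`` of the section minimizing the
    TL equivalent diameter, restricted (by default) to sections where the
    false lumen is present — the PMC is a feature of the dissected extent,
    and without the restriction an undissected tapering segment could win
    the argmin.

    The sectional TL area profile carries pixel-counting noise of roughly
    one section-grid pixel, so the profile is smoothed with a centered
    moving average over ``smooth_window`` sections before the argmin (the
    reported diameter is still the raw measurement of the chosen section).
    Tied minima are returned as the (lower) median-s tied section: on a
    voxel grid a smooth compression minimum flattens into a plateau of
    exactly equal sections, and the plateau midpoint is the unbiased
    location of the underlying minimum.  This also makes the result exactly
    invariant under centerline orientation reversal (up to the half-step of
    an even-sized plateau).
    """
    usable = sorted(
        (sec for sec in sections if sec.tl_area_mm2 > 0), key=lambda sec: sec.s_mm
    )
    if dissected_extent_only:
        usable = [sec for sec in usable if sec.fl_area_mm2 > 0]
    if not usable:
        raise ValueError("no dissected sections with a true lumen; cannot locate the PMC")
    areas = np.array([sec.tl_area_mm2 for sec in usable])
    w = max(1, int(smooth_window))
    half = w // 2
    smoothed = np.array(
        [areas[max(0, i - half): i + half + 1].mean() for i in range(len(areas))]
    )
    amin = smoothed.min()
    tied = [i for i in range(len(usable)) if smoothed[i] <= amin + 1e-12]
    chosen = usable[tied[(len(tied) - 1) // 2]]
    return float(chosen.s_mm), float(chosen.tl_equiv_diameter_cm)


# ---------------------------------------------------------------------------
# composite measurement

def fli(tl_vol_cm3: float, fl_vol_cm3: float) -> float:
    """False lumen index: FL volume divided by TL volume (dimensionless)."""
    if tl_vol_cm3 <= 0:
        raise ValueError(f"true lumen volume must be positive, got {tl_vol_cm3}")
    return float(fl_vol_cm3) / float(tl_vol_cm3)


@dataclass
class CaseMeasurement:
    """The four remodeling read-outs of one case at one stage."""

    tl_vol_cm3: float
    fl_vol_cm3: float
    total_vol_cm3: float
    tl_pmc_cm: float
    fli: float
    pmc_position_mm: float | None = None
    pmc_point_mm: np.ndarray | None = None
    case_id: int | None = None
    stage: str | None = None


def measure_case(
    labels: LumenLabelMap,
    centerline: Centerline | None = None,
    section_step_mm: float = 2.0,
    end_margin_mm: float = 5.0,
    case_id: int | None = None,
    stage: str | None = None,
) -> CaseMeasurement:
    """Compose volumes, PMC diameter and FLI into one case record.

    If no centerline is given, one is extracted from the full aorta mask
    (TL + FL + flap).  Sections within ``end_margin_mm`` of either centerline
    end are excluded from the PMC search: there the tangent still bends from
    the boundary cap toward the axis, and the obliquely clipped sections
    produce meaningless sliver areas.  A case with no false lumen gets FLI 0,
    but the PMC search then fails (no dissected sections) and the error
    propagates.
    """
    tl = voxel_volume(labels, LumenLabelMap.TL)
    fl = voxel_volume(labels, LumenLabelMap.FL)
    if tl <= 0:
        raise ValueError("no true lumen voxels; cannot measure the case")
    index = fli(tl, fl) if fl > 0 else 0.0
    if centerline is None:
        aorta = labels.mask(LumenLabelMap.TL, LumenLabelMap.FL, LumenLabelMap.FLAP)
        centerline = extract_centerline(aorta, labels.spacing_mm, labels.origin_mm)
    sections = cross_sections(labels, centerline, step_mm=section_step_mm)
    lo = centerline.s_mm[0] + end_margin_mm
    hi = centerline.s_mm[-1] - end_margin_mm
    interior = [sec for sec in sections if lo <= sec.s_mm <= hi]
    s_pmc, d_pmc = find_pmc(interior or sections)
    pmc_point = next(sec.origin_mm for sec in sections if sec.s_mm == s_pmc)
    return CaseMeasurement(
        tl_vol_cm3=tl,
        fl_vol_cm3=fl,
        total_vol_cm3=tl + fl,
        tl_pmc_cm=d_pmc,
        fli=index,
        pmc_position_mm=s_pmc,
        pmc_point_mm=np.asarray(pmc_point),
        case_id=case_id,
        stage=stage,
    )
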