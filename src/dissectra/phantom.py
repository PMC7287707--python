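"""Synthetic dissected-aorta phantoms with analytic ground truth.

A phantom is a contrast-bright tube (the aortic lumen) split lengthwise by a
thin low-attenuation intimal flap into a compressed true lumen (TL) and a
larger false lumen (FL).  The flap is a chordal plane through the local
centerline frame; its chord offset is solved per cross-section so that the TL
occupies a prescribed area fraction ``alpha(s)`` of the lumen disk.  A
Gaussian dip in ``alpha(s)`` realizes a localized site of maximum TL
compression, and tear windows (flap fenestrations) connect the two lumens.
Because every cross-section is a circular segment, all areas — and hence the
TL/FL volumes, the compression-site TL diameter and the false lumen index
(FLI = FL/TL) — have closed forms, evaluated by fine quadrature along the
centerline independently of any voxel grid.

The "post-treatment" state reuses the identical outer geometry, flap plane
and noise stream but replaces the compressed TL fraction profile with a wide
constant fraction, emulating stent-induced TL re-expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
import json

import numpy as np
from scipy.spatial import cKDTree

from .imaging_io import ImageVolume, LumenLabelMap

__all__ = ["PhantomSpec", "GroundTruth", "generate_phantom", "make_pre_post_pair"]

_QUADRATURE_STEP_MM = 0.1
_CENTERLINE_SAMPLE_MM = 0.25


# ---------------------------------------------------------------------------
# circular-segment analytics

def segment_area(t: np.ndarray | float, r: float) -> np.ndarray:
    """Area of the disk segment {u >= t} of a radius-``r`` disk.

    ``t`` is the signed chord offset from the center along the flap normal;
    the area decreases monotonically from pi*r^2 at t=-r to 0 at t=+r.
    """
    t = np.clip(np.asarray(t, dtype=float), -r, r)
    return r * r * np.arccos(t / r) - t * np.sqrt(np.maximum(r * r - t * t, 0.0))


def chord_offset_for_fraction(alpha: np.ndarray | float, r: float) -> np.ndarray:
    """Invert :func:`segment_area`: offset t with segment fraction ``alpha``.

    Solved by bisection (the map is strictly decreasing); accurate to ~1e-12*r.
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    if np.any((alpha <= 0) | (alpha >= 1)):
        raise ValueError("area fraction must lie strictly inside (0, 1)")
    target = alpha * np.pi * r * r
    lo = np.full_like(target, -r)
    hi = np.full_like(target, r)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_big = segment_area(mid, r) > target  # area too large -> move chord up
        lo = np.where(too_big, mid, lo)
        hi = np.where(too_big, hi, mid)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# specification

@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic dissected aorta.

    Geometry defaults are chosen to land inside the value ranges of the
    16-case cohort tables (TL volume a few tens of cm³, FL several times
    larger, pre-treatment FLI between 2 and 3) without matching any one case.

    Parameters
    ----------
    centerline_shape : {"straight", "arch"}
        Straight tube along +z, or a half-circle arch (radius
        ``arch_radius_mm``, arc length pi*R) followed by a straight
        descending segment so the total centerline length is ``length_mm``.
    length_mm, lumen_radius_mm : float
        Centerline length and outer lumen radius (mm).
    axis_tilt_deg : float
        Tilt of the straight centerline away from the grid z axis (in the
        x–z plane).  Real vessels are never aligned with the scanner grid;
        an exactly axis-aligned tube is also a voxelization pathology (every
        slice repeats the same lattice/disk offset, so quantization bias
        accumulates coherently instead of averaging out).  Ignored for the
        arch shape, whose orientation varies along the arc anyway.
    flap_angle_deg : float
        Orientation of the flap plane about the local centerline tangent.
    tl_fraction_base : float
        TL cross-sectional area fraction alpha0 away from the compression.
    compression_depth, compression_center_mm, compression_width_mm : float
        Gaussian dip of the TL fraction: alpha(s) = alpha0 -
        depth*exp(-(s-s*)^2/(2 w^2)).  Depth must stay below alpha0.
    flap_thickness_mm : float
        Flap slab thickness (>= 0; 0 gives a zero-measure flap).
    dissection_start_mm, dissection_end_mm : float
        Arc-length extent of the dissection.  Outside it the aorta is an
        undissected round lumen (all TL), so the proximal inlet cross-section
        is identical in the pre and post states.  Where an extent bound lies
        strictly inside the tube, a transverse flap cap of thickness
        ``fl_end_cap_mm`` seals the false lumen end, leaving the entry and
        re-entry tears as its only openings — the classic TBAD topology.
        Bounds at 0 / ``length_mm`` leave the FL open at that grid face.
    tear_positions_mm : tuple of (center, extent)
        Entry/re-entry fenestrations: square holes of side ``extent`` punched
        through the flap, centered at arc length ``center`` on the chord
        midline.  Tear voxels belong to the TL, and the fluid domain is
        connected through each hole.
    hu_lumen, hu_flap, hu_background : float
        Mean intensities (defaults 300 / 60 / 20 HU); contrast-enhanced
        lumen sits far above the 175 HU segmentation threshold, flap and
        background below it.
    noise_sd_hu : float
        Additive Gaussian noise; the only stochastic element.  Default 10 HU,
        a typical contrast-CT noise magnitude.
    state : {"pre", "post"}
        "post" replaces alpha(s) by the constant ``tl_fraction_post``.
    """

    centerline_shape: str = "straight"
    length_mm: float = 150.0
    arch_radius_mm: float = 40.0
    lumen_radius_mm: float = 15.0
    axis_tilt_deg: float = 7.0
    flap_angle_deg: float = 20.0
    tl_fraction_base: float = 0.22
    compression_depth: float = 0.12
    compression_center_mm: float = 75.0
    compression_width_mm: float = 12.0
    flap_thickness_mm: float = 2.5
    dissection_start_mm: float = 8.0
    dissection_end_mm: float = 142.0
    fl_end_cap_mm: float = 4.0
    tear_positions_mm: tuple = ((30.0, 12.0), (120.0, 12.0))
    voxel_spacing_mm: tuple = (1.0, 1.0, 1.0)
    hu_lumen: float = 300.0
    hu_flap: float = 60.0
    hu_background: float = 20.0
    noise_sd_hu: float = 10.0
    rng_seed: int = 0
    state: str = "pre"
    tl_fraction_post: float = 0.85

    # -- profiles ----------------------------------------------------------
    def alpha(self, s: np.ndarray | float) -> np.ndarray:
        """TL area fraction profile alpha(s) for the current state."""
        s = np.asarray(s, dtype=float)
        if self.state == "post":
            return np.full_like(s, self.tl_fraction_post)
        dip = self.compression_depth * np.exp(
            -((s - self.compression_center_mm) ** 2) / (2.0 * self.compression_width_mm**2)
        )
        return self.tl_fraction_base - dip

    def in_tear(self, s: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
        """Membership in a fenestration: |s - center| and |b| both within extent/2.

        ``b`` is the in-plane coordinate along the flap chord (0 at the chord
        midline), so each tear is a roughly square hole of side ``extent``
        punched through the flap sheet, not a full-width absence.
        """
        s = np.asarray(s, dtype=float)
        b = np.asarray(b, dtype=float)
        hit = np.zeros(np.broadcast(s, b).shape, dtype=bool)
        for center, extent in self.tear_positions_mm:
            hit |= (np.abs(s - center) <= 0.5 * extent) & (np.abs(b) <= 0.5 * extent)
        return hit

    def tear_chord_width(self, s: np.ndarray) -> np.ndarray:
        """Chordwise width (mm) of the fenestration opening at arc length s."""
        s = np.asarray(s, dtype=float)
        r = self.lumen_radius_mm
        t = chord_offset_for_fraction(self.alpha(s), r)
        half_chord = np.sqrt(np.maximum(r * r - t * t, 0.0))
        width = np.zeros_like(s)
        for center, extent in self.tear_positions_mm:
            in_s = np.abs(s - center) <= 0.5 * extent
            width = np.where(in_s, np.maximum(width, np.minimum(extent, 2.0 * half_chord)), width)
        return width

    def _regions(self, s: np.ndarray):
        """Classify arc lengths: outside the dissection / FL end cap / interior."""
        s = np.asarray(s, dtype=float)
        s0, s1 = self.dissection_start_mm, self.dissection_end_mm
        cap = self.fl_end_cap_mm
        outside = (s < s0) | (s > s1)
        in_cap = np.zeros(s.shape, dtype=bool)
        if s0 > 0:
            in_cap |= (s >= s0) & (s < s0 + cap)
        if s1 < self.length_mm:
            in_cap |= (s <= s1) & (s > s1 - cap)
        interior = ~outside & ~in_cap
        return outside, in_cap, interior

    def area_profiles(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Analytic (TL, FL, flap) cross-sectional areas (mm²) at arc lengths s.

        Within the dissection the flap slab of thickness h is centered on the
        chord solved from alpha(s): TL is the segment beyond ``t + h/2``, FL
        the segment below ``t - h/2``, and where a fenestration crosses the
        section the opened fraction of the flap band (hole width over full
        chord width) counts as TL, matching the voxel labeling.  In the FL
        end caps the would-be FL is flap material; outside the dissection the
        whole disk is TL.
        """
        s = np.asarray(s, dtype=float)
        r = self.lumen_radius_mm
        h = self.flap_thickness_mm
        t = chord_offset_for_fraction(self.alpha(s), r)
        disk = np.pi * r * r
        seg_fl_side = segment_area(t - 0.5 * h, r)
        a_tl_chord = segment_area(t + 0.5 * h, r)
        band = seg_fl_side - a_tl_chord
        full_width = 2.0 * np.sqrt(np.maximum(r * r - t * t, 0.0))
        frac = np.clip(self.tear_chord_width(s) / np.maximum(full_width, 1e-12), 0.0, 1.0)
        hole = band * frac

        outside, in_cap, interior = self._regions(s)
        a_tl = np.where(outside, disk, np.where(in_cap, a_tl_chord, a_tl_chord + hole))
        a_fl = np.where(interior, disk - seg_fl_side, 0.0)
        a_flap = np.where(outside, 0.0, np.where(in_cap, disk - a_tl_chord, band - hole))
        return a_tl, a_fl, a_flap

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.centerline_shape not in ("straight", "arch"):
            raise ValueError(f"unknown centerline shape {self.centerline_shape!r}")
        if self.state not in ("pre", "post"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.length_mm <= 0 or self.lumen_radius_mm <= 0:
            raise ValueError("length and lumen radius must be positive")
        if self.centerline_shape == "arch":
            if self.arch_radius_mm <= 0:
                raise ValueError("arch radius must be positive")
            if self.length_mm <= np.pi * self.arch_radius_mm:
                raise ValueError("arch phantom needs length_mm > pi * arch_radius_mm")
        if any(sp <= 0 for sp in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if max(self.voxel_spacing_mm) >= self.lumen_radius_mm:
            raise ValueError("voxel spacing must be finer than the lumen radius")
        if not (0 < self.tl_fraction_base < 1) or not (0 < self.tl_fraction_post < 1):
            raise ValueError("TL area fractions must lie in (0, 1)")
        if not (0 <= self.compression_depth < self.tl_fraction_base):
            raise ValueError("compression depth must lie in [0, tl_fraction_base)")
        if self.compression_width_mm <= 0:
            raise ValueError("compression width must be positive")
        if self.flap_thickness_mm < 0 or self.fl_end_cap_mm < 0:
            raise ValueError("flap and end-cap thickness must be non-negative")
        if self.noise_sd_hu < 0:
            raise ValueError("noise SD must be non-negative")
        s0, s1 = self.dissection_start_mm, self.dissection_end_mm
        if not (0 <= s0 < s1 <= self.length_mm):
            raise ValueError("dissection extent must satisfy 0 <= start < end <= length")
        i0 = s0 + (self.fl_end_cap_mm if s0 > 0 else 0.0)
        i1 = s1 - (self.fl_end_cap_mm if s1 < self.length_mm else 0.0)
        if i0 >= i1:
            raise ValueError("FL end caps leave no dissection interior")
        for center, extent in self.tear_positions_mm:
            if extent <= 0 or center - 0.5 * extent < i0 or center + 0.5 * extent > i1:
                raise ValueError(
                    f"tear window ({center}, {extent}) outside the dissection interior "
                    f"[{i0}, {i1}]"
                )
        if self.compression_depth > 0 and not (i0 <= self.compression_center_mm <= i1):
            raise ValueError("compression center must lie inside the dissection interior")
        step = _QUADRATURE_STEP_MM
        s = np.arange(0.0, self.length_mm + step, step)
        a = self.alpha(s)
        if np.any(a <= 0) or np.any(a >= 1):
            raise ValueError("alpha(s) leaves (0, 1); reduce compression depth")
        a_tl, a_fl, _ = self.area_profiles(s)
        interior = self._regions(s)[2]
        if np.any(a_tl <= 0) or np.any(a_fl[interior] <= 0):
            raise ValueError("flap thickness swallows a lumen somewhere along s")

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        """Serialize as a flat JSON object (keys = field names)."""
        d = asdict(self)
        d["tear_positions_mm"] = [list(t) for t in self.tear_positions_mm]
        d["voxel_spacing_mm"] = list(self.voxel_spacing_mm)
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PhantomSpec":
        """Load a spec from a JSON string or file path."""
        try:
            d = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                d = json.load(fh)
        d["tear_positions_mm"] = tuple(tuple(t) for t in d.get("tear_positions_mm", ()))
        d["voxel_spacing_mm"] = tuple(d.get("voxel_spacing_mm", (1.0, 1.0, 1.0)))
        return cls(**d)


@dataclass
class GroundTruth:
    """Analytic measurements of a phantom, from 0.1 mm quadrature along s."""

    tl_volume_cm3: float
    fl_volume_cm3: float
    pmc_position_mm: float
    tl_diameter_at_pmc_cm: float
    fli: float


def ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Integrate the analytic area profiles; voxelization-independent.

    Volumes describe the *scanned* phantom: for a tilted straight tube the
    image grid is bounded by the z planes through the centerline endpoints,
    which clip an oblique wedge of volume (2/3)·r³·tan(tilt) off each end.
    The wedges are subtracted from the true lumen provided the dissection
    does not reach into them (the undissected margins cover r·tan(tilt));
    otherwise the clipped tissue mix is not closed-form and no correction
    is applied.
    """
    s = np.arange(0.0, spec.length_mm + 1e-9, _QUADRATURE_STEP_MM)
    a_tl, a_fl, _ = spec.area_profiles(s)
    tl_mm3 = np.trapezoid(a_tl, s)
    fl_mm3 = np.trapezoid(a_fl, s)
    if spec.centerline_shape == "straight" and spec.axis_tilt_deg != 0:
        r = spec.lumen_radius_mm
        reach = r * abs(np.tan(np.deg2rad(spec.axis_tilt_deg)))
        if spec.dissection_start_mm >= reach and spec.dissection_end_mm <= spec.length_mm - reach:
            tl_mm3 -= 2.0 * (2.0 / 3.0) * r**3 * abs(np.tan(np.deg2rad(spec.axis_tilt_deg)))
    # the compression center is the analytic argmin of the TL area profile;
    # in the flat post state it is retained as the nominal reference plane
    s_pmc = spec.compression_center_mm
    a_pmc = spec.area_profiles(np.asarray([s_pmc]))[0][0]
    d_pmc_cm = 2.0 * np.sqrt(a_pmc / np.pi) / 10.0
    return GroundTruth(
        tl_volume_cm3=float(tl_mm3 / 1000.0),
        fl_volume_cm3=float(fl_mm3 / 1000.0),
        pmc_position_mm=float(s_pmc),
        tl_diameter_at_pmc_cm=float(d_pmc_cm),
        fli=float(fl_mm3 / tl_mm3),
    )


# ---------------------------------------------------------------------------
# centerline frames

def _centerline_frames(spec: PhantomSpec, step: float = _CENTERLINE_SAMPLE_MM):
    """Sample the centerline: points, unit tangents, flap normals, arc length.

    The local frame transports the binormal B = +y along the curve (both
    shapes lie in the x–z plane), with N = B × T; the flap normal is
    e = cos(angle)·N + sin(angle)·B, continuous along s.
    """
    s = np.arange(0.0, spec.length_mm + 1e-9, step)
    if spec.centerline_shape == "straight":
        tilt = np.deg2rad(spec.axis_tilt_deg)
        axis = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
        pts = s[:, None] * axis
        tangents = np.tile(axis, (s.size, 1))
        normals = np.tile([np.cos(tilt), 0.0, -np.sin(tilt)], (s.size, 1))
    else:  # arch: half circle of arc pi*R, then straight descending tail
        R = spec.arch_radius_mm
        arc_len = np.pi * R
        pts = np.zeros((s.size, 3))
        tangents = np.zeros((s.size, 3))
        normals = np.zeros((s.size, 3))
        on_arc = s <= arc_len
        phi = s[on_arc] / R
        pts[on_arc, 0] = R * (1.0 - np.cos(phi))
        pts[on_arc, 2] = R * np.sin(phi)
        tangents[on_arc, 0] = np.sin(phi)
        tangents[on_arc, 2] = np.cos(phi)
        normals[on_arc, 0] = np.cos(phi)
        normals[on_arc, 2] = -np.sin(phi)
        tail = ~on_arc
        pts[tail, 0] = 2.0 * R
        pts[tail, 2] = -(s[tail] - arc_len)
        tangents[tail] = [0.0, 0.0, -1.0]
        normals[tail] = [-1.0, 0.0, 0.0]
    binormals = np.cross(tangents, normals)  # = +y everywhere by construction
    ang = np.deg2rad(spec.flap_angle_deg)
    flap_dirs = np.cos(ang) * normals + np.sin(ang) * binormals
    return pts, tangents, flap_dirs, s


# ---------------------------------------------------------------------------
# generation

def generate_phantom(spec: PhantomSpec):
    """Voxelize a phantom: returns ``(ImageVolume, LumenLabelMap, GroundTruth)``.

    Every voxel center is classified by its nearest-centerline radial test
    (inside the lumen tube or not) and by its side of the flap chord in the
    local frame; the HU volume is the label-dependent mean plus seeded
    Gaussian noise.  The ground truth comes from analytic quadrature, not
    from the voxel grid.
    """
    spec.validate()
    pts, tangents, flap_dirs, s_nodes = _centerline_frames(spec)
    r = spec.lumen_radius_mm
    margin = max(6.0, 2.0 * max(spec.voxel_spacing_mm))

    lo = pts.min(axis=0) - (r + margin)
    hi = pts.max(axis=0) + (r + margin)
    if spec.centerline_shape == "straight":
        # tube ends flush with the grid z faces (open caps for the flow stage)
        lo[2], hi[2] = 0.0, pts[:, 2].max()
    else:
        lo[2] = pts[:, 2].min()  # descending cap flush, ascending cap interior

    spacing = np.asarray(spec.voxel_spacing_mm, dtype=float)
    shape = np.maximum(np.round((hi - lo) / spacing).astype(int), 1)
    origin = lo

    centers = [origin[i] + (np.arange(shape[i]) + 0.5) * spacing[i] for i in range(3)]
    grid = np.stack(np.meshgrid(*centers, indexing="ij"), axis=-1).reshape(-1, 3)

    tree = cKDTree(pts)
    _, idx = tree.query(grid, workers=-1)
    v = grid - pts[idx]
    t_axis = tangents[idx]
    s_ref = s_nodes[idx] + np.einsum("ij,ij->i", v, t_axis)
    v_perp = v - np.einsum("ij,ij->i", v, t_axis)[:, None] * t_axis
    rho = np.linalg.norm(v_perp, axis=1)
    inside = (rho <= r) & (s_ref >= 0.0) & (s_ref <= spec.length_mm)

    labels = np.zeros(grid.shape[0], dtype=np.uint8)
    if np.any(inside):
        chord_dirs = np.cross(tangents, flap_dirs)
        u = np.einsum("ij,ij->i", v_perp[inside], flap_dirs[idx[inside]])
        b = np.einsum("ij,ij->i", v_perp[inside], chord_dirs[idx[inside]])
        s_in = np.clip(s_ref[inside], 0.0, spec.length_mm)
        t_chord = chord_offset_for_fraction(spec.alpha(s_in), r)
        half = 0.5 * spec.flap_thickness_mm
        outside, in_cap, interior = spec._regions(s_in)
        lab = np.full(u.shape, LumenLabelMap.TL, dtype=np.uint8)
        tl_side = u >= t_chord + half
        fl_side = u <= t_chord - half
        lab[in_cap & ~tl_side] = LumenLabelMap.FLAP
        lab[interior & ~tl_side & ~fl_side & ~spec.in_tear(s_in, b)] = LumenLabelMap.FLAP
        lab[interior & fl_side] = LumenLabelMap.FL
        labels[inside] = lab
    labels = labels.reshape(tuple(shape))

    hu_means = np.array([spec.hu_background, spec.hu_lumen, spec.hu_lumen, spec.hu_flap])
    hu = hu_means[labels].astype(np.float32)
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.rng_seed)
        hu += rng.normal(0.0, spec.noise_sd_hu, size=hu.shape).astype(np.float32)

    spacing_t = tuple(float(x) for x in spacing)
    origin_t = tuple(float(x) for x in origin)
    vol = ImageVolume(hu, spacing_t, origin_t)
    labelmap = LumenLabelMap(labels.astype(np.int16), spacing_t, origin_t)
    return vol, labelmap, ground_truth(spec)


def make_pre_post_pair(spec: PhantomSpec):
    """Generate matched pre/post phantoms differing only in the TL fraction.

    Both states share the outer geometry, flap plane, tears, grid and RNG
    seed, so the background/noise realizations are voxelwise identical and
    pre/post differences are purely geometric.
    """
    pre = generate_phantom(replace(spec, state="pre"))
    post = generate_phantom(replace(spec, state="post"))
    return pre, post
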