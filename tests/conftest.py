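"""Shared fixtures: phantoms, segmentations and flow solutions are expensive,
so they are computed once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from dissectra.hemodynamics import FlowParameters, build_domain, flow_summary, solve_steady_flow
from dissectra.phantom import PhantomSpec, generate_phantom, make_pre_post_pair
from dissectra.pipeline import PipelineConfig, segment_phantom
from dissectra.imaging_io import load_paper_tables
from dissectra.segmentation import SegmentationConfig


@pytest.fixture(scope="session")
def cohort():
    return load_paper_tables()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default study phantom, noise off: (volume, ground-truth labels, truth)."""
    return generate_phantom(PhantomSpec(noise_sd_hu=0.0))


@pytest.fixture(scope="session")
def segmented_phantom(noiseless_phantom):
    """Protocol segmentation of the noiseless default phantom."""
    vol, gt_labels, _ = noiseless_phantom
    return segment_phantom(vol, gt_labels, SegmentationConfig())


@pytest.fixture(scope="session")
def prepost_pair():
    """Matched pre/post phantom pair (noiseless)."""
    return make_pre_post_pair(PhantomSpec(noise_sd_hu=0.0))


def cylinder_mask(radius_mm=10.0, length_mm=40.0, h_mm=1.0, margin_mm=1.5):
    n = int(round(2 * (radius_mm + margin_mm) / h_mm))
    nz = int(round(length_mm / h_mm))
    ax = (np.arange(n) + 0.5) * h_mm - (radius_mm + margin_mm)
    x, y = np.meshgrid(ax, ax, indexing="ij")
    disk = x**2 + y**2 <= radius_mm**2
    return np.repeat(disk[:, :, None], nz, axis=2), (h_mm, h_mm, h_mm)


def poiseuille_metrics(h_mm, max_steps=3000):
    """Solve developed pipe flow at grid ``h_mm`` and measure the read-outs."""
    mask, spacing = cylinder_mask(h_mm=h_mm)
    dom = build_domain(mask, spacing, h_mm=h_mm, inlet="z-")
    params = FlowParameters(inlet_profile="parabolic", max_pseudo_steps=max_steps)
    fld = solve_steady_flow(dom, params)
    summ = flow_summary(fld, dom)
    speeds = fld.cell_speeds()
    c = speeds.shape[0] // 2
    centerline = speeds[c, c, :]
    nz = centerline.size
    k0, k1 = nz // 4, 3 * nz // 4
    fluid = dom.fluid
    pz = np.array([fld.p[:, :, k][fluid[:, :, k]].mean() for k in range(nz)])
    z = (np.arange(nz) + 0.5) * h_mm * 1e-3
    slope = -np.polyfit(z[k0:k1], pz[k0:k1], 1)[0]
    return {
        "centerline_speed": float(centerline[k0:k1].mean()),
        "pressure_gradient": float(slope),
        "summary": summ,
        "converged": fld.converged,
    }


@pytest.fixture(scope="session")
def poiseuille_by_h():
    """Pipe-flow validation at three grids (coarse → fine)."""
    return {h: poiseuille_metrics(h) for h in (2.0, 1.0, 0.5)}


@pytest.fixture(scope="session")
def prepost_flow(prepost_pair):
    """Steady-flow summaries for the pre and post phantom states."""
    (_, pre_labels, _), (_, post_labels, _) = prepost_pair
    out = {}
    for name, labels in (("pre", pre_labels), ("post", post_labels)):
        dom = build_domain(labels, h_mm=2.0, inlet="z-")
        fld = solve_steady_flow(dom, FlowParameters(max_pseudo_steps=4000))
        out[name] = flow_summary(fld, dom)
    return out


def small_pipeline_config(seed=0):
    """Scaled-down pipeline configuration for reproducibility checks."""
    spec = PhantomSpec(
        length_mm=100.0,
        lumen_radius_mm=12.0,
        compression_center_mm=50.0,
        dissection_start_mm=8.0,
        dissection_end_mm=92.0,
        tear_positions_mm=((25.0, 12.0), (75.0, 12.0)),
        noise_sd_hu=10.0,
    )
    flow = FlowParameters(max_pseudo_steps=2500)
    return PipelineConfig(phantom=spec, flow=flow, flow_grid_mm=2.5, rng_seed=seed)
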