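"""End-to-end orchestration: phantom → segmentation → meshing → morphometry
→ steady flow → cohort statistics, with a deterministic JSON report.

The demo pipeline builds a matched pre/post phantom pair, runs the full
measurement protocol on each state, solves the steady-flow problem on both
fluid domains, and reports the remodeling directions (TL up, FL down, FLI
down, PMC up, overall velocity and pressure down) together with the cohort
statistics reproduced from the packaged tables.  Identical configuration
and seed give byte-identical reports: the only randomness is the phantom
noise (seeded), the solver and segmentation are deterministic, and the
report serialization is canonical (sorted keys, no timestamps).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import __version__
from .geometry import measure_case
from .hemodynamics import FlowParameters, build_domain, compare_states, flow_summary, solve_steady_flow
from .imaging_io import LumenLabelMap, load_paper_tables
from .phantom import PhantomSpec, make_pre_post_pair
from .remodeling_stats import cohort_report
from .segmentation import SegmentationConfig, close_mask, region_grow, split_lumens

__all__ = ["PipelineConfig", "run_pipeline", "suggest_seeds", "segment_phantom"]


@dataclass
class PipelineConfig:
    """One bundle of every stage's parameters.

    Physical defaults are the protocol's throughout: 175 HU threshold,
    blood at 1060 kg/m³ and 0.0035 kg/(m·s), 0.35 m/s plug inlet, 0 Pa
    outlets, 0.001 geometry scale.
    """

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    flow: FlowParameters = field(default_factory=FlowParameters)
    flow_grid_mm: float = 2.0
    section_step_mm: float = 2.0
    rng_seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def suggest_seeds(labels: LumenLabelMap, z_index: int | None = None):
    """Operator surrogate: deepest point of each lumen on one axial slice.

    The protocol expects one click inside each lumen on a mid-dissection
    slice; here the click is replaced by the in-slice distance-transform
    maximum of each label.  ``z_index`` defaults to two fifths of the
    axial extent (between the entry and re-entry tears of the default
    phantom geometry).
    """
    nz = labels.data.shape[2]
    z = int(0.4 * nz) if z_index is None else z_index
    seeds = {}
    for name, lab in (("tl", LumenLabelMap.TL), ("fl", LumenLabelMap.FL)):
        m = labels.data[:, :, z] == lab
        if not m.any():
            raise ValueError(f"slice {z} contains no {name.upper()} voxels")
        d = ndimage.distance_transform_edt(m)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        seeds[name] = (int(i), int(j), z)
    return seeds["tl"], seeds["fl"]


def segment_phantom(vol, gt_labels, cfg: SegmentationConfig):
    """Run the segmentation protocol on a phantom volume.

    Seeds come from :func:`suggest_seeds` on the generator's labels (the
    stand-in for the operator's two clicks); everything else sees only the
    HU volume: windowed region growing from the seeds, closing to rebuild
    the flap, and the membrane-guided lumen split.
    """
    tl_seed, fl_seed = suggest_seeds(gt_labels)
    grown = region_grow(vol, [tl_seed, fl_seed], cfg)
    aorta = close_mask(grown, cfg)
    barrier = aorta & ~grown
    return split_lumens(
        aorta, tl_seed, fl_seed, barrier, vol.spacing_mm, vol.origin_mm, cfg
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full demo protocol and return (and optionally write) the report."""
    spec = replace(config.phantom, rng_seed=config.rng_seed)
    report: dict = {
        "manifest": {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "rng_seed": config.rng_seed,
        }
    }

    try:
        (pre_vol, pre_gt, pre_truth), (post_vol, post_gt, post_truth) = make_pre_post_pair(spec)
    except Exception as exc:
        raise RuntimeError(f"phantom stage failed: {exc}") from exc

    measurements = {}
    flows = {}
    for state, vol, gt_labels, truth in (
        ("pre", pre_vol, pre_gt, pre_truth),
        ("post", post_vol, post_gt, post_truth),
    ):
        try:
            labels = segment_phantom(vol, gt_labels, config.segmentation)
        except Exception as exc:
            raise RuntimeError(f"segmentation stage failed ({state}): {exc}") from exc
        try:
            meas = measure_case(labels, section_step_mm=config.section_step_mm, stage=state)
        except Exception as exc:
            raise RuntimeError(f"measurement stage failed ({state}): {exc}") from exc
        measurements[state] = meas
        report[f"measurement_{state}"] = {
            "tl_vol_cm3": round(meas.tl_vol_cm3, 3),
            "fl_vol_cm3": round(meas.fl_vol_cm3, 3),
            "tl_pmc_cm": round(meas.tl_pmc_cm, 3),
            "fli": round(meas.fli, 4),
            "analytic_tl_vol_cm3": round(truth.tl_volume_cm3, 3),
            "analytic_fl_vol_cm3": round(truth.fl_volume_cm3, 3),
            "analytic_fli": round(truth.fli, 4),
        }
        try:
            dom = build_domain(labels, h_mm=config.flow_grid_mm)
            fld = solve_steady_flow(dom, config.flow)
            flows[state] = flow_summary(fld, dom)
        except Exception as exc:
            raise RuntimeError(f"flow stage failed ({state}): {exc}") from exc
        report[f"flow_{state}"] = {
            "overall_velocity_m_per_s": round(flows[state].overall_velocity, 5),
            "overall_pressure_pa": round(flows[state].overall_pressure, 3),
            "max_speed_m_per_s": round(flows[state].max_speed, 4),
            "mass_imbalance": float(f"{flows[state].mass_imbalance:.2e}"),
            "converged": flows[state].converged,
        }

    pre_m, post_m = measurements["pre"], measurements["post"]
    report["remodeling_directions"] = {
        "tl_volume_increased": post_m.tl_vol_cm3 > pre_m.tl_vol_cm3,
        "fl_volume_decreased": post_m.fl_vol_cm3 < pre_m.fl_vol_cm3,
        "fli_decreased": post_m.fli < pre_m.fli,
        "tl_pmc_increased": post_m.tl_pmc_cm > pre_m.tl_pmc_cm,
        "overall_velocity_decreased": flows["post"].overall_velocity < flows["pre"].overall_velocity,
        "overall_pressure_decreased": flows["post"].overall_pressure < flows["pre"].overall_pressure,
    }
    cmp = compare_states(flows["pre"], flows["post"])
    report["flow_percent_decreases"] = {k: round(v, 2) for k, v in cmp.items()}

    try:
        report["cohort"] = cohort_report(load_paper_tables()).as_dict()
    except Exception as exc:
        raise RuntimeError(f"statistics stage failed: {exc}") from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            fh.write(canonical_json(report))
    return report


def canonical_json(obj) -> str:
    """Deterministic serialization: sorted keys, fixed float handling."""
    return json.dumps(obj, sort_keys=True, indent=2, allow_nan=False) + "\n"
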