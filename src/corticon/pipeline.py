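"""Per-subject analysis orchestration and cohort batch runs.

Chains segmentation -> thickness metrics -> radial profile -> ICON fit ->
zone and cancellous summaries for a baseline volume, and adds the frozen
-baseline apposition fit for a longitudinal pair.  Longitudinal profiles
are extracted in the baseline segmentation's distance frame so that the
apposition fit sees a consistent geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import icon
from .cancellous import compartment_bmd_bmc
from .errors import CorticonError
from .phantoms import SubjectTruth, realize_subject
from .profiles import ProfileConfig, ZoneConfig, extract_profile, zone_summary
from .segmentation import VoiConfig, VoiLabel, segment_cortex, vertical_cortex_only
from .thickness import ctth, local_thickness, wctth
from .volume import VoxelVolume

__all__ = ["PipelineConfig", "analyze_baseline", "analyze_pair", "run_cohort"]


@dataclass
class PipelineConfig:
    voi: VoiConfig = field(default_factory=VoiConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    zones: ZoneConfig = field(default_factory=ZoneConfig)
    mineralization_fraction: float = 0.5
    cancellous_threshold: float = 250.0


def _thickness_metrics(volume: VoxelVolume, seg) -> dict:
    labels = local_thickness(seg.cortical_mask, volume.spacing)
    vert = vertical_cortex_only(seg)
    out = {
        "ctth_um": ctth(labels, vert),
        "wctth_um": wctth(labels, volume, vert),
        "ctth_complete_um": ctth(labels, seg.cortical_mask),
        "wctth_complete_um": wctth(labels, volume, seg.cortical_mask),
    }
    vals = np.asarray(volume.values)
    for name, mask in (("cortical", vert), ("cortical_complete", seg.cortical_mask)):
        out[f"{name}_bmd"] = float(vals[mask].mean())
        out[f"{name}_bmc_mg"] = (
            float(vals[mask].sum(dtype=np.float64)) * volume.voxel_volume_mm3 / 1000.0
        )
    return out, labels


def analyze_baseline(volume: VoxelVolume, scanner_sigma: float, cfg: PipelineConfig | None = None):
    """Full baseline analysis; returns (metrics dict, objects dict)."""
    cfg = cfg or PipelineConfig()
    seg = segment_cortex(volume, cfg.voi)
    metrics, labels = _thickness_metrics(volume, seg)

    profile = extract_profile(volume, seg, cfg.profile)
    model = icon.fit_baseline(
        profile, init_width=metrics["wctth_um"] / 1000.0, scanner_sigma=scanner_sigma
    )
    metrics["dcctth_um"] = icon.dcctth(model) if not model.degenerate else np.nan
    metrics["icon_sigma_mm"] = model.sigma
    metrics["icon_plateau"] = model.plateau
    metrics["icon_residual_rms"] = model.residual_rms

    zones = zone_summary(profile, model.center, cfg.zones)
    for name, v in zones.bmd.items():
        metrics[f"zone_{name.lower()}_bmd"] = v
    for name, v in zones.bmc.items():
        metrics[f"zone_{name.lower()}_bmc"] = v

    for comp in (VoiLabel.SPONGIOSA_PEELED, VoiLabel.SUBCORTEX):
        res = compartment_bmd_bmc(volume, seg, comp, cfg.cancellous_threshold)
        tag = "spongiosa" if comp == VoiLabel.SPONGIOSA_PEELED else "subcortex"
        metrics[f"{tag}_bmd"] = res.compartment_bmd
        metrics[f"{tag}_bmc_mg"] = res.compartment_bmc
        metrics[f"{tag}_bvtv_pct"] = res.bvtv
        metrics[f"{tag}_tmd"] = res.tmd

    objects = {"seg": seg, "profile": profile, "model": model, "labels": labels}
    return metrics, objects


def analyze_pair(
    baseline: VoxelVolume,
    followup: VoxelVolume,
    scanner_sigma: float,
    cfg: PipelineConfig | None = None,
):
    """Longitudinal analysis of a registered baseline/follow-up pair.

    Returns ``(per-metric {name: (baseline, followup)}, objects dict)``.
    Thickness and cancellous metrics use each time point's own
    segmentation; the ICON apposition fit freezes the baseline geometry.
    """
    cfg = cfg or PipelineConfig()
    base_metrics, objs = analyze_baseline(baseline, scanner_sigma, cfg)

    seg_f = segment_cortex(followup, cfg.voi)
    fu_metrics, labels_f = _thickness_metrics(followup, seg_f)
    for comp in (VoiLabel.SPONGIOSA_PEELED, VoiLabel.SUBCORTEX):
        res = compartment_bmd_bmc(followup, seg_f, comp, cfg.cancellous_threshold)
        tag = "spongiosa" if comp == VoiLabel.SPONGIOSA_PEELED else "subcortex"
        fu_metrics[f"{tag}_bmd"] = res.compartment_bmd
        fu_metrics[f"{tag}_bmc_mg"] = res.compartment_bmc
        fu_metrics[f"{tag}_bvtv_pct"] = res.bvtv
        fu_metrics[f"{tag}_tmd"] = res.tmd

    profile_f = extract_profile(followup, objs["seg"], cfg.profile)
    app = icon.fit_apposition(objs["model"], profile_f, cfg.mineralization_fraction)
    fu_metrics["dcctth_um"] = icon.dcctth_followup(objs["model"], app)

    zones_f = zone_summary(profile_f, objs["model"].center, cfg.zones)
    for name, v in zones_f.bmd.items():
        fu_metrics[f"zone_{name.lower()}_bmd"] = v
    for name, v in zones_f.bmc.items():
        fu_metrics[f"zone_{name.lower()}_bmc"] = v

    paired = {}
    for key, bval in base_metrics.items():
        if key in fu_metrics:
            paired[key] = (bval, fu_metrics[key])
    paired["apposition_total_um"] = (0.0, app.total_width * 1000.0)
    paired["apposition_endosteal_um"] = (0.0, app.endosteal_width * 1000.0)
    paired["apposition_periosteal_um"] = (0.0, app.periosteal_width * 1000.0)

    objs.update({"seg_followup": seg_f, "profile_followup": profile_f, "apposition": app})
    return paired, objs


def run_cohort(
    subjects: list[SubjectTruth],
    cfg: PipelineConfig | None = None,
    supersampling: int = 2,
    longitudinal: bool = True,
) -> pd.DataFrame:
    """Render, acquire and analyze every cohort subject.

    Returns a long-form table (subject_id, arm, metric, baseline,
    followup) ready for :func:`corticon.stats.summarize_changes`.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for subj in subjects:
        base, follow, _ = realize_subject(subj, supersampling=supersampling)
        sigma = subj.imaging.psf_sigma_inplane
        if longitudinal:
            paired, _ = analyze_pair(base, follow, sigma, cfg)
        else:
            metrics, _ = analyze_baseline(base, sigma, cfg)
            paired = {k: (v, np.nan) for k, v in metrics.items()}
        for metric, (b, fu) in paired.items():
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "arm": subj.arm,
                    "metric": metric,
                    "baseline": b,
                    "followup": fu,
                }
            )
    if not rows:
        raise CorticonError("empty cohort")
    return pd.DataFrame(rows)
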