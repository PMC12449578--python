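"""Study conditions of the emulated romosozumab/teriparatide/placebo trial.

Arm-level summaries printed for the deconvolved cortical thickness of the
vertical cortex (um), the scanner mix, and cohort builders that pattern
the phantom generator on those conditions.  These constants are inputs to
reproduction runs, not outputs of this package.
"""

from __future__ import annotations

import numpy as np

from .phantoms import ArmSpec, ImagingSpec, PhantomSpec

__all__ = [
    "TABLE1_DCCTTH",
    "APPARENT_CTTH_BASELINE_UM",
    "DECONVOLVED_CTTH_BASELINE_UM",
    "SCANNER_MIX",
    "SPONGIOSA_BMD_BASELINE",
    "study_arms",
    "study_imaging_mix",
    "baseline_reference_arm",
]

# dcCt.Th (um) of the vertical cortex: mean +- SD at baseline / Month 12,
# and the absolute change, per treatment arm.
TABLE1_DCCTTH = {
    "placebo": {
        "n": 8,
        "baseline": (366.0, 76.0),
        "month12": (378.0, 73.0),
        "change": (12.0, 21.0),
    },
    "teriparatide": {
        "n": 12,
        "baseline": (349.0, 49.0),
        "month12": (420.0, 78.0),
        "change": (71.0, 46.0),
    },
    "romosozumab": {
        "n": 11,
        "baseline": (364.0, 36.0),
        "month12": (558.0, 77.0),
        "change": (194.0, 66.0),
    },
}

# Baseline apparent (segmentation-based) vs deconvolved cortical thickness.
APPARENT_CTTH_BASELINE_UM = (1280.0, 104.0)
DECONVOLVED_CTTH_BASELINE_UM = (359.0, 52.0)

# Scanner counts across the imaged cohort (n = 31).
SCANNER_MIX = [("SIEMENS_B70S", 4), ("PHILIPS_D", 7), ("GE_BONE", 20)]

# Peeled-spongiosa BMD baselines (mg/cc) per arm.
SPONGIOSA_BMD_BASELINE = {
    "placebo": (95.0, 28.0),
    "teriparatide": (99.0, 21.0),
    "romosozumab": (85.0, 23.0),
}

# Fraction of total apposition placed at the endosteal surface (the study
# observed the greatest changes endosteally).
ENDOSTEAL_FRACTION = 0.7


def study_arms(mineralization: float = 0.5, endosteal_fraction: float = ENDOSTEAL_FRACTION):
    """Three-arm generator specs patterned on the trial's printed summaries."""
    arms = []
    for name, row in TABLE1_DCCTTH.items():
        wmean, wsd = row["baseline"]
        cmean, csd = row["change"]
        tmean, tsd = SPONGIOSA_BMD_BASELINE[name]
        arms.append(
            ArmSpec(
                name=name,
                n=row["n"],
                width_mean=wmean,
                width_sd=wsd,
                trabecular_mean=tmean + 20.0,  # plateau sits above peeled-spongiosa BMD
                trabecular_sd=tsd / 2.0,
                endo_mean=endosteal_fraction * cmean,
                endo_sd=endosteal_fraction * csd,
                peri_mean=(1.0 - endosteal_fraction) * cmean,
                peri_sd=(1.0 - endosteal_fraction) * csd,
                mineralization_fraction=mineralization,
            )
        )
    return arms


def study_imaging_mix(noise_sd: float = 25.0):
    """Scanner presets weighted 4 Siemens : 7 Philips : 20 GE."""
    return [(ImagingSpec.preset(name, noise_sd=noise_sd), n) for name, n in SCANNER_MIX]


def baseline_reference_arm(n: int = 31) -> ArmSpec:
    """Single-arm cohort at the study's baseline deconvolved width.

    True cortical width fixed at 359 um over a trabecular plateau drawn
    from ~N(115, 15) mg/cc (the 85-145 mg/cc apparent-BMD range).
    """
    return ArmSpec(
        name="baseline",
        n=n,
        width_mean=DECONVOLVED_CTTH_BASELINE_UM[0],
        width_sd=0.0,
        trabecular_mean=115.0,
        trabecular_sd=15.0,
    )


def default_phantom_template() -> PhantomSpec:
    return PhantomSpec()


def scaled_scanner_mix(n: int, noise_sd: float = 25.0):
    """Scanner mix for an n-subject cohort, proportions 4:7:20 preserved."""
    total = sum(c for _, c in SCANNER_MIX)
    counts = [max(1, round(n * c / total)) for _, c in SCANNER_MIX]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        counts[int(np.argmax([c for _, c in SCANNER_MIX]))] += 1
    return [
        (ImagingSpec.preset(name, noise_sd=noise_sd), k)
        for (name, _), k in zip(SCANNER_MIX, counts)
    ]


def simulate_baseline_thickness(
    n: int = 31,
    seed: int = 1,
    noise_sd: float = 25.0,
    supersampling: int = 2,
):
    """Image n phantoms at the study's baseline cortical width and measure
    apparent (Maximum-Sphere) and deconvolved cortical thickness.

    Returns a DataFrame with one row per subject (ctth_um, wctth_um,
    dcctth_um, scanner preset).
    """
    import pandas as pd

    from .phantoms import acquire, generate_cohort, render_phantom
    from .pipeline import analyze_baseline

    mix = scaled_scanner_mix(n, noise_sd) if n != 31 else study_imaging_mix(noise_sd)
    subjects, _ = generate_cohort([baseline_reference_arm(n)], mix, seed=seed)
    rows = []
    for subj in subjects:
        truth = render_phantom(subj.phantom, supersampling=supersampling)
        vol = acquire(truth, subj.imaging, seed=subj.seed)
        metrics, _ = analyze_baseline(vol, subj.imaging.psf_sigma_inplane)
        rows.append(
            {
                "subject_id": subj.subject_id,
                "scanner_preset": subj.imaging.scanner_preset,
                "ctth_um": metrics["ctth_um"],
                "wctth_um": metrics["wctth_um"],
                "dcctth_um": metrics["dcctth_um"],
            }
        )
    return pd.DataFrame(rows)
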