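"""Published reference quantities for cis-/trans-parinaric acid (c-PnA,
t-PnA) in POPC (fluid) and DPPC (gel) bilayers.

These are literature best-fit values used as *inputs* to desk-scale
reproductions: multiexponential rotational-ACF parameters per
probe/lipid system, and gel-phase sn-1 tilt-distribution variances binned
by the lipid-to-probe COM distance R (near: R < 0.7 nm, mid:
0.7-1.2 nm, far: R > 1.2 nm).
"""

from __future__ import annotations

from .dynamics import ACFFitParams

#: Rotational-ACF model parameters (amplitudes dimensionless, times in ns)
#: keyed by (probe, lipid).
ACF_FIT_PARAMS: dict[tuple[str, str], dict] = {
    ("c-PnA", "POPC"): {
        "amplitudes": [0.42, 0.58],
        "times": [0.10, 1.8],
        "a_inf": 0.032,
    },
    ("t-PnA", "POPC"): {
        "amplitudes": [0.27, 0.33, 0.047],
        "times": [0.46, 2.6, 15.0],
        "a_inf": 0.26,
    },
    ("c-PnA", "DPPC"): {
        "amplitudes": [0.11, 0.050],
        "times": [2.9, 120.0],
        "a_inf": 0.71,
    },
    ("t-PnA", "DPPC"): {
        "amplitudes": [0.02, 0.01, 0.01],
        "times": [0.16, 22.0, 850.0],
        "a_inf": 0.92,
    },
}

#: DPPC sn-1 tilt-distribution variances (deg^2) by proximity bin, keyed
#: by the probe present in the bilayer.
TILT_VARIANCES_DPPC: dict[str, dict[str, float]] = {
    "c-PnA": {"far": 33.5, "mid": 64.4, "near": 85.1},
    "t-PnA": {"far": 37.3, "mid": 49.6, "near": 51.4},
}


def reference_acf_fit(probe: str, lipid: str) -> ACFFitParams:
    """Build an :class:`ACFFitParams` from the published parameter set for
    the given probe/lipid system."""
    p = ACF_FIT_PARAMS[(probe, lipid)]
    return ACFFitParams(
        amplitudes=p["amplitudes"], times=p["times"], a_inf=p["a_inf"]
    )
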