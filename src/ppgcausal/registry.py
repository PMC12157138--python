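"""Machine-readable registry of the 218 PPG features.

The registry fixes the name, category and order of every feature the
extractor emits.  Category slot counts follow the standard taxonomy for
PPG morphology features: 3 frequency-domain, 27 point-of-interest
amplitudes, 28 intervals, 12 areas, 21 cyclicality, 21 systolic/
diastolic widths, 2 signal-quality indices, 4 vascular indices, 25
slope-deviation-curve summaries and 75 histogram bins (15 per signal
over PPG and its four derivatives), for 218 features in total.

Names encode the definition: e.g. ``ppg_amp_w`` is the onset-referenced
PPG amplitude at the w point (steepest systolic rise on VPG),
``t_on_sys_norm`` the onset-to-systolic-peak interval divided by the
cycle duration Tc, ``sw50_s`` the systolic width at 50% of the systolic
peak amplitude in seconds.
"""

from __future__ import annotations

import json
from functools import lru_cache

__all__ = [
    "SIGNALS",
    "CATEGORY_COUNTS",
    "feature_registry",
    "feature_names",
    "category_of",
    "registry_json",
]

#: PPG and its first four derivatives (velocity, acceleration, jerk, snap)
SIGNALS = ("ppg", "vpg", "apg", "jpg", "spg")

#: fiducial points carrying an onset-referenced PPG amplitude
PPG_POI = ("sys", "notch", "dia", "w", "y", "z", "a", "b", "c", "d", "e")
#: fiducial points read on the VPG
VPG_POI = ("w", "y", "z", "a", "b", "c", "d", "e")
#: fiducial points read on the APG
APG_POI = ("a", "b", "c", "d", "e")

#: Tc-normalized inter-event intervals (pairs of fiducials)
INTERVAL_PAIRS = (
    ("sys", "notch"),
    ("notch", "dia"),
    ("sys", "dia"),
    ("sys", "end"),
    ("w", "y"),
    ("y", "z"),
    ("a", "b"),
    ("b", "c"),
    ("c", "d"),
    ("d", "e"),
)

WIDTH_LEVELS = (25, 50, 75)

DEVIATION_STATS = (
    "max",
    "min",
    "mean",
    "sd",
    "rms",
    "area",
    "argmax_norm",
    "argmin_norm",
    "skew",
    "zero_crossings",
)

CATEGORY_COUNTS = {
    "frequency": 3,
    "poi": 27,
    "interval": 28,
    "area": 12,
    "cyclicality": 21,
    "width": 21,
    "sqi": 2,
    "index": 4,
    "deviation": 25,
    "histogram": 75,
}

N_HIST_BINS = 15


@lru_cache(maxsize=1)
def feature_registry() -> tuple[tuple[str, str], ...]:
    """Ordered (name, category) pairs for all 218 features."""
    reg: list[tuple[str, str]] = []

    for name in ("fft_peak_freq", "fft_peak_height", "fft_peak_band_mean"):
        reg.append((name, "frequency"))

    for p in PPG_POI:
        reg.append((f"ppg_amp_{p}", "poi"))
    for p in VPG_POI:
        reg.append((f"vpg_at_{p}", "poi"))
    for p in APG_POI:
        reg.append((f"apg_at_{p}", "poi"))
    for name in ("ratio_notch_sys", "ratio_dia_sys", "ratio_vpg_y_w"):
        reg.append((name, "poi"))

    reg.append(("tc_s", "interval"))
    for p in PPG_POI:
        reg.append((f"t_on_{p}_norm", "interval"))
    for a, b in INTERVAL_PAIRS:
        reg.append((f"t_{a}_{b}_norm", "interval"))
    for name in (
        "t_on_sys_s",
        "t_on_notch_s",
        "t_sys_end_s",
        "t_a_e_s",
        "t_w_y_s",
        "hr_tc_bpm",
    ):
        reg.append((name, "interval"))

    for name in (
        "s1_frac",
        "s2_frac",
        "s3_frac",
        "s4_frac",
        "s1_area",
        "s2_area",
        "s3_area",
        "s4_area",
        "area_total",
        "ipa_s4_s1",
        "area_sys_dia_ratio",
        "area_mean_amp",
    ):
        reg.append((name, "area"))

    for s in SIGNALS:
        reg.append((f"ac_lag_norm_{s}", "cyclicality"))
        reg.append((f"ac_height_{s}", "cyclicality"))
        reg.append((f"periodicity_{s}", "cyclicality"))
    for name in ("hr_bpm", "ibi_mean_s", "ibi_sd_s", "ibi_cv", "ibi_range_s", "n_beats"):
        reg.append((name, "cyclicality"))

    for lvl in WIDTH_LEVELS:
        reg.append((f"sw{lvl}_s", "width"))
        reg.append((f"dw{lvl}_s", "width"))
    for lvl in WIDTH_LEVELS:
        reg.append((f"sw{lvl}_norm", "width"))
        reg.append((f"dw{lvl}_norm", "width"))
    for lvl in WIDTH_LEVELS:
        reg.append((f"dw_sw_ratio_{lvl}", "width"))
    for lvl in WIDTH_LEVELS:
        reg.append((f"width{lvl}_s", "width"))
    for lvl in WIDTH_LEVELS:
        reg.append((f"width{lvl}_norm", "width"))

    reg.append(("sqi_skew", "sqi"))
    reg.append(("sqi_kurtosis", "sqi"))

    for name in ("aging_index", "ibd_index", "ibcda_index", "isdoo_index"):
        reg.append((name, "index"))

    for side in ("usdc", "dsdc"):
        for stat in DEVIATION_STATS:
            reg.append((f"{side}_{stat}", "deviation"))
    for name in (
        "usdc_dsdc_rms_ratio",
        "usdc_dsdc_area_ratio",
        "usdc_dsdc_absmax_ratio",
        "usdc_dsdc_sd_ratio",
        "rise_fall_duration_ratio",
    ):
        reg.append((name, "deviation"))

    for s in SIGNALS:
        for i in range(N_HIST_BINS):
            reg.append((f"hist_{s}_{i:02d}", "histogram"))

    assert len(reg) == sum(CATEGORY_COUNTS.values()) == 218
    assert len({n for n, _ in reg}) == 218, "registry names must be unique"
    return tuple(reg)


def feature_names() -> list[str]:
    return [name for name, _ in feature_registry()]


def category_of(name: str) -> str:
    return dict(feature_registry())[name]


def registry_json() -> str:
    """Serialize the registry (for export as package-side metadata)."""
    return json.dumps(
        [{"name": n, "category": c} for n, c in feature_registry()], indent=1
    )
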