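"""PPG derivative computation, fiducial detection and the 218-feature vector.

Per segment, the PPG and its first four derivatives (VPG, APG, JPG,
SPG) are scanned beat by beat for fiducial points: pulse onset,
systolic peak, dicrotic notch and diastolic peak on the PPG; the
steepest rise (w), maximum negative slope (y) and diastolic rise (z) on
the VPG; and the five early-to-late waves a, b, c, d, e on the APG.
Morphological features (amplitudes, Tc-normalized intervals, widths at
25/50/75% of the systolic amplitude, segmental areas S1-S4, slope
deviation curves, vascular indices) are computed per beat and
aggregated by the median over accepted beats; frequency, SQI,
cyclicality and histogram features are computed once per segment.  The
output always has the 218 registry names in registry order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from . import registry
from .exceptions import InsufficientData, InvalidInput
from .signals import TARGET_FS, CleanSegment

__all__ = [
    "DerivativeStack",
    "BeatFiducials",
    "FiducialSet",
    "derivatives",
    "detect_fiducials",
    "fft_features",
    "time_features",
    "deviation_features",
    "histogram_features",
    "index_features",
    "extract_features",
    "build_feature_table",
]


def _smooth5(x: np.ndarray) -> np.ndarray:
    """5-point moving average with edge replication (length preserving)."""
    kernel = np.ones(5) / 5.0
    return np.convolve(np.pad(x, 2, mode="edge"), kernel, mode="valid")


@dataclass
class DerivativeStack:
    """PPG and its first four time derivatives, all aligned at one rate."""

    ppg: np.ndarray
    vpg: np.ndarray
    apg: np.ndarray
    jpg: np.ndarray
    spg: np.ndarray
    fs: float = TARGET_FS

    @property
    def signals(self) -> dict[str, np.ndarray]:
        return {
            "ppg": self.ppg,
            "vpg": self.vpg,
            "apg": self.apg,
            "jpg": self.jpg,
            "spg": self.spg,
        }


def derivatives(ppg: np.ndarray, fs: float = TARGET_FS) -> DerivativeStack:
    """Successive smoothed central-difference derivatives of the PPG.

    A 5-point moving average is applied before each differentiation;
    without it the 3rd/4th derivatives (JPG/SPG) are dominated by noise.
    """
    ppg = np.asarray(ppg, dtype=float)
    if ppg.size < 5:
        raise InvalidInput("need at least 5 samples to differentiate")
    out = [ppg]
    cur = ppg
    for _ in range(4):
        cur = np.gradient(_smooth5(cur)) * fs
        out.append(cur)
    return DerivativeStack(*out, fs=fs)


@dataclass
class BeatFiducials:
    """Fiducial sample indices for one beat (None when undetectable)."""

    onset: int
    next_onset: int
    sys_peak: int
    w: int
    y: int
    a: int
    b: int
    z: int | None = None
    notch: int | None = None
    dia_peak: int | None = None
    c: int | None = None
    d: int | None = None
    e: int | None = None
    tc: float = 0.0


@dataclass
class FiducialSet:
    beats: list[BeatFiducials] = field(default_factory=list)
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.beats)


def _first_peak(x: np.ndarray, prominence: float | None = None) -> int | None:
    peaks, _ = sps.find_peaks(x, prominence=prominence)
    return int(peaks[0]) if peaks.size else None


def detect_fiducials(
    stack: DerivativeStack, onsets: np.ndarray, fs: float = TARGET_FS
) -> FiducialSet:
    """Locate per-beat fiducials on the PPG/VPG/APG between onsets.

    w is the VPG maximum within the systolic upstroke, y the VPG minimum
    after the systolic peak, z the first VPG local maximum of diastole;
    a and b are the first APG maximum/minimum, c, d, e the subsequent
    alternating APG extrema.  Beats whose core extrema are missing (flat
    beats) are skipped and logged.
    """
    ppg, vpg, apg = stack.ppg, stack.vpg, stack.apg
    onsets = np.asarray(onsets, dtype=int)
    fset = FiducialSet()
    for k, (on, nxt) in enumerate(zip(onsets[:-1], onsets[1:])):
        if nxt - on < 10 or np.ptp(ppg[on:nxt]) == 0:
            fset.skipped.append((k, "flat_beat"))
            continue
        sys_peak = on + int(np.argmax(ppg[on:nxt]))
        if sys_peak <= on + 1 or sys_peak >= nxt - 2:
            fset.skipped.append((k, "no_systolic_peak"))
            continue
        # landmark scans are prominence-gated (relative to the beat's
        # own derivative range) so residual-noise wiggles are ignored,
        # and the w search skips the foot transient
        ppg_prom = 0.02 * np.ptp(ppg[on:nxt])
        vpg_prom = 0.03 * np.ptp(vpg[on:nxt])
        apg_prom = 0.05 * np.ptp(apg[on:nxt])
        delta = max(3, int(0.08 * (nxt - on)))
        w_lo = on + delta if on + delta < sys_peak else on
        w = w_lo + int(np.argmax(vpg[w_lo : sys_peak + 1]))
        y = sys_peak + int(np.argmin(vpg[sys_peak:nxt]))
        zp = _first_peak(vpg[y:nxt], vpg_prom)
        z = y + zp if zp is not None else None
        np_ = _first_peak(-ppg[sys_peak:nxt], ppg_prom)
        notch = sys_peak + np_ if np_ is not None else None
        dia = None
        if notch is not None:
            dp = _first_peak(ppg[notch:nxt], ppg_prom)
            dia = notch + dp if dp is not None else None
        a = on + int(np.argmax(apg[on : w + 1])) if w > on else None
        if a is None:
            fset.skipped.append((k, "no_a_wave"))
            continue
        valleys, _ = sps.find_peaks(-apg[a + 1 : nxt], prominence=apg_prom)
        if valleys.size == 0:
            fset.skipped.append((k, "no_b_wave"))
            continue
        b = a + 1 + int(valleys[0])
        # c, d, e: alternating max/min/max after b
        seg_peaks, _ = sps.find_peaks(apg[b + 1 : nxt], prominence=apg_prom)
        seg_valleys, _ = sps.find_peaks(-apg[b + 1 : nxt], prominence=apg_prom)
        c = d = e = None
        maxima = [b + 1 + int(i) for i in seg_peaks]
        minima = [b + 1 + int(i) for i in seg_valleys]
        if maxima:
            c = maxima[0]
            later_min = [m for m in minima if m > c]
            if later_min:
                d = later_min[0]
                later_max = [m for m in maxima if m > d]
                if later_max:
                    e = later_max[0]
        fset.beats.append(
            BeatFiducials(
                onset=int(on),
                next_onset=int(nxt),
                sys_peak=sys_peak,
                w=w,
                y=y,
                a=a,
                b=b,
                z=z,
                notch=notch,
                dia_peak=dia,
                c=c,
                d=d,
                e=e,
                tc=(nxt - on) / fs,
            )
        )
    return fset


def fft_features(x: np.ndarray, fs: float = TARGET_FS) -> tuple[float, float, float]:
    """Dominant-spectral-peak features in the 0.5-10 Hz cardiac band.

    Returns (peak frequency, peak magnitude, mean magnitude over the
    +/-3 bins around the peak) of the mean-removed magnitude spectrum.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 128:
        raise InvalidInput("need at least 128 samples for spectral features")
    if np.ptp(x) == 0:
        return 0.0, 0.0, 0.0
    mag = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    band = np.nonzero((freqs >= 0.5) & (freqs <= 10.0))[0]
    if band.size == 0:
        return 0.0, 0.0, 0.0
    peak = band[int(np.argmax(mag[band]))]
    lo, hi = max(0, peak - 3), min(mag.size, peak + 4)
    return float(freqs[peak]), float(mag[peak]), float(mag[lo:hi].mean())


def _safe_div(num: float, den: float) -> float:
    if den == 0 or not math.isfinite(den) or not math.isfinite(num):
        return float("nan")
    return num / den


def _amp(ppg: np.ndarray, fid: BeatFiducials, idx: int | None) -> float:
    if idx is None:
        return float("nan")
    return float(ppg[idx] - ppg[fid.onset])


def _poi_features(fid: BeatFiducials, stack: DerivativeStack) -> dict[str, float]:
    ppg, vpg, apg = stack.ppg, stack.vpg, stack.apg
    loc = {
        "sys": fid.sys_peak,
        "notch": fid.notch,
        "dia": fid.dia_peak,
        "w": fid.w,
        "y": fid.y,
        "z": fid.z,
        "a": fid.a,
        "b": fid.b,
        "c": fid.c,
        "d": fid.d,
        "e": fid.e,
    }
    out: dict[str, float] = {}
    for p in registry.PPG_POI:
        out[f"ppg_amp_{p}"] = _amp(ppg, fid, loc[p])
    for p in registry.VPG_POI:
        out[f"vpg_at_{p}"] = float(vpg[loc[p]]) if loc[p] is not None else float("nan")
    for p in registry.APG_POI:
        out[f"apg_at_{p}"] = float(apg[loc[p]]) if loc[p] is not None else float("nan")
    out["ratio_notch_sys"] = _safe_div(out["ppg_amp_notch"], out["ppg_amp_sys"])
    out["ratio_dia_sys"] = _safe_div(out["ppg_amp_dia"], out["ppg_amp_sys"])
    out["ratio_vpg_y_w"] = _safe_div(out["vpg_at_y"], out["vpg_at_w"])
    return out


def _interval_features(fid: BeatFiducials, fs: float) -> dict[str, float]:
    span = fid.next_onset - fid.onset
    loc = {
        "sys": fid.sys_peak,
        "notch": fid.notch,
        "dia": fid.dia_peak,
        "w": fid.w,
        "y": fid.y,
        "z": fid.z,
        "a": fid.a,
        "b": fid.b,
        "c": fid.c,
        "d": fid.d,
        "e": fid.e,
        "end": fid.next_onset,
    }
    out = {"tc_s": fid.tc}
    for p in registry.PPG_POI:
        out[f"t_on_{p}_norm"] = (
            (loc[p] - fid.onset) / span if loc[p] is not None else float("nan")
        )
    for a, b in registry.INTERVAL_PAIRS:
        if loc[a] is None or loc[b] is None:
            out[f"t_{a}_{b}_norm"] = float("nan")
        else:
            out[f"t_{a}_{b}_norm"] = (loc[b] - loc[a]) / span
    out["t_on_sys_s"] = (fid.sys_peak - fid.onset) / fs
    out["t_on_notch_s"] = (
        (fid.notch - fid.onset) / fs if fid.notch is not None else float("nan")
    )
    out["t_sys_end_s"] = (fid.next_onset - fid.sys_peak) / fs
    out["t_a_e_s"] = (fid.e - fid.a) / fs if fid.e is not None else float("nan")
    out["t_w_y_s"] = (fid.y - fid.w) / fs
    out["hr_tc_bpm"] = 60.0 / fid.tc
    return out


def _area_features(fid: BeatFiducials, stack: DerivativeStack, fs: float) -> dict[str, float]:
    nan = float("nan")
    out = {k: nan for k in (
        "s1_frac", "s2_frac", "s3_frac", "s4_frac",
        "s1_area", "s2_area", "s3_area", "s4_area",
        "area_total", "ipa_s4_s1", "area_sys_dia_ratio", "area_mean_amp",
    )}
    if fid.notch is None or fid.dia_peak is None:
        return out
    y = stack.ppg - stack.ppg[fid.onset]
    bounds = [fid.onset, fid.sys_peak, fid.notch, fid.dia_peak, fid.next_onset]
    if any(b2 <= b1 for b1, b2 in zip(bounds[:-1], bounds[1:])):
        return out
    areas = [
        float(np.trapezoid(y[b1 : b2 + 1], dx=1.0 / fs))
        for b1, b2 in zip(bounds[:-1], bounds[1:])
    ]
    total = sum(areas)
    for i, s in enumerate(areas, start=1):
        out[f"s{i}_area"] = s
        out[f"s{i}_frac"] = _safe_div(s, total)
    out["area_total"] = total
    out["ipa_s4_s1"] = _safe_div(areas[3], areas[0])
    out["area_sys_dia_ratio"] = _safe_div(areas[0] + areas[1], areas[2] + areas[3])
    out["area_mean_amp"] = _safe_div(total, fid.tc)
    return out


def _width_features(fid: BeatFiducials, stack: DerivativeStack, fs: float) -> dict[str, float]:
    ppg = stack.ppg
    base = ppg[fid.onset]
    amp = ppg[fid.sys_peak] - base
    out: dict[str, float] = {}
    for lvl in registry.WIDTH_LEVELS:
        level = base + (lvl / 100.0) * amp
        rise = ppg[fid.onset : fid.sys_peak + 1]
        fall = ppg[fid.sys_peak : fid.next_onset]
        sw = dw = float("nan")
        above_r = np.nonzero(rise >= level)[0]
        if above_r.size:
            sw = (rise.size - 1 - above_r[0]) / fs
        above_f = np.nonzero(fall >= level)[0]
        if above_f.size:
            dw = above_f[-1] / fs
        out[f"sw{lvl}_s"] = sw
        out[f"dw{lvl}_s"] = dw
        out[f"sw{lvl}_norm"] = _safe_div(sw, fid.tc)
        out[f"dw{lvl}_norm"] = _safe_div(dw, fid.tc)
        out[f"dw_sw_ratio_{lvl}"] = _safe_div(dw, sw)
        out[f"width{lvl}_s"] = sw + dw
        out[f"width{lvl}_norm"] = _safe_div(sw + dw, fid.tc)
    return out


def _curve_stats(curve: np.ndarray, span: int, fs: float) -> dict[str, float]:
    if curve.size < 3:
        return {s: 0.0 for s in registry.DEVIATION_STATS}
    sd = float(curve.std())
    signs = np.sign(curve)
    signs = signs[signs != 0]
    zc = int(np.sum(signs[1:] != signs[:-1])) if signs.size > 1 else 0
    return {
        "max": float(curve.max()),
        "min": float(curve.min()),
        "mean": float(curve.mean()),
        "sd": sd,
        "rms": float(np.sqrt(np.mean(curve**2))),
        "area": float(np.trapezoid(curve, dx=1.0 / fs)),
        "argmax_norm": float(np.argmax(curve)) / span,
        "argmin_norm": float(np.argmin(curve)) / span,
        "skew": float(stats.skew(curve)) if sd > 0 else 0.0,
        "zero_crossings": float(zc),
    }


def deviation_features(
    ppg: np.ndarray, fid: BeatFiducials, fs: float = TARGET_FS
) -> dict[str, float]:
    """Rising/descending slope-deviation-curve summaries (25 values).

    USDC_i = x_i - (x_onset + s_bar * (t_i - t_onset)) with s_bar the
    mean rising slope over onset -> systolic peak; DSDC analogously on
    the descending edge.  A degenerate (<3 sample) edge yields zeros.
    """
    span = fid.next_onset - fid.onset
    out: dict[str, float] = {}
    edges = {}
    for side, (lo, hi) in (
        ("usdc", (fid.onset, fid.sys_peak)),
        ("dsdc", (fid.sys_peak, fid.next_onset - 1)),
    ):
        n = hi - lo + 1
        if n < 3:
            curve = np.zeros(0)
        else:
            y = ppg[lo : hi + 1]
            slope = (y[-1] - y[0]) / (n - 1)
            curve = y - (y[0] + slope * np.arange(n))
        edges[side] = curve
        for stat, val in _curve_stats(curve, span, fs).items():
            out[f"{side}_{stat}"] = val
    out["usdc_dsdc_rms_ratio"] = _safe_div(out["usdc_rms"], out["dsdc_rms"])
    out["usdc_dsdc_area_ratio"] = _safe_div(out["usdc_area"], out["dsdc_area"])
    out["usdc_dsdc_absmax_ratio"] = _safe_div(
        max(abs(out["usdc_max"]), abs(out["usdc_min"])),
        max(abs(out["dsdc_max"]), abs(out["dsdc_min"])),
    )
    out["usdc_dsdc_sd_ratio"] = _safe_div(out["usdc_sd"], out["dsdc_sd"])
    out["rise_fall_duration_ratio"] = _safe_div(
        fid.sys_peak - fid.onset, (fid.next_onset - 1) - fid.sys_peak
    )
    return out


def index_features(fid: BeatFiducials, stack: DerivativeStack) -> dict[str, float]:
    """Vascular aging indices from the APG a-e wave amplitudes.

    AgingIndex = (b - c - d - e) / a; I_bd = (b - d)/a;
    I_bcda = (b - c - d)/a; I_sdoo = (s - d)/a with s the systolic-peak
    PPG amplitude.  Undefined (recorded missing) when a = 0 or any
    required wave is absent.
    """
    nan = float("nan")
    names = ("aging_index", "ibd_index", "ibcda_index", "isdoo_index")
    if any(getattr(fid, p) is None for p in ("a", "b", "c", "d", "e")):
        return {k: nan for k in names}
    apg = stack.apg
    a, b, c, d, e = (float(apg[getattr(fid, p)]) for p in ("a", "b", "c", "d", "e"))
    if a == 0:
        return {k: nan for k in names}
    s = float(stack.ppg[fid.sys_peak] - stack.ppg[fid.onset])
    return {
        "aging_index": (b - c - d - e) / a,
        "ibd_index": (b - d) / a,
        "ibcda_index": (b - c - d) / a,
        "isdoo_index": (s - d) / a,
    }


def histogram_features(stack: DerivativeStack) -> dict[str, float]:
    """15-bin density-normalized histogram per signal (75 values).

    Bins span each signal's own min-max range; masses sum to 1.  A
    constant signal puts all mass in the first bin.
    """
    out: dict[str, float] = {}
    for name, sig in stack.signals.items():
        if np.ptp(sig) == 0:
            masses = np.zeros(registry.N_HIST_BINS)
            masses[0] = 1.0
        else:
            counts, _ = np.histogram(sig, bins=registry.N_HIST_BINS)
            masses = counts / sig.size
        for i, m in enumerate(masses):
            out[f"hist_{name}_{i:02d}"] = float(m)
    return out


def _cyclicality_features(
    stack: DerivativeStack, onsets: np.ndarray, fs: float
) -> dict[str, float]:
    nan = float("nan")
    out: dict[str, float] = {}
    onsets = np.asarray(onsets, dtype=int)
    ibis = np.diff(onsets) / fs if onsets.size >= 2 else np.zeros(0)
    mean_ibi = float(ibis.mean()) if ibis.size else nan
    out["hr_bpm"] = 60.0 / mean_ibi if ibis.size else nan
    out["ibi_mean_s"] = mean_ibi
    out["ibi_sd_s"] = float(ibis.std()) if ibis.size else nan
    out["ibi_cv"] = _safe_div(out["ibi_sd_s"], mean_ibi)
    out["ibi_range_s"] = float(np.ptp(ibis)) if ibis.size else nan
    out["n_beats"] = float(ibis.size)
    lo = int(0.3 * fs)
    for name, sig in stack.signals.items():
        n = sig.size
        hi = min(int(2.2 * fs), n - 2)
        if np.ptp(sig) == 0 or hi <= lo:
            out[f"ac_lag_norm_{name}"] = nan
            out[f"ac_height_{name}"] = nan
            out[f"periodicity_{name}"] = nan
            continue
        x0 = sig - sig.mean()
        ac = np.correlate(x0, x0, mode="full")[n - 1 :]
        ac = ac / ac[0]
        window = ac[lo : hi + 1]
        peaks, _ = sps.find_peaks(window)
        if peaks.size:
            lag = lo + int(peaks[np.argmax(window[peaks])])
        else:
            lag = lo + int(np.argmax(window))
        out[f"ac_lag_norm_{name}"] = _safe_div(lag / fs, mean_ibi)
        out[f"ac_height_{name}"] = float(ac[lag])
        power = np.abs(np.fft.rfft(x0)) ** 2
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        band = (freqs >= 0.5) & (freqs <= 10.0)
        cardiac = (freqs >= 0.5) & (freqs <= 3.0)
        if not np.any(cardiac) or power[band].sum() == 0:
            out[f"periodicity_{name}"] = nan
            continue
        f0 = np.nonzero(cardiac)[0][int(np.argmax(power[cardiac]))]
        sel = power[max(0, f0 - 2) : f0 + 3].sum()
        out[f"periodicity_{name}"] = float(sel / power[band].sum())
    return out


def time_features(
    fiducials: FiducialSet, stack: DerivativeStack, fs: float = TARGET_FS
) -> pd.DataFrame:
    """Per-beat interval, area and width features (one row per beat)."""
    rows = []
    for fid in fiducials.beats:
        row: dict[str, float] = {}
        row.update(_interval_features(fid, fs))
        row.update(_area_features(fid, stack, fs))
        row.update(_width_features(fid, stack, fs))
        rows.append(row)
    return pd.DataFrame(rows)


def extract_features(segment: CleanSegment) -> pd.Series:
    """The full 218-feature vector for one cleaned segment.

    Per-beat features are aggregated by the median over accepted beats
    (NaN-aware); features that cannot be computed on any beat are set to
    0.  Raises when no beat yields usable fiducials.
    """
    fs = segment.fs
    stack = derivatives(segment.ppg, fs)
    fiducials = detect_fiducials(stack, segment.onsets, fs)
    if len(fiducials) == 0:
        raise InsufficientData("segment unusable: no beat with detectable fiducials")
    per_beat: list[dict[str, float]] = []
    for fid in fiducials.beats:
        row: dict[str, float] = {}
        row.update(_poi_features(fid, stack))
        row.update(_interval_features(fid, fs))
        row.update(_area_features(fid, stack, fs))
        row.update(_width_features(fid, stack, fs))
        row.update(deviation_features(stack.ppg, fid, fs))
        row.update(index_features(fid, stack))
        per_beat.append(row)
    beat_df = pd.DataFrame(per_beat)
    values: dict[str, float] = {
        col: float(np.nanmedian(beat_df[col])) if beat_df[col].notna().any() else float("nan")
        for col in beat_df.columns
    }
    pk_freq, pk_height, pk_mean = fft_features(segment.ppg, fs)
    values["fft_peak_freq"] = pk_freq
    values["fft_peak_height"] = pk_height
    values["fft_peak_band_mean"] = pk_mean
    values["sqi_skew"] = segment.sqi_skew
    values["sqi_kurtosis"] = segment.sqi_kurtosis
    values.update(histogram_features(stack))
    values.update(_cyclicality_features(stack, segment.onsets, fs))
    names = registry.feature_names()
    missing = set(names) - set(values)
    if missing:
        raise RuntimeError(f"extractor/registry mismatch: {sorted(missing)[:5]}")
    vec = pd.Series({name: values[name] for name in names}, dtype=float)
    return vec.fillna(0.0)


def build_feature_table(
    segments: list[CleanSegment], dataset_id: str = "dataset"
) -> pd.DataFrame:
    """Stack per-segment feature vectors into a labelled feature table."""
    rows = []
    for seg in segments:
        vec = extract_features(seg)
        vec["sbp"] = seg.sbp
        vec["dbp"] = seg.dbp
        vec["subject_id"] = seg.subject_id
        vec["dataset"] = dataset_id
        rows.append(vec)
    return pd.DataFrame(rows).reset_index(drop=True)
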