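"""Synthetic data with known ground truth.

Two families of generators make the whole pipeline testable without any
recorded data:

* waveform generators (:func:`gen_ppg`, :func:`gen_abp`) emit multi-beat
  pulse trains from a fixed beat template -- a systolic Gaussian lobe, a
  dicrotic Gaussian lobe and an end-diastolic runoff term -- with
  controllable heart rate, additive white noise and sinusoidal baseline
  drift, and record the exact generated onsets and fiducial points;

* :func:`gen_multisource` draws K feature tables from a structural
  causal model in which the target (blood pressure) has a known Markov
  blanket (parents, child, spouse) whose mechanism is shared across
  datasets, while designated spurious features are correlated with the
  target only inside their own dataset.  This embodies the causal-
  invariance notion the selection algorithm is built around: the
  blanket's feature-target relationship is stable across environments,
  the spurious ones are not.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .signals import RawRecord

__all__ = [
    "WaveformTruth",
    "SCMSpec",
    "SCMTruth",
    "ppg_beat_template",
    "gen_ppg",
    "gen_abp",
    "gen_multisource",
    "default_scm_spec",
    "gen_mb_benchmark",
    "gen_two_parent",
    "gen_bp_table",
    "MultiSourceStudy",
]

# imported late to avoid a cycle (invariance imports gcmi only)
from .invariance import MultiSourceStudy  # noqa: E402


def ppg_beat_template(n: int) -> np.ndarray:
    """One beat sampled at ``n`` points over the cycle [0, 1).

    Systolic lobe (amplitude 1.0 at 30% of the cycle, width 8%), a
    dicrotic lobe (0.25 at 65%, width 10%) and an end-diastolic runoff
    0.5*(1-u)^0.25 whose accelerating decay gives the pulse foot a
    deep, sharp minimum.  The shape is smoothed periodically (Gaussian,
    ~1.2% of the cycle) so the cycle wrap is continuous, then rolled so
    the foot sits exactly at index 0.  Chosen so that the VPG/APG
    extrema (w, y, z; a-e) all exist and are numerically locatable.
    """
    from scipy.ndimage import gaussian_filter1d

    u = np.arange(n) / n
    raw = (
        np.exp(-0.5 * ((u - 0.30) / 0.08) ** 2)
        + 0.25 * np.exp(-0.5 * ((u - 0.65) / 0.10) ** 2)
        + 0.5 * (1.0 - u) ** 0.25
    )
    beat = gaussian_filter1d(raw, sigma=max(1.0, 0.012 * n), mode="wrap")
    # start the cycle at the foot: the maximum-curvature point of the
    # pre-systolic basin (the standard pulse-foot landmark; one sample
    # off the plain minimum here)
    ext = np.concatenate([beat[-2:], beat, beat[:2]])
    curv = ext[:-4] + ext[4:] - 2.0 * beat
    basin = np.argsort(beat)[: max(4, n // 10)]
    foot = int(basin[np.argmax(curv[basin])])
    return np.roll(beat, -foot)


@dataclass
class WaveformTruth:
    """Exact generated fiducials for a synthetic pulse train."""

    onsets: np.ndarray
    systolic_peaks: np.ndarray
    fiducials: dict[str, np.ndarray]
    period: int
    fs: float
    seed: int | None = None
    sbp: float | None = None
    dbp: float | None = None


def _template_fiducials(beat: np.ndarray) -> dict[str, int]:
    """Fiducial offsets within one clean template beat (sample units).

    The noise-free template is tiled and scanned with the package's
    fiducial definition, so the stored truth is the exact noiseless
    location of every landmark under that definition; recovery tests on
    noisy waveforms then measure noise-induced displacement only.
    """
    from .features import derivatives, detect_fiducials

    n = beat.size
    tiled = np.tile(beat, 3)
    stack = derivatives(tiled, fs=float(n))  # fs only scales amplitudes
    fset = detect_fiducials(stack, np.array([0, n, 2 * n, 3 * n - 1]), fs=float(n))
    mid = next(bf for bf in fset.beats if bf.onset == n)
    name_map = {
        "sys": "sys_peak",
        "w": "w",
        "y": "y",
        "z": "z",
        "notch": "notch",
        "dia": "dia_peak",
        "a": "a",
        "b": "b",
        "c": "c",
        "d": "d",
        "e": "e",
    }
    out = {}
    for key, attr in name_map.items():
        val = getattr(mid, attr)
        out[key] = int(val) - n if val is not None else 0
    return out


def gen_ppg(
    hr_bpm: float = 60.0,
    n_beats: int = 30,
    noise_sd: float = 0.02,
    drift_amp: float = 0.1,
    fs: float = 125.0,
    seed: int = 0,
    subject_id: str = "sim",
    labels: tuple[float, float] | None = None,
) -> tuple[RawRecord, WaveformTruth]:
    """Synthetic PPG pulse train with known onsets and fiducials.

    The waveform is a periodic repetition of the beat template plus
    white noise (``noise_sd``) and a sinusoidal baseline drift
    (``drift_amp``, 10 s period).  Identical seeds give bit-identical
    waveforms.
    """
    if not (30.0 <= hr_bpm <= 180.0):
        raise ConfigurationError(f"heart rate {hr_bpm} outside 30-180 bpm")
    if fs < 50.0:
        raise ConfigurationError("sampling rate must be at least 50 Hz")
    if n_beats < 1 or noise_sd < 0 or drift_amp < 0:
        raise ConfigurationError("invalid generator parameters")
    period = int(round(fs * 60.0 / hr_bpm))
    beat = ppg_beat_template(period)
    clean = np.tile(beat, n_beats)
    n = clean.size
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    x = clean + drift_amp * np.sin(2.0 * np.pi * t / 10.0) + rng.normal(0.0, noise_sd, n)
    offsets = _template_fiducials(beat)
    onsets = np.arange(n_beats) * period
    truth = WaveformTruth(
        onsets=onsets,
        systolic_peaks=onsets + offsets["sys"],
        fiducials={k: onsets + v for k, v in offsets.items()},
        period=period,
        fs=fs,
        seed=seed,
    )
    record = RawRecord(subject_id=subject_id, ppg=x, fs=fs, labels=labels)
    return record, truth


def gen_abp(
    sbp: float,
    dbp: float,
    hr_bpm: float = 60.0,
    n_beats: int = 30,
    fs: float = 125.0,
) -> np.ndarray:
    """Synthetic ABP waveform whose cycle peaks/troughs equal sbp/dbp exactly."""
    if not (40.0 <= dbp < sbp <= 200.0):
        raise ConfigurationError(
            f"require 40 <= dbp < sbp <= 200 mmHg, got sbp={sbp}, dbp={dbp}"
        )
    period = int(round(fs * 60.0 / hr_bpm))
    beat = ppg_beat_template(period)
    norm = (beat - beat.min()) / (beat.max() - beat.min())
    return dbp + (sbp - dbp) * np.tile(norm, n_beats)


@dataclass
class SCMSpec:
    """Specification of the multi-source structural causal model.

    The target M is generated from the blanket features with identical
    coefficients in every dataset (causal invariance); each dataset may
    additionally carry a spurious feature coupled to the target only
    there.  Default: 30 features, blanket of 5 (parents f00, f01 and a
    partly quadratic parent f02; child f03; spouse f04), K = 3 datasets
    of n = 1000 rows, and one spurious feature per dataset with
    heterogeneous coupling strengths, emulating sources that differ in
    confounding severity.
    """

    n_features: int = 30
    n_per_dataset: int = 1000
    dataset_ids: tuple[str, ...] = ("d1", "d2", "d3")
    parent_coefs: tuple[float, float] = (0.8, 0.8)
    quad_coefs: tuple[float, float] = (0.6, 0.3)
    child_coef: float = 0.8
    spouse_coef: float = 0.7
    target_noise_sd: float = 0.8
    child_noise_sd: float = 0.6
    spurious_plan: dict[str, tuple[str, float]] = field(
        default_factory=lambda: {
            "d1": ("f27", 0.70),
            "d2": ("f28", 0.50),
            "d3": ("f29", 0.35),
        }
    )
    target: str = "sbp"
    target_loc: float = 120.0
    target_scale: float = 12.0
    subjects_per_dataset: int = 50

    @property
    def feature_names(self) -> list[str]:
        return [f"f{i:02d}" for i in range(self.n_features)]

    @property
    def blanket(self) -> frozenset[str]:
        return frozenset({"f00", "f01", "f02", "f03", "f04"})

    @property
    def spurious_features(self) -> frozenset[str]:
        return frozenset(f for f, _ in self.spurious_plan.values())

    def validate(self) -> None:
        names = set(self.feature_names)
        if self.n_features < 6:
            raise ConfigurationError("need at least 6 features for the blanket")
        if not self.blanket <= names:
            raise ConfigurationError("blanket not contained in feature namespace")
        for ds, (feat, rho) in self.spurious_plan.items():
            if ds not in self.dataset_ids:
                raise ConfigurationError(f"spurious plan references unknown dataset {ds}")
            if feat not in names or feat in self.blanket:
                raise ConfigurationError(f"spurious feature {feat} invalid")
            if not (0.0 < abs(rho) < 1.0):
                raise ConfigurationError("spurious correlation must be in (0, 1)")
        if len(self.dataset_ids) < 2:
            raise ConfigurationError("need at least two datasets")


@dataclass
class SCMTruth:
    blanket: frozenset[str]
    spurious: dict[str, str]  # feature -> dataset where it is coupled
    spec: SCMSpec


def default_scm_spec() -> SCMSpec:
    return SCMSpec()


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def gen_multisource(
    spec: SCMSpec | None = None, seed: int = 0
) -> tuple[MultiSourceStudy, SCMTruth]:
    """Draw the K-dataset benchmark study from the structural causal model.

    Per dataset: features start as independent standard normals; the
    target is built from the blanket mechanism with shared coefficients;
    the child column is overwritten from target + spouse; the dataset's
    spurious feature is rebuilt as rho * standardized(target) plus
    independent noise, so its empirical target correlation is ~rho in
    its own dataset and ~0 elsewhere.  Mild per-dataset location/scale
    shifts on the features emulate device/population heterogeneity
    (rank-based dependence measures are unaffected by them).
    """
    spec = spec if spec is not None else default_scm_spec()
    spec.validate()
    tables: dict[str, pd.DataFrame] = {}
    names = spec.feature_names
    col = {f: i for i, f in enumerate(names)}
    for i, ds in enumerate(spec.dataset_ids):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        n = spec.n_per_dataset
        x = rng.standard_normal((n, spec.n_features))
        b1, b2 = spec.parent_coefs
        q1, q2 = spec.quad_coefs
        f0, f1, f2 = x[:, col["f00"]], x[:, col["f01"]], x[:, col["f02"]]
        m = (
            b1 * f0
            + b2 * f1
            + q1 * f2
            + q2 * (f2**2 - 1.0)
            + rng.normal(0.0, spec.target_noise_sd, n)
        )
        mz = _standardize(m)
        x[:, col["f03"]] = (
            spec.child_coef * mz
            + spec.spouse_coef * x[:, col["f04"]]
            + rng.normal(0.0, spec.child_noise_sd, n)
        )
        if ds in spec.spurious_plan:
            feat, rho = spec.spurious_plan[ds]
            x[:, col[feat]] = rho * mz + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        # heterogeneous acquisition: per-dataset affine shifts of the features
        scale = rng.uniform(0.8, 1.2, spec.n_features)
        loc = rng.uniform(-0.5, 0.5, spec.n_features)
        df = pd.DataFrame(x * scale + loc, columns=names)
        df[spec.target] = spec.target_loc + spec.target_scale * mz
        df["subject_id"] = [
            f"{ds}_s{j % spec.subjects_per_dataset:03d}" for j in range(n)
        ]
        df["dataset"] = ds
        tables[ds] = df
    truth = SCMTruth(
        blanket=spec.blanket,
        spurious={feat: ds for ds, (feat, _) in spec.spurious_plan.items()},
        spec=spec,
    )
    return MultiSourceStudy(datasets=tables, target=spec.target), truth


def gen_mb_benchmark(n: int = 3000, seed: int = 0) -> tuple[pd.DataFrame, frozenset[str]]:
    """8-node linear-Gaussian benchmark with known Markov blanket.

    Graph: x5 -> x1 -> t <- x2;  t -> x3 <- x4;  x3 -> x6;  x7 isolated.
    MB(t) = {x1, x2 (parents), x3 (child), x4 (spouse)}; x5 is screened
    off by x1, x6 by x3.
    """
    rng = np.random.default_rng(seed)
    x5 = rng.standard_normal(n)
    x1 = 0.8 * x5 + rng.normal(0.0, 0.6, n)
    x2 = rng.standard_normal(n)
    t = 0.8 * x1 + 0.8 * x2 + rng.normal(0.0, 0.7, n)
    x4 = rng.standard_normal(n)
    x3 = 0.7 * t + 0.7 * x4 + rng.normal(0.0, 0.6, n)
    x6 = 0.8 * x3 + rng.normal(0.0, 0.6, n)
    x7 = rng.standard_normal(n)
    df = pd.DataFrame(
        {"x1": x1, "x2": x2, "x3": x3, "x4": x4, "x5": x5, "x6": x6, "x7": x7, "t": t}
    )
    return df, frozenset({"x1", "x2", "x3", "x4"})


def gen_two_parent(
    n: int = 500, n_noise: int = 10, seed: int = 0
) -> tuple[pd.DataFrame, frozenset[str]]:
    """Small-sample benchmark: t has exactly two parents among noise."""
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    t = 0.8 * x1 + 0.8 * x2 + rng.normal(0.0, 0.6, n)
    data = {"x1": x1, "x2": x2}
    for j in range(n_noise):
        data[f"z{j:02d}"] = rng.standard_normal(n)
    data["t"] = t
    return pd.DataFrame(data), frozenset({"x1", "x2"})


def gen_bp_table(
    n_subjects: int = 100,
    per_subject: int = 20,
    noise_sd: float = 6.0,
    seed: int = 0,
    target: str = "sbp",
) -> pd.DataFrame:
    """Linear synthetic BP regression table with subject identifiers.

    sbp = 120 + 7 x1 + 4 x2 + 2 x3 + N(0, noise_sd); rows carry subject
    ids so both record-level and sample-level splitting are exercised.
    """
    rng = np.random.default_rng(seed)
    n = n_subjects * per_subject
    x = rng.standard_normal((n, 3))
    y = 120.0 + 7.0 * x[:, 0] + 4.0 * x[:, 1] + 2.0 * x[:, 2] + rng.normal(0.0, noise_sd, n)
    df = pd.DataFrame(x, columns=["x1", "x2", "x3"])
    df[target] = y
    df["subject_id"] = [f"s{j // per_subject:03d}" for j in range(n)]
    return df
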