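"""Synthetic single-lead iECG strips with exact ground truth.

Pediatric iECG datasets are restricted, so every stage of the pipeline
is exercised against generated strips whose R-peak positions, per-beat
morphology classes, and record-level rhythm label are known by
construction.

Beats are synthesized from parametric templates (sums of Gaussian
lobes per wave: P, QRS, T) rather than a dynamical heart model; this
gives full, independent control over the morphological features the
classifier must separate — QRS width, notching, pacing spikes, absent
P waves — at the cost of physiological realism (see docs/methods.md).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import DEFAULT_SAMPLING_RATE_HZ, IECGRecord


class BeatClass(str, enum.Enum):
    """Single-beat morphology classes.

    N  normal (sinus) beat: P wave, narrow QRS, T wave
    R  right bundle branch block: widened, notched QRS
    P  paced beat: sharp pacing spike immediately before a wide QRS
    V  premature ventricular contraction: wide QRS, no preceding P
    W  Wolff-Parkinson-White: short PR, slurred QRS upstroke
    S  premature atrial contraction: early narrow beat, abnormal P

    W and S exist as labels but are excluded from classifier training
    (too few real examples exist to learn them).
    """

    N = "N"
    R = "R"
    P = "P"
    V = "V"
    W = "W"
    S = "S"


TRAINABLE_CLASSES: tuple[BeatClass, ...] = (
    BeatClass.N,
    BeatClass.R,
    BeatClass.P,
    BeatClass.V,
)

#: Default QRS width (ms, measured at 10 % of peak amplitude) per class.
DEFAULT_QRS_WIDTH_MS: Mapping[BeatClass, float] = {
    BeatClass.N: 70.0,
    BeatClass.R: 110.0,
    BeatClass.P: 100.0,
    BeatClass.V: 160.0,
    BeatClass.W: 95.0,
    BeatClass.S: 70.0,
}

#: Default R-wave amplitude in µV (typical single-lead pediatric R wave).
DEFAULT_QRS_AMPLITUDE_UV = 800.0

#: Age (years) → normal resting heart-rate band (bpm). General pediatric
#: reference ranges; configurable, and NOT taken from any single study.
DEFAULT_AGE_HR_BANDS: tuple[tuple[float, float, float, float], ...] = (
    (0.0, 1.0, 90.0, 180.0),
    (1.0, 3.0, 80.0, 160.0),
    (3.0, 6.0, 75.0, 140.0),
    (6.0, 12.0, 65.0, 130.0),
    (12.0, 18.0, 55.0, 120.0),
)

#: Margin (bpm) kept between a generated heart rate and its band edge so
#: that synthetic truths are never borderline.
HR_MARGIN_BPM = 8.0

_TEMPLATE_HALF_SPAN_MS = 360.0

# Width of a Gaussian at 10 % of its peak, in units of sigma.
_W10_SIGMA = 2.0 * np.sqrt(2.0 * np.log(10.0))  # ≈ 4.292


def _gauss(t_ms: np.ndarray, mu_ms: float, sigma_ms: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t_ms - mu_ms) / sigma_ms) ** 2)


def beat_template(
    cls: BeatClass | str,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    amplitude_uv: float = DEFAULT_QRS_AMPLITUDE_UV,
    qrs_width_ms: float | None = None,
) -> np.ndarray:
    """One beat of class ``cls`` as a waveform segment in µV.

    The segment spans ±360 ms around the R-peak, which sits at the
    center sample and carries the maximum absolute amplitude
    (``amplitude_uv``). ``qrs_width_ms`` is the QRS width measured at
    10 % of the peak; it defaults per class (narrow < 90 ms for N/S,
    wide > 120 ms for V). The template is zero outside the complex.
    """
    cls = BeatClass(cls)
    if qrs_width_ms is None:
        qrs_width_ms = DEFAULT_QRS_WIDTH_MS[cls]
    n_half = int(round(_TEMPLATE_HALF_SPAN_MS / 1000.0 * sampling_rate_hz))
    t = (np.arange(-n_half, n_half + 1) / sampling_rate_hz) * 1000.0  # ms

    sigma = qrs_width_ms / _W10_SIGMA
    x = np.zeros_like(t)

    if cls is BeatClass.N:
        x += _gauss(t, -160.0, 25.0, 0.15)          # P wave
        x += _gauss(t, 0.0, sigma, 1.0)             # R
        x += _gauss(t, 250.0, 55.0, 0.28)           # T wave
    elif cls is BeatClass.R:
        # widened, notched QRS: two merged lobes
        lobe_sigma = qrs_width_ms / 8.0
        sep = qrs_width_ms * 0.45
        x += _gauss(t, -160.0, 25.0, 0.15)
        x += _gauss(t, 0.0, lobe_sigma, 1.0)
        x += _gauss(t, sep, lobe_sigma, 0.80)       # second (notched) lobe
        x += _gauss(t, 280.0, 55.0, -0.25)          # discordant T
    elif cls is BeatClass.P:
        x += _gauss(t, -55.0, 2.5, 0.65)            # pacing spike
        x += _gauss(t, 0.0, sigma, 1.0)             # wide QRS
        x += _gauss(t, 280.0, 60.0, -0.30)
    elif cls is BeatClass.V:
        x += _gauss(t, 0.0, sigma, 1.0)             # wide QRS, no P wave
        x += _gauss(t, 300.0, 55.0, -0.35)          # discordant T
    elif cls is BeatClass.W:
        x += _gauss(t, -140.0, 25.0, 0.15)          # P wave (short PR)
        x += _gauss(t, -45.0, 18.0, 0.35)           # delta wave (slurred upstroke)
        x += _gauss(t, 0.0, sigma, 1.0)
        x += _gauss(t, 250.0, 55.0, 0.25)
    elif cls is BeatClass.S:
        x += _gauss(t, -140.0, 22.0, -0.12)         # abnormal (inverted) P
        x += _gauss(t, 0.0, sigma, 1.0)
        x += _gauss(t, 250.0, 55.0, 0.25)

    if amplitude_uv == 0:
        return np.zeros_like(x)
    peak = np.max(np.abs(x))
    x = x * (amplitude_uv / peak)
    # guarantee the R-peak (max |x|) sits exactly at the center sample
    shift = n_half - int(np.argmax(np.abs(x)))
    if shift:
        x = np.roll(x, shift)
        if shift > 0:
            x[:shift] = 0.0
        else:
            x[shift:] = 0.0
    return x


def measure_qrs_width_ms(
    template: np.ndarray, sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
) -> float:
    """QRS width at 10 % of peak: the contiguous |x| ≥ 0.1·peak region
    around the center (R-peak) sample, in ms."""
    peak_idx = int(np.argmax(np.abs(template)))
    thresh = 0.1 * np.abs(template[peak_idx])
    above = np.abs(template) >= thresh
    lo = peak_idx
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_idx
    while hi < len(template) - 1 and above[hi + 1]:
        hi += 1
    return (hi - lo) / sampling_rate_hz * 1000.0


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic iECG strip.

    ``class_sequence`` is either an explicit list of beat classes
    (cycled over the placed beats) or a class→fraction mapping, in
    which case each class receives round(fraction × beat count) beats
    (largest-remainder rounding) at shuffled positions.
    """

    duration_s: float = 30.0
    heart_rate_bpm: float = 100.0
    age_years: float = 9.0
    class_sequence: Sequence[BeatClass] | Mapping[BeatClass, float] = (BeatClass.N,)
    noise_sd_uv: float = 20.0
    baseline_wander_uv: float = 50.0
    baseline_wander_hz: float = 0.3
    leading_artifact_s: float = 0.0
    rr_jitter_fraction: float = 0.05
    qrs_amplitude_uv: float = DEFAULT_QRS_AMPLITUDE_UV
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    record_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.heart_rate_bpm <= 0:
            raise ValueError("duration_s and heart_rate_bpm must be positive")
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.noise_sd_uv < 0 or self.baseline_wander_uv < 0:
            raise ValueError("noise levels must be non-negative")
        if not (0 <= self.rr_jitter_fraction < 0.5):
            raise ValueError("rr_jitter_fraction must be in [0, 0.5)")
        if self.leading_artifact_s < 0:
            raise ValueError("leading_artifact_s must be non-negative")


@dataclass
class GroundTruth:
    """Exact truth for one synthetic strip."""

    r_peak_indices: np.ndarray          # sorted sample indices
    beat_classes: list[BeatClass]       # aligned to r_peak_indices
    rhythm_label: str                   # "healthy" | "pathological"
    diagnosis_name: str

    def __post_init__(self) -> None:
        self.r_peak_indices = np.asarray(self.r_peak_indices, dtype=int)
        if len(self.beat_classes) != len(self.r_peak_indices):
            raise ValueError("beat_classes must align with r_peak_indices")
        if len(self.r_peak_indices) > 1 and not np.all(
            np.diff(self.r_peak_indices) > 0
        ):
            raise ValueError("r_peak_indices must be strictly increasing")


def hr_band_for_age(
    age_years: float,
    bands: Sequence[tuple[float, float, float, float]] = DEFAULT_AGE_HR_BANDS,
) -> tuple[float, float]:
    """(hr_low, hr_high) of the age band containing ``age_years``."""
    for lo, hi, hr_lo, hr_hi in bands:
        if lo <= age_years < hi:
            return hr_lo, hr_hi
    raise ValueError(f"age {age_years} outside configured bands")


def rhythm_from_truth(
    beat_classes: Sequence[BeatClass],
    rr_ms: Sequence[float],
    age_years: float,
    bands: Sequence[tuple[float, float, float, float]] = DEFAULT_AGE_HR_BANDS,
    pvc_count_threshold: int = 1,
    dominant_class_fraction: float = 0.6,
    irregularity_cv_threshold: float = 0.15,
) -> tuple[str, str]:
    """(diagnosis_name, healthy|pathological) from truth alone.

    Same rule order as the decision tree: PVCs, dominant RBBB, dominant
    paced, rate vs. age band, RR irregularity, else sinus rhythm.
    """
    classes = [BeatClass(c) for c in beat_classes]
    rr = np.asarray(rr_ms, dtype=float)
    n = len(classes)
    if n == 0:
        raise ValueError("no beats")
    if sum(c is BeatClass.V for c in classes) >= pvc_count_threshold:
        return "sinus_with_pvc", "pathological"
    if sum(c is BeatClass.R for c in classes) / n >= dominant_class_fraction:
        return "rbbb", "pathological"
    if sum(c is BeatClass.P for c in classes) / n >= dominant_class_fraction:
        return "paced_rhythm", "pathological"
    hr = 60000.0 / float(np.median(rr))
    hr_lo, hr_hi = hr_band_for_age(age_years, bands)
    if hr < hr_lo:
        return "bradycardia", "pathological"
    if hr > hr_hi:
        return "tachycardia", "pathological"
    cv = float(np.std(rr) / np.mean(rr))
    if cv > irregularity_cv_threshold:
        return "irregular_rhythm", "pathological"
    if all(c is BeatClass.N for c in classes):
        return "sinus_rhythm", "healthy"
    return "atypical_beats", "pathological"


def _assign_classes(
    spec_classes: Sequence[BeatClass] | Mapping[BeatClass, float],
    n_beats: int,
    rng: np.random.Generator,
) -> list[BeatClass]:
    if isinstance(spec_classes, Mapping):
        fracs = {BeatClass(k): float(v) for k, v in spec_classes.items()}
        total = sum(fracs.values())
        if total <= 0:
            raise ValueError("class mix fractions must sum to a positive value")
        fracs = {k: v / total for k, v in fracs.items()}
        # largest-remainder rounding to exact per-class counts
        raw = {k: v * n_beats for k, v in fracs.items()}
        counts = {k: int(round(v)) for k, v in raw.items()}
        drift = n_beats - sum(counts.values())
        if drift != 0:
            order = sorted(raw, key=lambda k: raw[k] - np.floor(raw[k]), reverse=drift > 0)
            for k in order[: abs(drift)]:
                counts[k] += 1 if drift > 0 else -1
        labels: list[BeatClass] = []
        for k, c in counts.items():
            labels.extend([k] * c)
        perm = rng.permutation(n_beats)
        return [labels[i] for i in perm]
    seq = [BeatClass(c) for c in spec_classes]
    if not seq:
        raise ValueError("class_sequence must not be empty")
    return [seq[i % len(seq)] for i in range(n_beats)]


def generate_iecg(spec: SyntheticSpec) -> tuple[IECGRecord, GroundTruth]:
    """Generate one strip and its exact ground truth.

    Beats are placed at RR = 60000/heart_rate_bpm ms with multiplicative
    uniform jitter; each beat adds its class template at its R-peak
    anchor. Gaussian broadband noise and a slow sinusoidal baseline
    wander are superimposed; if ``leading_artifact_s`` > 0, a
    high-amplitude broadband motion-artifact burst occupies the first
    seconds of the strip (such artifacts are common at the start of
    pediatric recordings, especially in neonates).
    """
    fs = spec.sampling_rate_hz
    n_total = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(spec.seed)

    rr0_s = 60.0 / spec.heart_rate_bpm
    margin_s = _TEMPLATE_HALF_SPAN_MS / 1000.0
    t = 0.5 * rr0_s + margin_s * 0.5
    peak_times = []
    while t < spec.duration_s - margin_s:
        peak_times.append(t)
        jitter = spec.rr_jitter_fraction * rng.uniform(-1.0, 1.0)
        t += rr0_s * (1.0 + jitter)
    if not peak_times:
        raise ValueError("duration too short for a single beat at this heart rate")

    r_indices = np.asarray([int(round(pt * fs)) for pt in peak_times])
    classes = _assign_classes(spec.class_sequence, len(r_indices), rng)

    signal = np.zeros(n_total)
    for idx, cls in zip(r_indices, classes):
        tpl = beat_template(cls, fs, spec.qrs_amplitude_uv)
        half = len(tpl) // 2
        lo, hi = idx - half, idx + half + 1
        tlo, thi = max(0, -lo), len(tpl) - max(0, hi - n_total)
        signal[max(0, lo) : min(n_total, hi)] += tpl[tlo:thi]

    tt = np.arange(n_total) / fs
    if spec.baseline_wander_uv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += spec.baseline_wander_uv * np.sin(
            2 * np.pi * spec.baseline_wander_hz * tt + phase
        )
    if spec.noise_sd_uv > 0:
        signal += rng.normal(0.0, spec.noise_sd_uv, n_total)
    if spec.leading_artifact_s > 0:
        n_art = min(n_total, int(round(spec.leading_artifact_s * fs)))
        burst = rng.normal(0.0, 8.0 * spec.qrs_amplitude_uv, n_art)
        taper = np.ones(n_art)
        ramp = max(1, int(0.05 * n_art))
        taper[-ramp:] = np.linspace(1.0, 0.0, ramp)
        signal[:n_art] += burst * taper

    rr_ms = np.diff(r_indices) / fs * 1000.0
    if len(rr_ms) == 0:
        rr_ms = np.asarray([rr0_s * 1000.0])
    diagnosis, label = rhythm_from_truth(classes, rr_ms, spec.age_years)

    record = IECGRecord(
        samples=signal,
        sampling_rate_hz=fs,
        age_years=spec.age_years,
        record_id=spec.record_id,
        metadata={"source": "pediecg-synthetic", "seed": str(spec.seed)},
    )
    truth = GroundTruth(
        r_peak_indices=r_indices,
        beat_classes=classes,
        rhythm_label=label,
        diagnosis_name=diagnosis,
    )
    return record, truth


_PATHOLOGY_CYCLE = ("rbbb", "pvc", "paced", "bradycardia", "tachycardia")


def _spec_for_pathology(
    kind: str, age: float, rng: np.random.Generator, seed: int, record_id: str
) -> SyntheticSpec:
    hr_lo, hr_hi = hr_band_for_age(age)
    hr_inside = rng.uniform(hr_lo + HR_MARGIN_BPM, hr_hi - HR_MARGIN_BPM)
    base = dict(age_years=age, seed=seed, record_id=record_id)
    if kind == "rbbb":
        return SyntheticSpec(heart_rate_bpm=hr_inside, class_sequence=(BeatClass.R,), **base)
    if kind == "pvc":
        mix = {BeatClass.N: 0.85, BeatClass.V: 0.15}
        return SyntheticSpec(heart_rate_bpm=hr_inside, class_sequence=mix, **base)
    if kind == "paced":
        return SyntheticSpec(heart_rate_bpm=hr_inside, class_sequence=(BeatClass.P,), **base)
    if kind == "bradycardia":
        hr = rng.uniform(max(35.0, 0.6 * hr_lo), hr_lo - HR_MARGIN_BPM)
        return SyntheticSpec(heart_rate_bpm=hr, class_sequence=(BeatClass.N,), **base)
    if kind == "tachycardia":
        hr = rng.uniform(hr_hi + HR_MARGIN_BPM, hr_hi + 45.0)
        return SyntheticSpec(heart_rate_bpm=hr, class_sequence=(BeatClass.N,), **base)
    raise ValueError(f"unknown pathology kind {kind!r}")


def generate_cohort(
    n: int,
    seed: int = 0,
    pathology_fraction: float = 0.375,
    duration_s: float = 30.0,
    noise_sd_uv: float = 20.0,
    baseline_wander_uv: float = 50.0,
) -> list[tuple[IECGRecord, GroundTruth]]:
    """Generate a reproducible cohort of strips.

    Ages are uniform over [0, 18); exactly round(n × pathology_fraction)
    records carry a pathological truth, cycling through RBBB runs, PVCs,
    paced rhythm, bradycardia, and tachycardia. The rest are sinus
    rhythm at an age-appropriate rate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= pathology_fraction <= 1.0):
        raise ValueError("pathology_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_path = int(round(n * pathology_fraction))
    ages = rng.uniform(0.0, 18.0, n)
    seeds = rng.integers(0, 2**31 - 1, n)
    path_slots = set(rng.choice(n, size=n_path, replace=False).tolist())

    cohort = []
    path_counter = 0
    for i in range(n):
        record_id = f"synthetic-{i:03d}"
        if i in path_slots:
            kind = _PATHOLOGY_CYCLE[path_counter % len(_PATHOLOGY_CYCLE)]
            path_counter += 1
            spec = _spec_for_pathology(kind, ages[i], rng, int(seeds[i]), record_id)
        else:
            hr_lo, hr_hi = hr_band_for_age(ages[i])
            hr = rng.uniform(hr_lo + HR_MARGIN_BPM, hr_hi - HR_MARGIN_BPM)
            spec = SyntheticSpec(
                heart_rate_bpm=hr,
                age_years=ages[i],
                seed=int(seeds[i]),
                record_id=record_id,
            )
        spec.duration_s = duration_s
        spec.noise_sd_uv = noise_sd_uv
        spec.baseline_wander_uv = baseline_wander_uv
        cohort.append(generate_iecg(spec))
    return cohort
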