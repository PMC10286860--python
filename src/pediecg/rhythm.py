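"""Rule-based, age-aware rhythm decision tree.

Workflow step 3: per-beat morphology labels, the RR-interval series,
and the patient's age feed an "if, then" decision tree that returns a
record-level diagnosis. Heart-rate normality is judged against
age-specific bands because pediatric resting rates fall steeply from
neonates (~90–180 bpm) to adolescents (~55–120 bpm); the default bands
are general pediatric reference ranges, shipped as editable
configuration (they are defaults of this package, not published study
thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .synthetic import DEFAULT_AGE_HR_BANDS, BeatClass

HEALTHY = "healthy"
PATHOLOGICAL = "pathological"
INCONCLUSIVE = "inconclusive"

CATEGORIES = (
    "sinus_rhythm",
    "sinus_with_pvc",
    "rbbb",
    "paced_rhythm",
    "bradycardia",
    "tachycardia",
    "irregular_rhythm",
    "inconclusive",
)


@dataclass
class DecisionThresholds:
    """Tunables of the decision tree.

    age_bands: ordered (age_lo, age_hi, hr_low, hr_high) rows covering
        [0, 18) years; contiguous and non-overlapping.
    min_beat_confidence: beats classified below this confidence count
        as uninterpretable.
    max_inconclusive_fraction: above this fraction of uninterpretable
        beats the whole record is inconclusive.
    pvc_count_threshold: number of V beats that already makes the
        record pathological (any PVC is abnormal in a 30-s strip).
    dominant_class_fraction: fraction of R (or P) beats required to
        call a bundle-branch-block (or paced) rhythm.
    irregularity_cv_threshold: coefficient of variation of the RR
        series above which the rhythm is called irregular.
    """

    age_bands: tuple[tuple[float, float, float, float], ...] = DEFAULT_AGE_HR_BANDS
    min_beat_confidence: float = 0.5
    max_inconclusive_fraction: float = 0.3
    pvc_count_threshold: int = 1
    dominant_class_fraction: float = 0.6
    irregularity_cv_threshold: float = 0.15

    def __post_init__(self) -> None:
        bands = sorted(self.age_bands)
        if not bands:
            raise ValueError("age_bands must not be empty")
        prev_hi = bands[0][0]
        for lo, hi, hr_lo, hr_hi in bands:
            if lo != prev_hi:
                raise ValueError("age_bands must be contiguous and non-overlapping")
            if not hr_lo < hr_hi:
                raise ValueError("hr_low must be < hr_high in every band")
            prev_hi = hi
        self.age_bands = tuple(bands)
        if not (0 <= self.min_beat_confidence <= 1):
            raise ValueError("min_beat_confidence in [0, 1]")
        if not (0 <= self.max_inconclusive_fraction <= 1):
            raise ValueError("max_inconclusive_fraction in [0, 1]")
        if not (0.5 < self.dominant_class_fraction <= 1):
            raise ValueError("dominant_class_fraction in (0.5, 1]")
        if self.irregularity_cv_threshold <= 0:
            raise ValueError("irregularity_cv_threshold must be positive")

    def band_for_age(self, age_years: float) -> tuple[float, float]:
        for lo, hi, hr_lo, hr_hi in self.age_bands:
            if lo <= age_years < hi:
                return hr_lo, hr_hi
        raise ValueError(f"age {age_years} outside configured bands")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DecisionThresholds":
        data = yaml.safe_load(Path(path).read_text())
        if "age_bands" in data:
            data["age_bands"] = tuple(tuple(row) for row in data["age_bands"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "age_bands": [list(row) for row in self.age_bands],
            "min_beat_confidence": self.min_beat_confidence,
            "max_inconclusive_fraction": self.max_inconclusive_fraction,
            "pvc_count_threshold": self.pvc_count_threshold,
            "dominant_class_fraction": self.dominant_class_fraction,
            "irregularity_cv_threshold": self.irregularity_cv_threshold,
        }
        Path(path).write_text(yaml.safe_dump(data))


@dataclass
class RhythmDiagnosis:
    """Decision-tree output: category, binarization, and evidence.

    ``binary`` is healthy iff the category is sinus_rhythm and
    inconclusive iff the category is inconclusive; every named
    pathology is pathological. ``evidence`` records each evaluated
    quantity plus the single fired rule under ``"fired_rule"``.
    """

    category: str
    binary: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        expected = (
            HEALTHY
            if self.category == "sinus_rhythm"
            else INCONCLUSIVE
            if self.category == "inconclusive"
            else PATHOLOGICAL
        )
        if self.binary != expected:
            raise ValueError(
                f"binary {self.binary!r} inconsistent with category {self.category!r}"
            )


def classify_rhythm(
    beat_labels: Sequence[tuple[BeatClass | str, float]],
    rr_ms: Sequence[float],
    age_years: float,
    thresholds: DecisionThresholds | None = None,
) -> RhythmDiagnosis:
    """Run the decision tree; rules fire in fixed order, first match wins.

    1. too many low-confidence beats → inconclusive
    2. V-beat count ≥ pvc_count_threshold → sinus_with_pvc
    3. R-beat fraction ≥ dominant_class_fraction → rbbb
    4. P-beat fraction ≥ dominant_class_fraction → paced_rhythm
    5. heart rate (60000 / median RR) below/above the age band →
       bradycardia / tachycardia
    6. RR coefficient of variation > irregularity_cv_threshold →
       irregular_rhythm
    7. otherwise → sinus_rhythm

    Fewer than 3 beats or 2 RR intervals yields inconclusive with a
    reason (too little signal to judge a rhythm).
    """
    thresholds = thresholds or DecisionThresholds()
    hr_lo, hr_hi = thresholds.band_for_age(age_years)  # validates age first

    labels = [(BeatClass(c), float(conf)) for c, conf in beat_labels]
    rr = np.asarray(rr_ms, dtype=float)

    evidence: dict = {
        "n_beats": len(labels),
        "n_rr": len(rr),
        "age_years": age_years,
        "hr_band_bpm": [hr_lo, hr_hi],
    }
    if len(labels) < 3 or len(rr) < 2:
        evidence["fired_rule"] = "too_few_beats"
        return RhythmDiagnosis("inconclusive", INCONCLUSIVE, evidence)

    n = len(labels)
    histogram = {c.value: 0 for c in BeatClass}
    for c, _ in labels:
        histogram[c.value] += 1
    low_conf = sum(conf < thresholds.min_beat_confidence for _, conf in labels)
    median_rr = float(np.median(rr))
    hr = 60000.0 / median_rr
    cv = float(np.std(rr) / np.mean(rr))
    evidence.update(
        class_histogram=histogram,
        low_confidence_fraction=low_conf / n,
        median_rr_ms=median_rr,
        heart_rate_bpm=hr,
        rr_cv=cv,
    )

    def done(category: str, rule: str) -> RhythmDiagnosis:
        evidence["fired_rule"] = rule
        binary = (
            HEALTHY
            if category == "sinus_rhythm"
            else INCONCLUSIVE
            if category == "inconclusive"
            else PATHOLOGICAL
        )
        return RhythmDiagnosis(category, binary, evidence)

    if low_conf / n > thresholds.max_inconclusive_fraction:
        return done("inconclusive", "low_confidence_beats")
    if histogram["V"] >= thresholds.pvc_count_threshold:
        return done("sinus_with_pvc", "pvc_count")
    if histogram["R"] / n >= thresholds.dominant_class_fraction:
        return done("rbbb", "dominant_rbbb")
    if histogram["P"] / n >= thresholds.dominant_class_fraction:
        return done("paced_rhythm", "dominant_paced")
    if hr < hr_lo:
        return done("bradycardia", "rate_below_band")
    if hr > hr_hi:
        return done("tachycardia", "rate_above_band")
    if cv > thresholds.irregularity_cv_threshold:
        return done("irregular_rhythm", "rr_irregularity")
    return done("sinus_rhythm", "default_sinus")


def binarize_diagnosis(d: RhythmDiagnosis) -> str:
    """Healthy / pathological / inconclusive projection of a diagnosis."""
    return d.binary
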