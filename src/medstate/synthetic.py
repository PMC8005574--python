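"""Synthetic two-condition, two-hemisphere source-space cohorts.

Generates band-structured oscillatory signals over a 1/f background with an
optional per-band medication-induced log-power shift, occasional
high-frequency muscle-artifact bursts, and 33-item motor exam ratings whose
improvement is statistically coupled to the spectral effect magnitude.
Everything is deterministic given the cohort seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .clinical import ITEM_CODES, default_factor_structure

CONDITIONS = ("OFF", "ON")
HEMISPHERES = ("left", "right")

#: frequency bands (Hz) whose log power the generator controls
BANDS = ((7.0, 13.0), (13.0, 20.0), (20.0, 30.0), (35.0, 45.0))

_BURST_LEN_S = 0.25
_BURST_BAND = (60.0, 300.0)


@dataclass(frozen=True)
class SubjectSpec:
    """Generative parameters for one synthetic subject.

    ``baseline_band_log_power`` and ``effect_log_power_shift`` are per-band
    log variances: the oscillatory component in band *b* has variance
    ``exp(baseline[b] + effect[b])`` in the ON condition and
    ``exp(baseline[b])`` in OFF.  ``clinical_coupling`` maps the Euclidean
    norm of the spectral effect vector to a reduction of the latent factor
    severities in ON; it may be a scalar (applied to every factor) or a
    7-vector of per-factor coupling weights.
    """

    subject_id: str
    baseline_band_log_power: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    effect_log_power_shift: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    one_over_f_exponent: float = 1.0
    one_over_f_level: float = 0.1
    broadband_noise_level: float = 0.2
    artifact_burst_rate: float = 0.0
    clinical_severity: tuple[float, ...] = (2.0, 1.0, 2.0, 2.0, 2.0, 1.0, 2.0)
    clinical_coupling: float | tuple[float, ...] = 0.0
    rating_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if len(self.baseline_band_log_power) != len(BANDS):
            raise ValueError("baseline_band_log_power must have 4 entries")
        if len(self.effect_log_power_shift) != len(BANDS):
            raise ValueError("effect_log_power_shift must have 4 entries")
        if len(self.clinical_severity) != 7:
            raise ValueError("clinical_severity must have 7 entries")
        if self.one_over_f_exponent < 0:
            raise ValueError("one_over_f_exponent must be >= 0")
        if self.broadband_noise_level <= 0:
            raise ValueError("broadband_noise_level must be > 0")
        if self.artifact_burst_rate < 0:
            raise ValueError("artifact_burst_rate must be >= 0")
        if any(s < 0 for s in self.clinical_severity):
            raise ValueError("clinical_severity must be >= 0")

    @property
    def coupling_vector(self) -> np.ndarray:
        c = self.clinical_coupling
        if np.isscalar(c):
            return np.full(7, float(c))
        c = np.asarray(c, dtype=float)
        if c.shape != (7,):
            raise ValueError("clinical_coupling must be a scalar or length-7")
        return c


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a full synthetic cohort."""

    subject_specs: tuple[SubjectSpec, ...]
    duration_s: float = 180.0
    sampling_rate_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subject_specs) < 1:
            raise ValueError("need at least one subject")
        ids = [s.subject_id for s in self.subject_specs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in cohort")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_specs)


@dataclass(frozen=True)
class SourceRecording:
    subject_id: str
    condition: str
    hemisphere: str
    samples: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")


def _stream(seed: int, *tags: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a seed and tags.

    Tags are hashed with a process-independent digest so identical inputs
    reproduce identical streams across runs and machines.
    """
    digest = [
        int.from_bytes(hashlib.blake2s(t.encode()).digest()[:4], "little")
        for t in tags
    ]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *digest]))


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float], variance: float) -> np.ndarray:
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    if sd == 0:
        return x
    return x * (np.sqrt(variance) / sd)


def _one_over_f_noise(rng: np.random.Generator, n: int,
                      exponent: float, level: float) -> np.ndarray:
    """White noise spectrally shaped to power ~ 1/f**exponent, total sd = level."""
    if level == 0:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0)  # unit spacing; only the shape matters
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    if sd == 0:
        return x
    return x * (level / sd)


def _artifact_bursts(rng: np.random.Generator, n: int, fs: float,
                     rate_per_min: float, amplitude: float) -> np.ndarray:
    out = np.zeros(n)
    if rate_per_min == 0:
        return out
    n_bursts = rng.poisson(rate_per_min * (n / fs) / 60.0)
    burst_len = int(round(_BURST_LEN_S * fs))
    if burst_len < 8 or n_bursts == 0:
        return out
    hi = min(_BURST_BAND[1], 0.45 * fs)
    sos = sps.butter(4, (_BURST_BAND[0], hi), btype="bandpass", fs=fs, output="sos")
    window = sps.windows.hann(burst_len)
    for start in rng.integers(0, max(1, n - burst_len), size=n_bursts):
        burst = sps.sosfilt(sos, rng.standard_normal(burst_len))
        sd = burst.std()
        if sd > 0:
            burst *= amplitude / sd
        out[start:start + burst_len] += window * burst
    return out


def generate_source_signal(spec: SubjectSpec, condition: str, hemisphere: str,
                           duration_s: float, fs: float, seed: int) -> SourceRecording:
    """One source-space recording: band oscillations + 1/f + white noise + bursts."""
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if fs < 2 * BANDS[-1][1] * 1.1:
        raise ValueError(f"fs={fs} too low for the {BANDS[-1]} Hz band")
    if duration_s <= 5:
        raise ValueError("duration_s must exceed 5 s")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}")

    n = int(round(duration_s * fs))
    on = condition == "ON"
    x = np.zeros(n)
    for b, band in enumerate(BANDS):
        log_var = spec.baseline_band_log_power[b]
        if on:
            log_var += spec.effect_log_power_shift[b]
        rng = _stream(seed, spec.subject_id, condition, hemisphere, f"band{b}")
        x += _band_noise(rng, n, fs, band, np.exp(log_var))
    rng = _stream(seed, spec.subject_id, condition, hemisphere, "pink")
    x += _one_over_f_noise(rng, n, spec.one_over_f_exponent, spec.one_over_f_level)
    rng = _stream(seed, spec.subject_id, condition, hemisphere, "white")
    x += spec.broadband_noise_level * rng.standard_normal(n)
    rng = _stream(seed, spec.subject_id, condition, hemisphere, "bursts")
    x += _artifact_bursts(rng, n, fs, spec.artifact_burst_rate,
                          amplitude=10.0 * spec.broadband_noise_level)
    return SourceRecording(spec.subject_id, condition, hemisphere, x, fs)


def generate_item_ratings(spec: SubjectSpec, condition: str, seed: int) -> dict[str, int]:
    """33 integer item scores in 0..4 for one condition.

    Latent factor severities are reduced in ON by
    ``coupling[f] * ||effect_log_power_shift||``; each item draws a
    multiplicative log-normal perturbation of its factor severity, then is
    clipped to [0, 4] and rounded.  Zero severity therefore yields zero items
    exactly, and zero coupling makes OFF and ON identically distributed.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    severity = np.asarray(spec.clinical_severity, dtype=float)
    if condition == "ON":
        effect_norm = float(np.linalg.norm(spec.effect_log_power_shift))
        severity = np.clip(severity - spec.coupling_vector * effect_norm, 0.0, None)
    structure = default_factor_structure()
    rng = _stream(seed, spec.subject_id, condition, "ratings")
    scores: dict[str, int] = {}
    for code in ITEM_CODES:
        f = structure.assignment[code] - 1
        latent = severity[f] * np.exp(spec.rating_noise_sd * rng.standard_normal())
        scores[code] = int(np.clip(np.rint(latent), 0, 4))
    return scores


@dataclass
class Cohort:
    """All generated artifacts plus the ground truth used to generate them."""

    spec: CohortSpec
    recordings: dict[tuple[str, str, str], SourceRecording] = field(default_factory=dict)
    ratings: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    ground_truth: dict[str, dict] = field(default_factory=dict)

    def recording(self, subject_id: str, condition: str, hemisphere: str) -> SourceRecording:
        return self.recordings[(subject_id, condition, hemisphere)]

    def subject_recordings(self, subject_id: str) -> dict[tuple[str, str], SourceRecording]:
        return {(c, h): self.recordings[(subject_id, c, h)]
                for c in CONDITIONS for h in HEMISPHERES}


def generate_cohort(cohort: CohortSpec) -> Cohort:
    """Generate every recording and rating set for a cohort, reproducibly."""
    out = Cohort(spec=cohort)
    for spec in cohort.subject_specs:
        for condition in CONDITIONS:
            for hemisphere in HEMISPHERES:
                rec = generate_source_signal(
                    spec, condition, hemisphere,
                    cohort.duration_s, cohort.sampling_rate_hz, cohort.seed)
                out.recordings[(spec.subject_id, condition, hemisphere)] = rec
            out.ratings[(spec.subject_id, condition)] = generate_item_ratings(
                spec, condition, cohort.seed)
        out.ground_truth[spec.subject_id] = {
            "effect_log_power_shift": list(spec.effect_log_power_shift),
            "clinical_coupling": (
                float(spec.clinical_coupling) if np.isscalar(spec.clinical_coupling)
                else list(spec.clinical_coupling)),
        }
    return out


def null_cohort(n_subjects: int, seed: int, duration_s: float = 180.0,
                fs: float = 1000.0) -> CohortSpec:
    """Cohort in which OFF and ON signals are drawn from the same distribution."""
    specs = tuple(
        SubjectSpec(subject_id=f"S{i + 1:02d}")
        for i in range(n_subjects))
    return CohortSpec(specs, duration_s=duration_s, sampling_rate_hz=fs, seed=seed)


def effect_cohort(n_subjects: int, seed: int,
                  effect: Sequence[float] = (0.0, 0.0, 1.0, 0.0),
                  coupling: float | Sequence[float] = 0.0,
                  duration_s: float = 180.0, fs: float = 1000.0,
                  severity: Sequence[float] = (2.0, 1.0, 2.0, 2.0, 2.0, 1.0, 2.0),
                  ) -> CohortSpec:
    """Cohort with a shared medication effect vector and clinical coupling."""
    coupling_val = (float(coupling) if np.isscalar(coupling)
                    else tuple(float(c) for c in coupling))
    specs = tuple(
        SubjectSpec(subject_id=f"S{i + 1:02d}",
                    effect_log_power_shift=tuple(float(e) for e in effect),
                    clinical_severity=tuple(float(s) for s in severity),
                    clinical_coupling=coupling_val)
        for i in range(n_subjects))
    return CohortSpec(specs, duration_s=duration_s, sampling_rate_hz=fs, seed=seed)


def graded_effect_cohort(n_subjects: int, seed: int, band: int = 2,
                         max_effect: float = 0.6, coupling7: float = 2.0,
                         duration_s: float = 60.0, fs: float = 1000.0,
                         ) -> CohortSpec:
    """Cohort whose spectral effect magnitudes grade from 0 to ``max_effect``.

    Clinical coupling acts on factor 7 only, so decoding accuracy and
    factor-7 improvement should covary across subjects — the structure the
    accuracy-vs-change regression is meant to recover.
    """
    specs = []
    for i in range(n_subjects):
        magnitude = max_effect * i / max(1, n_subjects - 1)
        effect = [0.0, 0.0, 0.0, 0.0]
        effect[band] = magnitude
        specs.append(SubjectSpec(
            subject_id=f"S{i + 1:02d}",
            effect_log_power_shift=tuple(effect),
            clinical_severity=(2.0, 1.0, 2.0, 2.0, 2.0, 1.0, 2.5),
            clinical_coupling=(0, 0, 0, 0, 0, 0, coupling7)))
    return CohortSpec(tuple(specs), duration_s=duration_s,
                      sampling_rate_hz=fs, seed=seed)


def contaminated_preset(subject_id: str = "S01", burst_rate: float = 6.0) -> SubjectSpec:
    """Subject preset with muscle-artifact bursts, for exercising epoch rejection."""
    return SubjectSpec(subject_id=subject_id, artifact_burst_rate=burst_rate)


# ---------------------------------------------------------------------------
# persistence

def write_recordings_hdf5(cohort: Cohort, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for (sid, cond, hemi), rec in cohort.recordings.items():
            g = f.require_group(f"{sid}/{cond}/{hemi}")
            d = g.create_dataset("samples", data=rec.samples)
            d.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
            d.attrs["duration_s"] = len(rec.samples) / rec.sampling_rate_hz


def read_recordings_hdf5(path) -> dict[tuple[str, str, str], SourceRecording]:
    import h5py

    out: dict[tuple[str, str, str], SourceRecording] = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            for cond in f[sid]:
                for hemi in f[sid][cond]:
                    d = f[sid][cond][hemi]["samples"]
                    out[(sid, cond, hemi)] = SourceRecording(
                        sid, cond, hemi, d[()], float(d.attrs["sampling_rate_hz"]))
    return out


def ratings_to_frame(cohort: Cohort):
    import pandas as pd

    rows = [
        {"subject_id": sid, "condition": cond, "item_code": code, "score": score}
        for (sid, cond), items in cohort.ratings.items()
        for code, score in items.items()
    ]
    return pd.DataFrame(rows, columns=["subject_id", "condition", "item_code", "score"])


def write_ground_truth_json(cohort: Cohort, path) -> None:
    with open(path, "w") as f:
        json.dump(cohort.ground_truth, f, indent=2, sort_keys=True)
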