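"""Synthetic 15-patient cohort and per-patient level-walking gait cycles.

The virtual cohort stands in for CT-derived patient-specific musculoskeletal
models: demographics (8 of 15 male, age 50 +/- 14 y, BMI 30 +/- 4 kg/m^2)
are drawn from truncated normals, and each patient receives a smooth,
periodic level-walking cycle — three hip joint angles plus a 3-component
joint reaction force (JRF) in the pelvis frame — built from sum-of-harmonics
templates.  The JRF scales exactly linearly with body weight times a
patient-level multiplier ``jrf_scale``, so wear correlates with peak JRF but
with BMI only through the body-weight pathway.

Pelvis frame (right hip): x anterior, y superior, z lateral; the JRF is the
force exerted by the femoral head on the acetabulum (pointing
supero-medially during stance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

__all__ = [
    "Patient",
    "GaitCycle",
    "Harmonic",
    "Channel",
    "GaitParams",
    "sample_cohort",
    "synthesize_gait",
    "average_cycles",
    "read_gait_csv",
    "write_gait_csv",
    "cohort_to_frame",
]

GRAVITY = 9.81  # m s^-2

GAIT_CSV_COLUMNS = [
    "time_s",
    "flex_deg",
    "abd_deg",
    "rot_deg",
    "jrf_x_N",
    "jrf_y_N",
    "jrf_z_N",
]


@dataclass(frozen=True)
class Patient:
    id: str
    sex: str  # "M" | "F"
    age: float  # years
    height: float  # m
    body_mass: float  # kg
    jrf_scale: float = 1.0  # patient-level multiplier on the JRF waveform

    def __post_init__(self) -> None:
        if min(self.age, self.height, self.body_mass) <= 0:
            raise ValueError("age, height and body mass must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")

    @property
    def bmi(self) -> float:
        return self.body_mass / self.height**2

    @property
    def body_weight(self) -> float:
        """Body weight in newtons."""
        return self.body_mass * GRAVITY


@dataclass(frozen=True)
class GaitCycle:
    """One normalized level-walking cycle.

    Angles in degrees, JRF in newtons (pelvis frame, one row per sample).
    The time grid spans [0, 1] inclusive and every channel is periodic
    (first sample equals last).
    """

    t: np.ndarray  # (n,) normalized time on [0, 1]
    flexion_extension: np.ndarray  # (n,) deg
    abduction_adduction: np.ndarray  # (n,) deg
    internal_external_rotation: np.ndarray  # (n,) deg
    jrf: np.ndarray  # (n, 3) N, pelvis frame
    cycle_duration: float = 1.1  # s

    def __post_init__(self) -> None:
        n = len(self.t)
        if n < 16:
            raise ValueError("a gait cycle needs at least 16 samples")
        for name in (
            "flexion_extension",
            "abduction_adduction",
            "internal_external_rotation",
        ):
            ch = getattr(self, name)
            if len(ch) != n:
                raise ValueError(f"channel {name} length mismatch")
            if abs(ch[0] - ch[-1]) > 1e-9:
                raise ValueError(f"channel {name} is not periodic")
        if self.jrf.shape != (n, 3):
            raise ValueError("jrf must be (n, 3)")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def angles(self) -> np.ndarray:
        """(n, 3) stack: flexion, abduction, rotation in degrees."""
        return np.column_stack(
            [
                self.flexion_extension,
                self.abduction_adduction,
                self.internal_external_rotation,
            ]
        )

    @property
    def jrf_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.jrf, axis=1)

    @property
    def peak_jrf(self) -> float:
        return float(self.jrf_magnitude.max())


@dataclass(frozen=True)
class Harmonic:
    order: int  # cycles per gait cycle
    amplitude: float
    phase: float  # fraction of cycle

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.cos(
            2.0 * np.pi * self.order * (t - self.phase)
        )


@dataclass(frozen=True)
class Channel:
    """A periodic waveform template: offset plus cosine harmonics."""

    offset: float
    harmonics: tuple[Harmonic, ...] = ()

    def evaluate(self, t: np.ndarray, amp_scale: float = 1.0) -> np.ndarray:
        out = np.full_like(t, self.offset, dtype=float)
        for h in self.harmonics:
            out = out + amp_scale * h(t)
        return out

    @property
    def amplitude(self) -> float:
        return float(sum(abs(h.amplitude) for h in self.harmonics))

    @staticmethod
    def from_dict(d: dict) -> "Channel":
        return Channel(
            offset=float(d.get("offset", 0.0)),
            harmonics=tuple(
                Harmonic(int(k), float(a), float(p))
                for k, a, p in d.get("harmonics", [])
            ),
        )


@dataclass(frozen=True)
class GaitParams:
    """Templates and variability of the parametric gait synthesizer.

    Angle channels in degrees; ``jrf_magnitude_bw`` in units of body weight;
    the JRF direction is set by two tilt channels (degrees): ``jrf_frontal``
    tilts the force from the pelvis superior axis toward medial, and
    ``jrf_sagittal`` toward anterior.  ``inter_patient_amp_sd`` and
    ``intra_cycle_noise`` are fractional variabilities (must lie in
    [0, 0.5]).
    """

    flexion: Channel
    abduction: Channel
    rotation: Channel
    jrf_magnitude_bw: Channel
    jrf_frontal: Channel
    jrf_sagittal: Channel
    inter_patient_amp_sd: float = 0.08
    intra_cycle_noise: float = 0.02
    cycle_duration: float = 1.1
    max_angle_amplitude: float = 60.0  # deg, physiological bound
    max_jrf_bw: float = 4.0  # peak |JRF| bound in body weights

    def __post_init__(self) -> None:
        for frac in (self.inter_patient_amp_sd, self.intra_cycle_noise):
            if not (0.0 <= frac <= 0.5):
                raise ValueError("variability fractions must lie in [0, 0.5]")
        for ch in (self.flexion, self.abduction, self.rotation):
            if ch.amplitude + abs(ch.offset) > self.max_angle_amplitude:
                raise ValueError("angle template exceeds physiological bound")
        if self.jrf_magnitude_bw.offset + self.jrf_magnitude_bw.amplitude > self.max_jrf_bw:
            raise ValueError("JRF template exceeds the body-weight bound")

    @staticmethod
    def from_dict(d: dict) -> "GaitParams":
        kwargs = {}
        for key in (
            "flexion",
            "abduction",
            "rotation",
            "jrf_magnitude_bw",
            "jrf_frontal",
            "jrf_sagittal",
        ):
            kwargs[key] = Channel.from_dict(d[key])
        for key in (
            "inter_patient_amp_sd",
            "intra_cycle_noise",
            "cycle_duration",
            "max_angle_amplitude",
            "max_jrf_bw",
        ):
            if key in d:
                kwargs[key] = float(d[key])
        return GaitParams(**kwargs)


def default_gait_params() -> GaitParams:
    from .config import load_default_config

    return GaitParams.from_dict(load_default_config()["gait"])


def _truncnorm_rvs(mean, sd, lo, hi, size, rng):
    if sd <= 0:
        raise ValueError("SD must be positive")
    if lo >= hi:
        raise ValueError("impossible truncation bounds")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if truncnorm.cdf(b, a, b) <= 0:  # pragma: no cover - guarded by lo < hi
        raise ValueError("truncation bounds exclude all mass")
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(
    n: int = 15,
    n_male: int = 8,
    age_mean: float = 50.0,
    age_sd: float = 14.0,
    bmi_mean: float = 30.0,
    bmi_sd: float = 4.0,
    age_bounds: tuple[float, float] = (18.0, 90.0),
    bmi_bounds: tuple[float, float] = (18.0, 45.0),
    height_male: tuple[float, float] = (1.75, 0.07),
    height_female: tuple[float, float] = (1.62, 0.065),
    jrf_scale_sd: float = 0.12,
    seed: int = 0,
) -> list[Patient]:
    """Draw a reproducible synthetic cohort.

    Age and BMI come from truncated normals; height from sex-specific
    normals; body mass is derived as BMI x height^2.  ``jrf_scale`` is an
    independent truncated-normal multiplier (mean 1) expressing patient-level
    gait vigour not explained by body weight.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if not (0 <= n_male <= n):
        raise ValueError("need 0 <= n_male <= n")
    rng = np.random.default_rng(seed)
    ages = _truncnorm_rvs(age_mean, age_sd, *age_bounds, size=n, rng=rng)
    bmis = _truncnorm_rvs(bmi_mean, bmi_sd, *bmi_bounds, size=n, rng=rng)
    sexes = ["M"] * n_male + ["F"] * (n - n_male)
    heights = np.empty(n)
    for i, sex in enumerate(sexes):
        mu, sd = height_male if sex == "M" else height_female
        heights[i] = _truncnorm_rvs(mu, sd, mu - 3 * sd, mu + 3 * sd, 1, rng)[0]
    jrf_scales = _truncnorm_rvs(1.0, jrf_scale_sd, 0.6, 1.4, size=n, rng=rng)
    return [
        Patient(
            id=f"P{i + 1:02d}",
            sex=sexes[i],
            age=float(ages[i]),
            height=float(heights[i]),
            body_mass=float(bmis[i] * heights[i] ** 2),
            jrf_scale=float(jrf_scales[i]),
        )
        for i in range(n)
    ]


def cohort_to_frame(cohort: Sequence[Patient]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in cohort],
            "sex": [p.sex for p in cohort],
            "age": [p.age for p in cohort],
            "height_m": [p.height for p in cohort],
            "mass_kg": [p.body_mass for p in cohort],
            "bmi": [p.bmi for p in cohort],
            "jrf_scale": [p.jrf_scale for p in cohort],
        }
    )


def _direction_from_tilts(frontal_deg: np.ndarray, sagittal_deg: np.ndarray) -> np.ndarray:
    """Unit JRF direction from tilts off the pelvis superior axis."""
    tf = np.radians(frontal_deg)
    ts = np.radians(sagittal_deg)
    v = np.column_stack(
        [np.sin(ts), np.cos(ts) * np.cos(tf), -np.cos(ts) * np.sin(tf)]
    )
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def synthesize_gait(
    patient: Patient,
    gait_params: GaitParams | None = None,
    n_samples: int = 101,
    seed: int = 0,
    cycle_index: int | None = None,
) -> GaitCycle:
    """Synthesize one level-walking cycle for ``patient``.

    ``seed`` fixes the patient-level perturbation (per-channel amplitude
    multipliers and a small phase jitter drawn once per patient); passing a
    ``cycle_index`` additionally applies cycle-to-cycle noise scaled by
    ``intra_cycle_noise`` — used to emulate averaging several recorded
    cycles into one representative cycle per patient.

    The JRF is the magnitude template (body weights) times
    ``patient.body_weight x patient.jrf_scale`` along the tilt-template
    direction, so it scales exactly linearly with body weight.
    """
    if gait_params is None:
        gait_params = default_gait_params()
    if n_samples < 16:
        raise ValueError("need n_samples >= 16")
    p = gait_params

    rng = np.random.default_rng([seed, 0xD0])
    amp_sd = p.inter_patient_amp_sd
    amp = {}
    for name in ("flexion", "abduction", "rotation", "jrf"):
        amp[name] = float(np.clip(rng.normal(1.0, amp_sd), 1 - 3 * amp_sd, 1 + 3 * amp_sd))
    phase_jitter = float(rng.normal(0.0, 0.01))
    if cycle_index is not None:
        crng = np.random.default_rng([seed, 0xC1, cycle_index])
        noise = p.intra_cycle_noise
        for name in amp:
            amp[name] *= float(np.clip(crng.normal(1.0, noise), 1 - 3 * noise, 1 + 3 * noise))
        phase_jitter += float(crng.normal(0.0, 0.3 * noise))

    t = np.linspace(0.0, 1.0, n_samples)
    tj = t - phase_jitter  # harmonics are periodic; a shift keeps periodicity
    flex = p.flexion.evaluate(tj, amp["flexion"])
    abd = p.abduction.evaluate(tj, amp["abduction"])
    rot = p.rotation.evaluate(tj, amp["rotation"])
    mag_bw = p.jrf_magnitude_bw.evaluate(tj, amp["jrf"])
    mag_bw = np.clip(mag_bw, 0.0, None)
    direction = _direction_from_tilts(
        p.jrf_frontal.evaluate(tj), p.jrf_sagittal.evaluate(tj)
    )
    jrf = (mag_bw * patient.body_weight * patient.jrf_scale)[:, None] * direction
    return GaitCycle(
        t=t,
        flexion_extension=flex,
        abduction_adduction=abd,
        internal_external_rotation=rot,
        jrf=jrf,
        cycle_duration=p.cycle_duration,
    )


def average_cycles(cycles: Sequence[GaitCycle]) -> GaitCycle:
    """Pointwise mean of cycles sharing one time grid (periodicity preserved)."""
    if len(cycles) == 0:
        raise ValueError("need at least one cycle")
    ref = cycles[0]
    for c in cycles[1:]:
        if c.n_samples != ref.n_samples or not np.allclose(c.t, ref.t, atol=1e-12):
            raise ValueError("cycles must share a common time grid")
    return GaitCycle(
        t=ref.t.copy(),
        flexion_extension=np.mean([c.flexion_extension for c in cycles], axis=0),
        abduction_adduction=np.mean([c.abduction_adduction for c in cycles], axis=0),
        internal_external_rotation=np.mean(
            [c.internal_external_rotation for c in cycles], axis=0
        ),
        jrf=np.mean([c.jrf for c in cycles], axis=0),
        cycle_duration=float(np.mean([c.cycle_duration for c in cycles])),
    )


def representative_cycle(
    patient: Patient,
    gait_params: GaitParams | None = None,
    n_samples: int = 101,
    seed: int = 0,
    n_cycles: int = 11,
) -> GaitCycle:
    """Average ``n_cycles`` perturbed cycles into one per-patient cycle."""
    cycles = [
        synthesize_gait(patient, gait_params, n_samples, seed, cycle_index=i)
        for i in range(n_cycles)
    ]
    return average_cycles(cycles)


def write_gait_csv(cycle: GaitCycle, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": cycle.t * cycle.cycle_duration,
            "flex_deg": cycle.flexion_extension,
            "abd_deg": cycle.abduction_adduction,
            "rot_deg": cycle.internal_external_rotation,
            "jrf_x_N": cycle.jrf[:, 0],
            "jrf_y_N": cycle.jrf[:, 1],
            "jrf_z_N": cycle.jrf[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_gait_csv(path: str | Path) -> GaitCycle:
    """Read a gait cycle CSV (schema ``time_s, flex_deg, ..., jrf_z_N``).

    Malformed numeric rows and non-monotone time are reported with their
    1-based data row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in GAIT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gait CSV missing column(s): {', '.join(missing)}")
    numeric = df[GAIT_CSV_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        rows = ", ".join(str(i + 1) for i in numeric.index[bad][:10])
        raise ValueError(f"gait CSV has malformed row(s): {rows}")
    time = numeric["time_s"].to_numpy()
    dt = np.diff(time)
    if (dt <= 0).any():
        row = int(np.argmax(dt <= 0)) + 2
        raise ValueError(f"non-monotone time column at data row {row}")
    duration = float(time[-1] - time[0])
    if duration <= 0:
        raise ValueError("cycle duration must be positive")
    t = (time - time[0]) / duration
    return GaitCycle(
        t=t,
        flexion_extension=numeric["flex_deg"].to_numpy(),
        abduction_adduction=numeric["abd_deg"].to_numpy(),
        internal_external_rotation=numeric["rot_deg"].to_numpy(),
        jrf=numeric[["jrf_x_N", "jrf_y_N", "jrf_z_N"]].to_numpy(),
        cycle_duration=duration,
    )
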