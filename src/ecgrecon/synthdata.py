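"""Synthetic 12-lead ECG generator with vectorcardiographic structure.

Cardiac electrical activity is modelled as a 3-D dipole trajectory built from
Gaussian bumps in cardiac phase — one bump per P, Q, R, S and T wave, each
with a 3-vector amplitude (millivolts per dipole axis), a phase width and a
phase center.  Surface leads are linear projections of the dipole through a
:class:`~ecgrecon.leads.LeadMatrix`, so noise-free 12-lead output lies exactly
in a rank-3 subspace and satisfies the Einthoven and Goldberger identities by
construction — the geometric assumptions the reduced-lead reconstruction task
rests on, in analytically checkable form.

Beat-to-beat variability comes from per-beat RR intervals drawn from a
subject's heart-rate distribution; per-subject morphology variation from
seeded jitter of wave parameters.  Pathology-like labels are produced by
explicit morphology edits (ST offset, T inversion, frontal-axis rotation, PR
shortening) declared as :class:`LabelRule` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .leads import CANONICAL_LEADS, LeadMatrix, lead_indices
from .records import EcgRecord

WAVE_NAMES = ("P", "Q", "R", "S", "T")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)


#: Baseline wave morphology: (amplitude mV, direction, width rad, center rad).
_BASE_WAVES = {
    "P": (0.12, _unit([0.55, 0.80, 0.20]), 0.22, -2.00),
    "Q": (-0.12, _unit([0.85, 0.35, 0.40]), 0.06, -0.33),
    "R": (1.40, _unit([0.60, 0.75, 0.30]), 0.09, 0.00),
    "S": (-0.25, _unit([0.35, 0.20, 0.90]), 0.06, 0.33),
    "T": (0.35, _unit([0.50, 0.65, 0.35]), 0.35, 1.60),
}


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian phase bump of the dipole trajectory."""

    amplitude: np.ndarray  # mV, 3-vector (one entry per dipole axis)
    width: float           # radians of cardiac phase, > 0
    center: float          # radians in [-pi, pi)

    def __post_init__(self):
        object.__setattr__(self, "amplitude",
                           np.asarray(self.amplitude, dtype=np.float64))
        if self.amplitude.shape != (3,):
            raise ValueError("amplitude must be a 3-vector")
        if not self.width > 0:
            raise ValueError("width must be strictly positive")
        if not (-np.pi <= self.center < np.pi):
            raise ValueError("center must lie in [-pi, pi)")


@dataclass(frozen=True)
class SubjectParams:
    subject_id: str
    heart_rate_mean: float          # beats/min
    heart_rate_sd: float            # beats/min, >= 0
    waves: tuple[WaveComponent, ...]  # exactly P, Q, R, S, T
    amplitude_scale: float = 1.0

    def __post_init__(self):
        if not (30.0 <= self.heart_rate_mean <= 220.0):
            raise ValueError("heart_rate_mean must lie in [30, 220] bpm")
        if self.heart_rate_sd < 0:
            raise ValueError("heart_rate_sd must be >= 0")
        if len(self.waves) != 5:
            raise ValueError("exactly five wave components required")
        centers = [w.center for w in self.waves]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError("wave centers must be strictly increasing")
        if not self.amplitude_scale >= 0:
            raise ValueError("amplitude_scale must be >= 0")

    def wave(self, name: str) -> WaveComponent:
        return self.waves[WAVE_NAMES.index(name)]

    def phase_windows(self) -> dict[str, tuple[float, float]]:
        """Deterministic phase windows used by label rules and tests.

        ST runs from just after the S bump to just before the T bump; the P
        and T windows cover +-2 widths around their centers.
        """
        p, _, _, s, t = self.waves
        return {
            "P": (p.center - 2.0 * p.width, p.center + 2.0 * p.width),
            "ST": (s.center + 2.0 * s.width, t.center - 1.5 * t.width),
            "T": (t.center - 1.5 * t.width, t.center + 2.0 * t.width),
        }


@dataclass(frozen=True)
class NoiseConfig:
    baseline_wander_amp: float = 0.08   # mV
    baseline_wander_freq: float = 0.33  # Hz
    broadband_sd: float = 0.02          # mV
    powerline_amp: float = 0.02         # mV
    powerline_freq: float = 50.0        # Hz
    nan_burst_prob: float = 0.1         # per record
    nan_burst_len: int = 25             # samples

    def __post_init__(self):
        if min(self.baseline_wander_amp, self.broadband_sd,
               self.powerline_amp) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not (0.0 <= self.nan_burst_prob <= 1.0):
            raise ValueError("nan_burst_prob must lie in [0, 1]")
        if self.nan_burst_len < 1:
            raise ValueError("nan_burst_len must be >= 1")

    @property
    def silent(self) -> bool:
        return (self.baseline_wander_amp == 0 and self.broadband_sd == 0
                and self.powerline_amp == 0 and self.nan_burst_prob == 0)


NOISE_PROFILES: dict[str, NoiseConfig] = {
    "none": NoiseConfig(0.0, 0.33, 0.0, 0.0, 50.0, 0.0, 1),
    "mild": NoiseConfig(0.04, 0.33, 0.01, 0.01, 50.0, 0.05, 15),
    "default": NoiseConfig(),
}

PERTURBATION_KINDS = ("st_offset", "t_inversion", "axis_rotation", "pr_shortening")


@dataclass(frozen=True)
class LabelRule:
    """A declarative morphology edit that defines one condition label."""

    name: str
    perturbation: str               # one of PERTURBATION_KINDS
    magnitude: float                # mV (offsets), fraction (inversion), deg (rotation), ms (PR)
    leads: tuple[str, ...] = ()     # affected leads (ignored for rotation/PR)
    prevalence: float = 0.5

    def __post_init__(self):
        if self.perturbation not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.perturbation!r}")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        for lead in self.leads:
            if lead not in CANONICAL_LEADS:
                raise ValueError(f"unknown lead {lead!r}")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in [0, 1]")


def load_rules(path: str | Path) -> list[LabelRule]:
    """Read label rules from a YAML file (list of name/perturbation/... maps)."""
    raw = yaml.safe_load(Path(path).read_text())
    return [LabelRule(name=r["name"], perturbation=r["perturbation"],
                      magnitude=float(r["magnitude"]),
                      leads=tuple(r.get("leads", ())),
                      prevalence=float(r.get("prevalence", 0.5)))
            for r in raw]


# ---------------------------------------------------------------------------
# subjects and trajectories
# ---------------------------------------------------------------------------

def make_subject(seed: int) -> SubjectParams:
    """Draw per-subject morphology and rate parameters (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    waves = []
    prev_center = -np.pi
    for name in WAVE_NAMES:
        amp, direction, width, center = _BASE_WAVES[name]
        amp = amp * (1.0 + 0.15 * rng.standard_normal())
        direction = _unit(direction + 0.08 * rng.standard_normal(3))
        width = width * float(np.clip(1.0 + 0.10 * rng.standard_normal(), 0.6, 1.4))
        center = center + 0.04 * rng.standard_normal()
        center = float(np.clip(center, prev_center + 0.02, np.pi - 1e-6))
        prev_center = center
        waves.append(WaveComponent(amplitude=amp * direction, width=width,
                                   center=center))
    hr_mean = float(np.clip(rng.normal(70.0, 8.0), 45.0, 110.0))
    hr_sd = float(abs(rng.normal(2.0, 1.0)))
    return SubjectParams(
        subject_id=f"subject-{seed}",
        heart_rate_mean=hr_mean,
        heart_rate_sd=hr_sd,
        waves=tuple(waves),
        amplitude_scale=float(np.exp(0.10 * rng.standard_normal())),
    )


def _wrap(delta: np.ndarray) -> np.ndarray:
    return (delta + np.pi) % (2.0 * np.pi) - np.pi


def cardiac_phase(params: SubjectParams, duration: float, fs: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample-wise cardiac phase in [-pi, pi); a beat spans one 2*pi sweep."""
    T = int(round(duration * fs))
    t = np.arange(T) / fs
    max_beats = int(np.ceil(duration * 220.0 / 60.0)) + 2
    rates = np.clip(rng.normal(params.heart_rate_mean, params.heart_rate_sd,
                               size=max_beats), 30.0, 220.0)
    rr = 60.0 / rates
    onsets = np.concatenate([[0.0], np.cumsum(rr)])
    idx = np.searchsorted(onsets, t, side="right") - 1
    frac = (t - onsets[idx]) / rr[idx]
    return -np.pi + 2.0 * np.pi * frac


def dipole_from_phase(params: SubjectParams, phase: np.ndarray) -> np.ndarray:
    """Evaluate the Gaussian-bump dipole model [3 x T] at given phases."""
    dipole = np.zeros((3, phase.size))
    for w in params.waves:
        bump = np.exp(-_wrap(phase - w.center) ** 2 / (2.0 * w.width ** 2))
        dipole += w.amplitude[:, None] * bump[None, :]
    return params.amplitude_scale * dipole


def dipole_trajectory(params: SubjectParams, duration: float, fs: float,
                      seed: int, return_phase: bool = False):
    """Simulate a [3 x T] dipole trajectory with beat-to-beat rate variation."""
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    rng = np.random.default_rng(seed)
    phase = cardiac_phase(params, duration, fs, rng)
    dipole = dipole_from_phase(params, phase)
    return (dipole, phase) if return_phase else dipole


def project_leads(dipole: np.ndarray, lm: LeadMatrix) -> np.ndarray:
    """Project a [3 x T] dipole to the 12 standard leads."""
    return lm.project(dipole)


# ---------------------------------------------------------------------------
# label rules
# ---------------------------------------------------------------------------

def apply_label_rule(clean: np.ndarray, rule: LabelRule, fs: float,
                     phase: np.ndarray, params: SubjectParams,
                     lead_matrix: LeadMatrix | None = None) -> np.ndarray:
    """Apply one declared morphology edit; magnitude 0 returns the input copy."""
    clean = np.asarray(clean, dtype=np.float64)
    if clean.shape[0] != 12 or clean.shape[1] != phase.size:
        raise ValueError("clean must be [12 x T] aligned with phase")
    out = clean.copy()
    if rule.magnitude == 0:
        return out
    windows = params.phase_windows()
    rows = lead_indices(rule.leads) if rule.leads else list(range(12))

    if rule.perturbation == "st_offset":
        lo, hi = windows["ST"]
        mask = (phase >= lo) & (phase < hi)
        out[np.ix_(rows, np.where(mask)[0])] += rule.magnitude
    elif rule.perturbation == "t_inversion":
        lo, hi = windows["T"]
        mask = (phase >= lo) & (phase < hi)
        factor = 1.0 - 2.0 * min(rule.magnitude, 1.0)
        out[np.ix_(rows, np.where(mask)[0])] *= factor
    elif rule.perturbation == "axis_rotation":
        lm = lead_matrix or LeadMatrix.default()
        a = np.deg2rad(rule.magnitude)
        rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                        [np.sin(a), np.cos(a), 0.0],
                        [0.0, 0.0, 1.0]])
        out = lm.matrix @ rot @ np.linalg.pinv(lm.matrix) @ out
    elif rule.perturbation == "pr_shortening":
        lo, hi = windows["P"]
        shift = int(round(rule.magnitude * fs / 1000.0))
        if shift > 0:
            out = _shift_p_waves(out, phase, lo, hi, shift, rows)
    return out


def _shift_p_waves(x: np.ndarray, phase: np.ndarray, lo: float, hi: float,
                   shift: int, rows: list[int]) -> np.ndarray:
    """Move each beat's P-window segment `shift` samples toward the QRS."""
    out = x.copy()
    in_p = (phase >= lo) & (phase < hi)
    edges = np.flatnonzero(np.diff(in_p.astype(int)) == 1) + 1
    starts = ([0] if in_p[0] else []) + list(edges)
    for start in starts:
        end = start
        while end < phase.size and in_p[end]:
            end += 1
        seg = x[np.ix_(rows, range(start, end))]
        dst0 = min(start + shift, phase.size)
        dst1 = min(end + shift, phase.size)
        out[np.ix_(rows, range(start, dst1))] = seg[:, :1]  # baseline fill
        out[np.ix_(rows, range(dst0, dst1))] = seg[:, :dst1 - dst0]
    return out


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def add_noise_and_nans(clean: np.ndarray, cfg: NoiseConfig, fs: float,
                       seed: int) -> np.ndarray:
    """Additive wander/broadband/powerline noise plus contiguous NaN bursts."""
    clean = np.asarray(clean, dtype=np.float64)
    if cfg.silent:
        return clean.copy()
    rng = np.random.default_rng(seed)
    L, T = clean.shape
    t = np.arange(T) / fs
    out = clean.copy()
    if cfg.baseline_wander_amp > 0:
        ph = rng.uniform(0, 2 * np.pi, size=L)
        out += cfg.baseline_wander_amp * np.sin(
            2 * np.pi * cfg.baseline_wander_freq * t[None, :] + ph[:, None])
    if cfg.broadband_sd > 0:
        out += rng.normal(0.0, cfg.broadband_sd, size=(L, T))
    if cfg.powerline_amp > 0:
        ph = rng.uniform(0, 2 * np.pi)
        out += cfg.powerline_amp * np.sin(2 * np.pi * cfg.powerline_freq * t + ph)
    if cfg.nan_burst_prob > 0 and rng.random() < cfg.nan_burst_prob:
        lead = int(rng.integers(L))
        start = int(rng.integers(max(T - cfg.nan_burst_len, 1)))
        out[lead, start:start + cfg.nan_burst_len] = np.nan
    return out


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def generate_dataset(n_subjects: int, records_per_subject: int, duration: float,
                     fs: float, rules: list[LabelRule] = (),
                     label_prevalence: float | list[float] | None = None,
                     noise: NoiseConfig | None = None, seed: int = 0,
                     lead_matrix: LeadMatrix | None = None) -> list[EcgRecord]:
    """Generate n_subjects x records_per_subject labelled 12-lead records.

    All records of one subject share SubjectParams; labels are multi-hot over
    the rule names, drawn per record with each rule's prevalence.  Output is
    bit-reproducible for a fixed seed.  Each record's meta carries the cardiac
    phase track and its SubjectParams for windowed downstream analysis.
    """
    if n_subjects < 1 or records_per_subject < 1:
        raise ValueError("need at least one subject and one record per subject")
    rules = list(rules)
    if label_prevalence is not None:
        if not rules and np.any(np.asarray(label_prevalence, float) > 0):
            raise ValueError("nonzero label prevalence requires label rules")
        prevs = (np.full(len(rules), label_prevalence, dtype=float)
                 if np.isscalar(label_prevalence) else np.asarray(label_prevalence, float))
        if len(prevs) != len(rules):
            raise ValueError("one prevalence per rule required")
        rules = [replace(r, prevalence=float(p)) for r, p in zip(rules, prevs)]
    noise = noise if noise is not None else NOISE_PROFILES["default"]
    lm = lead_matrix or LeadMatrix.default()
    label_names = tuple(r.name for r in rules)

    root = np.random.default_rng(seed)
    records: list[EcgRecord] = []
    for s in range(n_subjects):
        subject_seed = int(root.integers(2 ** 31))
        params = make_subject(subject_seed)
        subject_id = f"S{s:04d}"
        for r in range(records_per_subject):
            rec_seed = int(root.integers(2 ** 31))
            dipole, phase = dipole_trajectory(params, duration, fs, rec_seed,
                                              return_phase=True)
            signal = project_leads(dipole, lm)
            label_rng = np.random.default_rng(rec_seed + 1)
            labels = np.array([1 if label_rng.random() < rule.prevalence else 0
                               for rule in rules], dtype=np.int8)
            for rule, flag in zip(rules, labels):
                if flag:
                    signal = apply_label_rule(signal, rule, fs, phase, params,
                                              lead_matrix=lm)
            signal = add_noise_and_nans(signal, noise, fs, rec_seed + 2)
            records.append(EcgRecord(
                signal=signal, fs=fs, lead_names=CANONICAL_LEADS,
                subject_id=subject_id, record_id=f"{subject_id}R{r:03d}",
                labels=labels if rules else None, label_names=label_names,
                meta={"phase": phase, "params": params},
            ))
    return records
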