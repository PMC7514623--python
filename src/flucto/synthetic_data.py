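"""Synthetic two-site gyroscope cohorts with known fluctuation severity.

No public dataset accompanies this problem, so every pipeline stage is
exercised on simulated recordings whose ground truth is known by
construction.  The simulator is deliberately simple — its contract is only
that the severity parameters move the feature families associated with each
motor sign in the right direction:

* tremor: an amplitude-modulated sinusoid whose frequency is redrawn from
  U(4, 6) Hz every 5 s block and whose amplitude scales with
  ``tremor_level`` (40 deg/s at level 1 on the wrist; the ankle expresses
  tremor at half the wrist amplitude);
* free-living activity background: band-limited (0.5–3 Hz) Gaussian noise,
  25 deg/s RMS, suppressed by bradykinesia as (1 − 0.7·brady_level) — so
  ``brady_level`` lowers 1–4 Hz power and average jerk;
* white measurement noise, 1.5 deg/s SD.

A pseudo-UPDRS III score is a deterministic monotone map of the two levels,
round(5 + 25·tremor + 30·brady), spanning 5–60 as in a moderately to
severely affected cohort.  A subject is a sequence of rounds: the first
half at the OFF profile, the rest at (or interpolating toward) the ON
profile, so the AC-UPDRS III severity class of the subject — and the
change degree of every round pair — follows directly from the profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal as sps

from .io_preproc import (
    INC,
    GyroRecording,
    Inconclusive,
    Round,
    Site,
    compute_ac_updrs,
    severity_label,
)

__all__ = [
    "SeverityProfile",
    "CohortSpec",
    "SyntheticSubject",
    "Cohort",
    "simulate_recording",
    "generate_subject",
    "generate_cohort",
]

#: Pseudo-UPDRS mapping weights: base score plus contributions of the two
#: severity levels, spanning 5 (asymptomatic) to 60 (maximal) — the upper
#: end of the scale seen in severely affected OFF-state patients.
UPDRS_BASE = 5.0
UPDRS_W_TREMOR = 25.0
UPDRS_W_BRADY = 30.0

TREMOR_AMPLITUDE = 40.0  # deg/s at tremor_level = 1 (wrist)
ANKLE_TREMOR_DAMPING = 0.5
BACKGROUND_AMPLITUDE = 25.0  # deg/s RMS of the activity background
BRADY_SUPPRESSION = 0.7
NOISE_SD = 1.5  # deg/s


@dataclass(frozen=True)
class SeverityProfile:
    """Latent symptom severities in [0, 1] driving the signal generator."""

    tremor_level: float
    brady_level: float

    def __post_init__(self) -> None:
        for name, v in (("tremor_level", self.tremor_level), ("brady_level", self.brady_level)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def pseudo_updrs(self) -> int:
        """Monotone integer pseudo-UPDRS III score of this profile."""
        return int(
            round(
                UPDRS_BASE
                + UPDRS_W_TREMOR * self.tremor_level
                + UPDRS_W_BRADY * self.brady_level
            )
        )

    def interpolate(self, other: "SeverityProfile", t: float) -> "SeverityProfile":
        return SeverityProfile(
            tremor_level=(1 - t) * self.tremor_level + t * other.tremor_level,
            brady_level=(1 - t) * self.brady_level + t * other.brady_level,
        )


def _bandlimited_noise(
    n: int, fs: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    white = rng.standard_normal(n)
    nyq = fs / 2
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_recording(
    profile: SeverityProfile,
    duration_s: float,
    fs: float = 64.0,
    seed: int = 0,
    site: Site = Site.WRIST,
    subject_id: str = "sim",
    t0: float = 0.0,
    tremor_direction: Optional[np.ndarray] = None,
) -> GyroRecording:
    """One site's tri-axial recording under a fixed severity profile.

    Deterministic for a given seed.  Tremor energy is distributed over the
    three axes through a unit direction vector; with a strapped sensor the
    tremor axis is anatomically fixed, so callers simulating several rounds
    of one subject should pass the same ``tremor_direction`` for each (when
    omitted, a direction is drawn from the seed).  The activity background
    is independent per axis.
    """
    if duration_s < 5:
        raise ValueError("duration must be at least 5 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    damping = ANKLE_TREMOR_DAMPING if site == Site.ANKLE else 1.0
    block = int(round(5 * fs))
    n_blocks = int(math.ceil(n / block))
    freqs = rng.uniform(4.0, 6.0, size=n_blocks)
    inst_freq = np.repeat(freqs, block)[:n]
    phase = 2 * np.pi * np.cumsum(inst_freq) / fs
    envelope = 1.0 + 0.2 * np.repeat(rng.standard_normal(n_blocks), block)[:n]
    tremor_amp = TREMOR_AMPLITUDE * profile.tremor_level * damping
    tremor = tremor_amp * np.clip(envelope, 0.3, None) * np.sin(phase)
    if tremor_direction is None:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
    else:
        direction = np.asarray(tremor_direction, dtype=float)
        direction = direction / np.linalg.norm(direction)

    bg_amp = BACKGROUND_AMPLITUDE * (1.0 - BRADY_SUPPRESSION * profile.brady_level)
    axes = []
    for ax in range(3):
        background = bg_amp * _bandlimited_noise(n, fs, 0.5, 3.0, rng)
        noise = NOISE_SD * rng.standard_normal(n)
        axes.append(background + direction[ax] * tremor + noise)
    samples = np.column_stack(axes)
    return GyroRecording(
        subject_id=subject_id, site=site, fs=fs, samples=samples, t0=t0
    )


@dataclass
class SyntheticSubject:
    """A simulated subject: a day of rounds plus the ground-truth severity.

    ``timeline_rounds`` is the subject's full day segmented into fixed
    rounds; ``rounds`` is the scored subset (those with a concurrent
    pseudo-UPDRS assessment) used for classifier training.  The subject-
    level decision stage operates on all timeline rounds, as a day-long
    recording provides far more round pairs than were clinically scored.
    """

    subject_id: str
    rounds: list[Round]
    profiles: list[SeverityProfile]
    true_severity: Union[int, Inconclusive]
    ac_updrs: Union[float, Inconclusive]
    seed: int
    timeline_rounds: list[Round] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.timeline_rounds:
            self.timeline_rounds = list(self.rounds)

    @property
    def pseudo_updrs_scores(self) -> list[int]:
        return [p.pseudo_updrs for p in self.profiles]


def _schedule(n_rounds: int, kind: str) -> list[float]:
    if kind == "step":
        n_off = -(-n_rounds // 2)  # ceil: first half OFF
        return [0.0] * n_off + [1.0] * (n_rounds - n_off)
    if kind == "linear":
        return [0.0] + [i / (n_rounds - 1) for i in range(1, n_rounds)]
    raise ValueError(f"unknown schedule {kind!r}")


def generate_subject(
    off_profile: SeverityProfile,
    on_profile: Optional[SeverityProfile],
    n_rounds: int,
    seed: int,
    subject_id: str = "synth",
    schedule: str = "step",
    round_duration_s: float = 180.0,
    fs: float = 64.0,
    n_timeline_rounds: Optional[int] = None,
) -> SyntheticSubject:
    """Simulate one subject's day of rounds with a scored subset.

    The day spans ``n_timeline_rounds`` consecutive rounds (defaults to
    ``n_rounds``): the first round(s) express the OFF profile and later
    rounds move toward the ON profile following the schedule ("step": half
    OFF, half ON; "linear": gradual interpolation).  ``n_rounds`` of them
    — the earliest OFF rounds and the latest ON rounds, emulating clinical
    assessments before medication and after conversion — carry pseudo-UPDRS
    scores and form the training subset.  Scores are monotone along the
    schedule.  ``on_profile=None`` models a subject who never converts:
    every round stays OFF and the ground-truth severity is INC.
    """
    if not 2 <= n_rounds <= 8:
        raise ValueError("n_rounds must lie in [2, 8]")
    n_timeline = n_timeline_rounds if n_timeline_rounds is not None else n_rounds
    if n_timeline < n_rounds:
        raise ValueError("n_timeline_rounds must be >= n_rounds")
    rng = np.random.default_rng(seed)
    ts = (
        _schedule(n_timeline, schedule)
        if on_profile is not None
        else [0.0] * n_timeline
    )
    # fixed per subject and site: sensor mounting and tremor axis do not
    # change between rounds of the same day
    directions = {}
    for site in (Site.WRIST, Site.ANKLE):
        d = rng.standard_normal(3)
        directions[site] = d / np.linalg.norm(d)

    profiles = [
        off_profile if on_profile is None else off_profile.interpolate(on_profile, t)
        for t in ts
    ]
    states = [
        "off" if (on_profile is None or t == 0.0) else "on" for t in ts
    ]
    off_idx = [i for i, s in enumerate(states) if s == "off"]
    on_idx = [i for i, s in enumerate(states) if s == "on"]
    if on_profile is None:
        scored = set(off_idx[:n_rounds])
    else:
        # aim for a half/half scored split, adapting to the schedule's
        # actual OFF/ON occupancy (a linear schedule has one OFF round)
        n_off_scored = min(-(-n_rounds // 2), len(off_idx))
        n_on_scored = min(n_rounds - n_off_scored, len(on_idx))
        n_off_scored = n_rounds - n_on_scored
        if n_off_scored > len(off_idx):
            raise ValueError("timeline too short for the requested scored rounds")
        scored = set(off_idx[:n_off_scored]) | set(on_idx[-n_on_scored:])

    timeline: list[Round] = []
    off_scores: list[float] = []
    on_scores: list[float] = []
    for i, (state, prof) in enumerate(zip(states, profiles)):
        score = prof.pseudo_updrs
        recs = {}
        for site in (Site.WRIST, Site.ANKLE):
            recs[site] = simulate_recording(
                prof,
                round_duration_s,
                fs=fs,
                seed=int(rng.integers(2**31)),
                site=site,
                subject_id=subject_id,
                t0=i * round_duration_s,
                tremor_direction=directions[site],
            )
        is_scored = i in scored
        if is_scored:
            (off_scores if state == "off" else on_scores).append(score)
        timeline.append(
            Round(
                round_id=f"{subject_id}-r{i + 1}",
                recordings=recs,
                start_s=i * round_duration_s,
                end_s=(i + 1) * round_duration_s,
                updrs_iii=float(score) if is_scored else None,
                state=state,
            )
        )
    rounds = [timeline[i] for i in sorted(scored)]
    ac = compute_ac_updrs(off_scores, on_scores)
    severity = INC if isinstance(ac, Inconclusive) else severity_label(ac)
    return SyntheticSubject(
        subject_id=subject_id,
        rounds=rounds,
        profiles=[profiles[i] for i in sorted(scored)],
        true_severity=severity,
        ac_updrs=ac,
        seed=seed,
        timeline_rounds=timeline,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic cohort.

    n_per_class gives the number of converting subjects per severity class
    0–3; the default (5, 5, 5, 9) keeps the severe class the largest, as in
    a fluctuating-PD clinic population, with 24 subjects total.
    n_inconclusive adds non-converting subjects (no ON rounds).
    """

    n_per_class: tuple[int, int, int, int] = (5, 5, 5, 9)
    n_inconclusive: int = 0
    rounds_range: tuple[int, int] = (3, 4)
    #: probability of each round count in rounds_range (inclusive); the
    #: default favours four-round subjects, matching a cohort averaging
    #: just under four scored rounds per subject
    rounds_weights: Optional[tuple[float, ...]] = (0.2, 0.8)
    #: span of the full-day timeline (3-min rounds) the decision stage
    #: operates on; day-long monitoring yields far more rounds than are
    #: clinically scored
    timeline_rounds_range: tuple[int, int] = (8, 12)
    round_duration_s: float = 180.0
    fs: float = 64.0
    schedule: str = "step"
    seed: int = 0


@dataclass
class Cohort:
    """A generated cohort with full provenance (spec and per-subject seeds)."""

    subjects: list[SyntheticSubject]
    spec: CohortSpec

    @property
    def class_counts(self) -> dict[Union[int, Inconclusive], int]:
        counts: dict[Union[int, Inconclusive], int] = {}
        for s in self.subjects:
            counts[s.true_severity] = counts.get(s.true_severity, 0) + 1
        return counts


#: AC-UPDRS target bands per severity class.  Targets keep a margin of at
#: least 1 point from the 5/10/15 cutoffs so that integer score rounding
#: cannot move a pair across a class boundary.
_DELTA_RANGE = {0: (2, 4), 1: (7, 9), 2: (12, 14), 3: (18, 23)}


def _profiles_for_class(
    severity: int, rng: np.random.Generator
) -> tuple[SeverityProfile, SeverityProfile]:
    """Draw OFF/ON profiles whose pseudo-UPDRS difference lands in the class.

    The OFF→ON improvement allocates the UPDRS change half to tremor and
    half to bradykinesia through the score weights, so a given change in
    score corresponds to the same change in signal expression for every
    subject regardless of their baseline profile — keeping the scores
    consistent with the simulated severities.
    """
    lo, hi = _DELTA_RANGE[severity]
    delta = int(rng.integers(lo, hi + 1))
    off = SeverityProfile(
        tremor_level=float(rng.uniform(0.6, 0.9)),
        brady_level=float(rng.uniform(0.5, 0.85)),
    )
    on = SeverityProfile(
        tremor_level=off.tremor_level - 0.5 * delta / UPDRS_W_TREMOR,
        brady_level=off.brady_level - 0.5 * delta / UPDRS_W_BRADY,
    )
    return off, on


def generate_cohort(spec: CohortSpec = CohortSpec()) -> Cohort:
    """Generate a full cohort, reproducible from spec.seed."""
    rng = np.random.default_rng(spec.seed)

    choices = list(range(spec.rounds_range[0], spec.rounds_range[1] + 1))
    weights = spec.rounds_weights
    if weights is not None and len(weights) != len(choices):
        raise ValueError("rounds_weights must match the rounds_range span")

    def _n_rounds() -> int:
        return int(rng.choice(choices, p=weights))

    def _n_timeline() -> int:
        lo, hi = spec.timeline_rounds_range
        return int(rng.integers(lo, hi + 1))

    subjects: list[SyntheticSubject] = []
    idx = 1
    for severity, count in enumerate(spec.n_per_class):
        for _ in range(count):
            off, on = _profiles_for_class(severity, rng)
            n_rounds = _n_rounds()
            sub = generate_subject(
                off,
                on,
                n_rounds=n_rounds,
                seed=int(rng.integers(2**31)),
                subject_id=f"S{idx:02d}",
                schedule=spec.schedule,
                round_duration_s=spec.round_duration_s,
                fs=spec.fs,
                n_timeline_rounds=max(_n_timeline(), n_rounds),
            )
            subjects.append(sub)
            idx += 1
    for _ in range(spec.n_inconclusive):
        off, _on = _profiles_for_class(3, rng)
        n_rounds = _n_rounds()
        sub = generate_subject(
            off,
            None,
            n_rounds=n_rounds,
            seed=int(rng.integers(2**31)),
            subject_id=f"S{idx:02d}",
            schedule=spec.schedule,
            round_duration_s=spec.round_duration_s,
            fs=spec.fs,
            n_timeline_rounds=max(_n_timeline(), n_rounds),
        )
        subjects.append(sub)
        idx += 1
    return Cohort(subjects=subjects, spec=spec)
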