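"""Sensor I/O, band-pass preprocessing, windowing, rounds and round pairs.

A *round* is a contiguous stretch of recording during which the subject's
motor state is assumed stable, optionally tagged with a concurrently scored
UPDRS-III value.  Rounds are arranged into all unordered pairs; the absolute
UPDRS-III change over a pair defines its motor-fluctuation degree (0 minimal,
1 mild, 2 moderate, 3 severe).  The subject-level fluctuation measure is
AC-UPDRS III: mean OFF-state score minus mean ON-state score.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

__all__ = [
    "Site",
    "INC",
    "Inconclusive",
    "GyroRecording",
    "Round",
    "RoundPair",
    "PreprocConfig",
    "bandpass_filter",
    "segment_windows",
    "segment_rounds",
    "pair_rounds",
    "severity_label",
    "compute_ac_updrs",
    "read_sensor_csv",
    "write_sensor_csv",
    "read_rounds_csv",
    "write_rounds_csv",
]


class Site(str, Enum):
    """Sensor mounting site."""

    WRIST = "wrist"
    ANKLE = "ankle"


class Inconclusive:
    """Singleton marker for an inconclusive (INC) outcome."""

    _instance: Optional["Inconclusive"] = None

    def __new__(cls) -> "Inconclusive":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "INC"


#: The inconclusive sentinel. ``compute_ac_updrs`` returns it when a subject
#: never reached the medication ON state; the decision rule emits it when the
#: change histogram supports neither fluctuation nor its absence.
INC = Inconclusive()


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing parameters.

    band_lo, band_hi
        FIR band-pass edges in Hz (0.5–15 Hz keeps voluntary movement,
        bradykinesia-band 1–4 Hz and tremor-band 4–6 Hz content while
        rejecting drift and high-frequency noise).
    window_s, overlap_s
        Sliding-window length and overlap in seconds for symptom-feature
        extraction (5 s windows, 4 s overlap).
    round_duration_s
        Duration of the fixed rounds used by the subject-level decision
        stage (3 min).
    severity_cutoffs
        UPDRS-III change cutoffs separating minimal/mild/moderate/severe.
    """

    band_lo: float = 0.5
    band_hi: float = 15.0
    window_s: float = 5.0
    overlap_s: float = 4.0
    round_duration_s: float = 180.0
    severity_cutoffs: tuple[float, float, float] = (5.0, 10.0, 15.0)

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("require 0 < band_lo < band_hi")
        if not 0 <= self.overlap_s < self.window_s:
            raise ValueError("require 0 <= overlap_s < window_s")
        if len(self.severity_cutoffs) != 3 or list(self.severity_cutoffs) != sorted(
            self.severity_cutoffs
        ):
            raise ValueError("severity_cutoffs must be three increasing numbers")


@dataclass
class GyroRecording:
    """One sensor site's tri-axial angular-velocity series.

    samples is an (n, 3) array of (x, y, z) angular velocities in deg/s
    sampled at fs Hz; t0 is the recording start time in seconds.
    """

    subject_id: str
    site: Site
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.site = Site(self.site)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if len(self.samples) < 1:
            raise ValueError("recording must contain at least one sample")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def slice_time(self, start_s: float, end_s: float) -> "GyroRecording":
        """Return the sub-recording covering [start_s, end_s) relative to t0."""
        i0 = int(round((start_s - self.t0) * self.fs))
        i1 = int(round((end_s - self.t0) * self.fs))
        i0 = max(i0, 0)
        i1 = min(i1, len(self.samples))
        if i1 <= i0:
            raise ValueError("empty time slice")
        return replace(self, samples=self.samples[i0:i1], t0=start_s)


@dataclass
class Round:
    """A contiguous recording segment, optionally with a UPDRS-III score."""

    round_id: str
    recordings: dict[Site, GyroRecording]
    start_s: float
    end_s: float
    updrs_iii: Optional[float] = None
    state: Optional[str] = None  # "off"/"on" when known

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("round must satisfy end_s > start_s")
        if self.updrs_iii is not None and self.updrs_iii < 0:
            raise ValueError("updrs_iii must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class RoundPair:
    """An unordered pair of rounds; round_i starts no later than round_j."""

    round_i: Round
    round_j: Round
    delta_updrs: Optional[float] = None
    severity_label: Optional[int] = None

    @property
    def pair_id(self) -> str:
        return f"{self.round_i.round_id}|{self.round_j.round_id}"


def _design_fir(fs: float, cfg: PreprocConfig) -> np.ndarray:
    order = int(round(4 * fs / cfg.band_lo))
    order += order % 2  # even order -> odd tap count, type-I linear phase
    taps = signal.firwin(
        order + 1,
        [cfg.band_lo, cfg.band_hi],
        pass_zero=False,
        window="hamming",
        fs=fs,
    )
    # Force an exact null at DC: the Hamming stopband alone leaves a small
    # residual gain at 0 Hz that a constant input would leak through.
    taps = taps - taps.sum() / len(taps)
    return taps


def bandpass_filter(rec: GyroRecording, cfg: PreprocConfig) -> GyroRecording:
    """Zero-phase FIR band-pass of all three axes.

    The windowed-sinc filter (Hamming window, order 4·fs/band_lo) is applied
    forward–backward so the two sensor sites stay time-aligned.
    """
    if rec.fs <= 2 * cfg.band_hi:
        raise ValueError(
            f"fs={rec.fs} Hz too low for band_hi={cfg.band_hi} Hz (need fs > 2*band_hi)"
        )
    taps = _design_fir(rec.fs, cfg)
    n = len(rec.samples)
    padlen = min(3 * len(taps), n - 1)
    filtered = signal.filtfilt(taps, [1.0], rec.samples, axis=0, padlen=padlen)
    return replace(rec, samples=filtered)


def segment_windows(rec: GyroRecording, cfg: PreprocConfig) -> np.ndarray:
    """Slide a window of window_s seconds with overlap_s overlap.

    Returns an array of shape (n_windows, window_len, 3).  Window starts
    advance by (window_s − overlap_s); a recording shorter than one window
    yields an empty result with a logged warning.
    """
    win = int(round(cfg.window_s * rec.fs))
    step = int(round((cfg.window_s - cfg.overlap_s) * rec.fs))
    if step < 1:
        raise ValueError("window step is below one sample")
    n = len(rec.samples)
    if n < win:
        log.warning(
            "recording %s/%s shorter than one window (%.2f s < %.2f s)",
            rec.subject_id,
            rec.site.value,
            rec.duration_s,
            cfg.window_s,
        )
        return np.empty((0, win, 3))
    starts = range(0, n - win + 1, step)
    return np.stack([rec.samples[s : s + win] for s in starts])


def segment_rounds(rec: GyroRecording, cfg: PreprocConfig) -> list[Round]:
    """Cut a recording into consecutive fixed-duration rounds.

    The trailing remainder shorter than round_duration_s is dropped; a
    recording shorter than one round yields an empty list with a warning.
    """
    dur = cfg.round_duration_s
    n_rounds = int(rec.duration_s // dur)
    if n_rounds == 0:
        log.warning(
            "recording %s shorter than one round (%.1f s < %.1f s)",
            rec.subject_id,
            rec.duration_s,
            dur,
        )
        return []
    rounds = []
    for i in range(n_rounds):
        start = rec.t0 + i * dur
        end = start + dur
        sub = rec.slice_time(start, end)
        rounds.append(
            Round(
                round_id=f"{rec.subject_id}-r{i + 1}",
                recordings={rec.site: sub},
                start_s=start,
                end_s=end,
            )
        )
    return rounds


def merge_site_rounds(rounds_by_site: Sequence[list[Round]]) -> list[Round]:
    """Merge per-site round lists (same segmentation) into two-site rounds."""
    merged: list[Round] = []
    for rounds in zip(*rounds_by_site, strict=True):
        first = rounds[0]
        recs: dict[Site, GyroRecording] = {}
        for r in rounds:
            recs.update(r.recordings)
        merged.append(replace(first, recordings=recs))
    return merged


def severity_label(
    delta_updrs: float, cutoffs: tuple[float, float, float] = (5.0, 10.0, 15.0)
) -> int:
    """Degree of motor-fluctuation severity from a UPDRS-III change.

    The absolute change is compared against the cutoffs: ≤5 minimal (0),
    (5,10] mild (1), (10,15] moderate (2), >15 severe (3).
    """
    if not np.isfinite(delta_updrs):
        raise ValueError("delta_updrs must be finite")
    a = abs(delta_updrs)
    lo, mid, hi = cutoffs
    if a <= lo:
        return 0
    if a <= mid:
        return 1
    if a <= hi:
        return 2
    return 3


def pair_rounds(rounds: Sequence[Round]) -> list[RoundPair]:
    """All C(n, 2) unordered round pairs, earlier round first.

    When both rounds carry UPDRS-III scores the pair gets delta_updrs
    (score_i − score_j) and the severity label of |delta|.
    """
    ordered = sorted(rounds, key=lambda r: r.start_s)
    pairs = []
    for ri, rj in itertools.combinations(ordered, 2):
        delta = None
        label = None
        if ri.updrs_iii is not None and rj.updrs_iii is not None:
            delta = ri.updrs_iii - rj.updrs_iii
            label = severity_label(delta)
        pairs.append(RoundPair(ri, rj, delta_updrs=delta, severity_label=label))
    return pairs


def compute_ac_updrs(
    off_scores: Sequence[float], on_scores: Sequence[float]
) -> float | Inconclusive:
    """AC-UPDRS III: mean OFF-state score minus mean ON-state score.

    Returns INC when the subject has no ON-state scores (never converted).
    """
    if len(off_scores) == 0:
        raise ValueError("off_scores must be non-empty")
    if len(on_scores) == 0:
        return INC
    return float(np.mean(off_scores) - np.mean(on_scores))


# ---------------------------------------------------------------------------
# CSV interchange


def write_sensor_csv(rec: GyroRecording, path) -> None:
    t = rec.t0 + np.arange(len(rec.samples)) / rec.fs
    df = pd.DataFrame(
        {
            "time_s": t,
            "x": rec.samples[:, 0],
            "y": rec.samples[:, 1],
            "z": rec.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_sensor_csv(path, subject_id: str, site: Site | str) -> GyroRecording:
    """Read a `time_s,x,y,z` sensor CSV; fs is inferred from the time column."""
    df = pd.read_csv(path)
    for col in ("time_s", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"sensor CSV missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("sensor CSV must contain at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    samples = df[["x", "y", "z"]].to_numpy(dtype=float)
    return GyroRecording(
        subject_id=subject_id, site=Site(site), fs=fs, samples=samples, t0=float(t[0])
    )


def write_rounds_csv(rounds: Sequence[Round], subject_id: str, path) -> None:
    rows = []
    for r in rounds:
        rows.append(
            {
                "subject_id": subject_id,
                "round_id": r.round_id,
                "site_files": ";".join(s.value for s in r.recordings),
                "start_s": r.start_s,
                "end_s": r.end_s,
                "updrs_iii": "" if r.updrs_iii is None else r.updrs_iii,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rounds_csv(path) -> pd.DataFrame:
    """Round metadata as a DataFrame (updrs_iii NaN when unscored)."""
    df = pd.read_csv(path)
    required = {"subject_id", "round_id", "start_s", "end_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rounds CSV missing columns {sorted(missing)}")
    if "updrs_iii" not in df.columns:
        df["updrs_iii"] = np.nan
    return df
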