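"""Core gaze-recording types and the preprocessing chain.

A reading trial is a timestamped binocular gaze stream recorded while a
subject reads one short text segment presented on one of 13 color
configurations (CC): black on white, or six colors used either as background
or as a transparent overlay.  Preprocessing turns the raw binocular stream
into a single monocular-equivalent point sequence:

1. drop samples where *both* eyes are invalid (gaze off screen / blink),
2. average the two eyes when both are valid, otherwise take the valid one,
3. optionally decimate 60 Hz -> 30 Hz by keeping every k-th sample,
4. exclude trials shorter than 5 s of reading (insufficient focus on text).

Timestamps are milliseconds from trial start and are preserved through
sample removal — downstream scoring windows are defined in time, not in
sample counts, so gaps must remain gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, NamedTuple, Optional, Sequence, Tuple

import numpy as np

#: The closed set of 13 color-configuration labels, in canonical order.
#: ``_bg`` = black text on a colored background, ``_ov`` = transparent
#: colored overlay on black text over white.
CC_LABELS: Tuple[str, ...] = (
    "white",
    "red_bg", "red_ov",
    "blue_bg", "blue_ov",
    "yellow_bg", "yellow_ov",
    "orange_bg", "orange_ov",
    "turquoise_bg", "turquoise_ov",
    "purple_bg", "purple_ov",
)

GROUPS: Tuple[str, ...] = ("dyslexic", "control")

#: Feature names used in cohort tables: SI / VAS totals at the native and
#: decimated rates, plus total reading time as the baseline feature.
FEATURE_NAMES: Tuple[str, ...] = ("si_60", "si_30", "vas_60", "vas_30", "reading_time")

#: Trials with less than this much reading are excluded (strictly-less).
MIN_READING_SECONDS: float = 5.0


class GazeError(Exception):
    """Base class for gaze-data errors."""


class FormatError(GazeError):
    """A file or table does not conform to the expected format."""


class DataError(GazeError):
    """The data are well-formed but internally inconsistent."""


class EmptyTrialError(GazeError):
    """A trial has no usable samples for the requested operation."""


class GazeSample(NamedTuple):
    """One binocular gaze measurement.

    ``left`` / ``right`` are ``(x, y)`` screen coordinates in pixels, or
    ``None`` when that eye could not be located.
    """

    t: float
    left: Optional[Tuple[float, float]]
    right: Optional[Tuple[float, float]]


def _first_nonmonotonic(t: np.ndarray) -> int:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    return int(bad[0]) + 1 if bad.size else -1


@dataclass
class GazeTrial:
    """An ordered raw gaze stream plus trial metadata.

    Coordinates are stored as ``(n, 2)`` float arrays with NaN rows where
    the corresponding eye is invalid; ``left_valid`` / ``right_valid`` are
    boolean masks.  Timestamps must be finite, non-negative and strictly
    increasing.
    """

    trial_id: str
    subject_id: str
    group: str
    cc: str
    rate_hz: float
    t: np.ndarray
    left: np.ndarray
    right: np.ndarray
    left_valid: np.ndarray
    right_valid: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.cc not in CC_LABELS:
            raise FormatError(
                f"unknown color configuration {self.cc!r}; expected one of {CC_LABELS}"
            )
        if not self.rate_hz > 0:
            raise FormatError(f"rate_hz must be positive, got {self.rate_hz}")
        self.t = np.asarray(self.t, dtype=float)
        self.left = np.asarray(self.left, dtype=float).reshape(-1, 2)
        self.right = np.asarray(self.right, dtype=float).reshape(-1, 2)
        self.left_valid = np.asarray(self.left_valid, dtype=bool)
        self.right_valid = np.asarray(self.right_valid, dtype=bool)
        n = self.t.size
        for name, arr in (("left", self.left), ("right", self.right),
                          ("left_valid", self.left_valid), ("right_valid", self.right_valid)):
            if arr.shape[0] != n:
                raise FormatError(f"trial {self.trial_id!r}: {name} has {arr.shape[0]} rows, expected {n}")
        if n and (not np.isfinite(self.t).all() or (self.t < 0).any()):
            raise DataError(f"trial {self.trial_id!r}: timestamps must be finite and non-negative")
        i = _first_nonmonotonic(self.t)
        if i >= 0:
            raise DataError(
                f"trial {self.trial_id!r}: timestamps not strictly increasing at sample index {i}"
            )
        for name, xy, valid in (("left", self.left, self.left_valid),
                                ("right", self.right, self.right_valid)):
            if n and not np.isfinite(xy[valid]).all():
                raise DataError(f"trial {self.trial_id!r}: non-finite {name}-eye coordinates marked valid")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    def iter_samples(self) -> Iterator[GazeSample]:
        for i in range(self.n_samples):
            left = tuple(self.left[i]) if self.left_valid[i] else None
            right = tuple(self.right[i]) if self.right_valid[i] else None
            yield GazeSample(float(self.t[i]), left, right)


@dataclass
class CleanTrial:
    """A preprocessed monocular-equivalent gaze point sequence.

    ``t``, ``x``, ``y`` are parallel float arrays; every point derives from
    a sample with at least one valid eye.  Timestamps keep the gaps left by
    removed samples.
    """

    trial_id: str
    subject_id: str
    group: str
    cc: str
    rate_hz: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise FormatError(f"trial {self.trial_id!r}: t/x/y length mismatch")
        if self.t.size and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise DataError(f"trial {self.trial_id!r}: non-finite cleaned coordinates")
        i = _first_nonmonotonic(self.t)
        if i >= 0:
            raise DataError(
                f"trial {self.trial_id!r}: timestamps not strictly increasing at point index {i}"
            )

    @property
    def n_points(self) -> int:
        return int(self.t.size)

    def points(self) -> np.ndarray:
        """Return the points as an ``(n, 3)`` array of ``(t, x, y)`` rows."""
        return np.column_stack([self.t, self.x, self.y])


def clean_trial(trial: GazeTrial) -> CleanTrial:
    """Combine eyes and drop samples where both eyes are invalid.

    When both eyes are valid the point is the arithmetic mean of the two
    eyes' coordinates; with a single valid eye that eye is used directly.
    Timestamps of retained samples are preserved unchanged.

    Raises
    ------
    EmptyTrialError
        If no sample has at least one valid eye.
    """
    keep = trial.left_valid | trial.right_valid
    if not keep.any():
        raise EmptyTrialError(f"trial {trial.trial_id!r}: no sample with a valid eye")
    lv = trial.left_valid[keep]
    rv = trial.right_valid[keep]
    left = trial.left[keep]
    right = trial.right[keep]
    xy = np.where(lv[:, None], left, 0.0) + np.where(rv[:, None], right, 0.0)
    xy = xy / (lv.astype(float) + rv.astype(float))[:, None]
    return CleanTrial(
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        group=trial.group,
        cc=trial.cc,
        rate_hz=trial.rate_hz,
        t=trial.t[keep],
        x=xy[:, 0],
        y=xy[:, 1],
    )


def downsample(clean: CleanTrial, factor: int) -> CleanTrial:
    """Decimate by keeping points at indices 0, factor, 2*factor, ...

    Emulates acquisition with a slower sampler; no averaging is applied,
    since smoothing would erase the very direction changes being scored.
    ``rate_hz`` is divided by ``factor``.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    return CleanTrial(
        trial_id=clean.trial_id,
        subject_id=clean.subject_id,
        group=clean.group,
        cc=clean.cc,
        rate_hz=clean.rate_hz / factor,
        t=clean.t[::factor],
        x=clean.x[::factor],
        y=clean.y[::factor],
    )


def reading_time(clean: CleanTrial) -> float:
    """Total reading time of the trial in seconds (last t minus first t)."""
    if clean.n_points < 2:
        raise EmptyTrialError(
            f"trial {clean.trial_id!r}: need at least 2 points for a reading time"
        )
    return float(clean.t[-1] - clean.t[0]) / 1000.0


def exclude_short(
    trials: Sequence[CleanTrial], min_seconds: float = MIN_READING_SECONDS
) -> list[CleanTrial]:
    """Drop trials with reading time strictly less than ``min_seconds``.

    A trial of exactly ``min_seconds`` is retained.  Trials with fewer than
    two points have no reading time and are dropped as well.
    """
    kept = []
    for tr in trials:
        try:
            rt = reading_time(tr)
        except EmptyTrialError:
            continue
        if rt >= min_seconds:
            kept.append(tr)
    return kept


__all__ = [
    "CC_LABELS", "GROUPS", "FEATURE_NAMES", "MIN_READING_SECONDS",
    "GazeError", "FormatError", "DataError", "EmptyTrialError",
    "GazeSample", "GazeTrial", "CleanTrial",
    "clean_trial", "downsample", "reading_time", "exclude_short",
]
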