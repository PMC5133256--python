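"""Inter-nucleus-interval (INI) series with break-masked missing values.

An annotation sequence with n nuclei yields n − 1 intervals.  Intervals
that span an annotated phrase/sentence break or a part boundary are kept
in place but set to NaN, so the temporal ordering of the series is
preserved for time-series analysis.  The log-ratio view r_s =
log d_{s+1} − log d_s abstracts over speaking rate: scaling all times by
a constant leaves it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from speechtiming.annotations import AnnotationSequence

__all__ = [
    "IniSeries",
    "LogRatioSeries",
    "SeriesError",
    "extract_ini",
    "log_ini",
    "log_ratio",
    "median_ini_ms",
]


class SeriesError(ValueError):
    """Raised for sequences that cannot yield a valid interval series."""


@dataclass
class IniSeries:
    """Interval durations and intensity differences for one language.

    ``d[s]`` is the duration (seconds) between nuclei s and s+1, NaN if
    the interval spans a break; ``i[s]`` the corresponding intensity
    difference (dB).  ``n_phrases`` counts maximal runs of nuclei with
    no break between them (a singleton nucleus still counts as a
    phrase).
    """

    d: np.ndarray
    i: np.ndarray
    n_nuclei: int
    n_phrases: int

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.d.shape != self.i.shape:
            raise SeriesError("d and i must have equal length")
        if len(self.d) != self.n_nuclei - 1:
            raise SeriesError(
                f"expected {self.n_nuclei - 1} intervals for {self.n_nuclei} "
                f"nuclei, got {len(self.d)}"
            )
        present = self.d[np.isfinite(self.d)]
        if np.any(present <= 0):
            raise SeriesError("all present interval durations must be positive")

    @property
    def n_present(self) -> int:
        return int(np.isfinite(self.d).sum())


@dataclass
class LogRatioSeries:
    """Differences of log-INIs, r_s = log d_{s+1} − log d_s (NaN-masked)."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)

    @property
    def n_obs(self) -> int:
        return int(np.isfinite(self.r).sum())

    def present(self) -> np.ndarray:
        return self.r[np.isfinite(self.r)]


def extract_ini(seq: AnnotationSequence) -> IniSeries:
    """Compute the interval series of an annotation sequence.

    Any break event between two nuclei, or a part boundary, masks the
    spanning interval with NaN and starts a new rhythmic phrase.
    Intensity differences are NaN wherever the duration is, or when
    either nucleus lacks an intensity value.
    """
    d: list[float] = []
    i: list[float] = []
    n_phrases = 0
    prev = None  # previous nucleus
    broke = False  # a break event seen since the previous nucleus
    for ev in seq.events:
        if ev.is_break:
            broke = True
            continue
        if prev is None:
            n_phrases += 1
        else:
            if broke or ev.part != prev.part:
                d.append(np.nan)
                i.append(np.nan)
                n_phrases += 1
            else:
                dt = ev.time - prev.time
                if dt <= 0:
                    raise SeriesError(
                        f"nonpositive interval {dt} at t={ev.time} (part {ev.part})"
                    )
                d.append(dt)
                if ev.intensity is None or prev.intensity is None:
                    i.append(np.nan)
                else:
                    i.append(ev.intensity - prev.intensity)
        prev = ev
        broke = False
    n_nuclei = seq.n_nuclei
    if n_nuclei < 2:
        raise SeriesError(f"need at least 2 nuclei, got {n_nuclei}")
    return IniSeries(
        d=np.array(d), i=np.array(i), n_nuclei=n_nuclei, n_phrases=n_phrases
    )


def log_ini(s: IniSeries) -> np.ndarray:
    """Natural log of the durations; NaN (missing) propagates."""
    with np.errstate(invalid="ignore"):
        return np.log(s.d)


def log_ratio(s: IniSeries) -> LogRatioSeries:
    """Log-ratio of adjacent intervals; missing if either neighbour is."""
    y = log_ini(s)
    if len(y) < 2:
        return LogRatioSeries(r=np.empty(0))
    return LogRatioSeries(r=np.diff(y))


def median_ini_ms(s: IniSeries) -> float:
    """Median present duration in milliseconds (linear-interpolation
    quantile convention)."""
    present = s.d[np.isfinite(s.d)]
    if len(present) == 0:
        raise SeriesError("no present intervals")
    return float(np.median(present) * 1000.0)
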