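"""Synthetic annotation sequences with recorded ground truth.

Stands in for the annotated narrative corpus: each generated "language"
is a sequence of syllable-nucleus events grouped into rhythmic phrases
separated by break events, with interval durations drawn from a
controlled process in log space (iid normal log-durations, or an
ARMA/ARIMA process) and a per-nucleus intensity track.  The generator
records everything it drew, so extraction and model-fitting code can be
tested against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from speechtiming.annotations import (
    NUCLEUS,
    PHRASE_BREAK,
    AnnotationSequence,
    NucleusAnnotation,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "ConfigError",
    "generate_language",
    "generate_corpus",
    "default_profile",
]

IID_LOGNORMAL = "iid_lognormal"
ARIMA = "arima"


class ConfigError(ValueError):
    """Raised for inconsistent or non-stationary configurations."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one generated language.

    ``log_sd`` is the standard deviation of the log-durations for the
    iid process; for the ``arima`` process, ``ar``/``ma`` are the
    stationary/invertible lag-polynomial coefficients, ``d_order``
    optionally integrates the series once, and ``innovation_sd`` scales
    the innovations.  ``exog_coef`` couples each log-duration to the
    preceding intensity difference.  The intensity track is
    ``intensity_base`` plus iid noise plus an optional alternating
    stress offset.
    """

    language_iso: str = "syn"
    annotator: str = "GEN"
    n_nuclei: int = 180
    n_phrases: int = 20
    median_ini_ms: float = 200.0
    process: str = IID_LOGNORMAL
    log_sd: float = 0.35
    ar: tuple[float, ...] = ()
    ma: tuple[float, ...] = ()
    d_order: int = 0
    innovation_sd: float = 0.3
    exog_coef: float = 0.0
    intensity_base: float = 70.0
    intensity_sd: float = 3.0
    stress_offset: float = 0.0
    phrase_jitter: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_nuclei < 2:
            raise ConfigError("n_nuclei must be >= 2")
        if not (1 <= self.n_phrases <= self.n_nuclei):
            raise ConfigError("need 1 <= n_phrases <= n_nuclei")
        if self.median_ini_ms <= 0:
            raise ConfigError("median_ini_ms must be positive")
        if self.process not in (IID_LOGNORMAL, ARIMA):
            raise ConfigError(f"unknown process {self.process!r}")
        if self.process == ARIMA:
            if len(self.ar) > 5 or len(self.ma) > 5 or not (0 <= self.d_order <= 1):
                raise ConfigError("arima orders limited to p, q <= 5 and d <= 1")
            _check_stationary_invertible(self.ar, self.ma)


@dataclass
class GroundTruth:
    """Everything the generator drew for one language."""

    config: SyntheticConfig
    log_inis: list[np.ndarray]  # per phrase, after median scaling
    ini_durations: np.ndarray  # length n_nuclei − 1, NaN at phrase joins
    break_times: list[float]
    intensities: np.ndarray = field(default_factory=lambda: np.empty(0))


def _check_stationary_invertible(ar: tuple[float, ...], ma: tuple[float, ...]) -> None:
    # AR polynomial 1 − φ1 z − … − φp z^p must have roots outside the
    # unit circle; MA polynomial 1 + θ1 z + … likewise.
    if ar:
        roots = np.roots(np.r_[-np.array(ar)[::-1], 1.0])
        if np.any(np.abs(roots) <= 1.0 + 1e-10):
            raise ConfigError("AR coefficients are not stationary")
    if ma:
        roots = np.roots(np.r_[np.array(ma)[::-1], 1.0])
        if np.any(np.abs(roots) <= 1.0 + 1e-10):
            raise ConfigError("MA coefficients are not invertible")


def _phrase_sizes(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Split n_nuclei into n_phrases parts, near-equal by default."""
    base = np.full(cfg.n_phrases, cfg.n_nuclei // cfg.n_phrases, dtype=int)
    base[: cfg.n_nuclei % cfg.n_phrases] += 1
    if cfg.phrase_jitter > 0:
        for _ in range(int(cfg.phrase_jitter * cfg.n_phrases)):
            src, dst = rng.integers(0, cfg.n_phrases, size=2)
            if base[src] > 1:
                base[src] -= 1
                base[dst] += 1
    return base


def _log_ini_process(cfg: SyntheticConfig, m: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.process == IID_LOGNORMAL:
        return rng.normal(0.0, cfg.log_sd, size=m)
    burn = 200
    w = rng.normal(0.0, cfg.innovation_sd, size=m + burn)
    ar_poly = np.r_[1.0, -np.array(cfg.ar)] if cfg.ar else np.array([1.0])
    ma_poly = np.r_[1.0, np.array(cfg.ma)] if cfg.ma else np.array([1.0])
    z = lfilter(ma_poly, ar_poly, w)[burn:]
    if cfg.d_order == 1:
        z = np.cumsum(z)
    return z


def generate_language(cfg: SyntheticConfig) -> tuple[AnnotationSequence, GroundTruth]:
    """Generate one language and its ground truth.

    Log-durations come from the configured process, shifted so the
    median duration matches ``median_ini_ms`` (a constant shift in log
    space, preserving the process structure).  Phrase breaks are placed
    strictly between phrases with an inter-phrase gap larger than the
    largest duration.  Identical seeds give identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sizes = _phrase_sizes(cfg, rng)
    m = int(cfg.n_nuclei - cfg.n_phrases)  # total generated intervals

    intensities = rng.normal(cfg.intensity_base, cfg.intensity_sd, size=cfg.n_nuclei)
    if cfg.stress_offset:
        intensities[::2] += cfg.stress_offset

    z = _log_ini_process(cfg, m, rng)
    if cfg.exog_coef and m > 0:
        # couple each interval to the preceding intensity difference,
        # phrase-locally (the first interval of a phrase has none)
        idx = 0
        nuc = 0
        for size in sizes:
            for j in range(size - 1):
                if j > 0:
                    z[idx] += cfg.exog_coef * (intensities[nuc + j] - intensities[nuc + j - 1])
                idx += 1
            nuc += size
    if m > 0:
        raw = np.exp(z)
        factor = (cfg.median_ini_ms / 1000.0) / float(np.median(raw))
        durations = raw * factor
        z = z + np.log(factor)
    else:
        durations = np.empty(0)

    events: list[NucleusAnnotation] = []
    log_inis: list[np.ndarray] = []
    break_times: list[float] = []
    full_d: list[float] = []
    gap = (durations.max() if m > 0 else 0.2) * 1.5 + 0.1
    t = 0.5
    idx = 0
    nuc = 0
    for pi, size in enumerate(sizes):
        phrase_d = durations[idx : idx + size - 1]
        log_inis.append(z[idx : idx + size - 1].copy())
        idx += size - 1
        for j in range(size):
            events.append(
                NucleusAnnotation(
                    part=1, time=t, kind=NUCLEUS, intensity=float(intensities[nuc])
                )
            )
            nuc += 1
            if j < size - 1:
                full_d.append(float(phrase_d[j]))
                t += phrase_d[j]
        if pi < len(sizes) - 1:
            bt = t + gap / 2.0
            events.append(NucleusAnnotation(part=1, time=bt, kind=PHRASE_BREAK))
            break_times.append(bt)
            full_d.append(np.nan)
            t += gap
    seq = AnnotationSequence(cfg.language_iso, cfg.annotator, events)
    truth = GroundTruth(
        config=cfg,
        log_inis=log_inis,
        ini_durations=np.array(full_d),
        break_times=break_times,
        intensities=intensities,
    )
    return seq, truth


def default_profile(seed: int = 0) -> list[SyntheticConfig]:
    """An 18-language profile mirroring the reference corpus table:
    per-language nucleus/phrase counts, median durations, and iid
    log-duration variances chosen so the log-ratio variance matches the
    table (var(r) = 2·var(log d) for iid durations)."""
    from speechtiming.reference import load_reference_table

    df = load_reference_table()
    profile = []
    for k, row in enumerate(df.itertuples(index=False)):
        profile.append(
            SyntheticConfig(
                language_iso=row.iso,
                annotator="GEN",
                n_nuclei=int(row.n_nuclei),
                n_phrases=int(row.n_phrases),
                median_ini_ms=float(row.median_ini_ms),
                process=IID_LOGNORMAL,
                log_sd=float(np.sqrt(row.lr_ini_variance / 2.0)),
                seed=seed + k,
            )
        )
    return profile


def generate_corpus(
    profile: list[SyntheticConfig] | None = None, seed: int = 0
) -> list[AnnotationSequence]:
    """Generate one sequence per config (default: the bundled
    18-language profile)."""
    if profile is None:
        profile = default_profile(seed=seed)
    if not profile:
        raise ConfigError("profile must be nonempty")
    return [generate_language(cfg)[0] for cfg in profile]
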