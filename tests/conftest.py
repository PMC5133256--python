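import numpy as np
import pytest

from speechtiming.annotations import (
    NUCLEUS,
    PHRASE_BREAK,
    AnnotationSequence,
    NucleusAnnotation,
)
from speechtiming.synthetic import SyntheticConfig, generate_language


def make_seq(events, language_iso="tst", annotator="AA"):
    return AnnotationSequence(language_iso, annotator, events)


def nucleus(time, intensity=70.0, part=1):
    return NucleusAnnotation(part=part, time=time, kind=NUCLEUS, intensity=intensity)


def brk(time, kind=PHRASE_BREAK, part=1):
    return NucleusAnnotation(part=part, time=time, kind=kind, intensity=None)


@pytest.fixture
def simple_seq():
    """Three nuclei, no breaks: d = (0.20, 0.25), i = (+2, -3)."""
    return make_seq(
        [nucleus(1.00, 70.0), nucleus(1.20, 72.0), nucleus(1.45, 69.0)]
    )


@pytest.fixture
def broken_seq():
    """Nuclei at (1.0, 1.2, 2.5, 2.7) with a phrase break at 1.8."""
    return make_seq(
        [
            nucleus(1.0, 70.0),
            nucleus(1.2, 71.0),
            brk(1.8),
            nucleus(2.5, 72.0),
            nucleus(2.7, 70.0),
        ]
    )


@pytest.fixture
def synth_language():
    cfg = SyntheticConfig(
        language_iso="syn", n_nuclei=120, n_phrases=10, median_ini_ms=180.0,
        log_sd=0.3, seed=42,
    )
    return generate_language(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
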