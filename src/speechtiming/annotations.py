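"""Reading and writing syllable-nucleus annotations.

Two on-disk dialects are supported:

* Praat TextGrid files (long or short text form) with a point tier
  whose labels are syllable numbers for nuclei and ``/`` or ``//`` for
  phrase and sentence breaks;
* tab-separated ``.out`` files with columns ``part``, ``time``,
  ``mark``, ``intensity`` (one row per annotation event), plus the
  concatenated variant with two extra columns ``language`` and
  ``annotator``.

Times are stored in seconds.  Break rows are events of their own, not
nuclei; their intensity column may be empty.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "NucleusAnnotation",
    "AnnotationSequence",
    "AnnotationError",
    "AnnotationParseError",
    "AnnotationValidationError",
    "read_out_file",
    "write_out_file",
    "read_textgrid",
    "write_textgrid",
    "read_concatenated",
    "write_concatenated",
    "DEFAULT_TIER_NAME",
]

#: Tier name assumed when none is given; the deposited annotations use a
#: single point tier per file, so the default is only a convention.
DEFAULT_TIER_NAME = "nuclei"

NUCLEUS = "nucleus"
PHRASE_BREAK = "phrase_break"
SENTENCE_BREAK = "sentence_break"

_BREAK_KINDS = frozenset({PHRASE_BREAK, SENTENCE_BREAK})
_MARK_TO_KIND = {"/": PHRASE_BREAK, "//": SENTENCE_BREAK}
_KIND_TO_MARK = {NUCLEUS: "", PHRASE_BREAK: "/", SENTENCE_BREAK: "//"}


class AnnotationError(Exception):
    """Base class for annotation I/O failures."""


class AnnotationParseError(AnnotationError):
    """A file could not be parsed; the message names the offending line."""


class AnnotationValidationError(AnnotationError):
    """Parsed events violate an ordering or content invariant."""


@dataclass(frozen=True)
class NucleusAnnotation:
    """One annotated event: a syllable nucleus or a break marker.

    Parameters
    ----------
    part : int
        1-based index of the audio file within a multi-part narrative.
    time : float
        Seconds from the start of that part.
    kind : str
        ``"nucleus"``, ``"phrase_break"`` or ``"sentence_break"``.
    intensity : float or None
        Intensity in dB at the annotated point.  Required semantics only
        for nuclei read from ``.out`` files; TextGrid annotations carry
        no intensity and leave this ``None``.
    """

    part: int
    time: float
    kind: str = NUCLEUS
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.part < 1:
            raise AnnotationValidationError(f"part must be >= 1, got {self.part}")
        if self.time < 0:
            raise AnnotationValidationError(f"time must be >= 0, got {self.time}")
        if self.kind not in _KIND_TO_MARK:
            raise AnnotationValidationError(f"unknown event kind {self.kind!r}")

    @property
    def is_nucleus(self) -> bool:
        return self.kind == NUCLEUS

    @property
    def is_break(self) -> bool:
        return self.kind in _BREAK_KINDS


@dataclass
class AnnotationSequence:
    """Ordered annotation events for one language/annotator pair."""

    language_iso: str
    annotator: str
    events: list[NucleusAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check (part, time) ordering: parts non-decreasing, times
        strictly increasing within a part."""
        prev: NucleusAnnotation | None = None
        for idx, ev in enumerate(self.events):
            if prev is not None:
                if ev.part < prev.part:
                    raise AnnotationValidationError(
                        f"event {idx}: part {ev.part} after part {prev.part}"
                    )
                if ev.part == prev.part and ev.time <= prev.time:
                    raise AnnotationValidationError(
                        f"event {idx}: time {ev.time} not after {prev.time} "
                        f"in part {ev.part}"
                    )
            prev = ev

    @property
    def nuclei(self) -> list[NucleusAnnotation]:
        return [ev for ev in self.events if ev.is_nucleus]

    @property
    def n_nuclei(self) -> int:
        return sum(1 for ev in self.events if ev.is_nucleus)

    def nucleus_times(self) -> list[float]:
        return [ev.time for ev in self.events if ev.is_nucleus]

    def parts(self) -> list[int]:
        return sorted({ev.part for ev in self.events})

    def with_identity(self, language_iso: str, annotator: str) -> "AnnotationSequence":
        return AnnotationSequence(language_iso, annotator, list(self.events))


# ---------------------------------------------------------------------------
# .out dialect
# ---------------------------------------------------------------------------


def _format_float(x: float) -> str:
    # repr round-trips exactly through float(); avoid "1.0" for ints in
    # the part column only (handled separately).
    return repr(float(x))


def _looks_like_header(fields: Sequence[str]) -> bool:
    try:
        float(fields[1])
    except ValueError:
        return True
    return False


def _parse_out_row(
    fields: Sequence[str], lineno: int, path: Path
) -> NucleusAnnotation:
    part_s, time_s, mark, intensity_s = fields
    try:
        part = int(part_s)
    except ValueError as exc:
        raise AnnotationParseError(
            f"{path}:{lineno}: non-integer part {part_s!r}"
        ) from exc
    try:
        time = float(time_s)
    except ValueError as exc:
        raise AnnotationParseError(
            f"{path}:{lineno}: non-numeric time {time_s!r}"
        ) from exc
    mark = mark.strip()
    if mark and mark not in _MARK_TO_KIND:
        raise AnnotationParseError(
            f"{path}:{lineno}: unknown mark {mark!r} (expected empty, '/' or '//')"
        )
    kind = _MARK_TO_KIND.get(mark, NUCLEUS)
    intensity_s = intensity_s.strip()
    intensity = float(intensity_s) if intensity_s else None
    return NucleusAnnotation(part=part, time=time, kind=kind, intensity=intensity)


def read_out_file(
    path: str | Path, language_iso: str = "und", annotator: str = "NA"
) -> AnnotationSequence:
    """Read a 4-column tab-separated annotation file.

    Columns are ``part``, ``time``, ``mark``, ``intensity``.  An
    optional header row (detected by a non-numeric ``time`` field on the
    first line) is skipped.  Empty mark means nucleus; ``/`` and ``//``
    mean phrase and sentence break.
    """
    path = Path(path)
    events: list[NucleusAnnotation] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if lineno == 1 and _looks_like_header(fields):
                continue
            events.append(_parse_out_row(fields, lineno, path))
    try:
        return AnnotationSequence(language_iso, annotator, events)
    except AnnotationValidationError as exc:
        raise AnnotationValidationError(f"{path}: {exc}") from exc


def _out_row(ev: NucleusAnnotation) -> list[str]:
    return [
        str(ev.part),
        _format_float(ev.time),
        _KIND_TO_MARK[ev.kind],
        "" if ev.intensity is None else _format_float(ev.intensity),
    ]


def write_out_file(seq: AnnotationSequence, path: str | Path) -> None:
    """Write a 4-column ``.out`` file (no header, LF line endings)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ev in seq.events:
            fh.write("\t".join(_out_row(ev)) + "\n")


def read_concatenated(path: str | Path) -> list[AnnotationSequence]:
    """Read a 6-column concatenated file into per-(language, annotator)
    sequences, preserving first-appearance order of the groups."""
    path = Path(path)
    groups: dict[tuple[str, str], list[NucleusAnnotation]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if lineno == 1 and _looks_like_header(fields):
                continue
            ev = _parse_out_row(fields[:4], lineno, path)
            key = (fields[4].strip(), fields[5].strip())
            groups.setdefault(key, []).append(ev)
    return [
        AnnotationSequence(language_iso=lang, annotator=ann, events=evs)
        for (lang, ann), evs in groups.items()
    ]


def write_concatenated(seqs: Iterable[AnnotationSequence], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for seq in seqs:
            for ev in seq.events:
                fh.write(
                    "\t".join(_out_row(ev) + [seq.language_iso, seq.annotator]) + "\n"
                )


# ---------------------------------------------------------------------------
# Praat TextGrid (text form)
# ---------------------------------------------------------------------------


def _unquote(s: str) -> str:
    s = s.strip()
    if s.startswith('"') and s.endswith('"') and len(s) >= 2:
        s = s[1:-1]
    return s.replace('""', '"')


def _textgrid_tiers(text: str, path: Path) -> list[tuple[str, str, list[tuple[float, str]]]]:
    """Return (class, name, points) for every tier.

    Interval tiers are returned with an empty point list; callers decide
    whether that is an error.  Handles both the long form (``key = value``
    lines) and the short form (bare values).
    """
    if "ooTextFile" not in text:
        raise AnnotationParseError(f"{path}: not a Praat text file")
    if re.search(r"File type\s*=", text):
        return _parse_long_form(text)
    return _parse_short_form(text, path)


def _parse_long_form(text: str) -> list[tuple[str, str, list[tuple[float, str]]]]:
    tiers: list[tuple[str, str, list[tuple[float, str]]]] = []
    cls = name = None
    points: list[tuple[float, str]] = []
    pending_number: float | None = None
    for line in text.splitlines():
        m = re.match(r'\s*class\s*=\s*"(.*)"\s*$', line)
        if m:
            if cls is not None:
                tiers.append((cls, name or "", points))
            cls, name, points, pending_number = m.group(1), None, [], None
            continue
        m = re.match(r'\s*name\s*=\s*"(.*)"\s*$', line)
        if m and cls is not None and name is None:
            name = _unquote(f'"{m.group(1)}"')
            continue
        m = re.match(r"\s*(?:number|time)\s*=\s*([-\d.eE+]+)\s*$", line)
        if m:
            pending_number = float(m.group(1))
            continue
        m = re.match(r'\s*(?:mark|text)\s*=\s*"(.*)"\s*$', line)
        if m and pending_number is not None:
            points.append((pending_number, _unquote(f'"{m.group(1)}"')))
            pending_number = None
    if cls is not None:
        tiers.append((cls, name or "", points))
    return tiers


def _parse_short_form(
    text: str, path: Path
) -> list[tuple[str, str, list[tuple[float, str]]]]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    # header: "ooTextFile", "TextGrid", xmin, xmax, <exists>, ntiers
    try:
        ntiers = int(lines[5])
        pos = 6
    except (IndexError, ValueError) as exc:
        raise AnnotationParseError(f"{path}: malformed short TextGrid header") from exc
    tiers: list[tuple[str, str, list[tuple[float, str]]]] = []
    for _ in range(ntiers):
        try:
            cls = _unquote(lines[pos])
            name = _unquote(lines[pos + 1])
            n = int(lines[pos + 4])
            pos += 5
            points: list[tuple[float, str]] = []
            if cls == "TextTier":
                for _ in range(n):
                    points.append((float(lines[pos]), _unquote(lines[pos + 1])))
                    pos += 2
            elif cls == "IntervalTier":
                pos += 3 * n  # xmin, xmax, label per interval
            else:
                raise AnnotationParseError(f"{path}: unknown tier class {cls!r}")
            tiers.append((cls, name, points))
        except (IndexError, ValueError) as exc:
            raise AnnotationParseError(f"{path}: truncated short TextGrid") from exc
    return tiers


def read_textgrid(
    path: str | Path,
    tier_name: str = DEFAULT_TIER_NAME,
    language_iso: str = "und",
    annotator: str = "NA",
    part: int = 1,
) -> AnnotationSequence:
    """Read one point tier of a TextGrid into an annotation sequence.

    Point labels ``/`` and ``//`` map to phrase and sentence breaks; any
    other label (typically the syllable number) maps to a nucleus.
    Intensities are not stored in TextGrids and are left ``None``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    tiers = _textgrid_tiers(text, path)
    available = [name for _, name, _ in tiers]
    match = [t for t in tiers if t[1] == tier_name]
    if not match:
        raise AnnotationParseError(
            f"{path}: no tier named {tier_name!r}; available tiers: {available}"
        )
    cls, _, points = match[0]
    if cls != "TextTier":
        raise AnnotationParseError(
            f"{path}: tier {tier_name!r} is an interval tier; "
            "only point tiers are supported"
        )
    events = [
        NucleusAnnotation(
            part=part,
            time=t,
            kind=_MARK_TO_KIND.get(label.strip(), NUCLEUS),
            intensity=None,
        )
        for t, label in points
    ]
    return AnnotationSequence(language_iso, annotator, events)


def write_textgrid(
    seq: AnnotationSequence, path: str | Path, tier_name: str = DEFAULT_TIER_NAME
) -> None:
    """Write a single-part sequence as a long-form TextGrid point tier.

    Nuclei are labeled with their 1-based syllable number, breaks with
    ``/`` or ``//``.  Multi-part sequences must be written one part per
    file (a TextGrid has a single time axis).
    """
    if len(seq.parts()) > 1:
        raise AnnotationValidationError(
            "write_textgrid supports single-part sequences; "
            "write one TextGrid per part"
        )
    path = Path(path)
    xmax = max((ev.time for ev in seq.events), default=0.0) + 1.0
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0 ",
        f"xmax = {xmax} ",
        "tiers? <exists> ",
        "size = 1 ",
        "item []: ",
        "    item [1]:",
        '        class = "TextTier" ',
        f'        name = "{tier_name}" ',
        "        xmin = 0 ",
        f"        xmax = {xmax} ",
        f"        points: size = {len(seq.events)} ",
    ]
    syllable = 0
    for i, ev in enumerate(seq.events, start=1):
        if ev.is_nucleus:
            syllable += 1
            label = str(syllable)
        else:
            label = _KIND_TO_MARK[ev.kind]
        lines.append(f"        points [{i}]:")
        lines.append(f"            number = {_format_float(ev.time)} ")
        lines.append(f'            mark = "{label}" ')
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
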