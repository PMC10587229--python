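"""Light/dark exposure protocols and their string grammar.

Experimental exposure sequences are written as dash-separated tokens such as
``"5HL-10D-5HL"``: each token is a duration in minutes followed by the light
level (``HL`` for high light, ``D`` for darkness).  An optional suffix
``x<n>`` repeats the whole sequence, e.g. ``"2HL-2D x5"`` is five cycles of
2 min high light / 2 min dark.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, Tuple

__all__ = [
    "LightLevel",
    "LightProtocol",
    "ProtocolParseError",
    "parse_protocol",
    "format_protocol",
]


class LightLevel(Enum):
    """Piecewise-constant actinic light level."""

    HIGH = "HL"
    DARK = "D"


class ProtocolParseError(ValueError):
    """Raised when a protocol string does not conform to the grammar."""


@dataclass(frozen=True)
class LightProtocol:
    """An ordered sequence of constant-light phases.

    Parameters
    ----------
    phases
        Ordered ``(level, duration_min)`` pairs; durations are strictly
        positive, finite minutes.
    label
        Free-text name, by default the canonical protocol string.
    """

    phases: Tuple[Tuple[LightLevel, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        phases = tuple((LightLevel(lvl), float(dur)) for lvl, dur in self.phases)
        if not phases:
            raise ValueError("protocol must contain at least one phase")
        for lvl, dur in phases:
            if not (dur > 0.0 and math.isfinite(dur)):
                raise ValueError(f"phase duration must be positive and finite, got {dur!r}")
        object.__setattr__(self, "phases", phases)
        if not self.label:
            object.__setattr__(self, "label", format_protocol(self))

    @property
    def total_duration(self) -> float:
        """Total protocol duration in minutes."""
        return float(sum(dur for _, dur in self.phases))

    @property
    def boundaries(self) -> Tuple[float, ...]:
        """Cumulative phase end times (minutes), one per phase."""
        out, t = [], 0.0
        for _, dur in self.phases:
            t += dur
            out.append(t)
        return tuple(out)

    def level_at(self, t: float) -> LightLevel:
        """Light level at time ``t`` (phase boundaries belong to the later phase)."""
        if t < 0 or t > self.total_duration:
            raise ValueError(f"time {t} outside protocol [0, {self.total_duration}]")
        acc = 0.0
        for lvl, dur in self.phases:
            acc += dur
            if t < acc:
                return lvl
        return self.phases[-1][0]

    @classmethod
    def from_string(cls, s: str) -> "LightProtocol":
        return parse_protocol(s)

    def __str__(self) -> str:
        return format_protocol(self)


_TOKEN_RE = re.compile(r"^(\d+(?:\.\d+)?)(HL|D)$", re.IGNORECASE)
_REPEAT_RE = re.compile(r"^x(\d+)$", re.IGNORECASE)


def parse_protocol(s: str) -> LightProtocol:
    """Parse a protocol string like ``"5HL-10D-5HL"`` or ``"2HL-2D x5"``.

    Whitespace around tokens is ignored, so the typographic form
    ``"5 HL- 10 D- 5 HL"`` also parses.

    Raises
    ------
    ProtocolParseError
        On an empty string, an unknown token, or a non-positive duration;
        the message names the offending token.
    """
    if not isinstance(s, str) or not s.strip():
        raise ProtocolParseError("empty protocol string")

    text = s.strip()
    repeat = 1
    m = re.search(r"[xX]\s*(\d+)\s*$", text)
    if m is not None and "-" not in text[m.start():]:
        repeat = int(m.group(1))
        if repeat < 1:
            raise ProtocolParseError(f"repetition count must be >= 1, got token {text[m.start():]!r}")
        text = text[: m.start()].strip()
    if not text:
        raise ProtocolParseError("no phases before repetition suffix")

    phases = []
    for raw in text.split("-"):
        token = raw.replace(" ", "").replace("\t", "")
        if not token:
            raise ProtocolParseError(f"empty token in {s!r}")
        m = _TOKEN_RE.match(token)
        if m is None:
            raise ProtocolParseError(f"unrecognized protocol token {raw.strip()!r}")
        dur = float(m.group(1))
        if dur <= 0:
            raise ProtocolParseError(f"non-positive duration in token {raw.strip()!r}")
        level = LightLevel.HIGH if m.group(2).upper() == "HL" else LightLevel.DARK
        phases.append((level, dur))

    return LightProtocol(phases=tuple(phases * repeat), label="")


def _fmt_minutes(x: float) -> str:
    return f"{x:g}"


def format_protocol(protocol: LightProtocol) -> str:
    """Canonical string form, inverse of :func:`parse_protocol`."""
    return "-".join(f"{_fmt_minutes(dur)}{lvl.value}" for lvl, dur in protocol.phases)
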