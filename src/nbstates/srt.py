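"""Minimal SubRip (.srt) reading and writing.

Only the standard dialect is supported: numbered cues, a
``HH:MM:SS,mmm --> HH:MM:SS,mmm`` timing line, one or more text lines,
cues separated by blank lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_TIME_RE = re.compile(r"^(\d{2,}):(\d{2}):(\d{2})[,.](\d{3})$")


@dataclass(frozen=True)
class Cue:
    index: int
    start_seconds: float
    end_seconds: float
    text: str


class SRTParseError(ValueError):
    pass


def _parse_timestamp(stamp: str, cue_index: int) -> float:
    m = _TIME_RE.match(stamp.strip())
    if m is None:
        raise SRTParseError(f"malformed timestamp {stamp!r} in cue {cue_index}")
    h, mi, s, ms = (int(g) for g in m.groups())
    return h * 3600.0 + mi * 60.0 + s + ms / 1000.0


def _format_timestamp(seconds: float) -> str:
    ms = int(round(seconds * 1000.0))
    h, rem = divmod(ms, 3_600_000)
    mi, rem = divmod(rem, 60_000)
    s, ms = divmod(rem, 1000)
    return f"{h:02d}:{mi:02d}:{s:02d},{ms:03d}"


def parse_srt(text: str) -> list[Cue]:
    """Parse SubRip text into a list of cues, in file order."""
    cues: list[Cue] = []
    blocks = re.split(r"\n\s*\n", text.strip("﻿ \n\r\t"))
    for block in blocks:
        lines = [ln.rstrip("\r") for ln in block.splitlines() if ln.strip()]
        if not lines:
            continue
        cue_index = len(cues) + 1
        # the numeric counter line is optional in the wild; tolerate its absence
        if "-->" not in lines[0]:
            lines = lines[1:]
        if not lines or "-->" not in lines[0]:
            raise SRTParseError(f"cue {cue_index} has no timing line")
        try:
            start_raw, end_raw = lines[0].split("-->")
        except ValueError as exc:  # pragma: no cover - split never over-yields
            raise SRTParseError(f"bad timing line in cue {cue_index}") from exc
        start = _parse_timestamp(start_raw, cue_index)
        end = _parse_timestamp(end_raw, cue_index)
        if end < start:
            raise SRTParseError(f"cue {cue_index} ends before it starts")
        cues.append(Cue(cue_index, start, end, "\n".join(lines[1:])))
    return cues


def format_srt(cues: list[Cue]) -> str:
    """Serialize cues to SubRip text (re-numbered sequentially)."""
    blocks = []
    for i, cue in enumerate(cues, start=1):
        blocks.append(
            f"{i}\n{_format_timestamp(cue.start_seconds)} --> "
            f"{_format_timestamp(cue.end_seconds)}\n{cue.text}"
        )
    return "\n\n".join(blocks) + "\n"
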