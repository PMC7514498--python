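"""Minimal Praat TextGrid interval-tier reader and writer.

Supports the long ("ooTextFile") text format with interval tiers only,
which is what forced aligners emit.  Point tiers are ignored.
"""

from __future__ import annotations

import re
from pathlib import Path

from .exceptions import ParseError

_NUM = re.compile(r'=\s*([-+0-9.eE]+)')
_STR = re.compile(r'=\s*"(.*)"\s*$')


def _num(line: str, lineno: int) -> float:
    m = _NUM.search(line)
    if not m:
        raise ParseError(f"line {lineno}: expected a number in {line!r}")
    return float(m.group(1))


def _string(line: str, lineno: int) -> str:
    m = _STR.search(line)
    if m is None:
        raise ParseError(f"line {lineno}: expected a quoted string in {line!r}")
    return m.group(1).replace('""', '"')


def read_textgrid(path) -> dict[str, list[tuple[float, float, str]]]:
    """Read interval tiers from a long-format TextGrid.

    Returns a mapping ``tier name -> [(xmin, xmax, text), ...]`` with
    intervals in file order.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or "ooTextFile" not in lines[0]:
        raise ParseError(f"{path}: line 1: not an ooTextFile TextGrid header")
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("class") and "IntervalTier" in line:
            # next lines: name, xmin, xmax, intervals: size
            name = None
            size = None
            j = i + 1
            while j < n and (name is None or size is None):
                s = lines[j].strip()
                if s.startswith("name"):
                    name = _string(lines[j], j + 1)
                elif "intervals: size" in s or s.startswith("intervals: size"):
                    size = int(_num(lines[j], j + 1))
                elif s.startswith("intervals ["):
                    break
                j += 1
            if name is None:
                raise ParseError(f"{path}: tier at line {i + 1} has no name")
            intervals = []
            while j < n:
                s = lines[j].strip()
                if s.startswith("intervals ["):
                    xmin = _num(lines[j + 1], j + 2)
                    xmax = _num(lines[j + 2], j + 3)
                    text = _string(lines[j + 3], j + 4)
                    intervals.append((xmin, xmax, text))
                    j += 4
                elif s.startswith("item [") or (s.startswith("class") and "Tier" in s):
                    break
                else:
                    j += 1
            if size is not None and len(intervals) != size:
                raise ParseError(
                    f"{path}: tier {name!r}: declared {size} intervals, found {len(intervals)}"
                )
            tiers[name] = intervals
            i = j
        else:
            i += 1
    if not tiers:
        raise ParseError(f"{path}: no interval tiers found")
    return tiers


def write_textgrid(tiers: dict[str, list[tuple[float, float, str]]], path) -> None:
    """Write interval tiers as a long-format TextGrid."""
    xmin = min((iv[0] for ivs in tiers.values() for iv in ivs), default=0.0)
    xmax = max((iv[1] for ivs in tiers.values() for iv in ivs), default=0.0)
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin:.6f}",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for t, (name, intervals) in enumerate(tiers.items(), start=1):
        t_min = min((iv[0] for iv in intervals), default=xmin)
        t_max = max((iv[1] for iv in intervals), default=xmax)
        out += [
            f"    item [{t}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            f"        xmin = {t_min:.6f}",
            f"        xmax = {t_max:.6f}",
            f"        intervals: size = {len(intervals)}",
        ]
        for k, (a, b, text) in enumerate(intervals, start=1):
            out += [
                f"        intervals [{k}]:",
                f"            xmin = {a:.6f}",
                f"            xmax = {b:.6f}",
                f'            text = "{text.replace(chr(34), chr(34) * 2)}"',
            ]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
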