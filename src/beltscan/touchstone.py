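"""Touchstone v1 file I/O for 8-port S-parameter sweeps.

Writes .s8p files with an explicit option line (``# GHZ S RI R 50``) and
full-precision real/imaginary pairs so round trips are lossless to well
below 1e-9 relative. The reader accepts RI and MA encodings and Hz / kHz /
MHz / GHz unit tokens; anything else is rejected loudly. The sweep kind
(body / empty / calibrated) travels in a comment line so a file round trip
preserves it.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .errors import DimensionError, ParseError, ValidationError
from .types import FrequencyGrid, SMatrixSweep, SweepKind

_UNIT = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}


def _ports_from_suffix(path: Path) -> int | None:
    suf = path.suffix.lower()
    if suf.startswith(".s") and suf.endswith("p"):
        mid = suf[2:-1]
        if mid.isdigit():
            return int(mid)
    return None


def write_sweep(sweep: SMatrixSweep, path: str | os.PathLike) -> Path:
    """Write a sweep as Touchstone v1 (.s8p), frequencies in GHz, RI pairs."""
    path = Path(path)
    n = sweep.n_ports
    f_ghz = sweep.grid.frequencies / 1e9
    lines = [
        f"! beltscan S-parameter sweep, {n} ports, {sweep.grid.n_points} points",
        f"! kind: {sweep.kind.value}",
        "# GHZ S RI R 50",
    ]
    for q, fq in enumerate(f_ghz):
        for i in range(n):
            row = sweep.values[q, i]
            # Touchstone v1: at most 4 complex pairs per line
            for start in range(0, n, 4):
                chunk = row[start : start + 4]
                nums = " ".join(f"{v.real:.17e} {v.imag:.17e}" for v in chunk)
                if i == 0 and start == 0:
                    lines.append(f"{fq:.12f} {nums}")
                else:
                    lines.append(f"  {nums}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_sweep(path: str | os.PathLike, n_ports: int = 8) -> SMatrixSweep:
    """Read a Touchstone sweep; the port count must equal ``n_ports``.

    Raises :class:`DimensionError` if the file's port count differs and
    :class:`ParseError` (naming the offending line) on malformed content.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    file_ports = _ports_from_suffix(path)
    if file_ports is not None and file_ports != n_ports:
        raise DimensionError(
            f"{path.name}: {file_ports}-port file, expected {n_ports} ports"
        )

    unit = 1e9
    fmt = "RI"
    kind = SweepKind.BODY
    tokens: list[float] = []
    option_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)
            if len(line) > 1 and "kind:" in line[1]:
                k = line[1].split("kind:", 1)[1].strip()
                try:
                    kind = SweepKind(k)
                except ValueError:
                    pass
            text = line[0].strip()
            if not text:
                continue
            if text.startswith("#"):
                parts = text[1:].upper().split()
                for p in parts:
                    if p in _UNIT:
                        unit = _UNIT[p]
                    elif p in ("RI", "MA", "DB"):
                        fmt = p
                if "S" not in parts:
                    raise ParseError(f"{path.name}:{lineno}: not an S-parameter file")
                if fmt == "DB":
                    raise ParseError(f"{path.name}:{lineno}: DB encoding unsupported")
                option_seen = True
                continue
            try:
                tokens.extend(float(t) for t in text.split())
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
    if not option_seen:
        raise ParseError(f"{path.name}: missing '#' option line")

    per_freq = 1 + 2 * n_ports * n_ports
    if len(tokens) == 0 or len(tokens) % per_freq != 0:
        raise DimensionError(
            f"{path.name}: token count {len(tokens)} is not a multiple of "
            f"{per_freq} (1 frequency + {n_ports}x{n_ports} complex pairs)"
        )
    data = np.asarray(tokens, dtype=float).reshape(-1, per_freq)
    freqs = data[:, 0] * unit
    if not np.all(np.diff(freqs) > 0):
        raise ParseError(f"{path.name}: frequencies are not strictly increasing")
    pairs = data[:, 1:].reshape(-1, n_ports, n_ports, 2)
    if fmt == "RI":
        values = pairs[..., 0] + 1j * pairs[..., 1]
    else:  # MA: magnitude, angle in degrees
        values = pairs[..., 0] * np.exp(1j * np.deg2rad(pairs[..., 1]))

    grid = FrequencyGrid(float(freqs[0]), float(freqs[-1]), len(freqs))
    if not np.allclose(freqs, grid.frequencies, rtol=0, atol=1e-3):
        raise ValidationError(f"{path.name}: frequency grid is not uniform")
    return SMatrixSweep(grid=grid, values=values, kind=kind)
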