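"""Fixed-column GRO coordinate file reading and writing.

Single frames and concatenated multi-frame GRO trajectories are
supported.  Velocities, if present, are ignored on read.  Atom and
residue indices wrap modulo 100000 on write, per the format's
five-column field width.

Leaflet tags are not part of the GRO format; they are carried in the
title line as a compact ``leaflets=u15,l12,...`` run-length annotation
so that synthetic builds round-trip losslessly through disk.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence

import numpy as np

from .core import BeadConfiguration

__all__ = ["GroParseError", "read_gro", "read_gro_frames", "write_gro", "write_gro_frames"]

_TAG_CODE = {"upper": "u", "lower": "l", "none": "n"}
_CODE_TAG = {v: k for k, v in _TAG_CODE.items()}


class GroParseError(ValueError):
    """Raised when a GRO file does not conform to the fixed-column layout."""


def _encode_leaflets(tags: np.ndarray) -> str:
    runs: List[str] = []
    prev, count = None, 0
    for t in tags:
        if t == prev:
            count += 1
        else:
            if prev is not None:
                runs.append(f"{_TAG_CODE[prev]}{count}")
            prev, count = t, 1
    if prev is not None:
        runs.append(f"{_TAG_CODE[prev]}{count}")
    return ",".join(runs)


def _decode_leaflets(spec: str, n: int) -> np.ndarray:
    tags: List[str] = []
    for run in spec.split(","):
        m = re.fullmatch(r"([uln])(\d+)", run)
        if m is None:
            raise GroParseError(f"bad leaflet annotation run {run!r}")
        tags.extend([_CODE_TAG[m.group(1)]] * int(m.group(2)))
    if len(tags) != n:
        raise GroParseError("leaflet annotation length does not match atom count")
    return np.asarray(tags, dtype=object)


def _parse_frame(lines: Sequence[str], start: int, frame_index: int) -> tuple[BeadConfiguration, int]:
    if start >= len(lines):
        raise GroParseError(f"frame {frame_index}: unexpected end of file at line {start + 1}")
    title = lines[start].rstrip("\n")
    if start + 1 >= len(lines):
        raise GroParseError(f"frame {frame_index}: missing atom-count line at line {start + 2}")
    try:
        n_atoms = int(lines[start + 1].strip())
    except ValueError as exc:
        raise GroParseError(
            f"frame {frame_index}: line {start + 2}: atom count is not an integer"
        ) from exc
    atom_first = start + 2
    box_line_idx = atom_first + n_atoms
    if box_line_idx >= len(lines):
        raise GroParseError(
            f"frame {frame_index}: truncated frame, expected {n_atoms} atom lines "
            f"plus a box line after line {atom_first}"
        )
    names = np.empty(n_atoms, dtype=object)
    resnames = np.empty(n_atoms, dtype=object)
    resids = np.empty(n_atoms, dtype=np.int64)
    positions = np.empty((n_atoms, 3), dtype=np.float64)
    for i in range(n_atoms):
        line = lines[atom_first + i].rstrip("\n")
        lineno = atom_first + i + 1
        if len(line) < 44:
            raise GroParseError(f"line {lineno}: atom line shorter than 44 columns")
        try:
            resids[i] = int(line[0:5])
            resnames[i] = line[5:10].strip()
            names[i] = line[10:15].strip()
            positions[i, 0] = float(line[20:28])
            positions[i, 1] = float(line[28:36])
            positions[i, 2] = float(line[36:44])
        except ValueError as exc:
            raise GroParseError(f"line {lineno}: malformed atom line: {line!r}") from exc
    box_fields = lines[box_line_idx].split()
    if len(box_fields) < 3:
        raise GroParseError(
            f"frame {frame_index}: line {box_line_idx + 1}: missing or short box line"
        )
    try:
        box = np.array([float(v) for v in box_fields[:3]], dtype=np.float64)
    except ValueError as exc:
        raise GroParseError(f"frame {frame_index}: malformed box line") from exc

    leaflet_tags = None
    m = re.search(r"leaflets=([uln\d,]+)", title)
    if m is not None:
        leaflet_tags = _decode_leaflets(m.group(1), n_atoms)
    config = BeadConfiguration(
        names=names,
        residue_names=resnames,
        residue_ids=resids,
        positions=positions,
        box=box,
        leaflet_tags=leaflet_tags,
    )
    return config, box_line_idx + 1


def read_gro_frames(path: str | Path) -> List[BeadConfiguration]:
    """Read all frames of a (possibly multi-frame) GRO file."""
    lines = Path(path).read_text().splitlines()
    frames: List[BeadConfiguration] = []
    cursor = 0
    while cursor < len(lines) and lines[cursor].strip() != "":
        frame, cursor = _parse_frame(lines, cursor, frame_index=len(frames))
        frames.append(frame)
    if not frames:
        raise GroParseError(f"{path}: no frames found")
    return frames


def read_gro(path: str | Path) -> BeadConfiguration:
    """Read the first frame of a GRO file."""
    return read_gro_frames(path)[0]


def _format_frame(config: BeadConfiguration, title: str) -> str:
    if not np.all(np.isfinite(config.positions)):
        raise ValueError("refusing to write non-finite positions")
    full_title = f"{title} leaflets={_encode_leaflets(config.leaflet_tags)}"
    out = [full_title, f"{config.n_beads:5d}"]
    for i in range(config.n_beads):
        resid = int(config.residue_ids[i]) % 100000
        atomno = (i + 1) % 100000
        x, y, z = config.positions[i]
        out.append(
            f"{resid:5d}{str(config.residue_names[i])[:5]:<5s}"
            f"{str(config.names[i])[:5]:>5s}{atomno:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    out.append(f"{config.box[0]:10.5f}{config.box[1]:10.5f}{config.box[2]:10.5f}")
    return "\n".join(out) + "\n"


def write_gro(config: BeadConfiguration, path: str | Path, title: str = "xipore frame") -> None:
    """Write one frame as fixed-column GRO (nm units, box on the last line)."""
    Path(path).write_text(_format_frame(config, title))


def write_gro_frames(
    frames: Iterable[BeadConfiguration], path: str | Path, title: str = "xipore frame"
) -> None:
    """Write frames back-to-back as a multi-frame GRO trajectory."""
    with open(path, "w") as fh:
        for k, frame in enumerate(frames):
            fh.write(_format_frame(frame, f"{title} t={k}"))
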