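"""Extended-XYZ reading and writing.

Supports the common dialect: the comment line carries whitespace-separated
``key=value`` pairs, with ``Lattice="ax ay az bx by bz cx cy cz"`` (only
orthorhombic lattices are accepted) and a ``Properties`` descriptor of the
per-atom columns.  Recognized per-atom fields are ``species`` (S), ``pos``
(R:3) and optional ``masses`` (R:1); unknown trailing columns are ignored
on read and never written.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import MolecularConfiguration

_KV_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


class XYZParseError(ValueError):
    pass


def _parse_comment(comment: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(comment)}


def _parse_lattice(text: str, lineno: int) -> np.ndarray:
    vals = [float(v) for v in text.split()]
    if len(vals) != 9:
        raise XYZParseError(f"line {lineno}: Lattice needs 9 numbers, got {len(vals)}")
    mat = np.array(vals).reshape(3, 3)
    off = mat - np.diag(np.diag(mat))
    if np.any(np.abs(off) > 1e-10):
        raise XYZParseError(f"line {lineno}: only orthorhombic lattices are supported")
    diag = np.diag(mat)
    if np.any(diag <= 0):
        raise XYZParseError(f"line {lineno}: box lengths must be positive")
    return diag.copy()


def _parse_properties(text: str) -> list[tuple[str, str, int]]:
    toks = text.split(":")
    if len(toks) % 3 != 0:
        raise XYZParseError(f"malformed Properties string {text!r}")
    return [(toks[i], toks[i + 1], int(toks[i + 2])) for i in range(0, len(toks), 3)]


def read_xyz(path: str | Path) -> list[MolecularConfiguration]:
    """Read all frames of an (extended-)XYZ file."""
    lines = Path(path).read_text().splitlines()
    frames: list[MolecularConfiguration] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(f"line {i + 1}: expected atom count, got {lines[i]!r}")
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            pass
        if i + 1 + natoms > len(lines):
            raise XYZParseError(f"line {i + 1}: frame truncated ({natoms} atoms declared)")
        meta = _parse_comment(lines[i + 1])
        cell = None
        if "Lattice" in meta:
            cell = _parse_lattice(meta["Lattice"], i + 2)
        props = _parse_properties(meta.get("Properties", "species:S:1:pos:R:3"))
        # column layout
        col = 0
        layout: dict[str, tuple[int, int]] = {}
        for name, _kind, width in props:
            layout[name] = (col, width)
            col += width
        if "species" not in layout or "pos" not in layout:
            raise XYZParseError(f"line {i + 2}: Properties must include species and pos")
        elements: list[str] = []
        positions = np.empty((natoms, 3))
        masses = np.empty(natoms) if "masses" in layout else None
        for a in range(natoms):
            lineno = i + 3 + a
            toks = lines[i + 2 + a].split()
            if len(toks) < col:
                raise XYZParseError(f"line {lineno}: expected ≥{col} columns, got {len(toks)}")
            sc = layout["species"][0]
            elements.append(toks[sc])
            pc = layout["pos"][0]
            try:
                positions[a] = [float(toks[pc + k]) for k in range(3)]
                if masses is not None:
                    masses[a] = float(toks[layout["masses"][0]])
            except ValueError as exc:
                raise XYZParseError(f"line {lineno}: {exc}") from None
        frames.append(
            MolecularConfiguration(
                elements=elements,
                positions=positions,
                masses=masses,
                cell=cell,
                periodic=cell is not None,
            )
        )
        i += 2 + natoms
    return frames


def write_xyz(
    path: str | Path,
    frames: MolecularConfiguration | Sequence[MolecularConfiguration] | Iterable[MolecularConfiguration],
    comments: Sequence[str] | None = None,
    write_masses: bool = True,
) -> None:
    """Write one or more frames as extended XYZ."""
    if isinstance(frames, MolecularConfiguration):
        frames = [frames]
    out: list[str] = []
    for fi, frame in enumerate(frames):
        props = "species:S:1:pos:R:3" + (":masses:R:1" if write_masses else "")
        fields = [f"Properties={props}"]
        if frame.periodic:
            a, b, c = frame.cell
            fields.append(f'Lattice="{a:.10g} 0 0 0 {b:.10g} 0 0 0 {c:.10g}"')
        if comments is not None:
            fields.append(comments[fi])
        out.append(str(frame.n_atoms))
        out.append(" ".join(fields))
        for e, p, m in zip(frame.elements, frame.positions, frame.masses):
            row = f"{e} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}"
            if write_masses:
                row += f" {m:.6f}"
            out.append(row)
    Path(path).write_text("\n".join(out) + "\n")
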