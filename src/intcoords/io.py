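"""File formats: XYZ geometries, coordinate-system specifications (JSON
dialect and Gaussian-style text Z-matrices), and tensor archives.

Conventions at the I/O boundary: Å for lengths, degrees for angles in text
Z-matrices and CLI output (radians internally); atom indices are 0-based in
the JSON dialect and 1-based in text Z-matrices (converted on read).
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .coord_systems import InternalSystem
from .errors import FormatError
from .primitives import (
    CartesianGeometry,
    CoordinateDef,
    angle,
    dihedral,
    distance,
    linear_combination,
)
from .tensor_calculus import DerivativeExpansion

__all__ = [
    "RunConfig",
    "read_xyz",
    "write_xyz",
    "read_trajectory",
    "write_trajectory",
    "read_coordinate_spec",
    "write_coordinate_spec",
    "write_tensor_archive",
    "read_tensor_archive",
    "tensors_to_json",
]


@dataclass
class RunConfig:
    """Run-level knobs shared by the CLI and scripted use."""

    order: int = 2
    degeneracy_tol: float = 1e-10
    rank_cutoff: float = 1e-8
    convergence_tol: float = 1e-10
    degrees: bool = True  # unit choice at the I/O boundary
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        for name in ("degeneracy_tol", "rank_cutoff", "convergence_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _parse_xyz_block(lines: List[str], offset: int) -> Tuple[CartesianGeometry, int]:
    if offset >= len(lines):
        raise FormatError("unexpected end of XYZ file")
    try:
        count = int(lines[offset].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"line {offset + 1}: expected an atom count")
    if offset + 2 + count > len(lines):
        raise FormatError(f"line {offset + 1}: fewer than {count} atom lines follow")
    atoms, coords = [], []
    for ln in range(offset + 2, offset + 2 + count):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise FormatError(f"line {ln + 1}: expected 'element x y z'")
        atoms.append(parts[0])
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError:
            raise FormatError(f"line {ln + 1}: non-numeric coordinate")
    return CartesianGeometry(atoms, np.array(coords)), offset + 2 + count


def read_xyz(path: Union[str, Path]) -> CartesianGeometry:
    lines = Path(path).read_text().splitlines()
    if not any(l.strip() for l in lines):
        raise FormatError(f"{path}: empty XYZ file")
    geom, _ = _parse_xyz_block(lines, 0)
    return geom


def read_trajectory(path: Union[str, Path]) -> List[CartesianGeometry]:
    lines = Path(path).read_text().splitlines()
    frames, offset = [], 0
    while offset < len(lines):
        if not lines[offset].strip():
            offset += 1
            continue
        geom, offset = _parse_xyz_block(lines, offset)
        frames.append(geom)
    if not frames:
        raise FormatError(f"{path}: empty XYZ file")
    return frames


def _format_xyz(geom: CartesianGeometry, comment: str = "") -> str:
    out = [str(geom.n_atoms), comment]
    for el, (x, y, z) in zip(geom.atoms, geom.coords):
        out.append(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    return "\n".join(out) + "\n"


def write_xyz(path: Union[str, Path], geom: CartesianGeometry, comment: str = "") -> None:
    Path(path).write_text(_format_xyz(geom, comment))


def write_trajectory(
    path: Union[str, Path], frames: Sequence[CartesianGeometry], comments: Optional[Sequence[str]] = None
) -> None:
    comments = comments or [f"frame {i}" for i in range(len(frames))]
    Path(path).write_text("".join(_format_xyz(g, c) for g, c in zip(frames, comments)))


# ---------------------------------------------------------------------------
# coordinate specifications
# ---------------------------------------------------------------------------

_JSON_KINDS = {"dist": 2, "angle": 3, "dihedral": 4}


def _def_from_json(entry: dict) -> CoordinateDef:
    typ = entry.get("type")
    if typ in _JSON_KINDS:
        atoms = entry.get("atoms", [])
        if len(atoms) != _JSON_KINDS[typ]:
            raise FormatError(f"{typ} needs {_JSON_KINDS[typ]} atoms, got {atoms}")
        maker = {"dist": distance, "angle": angle, "dihedral": dihedral}[typ]
        return maker(*[int(a) for a in atoms], label=entry.get("label", ""))
    if typ == "lincomb":
        terms = entry.get("terms", [])
        coeffs = entry.get("coeffs", [])
        if len(terms) != len(coeffs):
            raise FormatError("lincomb terms/coeffs length mismatch")
        return linear_combination(
            [(_def_from_json(t), float(c)) for t, c in zip(terms, coeffs)],
            label=entry.get("label", ""),
        )
    raise FormatError(f"unknown coordinate type {typ!r}")


def _def_to_json(c: CoordinateDef) -> dict:
    if c.kind in ("distance", "angle", "dihedral"):
        typ = {"distance": "dist", "angle": "angle", "dihedral": "dihedral"}[c.kind]
        out = {"type": typ, "atoms": list(c.atom_indices)}
    elif c.kind == "linear_combination":
        out = {
            "type": "lincomb",
            "terms": [_def_to_json(t) for t, _ in c.terms],
            "coeffs": [coeff for _, coeff in c.terms],
        }
    else:
        raise FormatError(f"cannot serialize coordinate kind {c.kind}")
    if c.label:
        out["label"] = c.label
    return out


def read_coordinate_spec(path: Union[str, Path]) -> InternalSystem:
    """Internal system from the JSON dialect or a Gaussian-style Z-matrix.

    JSON files hold an ordered list of ``{"type": "dist"|"angle"|"dihedral"|
    "lincomb", "atoms": [...0-based...], ...}`` entries.  Text Z-matrices
    use 1-based references and may carry a variable section; each atom past
    the first contributes its distance, angle, and dihedral coordinates.
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})")
        entries = data["coords"] if isinstance(data, dict) else data
        label = data.get("label", "") if isinstance(data, dict) else ""
        try:
            coords = [_def_from_json(e) for e in entries]
            return InternalSystem(coords, label=label)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}")
    return _read_zmatrix(text, str(path))


def _read_zmatrix(text: str, name: str) -> InternalSystem:
    lines = [l.strip() for l in text.splitlines()]
    # atom section ends at the first blank line (variables may follow)
    atom_lines: List[str] = []
    for l in lines:
        if not l:
            if atom_lines:
                break
            continue
        if "=" in l:
            break
        atom_lines.append(l)
    coords: List[CoordinateDef] = []
    for i, l in enumerate(atom_lines):
        parts = l.split()
        refs = []
        for pos in (1, 3, 5):
            if len(parts) > pos:
                try:
                    refs.append(int(parts[pos]) - 1)  # 1-based in text Z-matrices
                except ValueError:
                    raise FormatError(f"{name}: atom line {i + 1}: reference must be an integer")
        expected = min(i, 3)
        if len(refs) != expected:
            raise FormatError(
                f"{name}: atom line {i + 1}: expected {expected} references, got {len(refs)}"
            )
        if any(r < 0 or r >= i for r in refs):
            raise FormatError(f"{name}: atom line {i + 1}: reference out of range")
        if i >= 1:
            coords.append(distance(i, refs[0]))
        if i >= 2:
            coords.append(angle(i, refs[0], refs[1]))
        if i >= 3:
            coords.append(dihedral(i, refs[0], refs[1], refs[2]))
    if not coords:
        raise FormatError(f"{name}: no internal coordinates defined")
    try:
        return InternalSystem(coords, label="zmatrix", completeness="complete")
    except ValueError as exc:
        raise FormatError(f"{name}: {exc}")


def write_coordinate_spec(path: Union[str, Path], sys: InternalSystem) -> None:
    entries = [_def_to_json(c) for c in sys.coords]
    Path(path).write_text(json.dumps(entries, indent=1) + "\n")


# ---------------------------------------------------------------------------
# tensor archives
# ---------------------------------------------------------------------------

def write_tensor_archive(path: Union[str, Path], expansion: DerivativeExpansion) -> None:
    """Compressed array archive (npz layout) of one expansion.

    One array per order named ``order_1..order_K`` plus metadata (direction
    tag, dimensions, reference point).  Written through a fixed-timestamp
    zip so identical inputs give bit-identical files.
    """
    arrays: Dict[str, np.ndarray] = {
        f"order_{k}": expansion[k] for k in expansion.orders()
    }
    arrays["direction"] = np.array(expansion.direction)
    arrays["source_dim"] = np.array(expansion.source_dim)
    arrays["target_dim"] = np.array(-1 if expansion.target_dim is None else expansion.target_dim)
    arrays["reference"] = (
        np.array([]) if expansion.reference is None else expansion.reference
    )
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(arrays):
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arrays[name]), allow_pickle=False)
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())


def read_tensor_archive(path: Union[str, Path]) -> DerivativeExpansion:
    with np.load(path, allow_pickle=False) as data:
        tensors = {}
        for name in data.files:
            if name.startswith("order_"):
                tensors[int(name.split("_")[1])] = data[name]
        target = int(data["target_dim"])
        ref = data["reference"]
        return DerivativeExpansion(
            str(data["direction"]),
            int(data["source_dim"]),
            None if target < 0 else target,
            tensors,
            reference=None if ref.size == 0 else ref,
            validate=False,
        )


def tensors_to_json(expansion: DerivativeExpansion, limit: int = 10_000) -> str:
    """JSON form for small expansions (≤ ``limit`` elements per tensor)."""
    out = {
        "direction": expansion.direction,
        "source_dim": expansion.source_dim,
        "target_dim": expansion.target_dim,
        "reference": None if expansion.reference is None else expansion.reference.tolist(),
        "tensors": {},
    }
    for k in expansion.orders():
        t = expansion[k]
        if t.size > limit:
            raise ValueError(f"order-{k} tensor has {t.size} > {limit} elements; use an archive")
        out["tensors"][str(k)] = t.tolist()
    return json.dumps(out)
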