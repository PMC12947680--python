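"""Extended-XYZ trajectory files and bond-list sidecars.

Frame format: the usual XYZ layout with a JSON comment line carrying the
box length and arbitrary metadata, and one row per bead::

    <n_beads>
    {"box_length": 36.0, "seed": 1, ...}
    monomer 1.234567 2.345678 3.456789 0
    ...

Columns are species label, x, y, z (nm, six decimals) and valence.  The
bond sidecar is two columns of 0-based bead indices and round-trips
exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .topology import Configuration

_ROLE_OF_SPECIES = {
    "monomer": "monomer",
    "charged_monomer": "monomer",
    "crosslinker": "crosslinker",
    "anion": "anion",
    "cation": "cation",
    "nanoparticle": "nanoparticle",
}

_DEFAULT_DIAMETERS = {
    "monomer": 0.65,
    "crosslinker": 0.65,
    "anion": 0.70,
    "cation": 0.70,
    "nanoparticle": 5.00,
}


def write_xyz_frame(
    fh, config: Configuration, metadata: dict | None = None, wrap: bool = True
) -> None:
    meta = {"box_length": config.box_length}
    if metadata:
        meta.update(metadata)
    pos = config.wrapped_positions() if wrap else config.positions
    fh.write(f"{config.n_beads}\n")
    fh.write(json.dumps(meta) + "\n")
    for label, p, z in zip(config.species, pos, config.valence):
        fh.write(f"{label} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {int(z)}\n")


def write_xyz(
    path: str | Path,
    config: Configuration,
    metadata: dict | None = None,
    wrap: bool = True,
) -> None:
    with open(path, "w") as fh:
        write_xyz_frame(fh, config, metadata, wrap)


def _parse_frame(lines: list[str], start: int, path, diameters: dict) -> tuple[Configuration, dict, int]:
    try:
        n = int(lines[start].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}:{start + 1}: expected a bead count")
    try:
        meta = json.loads(lines[start + 1])
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}:{start + 2}: bad metadata line: {exc}") from exc
    box = float(meta["box_length"])
    species, valence, positions = [], [], []
    for k in range(n):
        lineno = start + 2 + k
        parts = lines[lineno].split()
        if len(parts) != 5:
            raise ValueError(
                f"{path}:{lineno + 1}: expected 'label x y z valence', got {lines[lineno]!r}"
            )
        species.append(parts[0])
        positions.append([float(parts[1]), float(parts[2]), float(parts[3])])
        valence.append(int(parts[4]))
    roles = [_ROLE_OF_SPECIES.get(s, s) for s in species]
    dia = np.array([diameters.get(r, 1.0) for r in roles])
    valence = np.array(valence, dtype=int)
    config = Configuration(
        box_length=box,
        positions=np.array(positions, dtype=float).reshape(n, 3),
        species=species,
        roles=roles,
        valence=valence,
        diameter=dia,
        hydrophobic_eligible=np.array(
            [r in ("monomer", "crosslinker") and z == 0 for r, z in zip(roles, valence)]
        ),
    )
    return config, meta, start + 2 + n


def read_xyz(path: str | Path, diameters: dict | None = None) -> tuple[Configuration, dict]:
    """Read the first (or only) frame of an extended-XYZ file."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    config, meta, _ = _parse_frame(lines, 0, path, diameters or _DEFAULT_DIAMETERS)
    return config, meta


def read_xyz_frames(path: str | Path, diameters: dict | None = None):
    """All frames of a multi-frame extended-XYZ trajectory."""
    lines = Path(path).read_text().splitlines()
    out = []
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        config, meta, pos = _parse_frame(lines, pos, path, diameters or _DEFAULT_DIAMETERS)
        out.append((config, meta))
    return out


def write_bonds(path: str | Path, bonds: np.ndarray) -> None:
    with open(path, "w") as fh:
        for i, j in np.asarray(bonds, dtype=int).reshape(-1, 2):
            fh.write(f"{i} {j}\n")


def read_bonds(path: str | Path) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two integer columns")
        rows.append((int(parts[0]), int(parts[1])))
    return np.array(rows, dtype=int).reshape(-1, 2)
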