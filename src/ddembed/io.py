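"""Readers and writers: Tinker-style XYZ, the parameter table, PDB
coordinates, and TOML run configurations.

File formats (all plain text, coordinates in angstrom by default):

* **XYZ** (Tinker-style): first line ``natoms [title]``; then one line
  per atom: ``index  name  x  y  z  type  [connected indices...]``.
* **Parameter table**: comment lines start with ``#``; data lines are

  ``type  q  mux muy muz  qxx qxy qxz qyy qyz qzz  alpha  frame zslot
  xslot  radius  probe``

  keyed by the XYZ atom type.  Dipoles are e*angstrom; quadrupole
  components are stored Tinker-style as Theta/3 in e*angstrom^2 (the
  reader multiplies by 3, converts to bohr^2 and removes any residual
  trace); alpha is angstrom^3; ``frame`` is one of ``none``,
  ``z-then-x``, ``bisector``; ``zslot``/``xslot`` are 1-based positions
  in the atom's connectivity list (0 when unused); ``radius`` is the
  final cavity-sphere radius in angstrom (0 selects the default:
  1.1-scaled van der Waals radius plus the 1.4 angstrom solvent probe);
  ``probe`` is 0/1 and marks the sites standing in for the QM density.
* **PDB**: coordinates only (ATOM/HETATM records); parameters always
  come from the table.
* **Config**: TOML with keys mirroring :class:`ddembed.config.RunConfig`
  (a ``[tree]`` table maps to :class:`TreeConfig`).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .config import RunConfig, TreeConfig
from .errors import ParseError
from .local_frames import FrameDef, rotate_to_lab
from .multipoles import MultipoleSet, traceless
from .units import (
    BOHR_PER_ANGSTROM,
    DEFAULT_PROBE_RADIUS_ANG,
    DEFAULT_RADIUS_SCALE,
)

_DEFAULT_VDW_ANG = 1.7  # generic fallback when the table gives radius 0
DEFAULT_VDW_RADIUS_SCALED = _DEFAULT_VDW_ANG * DEFAULT_RADIUS_SCALE


@dataclass
class ParamRecord:
    """One row of the parameter table (file units, quadrupole unscaled)."""

    q: float
    mu: np.ndarray
    theta: np.ndarray
    alpha: float
    frame: str
    zslot: int
    xslot: int
    radius: float
    probe: bool


def read_parameters(path):
    records = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        txt = line.split("#", 1)[0].strip()
        if not txt:
            continue
        parts = txt.split()
        if len(parts) != 17:
            raise ParseError(f"{path}:{ln}: expected 17 columns, got {len(parts)}")
        try:
            typ = int(parts[0])
            q = float(parts[1])
            mu = np.array([float(x) for x in parts[2:5]])
            qc = [float(x) for x in parts[5:11]]
            alpha = float(parts[11])
            frame = parts[12]
            zslot, xslot = int(parts[13]), int(parts[14])
            radius = float(parts[15])
            probe = bool(int(parts[16]))
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: malformed value ({exc})") from None
        if frame not in ("none", "z-then-x", "bisector"):
            raise ParseError(f"{path}:{ln}: unknown frame rule {frame!r}")
        th = np.array(
            [
                [qc[0], qc[1], qc[2]],
                [qc[1], qc[3], qc[4]],
                [qc[2], qc[4], qc[5]],
            ]
        ) * 3.0  # stored as Theta/3
        records[typ] = ParamRecord(q, mu, th, alpha, frame, zslot, xslot, radius, probe)
    return records


def read_xyz(path):
    """Tinker-style XYZ; returns (names, coords, types, connectivity)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:1: first line must start with the atom count") from None
    names, coords, types, conn = [], [], [], []
    if len(lines) < natoms + 1:
        raise ParseError(f"{path}: expected {natoms} atom lines")
    for ln in range(1, natoms + 1):
        parts = lines[ln].split()
        if len(parts) < 6:
            raise ParseError(f"{path}:{ln + 1}: expected at least 6 fields")
        try:
            names.append(parts[1])
            coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
            types.append(int(parts[5]))
            conn.append([int(x) - 1 for x in parts[6:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln + 1}: malformed value ({exc})") from None
    return names, np.array(coords), types, conn


def read_pdb(path):
    """Coordinates-only PDB reader (ATOM/HETATM records)."""
    names, coords = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                names.append(line[12:16].strip())
                coords.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError:
                raise ParseError(f"{path}:{ln}: malformed coordinates") from None
    if not coords:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return names, np.array(coords)


def read_config(path) -> RunConfig:
    """Load a TOML run configuration."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    tree = TreeConfig(**data.pop("tree", {}))
    try:
        return RunConfig(tree=tree, **data)
    except TypeError as exc:
        raise ParseError(f"{path}: unknown configuration key ({exc})") from None


def read_system(xyz_path, parameter_path, config: Optional[RunConfig] = None):
    """Assemble the embedding system from an XYZ file and a parameter table.

    Returns ``(env, probe, cavity_radii_bohr)``: lab-frame multipole
    sets (frames resolved through the connectivity) and final cavity
    radii including the probe radius.
    """
    config = config or RunConfig()
    names, coords, types, conn = read_xyz(xyz_path)
    params = read_parameters(parameter_path)
    scale = BOHR_PER_ANGSTROM if config.coord_unit == "angstrom" else 1.0
    coords = coords * scale
    n = len(coords)
    recs = []
    for i, t in enumerate(types):
        if t not in params:
            raise ParseError(
                f"{xyz_path}: atom {i + 1} has unknown type {t} "
                f"(not in {parameter_path})"
            )
        recs.append(params[t])
    probe_mask = np.array([r.probe for r in recs])
    # frame defs with neighbour slots resolved through connectivity,
    # re-indexed within each subset
    order = np.concatenate([np.nonzero(probe_mask)[0], np.nonzero(~probe_mask)[0]])
    sets = {}
    for is_probe in (True, False):
        sel = np.nonzero(probe_mask == is_probe)[0]
        if len(sel) == 0:
            sets[is_probe] = None
            continue
        local = {g: l for l, g in enumerate(sel)}
        fdefs, mu_f, th_f = [], [], []
        for g in sel:
            r = recs[g]
            mu_ang = r.mu
            th_ang = traceless(r.theta * 1.0)
            if r.frame == "none":
                fdefs.append(FrameDef("none"))
            else:
                neigh = conn[g]
                for slot, label in ((r.zslot, "z"), (r.xslot, "x")):
                    if slot < 1 or slot > len(neigh):
                        raise ParseError(
                            f"{xyz_path}: atom {g + 1} ({names[g]}): frame rule "
                            f"{r.frame!r} references missing {label}-neighbour "
                            f"slot {slot} (atom has {len(neigh)} connections)"
                        )
                zg, xg = neigh[r.zslot - 1], neigh[r.xslot - 1]
                if zg not in local or xg not in local:
                    raise ParseError(
                        f"{xyz_path}: atom {g + 1}: frame neighbour crosses the "
                        f"probe/environment boundary"
                    )
                fdefs.append(FrameDef(r.frame, local[zg], local[xg]))
            mu_f.append(mu_ang * BOHR_PER_ANGSTROM)
            th_f.append(th_ang * BOHR_PER_ANGSTROM**2)
        mu_f = np.array(mu_f)
        th_f = traceless(np.array(th_f))
        pos_local = coords[sel]
        mu_lab = mu_f.copy()
        th_lab = th_f.copy()
        for l, fd in enumerate(fdefs):
            if fd.rule != "none":
                mu_lab[l], th_lab[l] = rotate_to_lab(mu_f[l], th_f[l], fd, l, pos_local)
        sets[is_probe] = MultipoleSet(
            pos_local,
            np.array([recs[g].q for g in sel]),
            mu_lab,
            traceless(th_lab),
            np.zeros(len(sel))
            if is_probe
            else np.array([recs[g].alpha for g in sel]) * BOHR_PER_ANGSTROM**3,
            role="probe" if is_probe else "environment",
            frame_defs=fdefs,
            mu_frame=mu_f,
            theta_frame=th_f,
            thole=config.thole,
            labels=[names[g] for g in sel],
        )
    radii_ang = np.array(
        [
            r.radius
            if r.radius > 0
            else DEFAULT_VDW_RADIUS_SCALED + DEFAULT_PROBE_RADIUS_ANG
            for r in recs
        ]
    )
    radii_bohr = radii_ang * BOHR_PER_ANGSTROM
    # reorder radii: probe atoms first, then environment
    radii_bohr = radii_bohr[order]
    return sets[False], sets[True], radii_bohr


def write_system(
    directory,
    env: MultipoleSet,
    probe: Optional[MultipoleSet] = None,
    radii_bohr: Optional[np.ndarray] = None,
    config: Optional[RunConfig] = None,
    prefix: str = "system",
):
    """Write XYZ + parameter table (+ config) round-trippable by
    :func:`read_system`.  Every atom gets its own type."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    a = 1.0 / BOHR_PER_ANGSTROM
    sets = [(probe, True), (env, False)]
    xyz_lines = []
    par_lines = [
        "# type q mux muy muz qxx qxy qxz qyy qyz qzz alpha frame zslot xslot radius probe"
    ]
    radii = radii_bohr
    atom_no = 0
    typ = 0
    offs = {}
    n_total = sum(s.n_sites for s, _ in sets if s is not None)
    for mset, is_probe in sets:
        if mset is None:
            continue
        offs[is_probe] = atom_no
        atom_no += mset.n_sites
    atom_no = 0
    conn_lines = []
    for mset, is_probe in sets:
        if mset is None:
            continue
        base = offs[is_probe]
        for i in range(mset.n_sites):
            typ += 1
            x, y, z = mset.positions[i] * a
            fd = (
                mset.frame_defs[i]
                if mset.frame_defs is not None
                else FrameDef("none")
            )
            conns = []
            zslot = xslot = 0
            if fd.rule != "none":
                conns = [base + fd.z_neighbor + 1, base + fd.x_neighbor + 1]
                zslot, xslot = 1, 2
            name = (mset.labels[i] if mset.labels else f"A{typ}")
            xyz_lines.append(
                f"{base + i + 1:6d} {name:<4s} {x:.16e} {y:.16e} {z:.16e} "
                f"{typ:5d} " + " ".join(str(c) for c in conns)
            )
            mu = (
                mset.mu_frame[i] if mset.mu_frame is not None else mset.mu[i]
            ) * a
            th = (
                mset.theta_frame[i] if mset.theta_frame is not None else mset.theta[i]
            ) * a**2 / 3.0
            rad = radii[base + i] * a if radii is not None else 0.0
            alpha = mset.alpha[i] * a**3
            par_lines.append(
                f"{typ} {mset.q[i]:.16e} "
                f"{mu[0]:.16e} {mu[1]:.16e} {mu[2]:.16e} "
                f"{th[0, 0]:.16e} {th[0, 1]:.16e} {th[0, 2]:.16e} "
                f"{th[1, 1]:.16e} {th[1, 2]:.16e} {th[2, 2]:.16e} "
                f"{alpha:.16e} {fd.rule} {zslot} {xslot} {rad:.16e} "
                f"{1 if is_probe else 0}"
            )
    xyz = directory / f"{prefix}.xyz"
    xyz.write_text(f"{n_total} generated by ddembed\n" + "\n".join(xyz_lines) + "\n")
    par = directory / f"{prefix}.prm"
    par.write_text("\n".join(par_lines) + "\n")
    cfgf = directory / f"{prefix}.toml"
    lines = []
    d = config.to_dict()
    tree = d.pop("tree")
    for k, v in d.items():
        if isinstance(v, str):
            lines.append(f'{k} = "{v}"')
        elif isinstance(v, bool):
            lines.append(f"{k} = {str(v).lower()}")
        else:
            lines.append(f"{k} = {v}")
    lines.append("[tree]")
    for k, v in tree.items():
        lines.append(f"{k} = {v}")
    cfgf.write_text("\n".join(lines) + "\n")
    return xyz, par, cfgf
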