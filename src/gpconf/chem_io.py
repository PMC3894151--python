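"""Conformer ensemble I/O.

A *conformation* is one geometry of a flexible molecule: nuclear charges plus
Cartesian coordinates in Angstrom, optionally tagged with an energy in kJ/mol.
An *ensemble* is an ordered collection of conformations of the same molecule
with identical atom ordering — the hard contract that makes the pairwise
descriptor comparable across members.

File formats: multi-frame XYZ for geometries (energies round-trip through an
``E=<float>`` token on the comment line, conformer ids through ``id=<token>``)
and two-column CSV (``conf_id,energy``) for energy tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: kJ per kcal, used only for reporting (energies are kJ/mol throughout).
KJ_PER_KCAL = 4.184

#: minimum allowed pairwise distance (Angstrom) between any two atoms
MIN_ATOM_SEPARATION = 1e-6

# symbol -> nuclear charge, H..Og
_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og"
).split()

PERIODIC_TABLE: dict[str, int] = {s: z for z, s in enumerate(_SYMBOLS, start=1)}
_Z_TO_SYMBOL: dict[int, str] = {z: s for s, z in PERIODIC_TABLE.items()}

_ENERGY_TOKEN = re.compile(r"(?:^|\s)E=([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)(?:\s|$)")
_ID_TOKEN = re.compile(r"(?:^|\s)id=(\S+)")


def symbol_to_z(symbol: str) -> int:
    """Map an element symbol to its nuclear charge; unknown symbols raise."""
    try:
        return PERIODIC_TABLE[symbol.capitalize()]
    except KeyError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None


def z_to_symbol(z: int) -> str:
    try:
        return _Z_TO_SYMBOL[int(z)]
    except KeyError:
        raise ValueError(f"no element with nuclear charge {z}") from None


@dataclass
class Conformation:
    """One geometry of the molecule.

    Parameters
    ----------
    conf_id : str
        Unique identifier within an ensemble.
    atomic_numbers : array-like of int
        Nuclear charges Z, one per atom. Atom order is significant.
    coords : (n, 3) array
        Cartesian coordinates in Angstrom.
    energy : float, optional
        Reference energy in kJ/mol.
    clash : bool
        Set by generators when the geometry contains atoms closer than the
        clash threshold (0.5 A); such frames are meant to be resampled.
    """

    conf_id: str
    atomic_numbers: np.ndarray
    coords: np.ndarray
    energy: float | None = None
    clash: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.atomic_numbers.ndim != 1 or np.any(self.atomic_numbers < 1):
            raise ValueError("atomic_numbers must be a 1-D sequence of positive integers")
        n = len(self.atomic_numbers)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} atoms"
            )
        if n < 2:
            raise ValueError("a conformation needs at least 2 atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        d = self.distance_matrix()
        iu = np.triu_indices(n, 1)
        if np.any(d[iu] <= MIN_ATOM_SEPARATION):
            i, j = [int(v[np.argmin(d[iu])]) for v in iu]
            raise ValueError(
                f"atoms {i + 1} and {j + 1} are coincident "
                f"(distance <= {MIN_ATOM_SEPARATION} A)"
            )
        if self.energy is not None:
            self.energy = float(self.energy)

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    def distance_matrix(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(-1))


@dataclass
class Ensemble:
    """Ordered conformations of one molecule with a shared atom ordering."""

    conformations: list[Conformation]
    run_label: str | None = None

    def __post_init__(self) -> None:
        self.conformations = list(self.conformations)
        if self.conformations:
            ref = self.conformations[0].atomic_numbers
            for i, conf in enumerate(self.conformations):
                if not np.array_equal(conf.atomic_numbers, ref):
                    raise ValueError(
                        f"ensemble must share atom ordering: conformation {i} "
                        f"({conf.conf_id!r}) differs from the first member"
                    )
            ids = [c.conf_id for c in self.conformations]
            if len(set(ids)) != len(ids):
                dup = next(x for x in ids if ids.count(x) > 1)
                raise ValueError(f"duplicate conf_id {dup!r} in ensemble")

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self.conformations)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Ensemble(self.conformations[i], run_label=self.run_label)
        return self.conformations[i]

    @property
    def atomic_numbers(self) -> np.ndarray:
        if not self.conformations:
            raise ValueError("empty ensemble has no atomic numbers")
        return self.conformations[0].atomic_numbers

    @property
    def conf_ids(self) -> list[str]:
        return [c.conf_id for c in self.conformations]

    def energies(self) -> np.ndarray:
        """Energies (kJ/mol), NaN where absent."""
        return np.array(
            [np.nan if c.energy is None else c.energy for c in self.conformations]
        )

    def with_energies(self, table: Mapping[str, float]) -> "Ensemble":
        """Return a copy with energies attached from a conf_id -> energy map."""
        confs = []
        for c in self.conformations:
            if c.conf_id not in table:
                raise KeyError(f"no energy for conformer {c.conf_id!r}")
            confs.append(
                Conformation(c.conf_id, c.atomic_numbers, c.coords.copy(),
                             energy=float(table[c.conf_id]))
            )
        return Ensemble(confs, run_label=self.run_label)


def concat_ensembles(ensembles: Sequence[Ensemble], run_label: str | None = None) -> Ensemble:
    """Concatenate ensembles of the same molecule, preserving order."""
    confs: list[Conformation] = []
    for e in ensembles:
        confs.extend(e.conformations)
    return Ensemble(confs, run_label=run_label)


def read_xyz(path: str | Path) -> Ensemble:
    """Read a multi-frame XYZ file into an :class:`Ensemble`.

    Each frame is ``n`` / comment / ``n`` atom lines. Column 1 may hold an
    element symbol or a nuclear charge. A comment token ``E=<float>`` is read
    as the frame's energy (kJ/mol), ``id=<token>`` as its conformer id;
    otherwise ids default to the 0-based frame index.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    pos, frame_idx = 0, 0
    confs: list[Conformation] = []
    # skip trailing blank lines between frames
    while pos < len(lines) and lines[pos].strip() == "":
        pos += 1
    if pos >= len(lines):
        raise ValueError(f"{path}: empty XYZ file")
    while pos < len(lines):
        if lines[pos].strip() == "":
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise ValueError(
                f"{path}: frame {frame_idx}: expected atom count, got {lines[pos]!r}"
            ) from None
        if pos + 1 + n >= len(lines) + 1 or len(lines) < pos + 2 + n:
            raise ValueError(f"{path}: frame {frame_idx}: truncated ({n} atoms declared)")
        comment = lines[pos + 1]
        zs, xyz = [], []
        for k in range(n):
            parts = lines[pos + 2 + k].split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: frame {frame_idx}: malformed atom line {k + 1}: "
                    f"{lines[pos + 2 + k]!r}"
                )
            sym = parts[0]
            z = int(sym) if sym.isdigit() else symbol_to_z(sym)
            try:
                xyz.append([float(v) for v in parts[1:4]])
            except ValueError:
                raise ValueError(
                    f"{path}: frame {frame_idx}: unparseable coordinate on atom line {k + 1}"
                ) from None
            zs.append(z)
        m_e = _ENERGY_TOKEN.search(comment)
        m_id = _ID_TOKEN.search(comment)
        conf_id = m_id.group(1) if m_id else f"frame{frame_idx:04d}"
        confs.append(
            Conformation(
                conf_id,
                np.array(zs),
                np.array(xyz),
                energy=float(m_e.group(1)) if m_e else None,
            )
        )
        pos += 2 + n
        frame_idx += 1
    try:
        return Ensemble(confs)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_xyz(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as multi-frame XYZ (coordinates to 10 decimals)."""
    path = Path(path)
    if len(ensemble) == 0:
        logger.warning("writing empty ensemble to %s", path)
        path.write_text("")
        return
    out = []
    for conf in ensemble:
        out.append(str(conf.n_atoms))
        comment = f"id={conf.conf_id}"
        if conf.energy is not None:
            comment += f" E={conf.energy:.10g}"
        out.append(comment)
        for z, (x, y, w) in zip(conf.atomic_numbers, conf.coords):
            out.append(f"{z_to_symbol(z):2s} {x: .10f} {y: .10f} {w: .10f}")
    path.write_text("\n".join(out) + "\n")


def read_energy_table(path: str | Path) -> dict[str, float]:
    """Read a ``conf_id,energy`` CSV into a mapping (energies in kJ/mol)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"conf_id": str})
    for col in ("conf_id", "energy"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    energies = pd.to_numeric(df["energy"], errors="coerce")
    bad = energies.isna() | ~np.isfinite(energies)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # header is row 1
        raise ValueError(f"{path}: non-numeric energy in row {row}")
    if df["conf_id"].duplicated().any():
        dup = df["conf_id"][df["conf_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate conf_id {dup!r}")
    return dict(zip(df["conf_id"], energies.astype(float)))


def write_energy_table(table: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame({"conf_id": list(table), "energy": list(table.values())}).to_csv(
        path, index=False
    )


def relative_energies(energies: Sequence[float] | np.ndarray) -> np.ndarray:
    """Energies relative to the ensemble minimum (Delta-E, kJ/mol)."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("cannot compute relative energies of an empty vector")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    return e - e.min()
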