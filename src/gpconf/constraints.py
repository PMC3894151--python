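"""Scoring conformers against NMR-derived interproton distance constraints.

ROESY/NOE cross-peaks translate into upper bounds on proton-proton distances,
classified by intensity: < 2.5 A (strong), < 3.5 A (medium), < 5 A (weak).
For correlations involving a methyl group, the plain average distance over the
three methyl protons is used (an r^-6 NOE average is available as an option).
A constraint is satisfied when the (averaged) distance is strictly below its
bound. Constraints that every conformer of an ensemble satisfies — or that
none does — carry no ranking information and are filtered out before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_io import Conformation, Ensemble

#: upper distance bound (Angstrom) per ROESY intensity class
STRENGTH_BOUNDS = {"weak": 5.0, "medium": 3.5, "strong": 2.5}


@dataclass(frozen=True)
class ProtonGroup:
    """A single proton or the three protons of a methyl group (0-based indices)."""

    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_indices", tuple(int(i) for i in self.atom_indices))
        if len(self.atom_indices) not in (1, 3):
            raise ValueError("a proton group has 1 (single proton) or 3 (methyl) atoms")
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValueError("duplicate atom index in proton group")
        if any(i < 0 for i in self.atom_indices):
            raise ValueError("atom indices must be non-negative (0-based)")


@dataclass(frozen=True)
class DistanceConstraint:
    """Classified upper bound on the (averaged) distance between two groups."""

    left: ProtonGroup
    right: ProtonGroup
    strength: str
    bound: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.strength not in STRENGTH_BOUNDS:
            raise ValueError(f"unknown strength {self.strength!r}")
        expected = STRENGTH_BOUNDS[self.strength]
        if self.bound is None:
            object.__setattr__(self, "bound", expected)
        elif self.bound != expected:
            raise ValueError(
                f"bound {self.bound} does not match strength {self.strength!r} ({expected})"
            )
        if set(self.left.atom_indices) & set(self.right.atom_indices):
            raise ValueError("constraint groups share an atom")

    def describe(self) -> str:
        l = "+".join(str(i + 1) for i in self.left.atom_indices)
        r = "+".join(str(i + 1) for i in self.right.atom_indices)
        return self.label or f"{l}/{r} ({self.strength})"


def constraint_distance(
    conf: Conformation, c: DistanceConstraint, averaging: str = "mean"
) -> float:
    """Averaged distance (A) between the two proton groups of a constraint.

    ``averaging="mean"`` is the arithmetic mean over all left x right atom
    pairs; ``averaging="r6"`` is the NOE-style (mean r^-6)^(-1/6).
    """
    for i in (*c.left.atom_indices, *c.right.atom_indices):
        if i >= conf.n_atoms:
            raise IndexError(f"atom index {i + 1} out of range for {conf.n_atoms} atoms")
    li = np.array(c.left.atom_indices)
    ri = np.array(c.right.atom_indices)
    d = np.linalg.norm(conf.coords[li][:, None, :] - conf.coords[ri][None, :, :], axis=-1)
    if averaging == "mean":
        return float(d.mean())
    if averaging == "r6":
        return float((d**-6.0).mean() ** (-1.0 / 6.0))
    raise ValueError(f"unknown averaging mode {averaging!r}")


def satisfied_count(
    conf: Conformation, constraints: list[DistanceConstraint], averaging: str = "mean"
) -> tuple[int, list[bool]]:
    """Number of constraints the conformer satisfies (strict '<' at the bound),
    plus the per-constraint booleans."""
    flags = [constraint_distance(conf, c, averaging) < c.bound for c in constraints]
    return sum(flags), flags


def informative_constraints(
    ensemble: Ensemble, constraints: list[DistanceConstraint], averaging: str = "mean"
) -> tuple[list[DistanceConstraint], list[tuple[DistanceConstraint, str]]]:
    """Drop constraints that are always or never fulfilled across the ensemble.

    Returns the informative subset and a report of (constraint, reason) for
    every dropped constraint, reason in {"always", "never"}.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble must be non-empty")
    kept, dropped = [], []
    for c in constraints:
        flags = [constraint_distance(conf, c, averaging) < c.bound for conf in ensemble]
        if all(flags):
            dropped.append((c, "always"))
        elif not any(flags):
            dropped.append((c, "never"))
        else:
            kept.append(c)
    return kept, dropped


def compliance_table(
    ensemble: Ensemble, constraints: list[DistanceConstraint], averaging: str = "mean"
) -> pd.DataFrame:
    """Per-conformer satisfaction matrix (one boolean column per constraint)
    plus the satisfied-count column."""
    cols = [c.describe() for c in constraints]
    rows = []
    for conf in ensemble:
        count, flags = satisfied_count(conf, constraints, averaging)
        rows.append([conf.conf_id, count, *flags])
    return pd.DataFrame(rows, columns=["conf_id", "n_satisfied", *cols])


def read_constraint_table(path: str | Path) -> list[DistanceConstraint]:
    """Read constraints from CSV with columns ``left_atoms``, ``right_atoms``
    (semicolon-joined 1-based atom indices) and ``strength``."""
    df = pd.read_csv(path)
    for col in ("left_atoms", "right_atoms", "strength"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")

    def parse(cell) -> ProtonGroup:
        return ProtonGroup(tuple(int(tok) - 1 for tok in str(cell).split(";")))

    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                DistanceConstraint(
                    parse(row["left_atoms"]), parse(row["right_atoms"]),
                    str(row["strength"]).strip().lower(),
                )
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from None
    return out
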