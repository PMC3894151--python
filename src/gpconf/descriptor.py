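"""Charge/inverse-distance matrix representation of a conformation.

A conformation with nuclear charges ``Z`` and coordinates ``R`` is encoded as
the symmetric matrix

    M_ij = Z_i * Z_j / ||R_i - R_j||   (i != j, distances in Angstrom)
    M_ii = 0.5 * Z_i ** 2.4

whose strict lower triangle, concatenated row by row, is the fixed-length
feature vector used by the regression models. The encoding is invariant under
rigid translation, rotation and inversion of the coordinates, but *not* under
permutation of atoms — ensembles therefore carry a fixed atom ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import Conformation, Ensemble, MIN_ATOM_SEPARATION

DIAGONAL_EXPONENT = 2.4


@dataclass
class DescriptorVector:
    """Strict lower triangle of the charge/inverse-distance matrix.

    ``values`` has length ``n_atoms * (n_atoms - 1) / 2``; entries are ordered
    row-major over pairs (i, j) with i > j, i.e. (2,1), (3,1), (3,2), ...
    in 1-based atom labels.
    """

    values: np.ndarray
    n_atoms: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_atoms * (self.n_atoms - 1) // 2
        if self.values.shape != (expected,):
            raise ValueError(
                f"descriptor length {self.values.shape} does not match "
                f"n_atoms={self.n_atoms} (expected {expected})"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("descriptor entries must be finite and positive")


def _resolve_mask(n: int, atom_mask) -> np.ndarray:
    if atom_mask is None:
        return np.arange(n)
    idx = np.asarray(atom_mask)
    if idx.dtype == bool:
        if idx.shape != (n,):
            raise ValueError("boolean atom_mask must have one entry per atom")
        idx = np.flatnonzero(idx)
    if idx.size < 2:
        raise ValueError("atom_mask must select at least 2 atoms")
    if np.any(idx < 0) or np.any(idx >= n):
        raise ValueError("atom_mask index out of range")
    return idx


def coulomb_matrix(conf: Conformation, atom_mask=None) -> np.ndarray:
    """Full symmetric charge/inverse-distance matrix of a conformation.

    ``atom_mask`` optionally restricts the matrix to a subset of atoms
    (0-based indices or boolean mask), e.g. to drop selected hydrogens.
    """
    idx = _resolve_mask(conf.n_atoms, atom_mask)
    z = conf.atomic_numbers[idx].astype(float)
    r = conf.coords[idx]
    diff = r[:, None, :] - r[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    if np.any(d[np.triu_indices(len(idx), 1)] <= MIN_ATOM_SEPARATION):
        raise ValueError("coincident atoms: inverse distance diverges")
    with np.errstate(divide="ignore"):
        m = np.outer(z, z) / d
    np.fill_diagonal(m, 0.5 * z**DIAGONAL_EXPONENT)
    return m


def vectorize(conf: Conformation, atom_mask=None) -> DescriptorVector:
    """Encode a conformation as its strict-lower-triangle descriptor vector."""
    m = coulomb_matrix(conf, atom_mask=atom_mask)
    n = m.shape[0]
    return DescriptorVector(m[np.tril_indices(n, -1)], n_atoms=n)


def featurize_ensemble(ensemble: Ensemble, atom_mask=None) -> np.ndarray:
    """Stack descriptor vectors of all ensemble members into an (m, d) matrix."""
    if len(ensemble) == 0:
        raise ValueError("cannot featurize an empty ensemble")
    return np.stack([vectorize(c, atom_mask=atom_mask).values for c in ensemble])


def pair_labels(n_atoms: int, atom_mask=None) -> list[str]:
    """1-based "i-j" labels for the descriptor dimensions, in vector order."""
    idx = _resolve_mask(n_atoms, atom_mask) + 1
    rows, cols = np.tril_indices(len(idx), -1)
    return [f"{idx[i]}-{idx[j]}" for i, j in zip(rows, cols)]


def standardize_features(
    X_train: np.ndarray, X_test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, tuple[np.ndarray, np.ndarray]]:
    """Per-dimension standardization fit on training rows only.

    Returns transformed train and test matrices plus the (mean, scale) pair.
    Constant dimensions get scale 1 so they map to zero. Off by default
    everywhere; provided for preprocessing experiments.
    """
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xt = (X_train - mu) / sd
    Xs = None if X_test is None else (X_test - mu) / sd
    return Xt, Xs, (mu, sd)
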