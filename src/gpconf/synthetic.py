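"""Synthetic conformer studies with an analytic energy oracle.

The generator emulates the data situation of a surrogate-energy study of one
flexible molecule: several MD runs of a few hundred relaxed conformers each,
every run biased toward its own region of torsion space (imperfect per-run
sampling), energies from an expensive reference method. The stand-ins are

* a heteroatomic chain molecule with fixed bond lengths and angles whose only
  degrees of freedom are its backbone torsions (default: 12 atoms alternating
  C/H, 1.5 A bonds, 111 deg angles, 9 torsions);
* an analytic energy: cosine torsion terms A_t (1 + cos(m_t phi_t - gamma_t))
  plus a Lennard-Jones term over atom pairs four or more bonds apart, plus
  i.i.d. Gaussian observation noise seeded *per conformer id* so repeated
  oracle queries for the same conformer agree, as repeated reference
  calculations would;
* per-run sampling bias: run r draws torsions from Normal(bias_r, jitter^2)
  with pairwise-distinct bias vectors, so runs occupy distinct basins and a
  model trained on one run generalizes worse than one trained on a pooled
  sample of the same size.

Defaults (first/second-harmonic torsion terms of 1-8 kJ/mol, jitter 0.2 rad,
biases offset by -60/0/+60 deg from the extended chain, LJ epsilon 0.3 kJ/mol
/ sigma 2.5 A with a 2.0 A steric resampling filter, noise 0.5 kJ/mol) give a
smooth surface with an energy spread of tens of kJ/mol — large against the
noise, learnable from the inverse-distance representation yet curved enough
that accuracy keeps improving with training-set size before levelling off at
the noise floor.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_io import Conformation, Ensemble, write_energy_table, write_xyz

CLASH_DISTANCE = 0.5  # Angstrom; below this a built geometry is flagged

_DEFAULT_AMPLITUDES = (6.0, 4.0, 8.0, 5.0, 7.0, 3.0, 6.5, 4.5, 7.5)


@dataclass(frozen=True)
class ToyMoleculeSpec:
    """Chain molecule with fixed internal geometry and free torsions."""

    n_atoms: int = 12
    atomic_numbers: tuple[int, ...] | None = None
    bond_length: float = 1.5  # Angstrom
    bond_angle: float = 111.0  # degrees

    def __post_init__(self) -> None:
        if self.n_atoms < 6:
            raise ValueError("toy molecule needs n_atoms >= 6")
        if self.bond_length <= 0 or not 0 < self.bond_angle < 180:
            raise ValueError("geometry parameters must be positive (angle in (0, 180))")
        if self.atomic_numbers is None:
            zs = tuple(6 if i % 2 == 0 else 1 for i in range(self.n_atoms))
            object.__setattr__(self, "atomic_numbers", zs)
        else:
            zs = tuple(int(z) for z in self.atomic_numbers)
            if len(zs) != self.n_atoms or any(z < 1 for z in zs):
                raise ValueError("atomic_numbers must list one positive Z per atom")
            object.__setattr__(self, "atomic_numbers", zs)

    @property
    def n_torsions(self) -> int:
        return self.n_atoms - 3


@dataclass(frozen=True)
class EnergyParams:
    """Analytic surface parameters.

    ``torsion_terms`` is a (n_torsions, 3) array of (amplitude kJ/mol,
    multiplicity, phase rad) rows. Nonbonded Lennard-Jones applies to atom
    pairs separated by >= 4 bonds. ``noise_sd`` is the observation-noise
    standard deviation of the oracle (kJ/mol).
    """

    torsion_terms: tuple[tuple[float, int, float], ...]
    nb_epsilon: float = 0.3  # kJ/mol
    nb_sigma: float = 2.5  # Angstrom
    noise_sd: float = 0.5  # kJ/mol
    seed: int = 0

    def __post_init__(self) -> None:
        terms = tuple((float(a), int(m), float(g)) for a, m, g in self.torsion_terms)
        if any(a < 0 for a, _, _ in terms):
            raise ValueError("torsion amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "torsion_terms", terms)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.array(self.torsion_terms, dtype=float)
        return t[:, 0], t[:, 1], t[:, 2]


def default_energy_params(spec: ToyMoleculeSpec, noise_sd: float = 0.5, seed: int = 0) -> EnergyParams:
    """Default surface: cosine terms with a fixed 3-8 kJ/mol base-amplitude
    pattern, multiplicities alternating 1 and 2 along the chain (amplitude
    scaled by 1/m^2 so higher harmonics stay gentle), zero phases, mild
    Lennard-Jones."""
    nt = spec.n_torsions
    terms = []
    for i in range(nt):
        a = _DEFAULT_AMPLITUDES[i % len(_DEFAULT_AMPLITUDES)]
        m = 1 if i % 2 == 0 else 2
        terms.append((a / m**2, m, 0.0))
    return EnergyParams(torsion_terms=tuple(terms), noise_sd=noise_sd, seed=seed)


@dataclass(frozen=True)
class StudyConfig:
    """Multi-run study layout: how many runs, how they are biased, how noisy
    the torsion sampling is, and the steric filter for accepted frames."""

    n_runs: int = 4
    frames_per_run: int = 240
    run_bias: tuple[tuple[float, ...], ...] | None = None  # rad, per run per torsion
    torsion_jitter_sd: float = 0.2  # rad
    min_nb_distance: float = 2.0  # Angstrom, resample below this
    max_retries: int = 200  # resampling budget per accepted frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.frames_per_run < 1:
            raise ValueError("n_runs and frames_per_run must be >= 1")
        if self.torsion_jitter_sd <= 0:
            raise ValueError("torsion_jitter_sd must be positive")
        if self.run_bias is not None:
            rb = tuple(tuple(float(v) for v in row) for row in self.run_bias)
            if len(rb) != self.n_runs:
                raise ValueError("run_bias needs one row per run")
            if len(set(rb)) != len(rb):
                raise ValueError("run_bias rows must be pairwise distinct")
            object.__setattr__(self, "run_bias", rb)


def default_run_bias(spec: ToyMoleculeSpec, config: StudyConfig) -> tuple[tuple[float, ...], ...]:
    """Per-run torsion means: the extended chain (pi) offset per torsion by a
    seeded choice from {-60, 0, +60} degrees; rows are pairwise distinct."""
    rng = np.random.default_rng(config.seed)
    offsets = np.array([-np.pi / 3, 0.0, np.pi / 3])
    rows: list[tuple[float, ...]] = []
    while len(rows) < config.n_runs:
        row = tuple(np.pi + rng.choice(offsets, size=spec.n_torsions))
        if row not in rows:
            rows.append(row)
    return tuple(rows)


def build_conformation(
    spec: ToyMoleculeSpec, torsions, conf_id: str = "conf"
) -> Conformation:
    """Internal-to-Cartesian chain construction for a torsion vector.

    Atom 0 sits at the origin, atom 1 on +x, atom 2 in the xy-plane; each
    further atom is placed at the fixed bond length and angle with the given
    dihedral. Geometries with any atom pair closer than 0.5 A come back with
    ``clash=True`` so callers can resample.
    """
    torsions = np.asarray(torsions, dtype=float).ravel()
    if len(torsions) != spec.n_torsions:
        raise ValueError(
            f"expected {spec.n_torsions} torsions for {spec.n_atoms} atoms, got {len(torsions)}"
        )
    b = spec.bond_length
    theta = np.deg2rad(spec.bond_angle)
    coords = np.zeros((spec.n_atoms, 3))
    coords[1] = [b, 0.0, 0.0]
    coords[2] = coords[1] + b * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for i in range(3, spec.n_atoms):
        phi = torsions[i - 3]
        a, p, c = coords[i - 3], coords[i - 2], coords[i - 1]
        bc = c - p
        bc /= np.linalg.norm(bc)
        n1 = np.cross(p - a, bc)
        n1 /= np.linalg.norm(n1)
        m1 = np.cross(n1, bc)
        local = np.array(
            [-b * np.cos(theta), b * np.sin(theta) * np.cos(phi), b * np.sin(theta) * np.sin(phi)]
        )
        coords[i] = c + local[0] * bc + local[1] * m1 + local[2] * n1
    conf = Conformation(conf_id, np.array(spec.atomic_numbers), coords)
    d = conf.distance_matrix()
    iu = np.triu_indices(spec.n_atoms, 1)
    conf.clash = bool(np.any(d[iu] < CLASH_DISTANCE))
    return conf


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (rad) of four points, matching the torsion
    convention of :func:`build_conformation`."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def _noise_rng(params: EnergyParams, conf_id: str) -> np.random.Generator:
    tag = zlib.crc32(conf_id.encode("utf-8"))
    return np.random.default_rng((int(params.seed) * 1_000_003 + tag) % 2**31)


def _nonbonded_pairs(n_atoms: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(n_atoms, 4)  # chain topology: bond count == |i - j|
    return i, j


def energy(
    torsions,
    spec: ToyMoleculeSpec,
    params: EnergyParams,
    conf_id: str | None = None,
    include_noise: bool = True,
) -> float:
    """Analytic oracle energy (kJ/mol) of a torsion vector.

    Noise is drawn from a stream seeded by (params.seed, conf_id), so the same
    conformer always receives the same noisy energy. ``include_noise=False``
    (or noise_sd == 0) returns the noiseless surface.
    """
    torsions = np.asarray(torsions, dtype=float).ravel()
    amps, mults, phases = params.arrays()
    if len(torsions) != len(amps):
        raise ValueError("torsion vector length does not match torsion_terms")
    e = float(np.sum(amps * (1.0 + np.cos(mults * torsions - phases))))
    if params.nb_epsilon != 0.0:
        coords = build_conformation(spec, torsions).coords
        i, j = _nonbonded_pairs(spec.n_atoms)
        r = np.linalg.norm(coords[i] - coords[j], axis=1)
        sr6 = (params.nb_sigma / r) ** 6
        e += float(np.sum(4.0 * params.nb_epsilon * (sr6**2 - sr6)))
    if include_noise and params.noise_sd > 0:
        if conf_id is None:
            raise ValueError("noisy oracle queries need a conf_id to seed the noise stream")
        e += float(_noise_rng(params, conf_id).normal(0.0, params.noise_sd))
    return e


def oracle_for(spec: ToyMoleculeSpec, params: EnergyParams, include_noise: bool = True):
    """Conformation -> energy callable over the analytic surface, recovering
    torsions from the Cartesian geometry."""

    def _oracle(conf: Conformation) -> float:
        tors = np.array(
            [
                dihedral(*(conf.coords[k] for k in range(i - 3, i + 1)))
                for i in range(3, conf.n_atoms)
            ]
        )
        return energy(tors, spec, params, conf_id=conf.conf_id, include_noise=include_noise)

    return _oracle


def _min_nonbonded_distance(conf: Conformation) -> float:
    i, j = _nonbonded_pairs(conf.n_atoms)
    return float(np.min(np.linalg.norm(conf.coords[i] - conf.coords[j], axis=1)))


def generate_study(
    spec: ToyMoleculeSpec | None = None,
    params: EnergyParams | None = None,
    study: StudyConfig | None = None,
    outdir: str | Path | None = None,
) -> list[Ensemble]:
    """Generate the multi-run study: one ensemble per run, energies attached.

    Frames are drawn per run from Normal(run_bias_r, jitter^2) torsions;
    geometries with a steric clash or any nonbonded contact below
    ``min_nb_distance`` are resampled (bounded retries, emulating the fact
    that relaxed reference snapshots contain no hard clashes). Fully
    reproducible from the config seeds. With ``outdir`` set, runs are written
    as ``run<r>.xyz`` plus a pooled ``energies.csv`` and a ``manifest.json``
    of all parameters.
    """
    spec = spec or ToyMoleculeSpec()
    params = params or default_energy_params(spec)
    study = study or StudyConfig()
    biases = study.run_bias or default_run_bias(spec, study)
    rng = np.random.default_rng(study.seed + 1)
    runs: list[Ensemble] = []
    for r, bias in enumerate(biases):
        confs = []
        for f in range(study.frames_per_run):
            for attempt in range(study.max_retries + 1):
                tors = rng.normal(bias, study.torsion_jitter_sd)
                conf = build_conformation(spec, tors, conf_id=f"run{r + 1}-{f:04d}")
                if not conf.clash and _min_nonbonded_distance(conf) >= study.min_nb_distance:
                    break
            else:
                raise RuntimeError(
                    f"run {r + 1}: resampling budget exhausted at frame {f}; "
                    "increase torsion_jitter_sd or relax min_nb_distance"
                )
            conf.energy = energy(tors, spec, params, conf_id=conf.conf_id)
            confs.append(conf)
        runs.append(Ensemble(confs, run_label=f"run{r + 1}"))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table: dict[str, float] = {}
        for r, ens in enumerate(runs):
            write_xyz(ens, outdir / f"run{r + 1}.xyz")
            table.update({c.conf_id: c.energy for c in ens})
        write_energy_table(table, outdir / "energies.csv")
        manifest = {
            "molecule": {
                "n_atoms": spec.n_atoms,
                "atomic_numbers": list(spec.atomic_numbers),
                "bond_length": spec.bond_length,
                "bond_angle": spec.bond_angle,
            },
            "energy_params": {
                "torsion_terms": [list(t) for t in params.torsion_terms],
                "nb_epsilon": params.nb_epsilon,
                "nb_sigma": params.nb_sigma,
                "noise_sd": params.noise_sd,
                "seed": params.seed,
            },
            "study": {
                "n_runs": study.n_runs,
                "frames_per_run": study.frames_per_run,
                "run_bias": [list(b) for b in biases],
                "torsion_jitter_sd": study.torsion_jitter_sd,
                "min_nb_distance": study.min_nb_distance,
                "seed": study.seed,
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return runs
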