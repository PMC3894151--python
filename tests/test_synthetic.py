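import math

import numpy as np
import pytest

import gpconf as g
from gpconf.synthetic import CLASH_DISTANCE, default_run_bias, dihedral


class TestBuildConformation:
    def test_all_trans_is_extended(self, toy_spec):
        nt = toy_spec.n_torsions
        trans = g.build_conformation(toy_spec, np.full(nt, np.pi))
        rng = np.random.default_rng(0)
        end = lambda c: np.linalg.norm(c.coords[-1] - c.coords[0])
        for _ in range(25):
            other = g.build_conformation(toy_spec, rng.uniform(-np.pi, np.pi, nt))
            assert end(trans) >= end(other)
        # planar zigzag: all atoms in one plane
        assert np.allclose(np.linalg.svd(trans.coords - trans.coords.mean(0))[1][2], 0, atol=1e-9)

    def test_deterministic(self, toy_spec):
        tors = np.linspace(-2, 2, toy_spec.n_torsions)
        a = g.build_conformation(toy_spec, tors)
        b = g.build_conformation(toy_spec, tors)
        np.testing.assert_array_equal(a.coords, b.coords)

    @pytest.mark.parametrize("seed", range(5))
    def test_dihedral_round_trip(self, seed):
        spec = g.ToyMoleculeSpec(n_atoms=6)
        rng = np.random.default_rng(seed)
        tors = rng.uniform(-np.pi, np.pi, spec.n_torsions)
        c = g.build_conformation(spec, tors)
        rec = [
            dihedral(*(c.coords[k] for k in range(i - 3, i + 1)))
            for i in range(3, spec.n_atoms)
        ]
        np.testing.assert_allclose(rec, tors, atol=1e-6)

    def test_butane_like_60_degrees(self):
        spec = g.ToyMoleculeSpec(n_atoms=6)
        tors = np.array([np.pi / 3, np.pi, np.pi])
        c = g.build_conformation(spec, tors)
        assert dihedral(*c.coords[:4]) == pytest.approx(np.pi / 3, abs=1e-6)

    def test_clash_flagged(self, toy_spec):
        folded = g.build_conformation(toy_spec, np.zeros(toy_spec.n_torsions))
        assert folded.clash
        d = folded.distance_matrix()
        iu = np.triu_indices(toy_spec.n_atoms, 1)
        assert d[iu].min() < CLASH_DISTANCE

    def test_wrong_torsion_count(self, toy_spec):
        with pytest.raises(ValueError, match="torsions"):
            g.build_conformation(toy_spec, np.zeros(2))

    def test_geometry_parameters_respected(self):
        spec = g.ToyMoleculeSpec(n_atoms=6, bond_length=1.2, bond_angle=109.5)
        c = g.build_conformation(spec, np.full(3, np.pi))
        d = np.linalg.norm(np.diff(c.coords, axis=0), axis=1)
        np.testing.assert_allclose(d, 1.2, atol=1e-12)
        v1 = c.coords[0] - c.coords[1]
        v2 = c.coords[2] - c.coords[1]
        ang = np.degrees(np.arccos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        assert ang == pytest.approx(109.5, abs=1e-9)


class TestEnergy:
    def test_null_surface(self, toy_spec):
        params = g.EnergyParams(
            torsion_terms=tuple((0.0, 1, 0.0) for _ in range(toy_spec.n_torsions)),
            nb_epsilon=0.0, noise_sd=0.0,
        )
        tors = np.random.default_rng(0).uniform(-np.pi, np.pi, toy_spec.n_torsions)
        assert g.energy(tors, toy_spec, params) == 0.0

    def test_cosine_extremes(self):
        spec = g.ToyMoleculeSpec(n_atoms=6)
        terms = [(0.0, 1, 0.0)] * spec.n_torsions
        terms[0] = (10.0, 1, 0.0)
        params = g.EnergyParams(torsion_terms=tuple(terms), nb_epsilon=0.0, noise_sd=0.0)
        at = lambda phi: g.energy([phi, np.pi, np.pi], spec, params)
        assert at(np.pi) == pytest.approx(0.0)
        assert at(0.0) == pytest.approx(20.0)

    def test_noise_is_reproducible_per_conformer(self, toy_spec):
        params = g.default_energy_params(toy_spec)
        tors = np.full(toy_spec.n_torsions, np.pi)
        e1 = g.energy(tors, toy_spec, params, conf_id="abc")
        e2 = g.energy(tors, toy_spec, params, conf_id="abc")
        e3 = g.energy(tors, toy_spec, params, conf_id="abd")
        assert e1 == e2 != e3
        assert g.energy(tors, toy_spec, params, include_noise=False) != e1

    def test_noisy_query_requires_conf_id(self, toy_spec):
        params = g.default_energy_params(toy_spec)
        with pytest.raises(ValueError, match="conf_id"):
            g.energy(np.full(toy_spec.n_torsions, np.pi), toy_spec, params)

    @pytest.mark.parametrize("seed", range(4))
    def test_double_implementation_oracle(self, toy_spec, seed):
        """Agreement with an independently coded evaluator (plain Python loops)."""
        params = g.default_energy_params(toy_spec)
        rng = np.random.default_rng(seed)
        tors = rng.uniform(-np.pi, np.pi, toy_spec.n_torsions)

        amps, mults, phases = params.arrays()
        ref = 0.0
        for a, m, ph, t in zip(amps, mults, phases, tors):
            ref += a * (1.0 + math.cos(m * t - ph))
        coords = g.build_conformation(toy_spec, tors).coords
        n = toy_spec.n_atoms
        for i in range(n):
            for j in range(i + 4, n):
                r = math.dist(coords[i], coords[j])
                ref += 4.0 * params.nb_epsilon * (
                    (params.nb_sigma / r) ** 12 - (params.nb_sigma / r) ** 6
                )
        got = g.energy(tors, toy_spec, params, include_noise=False)
        assert got == pytest.approx(ref, abs=1e-9)

    def test_oracle_for_matches_generated_energies(self, toy_spec, energy_params, small_study):
        oracle = g.oracle_for(toy_spec, energy_params)
        for conf in small_study[0][0:10]:
            assert oracle(conf) == pytest.approx(conf.energy, abs=1e-9)


class TestGenerateStudy:
    def test_default_study_counts(self, full_study):
        assert len(full_study) == 4
        assert [len(r) for r in full_study] == [240] * 4
        ids = [c.conf_id for r in full_study for c in r]
        assert len(set(ids)) == 960

    def test_byte_identical_output(self, tmp_path, toy_spec, energy_params):
        study = g.StudyConfig(n_runs=2, frames_per_run=15, seed=5)
        g.generate_study(toy_spec, energy_params, study, outdir=tmp_path / "a")
        g.generate_study(toy_spec, energy_params, study, outdir=tmp_path / "b")
        for name in ("run1.xyz", "run2.xyz", "energies.csv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_runs_occupy_distinct_basins(self, toy_spec, full_study):
        """Between-run mean torsions separate by > 3x the within-run spread."""
        def torsions_of(run):
            return np.array([
                [dihedral(*(c.coords[k] for k in range(i - 3, i + 1)))
                 for i in range(3, toy_spec.n_atoms)]
                for c in run
            ])

        tors = [torsions_of(r) for r in full_study]
        within = np.mean([t.std(axis=0).mean() for t in tors])
        for a in range(len(tors)):
            for b in range(a + 1, len(tors)):
                gap = np.abs(tors[a].mean(axis=0) - tors[b].mean(axis=0)).max()
                assert gap > 3 * within

    def test_no_clashes_and_steric_filter_respected(self, full_study):
        study = g.StudyConfig()
        for run in full_study:
            for conf in run[0:20]:
                assert not conf.clash
                d = conf.distance_matrix()
                i, j = np.triu_indices(conf.n_atoms, 4)
                assert d[i, j].min() >= study.min_nb_distance

    def test_duplicate_run_bias_rejected(self):
        bias = tuple(np.full(9, np.pi))
        with pytest.raises(ValueError, match="distinct"):
            g.StudyConfig(n_runs=2, run_bias=(bias, bias))

    def test_default_biases_distinct_and_near_trans(self, toy_spec):
        study = g.StudyConfig(seed=0)
        biases = default_run_bias(toy_spec, study)
        assert len(set(biases)) == 4
        for row in biases:
            assert np.all(np.abs(np.array(row) - np.pi) <= np.pi / 3 + 1e-12)

    def test_resampling_budget_error(self, toy_spec, energy_params):
        study = g.StudyConfig(n_runs=1, frames_per_run=2, min_nb_distance=50.0,
                              max_retries=5, seed=0)
        with pytest.raises(RuntimeError, match="budget"):
            g.generate_study(toy_spec, energy_params, study)

    def test_energy_table_written_and_consistent(self, tmp_path, toy_spec, energy_params):
        study = g.StudyConfig(n_runs=1, frames_per_run=10, seed=2)
        runs = g.generate_study(toy_spec, energy_params, study, outdir=tmp_path)
        table = g.read_energy_table(tmp_path / "energies.csv")
        ens = g.read_xyz(tmp_path / "run1.xyz")
        assert set(table) == set(ens.conf_ids)
        for conf in runs[0]:
            assert table[conf.conf_id] == pytest.approx(conf.energy, abs=1e-9)
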