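"""Coarse-grained sampling: internal coordinates, moves, exploration and
discrepancy-guided refinement."""

import numpy as np
import pytest
from scipy import stats

from pfkit._geom import rmsd, torsion
from pfkit.exchange import protection_factors
from pfkit.fitting import NMRFitReport, nmr_fit
from pfkit.fixtures import make_ideal_helix, synthesize_observation
from pfkit.sampler import (
    CLASH_DISTANCE,
    DihedralVector,
    Fragment,
    SamplerConfig,
    _pick_fragment,
    clash_score,
    discrepancy_weights,
    explore,
    extract_dihedrals,
    iterate_refine,
    propose_move,
    rebuild_conformation,
)
from pfkit.structures import Atom

from conftest import make_random_coil


def backbone_coords(conf, names=("N", "CA", "C", "O")):
    return np.array([r.coord(n) for r in conf for n in names])


class TestDihedrals:
    def test_helix_angles(self, helix12):
        dv = extract_dihedrals(helix12)
        assert np.allclose(dv.phi[1:], -57.0, atol=1.0)
        assert np.allclose(dv.psi[:-1], -47.0, atol=1.0)
        assert np.isnan(dv.phi[0]) and np.isnan(dv.psi[-1])

    def test_extended_angles(self, extended12):
        dv = extract_dihedrals(extended12)
        assert np.all(np.abs(np.abs(dv.phi[1:])) >= 179.0)
        assert np.all(np.abs(np.abs(dv.psi[:-1])) >= 179.0)

    def test_roundtrip_on_ideal_fixture(self, helix12):
        rebuilt = rebuild_conformation(extract_dihedrals(helix12), helix12)
        assert rmsd(backbone_coords(helix12), backbone_coords(rebuilt)) <= 1e-3

    def test_roundtrip_on_random_ideal_coil(self):
        coil = make_random_coil(15, 9)
        rebuilt = rebuild_conformation(extract_dihedrals(coil), coil)
        assert rmsd(backbone_coords(coil), backbone_coords(rebuilt)) <= 1e-3

    def test_missing_backbone_atom_names_residue(self, helix12):
        conf = helix12.copy()
        conf.residues[6].atoms = [a for a in conf.residues[6].atoms if a.name != "CA"]
        with pytest.raises(ValueError, match="7"):
            extract_dihedrals(conf)


class TestRebuild:
    def test_perturbation_is_downstream_only(self):
        coil = make_random_coil(10, 2)
        dv = extract_dihedrals(coil)
        dv2 = dv.copy()
        k = 5  # flip psi of residue 5
        dv2.psi[k - 1] = dv2.psi[k - 1] - 180.0
        a = rebuild_conformation(dv, coil)
        b = rebuild_conformation(dv2, coil)
        for i in range(1, k):
            np.testing.assert_allclose(
                backbone_coords(a)[4 * (i - 1):4 * i - 1],
                backbone_coords(b)[4 * (i - 1):4 * i - 1],
                atol=1e-9,
            )
        assert np.linalg.norm(a.residue(k + 1).coord("CA")
                              - b.residue(k + 1).coord("CA")) > 1.0

    def test_helical_dihedrals_give_helical_rise(self, extended12):
        n = len(extended12)
        dv = DihedralVector(phi=np.full(n, -57.0), psi=np.full(n, -47.0))
        helixish = rebuild_conformation(dv, extended12)
        ca = np.array([r.coord("CA") for r in helixish])
        steps = ca[1:] - ca[:-1]
        axis = steps.mean(axis=0)
        axis /= np.linalg.norm(axis)
        rise = float(np.mean(steps @ axis))
        assert rise == pytest.approx(1.5, abs=0.15)

    def test_length_mismatch_rejected(self, helix12):
        dv = DihedralVector(phi=np.zeros(5), psi=np.zeros(5))
        with pytest.raises(ValueError):
            rebuild_conformation(dv, helix12)

    def test_omega_forced_trans(self):
        coil = make_random_coil(8, 3)
        rebuilt = rebuild_conformation(extract_dihedrals(coil), coil)
        for i in range(1, len(rebuilt)):
            om = torsion(
                rebuilt.residue(i).coord("CA"), rebuilt.residue(i).coord("C"),
                rebuilt.residue(i + 1).coord("N"), rebuilt.residue(i + 1).coord("CA"),
            )
            assert abs(abs(om) - 180.0) < 1e-6


class TestClashScore:
    def test_clash_free_structure_scores_zero(self, helix12):
        assert clash_score(helix12) == 0.0

    def test_forced_pair_contribution(self):
        from conftest import make_toy_chain

        conf = make_toy_chain(6)  # residues 100 A apart: no incidental clashes
        assert clash_score(conf) == 0.0
        # plant a pair of atoms 2.0 A apart owned by residues 1 and 4
        conf.residue(1).atoms.append(Atom("CX", "C", [50.0, 50.0, 0.0]))
        conf.residue(4).atoms.append(Atom("CY", "C", [50.0, 52.0, 0.0]))
        assert clash_score(conf) == pytest.approx((CLASH_DISTANCE - 2.0) ** 2)

    def test_adjacent_residues_do_not_count(self):
        conf = make_ideal_helix(6)
        # bonded neighbours sit well under 3 A but |i-j| < 2 is excluded
        assert clash_score(conf) == 0.0

    def test_brute_force_oracle(self):
        conf = make_random_coil(20, 7)
        coords, owner = conf.heavy_atoms()
        expected = 0.0
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                if abs(owner[i] - owner[j]) < 2:
                    continue
                d = np.linalg.norm(coords[i] - coords[j])
                if d < CLASH_DISTANCE:
                    expected += (CLASH_DISTANCE - d) ** 2
        assert clash_score(conf) == pytest.approx(expected, rel=1e-12)


class TestProposeMove:
    def test_upstream_coordinates_unchanged(self):
        coil = make_random_coil(10, 4)
        config = SamplerConfig(
            perturbation_sigma=10.0,
            fragments=[Fragment("f", frozenset({5}))],
            seed=0,
        )
        rng = np.random.default_rng(0)
        moved = propose_move(coil, config, rng)
        for i in range(1, 5):
            np.testing.assert_allclose(coil.residue(i).coord("CA"),
                                       moved.residue(i).coord("CA"), atol=1e-9)

    def test_small_sigma_limit_stays_close(self, helix12):
        config = SamplerConfig(perturbation_sigma=1e-6)
        rng = np.random.default_rng(1)
        moved = propose_move(helix12, config, rng)
        assert rmsd(backbone_coords(helix12), backbone_coords(moved)) < 1e-4

    def test_fragment_selection_frequency(self):
        fragments = [Fragment("A", frozenset({1}), 3.0),
                     Fragment("B", frozenset({2}), 1.0)]
        rng = np.random.default_rng(123)
        picks = sum(_pick_fragment(fragments, rng).id == "A" for _ in range(10_000))
        assert abs(picks / 10_000 - 0.75) <= 0.02

    def test_selection_matches_weights_chi_square(self):
        weights = [5.0, 2.0, 2.0, 1.0]
        fragments = [Fragment(str(k), frozenset({k + 1}), w)
                     for k, w in enumerate(weights)]
        rng = np.random.default_rng(99)
        counts = np.zeros(4)
        for _ in range(10_000):
            counts[int(_pick_fragment(fragments, rng).id)] += 1
        expected = np.array(weights) / sum(weights) * 10_000
        chi2 = float(np.sum((counts - expected) ** 2 / expected))
        assert chi2 < stats.chi2.ppf(0.99, df=3)

    def test_zero_weights_rejected(self, helix12):
        config = SamplerConfig(fragments=[Fragment("f", frozenset({3}), 0.0)])
        with pytest.raises(ValueError, match="zero"):
            propose_move(helix12, config, np.random.default_rng(0))


class TestExplore:
    def test_disabled_filter_yields_requested_count(self, helix12):
        ens = explore(helix12, SamplerConfig(n_conformations=5, seed=3,
                                             energy_threshold=np.inf))
        assert len(ens) == 5

    def test_accepted_members_satisfy_threshold(self):
        coil = make_random_coil(12, 5)
        thr = 1.1 * clash_score(coil) + 0.5
        ens = explore(coil, SamplerConfig(n_conformations=8, seed=4,
                                          perturbation_sigma=8.0,
                                          energy_threshold=thr))
        for conf in ens:
            assert clash_score(conf) <= thr

    def test_tiny_sigma_keeps_members_near_start(self, helix12):
        ens = explore(helix12, SamplerConfig(n_conformations=4, seed=5,
                                             perturbation_sigma=1e-4,
                                             energy_threshold=0.0))
        for conf in ens:
            assert rmsd(backbone_coords(helix12), backbone_coords(conf)) < 1e-2

    def test_seed_determinism(self, helix12):
        cfg = SamplerConfig(n_conformations=4, seed=11, perturbation_sigma=3.0)
        e1 = explore(helix12, cfg)
        e2 = explore(helix12, cfg)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(backbone_coords(a), backbone_coords(b))
        e3 = explore(helix12, SamplerConfig(n_conformations=4, seed=12,
                                            perturbation_sigma=3.0))
        assert not np.allclose(backbone_coords(e1[0]), backbone_coords(e3[0]))

    def test_impossible_threshold_raises(self, helix12):
        with pytest.raises(RuntimeError, match="threshold"):
            explore(helix12, SamplerConfig(n_conformations=3, seed=6,
                                           perturbation_sigma=60.0,
                                           energy_threshold=-1.0,
                                           max_attempts_per_accept=3))


class TestDiscrepancyWeights:
    @staticmethod
    def _report(errors):
        return NMRFitReport(per_residue_error=dict(errors),
                            mean_abs_error=float(np.mean(list(errors.values()))),
                            r_squared=None, r_sign=None, n=len(errors))

    def test_uniform_errors_keep_uniform_weights(self):
        fragments = [Fragment(str(k), frozenset({2 * k + 1, 2 * k + 2}))
                     for k in range(4)]
        report = self._report({i: 1.0 for i in range(1, 9)})
        out = discrepancy_weights(report, fragments, boost=4.0)
        weights = [f.weight for f in out]
        assert np.allclose(weights, weights[0])
        assert sum(weights) == pytest.approx(1.0)

    def test_single_hot_fragment_gets_boost_share(self):
        k, boost = 4, 4.0
        fragments = [Fragment(str(j), frozenset({j + 1})) for j in range(k)]
        report = self._report({1: 5.0, 2: 0.0, 3: 0.0, 4: 0.0})
        out = discrepancy_weights(report, fragments, boost=boost)
        assert out[0].weight == pytest.approx(boost / (boost + k - 1))
        for f in out[1:]:
            assert f.weight == pytest.approx(1.0 / (boost + k - 1))

    def test_top_quartile_matches_independent_sort(self):
        rng = np.random.default_rng(8)
        errors = {i: float(rng.uniform(0, 10)) for i in range(1, 17)}
        fragments = [Fragment(str(j), frozenset(range(2 * j + 1, 2 * j + 3)))
                     for j in range(8)]
        out = discrepancy_weights(self._report(errors), fragments, boost=3.0)
        disc = [np.mean([errors[i] for i in f.residue_indices]) for f in fragments]
        top = set(np.argsort(disc)[::-1][:2])  # ceil(8/4) = 2
        boosted = {j for j, f in enumerate(out)
                   if f.weight > min(x.weight for x in out) * 1.5}
        assert boosted == top

    def test_no_overlap_raises(self):
        fragments = [Fragment("f", frozenset({50}))]
        with pytest.raises(ValueError, match="overlap"):
            discrepancy_weights(self._report({1: 1.0}), fragments)


class TestIterateRefine:
    def test_planted_optimum_stops_immediately(self, helix12):
        observed = synthesize_observation(helix12, mode="nmr", noise_sigma=0.0)
        config = SamplerConfig(n_conformations=5, seed=1)
        best, trace = iterate_refine(helix12, observed, config, n_rounds=3)
        assert trace.best_scores == [0.0]
        assert nmr_fit(protection_factors(best), observed).mean_abs_error == 0.0

    def test_best_so_far_nonincreasing(self):
        start = make_ideal_helix(16)
        target = propose_move(
            start, SamplerConfig(perturbation_sigma=8.0), np.random.default_rng(77)
        )
        observed = synthesize_observation(target, mode="nmr")
        config = SamplerConfig(n_conformations=10, seed=2, perturbation_sigma=8.0,
                               energy_threshold=1.0)
        _, trace = iterate_refine(start, observed, config, n_rounds=3)
        assert all(b <= a + 1e-12 for a, b in zip(trace.best_scores,
                                                  trace.best_scores[1:]))

    def test_recovery_beats_start_with_preregistered_seed(self):
        from conftest import plant_recovery_case

        start = make_ideal_helix(16)
        fragments = [Fragment(f"seg{k}", frozenset(range(4 * k + 1, 4 * k + 5)))
                     for k in range(4)]
        _, observed, start_error = plant_recovery_case(start, 5, fragments)
        assert start_error > 0
        config = SamplerConfig(n_conformations=80, seed=3, perturbation_sigma=4.0,
                               energy_threshold=2.0, fragments=fragments)
        _, trace = iterate_refine(start, observed, config, n_rounds=3)
        assert trace.best_scores[-1] < start_error
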