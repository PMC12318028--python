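"""Templates, box construction and the pairwise energy model."""

import numpy as np
import pytest

from solvnet.model import (
    K_COULOMB,
    Configuration,
    MoleculeTemplate,
    PackingError,
    PotentialSet,
    Site,
    SingularityError,
    ammonia_template,
    build_box,
    lj_site_template,
    minimum_image,
    molecule_energy,
    pair_energy,
    total_energy,
    water_template,
)
from solvnet.io import config_from_molecules


def brute_force_pair_energy(cfg, a, b, potentials):
    """Independent O(n^2) site-loop evaluation of the same convention."""
    rc = potentials.effective_cutoff(cfg.box_length)
    sa, sb = cfg.mol_slice(a), cfg.mol_slice(b)
    total = 0.0
    for i in range(sa.start, sa.stop):
        for j in range(sb.start, sb.stop):
            d = minimum_image(cfg.positions[j] - cfg.positions[i],
                              cfg.box_length)
            r = float(np.linalg.norm(d))
            if rc is not None and r > rc:
                continue
            eps = np.sqrt(cfg.lj_eps[i] * cfg.lj_eps[j])
            if eps > 0:
                sg = 0.5 * (cfg.lj_sigma[i] + cfg.lj_sigma[j])
                total += 4 * eps * ((sg / r) ** 12 - (sg / r) ** 6)
                if rc is not None:
                    total -= 4 * eps * ((sg / rc) ** 12 - (sg / rc) ** 6)
            qq = cfg.charges[i] * cfg.charges[j]
            if qq != 0.0:
                if rc is not None:
                    total += potentials.coulomb_k * qq * (
                        1 / r + r / rc ** 2 - 2 / rc)
                else:
                    total += potentials.coulomb_k * qq / r
    return total


class TestTemplates:
    def test_water_geometry(self):
        w = water_template()
        xyz = w.coordinates()
        assert np.linalg.norm(xyz[1] - xyz[0]) == pytest.approx(1.0)
        cos = np.dot(xyz[1] - xyz[0], xyz[2] - xyz[0])
        assert np.degrees(np.arccos(cos)) == pytest.approx(109.47, abs=1e-6)

    def test_ammonia_geometry(self):
        a = ammonia_template()
        xyz = a.coordinates()
        for k in (1, 2, 3):
            assert np.linalg.norm(xyz[k]) == pytest.approx(1.01)
        u1, u2 = xyz[1] / 1.01, xyz[2] / 1.01
        assert np.degrees(np.arccos(np.clip(u1 @ u2, -1, 1))) == \
            pytest.approx(106.7, abs=1e-6)

    def test_templates_are_neutral(self):
        with pytest.raises(ValueError):
            MoleculeTemplate("bad", (
                Site("H_W", "H", (0, 0, 0), 0.5, 0.0, 0.0),))


class TestBuildBox:
    def test_box_length_from_number_density(self):
        tpl = lj_site_template()
        cfg = build_box([tpl], {"lj": 100}, number_density=0.0334, seed=0)
        assert cfg.box_length == pytest.approx((100 / 0.0334) ** (1 / 3))
        assert cfg.number_density == pytest.approx(0.0334, rel=1e-9)

    def test_mass_density_bookkeeping(self):
        cfg = build_box([water_template()], {"water": 64},
                        mass_density=1.0, seed=0)
        # 64 waters at 1 g/cm^3 -> 0.1 sites/A^3 (the textbook value)
        assert cfg.number_density == pytest.approx(0.100, abs=0.002)

    def test_deterministic_given_seed(self):
        tpls = [water_template(), ammonia_template()]
        a = build_box(tpls, {"water": 10, "ammonia": 3}, mass_density=0.92,
                      seed=1)
        b = build_box(tpls, {"water": 10, "ammonia": 3}, mass_density=0.92,
                      seed=1)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_min_distance_enforced(self):
        cfg = build_box([water_template()], {"water": 20}, mass_density=1.0,
                        seed=3)
        d = minimum_image(cfg.positions[None] - cfg.positions[:, None],
                          cfg.box_length)
        r = np.linalg.norm(d, axis=-1)
        inter = cfg.mol_index[None] != cfg.mol_index[:, None]
        assert r[inter].min() >= 1.5

    def test_packing_failure_signalled(self):
        with pytest.raises(PackingError):
            build_box([water_template()], {"water": 50}, mass_density=5.0,
                      seed=0, max_tries=20)

    def test_requires_exactly_one_density(self):
        with pytest.raises(ValueError):
            build_box([water_template()], {"water": 5}, seed=0)
        with pytest.raises(ValueError):
            build_box([water_template()], {"water": 5}, mass_density=1.0,
                      number_density=0.1, seed=0)


class TestPairEnergy:
    def test_two_point_charges_hand_value(self):
        # +-0.8476 e at 2.0 A, no LJ; partner charges parked far away
        tpl = lj_site_template(label="LJ", epsilon=0.0, sigma=0.0)
        plus = MoleculeTemplate("plus", (
            Site("H_W", "H", (0, 0, 0), 0.8476, 0, 0),
            Site("H_W", "H", (0, 0, 40.0), -0.8476, 0, 0)))
        minus = MoleculeTemplate("minus", (
            Site("H_W", "H", (0, 0, 0), -0.8476, 0, 0),
            Site("H_W", "H", (0, 0, -40.0), 0.8476, 0, 0)))
        cfg = config_from_molecules(200.0, [
            (plus, np.array([[0, 0, 50], [0, 0, 90]], float)),
            (minus, np.array([[2.0, 0, 50], [2.0, 0, 10]], float)),
        ])
        e = pair_energy(cfg, 0, 1, PotentialSet(cutoff=None))
        # leading term: -k_c q^2 / 2.0; the parked charges contribute O(k q^2/40)
        lead = -K_COULOMB * 0.8476 ** 2 / 2.0
        assert lead == pytest.approx(-499.07, abs=0.1)
        assert e == pytest.approx(
            brute_force_pair_energy(cfg, 0, 1, PotentialSet(cutoff=None)),
            rel=1e-12)

    def test_neutral_lj_free_molecules_have_zero_energy(self):
        tpl = lj_site_template(epsilon=0.0, sigma=0.0)
        cfg = config_from_molecules(50.0, [
            (tpl, np.array([[10.0, 10, 10]])),
            (tpl, np.array([[14.0, 10, 10]])),
        ])
        assert pair_energy(cfg, 0, 1) == 0.0

    @pytest.mark.parametrize("cutoff", [None, 8.0])
    def test_matches_brute_force_oracle(self, cutoff):
        cfg = build_box([water_template(), ammonia_template()],
                        {"water": 8, "ammonia": 3}, mass_density=0.92,
                        seed=5)
        pots = PotentialSet(cutoff=cutoff)
        for a, b in [(0, 1), (2, 9), (7, 10)]:
            assert pair_energy(cfg, a, b, pots) == pytest.approx(
                brute_force_pair_energy(cfg, a, b, pots), rel=1e-10)

    def test_exact_exchange_symmetry(self):
        cfg = build_box([water_template()], {"water": 12}, mass_density=1.0,
                        seed=6)
        pots = PotentialSet(cutoff=None)
        assert pair_energy(cfg, 3, 7, pots) == pair_energy(cfg, 7, 3, pots)

    def test_singularity_signalled(self):
        tpl = water_template()
        xyz = tpl.coordinates()
        cfg = config_from_molecules(50.0, [(tpl, xyz + 10.0),
                                           (tpl, xyz + 10.0)])
        with pytest.raises(SingularityError):
            pair_energy(cfg, 0, 1)

    def test_same_molecule_rejected(self):
        cfg = build_box([water_template()], {"water": 3}, mass_density=1.0,
                        seed=0)
        with pytest.raises(ValueError):
            pair_energy(cfg, 1, 1)


class TestTotalEnergy:
    def test_ideal_gas_zero(self):
        tpl = lj_site_template(epsilon=0.0, sigma=0.0)
        cfg = build_box([tpl], {"lj": 30}, number_density=0.01, seed=2,
                        min_distance=0.5)
        assert total_energy(cfg, PotentialSet(cutoff=None)) == 0.0

    def test_three_molecule_additivity(self):
        cfg = build_box([water_template()], {"water": 3}, mass_density=0.8,
                        seed=4)
        pots = PotentialSet(cutoff=None)
        expected = sum(pair_energy(cfg, a, b, pots)
                       for a, b in [(0, 1), (0, 2), (1, 2)])
        assert total_energy(cfg, pots) == pytest.approx(expected, rel=1e-12)

    def test_matches_pairwise_oracle_on_liquid_box(self):
        cfg = build_box([water_template(), ammonia_template()],
                        {"water": 15, "ammonia": 5}, mass_density=0.92,
                        seed=9)
        pots = PotentialSet(cutoff=7.0)
        oracle = sum(
            brute_force_pair_energy(cfg, a, b, pots)
            for a in range(cfg.n_molecules)
            for b in range(a + 1, cfg.n_molecules))
        assert total_energy(cfg, pots) == pytest.approx(oracle, rel=1e-9)

    def test_translation_invariance(self):
        cfg = build_box([water_template()], {"water": 20}, mass_density=1.0,
                        seed=11)
        pots = PotentialSet(cutoff=8.0)
        e0 = total_energy(cfg, pots)
        shifted = cfg.copy()
        shifted.positions = (shifted.positions + 4.321) % cfg.box_length
        assert total_energy(shifted, pots) == pytest.approx(e0, abs=1e-8)


class TestMinimumImage:
    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(0)
        box = 10.0
        a = rng.uniform(0, box, (50, 3))
        b = rng.uniform(0, box, (50, 3))
        d_ab = minimum_image(b - a, box)
        d_ba = minimum_image(a - b, box)
        np.testing.assert_allclose(d_ab, -d_ba, atol=1e-12)
        assert np.linalg.norm(d_ab, axis=1).max() <= np.sqrt(3) / 2 * box
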