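import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import chisquare

from qtaimnet.chemsys import Molecule
from qtaimnet.qct_properties import reconstruct_E, reconstruct_N
from qtaimnet.surrogate_data import (
    BindingEvent,
    GenerationError,
    SurrogateParams,
    chon_params,
    diatomic_charge_closed_form,
    generate_binding_trajectory,
    generate_dataset,
    generate_geometry,
    label_molecule,
    surrogate_charges,
    surrogate_delta,
    surrogate_electron_structure,
    surrogate_iqa,
    water_params,
)
from qtaimnet import xcai_analysis as xcai


def diatomic(z1, z2, r):
    return Molecule((z1, z2), np.array([[0.0, 0, 0], [0, 0, float(r)]]))


class TestGeometry:
    def test_single_atom(self, chon):
        mol = generate_geometry(chon, seed=5, M=1)
        assert mol.n_atoms == 1
        assert np.all(np.isfinite(mol.R))

    def test_min_distance_exhaustive(self, chon):
        for seed in range(20):
            mol = generate_geometry(chon, seed=seed)
            d = mol.distance_matrix()
            np.fill_diagonal(d, np.inf)
            assert d.min() >= chon.min_distance

    def test_determinism(self, chon):
        a = generate_geometry(chon, seed=77)
        b = generate_geometry(chon, seed=77)
        assert a.Z == b.Z and np.array_equal(a.R, b.R)

    def test_impossible_packing_raises(self, chon):
        from dataclasses import replace

        cramped = replace(chon, box_edge=1.0, min_distance=2.5, m_range=(8, 8))
        with pytest.raises(GenerationError, match="box_edge"):
            generate_geometry(cramped, seed=0, max_tries=20)

    def test_element_histogram_matches_pool(self, chon):
        counts = {z: 0 for z, _ in chon.element_pool}
        total = 0
        for seed in range(400):
            mol = generate_geometry(chon, seed=seed, M=5)
            for z in mol.Z:
                counts[z] += 1
                total += 1
        expected = [p * total for _, p in chon.element_pool]
        stat, pvalue = chisquare([counts[z] for z, _ in chon.element_pool], expected)
        assert pvalue > 1e-4  # multinomial noise only


class TestCharges:
    def test_homonuclear_diatomic_zero(self, chon):
        q = surrogate_charges(diatomic(8, 8, 2.0), chon)
        assert np.allclose(q, 0.0, atol=1e-12)

    def test_sign_follows_electronegativity(self, chon):
        # chi(O) > chi(H): H donates, O accepts
        q = surrogate_charges(diatomic(1, 8, 1.8), chon)
        assert q[0] > 0 > q[1]

    def test_closed_form_oracle(self):
        """Independent oracle: 1D constrained minimization of the two-site
        energy, compared against both the closed form and the KKT solve."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            chi1, chi2 = rng.uniform(0.1, 1.0, 2)
            eta1, eta2 = rng.uniform(1.5, 3.0, 2)
            r = rng.uniform(1.5, 4.0)
            params = SurrogateParams(
                chi={1: chi1, 8: chi2},
                eta={1: eta1, 8: eta2},
                s={1: 0.4, 8: 0.8},
                r0={1: 0.35, 8: 0.65},
                e0={1: -0.5, 8: -75.0},
                element_pool=((1, 0.5), (8, 0.5)),
            )
            q = surrogate_charges(diatomic(1, 8, r), params)
            analytic = diatomic_charge_closed_form(chi1, chi2, eta1, eta2, r)
            assert abs(q[0] - analytic) <= 1e-12
            # numerical minimization oracle (independent of both routes)
            def energy(q1):
                return (
                    chi1 * q1
                    - chi2 * q1
                    + 0.5 * (eta1 + eta2) * q1 * q1
                    - q1 * q1 / max(r, params.r_floor)
                )

            res = minimize_scalar(energy, bounds=(-5, 5), method="bounded",
                                  options={"xatol": 1e-12})
            assert abs(q[0] - res.x) <= 1e-7

    def test_neutrality_many_atom(self, chon, random_molecules):
        for mol in random_molecules[:10]:
            q = surrogate_charges(mol, chon)
            assert abs(q.sum()) <= 1e-12


class TestElectronStructure:
    def test_dissociation_limit(self, chon):
        _, lam, delta = surrogate_electron_structure(diatomic(1, 8, 60.0), chon)
        assert delta[0] <= 1e-12
        N_A, lam2, _ = surrogate_electron_structure(diatomic(1, 8, 60.0), chon)
        assert np.allclose(lam2, N_A, atol=1e-10)

    def test_sum_rule_closure(self, chon, random_molecules):
        for mol in random_molecules[:10]:
            N_A, lam, delta = surrogate_electron_structure(mol, chon)
            assert abs(reconstruct_N(lam, delta) - sum(mol.Z)) <= 1e-10

    def test_delta_at_reference_radius(self, chon):
        r0 = chon.pair_r0(1, 8)
        delta = surrogate_delta(diatomic(1, 8, r0), chon)
        assert delta[0] == pytest.approx(chon.s[1] * chon.s[8], abs=1e-12)

    def test_nonnegativity(self, chon, random_molecules):
        for mol in random_molecules:
            _, lam, delta = surrogate_electron_structure(mol, chon)
            assert np.all(lam >= 0) and np.all(delta >= 0)

    def test_negative_lambda_raises(self):
        # pathological bond-order prefactors drive lambda(H) below zero
        bad = chon_params()
        from dataclasses import replace

        bad = replace(bad, s={1: 8.0, 6: 8.0, 7: 8.0, 8: 8.0}, delta_max=50.0)
        mol = Molecule(
            (1, 1, 1, 1),
            np.array([[0, 0, 0], [1.8, 0, 0], [0, 1.8, 0], [0, 0, 1.8]], dtype=float),
        )
        with pytest.raises(GenerationError, match="localization"):
            surrogate_electron_structure(mol, bad)


class TestIqaSurrogate:
    def test_dissociation_limit(self, chon):
        mol = diatomic(8, 8, 80.0)
        E_intra, E_inter, E_total = surrogate_iqa(mol, chon)
        assert abs(E_inter[0]) <= 1e-10
        assert E_total == pytest.approx(sum(chon.e0[z] for z in mol.Z), abs=1e-8)

    def test_energy_closure(self, chon, random_molecules):
        for mol in random_molecules[:10]:
            E_intra, E_inter, E_total = surrogate_iqa(mol, chon)
            assert abs(reconstruct_E(E_intra, E_inter) - E_total) <= 1e-12

    def test_coulomb_term_sign_symmetric(self, chon):
        mol = diatomic(1, 8, 2.0)
        q = surrogate_charges(mol, chon)
        _, E_inter_a, _ = surrogate_iqa(mol, chon, q=q)
        _, E_inter_b, _ = surrogate_iqa(mol, chon, q=-q)
        assert E_inter_a[0] == pytest.approx(E_inter_b[0], abs=1e-14)


class TestDataset:
    def test_determinism(self, chon, tmp_path):
        from qtaimnet.chemsys import write_dataset

        a, _ = generate_dataset(30, chon, seed=1)
        b, _ = generate_dataset(30, chon, seed=1)
        pa, pb = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_dataset(a, pa)
        write_dataset(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_all_records_pass_sum_rules(self, small_dataset):
        from qtaimnet.qct_properties import sumrule_report

        for rec in small_dataset:
            assert all(abs(v) <= 1e-10 for v in sumrule_report(rec).values())

    def test_label_smoothness(self, chon):
        # labels vary continuously with geometry
        mol = generate_geometry(chon, seed=9, M=6)
        base = label_molecule(mol, chon)
        prev = np.inf
        for h in (1e-2, 1e-3, 1e-4):
            R = np.asarray(mol.R).copy()
            R[0, 0] += h
            rec = label_molecule(Molecule(mol.Z, R), chon)
            diff = max(
                np.max(np.abs(rec.props_1p["q"] - base.props_1p["q"])),
                np.max(np.abs(rec.props_2p["delta"] - base.props_2p["delta"])),
            )
            assert diff < prev
            prev = diff
        assert prev <= 1e-3

    def test_noise_preserves_stored_totals(self):
        params = chon_params(seed=2, sigma_noise=0.01)
        records, _ = generate_dataset(10, params, seed=2)
        for rec in records:
            # totals stored before noise: residuals now reflect the noise,
            # not the closure
            E = reconstruct_E(rec.props_1p["E_intra"], rec.props_2p["E_inter"])
            assert abs(E - rec.props_1p["E_total"][0]) > 0
            assert abs(E - rec.props_1p["E_total"][0]) < 1.0

    def test_water_preset_elements(self):
        records, _ = generate_dataset(10, water_params(), seed=4)
        seen = {z for rec in records for z in rec.molecule.Z}
        assert seen <= {1, 8}


class TestBindingTrajectory:
    def test_single_event_single_interior_maximum(self, chon):
        events = [BindingEvent("approach", "A", 50, 200, 350)]
        frames, groups, truth = generate_binding_trajectory(400, events)
        series = np.array(
            [
                xcai.group_delocalization(
                    surrogate_delta(f, chon), f.n_atoms, groups["guest"], groups["A"]
                )
                for f in frames
            ]
        )
        peak = int(np.argmax(series))
        assert abs(peak - 200) <= 1
        # strictly one interior local maximum region on the smoothed series
        interior = series[1:-1]
        rising = np.diff(series) > 1e-12
        sign_changes = np.sum(np.diff(rising.astype(int)) != 0)
        assert sign_changes <= 2

    def test_null_trajectory_flat(self, chon):
        frames, groups, truth = generate_binding_trajectory(50, [])
        vals = [
            xcai.group_delocalization(
                surrogate_delta(f, chon), f.n_atoms, groups["guest"], groups["A"]
            )
            for f in frames
        ]
        assert np.ptp(vals) <= 1e-12
        assert max(vals) < 0.05

    def test_truth_table(self):
        events = [
            BindingEvent("approach", "A", 10, 30, 50),
            BindingEvent("rotate", "B", 60, 80, 95),
        ]
        _, _, truth = generate_binding_trajectory(100, events)
        assert truth[0]["expected"] == "both" and truth[0]["frame"] == 30
        assert truth[1]["expected"] == "electronic-only" and truth[1]["frame"] == 80

    def test_rotate_keeps_com_distance_constant(self):
        events = [BindingEvent("rotate", "B", 10, 40, 70)]
        frames, groups, _ = generate_binding_trajectory(80, events)
        g_guest = xcai.GroupDefinition("guest", tuple(groups["guest"]))
        g_b = xcai.GroupDefinition("B", tuple(groups["B"]))
        d = [xcai.center_of_mass_distance(f, g_guest, g_b) for f in frames]
        assert np.ptp(d) <= 1e-9

    def test_overlap_schedule_rejected(self):
        events = [
            BindingEvent("approach", "A", 10, 30, 50),
            BindingEvent("approach", "B", 40, 60, 80),
        ]
        with pytest.raises(ValueError, match="overlap"):
            generate_binding_trajectory(100, events)

    def test_bad_event_frames(self):
        with pytest.raises(ValueError, match="start < contact < end"):
            BindingEvent("approach", "A", 50, 50, 60)
        with pytest.raises(ValueError, match="kind"):
            BindingEvent("hop", "A", 1, 2, 3)
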