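import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import rankdata

from memins.molecular_properties import (
    DEBYE_PER_E_ANGSTROM,
    IRSpectrum,
    MoleculeStructure,
    absorbance_ratios,
    count_significant_modes,
    dipole_moment,
    hbond_distance,
    read_structure,
    rigidity_correlation,
    write_structure,
)

# Published reference values used as fixtures throughout:
MODE_COUNTS = {"DOX": 6, "DAU": 7, "IDA": 9, "EPI": 12}
INSERTION_ORDER = ["DOX", "DAU", "IDA", "EPI"]  # fastest inserter first
DIPOLES_D = {"EPI": 7.5, "DOX": 4.5, "DAU": 2.83, "IDA": 2.15}

PDB_3ATOM = """\
HETATM    1  O1  LIG A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  H1  LIG A   1       0.000   0.000   0.957  1.00  0.00           H
HETATM    3  H2  LIG A   1       0.926   0.000  -0.239  1.00  0.00           H
END
"""


def simple_structure(coords, charges=None, elements=None):
    n = len(coords)
    return MoleculeStructure(
        name="toy",
        atom_labels=[f"A{i}" for i in range(n)],
        elements=elements or ["C"] * n,
        coords=np.asarray(coords, dtype=float),
        charges=None if charges is None else np.asarray(charges, dtype=float),
    )


class TestReadStructure:
    def test_hand_written_pdb(self, tmp_path):
        p = tmp_path / "water.pdb"
        p.write_text(PDB_3ATOM)
        s = read_structure(p)
        assert s.n_atoms == 3
        assert s.elements == ["O", "H", "H"]
        assert s.coords[1, 2] == pytest.approx(0.957)

    def test_element_inferred_from_name(self, tmp_path):
        p = tmp_path / "noelem.pdb"
        p.write_text(
            "HETATM    1  CA  LIG A   1       1.000   2.000   3.000  1.00  0.00\n"
            "HETATM    2 CL1  LIG A   1       0.000   0.000   0.000  1.00  0.00\nEND\n"
        )
        s = read_structure(p)
        assert s.elements[0] == "C"
        assert s.elements[1] == "Cl"

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        rng = np.random.default_rng(4)
        s = simple_structure(rng.uniform(-20, 20, size=(12, 3)))
        p = tmp_path / "rt.pdb"
        write_structure(s, p)
        back = read_structure(p)
        assert np.allclose(back.coords, s.coords, atol=1.01e-3)

    def test_unparseable_record_reports_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "HETATM    1  O1  LIG A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "HETATM    2  O2  LIG A   1       xxx.xxx   0.000   0.000  1.00  0.00           O\n"
        )
        with pytest.raises(Exception, match=r"(:2|line)"):
            read_structure(p)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MoleculeStructure("d", ["A1", "A1"], ["C", "C"], np.zeros((2, 3)))

    def test_charge_sidecar_join(self, tmp_path):
        p = tmp_path / "water.pdb"
        p.write_text(PDB_3ATOM)
        csv = tmp_path / "charges.csv"
        csv.write_text("atom_label,charge_e\nO1,-0.834\nH1,0.417\nH2,0.417\n")
        s = read_structure(p, charges_csv=csv)
        assert s.charges.sum() == pytest.approx(0.0, abs=1e-9)

    def test_noninteger_total_charge_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            simple_structure(np.zeros((2, 3)), charges=[0.3, 0.3])


class TestDipoleMoment:
    def test_unit_dipole_hand_conversion(self):
        # +-0.2082 e at 1.0 Å separation: 0.2082 * 4.80321 = 1.0001 D
        s = simple_structure([[0, 0, 0], [0, 0, 1.0]], charges=[-0.2082, 0.2082])
        mag, direction = dipole_moment(s)
        assert mag == pytest.approx(1.000, abs=1e-3)
        assert np.allclose(direction, [0, 0, 1])

    def test_zero_charges_undefined_direction(self):
        s = simple_structure([[0, 0, 0], [1, 1, 1]], charges=[0.0, 0.0])
        mag, direction = dipole_moment(s)
        assert mag == 0.0 and direction is None

    def test_missing_charges_rejected(self):
        with pytest.raises(ValueError, match="no partial charges"):
            dipole_moment(simple_structure([[0, 0, 0]]))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(15)
        coords = rng.normal(size=(6, 3))
        q = np.array([0.4, -0.4, 0.25, -0.25, 0.1, -0.1])
        s = simple_structure(coords, charges=q)
        mag0, _ = dipole_moment(s)
        for rot in Rotation.random(100, random_state=7):
            mag, _ = dipole_moment(simple_structure(rot.apply(coords), charges=q))
            assert mag == pytest.approx(mag0, abs=1e-9)

    def test_translation_invariance_for_neutral(self):
        coords = np.array([[0, 0, 0], [0, 0, 2.0]])
        q = [0.5, -0.5]
        mag0, _ = dipole_moment(simple_structure(coords, charges=q))
        mag1, _ = dipole_moment(simple_structure(coords + 17.3, charges=q))
        assert mag0 == pytest.approx(mag1, abs=1e-12)

    def test_net_charged_species_warns(self):
        s = simple_structure([[0, 0, 0], [0, 0, 1.0]], charges=[1.0, 0.0])
        with pytest.warns(UserWarning, match="origin-dependent"):
            dipole_moment(s)

    def test_published_magnitudes_rank(self):
        order = sorted(DIPOLES_D, key=DIPOLES_D.get, reverse=True)
        assert order == ["EPI", "DOX", "DAU", "IDA"]


class TestHbondDistance:
    def test_constructed_distance(self):
        s = MoleculeStructure(
            "frag", ["HN1", "O5"], ["H", "O"],
            np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2.3]]),
        )
        assert hbond_distance(s, "HN1", "O5") == pytest.approx(2.3)

    def test_isometry_invariance(self):
        rng = np.random.default_rng(2)
        coords = np.array([[0.0, 0.0, 0.0], [1.2, -0.7, 1.6]])
        base = MoleculeStructure("f", ["H1", "O1"], ["H", "O"], coords)
        d0 = hbond_distance(base, "H1", "O1")
        for rot in Rotation.random(20, random_state=3):
            moved = rot.apply(coords) + rng.normal(size=3)
            s = MoleculeStructure("f", ["H1", "O1"], ["H", "O"], moved)
            assert hbond_distance(s, "H1", "O1") == pytest.approx(d0, abs=1e-9)

    def test_missing_label_rejected(self):
        s = MoleculeStructure("f", ["H1"], ["H"], np.zeros((1, 3)))
        with pytest.raises(KeyError, match="O9"):
            hbond_distance(s, "H1", "O9")


class TestModeCounting:
    def dox_like_fixture(self):
        # the six significant low-frequency modes plus decoys below the
        # absorbance threshold and outside the frequency window
        freqs = [150.0, 209.0, 231.0, 333.0, 354.0, 367.0, 472.0, 650.0]
        eps = [150.0, 300.0, 500.0, 210.0, 260.0, 205.0, 250.0, 400.0]
        return IRSpectrum("DOX-like", np.array(freqs), np.array(eps))

    def test_reference_six_mode_fixture(self):
        assert count_significant_modes(self.dox_like_fixture()) == 6

    def test_empty_spectrum(self):
        assert count_significant_modes(IRSpectrum("e", np.empty(0), np.empty(0))) == 0

    def test_matches_brute_force_filter_oracle(self):
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            n = rng.integers(0, 30)
            freqs = np.sort(rng.uniform(0, 1200, n))
            eps = rng.uniform(0, 500, n)
            spec = IRSpectrum("r", freqs, eps)
            oracle = sum(
                1 for f, e in zip(freqs, eps) if 0 <= f <= 600 and e > 200
            )
            assert count_significant_modes(spec) == oracle

    def test_monotone_in_threshold_and_window(self):
        spec = self.dox_like_fixture()
        counts = [count_significant_modes(spec, thr) for thr in (0, 100, 200, 300, 600)]
        assert counts == sorted(counts, reverse=True)
        assert count_significant_modes(spec, window=(0, 300)) <= count_significant_modes(spec)

    def test_imaginary_frequency_spectrum_rejected(self):
        spec = IRSpectrum("bad", np.array([100.0]), np.array([300.0]), has_imaginary=True)
        with pytest.raises(ValueError, match="imaginary"):
            count_significant_modes(spec)


class TestAbsorbanceRatios:
    def test_six_mode_reference_ratio(self):
        eps = 37.0 * np.array([6, 10, 2, 3, 2, 3]) / 2.0  # min maps to 1.5x scale
        assert absorbance_ratios(eps) == [6, 10, 2, 3, 2, 3]

    def test_twelve_mode_reference_ratio(self):
        eps = 55.0 * np.array([4, 4, 3, 1, 1, 4, 3, 2, 2, 2, 3, 4])
        assert absorbance_ratios(eps) == [4, 4, 3, 1, 1, 4, 3, 2, 2, 2, 3, 4]

    def test_equal_values_all_ones(self):
        assert absorbance_ratios([7.7, 7.7, 7.7]) == [1, 1, 1]

    @given(st.floats(0.01, 100.0))
    @settings(derandomize=True, max_examples=50)
    def test_scale_invariance(self, c):
        eps = np.array([6, 10, 2, 3, 2, 3], dtype=float)
        assert absorbance_ratios(c * eps) == absorbance_ratios(eps)

    def test_zero_absorbance_rejected(self):
        with pytest.raises(ValueError):
            absorbance_ratios([1.0, 0.0])


class TestRigidityCorrelation:
    def test_reference_counts_perfectly_concordant(self):
        report = rigidity_correlation(MODE_COUNTS, INSERTION_ORDER)
        assert report.correlation == pytest.approx(1.0)

    def test_reversed_order_anticorrelated(self):
        report = rigidity_correlation(MODE_COUNTS, INSERTION_ORDER[::-1])
        assert report.correlation == pytest.approx(-1.0)

    def test_matches_direct_rank_formula(self):
        rng = np.random.default_rng(33)
        names = ["m1", "m2", "m3", "m4", "m5"]
        for _ in range(50):
            counts = {n: int(c) for n, c in zip(names, rng.choice(50, 5, replace=False))}
            order = list(rng.permutation(names))
            got = rigidity_correlation(counts, order).correlation
            x = rankdata([counts[n] for n in order])
            y = rankdata(np.arange(len(order)))
            oracle = np.corrcoef(x, y)[0, 1]
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_kendall_available_behind_flag(self):
        report = rigidity_correlation(MODE_COUNTS, INSERTION_ORDER, method="kendall")
        assert report.correlation == pytest.approx(1.0)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            rigidity_correlation({"A": 1, "B": 2, "C": 3}, ["A", "B", "D"])

    def test_too_few_molecules_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            rigidity_correlation({"A": 1, "B": 2}, ["A", "B"])
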