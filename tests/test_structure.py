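"""Structure parsing, Kabsch superposition and chain masses."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ddscan.simulate import gen_perturbed_coords
from ddscan.structure import (
    ChainModel,
    DegenerateCoordinatesError,
    RigidSuperposition,
    StructureParseError,
    chain_mass,
    kabsch_superpose,
    pair_ca,
    read_structure,
    superpose_dimers,
)

# ---------------------------------------------------------------------------
# parsing


def _write_two_chain_pdb(path):
    lines = []
    serial = 1
    for chain, seq in (("A", "GAS"), ("B", "GAS")):
        for i, aa in enumerate(seq, start=1):
            name = {"G": "GLY", "A": "ALA", "S": "SER"}[aa]
            x = serial * 3.0
            lines.append(
                f"ATOM  {serial:5d}  CA  {name} {chain}{i:4d}    "
                f"{x:8.3f}{1.0 + serial:8.3f}{2.0:8.3f}  1.00 20.00           C"
            )
            serial += 1
        lines.append("TER")
    path.write_text("\n".join(lines) + "\nEND\n")


def test_read_two_chain_fixture(tmp_path):
    p = tmp_path / "synthetic_two_chain.pdb"
    _write_two_chain_pdb(p)
    sm = read_structure(p)
    assert len(sm.chains) == 2
    assert sm.chains[0].sequence == "GAS"
    assert sm.chains[0].n_ca == 3


def test_unparseable_file_raises(tmp_path):
    p = tmp_path / "junk.cif"
    p.write_text("this is not a structure\n")
    with pytest.raises(StructureParseError):
        read_structure(p)


def test_structure_without_polymer_raises(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("HEADER    NOTHING\nEND\n")
    with pytest.raises(StructureParseError):
        read_structure(p)


def test_synthetic_crystal_standin_roundtrip(standin_structures):
    sm = read_structure(standin_structures["spa17"])
    assert len(sm.chains) == 4
    assert sm.cell[0] == pytest.approx(60.96, abs=0.01)
    assert sm.space_group == "P 32"


# ---------------------------------------------------------------------------
# Kabsch


def test_identical_sets_superpose_exactly():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 3))
    sup = kabsch_superpose(X, X)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
    assert sup.rotation == pytest.approx(np.eye(3), abs=1e-10)


def test_pure_rigid_motion_recovered():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(10, 3))
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    t = np.array([1.0, 2.0, 3.0])
    Y = X @ R.T + t
    sup = kabsch_superpose(X, Y)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
    assert sup.rotation == pytest.approx(R, abs=1e-9)
    assert sup.translation == pytest.approx(t, abs=1e-9)


def test_rotation_is_proper_and_orthonormal():
    X, Y, _ = gen_perturbed_coords(20, rotvec_deg=(10, 40, 70),
                                   translation=(3, -2, 1), noise_sd=0.3, seed=4)
    sup = kabsch_superpose(X, Y)
    R = sup.rotation
    assert R.T @ R == pytest.approx(np.eye(3), abs=1e-8)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)


def _numeric_min_rmsd(P, Q, restarts=8):
    """Brute-force numeric minimization over rotations + translations."""

    def loss(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        diff = P @ R.T + params[3:] - Q
        return np.sqrt((diff ** 2).sum() / len(P))

    rng = np.random.default_rng(123)
    best = np.inf
    starts = [np.zeros(6)] + [
        np.concatenate([rng.uniform(-np.pi, np.pi, 3), rng.uniform(-5, 5, 3)])
        for _ in range(restarts)
    ]
    for x0 in starts:
        res = minimize(loss, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = min(best, res.fun)
    return best


@pytest.mark.parametrize("n,noise", [(4, 0.3), (7, 0.5), (10, 0.15)])
def test_analytic_rmsd_matches_numeric_minimizer(n, noise):
    X, Y, _ = gen_perturbed_coords(n, rotvec_deg=(15, 25, 35),
                                   translation=(1, 2, 3), noise_sd=noise, seed=n)
    analytic = kabsch_superpose(X, Y).rmsd
    numeric = _numeric_min_rmsd(X, Y)
    assert analytic == pytest.approx(numeric, abs=1e-6)
    assert analytic <= numeric + 1e-9  # analytic solver is the true optimum


def test_perturbed_single_coordinate():
    X = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    Y = X.copy()
    Y[3, 2] += 0.3
    analytic = kabsch_superpose(X, Y).rmsd
    numeric = _numeric_min_rmsd(X, Y)
    assert analytic == pytest.approx(numeric, abs=1e-6)


def test_rmsd_invariant_under_rigid_motion_of_either_input():
    X, Y, _ = gen_perturbed_coords(15, noise_sd=0.4, seed=9)
    base = kabsch_superpose(X, Y).rmsd
    R = Rotation.from_euler("xyz", [11, 22, 33], degrees=True).as_matrix()
    t = np.array([5.0, -4.0, 2.0])
    assert kabsch_superpose(X @ R.T + t, Y).rmsd == pytest.approx(base, abs=1e-9)
    assert kabsch_superpose(X, Y @ R.T + t).rmsd == pytest.approx(base, abs=1e-9)


def test_collinear_points_rejected():
    X = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegenerateCoordinatesError):
        kabsch_superpose(X, X + 1.0)


def test_too_few_points_rejected():
    X = np.zeros((2, 3))
    with pytest.raises(DegenerateCoordinatesError):
        kabsch_superpose(X, X)


def test_rigid_superposition_estimator():
    X, Y, truth = gen_perturbed_coords(30, rotvec_deg=(0, 0, 45),
                                       translation=(2, 0, 0), noise_sd=0.0, seed=2)
    est = RigidSuperposition().fit(X, Y)
    assert est.rmsd_ == pytest.approx(0.0, abs=1e-10)
    assert est.transform(X) == pytest.approx(Y, abs=1e-9)
    assert est.get_params() == {}


# ---------------------------------------------------------------------------
# residue pairing


def _chain(seq, coords, cid="A"):
    return ChainModel(chain_id=cid, sequence=seq, ca=np.asarray(coords, float))


def test_identical_chains_pair_in_order():
    rng = np.random.default_rng(3)
    ca = rng.normal(size=(8, 3))
    a = _chain("GASGLVKE", ca)
    b = _chain("GASGLVKE", ca, "B")
    P, Q = pair_ca([a], [b])
    assert len(P) == 8
    assert P == pytest.approx(Q)


def test_nterminal_extension_pairs_offset():
    rng = np.random.default_rng(4)
    core = rng.normal(size=(8, 3))
    ext = np.vstack([rng.normal(size=(3, 3)) + 20, core])
    a = _chain("WHH" + "GASGLVKE", ext)
    b = _chain("GASGLVKE", core, "B")
    P, Q = pair_ca([a], [b])
    assert len(P) == 8
    assert P == pytest.approx(core)


def test_dimer_chain_swap_gives_same_rmsd(standin_structures):
    spa = read_structure(standin_structures["spa17"])
    rii = read_structure(standin_structures["rii"])
    core = (0, len(rii.chains[0].sequence))
    sup_ab = superpose_dimers([spa.chain("B"), spa.chain("C")], list(rii.chains),
                              core=core)
    sup_ba = superpose_dimers([spa.chain("C"), spa.chain("B")], list(rii.chains),
                              core=core)
    assert sup_ab.rmsd == pytest.approx(sup_ba.rmsd, abs=1e-9)


# ---------------------------------------------------------------------------
# masses


def test_free_glycine_mass():
    assert chain_mass("G") == pytest.approx(75.07, abs=0.01)


def test_diglycine_mass():
    assert chain_mass("GG") == pytest.approx(132.12, abs=0.01)


def test_mass_additivity():
    s1, s2 = "GASLV", "WYFKE"
    assert chain_mass(s1 + s2) == pytest.approx(
        chain_mass(s1) + chain_mass(s2) - 18.02, abs=0.02
    )


def test_nonstandard_letter_rejected():
    with pytest.raises(ValueError):
        chain_mass("GAX")
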