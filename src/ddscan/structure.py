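"""Coordinate parsing, rigid superposition and sequence-derived masses.

Four-helix-bundle D/D dimers are compared by least-squares rigid-body
superposition of paired C-alpha atoms (Kabsch, rotation-only: reflections
excluded); masses are average (not monoisotopic) chain masses, matching the
way solution molar masses are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import gemmi
import numpy as np
from Bio.SeqUtils import molecular_weight
from sklearn.base import BaseEstimator, TransformerMixin

from .align import AlignmentParams, align_strings

WATER_MASS = 18.02


@dataclass(frozen=True)
class ChainModel:
    chain_id: str
    sequence: str
    ca: np.ndarray  # (len(sequence), 3); NaN rows where no C-alpha present

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca, dtype=float)
        if ca.shape != (len(self.sequence), 3):
            raise ValueError("ca array must be (len(sequence), 3)")
        object.__setattr__(self, "ca", ca)

    @property
    def n_ca(self) -> int:
        return int(np.isfinite(self.ca).all(axis=1).sum())


@dataclass(frozen=True)
class StructureModel:
    entry_id: str
    chains: Tuple[ChainModel, ...]
    cell: Optional[Tuple[float, float, float, float, float, float]] = None
    space_group: Optional[str] = None

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.entry_id}")


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


class StructureParseError(ValueError):
    pass


def read_structure(path: str) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    All polymer (amino-acid) chains of the first model are extracted with
    their one-letter sequences and C-alpha coordinates; the unit cell and
    space group are kept when present.  For alternate locations the first
    conformer is used (gemmi's default when iterating atoms in file order).
    """
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    model = st[0]
    chains: List[ChainModel] = []
    for chain in model:
        polymer = chain.get_polymer()
        if len(polymer) == 0:
            continue
        seq_chars: List[str] = []
        coords: List[Tuple[float, float, float]] = []
        for res in polymer:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            one = gemmi.find_tabulated_residue(res.name).one_letter_code.upper()
            seq_chars.append(one if one.isalpha() else "X")
            ca = res.find_atom("CA", "*")
            if ca is not None:
                coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
            else:
                coords.append((np.nan, np.nan, np.nan))
        if seq_chars:
            chains.append(
                ChainModel(
                    chain_id=chain.name,
                    sequence="".join(seq_chars),
                    ca=np.array(coords, dtype=float),
                )
            )
    if not chains:
        raise StructureParseError(f"{path}: no polymer chains")
    cell = st.cell
    cell_tuple = None
    if cell is not None and cell.a > 1.0:
        cell_tuple = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    sg = st.spacegroup_hm or None
    entry = st.name or ""
    return StructureModel(
        entry_id=entry, chains=tuple(chains), cell=cell_tuple, space_group=sg
    )


# ---------------------------------------------------------------------------
# Kabsch


class DegenerateCoordinatesError(ValueError):
    """Fewer than 3 pairs, or a (near-)collinear point configuration."""


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rotation (det +1; reflections excluded) and
    translation minimizing the RMSD over the paired coordinates.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateCoordinatesError("need at least 3 paired points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1.0):
        raise DegenerateCoordinatesError("collinear point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


class RigidSuperposition(BaseEstimator, TransformerMixin):
    """Kabsch superposition as a transformer.

    ``fit(X, y)`` computes the optimal rigid motion of X onto y;
    ``transform`` applies it.  Fitted attributes: ``rotation_``,
    ``translation_``, ``rmsd_``, ``n_pairs_``.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RigidSuperposition":
        sup = kabsch_superpose(X, y)
        self.rotation_ = sup.rotation
        self.translation_ = sup.translation
        self.rmsd_ = sup.rmsd
        self.n_pairs_ = sup.n_pairs
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.rotation_.T + self.translation_


# ---------------------------------------------------------------------------
# residue pairing


def _chain_pairs(
    a: ChainModel,
    b: ChainModel,
    core: Optional[Tuple[int, int]] = None,
    params: Optional[AlignmentParams] = None,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Pair C-alphas of two chains via sequence alignment.

    ``core`` restricts pairs to a half-open residue interval on chain ``b``
    (the reference side), e.g. the helix-loop-helix bundle core.
    """
    aln = align_strings(a.chain_id, a.sequence, b.chain_id, b.sequence, params)
    out = []
    qi = ri = 0
    for qc, rc in aln.columns():
        qhere, rhere = qi, ri
        if qc != "-":
            qi += 1
        if rc != "-":
            ri += 1
        if qc == "-" or rc == "-":
            continue
        if core is not None and not (core[0] <= rhere < core[1]):
            continue
        pa, pb = a.ca[qhere], b.ca[rhere]
        if np.isfinite(pa).all() and np.isfinite(pb).all():
            out.append((pa, pb))
    return out


def pair_ca(
    mobile_chains: Sequence[ChainModel],
    target_chains: Sequence[ChainModel],
    core: Optional[Tuple[int, int]] = None,
    params: Optional[AlignmentParams] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Pair C-alpha coordinates between two monomers or two dimers.

    For dimer-vs-dimer, both chain-pair assignments are evaluated and the
    one giving the lower superposition RMSD is kept (the two bundles are
    pseudo-symmetric, so chain labelling is arbitrary).
    """
    if not 1 <= len(mobile_chains) <= 2 or not 1 <= len(target_chains) <= 2:
        raise ValueError("each side must contribute one or two chains")

    def _assemble(assignment):
        pairs = []
        for a, b in assignment:
            pairs.extend(_chain_pairs(a, b, core=core, params=params))
        if len(pairs) < 3:
            raise DegenerateCoordinatesError("fewer than 3 residue pairs")
        P = np.array([p for p, _ in pairs])
        Q = np.array([q for _, q in pairs])
        return P, Q

    if len(mobile_chains) == 2 and len(target_chains) == 2:
        best = None
        for assignment in (
            ((mobile_chains[0], target_chains[0]), (mobile_chains[1], target_chains[1])),
            ((mobile_chains[0], target_chains[1]), (mobile_chains[1], target_chains[0])),
        ):
            try:
                P, Q = _assemble(assignment)
                rmsd = kabsch_superpose(P, Q).rmsd
            except DegenerateCoordinatesError:
                continue
            if best is None or rmsd < best[0]:
                best = (rmsd, P, Q)
        if best is None:
            raise DegenerateCoordinatesError("fewer than 3 residue pairs")
        return best[1], best[2]

    assignment = tuple(zip(mobile_chains, target_chains))
    return _assemble(assignment)


def superpose_dimers(
    mobile: Sequence[ChainModel],
    target: Sequence[ChainModel],
    core: Optional[Tuple[int, int]] = None,
    trim_cycles: int = 0,
    trim_sigma: float = 2.0,
) -> Superposition:
    """Superpose two (mono/di)mers; optional iterative outlier trimming.

    With ``trim_cycles`` > 0, pairs whose residual exceeds ``trim_sigma``
    times the RMSD are discarded and the fit repeated, emulating the
    trimmed fits some structure viewers report.
    """
    P, Q = pair_ca(mobile, target, core=core)
    sup = kabsch_superpose(P, Q)
    for _ in range(trim_cycles):
        resid = np.linalg.norm(sup.apply(P) - Q, axis=1)
        keep = resid <= trim_sigma * sup.rmsd
        if keep.sum() < 3 or keep.all():
            break
        P, Q = P[keep], Q[keep]
        sup = kabsch_superpose(P, Q)
    return sup


# ---------------------------------------------------------------------------
# masses


def chain_mass(sequence: str) -> float:
    """Average molecular mass of a peptide chain in Da.

    Sum of average residue masses plus one water (18.02 Da); standard
    residues only, no modifications.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set("ACDEFGHIKLMNPQRSTVWY")
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    return float(molecular_weight(sequence, seq_type="protein", monoisotopic=False))
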