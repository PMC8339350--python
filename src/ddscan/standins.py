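"""Synthetic stand-ins for external reference objects.

Deposited crystal structures and database protein sequences are inputs the
pipeline normally receives as user-supplied files.  For self-contained
testing and demonstration this module constructs *synthetic* stand-ins that
reproduce the documented headline properties of those objects (chain
counts, unit-cell constants, construct length and mass, dimer-superposition
RMSD, per-member loop motifs) while containing no deposited coordinates or
database sequences.  Every object produced here is synthetic and labelled
as such; none of it is biological ground truth.
"""

from __future__ import annotations

import zlib
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

from .core import DDSequence, Source
from .reference import load_reference_profile

# ---------------------------------------------------------------------------
# synthetic SPA17-like crystal stand-in
#
# 75-residue chain; average mass 8812.9 Da (8.8 kDa to one decimal), the
# documented size of the crystallized 1-75 construct.  The sequence follows
# the R2D2 architecture of the packaged synthetic consensus.

SPA17_75_SYNTHETIC = (
    "MSVTIYVTQYGAELLEKAMQALPAGLDEAVEYFELLAKEASRVWEFNPDEWWEKMEANKELLWRQEAYEIDPKAV"
)

#: half-open interval of the helix-loop-helix bundle core on the 75-mer
CORE_ON_75 = (9, 62)

#: the core sequence doubles as the chain sequence of the RII-alpha-like
#: dimer stand-in (so residue pairing via alignment is exact)
RII_CORE_SYNTHETIC = SPA17_75_SYNTHETIC[CORE_ON_75[0] : CORE_ON_75[1]]

#: unit-cell constants and space group mirrored from the published
#: crystallographic table for the SPA17 entry
SPA17_CELL = (60.96, 60.96, 89.02, 90.0, 90.0, 120.0)
SPA17_SPACE_GROUP = "P 32"

THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _helix(n: int, start: np.ndarray, direction: int = 1) -> np.ndarray:
    """Idealized alpha-helix C-alpha trace: 2.3 A radius, 1.5 A rise, 100 deg."""
    i = np.arange(n)
    theta = np.deg2rad(100.0 * i)
    return start + np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), direction * 1.5 * i]
    )


def _strand(n: int, start: np.ndarray, step: np.ndarray) -> np.ndarray:
    return start + np.outer(np.arange(n), step)


def monomer_ca_75() -> np.ndarray:
    """Synthetic C-alpha trace for the 75-mer: strand-helix-loop-helix-strand."""
    h1 = _helix(24, np.array([0.0, 0.0, 0.0]), +1)  # residues 10-33
    h2 = _helix(24, np.array([9.0, 1.5, 36.0]), -1)  # residues 39-62
    nfl = _strand(9, h1[0] + np.array([-3.0, -2.0, -30.0]), np.array([0.2, 0.1, 3.3]))
    loop_pts = np.linspace(h1[-1], h2[0], 7)[1:-1]  # residues 34-38
    cfl = _strand(13, h2[-1] + np.array([2.0, -2.5, -3.0]), np.array([0.3, -0.2, -3.2]))
    return np.vstack([nfl, h1, loop_pts, h2, cfl])


def dimer_ca() -> Tuple[np.ndarray, np.ndarray]:
    """Antiparallel two-protomer bundle: second protomer flipped about z."""
    a = monomer_ca_75()
    flip = np.diag([-1.0, 1.0, -1.0])
    b = a @ flip.T + np.array([4.5, 4.0, 40.0])
    return a, b


def _add_chain(model: gemmi.Model, name: str, seq: str, ca: np.ndarray) -> None:
    chain = gemmi.Chain(name)
    for i, (aa, pos) in enumerate(zip(seq, ca), start=1):
        res = gemmi.Residue()
        res.name = THREE[aa]
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        atom.b_iso = 20.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)


def _new_structure(name: str, cell=None, space_group=None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    if cell is not None:
        st.cell = gemmi.UnitCell(*cell)
    if space_group is not None:
        st.spacegroup_hm = space_group
    return st


def write_synthetic_rii_dimer(path: str) -> None:
    """Synthetic RII-alpha-like core dimer (the 2IZX-role reference stand-in).

    Two chains carrying the 53-residue bundle core in the idealized dimer
    geometry.  Synthetic; contains no deposited coordinates.
    """
    a, b = dimer_ca()
    s, e = CORE_ON_75
    st = _new_structure("SYNTHETIC_RII_DIMER")
    model = gemmi.Model("1")
    _add_chain(model, "A", RII_CORE_SYNTHETIC, a[s:e])
    _add_chain(model, "B", RII_CORE_SYNTHETIC, b[s:e])
    st.add_model(model)
    st.write_pdb(str(path))


def write_synthetic_spa17_crystal(
    path: str, noise_sd: float = 0.2968, seed: int = 2021
) -> None:
    """Synthetic SPA17-like asymmetric unit stand-in (the 7MY4 role).

    Four 75-residue chains; chains B and C form the central dimer, built as
    a rigid transform of the idealized reference dimer plus isotropic
    Gaussian coordinate deviation of ``noise_sd`` (default 0.514/sqrt(3) A,
    so the core superposition RMSD against the reference dimer reproduces
    the documented 0.514 A comparison).  Chains A and D are additional
    copies completing the four-chain asymmetric unit.  The unit cell and
    space group mirror the published crystallographic table.  Synthetic;
    contains no deposited coordinates.
    """
    rng = np.random.default_rng(seed)
    a, b = dimer_ca()
    theta = np.deg2rad(35.0)
    R = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    t = np.array([12.0, -7.0, 5.0])
    chain_b = a @ R.T + t + rng.normal(0.0, noise_sd, a.shape)
    chain_c = b @ R.T + t + rng.normal(0.0, noise_sd, b.shape)
    # flanking copies, displaced so they do not contact the central dimer
    chain_a = a + np.array([35.0, 20.0, 0.0])
    chain_d = b + np.array([-35.0, -20.0, 10.0])

    st = _new_structure("SYNTHETIC_SPA17_XTAL", SPA17_CELL, SPA17_SPACE_GROUP)
    model = gemmi.Model("1")
    for name, ca in (("A", chain_a), ("B", chain_b), ("C", chain_c), ("D", chain_d)):
        _add_chain(model, name, SPA17_75_SYNTHETIC, ca)
    st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# synthetic 18-member human panel
#
# One stand-in per documented human superfamily member, constructed from the
# packaged class consensi with the per-member features the survey describes:
# exactly five members (ROPN1, ROPN1L, SPA17, RIIAD1, CATIP) carry the
# Pxx[ILV] loop; TPGS1 mixes a type-I loop/flank with type-II helix marks;
# RIIAD1 and CATIP carry a helix-forming N-flank.  C-flanks are mutated
# per member (seeded from the member name) so the panel is non-degenerate.

R1D2_LOOP = "PTDPE"
_PANEL_SPEC: Dict[str, Dict] = {
    # five Pxx[ILV] members
    "ROPN1": {"base": "R2D2", "loop": "PAGLD"},
    "ROPN1L": {"base": "R2D2", "loop": "PAGID"},
    "SPA17": {"base": "R2D2", "loop": "PAGLD"},
    "RIIAD1": {"base": "R2D2", "loop": "PAGVD", "nflank": "helix"},
    "CATIP": {"base": "R2D2", "loop": "PAGID", "nflank": "helix"},
    # type II subunits and fibrous-sheath relatives: type II flank/helix
    # marks but no canonical loop motif in the stand-in
    "PRKAR2A": {"base": "R2D2", "loop": "TAGLD"},
    "PRKAR2B": {"base": "R2D2", "loop": "TAGLD"},
    "ROPN1B": {"base": "R2D2", "loop": "TAGVD"},
    "CABYR": {"base": "R2D2", "loop": "TAGID"},
    # type I prototypes
    "PRKAR1A": {"base": "R1D2"},
    "PRKAR1B": {"base": "R1D2"},
    "EFCAB10": {"base": "R1D2"},
    "AK5": {"base": "R1D2"},
    "AK8": {"base": "R1D2"},
    "VEST1": {"base": "R1D2"},
    "FBXL13": {"base": "R1D2"},
    "TEX55": {"base": "R1D2"},
    # the documented boundary case: type I loop and flank, type II marks
    "TPGS1": {"base": "R1D2", "helix1_gly": True, "helix2_yf": True},
}

#: members whose loop carries the type II Pxx[ILV] motif
PXXPHI_MEMBERS = ("ROPN1", "ROPN1L", "SPA17", "RIIAD1", "CATIP")

AA = "ACDEFGHIKLMNPQRSTVWY"


def human_panel(cflank_divergence: float = 0.25) -> List[DDSequence]:
    """The synthetic 18-member human D/D superfamily panel."""
    ref = load_reference_profile()
    regions = ref.regions
    out: List[DDSequence] = []
    helical_nflank = ref.consensus_set["R1D2"][slice(*regions["nflank"])]
    for name, spec in _PANEL_SPEC.items():
        chars = list(ref.consensus_set[spec["base"]])
        ls, le = regions["loop"]
        if "loop" in spec:
            chars[ls:le] = list(spec["loop"])
        if spec.get("nflank") == "helix":
            ns, ne = regions["nflank"]
            chars[ns:ne] = list(helical_nflank)
        if spec.get("helix1_gly"):
            chars[regions["helix1"][0]] = "G"
        if spec.get("helix2_yf"):
            h2s = regions["helix2"][0]
            chars[h2s + 4 : h2s + 6] = list("YF")
        # per-member variation confined to the C-flank
        rng = np.random.default_rng(zlib.crc32(name.encode()) & 0x7FFFFFFF)
        cs, ce = regions["cflank"]
        for p in range(cs, ce):
            if rng.random() < cflank_divergence:
                alternatives = [a for a in AA if a != chars[p]]
                chars[p] = alternatives[rng.integers(0, 19)]
        out.append(
            DDSequence(
                id=name,
                residues="".join(chars),
                organism="Homo sapiens (synthetic stand-in)",
                source=Source.synthetic,
            )
        )
    return out
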