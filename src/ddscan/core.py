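"""Core domain types shared across the ddscan pipeline.

The docking and dimerization (D/D) domain is an N-terminal four-helix-bundle
module: two protomers, each contributing a helix-loop-helix unit, pack into an
X-type antiparallel bundle whose upper surface forms the amphipathic-helix
(AKAP) binding groove.  Throughout the package a candidate sequence is viewed
through a five-region architecture on an extended ~77-residue window:

    nflank | helix1 | loop | helix2 | cflank

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Tuple

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET = AA20 | {"X"}

#: residues counted as hydrophobic when scoring dimerization-interface
#: occupancy (Fig-style "dimerization determinant" positions)
HYDROPHOBIC = set("AILMFVWY")

MAX_SEQ_LEN = 500

REGION_NAMES = ("nflank", "helix1", "loop", "helix2", "cflank")


class Source(str, Enum):
    user = "user"
    fixture = "fixture"
    synthetic = "synthetic"


@dataclass(frozen=True)
class DDSequence:
    """A candidate D/D-domain N-terminal sequence."""

    id: str
    residues: str
    organism: Optional[str] = None
    source: Source = Source.user

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        if len(self.residues) > MAX_SEQ_LEN:
            raise ValueError(
                f"{self.id}: length {len(self.residues)} exceeds {MAX_SEQ_LEN}"
            )
        bad = [
            (i, c) for i, c in enumerate(self.residues) if c not in AA_ALPHABET
        ]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"{self.id}: illegal residue {c!r} at position {i}"
            )

    def __len__(self) -> int:
        return len(self.residues)


Interval = Tuple[int, int]


@dataclass(frozen=True)
class ReferenceProfile:
    """Reference extended D/D sequence with its five-region annotation.

    ``regions`` maps each region name to a half-open interval on the
    reference; the intervals are contiguous, ordered and tile [0, len).
    ``consensus_set`` holds one representative consensus per class
    (DPY30 / R1D2 / R2D2) used for superfamily assignment.
    """

    name: str
    residues: str
    regions: Dict[str, Interval]
    consensus_set: Dict[str, str] = field(default_factory=dict)
    dimer_positions: Tuple[int, ...] = ()
    docking_positions: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.residues)
        prev_end = 0
        for name in REGION_NAMES:
            if name not in self.regions:
                raise ValueError(f"missing region {name!r}")
            s, e = self.regions[name]
            if s != prev_end or e < s:
                raise ValueError("regions must be contiguous, ordered, non-overlapping")
            prev_end = e
        if prev_end != n:
            raise ValueError("regions must tile [0, len)")
        for h in ("helix1", "helix2"):
            s, e = self.regions[h]
            if e - s < 8:
                raise ValueError(f"{h} must span at least 8 residues")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Global pairwise alignment of a query against a reference profile."""

    query_id: str
    ref_name: str
    aligned_query: str
    aligned_ref: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("aligned strings must have equal length")

    def columns(self):
        """Yield (query_char, ref_char) pairs column by column."""
        return zip(self.aligned_query, self.aligned_ref)


class Coverage(str, Enum):
    full = "full"
    partial = "partial"
    absent = "absent"


@dataclass(frozen=True)
class RegionMap:
    """The five-region architecture projected onto query coordinates."""

    intervals: Dict[str, Interval]
    coverage: Dict[str, Coverage]

    def present(self, name: str) -> bool:
        return self.coverage[name] is not Coverage.absent


class LoopMotif(str, Enum):
    PxxP = "PxxP"          # type I hallmark: prolines on both ends of the loop
    PxxPhi = "PxxPhi"      # type II: second proline replaced by Ile/Leu/Val
    other = "other"


class SSClass(str, Enum):
    helix = "helix"
    strand = "strand"
    ambiguous = "ambiguous"


@dataclass(frozen=True)
class FeatureVector:
    """Diagnostic features separating DPY-30-like, R1D2 and R2D2 sequences."""

    loop_motif: LoopMotif
    nflank_ss: SSClass
    helix1_start_gly: bool
    helix2_yf: bool
    dimer_hydrophobic_frac: float
    docking_match_count: int
    loop_flagged: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dimer_hydrophobic_frac <= 1.0:
            raise ValueError("dimer_hydrophobic_frac outside [0, 1]")
        if self.docking_match_count < 0:
            raise ValueError("docking_match_count negative")


class Superfamily(str, Enum):
    DPY30 = "DPY30"
    PKAR = "PKAR"
    none = "none"


class Lineage(str, Enum):
    R1D2 = "R1D2"
    R2D2 = "R2D2"
    intermediate = "intermediate"
    not_applicable = "not_applicable"


@dataclass(frozen=True)
class ClassScore:
    superfamily: Superfamily
    lineage: Lineage
    score_r1: float
    score_r2: float
    margin: float
    evidence: Tuple[Tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if (
            self.lineage is not Lineage.not_applicable
            and self.superfamily is not Superfamily.PKAR
        ):
            raise ValueError("lineage only applies to the PKA-R superfamily")


@dataclass(frozen=True)
class TitrationSet:
    """Steady-state concentration/response pairs (concentrations in molar)."""

    points: Tuple[Tuple[float, float], ...]
    replicate_id: Optional[str] = None

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.points]
        if any(c <= 0 for c in concs):
            raise ValueError("concentrations must be positive")
        if len(set(concs)) != len(concs):
            raise ValueError("concentrations must be distinct")

    @property
    def concentrations(self):
        return tuple(c for c, _ in self.points)

    @property
    def responses(self):
        return tuple(r for _, r in self.points)


@dataclass(frozen=True)
class KineticTrace:
    """One BLI trace: association then dissociation at a fixed concentration."""

    concentration: float
    association: Tuple[Tuple[float, float], ...]
    dissociation: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        for phase in (self.association, self.dissociation):
            ts = [t for t, _ in phase]
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError("times must be strictly increasing within a phase")
        if self.association and self.dissociation:
            if self.dissociation[0][0] < self.association[-1][0]:
                raise ValueError("association must precede dissociation")


@dataclass(frozen=True)
class BindingFit:
    """Fitted 1:1 binding parameters (molar units internally)."""

    Rmax: float
    KD: float
    kon: Optional[float] = None
    koff: Optional[float] = None
    se_Rmax: Optional[float] = None
    se_KD: Optional[float] = None
    rss: float = 0.0
    kd_lower_bound: bool = False

    def __post_init__(self) -> None:
        if self.KD <= 0 and not self.kd_lower_bound:
            raise ValueError("KD must be positive")
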