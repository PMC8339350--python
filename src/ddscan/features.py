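"""Diagnostic sequence features of the D/D superfamily lineages.

Type I-like (R1D2) members carry prolines on both ends of the inter-helix
loop (PxxP) and a helix-forming N-flank; type II-like (R2D2) members replace
the second proline with Ile/Leu/Val (Pxx[ILV]), have a strand-forming
N-flank, a glycine leading helix I and a "YF" dipeptide in helix II.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

from .core import (
    HYDROPHOBIC,
    Coverage,
    DDSequence,
    FeatureVector,
    LoopMotif,
    ReferenceProfile,
    RegionMap,
    SSClass,
)
from .reference import DEFAULT_TAU, load_propensity_table

PHI = set("ILV")


class LoopUnresolvedError(ValueError):
    """Loop region absent or too short to scan for the P-x-x-Z motif."""


def _loop_window(seq: str, rm: RegionMap) -> str:
    """The loop interval widened by one residue on each side.

    The prolines sit "on each end" of the loop and projected boundaries are
    approximate, so the scan window extends one position into each helix.
    """
    s, e = rm.intervals["loop"]
    return seq[max(0, s - 1) : min(len(seq), e + 1)]


def loop_motif(seq: DDSequence, rm: RegionMap) -> LoopMotif:
    """Scan the loop window for P-x-x-Z; the most N-terminal match wins."""
    if not rm.present("loop"):
        raise LoopUnresolvedError(f"{seq.id}: loop region absent")
    window = _loop_window(seq.residues, rm)
    if len(window) < 4:
        raise LoopUnresolvedError(
            f"{seq.id}: loop window has {len(window)} residues (< 4)"
        )
    for i in range(len(window) - 3):
        if window[i] != "P":
            continue
        z = window[i + 3]
        if z == "P":
            return LoopMotif.PxxP
        if z in PHI:
            return LoopMotif.PxxPhi
    return LoopMotif.other


def nflank_ss_class(
    seq: DDSequence,
    rm: RegionMap,
    table: Optional[Dict[str, Dict[str, float]]] = None,
    tau: float = DEFAULT_TAU,
) -> SSClass:
    """Classify the N-flank as helix- or strand-forming by mean propensity.

    Returns helix when mean(P_helix) - mean(P_strand) > tau, strand when
    < -tau, otherwise ambiguous.  Flanks shorter than 3 residues (or absent)
    are ambiguous by convention.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not rm.present("nflank"):
        return SSClass.ambiguous
    table = table or load_propensity_table()
    s, e = rm.intervals["nflank"]
    residues = [c for c in seq.residues[s:e] if c != "X"]
    if len(residues) < 3:
        return SSClass.ambiguous
    dh = sum(table["helix"][c] for c in residues) / len(residues)
    ds = sum(table["strand"][c] for c in residues) / len(residues)
    diff = dh - ds
    if diff > tau:
        return SSClass.helix
    if diff < -tau:
        return SSClass.strand
    return SSClass.ambiguous


@dataclass
class FeatureConfig:
    """Configuration for feature extraction.

    Dimerization/docking determinant positions are reference coordinates;
    they are projected through the alignment before being read off the query.
    """

    tau: float = DEFAULT_TAU
    propensity_table: Optional[Dict[str, Dict[str, float]]] = None
    dimer_positions: Optional[Sequence[int]] = None
    docking_positions: Optional[Sequence[int]] = None


def _project_positions(aln, positions: Sequence[int]) -> Dict[int, Optional[int]]:
    """Map reference positions to query positions through the alignment."""
    wanted = set(positions)
    out: Dict[int, Optional[int]] = {p: None for p in wanted}
    q = r = 0
    for qc, rc in aln.columns():
        if rc != "-":
            if r in wanted and qc != "-":
                out[r] = q
            r += 1
        if qc != "-":
            q += 1
    return out


def extract_features(
    seq: DDSequence,
    rm: RegionMap,
    ref: ReferenceProfile,
    aln=None,
    config: Optional[FeatureConfig] = None,
) -> FeatureVector:
    """Assemble the full feature vector for one candidate.

    ``aln`` (the alignment used to build ``rm``) is needed to project the
    configured dimerization/docking determinant positions; without it the
    interface-occupancy features default to 0.
    """
    config = config or FeatureConfig()
    if not (rm.present("helix1") and rm.present("helix2")):
        raise NoCoreHelicesError(f"{seq.id}: helix1 and helix2 must both be present")

    loop_flagged = False
    try:
        motif = loop_motif(seq, rm)
    except LoopUnresolvedError:
        motif = LoopMotif.other
        loop_flagged = True

    ss = nflank_ss_class(seq, rm, config.propensity_table, config.tau)

    h1s, h1e = rm.intervals["helix1"]
    h2s, h2e = rm.intervals["helix2"]
    gly = "G" in seq.residues[h1s : min(h1s + 2, h1e)]
    yf = "YF" in seq.residues[h2s:h2e]

    dimer_pos = tuple(
        config.dimer_positions
        if config.dimer_positions is not None
        else ref.dimer_positions
    )
    dock_pos = tuple(
        config.docking_positions
        if config.docking_positions is not None
        else ref.docking_positions
    )
    frac = 0.0
    dock_matches = 0
    if aln is not None and (dimer_pos or dock_pos):
        proj = _project_positions(aln, tuple(dimer_pos) + tuple(dock_pos))
        if dimer_pos:
            occupied = sum(
                1
                for p in dimer_pos
                if proj[p] is not None and seq.residues[proj[p]] in HYDROPHOBIC
            )
            frac = occupied / len(dimer_pos)
        for p in dock_pos:
            if proj[p] is not None and seq.residues[proj[p]] == ref.residues[p]:
                dock_matches += 1

    return FeatureVector(
        loop_motif=motif,
        nflank_ss=ss,
        helix1_start_gly=gly,
        helix2_yf=yf,
        dimer_hydrophobic_frac=frac,
        docking_match_count=dock_matches,
        loop_flagged=loop_flagged,
    )


class NoCoreHelicesError(ValueError):
    """Feature extraction requires both core helices to be mapped."""
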