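"""Global pairwise alignment of candidates against the reference profile,
and projection of the five-region architecture through an alignment.

Each candidate is aligned pairwise (Needleman-Wunsch with affine gaps)
against the reference window rather than entering a multiple alignment; the
reference's region intervals are then projected through the alignment onto
query coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .core import (
    MAX_SEQ_LEN,
    REGION_NAMES,
    Coverage,
    DDSequence,
    PairwiseAlignment,
    ReferenceProfile,
    RegionMap,
)


class NoDDCoreError(ValueError):
    """Neither helix of the four-helix-bundle core maps onto the query."""


@dataclass
class AlignmentParams:
    """Substitution matrix + affine gap penalties.

    ``gap_open`` is the cost of the first gapped position in a run and
    ``gap_extend`` the cost of each subsequent one, so a length-L gap costs
    ``gap_open + (L - 1) * gap_extend``.  'X' scores 0 against everything.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def substitution_matrix(self):
        m = substitution_matrices.load(self.matrix).copy()
        if "X" in m.alphabet:
            for a in m.alphabet:
                m["X", a] = 0.0
                m[a, "X"] = 0.0
        return m


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = params.substitution_matrix()
    aligner.open_gap_score = -abs(params.gap_open)
    aligner.extend_gap_score = -abs(params.gap_extend)
    return aligner


def align_strings(
    query_id: str,
    query: str,
    ref_name: str,
    ref: str,
    params: Optional[AlignmentParams] = None,
) -> PairwiseAlignment:
    """Optimal global alignment of two residue strings.

    Ties between co-optimal alignments are broken deterministically by
    taking the aligner's first reported alignment.
    """
    if len(query) > MAX_SEQ_LEN:
        raise ValueError(f"{query_id}: query longer than {MAX_SEQ_LEN} residues")
    params = params or AlignmentParams()
    aligner = _make_aligner(params)
    aln = aligner.align(query, ref)[0]
    aligned_query, aligned_ref = aln[0], aln[1]
    matches = comparable = 0
    for q, r in zip(aligned_query, aligned_ref):
        if q == "-" and r == "-":
            continue
        comparable += 1
        if q == r and q != "-":
            matches += 1
    identity = matches / comparable if comparable else 0.0
    return PairwiseAlignment(
        query_id=query_id,
        ref_name=ref_name,
        aligned_query=aligned_query,
        aligned_ref=aligned_ref,
        score=float(aln.score),
        identity=identity,
    )


def align_pair(
    query: DDSequence,
    ref: Union[ReferenceProfile, Tuple[str, str]],
    params: Optional[AlignmentParams] = None,
) -> PairwiseAlignment:
    """Align a candidate against the reference profile (or a (name, seq) pair)."""
    if isinstance(ref, ReferenceProfile):
        name, seq = ref.name, ref.residues
    else:
        name, seq = ref
    return align_strings(query.id, query.residues, name, seq, params)


def map_regions(aln: PairwiseAlignment, ref: ReferenceProfile) -> RegionMap:
    """Project the reference's region intervals onto query coordinates.

    A region whose reference positions align only to gaps is flagged absent;
    a region with some but not all positions matched is flagged partial.
    """
    if aln.ref_name != ref.name:
        raise ValueError(
            f"alignment was made against {aln.ref_name!r}, not {ref.name!r}"
        )
    # query position aligned to each reference position (None if gapped)
    ref_to_query: Dict[int, Optional[int]] = {}
    q = r = 0
    for qc, rc in aln.columns():
        if rc != "-":
            ref_to_query[r] = q if qc != "-" else None
            r += 1
        if qc != "-":
            q += 1

    intervals: Dict[str, Tuple[int, int]] = {}
    coverage: Dict[str, Coverage] = {}
    cursor = 0  # insertion point for absent regions, keeps ordering valid
    for name in REGION_NAMES:
        s, e = ref.regions[name]
        hits = [ref_to_query[i] for i in range(s, e) if ref_to_query.get(i) is not None]
        if not hits:
            intervals[name] = (cursor, cursor)
            coverage[name] = Coverage.absent
            continue
        lo, hi = min(hits), max(hits) + 1
        intervals[name] = (lo, hi)
        coverage[name] = Coverage.full if len(hits) == e - s else Coverage.partial
        cursor = hi
    if coverage["helix1"] is Coverage.absent and coverage["helix2"] is Coverage.absent:
        raise NoDDCoreError(f"{aln.query_id}: no D/D core (both helices absent)")
    return RegionMap(intervals=intervals, coverage=coverage)
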