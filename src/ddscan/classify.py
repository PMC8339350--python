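"""Superfamily and lineage assignment.

Assignment is two-stage: a candidate is first placed in the DPY-30 or PKA-R
superfamily by alignment score against class consensus sequences, then PKA-R
members are scored into the type I-like (R1D2) or type II-like (R2D2)
lineage by an explicit additive weight scheme over the diagnostic features.
The loop motif is the defining feature and carries double weight; N-flank
secondary structure and the helix I glycine / helix II "YF" marks are
secondary determinants.  Calls whose R1/R2 margin does not exceed ``delta``
are reported as *intermediate* — a first-class outcome, mirroring genuinely
boundary-case family members (e.g. proteins with a type I loop but type II
helix marks), not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .align import AlignmentParams, align_pair, align_strings, map_regions
from .core import (
    ClassScore,
    DDSequence,
    FeatureVector,
    Lineage,
    LoopMotif,
    ReferenceProfile,
    SSClass,
    Superfamily,
)
from .features import FeatureConfig, extract_features
from .reference import load_reference_profile

#: additive scoring scheme: feature event -> (side, weight)
DEFAULT_WEIGHTS: Dict[str, Tuple[str, float]] = {
    "loop_PxxP": ("r1", 2.0),
    "loop_PxxPhi": ("r2", 2.0),
    "nflank_helix": ("r1", 1.0),
    "nflank_strand": ("r2", 1.0),
    "helix1_start_gly": ("r2", 1.0),
    "helix2_yf": ("r2", 1.0),
}

DEFAULT_DELTA = 1.0
DEFAULT_MIN_SCORE = 50.0


def superfamily_scores(
    seq: DDSequence,
    ref: ReferenceProfile,
    params: Optional[AlignmentParams] = None,
) -> Dict[str, float]:
    """Alignment score of the query against each class consensus."""
    if not ref.consensus_set:
        raise ValueError("reference profile carries no consensus sequences")
    if "DPY30" not in ref.consensus_set or not (
        {"R1D2", "R2D2"} & set(ref.consensus_set)
    ):
        raise ValueError("consensus_set needs DPY30 and at least one PKA-R class")
    return {
        cls: align_strings(seq.id, seq.residues, cls, cons, params).score
        for cls, cons in ref.consensus_set.items()
    }


def assign_superfamily(
    seq: DDSequence,
    ref: ReferenceProfile,
    min_score: float = DEFAULT_MIN_SCORE,
    params: Optional[AlignmentParams] = None,
) -> Superfamily:
    """Best-scoring consensus wins; below ``min_score`` the call is none.

    Exact ties between a DPY-30 and a PKA-R consensus break toward PKA-R.
    """
    scores = superfamily_scores(seq, ref, params)
    best = max(scores.values())
    if best < min_score:
        return Superfamily.none
    pkar_best = max(
        (v for k, v in scores.items() if k in ("R1D2", "R2D2")), default=-np.inf
    )
    # tie toward PKAR
    if pkar_best >= scores.get("DPY30", -np.inf):
        return Superfamily.PKAR
    return Superfamily.DPY30


def classify_lineage(
    fv: FeatureVector,
    weights: Optional[Dict[str, Tuple[str, float]]] = None,
    delta: float = DEFAULT_DELTA,
) -> ClassScore:
    """Score a PKA-R feature vector into R1D2 / R2D2 / intermediate."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    weights = weights or DEFAULT_WEIGHTS
    if any(w <= 0 for _, w in weights.values()):
        raise ValueError("weights must be positive")

    events: List[str] = []
    if fv.loop_motif is LoopMotif.PxxP:
        events.append("loop_PxxP")
    elif fv.loop_motif is LoopMotif.PxxPhi:
        events.append("loop_PxxPhi")
    if fv.nflank_ss is SSClass.helix:
        events.append("nflank_helix")
    elif fv.nflank_ss is SSClass.strand:
        events.append("nflank_strand")
    if fv.helix1_start_gly:
        events.append("helix1_start_gly")
    if fv.helix2_yf:
        events.append("helix2_yf")

    score = {"r1": 0.0, "r2": 0.0}
    evidence: List[Tuple[str, float]] = []
    for ev in events:
        if ev not in weights:
            continue
        side, w = weights[ev]
        score[side] += w
        evidence.append((f"{ev}->{side}", w))

    margin = abs(score["r1"] - score["r2"])
    if margin <= delta:
        lineage = Lineage.intermediate
    elif score["r1"] > score["r2"]:
        lineage = Lineage.R1D2
    else:
        lineage = Lineage.R2D2
    return ClassScore(
        superfamily=Superfamily.PKAR,
        lineage=lineage,
        score_r1=score["r1"],
        score_r2=score["r2"],
        margin=margin,
        evidence=tuple(evidence),
    )


class DDLineageClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based D/D superfamily / lineage classifier (sklearn-style).

    Parameters
    ----------
    weights : mapping feature-event -> (side, weight), default scheme above.
    delta : margin at or below which a PKA-R call is *intermediate*.
    tau : propensity threshold for the N-flank helix/strand call.
    min_score : minimum consensus alignment score for superfamily membership.
    reference : ReferenceProfile; the packaged profile when None.

    The classifier is deterministic and needs no training data; ``fit``
    validates parameters and resolves the reference profile.
    """

    def __init__(
        self,
        weights: Optional[Dict[str, Tuple[str, float]]] = None,
        delta: float = DEFAULT_DELTA,
        tau: float = 0.1,
        min_score: float = DEFAULT_MIN_SCORE,
        reference: Optional[ReferenceProfile] = None,
        alignment_params: Optional[AlignmentParams] = None,
    ):
        self.weights = weights
        self.delta = delta
        self.tau = tau
        self.min_score = min_score
        self.reference = reference
        self.alignment_params = alignment_params

    # -- sklearn plumbing ---------------------------------------------------
    def fit(self, X: Iterable = (), y=None) -> "DDLineageClassifier":
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        self.reference_ = self.reference or load_reference_profile()
        self.weights_ = dict(self.weights or DEFAULT_WEIGHTS)
        self.classes_ = np.array(
            ["DPY30", "R1D2", "R2D2", "intermediate", "none"], dtype=object
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "reference_"):
            self.fit()

    @staticmethod
    def _as_ddseq(x, i: int) -> DDSequence:
        if isinstance(x, DDSequence):
            return x
        return DDSequence(id=f"seq{i}", residues=str(x).upper())

    # -- classification -----------------------------------------------------
    def classify_one(self, seq: Union[DDSequence, str]) -> ClassScore:
        self._check_fitted()
        seq = self._as_ddseq(seq, 0)
        ref = self.reference_
        sf = assign_superfamily(seq, ref, self.min_score, self.alignment_params)
        if sf is not Superfamily.PKAR:
            return ClassScore(
                superfamily=sf,
                lineage=Lineage.not_applicable,
                score_r1=0.0,
                score_r2=0.0,
                margin=0.0,
            )
        aln = align_pair(seq, ref, self.alignment_params)
        rm = map_regions(aln, ref)
        fv = extract_features(
            seq, rm, ref, aln=aln, config=FeatureConfig(tau=self.tau)
        )
        return classify_lineage(fv, self.weights_, self.delta)

    def classify(self, X: Iterable) -> List[ClassScore]:
        self._check_fitted()
        return [self.classify_one(self._as_ddseq(x, i)) for i, x in enumerate(X)]

    def predict(self, X: Iterable) -> np.ndarray:
        """Predict one label per sequence: lineage for PKA-R members, else
        the superfamily call (DPY30 / none)."""
        labels = []
        for cs in self.classify(X):
            if cs.superfamily is Superfamily.PKAR:
                labels.append(cs.lineage.value)
            else:
                labels.append(cs.superfamily.value)
        return np.asarray(labels, dtype=object)

    def decision_function(self, X: Iterable) -> np.ndarray:
        """(n, 2) array of [score_r1, score_r2]."""
        return np.array(
            [[cs.score_r1, cs.score_r2] for cs in self.classify(X)], dtype=float
        )
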