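"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: family-typical D/D
sequences at controlled divergence, tip sequences evolved on a known tree,
1:1-model BLI titrations/traces with multiplicative noise, and coordinate
clouds related by a known rigid transform.  All generators are pure
functions of (config, seed).

By default the lineage-defining motif positions (loop prolines / Pxx[ILV],
helix I glycine, helix II "YF") are immune to mutation so that
classifier-recovery tests have a clean ground truth; a "leaky" mode
(``motif_mutation_prob`` > 0) exists for stress testing.  Substitutions are
uniform over the 19 alternative residues - the simplest process with
analytic expectations; real protein evolution is matrix-structured and has
indels, which these generators deliberately do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import dendropy
import numpy as np
from scipy.spatial.transform import Rotation

from .core import DDSequence, KineticTrace, ReferenceProfile, Source, TitrationSet
from .reference import load_reference_profile
from .structure import Superposition

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_ARR = np.array(list(AA))


# ---------------------------------------------------------------------------
# family sequences


@dataclass(frozen=True)
class SeqGenConfig:
    lineage: str  # DPY30 | R1D2 | R2D2
    n: int
    divergence: float
    seed: int
    motif_mutation_prob: float = 0.0  # leaky mode when > 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if self.n < 0:
            raise ValueError("n must be non-negative")


def motif_positions(consensus: str, regions: Dict[str, Tuple[int, int]]) -> Set[int]:
    """Positions defining the lineage motifs on a consensus sequence.

    The loop P-x-x-Z pair (first match in the loop +/- 1 window), the
    helix I leading glycine and the helix II "YF" dipeptide, where present.
    """
    protected: Set[int] = set()
    ls, le = regions["loop"]
    w0, w1 = max(0, ls - 1), min(len(consensus), le + 1)
    window = consensus[w0:w1]
    for i in range(len(window) - 3):
        if window[i] == "P" and (window[i + 3] == "P" or window[i + 3] in "ILV"):
            protected.update((w0 + i, w0 + i + 3))
            break
    h1s, h1e = regions["helix1"]
    for p in range(h1s, min(h1s + 2, h1e)):
        if consensus[p] == "G":
            protected.add(p)
            break
    h2s, h2e = regions["helix2"]
    k = consensus.find("YF", h2s, h2e)
    if k != -1:
        protected.update((k, k + 1))
    return protected


def gen_family_sequences(
    cfg: SeqGenConfig, ref: Optional[ReferenceProfile] = None
) -> List[DDSequence]:
    """Mutate the lineage consensus at per-site probability ``divergence``.

    Motif positions are never mutated (unless leaky mode is enabled), so
    every generated sequence passes its lineage's motif checks.
    """
    ref = ref or load_reference_profile()
    if cfg.lineage not in ref.consensus_set:
        raise ValueError(f"unknown lineage {cfg.lineage!r}")
    consensus = ref.consensus_set[cfg.lineage]
    protected = motif_positions(consensus, ref.regions)
    rng = np.random.default_rng(cfg.seed)
    out: List[DDSequence] = []
    for i in range(cfg.n):
        chars = list(consensus)
        for p, c in enumerate(chars):
            p_mut = (
                cfg.motif_mutation_prob if p in protected else cfg.divergence
            )
            if p_mut > 0 and rng.random() < p_mut:
                alternatives = [a for a in AA if a != c]
                chars[p] = alternatives[rng.integers(0, 19)]
        out.append(
            DDSequence(
                id=f"{cfg.lineage}_{i:04d}",
                residues="".join(chars),
                source=Source.synthetic,
            )
        )
    return out


# ---------------------------------------------------------------------------
# evolution on a tree


def evolve_on_tree(
    tree: Union[dendropy.Tree, str],
    root_seq: str,
    rate: float,
    seed: int,
) -> Dict[str, str]:
    """Independent-site substitution process down a tree.

    Per edge of length L, each site experiences Poisson(rate * L)
    substitution events, each a uniform replacement among the 19 other
    residues; a site is hit at all with probability 1 - exp(-rate * L).
    On long branches the per-site mismatch fraction against the root
    saturates at 19/20.  Returns a map tip label -> sequence.
    """
    if not root_seq:
        raise ValueError("empty root sequence")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    seqs: Dict[int, np.ndarray] = {id(tree.seed_node): np.array(list(root_seq))}
    tips: Dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            parent_seq = seqs[id(nd)]
        else:
            bl = nd.edge.length or 0.0
            if bl < 0:
                raise ValueError("branch lengths must be non-negative")
            parent_seq = seqs[id(nd.parent_node)].copy()
            if rate * bl > 0:
                events = rng.poisson(rate * bl, size=len(parent_seq))
                hit = np.nonzero(events)[0]
                # after k uniform-19 jumps the end state equals the start
                # with probability 1/20 + (19/20) * (-1/19)**k (jump chain
                # on the complete 20-state graph); sample it directly
                k = events[hit].astype(float)
                p_same = 1 / 20 + (19 / 20) * (-1.0 / 19.0) ** k
                stay = rng.random(len(hit)) < p_same
                for pos in hit[~stay]:
                    alternatives = AA_ARR[AA_ARR != parent_seq[pos]]
                    parent_seq[pos] = alternatives[rng.integers(0, 19)]
            seqs[id(nd)] = parent_seq
        if nd.is_leaf():
            tips[nd.taxon.label] = "".join(parent_seq)
    return tips


# ---------------------------------------------------------------------------
# BLI data


@dataclass(frozen=True)
class BLIGenConfig:
    Rmax: float
    KD: float
    concentrations: Tuple[float, ...]  # molar
    noise_cv: float = 0.0
    kon: Optional[float] = None
    koff: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if self.kon is not None and self.koff is not None:
            if not np.isclose(self.KD, self.koff / self.kon, rtol=1e-6):
                raise ValueError("KD must equal koff/kon when both rates are given")


def gen_titration(cfg: BLIGenConfig) -> TitrationSet:
    """Steady-state responses: exact 1:1 model times (1 + eps)."""
    rng = np.random.default_rng(cfg.seed)
    pts = []
    for c in cfg.concentrations:
        r = cfg.Rmax * c / (cfg.KD + c)
        eps = rng.normal(0.0, cfg.noise_cv) if cfg.noise_cv > 0 else 0.0
        pts.append((c, r * (1.0 + eps)))
    return TitrationSet(points=tuple(pts), replicate_id=f"sim_seed{cfg.seed}")


def gen_traces(
    cfg: BLIGenConfig,
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    n_points: int = 60,
) -> List[KineticTrace]:
    """Kinetic traces from the 1:1 exponentials with multiplicative noise."""
    if cfg.kon is None or cfg.koff is None:
        raise ValueError("kinetic traces need kon and koff")
    rng = np.random.default_rng(cfg.seed)
    traces: List[KineticTrace] = []
    for c in cfg.concentrations:
        kobs = cfg.kon * c + cfg.koff
        req = cfg.Rmax * c / (cfg.KD + c)
        ta = np.linspace(0.0, t_assoc, n_points)
        ra = req * (1.0 - np.exp(-kobs * ta))
        if cfg.noise_cv > 0:
            ra = ra * (1.0 + rng.normal(0.0, cfg.noise_cv, size=ra.shape))
        r_end = req * (1.0 - np.exp(-kobs * t_assoc))
        td = np.linspace(0.0, t_dissoc, n_points) + t_assoc
        rd = r_end * np.exp(-cfg.koff * (td - t_assoc))
        if cfg.noise_cv > 0:
            rd = rd * (1.0 + rng.normal(0.0, cfg.noise_cv, size=rd.shape))
        traces.append(
            KineticTrace(
                concentration=c,
                association=tuple(zip(ta.tolist(), ra.tolist())),
                dissociation=tuple(zip(td.tolist(), rd.tolist())),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# perturbed coordinate sets


def gen_perturbed_coords(
    n_points: int,
    rotvec_deg: Sequence[float] = (0.0, 0.0, 90.0),
    translation: Sequence[float] = (0.0, 0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    spread: float = 10.0,
) -> Tuple[np.ndarray, np.ndarray, Superposition]:
    """A random cloud and its rigid-transformed, noise-perturbed copy.

    Returns (X, Y, truth) with Y = X R^T + t + N(0, noise_sd).  The
    ground-truth transform is recorded in the returned Superposition
    (rmsd field 0; the realized fit RMSD reflects the noise).
    """
    if n_points < 4:
        raise ValueError("need at least 4 points")
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, spread, size=(n_points, 3))
    # guard against a degenerate (collinear) draw
    if np.linalg.matrix_rank(X - X.mean(axis=0), tol=1e-6) < 2:
        raise ValueError("degenerate point cloud")
    R = Rotation.from_rotvec(np.deg2rad(np.asarray(rotvec_deg, dtype=float))).as_matrix()
    t = np.asarray(translation, dtype=float)
    Y = X @ R.T + t
    if noise_sd > 0:
        Y = Y + rng.normal(0.0, noise_sd, size=Y.shape)
    truth = Superposition(rotation=R, translation=t, rmsd=0.0, n_pairs=n_points)
    return X, Y, truth
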