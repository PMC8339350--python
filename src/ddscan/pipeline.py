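"""End-to-end orchestration: fasta -> regions -> features -> classification
-> phylogeny, plus the structure and binding stages.

Every run writes its fully resolved configuration (including seeds and the
package version) alongside the results, so outputs are reproducible
byte-for-byte from the provenance file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .align import AlignmentParams, align_pair, map_regions
from .binding import kinetic_fit, steady_state_fit
from .classify import DDLineageClassifier
from .core import DDSequence, Superfamily, TitrationSet
from .features import FeatureConfig, extract_features
from .io import read_fasta, write_json, write_region_tsv, write_table_tsv
from .phylo import bootstrap_supports, check_monophyly, root_with_outgroup, write_newick
from .reference import load_reference_profile
from .structure import chain_mass, read_structure, superpose_dimers


@dataclass
class PipelineConfig:
    reference_fasta: Optional[str] = None
    reference_regions: Optional[str] = None
    gap_open: float = 11.0
    gap_extend: float = 1.0
    tau: float = 0.1
    delta: float = 1.0
    min_score: float = 50.0
    bootstrap_reps: int = 100
    seed: int = 0
    outgroup: Tuple[str, ...] = ()

    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(gap_open=self.gap_open, gap_extend=self.gap_extend)


def _write_provenance(outdir: Path, config: PipelineConfig, extra: Dict = ()):
    payload = {
        "tool": "ddscan",
        "version": __version__,
        "config": dataclasses.asdict(config),
    }
    payload.update(dict(extra or {}))
    write_json(payload, outdir / "provenance.json")


def run_classify(
    fasta: str, config: Optional[PipelineConfig] = None, outdir: str = "."
) -> Dict[str, object]:
    """Classify every sequence in a FASTA and build a supported phylogeny.

    Writes region maps (TSV), feature vectors (TSV), classification calls
    (TSV + JSON), a bootstrap-supported newick tree and a monophyly summary
    into ``outdir``; returns the in-memory results.
    """
    config = config or PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seqs = read_fasta(fasta)
    if not seqs:
        raise ValueError("no sequences")
    ref = load_reference_profile(config.reference_fasta, config.reference_regions)
    params = config.alignment_params()
    clf = DDLineageClassifier(
        delta=config.delta,
        tau=config.tau,
        min_score=config.min_score,
        reference=ref,
        alignment_params=params,
    ).fit()

    region_maps = {}
    feature_rows = []
    class_rows = []
    aligned = []
    for seq in seqs:
        try:
            aln = align_pair(seq, ref, params)
            rm = map_regions(aln, ref)
        except Exception as exc:
            raise RuntimeError(f"sequence {seq.id!r}: {exc}") from exc
        region_maps[seq.id] = rm
        fv = extract_features(seq, rm, ref, aln=aln, config=FeatureConfig(tau=config.tau))
        feature_rows.append(
            {
                "id": seq.id,
                "loop_motif": fv.loop_motif.value,
                "nflank_ss": fv.nflank_ss.value,
                "helix1_start_gly": fv.helix1_start_gly,
                "helix2_yf": fv.helix2_yf,
                "dimer_hydrophobic_frac": f"{fv.dimer_hydrophobic_frac:.4f}",
                "docking_match_count": fv.docking_match_count,
            }
        )
        cs = clf.classify_one(seq)
        class_rows.append(
            {
                "id": seq.id,
                "superfamily": cs.superfamily.value,
                "lineage": cs.lineage.value,
                "score_r1": cs.score_r1,
                "score_r2": cs.score_r2,
                "margin": cs.margin,
                "evidence": ";".join(f"{k}={v:g}" for k, v in cs.evidence),
            }
        )
        aligned.append((seq.id, aln.aligned_query, aln.aligned_ref))

    write_region_tsv(region_maps, out / "regions.tsv")
    write_table_tsv(feature_rows, out / "features.tsv")
    write_table_tsv(class_rows, out / "classification.tsv")
    write_json(class_rows, out / "classification.json")

    tree = supports = monophyly = None
    if len(seqs) >= 3:
        # common gapped coordinate frame: each query aligned to the reference
        # is padded column-wise per reference position (reference-anchored)
        ref_aligned = _reference_anchored(aligned, ref)
        tree, supports = bootstrap_supports(
            ref_aligned, n_reps=config.bootstrap_reps, seed=config.seed
        )
        if config.outgroup:
            tree = root_with_outgroup(tree, set(config.outgroup))
        write_newick(tree, out / "tree.nwk")
        labels = {r["id"]: r["lineage"] for r in class_rows}
        monophyly = check_monophyly(tree, labels)
        write_json({k: bool(v) for k, v in monophyly.items()}, out / "monophyly.json")

    _write_provenance(out, config, {"n_sequences": len(seqs)})
    return {
        "sequences": seqs,
        "region_maps": region_maps,
        "features": feature_rows,
        "classification": class_rows,
        "tree": tree,
        "supports": supports,
        "monophyly": monophyly,
    }


def _reference_anchored(aligned, ref) -> List[Tuple[str, str]]:
    """Project every query onto reference coordinates (one column per
    reference position; query insertions are dropped)."""
    L = len(ref.residues)
    rows = []
    for qid, aq, ar in aligned:
        cols = []
        for qc, rc in zip(aq, ar):
            if rc != "-":
                cols.append(qc if qc != "-" else "-")
        assert len(cols) == L
        rows.append((qid, "".join(cols)))
    return rows


def run_structure(
    ref_path: str,
    mobile_path: str,
    ref_chains: Optional[Sequence[str]] = None,
    mobile_chains: Optional[Sequence[str]] = None,
    core: Optional[Tuple[int, int]] = None,
    trim_cycles: int = 0,
    outdir: str = ".",
) -> Dict[str, object]:
    """Chain inventory, dimer superposition and sequence-derived masses."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    target = read_structure(ref_path)
    mobile = read_structure(mobile_path)

    def _select(model, wanted):
        if wanted is None:
            return list(model.chains)[:2]
        return [model.chain(c) for c in wanted]

    tsel = _select(target, ref_chains)
    msel = _select(mobile, mobile_chains)
    sup = superpose_dimers(msel, tsel, core=core, trim_cycles=trim_cycles)

    inventory = [
        {
            "entry": sm.entry_id,
            "chain": c.chain_id,
            "n_residues": len(c.sequence),
            "n_ca": c.n_ca,
            "mass_da": round(chain_mass(c.sequence.replace("X", "")), 2),
        }
        for sm in (target, mobile)
        for c in sm.chains
    ]
    report = {
        "reference": {"path": str(ref_path), "entry": target.entry_id,
                      "cell": target.cell, "space_group": target.space_group},
        "mobile": {"path": str(mobile_path), "entry": mobile.entry_id,
                   "cell": mobile.cell, "space_group": mobile.space_group},
        "superposition": {
            "rotation": sup.rotation.tolist(),
            "translation": sup.translation.tolist(),
            "rmsd_angstrom": sup.rmsd,
            "n_pairs": sup.n_pairs,
            "trim_cycles": trim_cycles,
        },
        "chains": inventory,
    }
    write_json(report, out / "structure_report.json")
    return report


def run_binding(
    csv_path: str, model: str = "steady", outdir: str = "."
) -> Dict[str, object]:
    """Fit the 1:1 model to a CSV of binding data.

    Steady state expects columns concentration,response (molar,
    instrument units); kinetic expects time,response,concentration,phase.
    """
    import pandas as pd

    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:
        raise ValueError(f"malformed CSV {csv_path}: {exc}") from exc

    if model == "steady":
        needed = {"concentration", "response"}
        if not needed <= set(df.columns):
            raise ValueError(f"CSV must have columns {sorted(needed)}")
        ts = TitrationSet(
            points=tuple(zip(df["concentration"].astype(float), df["response"].astype(float)))
        )
        fit = steady_state_fit(ts)
    elif model == "kinetic":
        needed = {"time", "response", "concentration", "phase"}
        if not needed <= set(df.columns):
            raise ValueError(f"CSV must have columns {sorted(needed)}")
        from .core import KineticTrace

        traces = []
        for conc, grp in df.groupby("concentration"):
            assoc = grp[grp["phase"] == "association"].sort_values("time")
            dissoc = grp[grp["phase"] == "dissociation"].sort_values("time")
            traces.append(
                KineticTrace(
                    concentration=float(conc),
                    association=tuple(zip(assoc["time"], assoc["response"])),
                    dissociation=tuple(zip(dissoc["time"], dissoc["response"])),
                )
            )
        fit = kinetic_fit(traces)
    else:
        raise ValueError(f"unknown model {model!r}")

    report = {
        "model": model,
        "Rmax": fit.Rmax,
        "KD_molar": fit.KD,
        "kon_per_M_s": fit.kon,
        "koff_per_s": fit.koff,
        "se_Rmax": fit.se_Rmax,
        "se_KD": fit.se_KD,
        "rss": fit.rss,
        "kd_lower_bound": fit.kd_lower_bound,
    }
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(report, out / "binding_fit.json")
    return report
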