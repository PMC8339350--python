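"""Packaged reference profile and propensity table.

The shipped reference is a synthetic RII-alpha-like 77-residue window carrying
the canonical extended D/D architecture (strand-forming N-flank, glycine-led
helix I, P-x-x-[ILV] loop, YF-containing helix II, C-flank).  It is a
constructed stand-in, not a deposited database sequence; region boundaries,
dimerization- and docking-determinant positions are configuration, loaded
from the packaged JSON and overridable by the user.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Dict, Optional

from Bio import SeqIO

from .core import ReferenceProfile


def _data_path(name: str):
    return resources.files("ddscan.data") / name


def load_propensity_table(path: Optional[str] = None) -> Dict[str, Dict[str, float]]:
    """Load helix/strand propensities; returns {'helix': {...}, 'strand': {...}, 'tau': t}."""
    if path is None:
        text = _data_path("propensity.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = json.loads(text)
    for key in ("helix", "strand"):
        if set(table[key]) != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError(f"propensity table {key!r} must cover all 20 residues")
        if any(v <= 0 for v in table[key].values()):
            raise ValueError("propensities must be positive")
    return table


def load_reference_profile(
    fasta_path: Optional[str] = None, regions_path: Optional[str] = None
) -> ReferenceProfile:
    """Load the reference profile (packaged default or user-supplied files)."""
    if fasta_path is None:
        fasta_text = _data_path("reference_profile.fasta").read_text()
        import io as _io

        records = {r.id: str(r.seq) for r in SeqIO.parse(_io.StringIO(fasta_text), "fasta")}
    else:
        records = {r.id: str(r.seq) for r in SeqIO.parse(fasta_path, "fasta")}
    if regions_path is None:
        meta = json.loads(_data_path("reference_regions.json").read_text())
    else:
        with open(regions_path) as fh:
            meta = json.load(fh)

    name = meta["name"]
    consensus = {
        cls: records[rec_id] for cls, rec_id in meta["consensus_ids"].items()
    }
    return ReferenceProfile(
        name=name,
        residues=records[name],
        regions={k: tuple(v) for k, v in meta["regions"].items()},
        consensus_set=consensus,
        dimer_positions=tuple(meta.get("dimer_positions", ())),
        docking_positions=tuple(meta.get("docking_positions", ())),
    )


DEFAULT_TAU = 0.1
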