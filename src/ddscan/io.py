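"""FASTA input and tabular output helpers."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Union

from Bio import SeqIO

from .core import AA_ALPHABET, DDSequence, RegionMap, Source

PathLike = Union[str, Path]


class FastaFormatError(ValueError):
    """Raised when a FASTA record cannot be turned into a DDSequence."""


def read_fasta(path: PathLike, source: Source = Source.user) -> List[DDSequence]:
    """Read a multi-record FASTA file into DDSequence objects.

    Residues are uppercased and trailing ``*`` terminators stripped; any
    remaining character outside the 20 standard letters + ``X`` raises a
    :class:`FastaFormatError` naming the record and position.
    """
    out: List[DDSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        residues = str(rec.seq).upper().rstrip("*")
        for i, c in enumerate(residues):
            if c not in AA_ALPHABET:
                raise FastaFormatError(
                    f"record {rec.id!r}: illegal residue {c!r} at position {i}"
                )
        if not residues:
            raise FastaFormatError(f"record {rec.id!r}: empty sequence")
        out.append(DDSequence(id=rec.id, residues=residues, source=source))
    return out


def write_fasta(seqs: Iterable[DDSequence], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def write_region_tsv(maps: Dict[str, RegionMap], path: PathLike) -> None:
    """Export RegionMaps as BED-like TSV: id, region, start, end, flag."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "region", "start", "end", "flag"])
        for seq_id, rm in maps.items():
            for region, (s, e) in rm.intervals.items():
                w.writerow([seq_id, region, s, e, rm.coverage[region].value])


def write_table_tsv(rows: Sequence[dict], path: PathLike) -> None:
    """Write a list of homogeneous dicts as a TSV with a header row."""
    rows = list(rows)
    if not rows:
        Path(path).write_text("")
        return
    cols = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for r in rows:
            w.writerow([r[c] for c in cols])


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
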