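# ddscan

Sequence, phylogenetic, structural and binding analysis for the **D/D
(docking and dimerization) domain superfamily**.

The D/D domain is a small N-terminal module of the PKA regulatory (PKA-R)
subunits and their relatives: two protomers each contribute a
helix-loop-helix unit that packs into an X-type antiparallel four-helix
bundle whose upper face binds the amphipathic anchoring helix of AKAPs
(A-kinase-anchoring proteins).  Beyond PKA itself, the fold defines a
superfamily (DPY-30-like proteins plus the PKA-R-like group) whose members
split into a type I-like (**R1D2**) and a type II-like (**R2D2**) lineage on
the basis of a handful of diagnostic sequence features:

| feature | R1D2 | R2D2 |
|---|---|---|
| inter-helix loop | `PxxP` (prolines on both ends) | `Pxx[ILV]` (second Pro replaced by a hydrophobic) |
| N-flank secondary structure | helix-forming | strand-forming |
| helix I start | — | glycine |
| helix II | — | `YF` dipeptide |

`ddscan` implements this analysis as a tested pipeline, for molecular
evolution and structural biology groups who want the classification,
phylogeny and binding arithmetic reproducible rather than embedded in
one-off notebooks:

- **seq/regions** — FASTA input, global pairwise alignment of each
  candidate against a 77-residue extended D/D reference window
  (Needleman-Wunsch, BLOSUM62, affine gaps), and projection of the
  five-region architecture (`nflank | helix1 | loop | helix2 | cflank`)
  onto the candidate.
- **features & classification** — loop-motif scan, Chou-Fasman-style
  N-flank helix/strand call, glycine/`YF` marks, dimerization- and
  docking-determinant occupancy; an explicit additive scoring scheme
  assigns R1D2 / R2D2 / *intermediate* with a margin and per-feature
  evidence (`DDLineageClassifier`, a scikit-learn-style estimator).
- **phylogeny** — p-distances, neighbor joining (Saitou-Nei), classical
  column-resampling bootstrap proportions, DPY-30-style outgroup rooting,
  clade-monophyly checks; trees are `dendropy` objects, serialized as
  newick.
- **structure** — PDB/mmCIF parsing (via `gemmi`), C-alpha pairing by
  sequence alignment, Kabsch least-squares superposition
  (`RigidSuperposition`), sequence-derived average chain masses.
- **binding** — the 1:1 interaction model.  Steady state:
  `R(c) = Rmax*c / (KD + c)`; kinetics: `R(t) = Req*(1 - exp(-(kon*c +
  koff)*t))` and `R(t) = R0*exp(-koff*t)`, fitted locally per trace with
  `KD = koff/kon` (`SteadyStateBindingModel`, `KineticBindingModel`).
- **simulate** — generators for all of the above with known ground truth:
  family sequences at controlled divergence, tip sequences evolved on a
  known tree, noisy BLI titrations/traces, rigid-transform coordinate
  clouds.

Deposited crystal structures and database sequences are user-supplied
inputs; for self-contained tests and demos, `ddscan.standins` builds
clearly-labelled *synthetic* stand-ins that reproduce their documented
headline properties (chain counts, cell constants, construct mass,
dimer-superposition RMSD, the loop-motif census).

## Worked example

Classify the synthetic 18-member human panel:

```python
from ddscan import DDLineageClassifier
from ddscan.standins import human_panel

clf = DDLineageClassifier().fit()
for seq, cs in zip(human_panel(), clf.classify(human_panel())):
    print(f"{seq.id:8s} {cs.lineage.value:13s} {cs.score_r1:.0f} {cs.score_r2:.0f} {cs.margin:.0f}")
```

```
ROPN1    R2D2          0 5 5
ROPN1L   R2D2          0 5 5
SPA17    R2D2          0 5 5
RIIAD1   R2D2          1 4 3
CATIP    R2D2          1 4 3
...
PRKAR1A  R1D2          3 0 3
TPGS1    intermediate  3 2 1
```

Reading the rows: ROPN1 collects every R2 feature (loop `Pxx[ILV]` +2,
strand N-flank +1, helix I Gly +1, helix II `YF` +1 = 5); RIIAD1 keeps the
R2 loop but has a helix-forming N-flank (+1 to R1); TPGS1 — a genuinely
boundary-case protein — scores 3:2 and, with a margin at the default
`delta = 1`, is reported *intermediate* rather than forced into a lineage.

The same analysis from the shell, including a bootstrap NJ tree:

```sh
ddscan simulate sequences --out fam.fasta --n 20 --lineage R2D2 --divergence 0.05
ddscan classify -f fam.fasta -o out/ --reps 100 --seed 1
ddscan binding --csv titration.csv --model steady
ddscan structure --ref rii_dimer.pdb --mobile spa17_crystal.pdb --mobile-chains B,C --core-only
```

Fit a titration in Python:

```python
from ddscan import SteadyStateBindingModel
model = SteadyStateBindingModel().fit(concentrations_molar, responses)
model.KD_, model.Rmax_, model.se_KD_
```

## Layout

```
src/ddscan/        core.py (types)  align.py  features.py  classify.py
                   phylo.py  structure.py  binding.py  simulate.py
                   standins.py  pipeline.py  cli.py  reference.py  data/
tests/             pytest suite (unit, property and headline checks)
scripts/           acceptance.py
docs/methods.md    models, parameters, numerical choices, limitations
```
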