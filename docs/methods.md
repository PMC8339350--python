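# Methods

This note documents the models implemented in `ddscan`, the parameters
that matter, the synthetic-data generators, and the numerical and design
choices made where the design was genuinely open.

## Sequence model: the five-region extended D/D window

Candidates are analysed through a 77-residue extended D/D window divided
into five contiguous half-open regions: `nflank` (default positions
0-10), `helix1` (10-22), `loop` (22-27), `helix2` (27-40) and `cflank`
(40-77).  All coordinates are 0-based and half-open throughout, so
interval arithmetic is unambiguous.  The boundaries are configuration
(packaged JSON, user-overridable), not asserted biology: the five-region
architecture of the fold is well established, but exact column boundaries
on any particular alignment are a modelling choice.

Each candidate is aligned *pairwise* to the reference window
(Needleman-Wunsch, affine gaps) rather than entering a multiple
alignment; the reference intervals are then projected through the
alignment.  This keeps every candidate's coordinates independent of the
rest of the input set.  Alignment defaults: BLOSUM62, gap open 11, gap
extend 1, where "open" is the cost of the first gapped position in a run
(a length-L gap costs `11 + (L-1)`).  `X` scores 0 against everything —
neutral handling of ambiguity.  Ties between co-optimal alignments are
resolved deterministically by taking the aligner's first reported
alignment.

The packaged reference profile and the three class consensi (DPY-30-like,
R1D2, R2D2) are **synthetic** sequences constructed to carry the
canonical architecture (strand-forming N-flank, Gly-led helix I,
`Pxx[ILV]` or `PxxP` loop, `YF`-bearing helix II).  They are stand-ins,
not database sequences; any user can supply their own profile FASTA +
regions JSON.

## Features and classification

- **Loop motif.**  The loop interval widened by one residue on each side
  is scanned for `P-x-x-Z`; `Z = P` gives `PxxP`, `Z` in {I, L, V} gives
  `PxxPhi`, the most N-terminal match wins.  The one-residue widening
  absorbs the approximation in projected region boundaries, since the
  prolines sit on the *ends* of the loop.
- **N-flank secondary structure.**  Mean Chou-Fasman helix propensity
  minus mean strand propensity over the flank; > tau → helix, < -tau →
  strand, else ambiguous.  Default `tau = 0.1`.  Flanks shorter than 3
  residues are ambiguous by convention.  A propensity average is used
  deliberately: it is transparent, configurable and reproducible, where a
  learned secondary-structure predictor would be none of the three.
- **Helix marks.**  Gly within the first two positions of helix I; `YF`
  dipeptide anywhere within helix II.
- **Interface occupancy.**  Dimerization-determinant positions (reference
  coordinates, default 7 positions) are projected through the alignment
  and scored for hydrophobic occupancy {A, I, L, M, F, V, W, Y};
  docking-determinant positions (default 5) are scored for identity to
  the reference residue.  Both position lists are configuration: such
  determinants are annotated graphically in structural work and are not
  an enumerable constant of the fold.  These two features are *reported*
  but do not enter lineage scoring, because they characterize
  AKAP-binding competence rather than lineage.

Classification is two-stage.  Superfamily membership (DPY-30-like vs
PKA-R-like vs none) is decided by best alignment score against the class
consensi, with a minimum-score floor (default 50) below which the call is
`none`; exact ties break toward PKA-R and the tie is visible in the
evidence.  Within PKA-R, an explicit additive scheme scores the lineages:

    loop PxxP     -> +2 R1        loop Pxx[ILV]  -> +2 R2
    nflank helix  -> +1 R1        nflank strand  -> +1 R2
                                  helix I Gly    -> +1 R2
                                  helix II YF    -> +1 R2

The loop motif is the defining feature and carries double weight; the
flank and helix marks are secondary determinants.  When the |R1 - R2|
margin is at or below `delta` (default 1) the call is **intermediate** —
a first-class outcome, not an error, because real family members (TPGS1
most prominently, with a type I loop and flank but type II helix marks)
genuinely straddle the boundary, and forcing a label would misrepresent
the evidence.  Every call carries per-feature evidence whose
contributions reproduce the scores exactly.  The classifier is
deterministic and weight-monotone.

## Phylogeny

Distances are p-distances (mismatches / comparable columns, columns with
a gap in either sequence excluded).  Trees are built by neighbor joining
(Studier-Keppler Q-criterion, Saitou-Nei branch lengths) with two
determinism contracts: Q-ties break toward the lowest taxon-index pair,
and negative branch lengths are clamped to zero with the deficit moved to
the sibling edge.  A distance + NJ + classical bootstrap stage was chosen
over maximum likelihood deliberately: it is fully self-contained,
closed-form testable (three-point formulas; least-squares oracles on
four-taxon topologies) and consistent on additive matrices, which is the
regime the synthetic generators produce.  It is *not* a substitute for ML
on hard empirical alignments.

Bootstrap supports are classical proportions: alignment columns resampled
with replacement, one tree per replicate, support of an internal edge =
fraction of replicates containing the same bipartition.  One seed governs
all replicates through spawned substreams (`numpy.random.SeedSequence`),
so supports are bitwise reproducible and independent of evaluation order.
When runs with and without an outgroup are combined, per-run supports are
reported and any cross-run aggregation (e.g. a mean) is an explicit,
flagged convention of the caller, not a default.

Outgroup rooting requires the outgroup to be monophyletic in the unrooted
tree and places the root at the midpoint of the separating edge; the
unrooted bipartition set is invariant under rooting/unrooting (tested on
random trees).  Monophyly of a label class means some edge isolates
exactly that class's leaves; singleton classes are monophyletic by
convention.

## Structure comparison

Coordinates are read with `gemmi` (PDB or mmCIF; first model, polymer
chains only, first alternate location, insertion codes preserved).
Chains carry one-letter sequences and C-alpha arrays with NaN rows for
unresolved residues.

Residue pairing between two monomers or dimers goes through sequence
alignment of the chains; for dimer-vs-dimer both chain-pair assignments
are evaluated and the one with the lower fitted RMSD kept, since the two
protomers of a pseudo-symmetric bundle have no canonical labelling.
Superposition is the closed-form Kabsch solution (SVD, determinant
correction so reflections are excluded); collinear configurations are
rejected by a singular-value rank check.  The analytic solver is verified
in the tests against a brute-force numeric minimizer over rotations and
translations to 1e-6 A.

RMSD is reported over **all** paired C-alphas by default, with an
optional iterative trim mode (drop pairs beyond `trim_sigma` x RMSD,
refit) because published superposition numbers do not always state
whether they derive from all-pair or trimmed fits; both modes are exposed
and reported side by side.  Dimer comparisons default to the
helix-loop-helix bundle core (configurable interval), excluding flanking
strands.

Chain masses are average (not monoisotopic) masses — the convention of
solution molar-mass measurements — computed as the sum of average residue
masses plus one water (18.02 Da), standard residues only.

## Binding model

Steady state: `R(c) = Rmax*c/(KD + c)`, unweighted nonlinear least
squares (matching typical instrument-software defaults; a weighted option
is exposed).  Initialization: `Rmax0` = top response, `KD0` = linearly
interpolated half-max concentration.  Standard errors come from the
linearized covariance.  Solver tolerances are tightened to 1e-14 so that
noise-free data are recovered to numerical precision.

Kinetics: association `R(t) = Req*(1 - exp(-(kon*c + koff)*t))` and
dissociation `R(t) = R0*exp(-koff*t)` are fitted locally per trace
(dissociation first, then association), `kon = (kobs - koff)/c`, and
rates averaged across traces with `KD = koff/kon` — the local-fit
convention of the instruments this emulates, not a global shared-Rmax
fit.  Fitted `koff` below 1e-6 /s is unresolvable within a
few-hundred-second dissociation window; the fit then reports `koff ~ 0`
and flags the derived KD as a lower bound only.  When a steady-state
response must be derived from traces, it is the time-average of the final
5% of the association phase.

Units are molar internally; micromolar ladders are converted at the
interface.  The shipped heterodimer ladder is `2.67, 0.889, 0.2963,
0.0988, 0.0329 uM` — an exact three-fold dilution series.  A source
listing `0.329` for the final step is accepted via
`heterodimer_ladder_um(literal=True)`; the default treats it as a decimal
slip because the other four steps are exact three-fold ratios, and user
data are never silently corrected.

## Synthetic-data generators

All generators are pure functions of (config, seed), with independent
substreams per replicate where applicable.

- **Family sequences** start from a lineage consensus and mutate each
  position independently with probability `divergence`, uniformly over
  the 19 alternatives.  Lineage-defining motif positions are *immune* to
  mutation, so classifier-recovery tests have a clean ground truth; a
  leaky mode (`motif_mutation_prob > 0`) exists for stress testing.
- **Tree evolution** applies, per edge of length L, Poisson(rate*L)
  substitution events per site, each a uniform jump among the 19 other
  residues.  A site is hit at all with probability `1 - exp(-rate*L)`,
  and on long branches the mismatch fraction saturates at 19/20 (the
  jump-chain stationary value, sampled exactly via the closed form
  `P(end = start | k) = 1/20 + (19/20)(-1/19)^k`).
- **BLI data** are exact 1:1-model values times `(1 + eps)`,
  `eps ~ N(0, noise_cv)` — multiplicative noise, matching the
  response-proportional error of the instrument class.
- **Coordinate clouds** are Gaussian point sets with a known rigid
  transform plus isotropic noise; the expected fitted RMSD is
  `sqrt(3)*sd` less the six fitted degrees of freedom.

What the generators do *not* emulate: indels, rate heterogeneity across
sites, empirical substitution matrices, baseline drift or mass-transport
effects in BLI, and real protein geometry beyond rigid-transform point
clouds.  Passing recovery tests therefore demonstrate correctness of the
estimators under their own model assumptions, not robustness to every
pathology of real data.

## Synthetic stand-ins for reference objects

Deposited structures and database sequences are user-supplied at run
time.  `ddscan.standins` builds synthetic stand-ins for demonstration and
testing: an SPA17-like crystal stand-in (four 75-residue chains, the
documented unit cell and space group, central dimer displaced from an
idealized reference dimer by a rigid transform plus coordinate noise
scaled to the documented 0.514 A core superposition), an RII-like core
dimer, and an 18-member human panel whose per-member features encode the
documented feature table (exactly five `Pxx[ILV]` members; TPGS1 as the
mixed case; helix-forming N-flanks on RIIAD1/CATIP).  These files and
sequences are labelled synthetic everywhere they appear and contain no
deposited coordinates or database residues; checks that run on them
validate the *pipeline arithmetic*, not the biology of the originals.

## Problem sizes and defaults used in shipped checks

Classifier recovery uses 500 sequences at divergence 0.1; bootstrap
demonstrations use tens of replicates on small alignments; the
KD-recovery script uses 50 replicates per ladder at 2% noise; Monte-Carlo
fit-bias checks use 200 replicates.  These sizes give stable medians and
proportions (binomial/SE arguments in the tests) while keeping any single
check in the seconds range.

## Known limitations

- The classifier is rule-based; weights express documented qualitative
  precedence, not a fitted model, and `intermediate` is the honest output
  for mixed feature sets.
- NJ + p-distance is consistent on additive data but will underperform ML
  on saturated or rate-heterogeneous alignments.
- Secondary-structure calls are propensity averages; they are intended
  for flank-level helix-vs-strand discrimination, not per-residue
  prediction.
- Kinetic fitting assumes clean 1:1 behaviour (no mass transport,
  bivalent analytes or reference-channel artifacts).
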