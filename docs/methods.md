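# Methods

## Statistical potentials

The package derives distance-dependent knowledge-based potentials from the
transmembrane (TM) and extramembrane (EM) regions of a set of labeled
membrane-protein structures (and optionally from whole globular structures,
tag GL). The interaction site of a residue is the unweighted centroid of its
side-chain heavy atoms; glycine uses CA, and a residue whose side-chain
atoms are all unresolved falls back to CA with a flag. Distances between
sites of residues more than one position apart along the chain are binned at
0.3 Å over [3.0, 9.9) Å — 23 regular bins — plus one overflow bin for
everything beyond 9.9 Å. Distances below 3 Å (clash artifacts) clamp into
the first bin by default; a discard policy is available. Inter-chain pairs
are excluded by default because the pair sum indexes a single sequence; a
flag includes them for oligomeric bundles, and the choice is recorded in
each table's provenance and checked at energy-evaluation time.

Counts use symmetric double storage: a pair event increments both (s1, s2)
and (s2, s1) cells (the diagonal twice), and each event contributes one
count to each endpoint's single-type table. Both tables then share the same
distance marginal and total, which makes the single-type and pair-type
log-ratios mutually consistent; all marginals are recomputed from the stored
tables so they remain exact after smoothing.

Two layers guard against sparse counts, applied in this order:

1. **Occurrence threshold.** A bin whose raw occupancy is below 10 yields a
   potential of exactly 0 and is masked. The guard inspects raw counts by
   default. The alternative — thresholding the smoothed counts — is kept as
   an option (`threshold_on="smoothed"`) but is not the default: near the
   3 Å boundary a bin can be almost empty yet inherit a sizable smoothed
   count from its populated neighbors while the reference n(d) stays tiny,
   which produces spuriously deep values supported by almost no events.
   Guarding on raw occupancy masks exactly those bins.
2. **Smoothing.** Surviving counts in each regular bin are replaced by the
   weighted sum of their ±4-bin neighborhood with geometric weights (3/4)^i
   (decay base 4/3), truncated at the boundaries without renormalization.
   The overflow bin is excluded from the neighborhood in both directions: it
   aggregates an unbounded distance range and would distort the 0.3 Å tail.

The potential is ΔW = −k_B·T · ln(n̂(·, d) · n̂ / (n̂(·) · n̂(d))) on smoothed
counts, with k_B·T = 0.5925 kcal/mol (298.15 K) by default and configurable.
Bins with a zero denominator are masked rather than infinite; masked bins
contribute exactly 0 to every downstream energy.

**Group potentials** pool amino acids with similar physicochemistry
(positive, negative, aromatic, aliphatic, uncharged-polar, small,
sulfur-containing). Before binning, each pair's distance is reduced by the
difference between each member's side-chain radius and the smallest radius
in its group, aligning interactions of differently sized members. The
reference terms n(d) and n come from the full unshifted pair counts of the
same region dataset, while n(g1, g2, d) and n(g1, g2) are group-pooled;
with this convention a one-member "group" pair reproduces the corresponding
per-amino-acid pair potential exactly. Radii are estimated from the input
structures as the mean distance of side-chain heavy atoms to their centroid
(Ala and Gly are 0 by this definition); shipped defaults from idealized
side-chain geometry cover types absent from the input.

## Energies and localization

The folding free energy under a table is the half pair-sum over ordered
pairs |i−j| > 1; per-residue contributions take each residue's half-share of
every pair it participates in, so they sum to the global energy to machine
precision (asserted at 1e-9 relative). Per-residue sums run over all
partners regardless of the partner's region label, because the classifier
scores every residue under both the TM and the EM tables. These are
effective statistical energies; no claim of experimental transferability is
made.

Leave-one-out potentials subtract the held-out protein's raw counts from the
pooled raw counts, then re-apply thresholding and smoothing. Smoothing is
linear but the threshold is not, so subtraction happens before both layers;
this makes the shortcut identical, bin for bin, to rebuilding the dataset
without that protein (asserted exactly in the tests). Each table's
provenance records the exclusion, and the benchmark asserts it before
scoring a held-out protein.

The localization index is the linear combination of the four per-residue
energies plus α5·ln N (natural log; the basis is absorbed by α5) and an
intercept, smoothed over a five-residue window with a literal ½ prefactor.
The ½·(5 terms) scale is kept as printed rather than a true mean because the
decision threshold absorbs it; at chain termini the truncated m-term sum is
rescaled by 5/m to keep the scale comparable, and windows never cross chain
boundaries. The decision rule is I_sm ≤ α0 ⇒ TM.

Balanced accuracy is piecewise constant in the weights, so direct
seven-parameter optimization is ill-posed. The fit is two-stage: α1…α6 from
unpenalized logistic regression of the TM label on the five features
(internally standardized, so rescaling any feature changes nothing — an
exact invariance, tested), negated so that low index means TM; then α0 by an
exhaustive sweep over the distinct smoothed-index values maximizing training
BACC, tie-broken toward the most balanced sensitivity/specificity and placed
midway between neighboring scores. On (near-)separable data the unpenalized
likelihood has no finite maximizer; the deterministic direction at the
iteration cap is used.

The benchmark is strictly leave-one-out: every protein's features are
computed under potentials that exclude it, and for each target the seven
parameters are refit on the other proteins' residues before the target is
scored. Pooled metrics aggregate all held-out residues (AUC by the rank
statistic with TM as the low-score positive class; pooled BACC from the
per-target calls); per-protein and per-topology (α-helical / β-barrel)
breakdowns are reported alongside, since pooling versus per-protein
averaging is a reporting choice.

## Synthetic data

The generator emulates the statistical structure the method consumes and
nothing else: no lipids, no rotamers, no energy minimization. α-helical
proteins are ideal-helix bundles (rise 1.5 Å, 100°/residue, CA 2.3 Å from
the axis, adjacent axes 10.4 Å apart) spanning a virtual slab, joined by
coil-like loops and capped by terminal tails; β-barrels place strands on a
cylinder with alternating in/out side chains. Side-chain centers sit 1.4 Å
radially beyond CA with Gaussian noise (σ = 0.15 Å) and are written as CB
pseudo-atoms plus backbone, so generated PDBs round-trip through the
parser; a full-atom mode is unnecessary except where radius estimation is
itself under test. All randomness derives from the seed; outputs are
byte-identical for equal (config, seed).

Residue types are sampled from region-conditional composition tables
(aliphatic/aromatic enriched in TM, charged/polar in EM) with two layers on
top:

- **Environment tilt.** Lipid-facing TM positions favor lipophilic types,
  core-facing positions polar and charged ones, and solvent-exposed loop
  apices favor charged types (strength 2.0 by default). This reproduces the
  radial organization of real membrane proteins and is what gives the
  potentials a broad type–distance coupling to learn from: the
  inverse-Boltzmann ratio normalizes composition itself away, so a
  composition contrast without positional structure is invisible to the
  method.
- **Steric budget.** A position only admits types whose side-chain radius
  fits half the nearest-neighbor distance minus a 0.8 Å surface gap. Real
  structures never show bulky pairs at overlapping center distances; without
  the veto, radius-shifted group counts acquire short-distance mass that no
  experimental dataset would contain.

**Planted contacts** enrich specific group pairs at a target distance in one
region (defaults: TM salt bridges at 4.0 Å, cation–aromatic 4.4 Å,
aliphatic packing 4.6 Å, aromatic stacking 5.5 Å; EM polar 4.5 Å,
sulfur–aromatic 5.2 Å, salt bridges 5.0 Å; each with retyping probability
0.6 within a ±0.35 Å window, at most 8 per protein). Planting
rejection-resamples residue types at pre-selected spatially close pairs —
geometry is never distorted — choosing member types whose radius shifts
make the center distance consistent with the target as a contact (surface)
distance, so the shifted group counts concentrate at the target. Planted
residues are locked against retyping by later contacts, and a contact with
zero candidate pairs anywhere in a dataset raises an infeasible-geometry
error.

The **matched null** generates uniform bundles in which every segment is a
TM-style helix, alternating TM/EM labels (with the parity carrying the TM
label randomized per protein), identical composition tables, a single
environment tilt shared by both labels, and no planted contacts. Each of
these conditions is necessary: labels attached to geometrically or
environmentally distinct segments leak real signal into the null.

What passing on this generator shows — and what it does not: the pipeline
recovers planted distance-specific contrasts and region-coupled composition
structure under strict leave-one-out, and finds nothing when the two regions
are statistically identical. It does not certify performance on
experimental structures, where contact geometry, composition gradients near
the interfaces, and dataset redundancy are all richer than the emulation.

## Numerical choices and problem sizes

- Bin edges are 3.0 + 0.3k exactly; binning adds a 1e-9 guard before the
  floor so that distances on an edge (e.g. 3.3 Å) land in the upper bin
  despite binary round-off.
- Potential TSVs store values with full repr precision and round-trip
  bit-exactly; counts bundles serialize the same way.
- altLoc conformers resolve to the highest occupancy; insertion codes are
  flattened into consecutive per-chain numbering; MSE/SEC map to Met/Cys and
  other hetero residues are skipped.
- Default test and acceptance problem sizes: 8–10 proteins for sum-rule and
  leave-one-out exactness, 200 proteins for planted-contact recovery, 50
  separable plus 40 null proteins (~9,000 residues each) for the classifier
  benchmark, 1e6 factorized pair events for the single-type independence
  null and 2e7 for the pair-type table, whose 20-fold larger cell count
  needs proportionally more events for the same maximum-deviation bound.

## Known limitations

- The classifier consumes 3D structures only; there is no sequence-based
  topology prediction.
- No membrane-plane geometry is computed; region labels come entirely from
  the annotation table, and boundary residues inherit whatever the
  annotation says.
- The five-residue index window inherently blurs TM/EM boundaries; most
  residual classification error sits within two residues of a segment
  boundary.
- Pooled group counts do not retain per-protein sub-counts, so group
  potentials are derived on full datasets only (the leave-one-out machinery
  covers the single-type and pair potentials the classifier uses).
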