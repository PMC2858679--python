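# Methods

## Chain model and secondary structure

A chain is an ordered list of residues keyed by author numbering plus
insertion code, each with atoms and a 3-state secondary-structure label
(H/E/C).  Three assignment paths exist, in order of fidelity:

1. a classic DSSP output file, reduced 8→3 as H, G, I → H; E → E;
   B, T, S, blank (and the newer P) → C.  B (isolated bridge) goes to
   coil because a single bridge residue lacks the extended geometry a
   strand axis needs.  The mapping is exposed (`DSSP_3STATE`) and can be
   overridden, since whether 3₁₀/π helices should brace motifs is a
   judgement call;
2. P-SEA assignment from Cα coordinates (biotite), for real structures
   without DSSP output;
3. ground-truth labels carried by the synthetic generator — synthetic
   chains never pass through an assignment heuristic, so decomposition
   and geometry are tested against exact truth.

Chain breaks are detected as consecutive-Cα distances above 4.5 Å (or a
missing Cα) and act as hard element boundaries: elements never span a
break, and Smotifs whose loop crosses one are dropped and logged.
Without this, physical gaps would masquerade as long loops.

## Decomposition

Maximal H/E runs meeting a minimum length (helix ≥ 4, strand ≥ 3
residues, configurable) become elements; shorter runs are demoted to
coil and absorbed into the loop between their neighbours, keeping the
Smotif string gapless.  k elements yield k − 1 overlapping Smotifs.  No
maximum loop length is imposed by default; a `max_loop` knob exists for
loop-library-style analyses restricted to short loops.  The minima are a
package choice: three Cα are the least that give a stable inertia axis,
and DSSP helices are at least four residues by construction.  Counts on
real chains can shift by ±1 element under different minima or assignment
heuristics, which is why both are exposed.

## Geometry

Element orientation is the eigenvector of the Cα inertia tensor (unit
masses) with the smallest moment, sign-fixed N→C.  For short ideal
helices this raw axis deviates measurably from the construction axis
(6.6° for a 10-residue, 2.8-turn helix, decaying roughly as 1/length) —
an intrinsic property of the estimator, not an error; all internal
contracts (placement round trips, binning) use the same estimator and
are self-consistent.

Frame convention for the meridian: e1 = M1; e2 = the component of L
orthogonal to e1, normalised (lies in plane Π); e3 = e1 × e2 (normal of
Π; Γ = span(e1, e3)); ρ = atan2(M2·e2, M2·e3) mapped to [0, 360).  A
signed azimuth is the only reading of a meridian with a 0–360 span; the
zero is placed in the Γ plane, so ρ measures how far M2 tilts out of Γ
toward the Π-plane direction.  Under this convention a mirror image maps
ρ → (180 − ρ) mod 360 while preserving D, δ, θ — chirality is captured
(a motif and its mirror coincide only at ρ = 90/270).  Any fixed
convention with the same span gives the same bin co-membership
relations; absolute ρ values are convention-specific.

Degenerate case: when L is within 1° of (anti)parallel to M1, Π is
undefined; the Smotif is flagged, ρ is reported as 0 and the motif is
binned in the wrapped ρ-bin containing 0.  Deterministic handling of a
measure-zero case beats an error.

Superposition RMSD pairs Cα C-terminus-anchored on SS1 and N-terminus-
anchored on SS2, each trimmed to the shorter element, loops excluded —
anchoring at the loop junction preserves exactly the feature the four
coordinates describe — and minimises by the Kabsch SVD fit with the
proper-rotation correction.

## Classification

Half-open bins [lo, hi); D is clamped to 40 Å before indexing, so all
larger distances share the last bin; δ/θ at exactly 180° fold into the
last angular bin; ρ is shifted by the 30° offset and wrapped, making
[330°, 30°) one bin.  The default ("tailored") scheme 4_60_60_60 has
10 × 3 × 3 × 6 = 540 cells per bracing class.  The number of *occupied*
cells in any given collection is far smaller and is reported separately
(`SmotifLibrary.occupied_bins`); the implementation deliberately exposes
both and hard-codes neither.

Scheme quality is evaluated by sampling same-bin and different-bin
Smotif pairs and superposing them; the headline statistic is the
fraction of same-bin pairs under 1 Å Cα RMSD.  On ensembles whose
motifs recur around archetype geometries (the realistic regime,
emulated by `clustered_smotif_ensemble`), the default scheme keeps that
fraction above 0.85 while a 8_90_90_180 coarsening roughly halves it;
on a uniformly random ensemble same-bin pairs are rare and loose for
every scheme, which is why the clustered generator exists.

## Frequency library

Fold classifications are redundant, so counting is done per round with
exactly one structure drawn uniformly per fold; per-bin instance counts
are averaged over n_rounds (default 100, matching the convention of
repeating the random representative selection 100 times) and normalised.
Normalisation is **global** across all four classes — one simplex —
because the novelty score multiplies frequencies of mixed-class motifs
in a single product; a per-class mode exists for class-wise frequency
profiles.  Instance counts (not fold-presence counts) are averaged.  One
seeded generator drives the whole build; identical seeds give identical
libraries.

Saturation curves count first appearances of distinct occupied bins per
class over deposition dates.  Fold-population categories are the
half-open partitions [1,2), [2,10), [10,50), [50,100), [100,∞), plus an
explicit "new" flag that overrides size.

## Novelty

S = (1/N) Σ ln fr_i — the length-normalised log of the product of the
string's frequencies, so S does not grow with chain length and equals
ln f when all frequencies are equal.  Unseen bins enter at a floor of
half the smallest nonzero library frequency (configurable): finite, yet
strictly rarer than everything observed.  Z-scores use the population
standard deviation, so mean 0/sd 1 hold by construction on every scored
population.  The strict flanking-length comparison applies each
element's tolerance by its own kind (strand 2, helix 4, boundary
inclusive), so mixed-class motifs use both.  Shared-motif counting
between two strings is a greedy one-to-one matching on (class, bin),
which attains the multiset-intersection maximum.

## Features

Non-bonded contacts: symmetric heavy-atom distance criterion, default
cutoff 4.5 Å, between the bracing elements only; loop atoms never
participate, and for a zero-length loop the sequence-adjacent junction
residue pair is excluded so covalent neighbours are not counted.  No
contact typing is attempted — the analysis consumes only the scalar
count — and the cutoff is exposed for sensitivity analysis.  The
kd-tree implementation is tested for exact agreement with the O(n²)
enumeration.  Motif "size" defaults to the bracing residues only; a
`total` mode also counts the loop.

Solvent exposure is Shrake–Rupley accessible surface (probe 1.4 Å,
element-keyed radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å, 1000 Fibonacci
points per atom, via biotite) summed per residue in the context of the
whole chain, then averaged over the motif's residues with or without the
loop.  When DSSP output is available its ACC column can be used
verbatim instead (`read_dssp_acc`).

## Synthetic generator

Ideal elements use canonical textbook parameters: helix rise 1.5
Å/residue, twist 100°/residue, radius 2.3 Å; strand rise 3.3 Å/residue
with an alternating ±1.0 Å zigzag.  Inverse placement poses an ideal
SS2 so the pair realises a prescribed (D, δ, θ, ρ): under the frame
convention the azimuth solution is unique, and the solver always
verifies by forward computation against the (0.5 Å, 3°, 3°, 5°)
tolerance, raising rather than approximating.  Degenerate requests
(δ ∈ {0°, 180°} with a constrained ρ, or θ ∈ {0°, 180°} with ρ ≠ 0) are
rejected with the violated constraint named.  Loop Cα are decorative
Catmull–Rom points — no geometry operation reads them — but their
spacing is validated against the chain-break threshold so generated
chains decompose without spurious breaks; contact and exposure tests use
dedicated atom fixtures instead.

Fold populations: a universe of bins (default 500, interleaved across
the four classes) carries Zipf(s = 1.5) base frequencies, shuffled so
frequency rank is independent of bin enumeration.  Known folds draw
string lengths uniformly from 3–12 and bins i.i.d. from the base;
novel folds draw each motif from the rarest quartile (base-renormalised)
with probability λ = 0.8, otherwise from the base.  These defaults are
the package's standard study conditions for novelty recovery: 200 known
+ 200 novel folds give a mean-z separation near 1.9 that is
sign-stable across seeds, and λ = 0 reduces exactly to the null.  What
the simulator does **not** emulate: real bin-frequency distributions are
not exactly Zipf, real novel folds mix rare-motif enrichment with
topological novelty, and real strings are not i.i.d. draws (adjacent
motifs share an element).  Passing tests therefore demonstrate that the
pipeline recovers planted enrichment under controlled conditions, not
that any particular real structure will score as novel.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small problems — 100 placement
round trips, 2 000-round library enumerations on ≤ 3 structures,
40-cluster × 6-member ensembles, 200 + 200-fold populations — chosen so
each check isolates one property with negligible Monte-Carlo ambiguity.
Tolerances: 1e-6 (degrees/Å) for rigid-motion invariance, the generator
tolerance (0.5 Å, 3°, 3°, 5°) for round trips, 1e-9 for normalisation
identities.  Ties at bin boundaries always resolve to the upper bin via
the half-open convention; exact 180° angles and the D cap are folded
into the last bin to keep assignment total.

## Known limitations

* Absolute meridian values depend on the documented frame convention;
  only bin co-membership is convention-independent.
* P-SEA and DSSP disagree at element termini; real-chain decomposition
  counts are sensitive to the assigner and the length minima (±1
  element is common).
* The contact count is a plain distance criterion: no hydrogen-bond
  geometry, no contact typing, no interface complementarity.
* The worked-example and bin-quality checks on real PDB entries require
  those entries to be present locally or fetchable; all other results
  are fully reproducible from seeds alone.
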