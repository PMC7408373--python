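# Methods

## Protein-block assignment

The alphabet is the canonical 16-prototype protein-block table (labels
a–p), shipped as plain text in `src/pbneq/data/pb_prototypes.dat`.  Each
prototype is the 8-vector (ψ<sub>i−2</sub>, φ<sub>i−1</sub>, ψ<sub>i−1</sub>,
φ<sub>i</sub>, ψ<sub>i</sub>, φ<sub>i+1</sub>, ψ<sub>i+1</sub>,
φ<sub>i+2</sub>) in degrees.  Assignment minimises the RMSDA
√(Σ d(w<sub>k</sub>, p<sub>k</sub>)²/8) where d is the shortest-arc angular
distance; ties (measure-zero on real data) break to the alphabetically
first label so assignment is a deterministic function of the window.  The
table's integrity is enforced at load (16 distinct labels, angles in
(−180, 180]) and validated behaviourally by the test suite: every prototype
is a fixed point of assignment, and an ideal α-helical window (φ = −57,
ψ = −47) assigns to block *m*, the core-helix block.  The pairwise
prototype RMSDA matrix (exposed as `separation_matrix`) has a minimum
off-diagonal entry of ≈ 54°, which is why nearest-prototype assignment is
essentially immune to the 5° angular noise used throughout: jittered
prototype windows reassign correctly in ≥ 99% of 10,000 trials.

Users may substitute any alphabet of size n in the same text format;
N_eq then ranges over [1, n].

## Dihedrals, chain breaks, undefined labels

φ(i) is the torsion C(i−1)–N(i)–CA(i)–C(i) and ψ(i) is
N(i)–CA(i)–C(i)–N(i+1), computed with the standard atan2 construction and
reduced to (−180, 180].  An angle is undefined (NaN) at chain termini, when
any contributing residue lacks one of N/CA/C, and across chain breaks.  A
break is declared between residues i and i+1 when their numbering is
non-consecutive **or** the C(i)–N(i+1) distance exceeds 2.5 Å; missing
residues are the typical signature of unresolved (disordered) stretches and
must not generate spurious torsions across the gap.  Any five-residue
window containing an undefined dihedral — in particular the first two and
last two positions of every chain — yields the undefined label Z.

PDB parsing is delegated to Biopython's `Bio.PDB`; alternate locations
resolve to the highest-occupancy conformer, waters and non-amino-acid
heteroatoms are ignored, and models with differing residue sets are
reconciled to the union with per-model gaps (logged).  Positions are
1-based sequential in chain order, matching the numbering convention of
per-residue predictor outputs; an integer offset parameter handles tracks
numbered against a different construct start.

## N_eq and classification

N_eq = exp(−Σ f<sub>x</sub> ln f<sub>x</sub>) over the 16 blocks, natural
logarithm, 0·ln 0 = 0.  Z cells are excluded from both numerator and
denominator rather than treated as a 17th symbol, since the sum runs over
the alphabet only; a position needs at least `min_models` (default 2) valid
observations for a defined N_eq — with a single observation the index is
trivially 1.  Ensemble-level summaries (fractions of positions at
N_eq = 1, > 2, > 8) are taken over defined positions only.

Class boundaries are left-closed: rigid < 4 ≤ flexible < 6 ≤
highly_flexible < 8 ≤ disordered.  The anchor values 4/6/8 are the
field's conventional markers on the continuum; the interval topology at the
exact boundaries is a package choice (configurable).

## Comparison battery

All correlations are Pearson product-moment on continuous values.  The
stratified means use N_eq < 4, 4 ≤ N_eq ≤ 8 (both ends included) and
N_eq > 8.  The twelve N_eq classes are [1,2), [2,3), …, [11,12), [12,16];
the class-level correlation uses the class **lower bound** as the x-value
(midpoint or within-class mean N_eq would be equally defensible; the lower
bound is the simplest deterministic representative and the choice is
documented here precisely because it is open).  In the prediction-rate
sweep the truth at threshold t is disordered iff N_eq > t; equality counts
as ordered, so at t = 1 every fully rigid position (N_eq = 1, the majority
in disordered-ensemble data) belongs to the ordered truth class.
Score-only tracks are binarized at 0.5, the midpoint of the documented
[0, 1] score range (each predictor documents its own operating point, so
the threshold is configurable); native two-state calls, where a predictor
provides them, are preserved unless explicitly overridden.  Multiple tracks
are analysed independently; no multiple-testing correction is applied.

## The synthetic generator

The generator's purpose is parameter recovery: every quantity the pipeline
reports must be checkable against known truth.

**Label sampling.** Each specified interior position carries a target PB
mixture; labels are drawn independently per model.  The default
`ped_like_spec` emulates the N_eq distribution characteristic of ensembles
of disordered proteins: 58% of positions fully rigid (one block), 15% with
near-uniform block usage (N_eq > 8, drawn as k-block uniform mixtures,
k ∈ 9..16), 21% intermediate (k ∈ 3..8), and the remaining 6% two-block
mixtures with N_eq in (1, 2].  Default sizes are 60 residues, 200 models,
σ = 5° angular noise — large enough for stable per-position frequencies,
small enough that the full pipeline runs in seconds.

**Backbone realisation.** Adjacent PB windows share six of their eight
dihedrals, so an arbitrary per-position label sequence cannot be realised
exactly on one continuous backbone: a residue cannot simultaneously satisfy
two conflicting prototype windows, and approximate compromises (averaging
the overlapping demands, or giving each residue only its own central φ/ψ)
were measured to destroy nearest-prototype recovery (≈ 18–25% for mixed
positions).  The generator therefore realises each sampled label as a
self-contained five-residue fragment: the 8 window dihedrals are exactly
the internal torsions needed to build five residues by natural-extension
(NeRF) chain construction with standard geometry (N–CA 1.46 Å, CA–C
1.52 Å, C–N 1.33 Å; N–CA–C 111.0°, CA–C–N 117.2°, C–N–CA 121.7°;
ω = 180°), plus wrapped Gaussian noise of s.d. σ per angle.  Fragments are
translated 50 Å apart, so every window that would straddle two fragments is
invalidated by the 2.5 Å break rule and labelled Z — fragment boundaries can
never produce wrong labels, only undefined ones.

Within one model, probes occupy every fifth position; the probe offset
rotates with the model index (model k realises positions ≡ first + k mod 5),
so across M models every specified position is realised in about M/5
models, each realisation drawn from that position's own mixture.  The
bookkeeping records exactly which label was realised where; the empirical
mixture over realised cells (not the target mixture) is the oracle for
recovery and N_eq tests, which removes multinomial sampling error from the
contract: re-assignment must recover ≥ 99% of realised labels, and the
recomputed N_eq must match the empirical mixture's exponential entropy
within 0.05.  In practice recovery is 100% at σ = 5° because of the ≈ 54°
prototype separation.

**What the generator does not emulate.** Chains are geometrically
discontinuous between fragments and may self-intersect; there are no
sequence-dependent conformational preferences (all residues are emitted as
ALA — assignment uses backbone atoms only), no glycine/proline dihedral
peculiarities, and no correlation between neighbouring positions' mixtures.
Passing tests therefore demonstrate the correctness of the measurement
machinery (dihedrals, assignment, entropy, statistics) on ensembles with
known truth — not that real ensembles satisfy any particular N_eq
distribution, nor anything about the biological accuracy of disorder
predictors.

**Score tracks.** Given a true N_eq profile and a target correlation ρ,
scores are clip<sub>[0,1]</sub>(0.5 + 0.15·(ρ·z + √(1−ρ²)·ε)) with z the
standardised N_eq and ε standard normal.  The affine map keeps ±3 s.d.
inside [0.05, 0.95], so clipping affects well under 1% of positions and the
measured Pearson correlation converges to ρ (attenuation < 0.01 at
|ρ| ≤ 0.75).  Emitters serialise tracks in the Disopred3, PrDOS and
IUPred2A dialects so the real parsers are exercised end to end.

## Numerical choices and edge cases

* Angles are reduced to (−180, 180] everywhere; angular distance is the
  shortest arc, in [0, 180].
* Degenerate torsion geometry (collinear or coincident atoms) yields NaN,
  which propagates to Z labels rather than raising mid-pipeline.
* `neq` validates non-negativity and normalisation (tolerance 1e-6) and
  evaluates the entropy via `scipy.stats.entropy`; the degenerate profile
  gives exactly 1.0 and the uniform 16-block profile 16.0 to machine
  precision.
* Correlation requires ≥ 3 pairs and non-constant series; the class-level
  correlation requires ≥ 3 populated classes; empty strata are reported
  with count 0 rather than dropped silently.
* Every CLI run writes `provenance.json` (configuration echo, seed,
  prototype-table fingerprint); identical configuration and inputs
  reproduce byte-identical outputs.

## Problem sizes used by the test suite

The shared end-to-end fixture uses the default study conditions (60
residues × 200 models, σ = 5°, fixed seed); statistical recovery tests use
1000-position tracks, where the ±0.06 tolerance on a recovered Pearson
correlation corresponds to the Fisher-z 95% band; multinomial N_eq recovery
tests use 2000 models.  The acceptance script's pipeline cross-check uses a
27-residue, 40-model ensemble — enough for an exact match on the
degenerate profile, which is noise-free by construction.
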