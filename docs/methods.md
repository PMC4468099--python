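# Methods

## Problem

Given a group of 3–6 homologous RNA sequences (as an alignment, or as
windows cut from a multiple genome alignment), decide whether the group is
a conserved, structured non-coding RNA.  The classifier consumes four
features — structure conservation index (SCI), mean single-sequence folding
free-energy Z score, mean single-sequence normalized ensemble-defect Z
score, and average alignment Shannon entropy — and emits P(ncRNA) from an
RBF-kernel support-vector classifier.

## Thermodynamic folding core

All structure prediction rests on a reduced nearest-neighbor free-energy
model ("Turner-lite", `data/turner_lite.dat`):

* helix stacking increments for all 36 ordered pairs of the six canonical
  pairs (AU, UA, GC, CG, GU, UG), satisfying strand-reversal symmetry;
* hairpin, bulge and internal loop initiation penalties tabulated to a
  maximum size and extrapolated as `dG(L) = dG(Lmax) + 1.75·RT·ln(L/Lmax)`;
* a linear multibranch model `a + b·(helices) + c·(unpaired)` with
  a = 9.3, b = −0.6, c = 0.0 kcal/mol.  The per-helix value −0.6 follows
  the estimate from optical melting experiments;
* a terminal AU/GU helix-end penalty of 0.5 kcal/mol, charged once per
  loop-bordering pair (equivalently, per helix end);
* temperature 310.15 K with RT = 0.6163 kcal/mol.

Dangling ends, coaxial stacking and special-case loops are deliberately
omitted.  The point of the reduction is exact internal consistency: the
energy of any structure decomposes identically in `energy_of`, in the
minimum-free-energy recursions, and in the partition function, so
enumeration over all pseudoknot-free structures of a short sequence is an
*exact* oracle for the whole core (MFE energy, Q, every base-pair
probability, ensemble defect, and the minimum-defect structure agree with
brute force to 1e−8 relative; see `tests/test_acceptance.py`).  No
bit-compatibility with any external folding package is attempted — features
downstream are Z scores and energy ratios, which are robust to the exact
parameter values.

Implementation notes:

* Minimum hairpin loop: 3 nt.  N residues never pair but count toward loop
  sizes.  Internal/bulge loops are capped at 30 unpaired nt in the search
  (standard practice; the cap cannot bind on oracle-sized sequences).
* The recursions run as numba-compiled kernels parameterized by
  per-position-pair matrices, so the identical code folds single sequences
  and alignment columns.
* Partition-function arrays are rescaled per nucleotide above 200 nt
  (Vienna-style `exp(−1.07·E_mfe/(RT·N))` factor); log Q is always exact in
  the log domain, keeping the computation finite far past N = 2000.
* Base-pair probabilities use the standard inside–outside construction; the
  multibranch outside term is accumulated naively per enclosing pair, which
  is O(N⁴) with a tiny constant — the right trade at window scale (N ≤ 150).
* Tracebacks are deterministic: candidate cases are evaluated in a fixed
  order and replaced only on strict improvement, so paired configurations
  win ties and identical inputs give bit-identical structures.
* MaxExpect-style structures maximize `Σ 2γ·p_ij + Σ q_i` by dynamic
  programming; at γ = 1 (the default) this minimizes the ensemble defect
  `n(s,Ω) = N − Σ_i P(i,s)` over the pseudoknot-free structure space, which
  is also how the defect statistic for the Z score is defined.

## Common structure and SCI

SCI = E_c / E_s, where E_s is the mean single-sequence MFE of the group
and E_c the mean per-sequence energy of one *common* structure.  The
default engine predicts that common structure by folding the alignment
columns with the same MFE recursions, averaging every energy term over the
rows (RNAalifold-flavored, without covariance bonuses).  A row that is
gapped or non-canonical at a paired column pair contributes a fixed
+0.5 kcal/mol penalty (per row, per pair) instead of its energy terms, so
sparse exceptions do not veto well-supported pairs; loop sizes are measured
in columns.  The consensus is projected onto each row by deleting gap
columns and dropping pairs that become non-canonical or sub-minimal, and
each projected structure is scored with `energy_of`.

On an alignment of identical sequences the column recursions reduce exactly
to single-sequence MFE folding, giving SCI = 1 — the anchor the feature is
calibrated around.  Degenerate groups where nothing folds (E_s ≥ 0) get
SCI = 0 by convention, and σ = 0 nulls give Z = 0, avoiding infinities on
pathological inputs.

An adapter for an external simultaneous-folding executable (e.g. Multilign)
fills the same result type when such a tool is installed; the pipeline
falls back to the internal engine with a logged warning when it is not.
The adapter passes tool options through verbatim rather than inventing
defaults.

## Z scores and their surrogates

The null for a sequence statistic is mononucleotide shuffling: uniform
permutations of the residues, preserving composition exactly.  Z =
(E − μ)/σ over that null, for (a) MFE free energy and (b) normalized
ensemble defect of the MEA structure.  Because null moments depend only on
length and composition, two ε-SVR regressors (RBF kernel) per statistic
predict μ and σ from (length, GC, G/(G+C), A/(A+U)).  Features are min–max
scaled to [−1, 1] and targets standardized; hyperparameters (C, γ, ε) come
from 5-fold cross-validated grid search over powers of two (C ∈ 2^−5..2^15,
γ ∈ 2^−15..2^3, exponent stride 2; ε ∈ {0.01, 0.05, 0.1, 0.2}); σ
predictions are clipped to ≥ 1e−6.  Models persist as JSON with all
scaling and grid metadata and predict with nothing but numpy.

The benchmark protocol (`multifind.protocols.surrogate_recovery`, also run
by `scripts/acceptance.py`) trains on 500 sequences stratified over the
4-D (length 30–60, GC 25–75%, G/GC 25–75%, A/AU 25–75%) box with 100
shuffles per sequence, and correlates predicted against sampled Z on 100
fresh sequences.  The held-out reference uses 1,000-shuffle nulls: a
100-shuffle reference Z carries sampling noise of ≈ 0.15 on a between-
sequence spread of ≈ 0.9, which by itself caps any achievable correlation
near 0.985 — too coarse to resolve a surrogate in the 0.99+ range.  At
1,000 shuffles the reference noise contributes < 0.001 to 1 − R.  The
remaining error budget at this training scale is dominated by sampling
noise in the 100-shuffle *training* targets (the σ estimates carry ≈ 7%
relative standard error), which bounds what any regressor can recover;
training with more sequences or deeper nulls tightens it further at
proportional cost (the full-scale analogue is ~17,000 sequences × 1,000
shuffles).

## Classifier

c-SVC with RBF kernel, trained on equal-sized positive and negative
feature-vector sets, (C, γ) by 5-fold CV grid search (ties resolve toward
moderate values), probabilities by the standard Platt sigmoid as
implemented in scikit-learn; the fitted machine is exported to plain
arrays + sigmoid coefficients and persists as JSON.  The feature order is
fixed (SCI, ΔG Z, defect Z, entropy); a three-feature variant omits the
defect Z for ablation.  Features are scaled per training split only
(leakage-safe), so cross-validation rounds never see test statistics.
Family-aware splits keep every family entirely in train or test, with test
sets disjoint across rounds and sized to ≈ 10% of groups (whole families
are added while they bring the count closer to the target).

## Synthetic data

The generator emulates the study conditions without any download:

* **Structured families**: a template sequence + structure, mutated per
  sequence at rate 0.15/position; mutations at paired positions are
  compensatory (a fresh random canonical pair) with probability 0.9,
  otherwise one side mutates freely.  Shipped layouts: a hairpin, a
  two-stem junction, and a cloverleaf; randomized variants of those shapes
  generate arbitrarily many families.  The alignment is positional (no
  indels by default).
* **Negatives**: uniform permutation of alignment columns — preserving
  length, composition and per-column entropy exactly, so classifier signal
  can only come from structure.
* **Composition-stratified random sequences**: scrambled-lattice sampling
  over the (length, GC, G/GC, A/AU) box with realized counts within one
  residue of target.
* **Synthetic genome blocks** (test fixtures): homologous background rows
  generated as point-mutated copies (rate 0.2) of a common ancestor, with
  one structured family embedded per block.  Background entropy then falls
  in the range the classifier was trained on, as in a real genome
  alignment; unrelated uniform-random rows would not.

What passing these tests does *not* show: performance on real genomic
alignments with indels, repeats, composition skew, or ncRNA classes whose
structure diverges from the template shapes; nor robustness of alignment
quality (alignments are taken as given).

## Genome windowing protocol

Blocks that contain every required genome and lie in intergenic regions of
the reference are kept (blocks straddling a boundary are trimmed to the
intergenic part); blocks are cut into 100-column windows at 50-column
steps, plus an end-anchored final window when the last full window falls
short of the block end.  Windows are defined over alignment *columns*, the
natural unit when the input is an alignment block; per-row genome
coordinates are recovered by gap-aware counting (internally 0-based
half-open; BED read as 0-based, GFF3 converted from 1-based inclusive).
A window is an ncRNA window when > 30% of its reference nucleotides overlap
any annotation, or it contains > 50% of an annotation's nucleotides (any
single annotation suffices).  Windows whose rows de-gap below 30 nt are
skipped.  Scanning is forward-strand by default.  Ranked results are
evaluated with ROC (threshold sweep over unique scores) and
true-positives-versus-candidates curves, optionally stratified by average
column entropy at S = 0.3 (S > 0.3 marking low-similarity/high-diversity
windows, where the thermodynamic features rather than SCI carry the
decision; ~0.25 may suit yeast-like alignments better).

## Known limitations

* The energy model is intentionally small; absolute energies differ from
  full Turner-2004 implementations (no dangles/coaxial terms).
* The consensus engine scores columns independently of phylogeny and skips
  covariance bonuses; on very low-identity alignments it will find fewer
  common pairs than a simultaneous fold-and-align method.
* Windows containing only a fragment of a structured element (31–50%
  overlap) are labeled ncRNA by the overlap rule yet carry weak folding
  signal; they are genuinely hard cases of the windowing protocol.
* Probability calibration inherits scikit-learn's Platt implementation;
  calibrated probabilities are monotone in the margin but not guaranteed
  to be well-calibrated on out-of-distribution windows.
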