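# Methods

This note documents the models and algorithms implemented in `cmprof`, the
choices made where the design was genuinely open, and what the synthetic
data used by the test suite does and does not establish.

## Correlated-mutation statistics

All counts come from a thinned MSA whose columns index the seed sequence
(seed-gap columns are removed on input). For a position pair (i, j), the
20×20 table N(a_i, b_j) counts sequences non-gap at both positions;
non-standard residue letters (B, Z, X, U, O) are treated as gaps so the
20-letter alphabet stays exact. The low-number correction is an additive
per-cell pseudocount:

    f(a_i, b_j) = (N(a_i, b_j) + λ) / (n_eff(i, j) + 400 λ),   λ = 0.05 by default.

λ is a free, unitless regularizer; 0.05 is a conventional choice for
20×20 pair tables and is exposed in `CoevolutionConfig`. Marginals are
derived from the corrected joint (not from raw single-column counts), so
exact statistical independence gives a log-odds of exactly zero even with
pseudocounts. The converse edge case is worth noting: a *fully conserved*
column pair has a degenerate (single-cell) empirical distribution whose
pseudocount-corrected joint is no longer exactly the product of its
marginals, so conserved alignments produce small nonzero — but always
finite — signals; they vanish only as λ → 0. When n_eff = 0 the corrected
joint is exactly uniform and every log-odds is exactly zero.

Natural logarithms are used throughout. The log base only rescales the
correlated-mutation signals and hence the cepstral features; since the
distance threshold d0 and the scale α of the CM score are free parameters,
the choice is immaterial up to their values.

The self term j = i is kept in each correlated-mutation vector so the
vector has length exactly n; it carries the column's self-association.
Ordered amino-acid pairs are indexed as 20·idx(a) + idx(b) over the
alphabet ACDEFGHIKLMNPQRSTVWY, fixed package-wide and recorded in each
profile's metadata so incompatible profiles cannot be compared silently.

## LPC and cepstral features

The signal model is the forward predictor ŝ(t) = Σ_{k=1..p} a_k s(t−k)
(Rabiner–Juang convention). Minimizing the summed squared error over the
full signal support gives symmetric Toeplitz normal equations in the
autocorrelation r(k) = Σ_t s(t) s(t+k), solved by Levinson–Durbin. No
windowing or pre-emphasis is applied to the signal. Degenerate inputs are
handled explicitly: a zero signal (r(0) = 0) short-circuits to zero
coefficients and zero cepstra; if the prediction error underflows
mid-recursion the order is truncated and the remaining coefficients are
zero. The cepstrum recursion

    c_m = a_m + Σ_{k=1..m−1} (k/m) c_k a_{m−k}        (m ≤ p)
    c_m =       Σ_{k=m−p..m−1} (k/m) c_k a_{m−k}      (m > p)

is the standard expansion of −log A(z) for A(z) = 1 − Σ a_k z^{−k}; the
sign convention is pinned by an independent test oracle (the FFT cepstrum
of the all-pole filter, computed from the magnitude spectrum via the
minimum-phase identity, which avoids phase unwrapping). c_0 is excluded
and the first L coefficients are kept; defaults p = 6, L = 9.

Normalization is per cepstral order, pooled over all n × 400 entries of
one protein, to zero mean and unit variance — so every order contributes
equally to Euclidean distances regardless of its natural decay. An
alternative per-position scope is available via a switch; per-order is the
default because the CM score compares the same (a, b) pair across
positions, and pooling across the protein preserves between-position
contrast within each order. Zero-variance orders map to zeros rather than
NaN.

## Scoring and alignment

The combined score is S = w_mut·S_mut + w_cor·S_cor + w_sec·S_sec.

* S_mut is the symmetric profile cross score ½ Σ_a [q(a_i) t(a_j) +
  q(a_j) t(a_i)] — the standard frequency-times-log-odds profile–profile
  form. It is isolated in one function so alternatives can be swapped.
* S_cor aggregates the 400 thresholded distances as a *mean*:
  α · (1/400) Σ_(a,b) [d0 − d(c(a_i,b), c(a_j,b))]. The mean keeps d0 on
  the scale of a single L = 9 z-normalized vector distance (null
  expectation ≈ √(2L) ≈ 4.2, against preset d0 of 2.8–3.2); a sum variant
  is available via `cor_aggregate`.
* S_sec is a binary state-match indicator over {H, E, C}.

Alignment is global Needleman–Wunsch with three states and affine gap
cost g_open + (k−1)·g_ext. The baseline is *subtracted* from every
substitution score (configurable sign): a larger baseline makes matching
less attractive and shortens alignments. End gaps are penalized by
default; a semi-global mode with free end gaps exists but is off.
Traceback tie-breaking is fixed (match > gap in protein 1 > gap in
protein 2) so results are deterministic. The DP is verified against
exhaustive enumeration of all global alignments for matrices up to 7×7.

The five bundled presets hold the selected parameter values for each
scoring-term combination, including gap penalties and baseline; the
CM-score scale is α = 0.025 throughout.

## Model building and MaxSub

Models are built by copying template Cα coordinates at aligned positions;
unaligned target residues are absent. MaxSub uses a threshold d = 3.5 Å,
seed windows of 4 consecutive aligned residues, and normalization by the
reference (experimental) length — the published defaults; the
normalization length is a flag since either chain could be used. Each
window seeds a Kabsch superposition (SVD-based, proper rotation enforced)
that is re-fit on the residues within d until a fixed point, capped at 20
rounds. The best subset scores Σ 1/(1 + (d_i/d)²), so a residue exactly
at the threshold contributes ½, a perfect model scores exactly 1, and
atoms far from their reference positions contribute nothing. PDB input
keeps first-model, first-altloc Cα atoms of one chain.

## Parameter selection

Simulated annealing maximizes an arbitrary objective — in the CLI, the
average MaxSub of models from a manifest of training pairs — with
Gaussian proposals clipped to per-parameter boxes, Metropolis acceptance
exp(Δ/T), and geometric cooling. Schedule, step sizes and boxes are
configuration, not fixed constants; runs are reproducible given the seed,
and the full evaluation trace is returned. The search-and-score loop is
general enough that it recovers a 1-D quadratic peak to within 0.05 in
the test suite.

## Synthetic data: what it emulates and what it does not

`simulate_msa` draws sequences independently around an ancestral sequence
(star phylogeny) with per-site mutation rate 0.35 into a 4-letter
per-column state set; planted pairs substitute compensatorily with a
given coupling probability (0.9 by default), which produces strong,
localized mutual-information peaks like those of contacting residue
pairs. `simulate_sister_families` derives two families from a shared
ancestor (30% of columns diverged in the second family's ancestor),
shares the planted pairings between them, and deletes non-planted columns
independently at rate 0.05 per family, yielding a known column
correspondence across families. The end-to-end study conditions used in
the tests are 80 columns × 300 sequences with 8 planted pairs. These
sizes keep the full pipeline — thinning, counting, 400·n LPC fits per
protein, alignment — in the seconds range on one CPU.

What this does *not* emulate: phylogenetic correlation between sequences
(star topology inflates effective counts relative to real MSAs and
contains no tree-induced spurious covariation), indel placement inside
coupled segments, alignment errors in the input MSA, and the weak,
distributed coevolution typical of real families. Passing the
planted-truth tests therefore shows the machinery is correct and that the
CM term does not degrade an easy correspondence — it does not certify
the benchmark-scale improvements achievable on real remote-homolog data,
which require database-derived MSAs, real PSSMs and predicted secondary
structure.

## Numerical choices and limitations

* Tolerances: corrected joints sum to 1 within 1e-12; Levinson–Durbin is
  held to 1e-8 relative residual against a dense Toeplitz solve; cepstra
  to 1e-6 against the FFT oracle; profile normalization to 1e-9 (mean)
  and 1e-6 (variance).
* Degenerate geometry (fewer than 3 points, collinear sets) raises an
  explicit error in Kabsch; MaxSub skips such seed windows.
* The fallback sequence profile (used when no PSI-BLAST PSSM is given)
  mixes counts with BLOSUM62 background frequencies and scores in log2
  units; real PSSM files take precedence and are parsed verbatim.
* Identity for MSA thinning is computed on the pre-aligned rows (no
  realignment), with the denominator taken over the columns of the
  lower-coverage member; clustering is greedy leader (Hobohm-1 style) in
  input order, which is deterministic but order-dependent.
* The aligner is O(n1·n2) per pair in pure Python loops — adequate for
  domain-sized proteins, not optimized for proteome-scale screening.
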