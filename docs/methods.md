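# Methods

This note documents the models, estimators and numerical choices behind
`sigdyn`, and what the synthetic study conditions do and do not establish.

## Ensemble construction

Members are mapped onto a single reference chain by global pairwise
alignment (Needleman–Wunsch, BLOSUM62, gap open 10 / extend 1, end gaps
penalized). Aligned non-gap columns define the member→reference position
pairing; the identity fraction is computed over aligned pairs, and members
below a 0.20 identity floor are flagged unmappable. A joint MSA is not
used: pairwise alignment is deterministic and order-independent, which
matters for reproducible matrices.

Filtering happens on the member × reference-position occupancy table:
positions resolved in fewer than 90% of members are dropped, then members
covering fewer than 80% of the retained positions are dropped, and the two
filters are iterated to a fixed point so the stated occupancy invariant
holds exactly on the final ensemble. Both thresholds are package defaults,
exposed in the pipeline config; they implement "low-occupancy" filtering
with concrete numbers.

Superposition is weighted Kabsch (SVD of the weighted cross-covariance;
the determinant correction excludes reflections; collinear point sets are
rejected because the in-plane rotation is then undetermined). Each member
is first fitted to the reference member on their shared resolved
positions, then refitted to the running occupancy-weighted mean until the
mean moves < 1e-4 Å RMSD (max 20 iterations). Positions a member does not
resolve are afterwards imputed with the per-position ensemble mean — this
keeps one common position set for PCA and the elastic network models — and
stay flagged in the mask so reports can mark them low-confidence.

## Similarity metrics

*Sequence*: identity fraction f over aligned non-gap columns (the
normalized Hamming distance is 1−f). *Structure*: Cα RMSD after a fresh
pairwise Kabsch fit on the pair's shared positions (not the ensemble-frame
coordinates, so the entry is the true pairwise minimum). *Dynamics*:
covariance overlap between GNM spectra with per-mode variances σ_k = 1/λ_k,

SO = 1 − sqrt[(Σσ_A + Σσ_B − 2 Σ_{k,l} √(σ_Ak σ_Bl)(u_k·v_l)²)/(Σσ_A + Σσ_B)],

clipped to [0,1], over a configurable mode window defaulting to 1–20 (the
slow/low-frequency range the signature analysis concentrates on); the
spectral distance is arccos(SO). Note the self-overlap equals 1 only to
about √ε (~1e-8): the bracket cancels at machine precision and the square
root amplifies it.

Heatmap ordering is the leaf order of average-linkage hierarchical
clustering, with a canonical child ordering (subtree containing the
smallest original index first) so equal distances preserve input order and
the result is fully deterministic. The sequence-derived order is reused
for the structure and dynamics heatmaps.

## PCA of the ensemble

Member coordinate vectors (3N-dimensional) are centered on the ensemble
mean; the covariance uses divisor M−1 and is diagonalized with a full
symmetric eigendecomposition. Component signs are fixed by making each
component's largest-magnitude entry positive. Mobility profiles are
per-residue triplet norms scaled by √λ so PC1/PC2/PC3 amplitudes are
comparable in Å. The pipeline refuses unsuperposed input (a rigid motion
would masquerade as leading variance) and ensembles with unimputed
missing positions.

## Elastic network models

GNM: Γ_ij = −γ for inter-Cα distance ≤ 10 Å (γ = 1; MSFs are reported in
units of 1/γ — the kT/γ prefactor is omitted since only profile shapes are
compared). Eigenvalues below 1e-8·λ_max count as zero modes; a connected
graph must have exactly one, otherwise the model errors (or the member is
dropped from ensemble runs, with a warning). ANM: 15 Å cutoff,
super-element blocks −γ(ddᵀ)/|d|², exactly six near-zero modes required.
Mode numbering is 1-based over nonzero modes. ANM–PC correlation is the
absolute inner product of unit vectors (eigenvector signs are arbitrary).

## Mode matching and signature profiles

Eigenvector sign and the order of near-degenerate eigenvalues are
arbitrary across members, so member modes are matched to a reference
spectrum — the GNM of the reference structure restricted to the ensemble's
positions — greedily in ascending reference order by absolute overlap,
with signs flipped positive (an optimal linear-assignment variant is
available behind a flag). Regime MSF profiles (global 1–3, LF 4–20, LTIF
21–60 via matched modes; "fastest" = each member's own 10 highest-λ modes)
are normalized to unit sum per member before aggregation, because the
γ-relative scale of each member's spectrum is arbitrary and only the shape
is comparable. Family profiles report elementwise mean, population
variance (divisor M — a descriptive envelope, not an inference), min and
max.

## State comparison and the randomized null

The labeled split compares the two states' signature profiles by absolute
mean difference and variance ratio (denominator floored at 1e-12). The
null repeats the comparison for seeded random size-matched relabelings
(default 500) and records per-position 50/95/99% quantiles. Mode–mode
overlap maps average |u_p(a)·u_q(b)| over all cross-subset member pairs —
pairwise first, then averaged, because the interesting second statistic is
the standard deviation over pairs, which an overlap of averaged profiles
would not provide. The summary statistic for "do the two states obey
distinct dynamics" is the mean *diagonal* overlap (mode p vs mode p):
off-diagonal entries are near-orthogonal noise that only dilutes the
signal. Its baseline is the same statistic averaged over several (default
5) random splits.

## Synthetic study conditions

The template is an idealized seven-helix bundle: antiparallel ideal
α-helices (rise 1.5 Å/residue, 100°/residue, helix radius 2.3 Å; 25
residues each) on a 12 Å circle, joined by six-residue circular loop arcs
whose subtended angle keeps consecutive Cα about 3 Å apart (geometry is
rejected if any inter-Cα distance falls below 2 Å). Total length 211;
helix/loop annotation is kept per position.

Ensembles follow a linear-Gaussian model — template + Σ_k z_k √(v_k)
mode_k + isotropic noise — so the PCA ground truth is exact and parameter
recovery is a sharp test. The labeled two-state conditions are: three
smooth orthonormal background modes with variances 4, 2, 1 Å² (kept below
the activation shift so the shift is the leading variance direction, as in
the receptor family emulated); isotropic noise 0.2 Å; a 6 Å shift between
state means along a unit mode localized on an "ICL3-like" segment (the
loop joining helices 5 and 6 plus 5 flanking residues on each side; a Hann
window times the per-residue radial direction, orthogonalized against
rigid translations); and extra isotropic noise of 2 Å per coordinate on
the segment for the "inactive" state only. The 2 Å figure models a
disordered inactive-state loop: excursions on the scale of the loop
geometry itself, large enough to rewire contacts at the 10 Å GNM cutoff
rather than merely jitter them. 20 members per state.

What the generator does *not* emulate: real sequence divergence coupled to
structural divergence (members share the template sequence), anisotropic
experimental noise, missing residues correlated with flexibility, ligand-
or crystal-contact-induced strain, and membrane constraints. Passing tests
therefore demonstrate the estimators' correctness and the pipeline's
statistical behavior under a controlled model, not performance on
experimental structure sets.

## Problem sizes and numerical conventions

Tests and the acceptance script use 211-position templates, 40-member
labeled ensembles, 500-rep nulls, 5 random-split baselines, M = 500
planted ensembles for PCA recovery (with the 9:4:1 fraction check averaged
over 5 replicate ensembles, since a single M = 500 draw has ~0.015
sampling scatter in its variance fractions), and 20-seed replications for
rate-based checks. Random state always flows from explicit integer seeds
through `numpy.random.default_rng`; CSV output uses a fixed float format
so reruns are byte-identical. Quantile bands use numpy's default linear
interpolation. The variance-ratio convention is subsetA/subsetB in the
order the labels are supplied; supplying ("inactive", "active") puts the
extra-disorder state in the numerator so the planted segment appears as
the argmax.

## Known limitations

- Greedy matching can cascade assignment errors once two members' spectra
  decorrelate (typically beyond mode ~40 at these sizes); the optimal
  variant mitigates but cannot resolve genuine degeneracies.
- The covariance-overlap formula is evaluated densely; for windows much
  larger than ~100 modes a low-rank evaluation would be preferable.
- Insertion-code ordering follows file order, not alphanumeric icode
  order; structures with heavily interleaved insertions should be checked.
- `mmCIF` input is out of scope (PDB text only), as is true multiple
  structure alignment (TM-align-style) — mapping is sequence-guided.
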