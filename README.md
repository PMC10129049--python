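# sigdyn

Signature-dynamics analysis of protein structural ensembles.

Protein families that share a fold also share a repertoire of collective
motions — their *signature dynamics*. For seven-transmembrane (7-TM)
receptors this is directly functional: activation opens the cytoplasmic
TM5–ICL3–TM6 region, and that opening is visible both in the spread of
experimentally resolved structures and in the low-frequency normal modes
encoded by the fold. `sigdyn` is a toolkit for making that comparison
quantitative for any family of Cα structures:

- **Ensemble construction** — parse PDB chains, map every member onto a
  reference by global sequence alignment (BLOSUM62, affine gaps), filter by
  residue occupancy, and superpose iteratively with a weighted Kabsch fit.
- **Similarity matrices** — pairwise sequence identity *f* (normalized
  Hamming distance 1−*f*), Cα RMSD after fresh pairwise superposition, and
  the spectral distance d_ij(A,B) = cos⁻¹ SO_ij(A,B), where SO is the
  covariance overlap between two Gaussian Network Model (GNM) mode spectra
  over modes i..j. One sequence-cluster ordering is reused for all three
  heatmaps.
- **Conformational landscape** — PCA of the member coordinate vectors:
  eigenvalues λ_k (Å²), variance fractions λ_k/Σλ, member projections onto
  PC1/PC2, and per-residue mobility profiles |u_k| √λ_k.
- **Elastic network models** — GNM (Kirchhoff matrix Γ, MSF_i = Σ_k
  u_k[i]²/λ_k) and ANM (3N×3N Hessian, six rigid-body modes removed), plus
  the correlation cosine |ANM mode · PC| linking intrinsic dynamics to the
  observed landscape.
- **Signature profiles** — per-member GNM spectra matched to a reference
  spectrum, then mean / variance / min–max envelopes of mode-regime MSFs
  across the family (global modes 1–3, low-frequency 4–20,
  low-to-intermediate 21–60, and the 10 fastest modes).
- **State comparison** — active-vs-inactive signature differences and
  variance ratios, judged against a randomized size-matched split null, and
  mode–mode overlap maps (mean and SD of |u_p(a)·u_q(b)| over cross-subset
  member pairs).
- **Synthetic data** — a fully seeded generator (idealized 7-helix bundle,
  planted orthonormal collective modes with prescribed variances, a labeled
  two-state variant with a segment-localized activation shift) so the whole
  pipeline is testable without downloading a single structure.

## Worked example

Generate a labeled synthetic dataset and run the full pipeline:

```bash
sigdyn synth --seed 3 --m-per-state 6 --out-dir demo
sigdyn run demo/config.yaml
```

The second command prints a stage summary such as:

```json
{
 "ensemble": {"members_in": 12, "members_out": 12, "positions": 211},
 "pca": {"components": 10, "pc1_fraction": 0.2262374964203765},
 "state_compare": {
  "n_active": 6, "n_inactive": 6,
  "true_diagonal_overlap": 0.6971583497092018,
  "random_diagonal_overlap": 0.6983149783721831
 },
 "anm": {"modes": 627, "best_pc1_mode": 2, "best_pc1_correlation": 0.399}
}
```

Reading this: 12 structures map cleanly onto the 211-position reference;
PC1 carries ~23% of the coordinate variance (it is the planted
activation-like shift); the mean same-index mode overlap between the
active and inactive subsets (0.697) falls below the random-split baseline
(0.698), the direction expected when the two states obey distinct
dynamics; and ANM mode 2 of the reference structure is the intrinsic mode
that best tracks PC1. All CSV outputs (similarity matrices, projections,
signature profiles, null quantiles, overlap maps) land in `demo/results/`
together with a JSON run manifest; reruns with the same config are
byte-identical.

The same steps are available from Python — see
`sigdyn.synthetic_data.default_two_state_spec`, `sigdyn.pipeline.run_pipeline`
and the per-stage functions they compose.

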