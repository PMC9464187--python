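# Methods

This note records the models implemented in `mimeseek`, the parameter
choices that matter, what the synthetic generators do and do not
emulate, and the numerical conventions used throughout.

## Specificity profile and mimetic score

The profile is a pure tally: for n unique peptides of common length L,

    f_p(aa) = 100 · (count of aa at position p + c) / (n + 20c)

with pseudocount c ≥ 0 in count units. The default is c = 0, which
reproduces raw percent frequencies and makes the score a *hard*
product — any residue never observed at a scored position zeroes the
candidate. This matches the normalisation of the score by the maximum
possible product (100^m over m scored positions): with c = 0 the score
of the consensus of a single-peptide profile is exactly 1. A non-zero
pseudocount is available for exploratory scoring but changes the
semantics (no candidate scores exactly 0 or 1).

Each peptide is tallied once regardless of read count; enrichment
influences the profile only through which peptides survive filtering.
Two filter chains are supported, mirroring the two profile variants a
panning analysis naturally produces: anchor filter only (all unique
anchored peptides) or anchor filter plus isolation count ≥ 2. The
profile records its provenance so downstream scans know which chain
produced it.

Scoring windows are 1-based closed intervals. The central window
(4, 7) corresponds to the TCR-contact residues of a decamer in the
class I groove: positions 1–3 and 8–10 are dominated by HLA anchoring
(position 10 R/K for HLA-A\*11) and contribute little to TCR
discrimination, so window scoring avoids overlooking mimetics that
diverge at HLA-facing positions. Ties anywhere in ranking are broken
by score (or count) descending, then lexicographically, for
determinism.

## Peptidome scan

The proteome is digested into overlapping k-mers (k = 10 by default);
identical k-mers from different proteins or isoforms merge into one
entry with all provenance spans retained (1-based starts, closed
intervals). K-mers containing X are dropped and tallied. HLA-binding
predictions are ingested as a peptide → IC50(nM) table (plain TSV or
netMHCpan-style whitespace output); the binder filter keeps IC50 ≤
1000 nM, and peptides absent from the table are excluded on the
grounds that the whole peptidome is assumed to have been run through
the predictor (a pass-through flag exists for testing). The target
epitope itself is excluded from mimetic output by the caller — it is
the epitope, not a mimetic.

## Binding thermodynamics

K_D is carried in molar, energies in kcal/mol, with R = 1.9872×10⁻³
kcal/(mol·K) and reference temperature T_ref = 298.15 K (25 °C, the
SPR measurement standard). Derived quantities:

- selectivity window K_D^WT / K_D^mut (dimensionless, scale-invariant);
- fold change K_D^ref / K_D^variant, so a 10-fold binding loss reads 0.1;
- ΔG = RT ln K_D; t½ = ln 2 / k_off (reported in hours).

Censored table entries (">" values, no-binding rows) are flagged as
lower bounds; a window computed with a censored numerator is itself a
lower bound on the true window.

The van't Hoff fit minimises unweighted squared residuals of ln K_D(T)
against ΔG(T)/(RT) with the integrated Gibbs–Helmholtz form

    ΔG(T) = ΔH + ΔC_p (T − T_ref) − T [ΔS + ΔC_p ln(T/T_ref)],

parameters quoted at T_ref. The linear model (ΔC_p = 0) is a closed-form
straight-line fit in 1/T; the nonlinear model adds ΔC_p and is solved
by Levenberg–Marquardt initialised from the linear solution.
Unweighted least squares on ln K_D was chosen because instrument-
software weighting schemes are generally undocumented; on the 6-point,
6 °C-interval grids typical of SPR thermodynamics this recovers
noiseless generating parameters to solver precision and, under 5%
multiplicative K_D noise with duplicate measurements, keeps the median
ΔH error below 1 kcal/mol (verified by simulation in the test suite).

## Structure metrics

- **Superposition**: Kabsch SVD with determinant correction, so the
  returned rotation is always proper. Model-level RMSD pairs atoms by
  (chain, residue number, insertion code, atom name); unpairable atoms
  are dropped. "ca" mode uses Cα only, "all" uses all heavy atoms.
- **SASA**: Shrake–Rupley with a deterministic golden-spiral point set
  (default 960 points), probe 1.4 Å, Bondi-type radii C 1.70, N 1.55,
  O 1.52, S 1.80, P 1.80, Se 1.90 Å. Hydrogens are skipped (crystal
  structures generally lack them); unknown heavy elements raise. The
  point set is fixed in space, so SASA is rotation-invariant only to
  sampling resolution (~1–2% at 960 points, ~0.2% at 10⁴ points);
  totals converge to <0.5% under point-count doubling.
- **BSA** on an entity due to a partner group is SASA(entity in its
  context without the partners) − SASA(entity in the full complex).
  The context defaults to every other assigned role, so the peptide is
  evaluated in its pHLA context, matching how interface burial on a
  presented peptide is quoted.
- **Contacts**: all inter-group heavy-atom pairs within 4.0 Å;
  pairs of N/O/S atoms within 3.5 Å are classed polar. These cutoffs
  are common crystallographic practice.
- **Crossing angle**: the TCR vector runs from the Vβ intradomain
  cystine Sγ midpoint to the Vα cystine midpoint; the groove axis is
  the first principal axis of the Cα atoms of the HLA α1/α2 helix
  ranges (defaults 50–85 and 138–180 in mature heavy-chain numbering,
  configurable), oriented along the peptide N→C direction. The angle
  is reported in [0°, 180°] without projection onto the groove plane;
  the convention is emitted in report metadata since published values
  are convention-dependent at the few-degree level.

Structure parsing (PDB and mmCIF, via gemmi) keeps the first model,
excludes waters by default, and resolves alternate locations per atom
site by highest occupancy, ties broken by altloc identifier order.

## Synthetic generators: what they emulate

The generators reproduce the *statistical structure* the analysis
assumes, not the biology:

- **Naive library**: i.i.d. peptides, each position uniform over the
  20 amino acids (expected 5% each) or NNK-weighted (codon counts over
  the 31 coding NNK codons, computed from the standard genetic code at
  run time — e.g. Leu:Met = 3:1). The default library size is 4×10⁶.
  This is a deliberate scale-down of a DNA-randomised library with
  ~6.6×10⁹ diversity chosen so that peptides matching a 4-residue
  central motif are still expected ~25 times over in the library —
  the regime in which "the most enriched peptides all share the
  central motif" is a property of selection rather than of sampling
  luck. Sampling depth per round defaults to 10⁵ reads, a scale-down
  of ~10⁶-read amplicon sequencing.
- **Panning**: per round, each peptide's weight is count ×
  Π_p w_p(aa_p) × an anchor display factor for C-terminal R/K; the
  next round is a single multinomial resample of the configured depth.
  This collapses binding, washing, elution, re-infection and PCR into
  one weighted bottleneck per round — there is no separate
  amplification-noise term, no sequencing-error model and no phage
  growth kinetics. The multiplicative-selection form is an assumption
  used for testing only, never for inference. `simulate_experiment`
  fuses generation and selection over integer-coded peptides for
  speed; it implements the identical process as the two-step
  `generate_naive_library` + `simulate_panning` path but consumes a
  different random stream.
- **Proteomes**: uniform-random sequences with mimetic 10-mers
  overwritten at recorded positions (collisions with earlier plants
  are redrawn, erroring after 100 attempts). Real proteomes have
  amino-acid composition bias, homology and low-complexity regions
  that random sequences lack, so decoy score distributions here are
  more pessimistic (flatter) than reality.
- **K_D(T) series**: exact inverse of the van't Hoff model plus
  log-normal multiplicative noise with the given coefficient of
  variation (mean 1). The default grid is 6 measurements at 6 °C
  intervals from 6–36 °C.
- **Toy structures**: two-sphere systems (analytic cap-overlap BSA),
  a groove/peptide/cystine fixture realising an exact crossing angle,
  and displaced-copy pairs for RMSD.

Consequently, passing tests demonstrate correctness of the *computations*
under the stated statistical assumptions; they do not validate the
enrichment model against real panning data, nor the mimetic ranking
against real proteome composition.

## Numerical conventions and degenerate inputs

Peptide positions and k-mer provenance are 1-based; windows are closed
intervals. Amino-acid axes are ordered alphabetically by one-letter
code (ACDEFGHIKLMNPQRSTVWY). Profile columns must sum to 100% within
1e-9 relative tolerance. Empty peptide sets, empty candidate pools,
non-positive K_D/k_off/IC50, mixed peptide lengths and insufficient
temperature points all raise immediately rather than propagating NaNs.
Amplicon reads failing flank location, insert length, base alphabet or
stop-codon checks are tallied by reason, not raised. Flank matching is
exact first-occurrence substring search; reads are assumed pre-merged.

## Problem sizes used in the checks

The packaged checks run at desk scale by design: 10⁵-member libraries
for composition envelopes, 4×10⁶-member libraries × 20 seeds for motif
recovery, 200 replicates for noisy thermodynamic recovery, and
10²-atom fixtures for geometry. The acceptance script tabulates a
10⁵-member library.

## Known limitations

- The enrichment simulator has no saturation or competition effects;
  relative enrichment ratios compound exactly multiplicatively.
- SASA/BSA use a fixed-orientation quadrature grid (see above);
  occupancy-weighted altloc averaging is not supported.
- The crossing-angle groove-axis definition (helix-Cα principal axis)
  is one of several in circulation; published angles can differ by a
  few degrees under other conventions.
- netMHCpan itself is not re-implemented; the binder filter is only as
  good as the supplied prediction table.
- Variable-domain boundaries for RMSD comparisons are configurable
  residue ranges, not an automatic domain assignment.
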