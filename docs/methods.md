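# Methods

## Protection-factor model

The forward model maps a conformation to per-residue natural-log protection
factors: `ln P_i = beta_h * N_h + beta_c * N_c`, with `beta_h = 2`,
`beta_c = 0.35`. Both counts are taken from the backbone amide hydrogen of
residue i:

* `N_h` counts main-chain carbonyl oxygens within 2.4 Å. The criterion is
  distance-only; adding an angle term would change the model, and the
  counts here are meant to capture the hydrogen bonds that maintain
  secondary structure, which the sequence-exclusion rule already selects
  for. Several in-range acceptors all count (bifurcated geometries give
  `N_h > 1`).
* `N_c` counts heavy atoms — main-chain or side-chain, of any residue —
  within 6.5 Å, as a packing-density proxy.
* Both counts exclude residues i−2…i+2 (inclusive of i itself, so a
  residue's own atoms never count); helical and sheet hydrogen bonds span
  at least three sequence positions. The window truncates at chain ends.
* Distance comparisons use ≤ at the cutoff. Only the backbone O is a
  candidate acceptor; the C-terminal OXT is excluded (whether carboxylate
  oxygens should count is ambiguous; excluding them is the conservative
  reading of "main-chain oxygens").
* Residues without an amide hydrogen (prolines, the N-terminal residue)
  have no protection factor.

Ensemble protection factors are the arithmetic mean of ln P over members —
averaging the logarithm, not P itself, which weights members equally rather
than letting the most-protected member dominate.

Because crystal structures lack hydrogens, amide H positions are
constructed with ideal geometry: 1.01 Å from N, in the plane of C(i−1),
N, CA, anti-parallel to the C(i−1)=O(i−1) carbonyl direction (projected
into that plane when the input geometry is not exactly planar).
Experimentally determined H positions (e.g. in NMR models) are preserved,
not overwritten; whether that matches how any particular study handled
them is unknowable from published descriptions, but recomputing over
measured coordinates would discard information.

## Exchange kinetics

Residue uptake is pseudo-first-order, `d_i(t) = 1 − exp(−(k_int/P_i) t)`;
peptide uptake `D_j(t)` averages `d_i(t)` over the peptide's exchangeable
positions. A peptide's first two positions are always excluded — after
proteolysis the first residue becomes a free amine and loses its deuterium,
and the second position back-exchanges as well — and prolines are excluded
everywhere. A proline in position 1 or 2 does not free an extra slot.

Intrinsic rates come from the standard reference-parameter prediction:
poly-DL-alanine base rates for acid, base and water catalysis in D2O
(log10 k = 1.62, 10.05, −1.5 at 293 K; pK_D = 15.05), nearest-neighbor
inductive corrections from a packaged table (λ applies to a side chain's
own amide, ρ to the following residue's amide; protonated-N-terminus and
carboxylate-C-terminus corrections at the chain ends), and Arrhenius
scaling with activation energies of 14, 17 and 19 kcal/mol for the three
channels. The input `pH` is read as the pD of the labelling buffer; side
chains are treated in their neutral-pH ionization states. Units are minutes
throughout; uptake is fractional (0–1) with solvent deuterium fraction 1.0
and no forward-exchange correction. Users with their own calibrated rates
can supply a per-residue CSV that bypasses prediction entirely.

## Goodness of fit

Residue-resolved (NMR-style) data: per-residue absolute error
|ln P_der − ln P_obs|, aggregated as the unweighted mean over compared
residues, plus R², the squared Pearson correlation between the two series.
The correlation's sign is reported alongside R² because perfect
anti-correlation also squares to 1. Observed values may arrive as log10 P
(flagged per row in the input schema) and are converted to natural log on
load. Items present in only one series are dropped with a logged count —
experimental coverage is always partial.

Peptide-resolved (MS-style) data: per-peptide error is the sum over the
experimental time grid of |D_der(t) − D_obs(t)|, aggregated as the
unweighted mean over peptides (no length weighting). Mismatched time grids
are an error, not silently interpolated.

Best-conformation selection scores every ensemble member through the full
forward pipeline and takes the minimizer; ties break to the lowest index.
Note the ensemble-average prediction can beat or lose to the best single
member — neither direction is asserted anywhere.

## Coarse-grained sampler

The sampler is a deliberately minimal coarse-grained explorer built on
three pieces:

* **Internal coordinates.** A conformation is a vector of backbone (φ, ψ)
  angles; bond lengths and angles are ideal and ω is fixed trans, so N+1
  residues have 2N degrees of freedom. Rebuilding anchors the chain on the
  template's first-residue frame; side chains are carried rigidly in each
  residue's local backbone frame (no repacking — a known accuracy
  limitation, since the contact count is sensitive to side-chain
  positions), and amide hydrogens are re-placed from the new geometry. The
  last residue's carbonyl orientation, a free degree of freedom once ψ is
  undefined, is preserved from the template.
* **Moves.** A fragment (any set of residues, with a sampling weight) is
  picked with probability proportional to weight; Gaussian noise of
  standard deviation `perturbation_sigma` (default 5°) is added to its
  (φ, ψ); coordinates are rebuilt. Kinematics make every move local in
  sequence but global in space downstream of the perturbed residues.
* **Filter.** A soft-sphere clash score: Σ (3.0 − d)² over heavy-atom
  pairs closer than 3.0 Å with sequence separation ≥ 2 residues. Proposals
  are accepted iff the score is at or below the energy threshold (default
  1.1× the start conformation's own score, so slightly strained inputs
  remain explorable). The scorer is a pluggable interface; the soft-sphere
  form is the simplest filter that rejects physically impossible
  structures while leaving the exploration permissive.

Exploration grows a pool: each step perturbs a uniformly random existing
member and keeps the proposal if it passes the filter, until
`n_conformations` are accepted or the attempt budget
(`n_conformations × max_attempts_per_accept`) is exhausted. Everything is
deterministic given the seed.

Refinement alternates exploration with discrepancy-guided reweighting:
after each round the fit report of the current best conformation is spread
onto residues (peptide errors are averaged over the peptides covering each
residue), each fragment's discrepancy is the mean per-residue error over
its residues, and the ceil(k/4) highest-discrepancy fragments (ties at the
boundary included) get their weight multiplied by `boost` (default 4)
before renormalization. The next round explores from the current best.
Default round budget is 5; the loop stops early when the best score
reaches `stop_score`. The best-so-far score is non-increasing by
construction.

## Synthetic data and what the tests show

The synthetic generators produce ideal-geometry poly-alanine chains
(α-helix (−57, −47), extended (180, 180), or random-coil dihedrals) with
N/CA/C/O/CB atoms, and forward-simulated "observations": model-derived
ln P or uptake curves plus Gaussian noise of chosen σ, seed-deterministic,
in the same schemas as real experimental input. These fixtures have no real
side chains beyond CB, uniform composition, and noise that is independent
and Gaussian — none of which is true of real HDX data, where errors are
correlated, coverage is uneven, and the forward model itself is the main
source of misfit. Passing tests therefore demonstrate internal
correctness of the pipeline (counting, kinetics, scoring, search), not
predictive accuracy on real proteins.

The refinement recovery experiment plants a target one clash-feasible
single-fragment move (σ = 8°) away from a 16-residue ideal helix split
into four 4-residue fragments, requires the planted discrepancy to be
detectable (mean |Δ ln P| ≥ 0.15 — a target indistinguishable from the
start cannot meaningfully be recovered), and searches with σ = 4°, 80
conformations per round, 3 rounds, clash threshold 2.0. These sizes keep a
20-run repetition under a minute while leaving the success criterion
(improving on the start's fit in ≥ 90% of seeded runs) comfortably met;
they are fixture-scale choices, not recommendations for real proteins,
where longer exploration is needed.

## Numerical choices and degenerate inputs

* Altloc resolution keeps the highest-occupancy atom, ties to altloc 'A'.
* Non-standard residues (MSE, SEC, phosphoresidues, …) map to their parent
  amino acid; unmapped amino acids are an error, other hetero groups and
  waters are dropped.
* Multi-chain files use the first protein chain, with a warning; the
  counters are anchored only for monomeric proteins.
* Internal numbering is 1-based contiguous; author numbering is retained
  per residue for joining experimental tables.
* CSV output is rounded to 6 significant digits so identical runs produce
  byte-identical files; JSON keeps full precision.
* R² is reported as undefined (None, with a warning) for fewer than two
  common residues or a zero-variance series; the mean error is still
  computed.
* Angles wrap to (−180, 180]; undefined terminal angles are NaN and any
  attempt to build through them is an error.
* The packaged CI2/Im7 tables are checksum-verified on load.

## Known limitations

* The protection-factor model is brittle: small structural changes flip
  integer counts and move ln P in steps of 0.35 or 2. This is a property
  of the model, and is the reason a conformational search is needed at
  all.
* Rigid side-chain transport during rebuilds can create or destroy
  contacts that repacking would resolve.
* The intrinsic-rate table is a transcription of the standard published
  reference set; applications that need calibrated absolute rates should
  supply their own rate file.
* The sampler's move set (fragment φ/ψ perturbation only) has no
  closure-preserving loop moves; the move interface is designed so they
  can be added.
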