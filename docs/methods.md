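# Methods

This note documents the models, algorithms, parameters and design choices
behind `xlgeom`, and what the synthetic benchmarks do and do not demonstrate.

## Problem setting

Pairwise disulfide cross-linking ("cysteine scanning") between a receptor's
flexible N-terminal peptide and a chemokine's folded core yields, for each
receptor-residue x chemokine-residue pair, a covalent-complex signal that is
large when the two residues are spatially close in the native complex. The
pipeline turns such a panel into residue-level distance restraints, docks the
peptide under those restraints, and scores candidate complex geometries by
how well their distance maps retrieve the strongest crosslinks.

## Efficiency quantification (`xlink_quant`)

Flow-cytometry GMFI (geometric mean fluorescence intensity of the live-gated
population) for each co-expressed mutant pair is normalized *within each
replicate* to a reference covalent pair measured in the same batch, which is
set to 100%. The per-pair efficiency is the **mean of per-replicate ratios**,
not the ratio of means: per-replicate normalization cancels batch-to-batch
expression and staining differences. Efficiencies above 100% are legal and
are never clamped. "Not studied" cells are stored explicitly and are distinct
from measured zeros.

Chemokine mutants whose surface display on a scavenger-receptor folding
control falls below 20% of wild type are flagged misfolded; every cell
involving such a mutant is excluded from restraint building, ROC positives,
and heat-map export. The 20% default is configurable — the biology only says
"negligible display", not a number.

Western-blot quantitation is the orthogonal readout: chemokine-channel band
intensity as % of the control lane, and crosslinked-receptor fraction as
upper-band over total receptor signal. Agreement between the two readouts is
summarized by a Spearman rank correlation over shared pairs (the reference
pair anchors both scales and is excluded as a data point).

## Restraints (`restraints`)

Pairs with efficiency **strictly above 65%** become distance restraints
between interaction atoms (Cβ, or Cα for glycine — the natural anchor
because disulfide-bonded cysteines sit at Cβ–Cβ ≈ 4 Å). Included
efficiencies are mapped linearly onto weights in **[0.5, 5]**; by default the
realized minimum and maximum included efficiencies anchor the endpoints
("range-of-included"), with an alternative mode anchoring the lower end at
the threshold. The transform is strictly order-preserving.

The penalty is a *local* flat-well function:

    E(d) = -w                          for d <= d0
    E(d) = -w / (1 + ((d - d0)/λ)²)    for d > d0

with d0 = 4 Å (favoring disulfide-compatible distances) and λ = 2 Å. The
Lorentzian shoulder is our choice among the admissible bounded,
asymptotically-zero forms; its defining properties — flat well, continuity,
monotone rise, asymptote at zero — are what the tests pin down. A global
multiplier cn_weight = 5 scales the whole restraint term relative to the
physical energy. Energies are in arbitrary reduced units throughout; no
kcal/mol fidelity is claimed.

## Peptide docking (`peptide_sampler`)

The receptor N-terminal peptide is built ab initio in internal coordinates
(ideal bond geometry, trans peptide bonds, extended start at φ=-139°,
ψ=135°) with a reduced side chain: Cβ plus one centroid pseudo-atom per
residue with residue-specific radius and formal charge (+1 Lys/Arg, -1
Asp/Glu, -1 sulfotyrosine). Sulfotyrosine is treated purely as a charge
feature. The chemokine core is rigid.

The energy is a sum of: soft van der Waals (12-6 with the per-pair term
capped at 7 units), a Gaussian hydrogen-bond proxy between backbone N/O
across the interface (2.9 ± 0.3 Å), Coulomb electrostatics with distance-
dependent dielectric εr = 4r (evaluated at an effective distance floored at
2 Å so opposite charges cannot collapse through the soft steric term),
3-fold torsional strain, a harmonic tether holding the C-terminal anchor Cα
at its known position, and the cn-weighted restraint penalty. The
decomposition always sums exactly to the total.

Sampling is Metropolis–Hastings in torsion + rigid-body space:

* **zone moves** — one residue's (φ, ψ) replaced by an independence draw
  from a four-basin Ramachandran prior (β, αR, αL, PPII; wrapped Gaussians,
  uniform basin choice) with the exact Hastings factor q(old)/q(new);
* **segment moves** — a 2-3 residue window redrawn *concertedly* from a
  single basin (the move that proposes strand-like stretches), with the
  corresponding product-mixture density in the Hastings factor;
* **local moves** — symmetric Gaussian perturbations (σ = 8°) of one
  torsion; side-chain χ moves at σ = 25°;
* **rigid moves** — small translations (σ = 0.4 Å) and rotations (σ = 6°)
  of the whole peptide about its centroid.

Torsion moves are applied as kinematic subtree rotations (identical to a
rebuild, ~10x faster). Each restart draws its start from the basin prior,
scores `n_seed_draws` random placements and begins from the best
(best-of-N seeding), runs an annealed phase (default geometric schedule),
then a cold "polish" phase restarted from the best state so downhill basin
flips (typically misfolded termini) can settle. The detailed-balance of the
torsion kernel is verified against exhaustive grid enumeration in the test
suite. The stack keeps the top-k energy-ranked poses after removing
duplicates within 0.5 Å mutual Cβ RMSD, with deterministic (energy, restart,
step) tie-breaking; a fixed seed reproduces the stack bit for bit.

`n_steps` is the total Metropolis budget split evenly over restarts. The
library default is 2x10^5 with 10 restarts — deliberately desk-scale;
production-grade runs of the method class use orders of magnitude more. The
pose-recovery benchmark uses 5x10^4 steps, 10 restarts, annealing from
T = 2.5 to 0.15, and 80 seed draws, which recovers a 6-residue planted pose
to < 2 Å Cβ RMSD in 8 of 10 seeds in a few minutes on one CPU.

β-registry of a docked pose is classified from the Cα contact map between
the peptide and the partner strand (6.5 Å cutoff): each peptide residue's
closest in-contact partner forms a rung; at least 3 rungs with monotonically
decreasing partner index mean antiparallel, increasing parallel, anything
else none.

## Ensemble analysis (`ensemble_analysis`)

SASA is computed by Shrake–Rupley numerical sphere sampling (960
quasi-uniform Fibonacci points per atom, probe 1.4 Å, standard element
radii), reported per residue with backbone and side-chain contributions
separated. Normalized SASA divides by the Tien et al. (2013) theoretical
maximum per residue type — a published, self-consistent reference that we
ship as a table rather than re-deriving tripeptide values in-package.
Normalized values may slightly exceed 1 for distorted conformers; tables
carry an unclamped and a clamped column.

Side-chain conformational variability of a residue across an ensemble is
the mean pairwise RMSD of its side-chain heavy atoms after superposing all
members on shared core backbone atoms (no per-pair refit; rigid motion of
whole members cancels exactly). Loop clustering superposes members on the
non-loop core, computes pairwise loop backbone (N, Cα, C, O) RMSD, applies
average-linkage hierarchical clustering cut at a stated height (default
1 Å), and selects the best-resolution member (ties by id) as each cluster's
representative. Exposure (normalized SASA > 0.3) and flexibility
(variability > 1 Å) flags use configurable defaults.

## Model assessment (`model_assessment`)

A model's distance map over the mutagenesis panel uses the same
interaction-atom convention as the restraints. Positives are the top
fraction of measured pairs by efficiency; the nominal count is
round-half-up of fraction x n (a floor variant is exposed since either
convention is defensible at, say, 10% of 144), efficiency ties at the
boundary are all included, and the realized count is reported. Pairs whose
residues a model does not contain are excluded from that model's ROC rather
than scored as misses. Scores are negated distances; the curve is a standard
threshold sweep and the AUC a trapezoidal area, equal (verified
exhaustively in tests) to the Mann–Whitney probability that a random
positive pair is closer than a random negative one.

## Pharmacological validation (`pharm_validation`)

Concentration-response data are fitted with the three-parameter logistic
(Hill slope fixed at 1) by least squares with a multistart grid of log EC50
over the tested range (ties broken by lower RSS then lower pEC50). Reported:
pEC50 = -log10 EC50 (M), Emax (top plateau) and baseline, with asymptotic
standard errors from the fit covariance. Flat datasets and curves whose
plateau is never approached within the tested range are flagged rather than
silently fitted. Two datasets are compared by the extra sum-of-squares F
test: one shared parameter triple versus separate triples,
F = ((SSE_s - SSE_f)/(df_s - df_f))/(SSE_f/df_f).

## Synthetic data (`synthetic_data`)

The toy complex is a chemokine-like scaffold assembled from explicitly
placed ideal-geometry segments — an exposed five-residue strand (with
lead-in), an antiparallel second strand 4.8 Å beneath it, and an α-helix a
further layer down — with a 6-residue peptide planted as an extra
antiparallel strand on the solvent side; lateral offset and axial shift are
chosen by a small deterministic grid search minimizing the worst rung
distance, and side-chain centroids on both sides are relaxed by a
deterministic χ scan (Cβ traces, and hence the recorded true distance
matrix, untouched).

Simulated crosslink efficiency follows
e(d) = e_max / (1 + exp((d - d50)/k)) with e_max = 130%, d50 = 8 Å,
k = 1.5 Å: ladder contacts (≈3-5 Å) land in the 80-135% band seen in real
panels, the 65% inclusion threshold is crossed at d50, and pairs beyond
~10 Å fall into the noise. One promiscuous chemokine position gets a 40%
efficiency floor regardless of distance (phenomenology of a reactive,
unspecific residue — no mechanism claimed); designated misfolded mutants
emit background GMFI and ~2% folding-control display. Replicate noise is
multiplicative Gaussian (default 10% relative SD); the control pair is
emitted in every replicate. Dose-response truths default to a wild-type
curve (pEC50 7.40, Emax 100%) and a loss-of-function mutant curve
(pEC50 6.68, Emax 87.9%) with 5-point additive noise over 0.1 nM - 1 µM.

**What passing the synthetic benchmarks shows** — that the implementation
correctly propagates distance information through quantification, weighting,
docking and ROC scoring under the statistical structure (normalization,
noise, promiscuity, misfolding, >100% values) of real panels. **What it
does not show** — anything about real receptor-chemokine energetics: the
toy fold is idealized, the chemokine is rigid, side chains are centroids,
backbone hydrogen bonding is a proxy, and the restraint functional form is
one admissible choice. Coordinate-level reproduction of a real complex is
out of scope by design.

## Numerical conventions and degenerate inputs

* Author (PDB) residue numbering everywhere; no renumbering. Altlocs keep
  the highest-occupancy conformer (ties by altloc id). Occupancies outside
  [0, 1] are clamped with a warning.
* A non-Gly residue missing Cβ falls back to Cα with a warning; a residue
  missing both is an error.
* A degenerate included-efficiency set (single pair, or all equal) gets
  weight_max with a warning; an all-below-threshold table yields an empty
  restraint set with a warning, not an error.
* Side-chain variability of byte-identical ensembles reports exactly 0
  (superposition round-off below 1e-10 Å is snapped).
* ROC with no positives or no negatives raises rather than returning a
  meaningless 0.5.
* All stochastic components take explicit seeds; identical seeds give
  bit-identical outputs.

## Problem sizes used in the shipped benchmarks

Pose recovery: 6-residue peptide, 26-residue scaffold, 14 restraints,
5x10^4 MC steps x 10 seeds. End-to-end recovery: 6 x 9 panel, 3 replicates,
10% noise. Logistic recovery: 100 curves x 27 points. Detailed balance:
2x10^5 kernel steps against a 36 x 36 grid oracle. These sizes make the full
suite runnable on a laptop CPU in minutes while leaving every algorithmic
path exercised.
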