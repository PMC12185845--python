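# Methods

This note documents the models and estimators implemented in
`calyxpath`, their assumptions, the parameters that matter, and the
numerical choices made where the underlying methods leave freedom.

## The system and its observables

Lipocalins enclose their ligand-binding cavity (the calyx) inside an
eight-stranded β-barrel that is not open to solvent in crystal
structures.  In rat odorant-binding protein 1 (rOBP1) access is
controlled by a gate formed by the Y82 hydroxyl hydrogen-bonded to the
S34 backbone carbonyl.  Three per-frame observables describe a binding
trajectory:

* **F100 distance** — distance between the ligand centre of mass and
  the mass-weighted centre of the F100 side chain (heavy atoms CB and
  beyond), which forms the cradle of the cavity.  The ligand counts as
  bound below 5 Å (strict inequality).
* **Gate distance** — Y82(OH)–S34(O) distance; the gate is closed
  below 3.4 Å (strict).  Both residue numbers are configurable so the
  same machinery applies to other lipocalins, but the author (PDB)
  numbering is always used verbatim.
* **Solvation fraction** — number of water oxygens within 3.5 Å of any
  ligand *heavy* atom, normalised by the count for the fully solvated
  ligand.  Counting heavy atoms only (not hydrogens) is a deliberate
  choice: hydrogen placement is force-field dependent and the shell
  radius absorbs the difference.  The bulk reference can be given
  explicitly or estimated from frames in which the ligand is more than
  `pocket_cutoff + 5` Å from every protein atom.

### Five-step state assignment

Frames are labelled `unbound → a_contact_closed → b_pocket_closed →
c_entry_open → d_site_open → e_site_closed` from the F100 distance d
and the gate state:

| state | condition |
|---|---|
| d_site_open / e_site_closed | d < 5 Å, gate open / closed |
| c_entry_open / b_pocket_closed | 5 ≤ d < 10 Å, gate open / closed |
| a_contact_closed | 10 ≤ d < 14.5 Å |
| unbound | d ≥ 14.5 Å |

Only the 5 Å and 3.4 Å thresholds are experimentally anchored; the
10 Å pocket boundary is taken from the location of the vestibule
minimum in the unbinding free-energy profile, and the contact band
adds one contact cutoff (4.5 Å) beyond it.  All four are fields of
`GateParams`.  A median filter of width `min_dwell_frames` (default 5
frames ≙ 1 ns at the default 0.2 ns frame interval) is applied to the
ordinal state code to suppress single-frame flicker; the raw rule is
recovered with `min_dwell_frames=1`.  Binding events are runs of at
least `min_dwell_frames` consecutive bound frames; an event is
*sustained* if its run reaches the end of the trajectory or lasts ten
dwell windows.

## dcTMD: free energy and friction from pulling work

In constant-velocity constraint pulling the constrained coordinate
moves as x(t) = x₀ + vt and the accumulated work W(x) = ∫ f_c dx
(trapezoidal integration of the recorded constraint force) mixes
reversible and dissipated contributions.  Assuming Gaussian work
fluctuations across an ensemble of independent replicas (second-order
cumulant truncation of the Jarzynski average),

    W_diss(x) = (β/2)·Var[W(x)]         (unbiased variance, ddof=1)
    ΔG(x)     = ⟨W(x)⟩ − W_diss(x)
    Γ(x)      = (1/v)·dW_diss/dx

Γ is reported in kg mol⁻¹ s⁻¹ and, in the CSV output, additionally in
kJ mol⁻¹ s m⁻² (a factor 10³ apart).  Numerical choices:

* replicas are interpolated onto a uniform grid (default 0.1 Å) before
  any ensemble statistics;
* W_diss is smoothed with a Gaussian kernel (default σ = 0.5 Å) before
  the central-difference derivative — the pointwise variance of a
  finite ensemble is too noisy to differentiate raw.  The smoothing
  widens sharp friction features by ≈ σ and shifts the apparent peak
  of a narrow bump by a comparable amount;
* the identity ΔG + W_diss = ⟨W⟩ holds exactly at every grid point by
  construction and is asserted in tests.

The cumulant truncation fails for strongly non-Gaussian work.
`normality_diagnostic` computes per-grid-point skewness and excess
kurtosis with bootstrap confidence bands and flags |skewness| > 1
(configurable).  A `jarzynski_profile` exponential-average estimator is
provided purely as a cross-check; its sampling error grows
exponentially with dissipated work and it should not be preferred.

With 200 replicas the relative standard error of any variance-derived
quantity is ~√(2/199) ≈ 10%; plateau friction estimates averaged over
a window inherit essentially this floor because local slopes telescope
to endpoint differences.  Error bars on Γ should be read accordingly.

## Unbinding-path separation

Pulled trajectories are fingerprinted by protein–ligand contacts:
features are protein residues whose minimal heavy-atom distance to the
ligand drops below 4.5 Å in at least one frame of the batch; entries
are per-frame minimal distances capped at 10 Å so bulk-solvent frames
do not dominate.  PCA (mean-centred, unscaled — all features share
ångström units) reduces the concatenated frames to four components.

Pairwise trajectory similarity uses a mean-nearest-neighbour
construction: d_ij is the mean distance from frames of i to the
nearest frame of j in PC space, D_ij = max(d_ij, d_ji), and
s_ij = exp(−D_ij/σ_s) with σ_s the median off-diagonal D (the
`radius_quantile` is configurable).  This construction is isolated in
one function (`trajectory_similarity`) precisely because it is the
least canonical part of the chain and may be swapped without touching
the clustering.

Communities maximise the constant Potts model objective

    Q = Σ_c [ e_c − γ·n_c(n_c−1)/2 ]

via Leiden optimisation (leidenalg) on the fully connected weighted
similarity graph, at resolution γ = median(s_ij) unless given
explicitly.  The optimiser runs 50 restarts from seeds derived from
one user seed and keeps the best quality, recomputed independently
from the labels as a self-check; on ≤ 8-node problems this reliably
attains the exhaustive-search optimum.  Two caveats are inherent to
the median heuristic: it is only meaningful when distinct paths exist
(on a homogeneous batch the median sits mid-distribution and shatters
it), and because σ_s is itself the median D, γ ≈ e⁻¹ always lies
inside the within-path similarity distribution, so single outlier
trajectories can legitimately split off.  Free-energy estimation then
proceeds on the work curves of the largest community only (ties break
to the lower community id).

## Residue-correlation communities

Internal collective motions are found from residue-pair contact
dynamics: candidate pairs are protein residue pairs at sequence
separation ≥ 2 (covalent neighbours correlate trivially); a pair is
retained when its minimal heavy-atom distance is below 4.5 Å in at
least 30% of frames (`min_contact_fraction`, a persistence filter the
all-pairs feature space needs to stay tractable); Pearson correlations
between the retained distance traces are clustered with the same
Leiden/CPM engine at γ = 0.2, using |ρ| as the similarity so that
anti-correlated but mechanically coupled pairs cluster together.
Communities are reported both at pair level and as the union of
residues their pairs touch.  When several replicas are analysed they
are concatenated frame-wise before the correlation.

## Transient-pocket clustering

Ligand poses (heavy-atom coordinates after Kabsch superposition of the
protein onto a reference frame) are clustered with DBSCAN under the
mass-weighted RMSD metric √(Σ mᵢ‖Δrᵢ‖²/Σ mᵢ) without refitting,
at eps = 5 Å and min_samples = 50 (a cluster must persist ~10 ns at
0.2 ns/frame).  DBSCAN is implemented directly on the precomputed
distance matrix so that the border-point rule is deterministic: a
border point reachable from several clusters joins its lowest-indexed
core neighbour.  Each cluster is summarised by the protein residues
within 4.5 Å of its centroid, tagged hydrophobic/hydrophilic by the
sign of the Kyte–Doolittle index — the quantitative handle behind the
hydrophilic/hydrophobic pocket distinction near the gate.

## Conservation and gate typing

Conservation is a plain residue frequency, not an entropy score: the
percentage of sequences carrying a residue from a given set at an
alignment column.  Because headline numbers depend on it, both the
family subset and the denominator (all sequences vs non-gap sequences)
are explicit arguments and the CLI reports both denominators; no
default pretends to be canonical.  Reference positions (e.g. Y82) are
mapped to columns by counting non-gap positions of a named reference
sequence, with a configurable construct start offset.  Gate typing
classifies the residue opposite the gate tyrosine into P, S, D/E or
Other (gaps counted separately), aggregated per family
(OBP/VEG/SAL/LCN9/MUP).

## ITC single-site fitting

The Wiseman single-site isotherm with perfusion-displacement dilution:
each injection of volume dV dilutes cell contents by (1 − dV/V₀);
bound ligand follows the mass-action quadratic

    B = [nM + X + K_d − √((nM + X + K_d)² − 4nMX)] / 2

and the heat of injection i is dH·V₀·(B_i − B_{i−1}(1 − dV/V₀)).
Defaults mirror a VP-ITC odorant experiment: 25 µM protein, 250 µM
ligand, 25 × 10 µL injections, 298.15 K, 1.4 mL cell (instrument-
typical; the cell volume rescales n and dH jointly and must match the
instrument for absolute numbers).  Fitting minimises squared heat
residuals over (n, log₁₀K_d, dH) with `scipy.optimize.least_squares`;
standard errors come from the Jacobian at the optimum (delta method
for K_d).  Two diagnostics guard interpretation: a *no-binding* flag
when the fitted enthalpy signal is below three times the residual
noise (reporting a K_d would be meaningless), and a c-value warning
when c = n·M₀/K_d leaves [1, 1000].  dG = RT ln K_d and TdS = dH − dG
are derived, in kcal/mol.

## Synthetic ground truth: what it does and does not show

Every stage is validated against generators that return their planted
truth alongside the data; identical spec + seed is bit-reproducible.

* **Work ensembles.** Two modes share one planted potential U(x)
  (Gaussian-well landscapes by default: a deep bound well and a
  shallower vestibule well ~55 kJ/mol apart) and friction profile
  γ(x) = γ₀ + bumps (default γ₀ = 2·10¹² kg mol⁻¹ s⁻¹ — the order of
  molar Stokes friction of a small solute in water — with one
  high-friction window at 9 Å, where hydration is shed).
  `gaussian_analytic` draws work increments with mean dU + γv·dx and
  variance 2γv·dx·k_BT, fluctuation–dissipation-consistent by
  construction; `langevin` time-steps the constrained coordinate with
  an explicit random force (⟨ξξ′⟩ = 2γk_BT δ) and integrates
  W = ∫f_c v dt.  Both therefore produce *exactly* Gaussian work — they
  validate the estimator algebra and its sampling behaviour, not the
  Gaussian assumption itself, which real anharmonic baths can break.
* **Binding scenarios.** A schedule of states with per-state levels of
  the three observables (distance/gate/solvation + Gaussian noise)
  yields analytic traces, and optionally an explicit coordinate
  realisation: a sparse rigid scaffold (anchor residues, S34 backbone,
  Y82 OH, F100 side chain), a three-atom ligand approaching along an
  axis, and waters placed so the in-shell count realises the scheduled
  solvation.  Default solvation levels are 1.0 / 0.75 / 0.60 / 0.15 /
  0.03 / 0.03 along unbound→e, matching the mechanism narrative
  (~25% dehydration on contact, stable 60% in the pocket, near-complete
  dehydration in the site).  The scaffold is deliberately sparse so
  cutoff counts are unambiguous; it has no internal protein dynamics,
  so it cannot test force-field realism, PBC imaging subtleties or
  water exchange kinetics — only the observable and classification
  machinery.
* **Path batches.** Each path touches its own residue fingerprint at
  contact distances (3–4.5 Å with per-trajectory offsets, frame drift
  and noise), all other residues sit at the far-field cap.  The
  default split is 130/70 over 200 trajectories.
* **Alignments.** Exact-count mode deals residues so realised non-gap
  column frequencies match the spec exactly: the non-gap row count is
  the largest multiple of the frequency's reduced denominator that
  fits (0.82 = 41/50 → 200 non-gap rows of 248, 164 Y, 48 gap rows),
  which makes conservation checks exact rather than stochastic.
* **ITC.** Isotherms from the same forward model plus Gaussian heat
  noise — recovery tests are self-consistency plus an independent
  root-finding equilibrium oracle for the forward model itself.

## Problem sizes

Default test and acceptance problem sizes were chosen to exercise the
estimators at the conditions stated above while keeping a full run in
well under a minute of compute per stage: 200 pulling replicas × 2.5 ns
at 0.05 ps steps, 200 path trajectories × 30 frames, 730-frame binding
trajectories with 40 waters, 248-sequence alignments, 25-injection
titrations, 100-seed ITC noise studies.

## Known limitations

* The s_ij trajectory-similarity construction is one reasonable choice
  among several; conclusions about borderline trajectories (single
  outliers splitting off near γ) depend on it.
* The friction estimator inherits the ~√(2/n) variance floor of the
  work-variance estimate; 200 replicas give ~10% on any plateau value.
* Conservation is frequency-based only; no substitution-matrix or
  entropy weighting.
* The ITC model is strictly single-site; competitive or sequential
  binding silently degrades into effective parameters.
* Median-filter state smoothing can misplace state boundaries by up to
  half the filter width.
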