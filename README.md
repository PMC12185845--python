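# calyxpath

Analysis stack for resolving how hydrophobic ligands enter and leave
the internal binding cavity (the *calyx*) of odorant-binding proteins
and related lipocalins.  Written for structural-bioinformatics and
molecular-simulation groups who have MD trajectories of a
protein–ligand system (or constraint-pulling output) and want the
complete downstream analysis as tested, scriptable components instead
of one-off notebooks.

The β-barrel of a lipocalin occludes its calyx from solvent; binding
requires a gate — in rat OBP1 the hydrogen bond between the Y82
hydroxyl and the S34 backbone carbonyl (closed below 3.4 Å) — to open.
`calyxpath` covers the full chain of analyses around that mechanism:

* **gate_dynamics** — per-frame binding observables (ligand–F100
  centre-of-mass distance, gate distance, normalised ligand solvation),
  binding-event detection (< 5 Å for ≥ a dwell window) and assignment
  of the five-step mechanism states: contact-closed (a), pocket-closed
  (b), entry-open (c), site-open (d), site-closed (e).
* **dctmd** — dissipation-corrected targeted MD post-processing.  From
  replica work curves W(x) of constant-velocity pulling, with
  β = 1/k_BT:

      W_diss(x) = (β/2)·Var[W(x)],   ΔG(x) = ⟨W(x)⟩ − W_diss(x),
      Γ(x) = (1/v)·dW_diss/dx

  i.e. the free-energy profile and friction field along the unbinding
  coordinate under the Gaussian-work (second-cumulant) approximation,
  plus a work-normality diagnostic for when that approximation is in
  doubt.
* **path_clustering** — separation of unbinding pathways: residue–
  ligand contact fingerprints → PCA (4 components) → pairwise
  trajectory similarities s_ij → Leiden communities under the constant
  Potts model, Q = Σ_c [e_c − γ·n_c(n_c−1)/2], at γ = median(s_ij);
  the largest community's work curves feed the dcTMD estimator.
* **residue_mosaic** — collectively moving residue groups from Pearson
  correlations of residue-pair contact distances (4.5 Å cutoff),
  clustered with the same Leiden/CPM engine at γ = 0.2.
* **pose_clustering** — transient ligand pockets by DBSCAN (eps 5 Å,
  min 50 poses) under mass-weighted RMSD, with per-pocket contact
  residues and Kyte–Doolittle hydropathy tags.
* **conservation** — alignment-column residue frequencies across
  lipocalin families (OBP/VEG/SAL/LCN9/MUP), reference-position
  mapping (e.g. "Y82"), and gate typing into {P, S, D/E, Other}.
* **itc_fit** — single-site (Wiseman) isotherm simulation and
  nonlinear fitting of ITC injection heats to (n, K_d, ΔH), with
  no-binding and c-value diagnostics.
* **synthetic** — generators with planted ground truth for every one
  of the above (Langevin/Gaussian work ensembles over a known
  potential and friction profile, five-step binding trajectories with
  explicit waters, planted path batches, factor-model correlation
  systems, exact-composition alignments, noisy isotherms), so the
  whole pipeline is verifiable without running MD.

See `docs/methods.md` for the models, assumptions and numerical
choices in detail.

## Worked example: free energy and friction of unbinding

Generate a 200-replica constrained-pulling ensemble (1 m/s, 2.5 ns,
300 K) over a planted double-well landscape with a high-friction
window, then recover both fields with the dcTMD estimator:

```python
import numpy as np
from calyxpath import synthetic, dctmd

spec = synthetic.PullSimSpec(seed=0)          # 200 replicas, 1 m/s, 2.5 ns, 300 K
ens, truth = synthetic.gen_work_ensemble(spec, mode="langevin")
profile = dctmd.estimate_profile(ens, smoothing_sigma=0.5)

gap = (profile.dG[(profile.grid >= 6) & (profile.grid <= 14)].min()
       - profile.dG[profile.grid < 6].min())
peak = profile.grid[np.argmax(profile.friction)]
rms = np.sqrt(np.mean((profile.dG - truth["dG"]) ** 2))
print(f"bound->vestibule free-energy gap: {gap:.1f} kJ/mol")
print(f"friction peak position:           {peak:.1f} A")
print(f"dG RMS error vs planted truth:    {rms:.2f} kJ/mol")
```

which prints

```
bound->vestibule free-energy gap: 54.4 kJ/mol
friction peak position:           9.2 A
dG RMS error vs planted truth:    0.49 kJ/mol
```

The recovered free-energy gap between the bound well and the vestibule
minimum matches the planted ~55 kJ/mol landscape, and the friction
peak sits at the planted 9 Å dehydration window (shifted ~0.2 Å by the
0.5 Å smoothing kernel).  The same estimator runs on real pull files
via the CLI:

```bash
calyxpath dctmd --pullf 'run*/pullf.xvg' --velocity 1.0 \
    --temperature 300 --sigma 0.5 --out profile.csv
```

Other subcommands follow the same pattern (`calyxpath gate`,
`pockets`, `paths`, `mosaic`, `conserve`, `itc fit`, `simulate ...`,
`run --recipe ...`); each writes CSV/JSON plus, for the workflow
recipes, a provenance manifest listing every effective parameter.

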