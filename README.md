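# msmbind

Markov-state-model estimation of the standard binding free energy, the
association/dissociation kinetics, and the bound-state contact profile of a
small molecule binding reversibly to an intrinsically disordered peptide.

Small molecules that bind disordered proteins — the motivating system is the
inhibitor 10058-F4 engaging the c-Myc<sub>402–412</sub> peptide — do not form
a single well-defined complex. Binding is "fuzzy": the ligand associates and
dissociates many times over a long simulation, visiting a broad ensemble of
loosely bound poses. Pose-restrained free-energy methods struggle here, but a
Markov state model (MSM) built on replicated equilibrium trajectories handles
it naturally: it yields the stationary populations of a bound and an unbound
macrostate *and* the interconversion kinetics in one framework. This package
implements that protocol end to end as a tested, reusable library, and ships
synthetic trajectory generators with analytically known ground truth so every
stage of the pipeline can be validated quantitatively.

## The model

Trajectories of one peptide (Cα trace) plus one ligand are featurised with
one of three protein–ligand distance metrics (the 11 ligand-N–Cα distances,
optionally tICA-projected; the shortest N–Cα distance; or the shortest
distance over the ligand's N and C atoms). Frames are discretised by k-means
(default 75 microstates), transition counts are collected at lag τ (default
200 ps for MD data) without ever crossing replica boundaries, and a reversible
transition matrix `T` is estimated by maximum likelihood under detailed
balance. Implied timescales and the Chapman–Kolmogorov test validate the
model; PCCA+ coarse-grains the microstates into two metastable sets, and the
set with the smaller population-weighted ligand–peptide distance is labelled
**bound**. With stationary macrostate probabilities π₂ (bound) and π₁
(unbound), the standard binding free energy is

```
ΔG° = −k_B T ln(π₂/π₁) − k_B T ln(V_unbound / V°),     V° = 1660 Å³
```

where `V_bound = (4/3)π r̄³` is a sphere whose radius is the mean
ligand–peptide centre-of-mass distance over snapshots sampled from the bound
macrostate, `V_unbound = V_total − V_bound`, and V° is the volume per molecule
at the 1 M standard state. The dissociation constant follows as
`K_d = exp(ΔG°/k_B T) · 1 M`. Treating binding as first order, mean first
passage times from the Bayesian MSM convert to rate constants

```
k_off = 1 / MFPT(bound → unbound)
k_on  = 1 / (MFPT(unbound → bound) · C_compound)
```

with `C_compound` the ligand concentration implied by the box volume.
Per-residue profiles of hydrophobic contacts (any ligand-C–residue-C pair
closer than 4 Å) and hydrogen bonds (donor–acceptor ≤ 3.0 Å, D–H···A ≥ 135°)
are computed over probability-weighted bound-state snapshot samples.

The synthetic generators provide (i) discrete Markov chains with a known
transition matrix and (ii) a Metropolis Monte Carlo "toy complex": a rigid
four-heavy-atom ligand diffusing in a periodic box around a static 11-bead
peptide whose N-terminal beads carry a square attractive well. Because
Metropolis sampling is exact, the bound-state probability — and hence ΔG° —
is computable by quadrature, giving a rigorous ground truth the full pipeline
must recover.

## Worked example

Generate a toy ensemble with a 2 kcal/mol well (12 replicas × 20 ns at
1 ps/frame) and run the full pipeline:

```bash
msmbind simulate --well-depth 2.0 --n-steps 20000 --n-replicas 12 --seed 7 \
    --out myc_toy.npz --print-ground-truth
# ground truth: dG° = -2.454 kcal/mol, pi_bound = 0.8129, V_bound = 3557.4 Å³

msmbind run --topology myc_toy.npz --metric n-cas-tica --lag 10 --clusters 75 \
    --n-snapshots 500 --repeats 4 --seed 11 --no-validation --out myc_report
```

which prints (abridged):

```json
{
  "pi_bound": 0.8469,
  "V_bound_A3": 3671.7,
  "dG_standard_kcal_mol": -2.595,
  "K_d_molar": 0.0129,
  "k_on_per_s_per_M": 2.52e11,
  "k_off_per_s": 2.84e9
}
```

The estimated ΔG° of −2.60 kcal/mol recovers the analytic ground truth of
−2.45 kcal/mol to 0.14 kcal/mol; the bound population (0.847 vs 0.813 exact)
and bound volume (3672 vs 3557 Å³) agree correspondingly, and K_d lands in
the tens-of-millimolar range typical of weak IDP binders. The per-residue
contact table written to `myc_report/contact_profile.csv` recovers the
generator's N-terminal binding preference — hydrophobic contact percentages
of ≈13% for Tyr402–Leu404 falling to ≈1–3% in the C-terminal half, with
hydrogen bonds essentially absent (≤ 0.3%), i.e. binding in this regime is
dominated by nonspecific hydrophobic contact, not directional interactions.

Real MD data flow through the same commands: pass a PDB topology and DCD/XTC
coordinate files (one per replica) instead of the `.npz` container; atom roles
are resolved from residue and element information.

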