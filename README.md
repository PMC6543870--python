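# ramdfp

Machine-learning analysis of ligand-dissociation trajectories for
drug-target residence times.

## The problem

How long a drug stays bound to its target — the residence time
τ = 1/k_off — often predicts efficacy better than binding affinity, but
dissociation happens on time scales (seconds to hours) far beyond what
molecular dynamics can reach. Random acceleration MD (RAMD) forces ligand
egress within nanoseconds by adding a randomly re-oriented force to the
ligand, and the *relative* egress times across many short trajectories
rank compounds by residence time (the tauRAMD protocol). The egress
trajectories also record *how* each compound leaves: which protein
residues it touches on the way out.

`ramdfp` turns those trajectories into quantitative structure-kinetics
models. It is aimed at computational chemists post-processing RAMD (or
other enhanced-sampling egress) simulations for congeneric inhibitor
series, e.g. HSP90 ATP-site binders:

1. **Fingerprints** — each frame is typed geometrically into 7 bits per
   contacted residue (hydrophobic, aromatic face/edge, H-bond donor /
   acceptor, cationic/anionic), collapsed to four contact categories per
   residue: HB, ARO, IP, APO. A dissociation event is the first frame
   where the ligand centre of mass has moved 30 Å from its bound position.
2. **Featurization** — the bound-state part of each trajectory is
   discarded under three truncation rules (data-sets **A**: ≥ 2 bound
   contacts lost, **B**: ≥ 20 %, **C**: ≥ 60 %); per-feature occurrences
   are averaged over the transition frames, then over trajectories per
   compound; features rarer than 5 % everywhere are dropped, and one of
   each feature pair with R² > 0.9 is removed; columns are scaled to [0, 1].
3. **Residence times** — per replica, the tauRAMD statistic is the time by
   which 50 % of trajectories have dissociated (interpolated median, with
   non-dissociating trajectories censored); the compound estimate averages
   replicas, and an OLS fit of log₁₀(τ_RAMD) on log₁₀(1/k_off) maps it onto
   the experimental scale.
4. **Regression** — ridge linear regression (LR), RBF support-vector
   regression (SVR), and a train-mean Dummy control predict
   log₁₀(1/k_off) over repeated (default 200) constrained 80/20 splits
   with per-round grid-search (10-fold random-permutation CV), scored by
   MAE and the external-validation coefficient Q²F3.
5. **Clustering** — Gaussian mixtures with full per-component covariance
   group compounds by dissociation fingerprints; the component count is
   chosen by AIC; 50 repeated clusterings are ordered by mean residence
   time and summarized by per-cluster feature weights and fragment
   occupancies.

A first-class synthetic-fixture module generates every input the pipeline
consumes — scripted contact streams, replica egress-time samples with a
planted scaling law, planted linear feature → log τ compound sets, and a
miniature PDB + DCD complex realizing all five contact archetypes — so the
whole chain is testable without simulation data.

## Worked example

Fingerprint a generated toy complex in which each contact archetype breaks
at a scripted frame and the ligand leaves at frame 12:

```python
from ramdfp.synthetic import gen_toy_complex
from ramdfp.traj_contacts import read_trajectory, fingerprint_trajectory

toy = gen_toy_complex({"hb": 4, "apolar": 6, "ionic": 8,
                       "aro_face": 9, "aro_edge": 10, "egress": 12},
                      "demo/toy", n_frames=16, seed=0)
series = read_trajectory(toy.topology_path, toy.trajectory_path,
                         ligand_typing=toy.ligand_typing, compound_id="toy")
ifs = fingerprint_trajectory(series)
print(ifs.feature_names, ifs.dissociation_frame)
```

```
['K58-IP', 'D93-HB', 'F138-APO', 'Y139-ARO', 'W162-ARO'] 12
```

The hydrogen bond to D93 disappears from frame 4 onward, the ionic contact
to K58 from frame 8, and so on, exactly as scripted.

Train regression models on a 94 × 47 synthetic compound set with a planted
linear law (noise SD 0.3 log units) and estimate residence times from
synthetic egress samples:

```python
import numpy as np
from ramdfp.featurize import minmax_normalize
from ramdfp.regress import repeated_evaluation
from ramdfp.synthetic import gen_compound_set, gen_scaling_dataset
from ramdfp.tau import tau_ramd, fit_scaling

matrix, manifest = gen_compound_set(seed=0)
res = repeated_evaluation(minmax_normalize(matrix), n_rounds=50, seed=0)
print(res.summary())

egress, koffs, _ = gen_scaling_dataset(n_compounds=80, seed=0)
fit = fit_scaling([tau_ramd(e) for e in egress], koffs)
print(f"slope={fit.slope:.3f} intercept={fit.intercept:.3f}")
```

```
model     subset  mae_mean  mae_sd  q2f3_mean  q2f3_sd  n_rounds
Dummy       test     1.154   0.171      0.012    0.397        50
   LR       test     0.493   0.067      0.839    0.050        50
  SVR       test     0.518   0.066      0.824    0.050        50
slope=0.390 intercept=-0.518
```

LR/SVR reach a test MAE of ~0.5 log units against ~1.15 for the null
model (test rows shown), and the scaling fit recovers the planted law
(slope 0.39, intercept −0.52) to three figures.

A `ramdfp` console script exposes the same pipeline as subcommands
(`fingerprint`, `featurize`, `tau`, `train`, `cluster`, `simulate`,
`report`); `ramdfp report config.yaml` runs the configured stages
end-to-end with one master seed and reproducible outputs.

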