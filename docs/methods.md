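# Methods

This note documents the models and procedures `ramdfp` implements, the
defaults it chooses where the field's conventions leave room, and what its
synthetic validation data do and do not establish.

## Contact typing

Each trajectory frame is reduced to one 7-bit record per protein residue
in contact with the ligand: hydrophobic, aromatic face-to-face, aromatic
edge-to-face, H-bond with the ligand as donor, H-bond with the ligand as
acceptor, ligand-cationic ionic pair, ligand-anionic ionic pair. The
records collapse to four binary categories per residue — HB (donor OR
acceptor), ARO (face OR edge), IP (cationic OR anionic), APO
(hydrophobic) — which, prefixed by the residue (e.g. `F138-APO`), are the
machine-learning features.

Geometric criteria (Å, degrees) follow common structural
interaction-fingerprint conventions and are fully configurable:

| interaction | criterion | default |
|---|---|---|
| hydrogen bond | donor–acceptor heavy-atom distance; D–H···A angle when an H is bonded to the donor | ≤ 3.5; ≥ 120° |
| hydrophobic | apolar-carbon C···C distance | ≤ 4.5 |
| aromatic, stacked | ring-centroid distance; ring-plane angle | ≤ 4.4; ≤ 30° |
| aromatic, T-shaped | ring-centroid distance; ring-plane angle | ≤ 5.5; ≥ 60° |
| ionic | distance between opposite formal-charge centres | ≤ 4.0 |

The donor-angle test is skipped when the structure carries no hydrogens
(the common case for backbone donors in crystal-derived topologies); ring
normals come from the smallest-variance SVD direction of the ring atoms,
and the plane angle is folded to [0°, 90°]. Protein atoms are typed from
residue/atom-name dictionaries for the twenty standard amino acids
(Lys/Arg cationic and Asp/Glu anionic at pH 7, His neutral); ligands are
typed from an explicit per-atom table (JSON) because reliable
small-molecule perception is out of scope. Contacts are computed against
protein residues only; waters and ions are not fingerprinted, and no
periodic-boundary treatment beyond the raw coordinates is applied.

A dissociation event is the first frame at which the ligand's
mass-weighted centre of mass lies ≥ 30 Å from its position in frame 0;
trajectories that never reach the threshold are kept with a censored flag.

## Truncation and featurization

The bound reference of a trajectory is the contact set of its first
frame. The transition part starts at the first frame where the number of
bound-reference features simultaneously absent reaches the rule's
threshold — A: 2 contacts; B: ⌈0.20·n_bound⌉; C: ⌈0.60·n_bound⌉ — and runs
through the dissociation frame inclusive (to the last frame when
censored). Ceilings are used because a fraction of contacts must
correspond to whole contacts; the loss count is taken on the
(residue, category) features, the granularity at which features are
defined everywhere else. Later re-formation of contacts never moves the
truncation point back, and because 2 ≤ ⌈0.2 n⌉ ≤ ⌈0.6 n⌉ for bound sets of
ten or more contacts, transition(C) is a suffix of transition(B), which
is a suffix of transition(A).

Occurrences (fraction of transition frames containing a feature) are
averaged per trajectory, then unweighted over a compound's trajectories,
features absent from a trajectory contributing zero. Two filters clean
the compound matrix:

- **Rare features.** A feature is dropped only when its occurrence is
  below 5 % in *every* compound (max-over-compounds rule). The wording
  "rarer than 5 % for any compound" is ambiguous; the max rule is used
  because a contact that matters for even one compound should survive.
  The 5 % boundary itself is kept (inclusive).
- **Correlated features.** Features are scanned in canonical order
  (ascending residue number, then HB < ARO < IP < APO) and dropped when
  their squared Pearson correlation with any already-kept feature exceeds
  0.9, so the survivor of each correlated pair is deterministic.
  Zero-variance columns have undefined correlation, treated as 0 (kept).

Normalization maps each feature linearly to [0, 1] over all compounds
(constant columns to 0). It is fit on the full matrix before splitting,
mirroring the protocol the models are meant to reproduce; this leaks the
test-set column ranges into training, which is harmless for [0, 1]-bounded
occurrences but worth knowing — fitting the scaler per training set is
available by normalizing after splitting.

## Residence-time statistic

For one equilibration replica with n egress times, the tauRAMD statistic
is the interpolated median — the time by which half of the trajectories
have dissociated. Censored trajectories count as larger than every
observed time; when they reach 50 % of a replica the statistic is
undefined and an error demands more sampling. The compound estimate is
the mean of replica medians, its uncertainty their standard deviation
(ddof 1; zero for a single replica). Scaling to experiment is ordinary
least squares of log₁₀(τ_RAMD [ns]) on log₁₀(1/k_off [s]), with flagged
outlier compounds excluded from the fit but still scalable through it.
Compounds whose k_off lies outside the assay range enter at the
measurement floor (default 10⁻⁴ s⁻¹). All model quantities are log₁₀;
agreement is reported as MAE and squared Pearson correlation, plus MAE
within experimental residence-time bins (< 1 s, 1–2 s, 2–3 s, > 3 s).

## Regression protocol

Labels are log₁₀(1/k_off). Each round:

1. **Split.** 20 % of compounds form the external test set, containing
   exactly 2 compounds drawn from the outlier pool (compounds whose
   residence times are badly estimated from trajectory lengths alone) and
   at least ⌈0.2·|pool|⌉ — at least 9 when the pool has ≥ 45 members —
   from the over-represented indazole pool; the remainder is drawn
   uniformly from compounds outside the outlier pool, so the outlier
   count is exact. Overlapping pools resolve outlier-first.
2. **Hyperparameters.** Exhaustive grid search minimizing mean validation
   MAE over 10 random-permutation folds (20 % validation). Grids: ridge
   strength 10⁻³…10³ (13 log-spaced); SVR C 10⁻¹…10³ (5), ε
   {0.01, 0.05, 0.1, 0.2}, RBF width 10⁻³…10¹ (5). The ridge grid is
   evaluated through one SVD per fold (all strengths from one
   decomposition), which is numerically identical to refitting per
   strength — an equivalence asserted in the test suite.
3. **Scoring.** 10 random-permutation CV fits on the training set; MAE
   and Q²F3 are recorded for the fitting subset, the validation subset,
   and the external test set, averaged over the 10 fits. LR coefficients
   are likewise averaged.

Q²F3 = 1 − [Σ_test(y−ŷ)²/n_test] / [Σ_train(y−ȳ_train)²/n_train]. For the
train-mean Dummy predictor its expectation is 0 up to a finite-sample
bias of order −4/n_train (≈ −0.05 at 75 training compounds); the
null-behaviour check therefore uses a sample large enough (400) for the
bias to be negligible. Rounds (default 200) run with per-round seeds
derived from one master seed; round failures are recorded and reported,
and the run aborts only if every round fails. Trajectory-length-based
(scaled tauRAMD) predictions can be evaluated on the identical test
subsets for comparison.

## Clustering

Compounds are clustered in normalized feature space by a Gaussian mixture
with a full covariance matrix per component (EM, hard assignment by
maximum responsibility). The component count is chosen by AIC over a 2–10
scan with 10 seeded restarts per count, neither of which is prescribed by
convention. The covariance floor is 10⁻³ (variance units of the [0, 1]
feature scale, i.e. an SD floor of ~3 % of the range): with the usual
10⁻⁶ floor, components collapse onto near-singular clumps of a few
compounds and the likelihood gain produces spurious AIC minima at large
counts. Clustering is repeated 50 times; within each repeat clusters are
ordered by the mean log residence time of their members, and repeats are
matched *by rank* (not composition). "Feature weights" of a cluster are
its component mean vector in normalized feature space. Stability is
summarized as the mean pairwise adjusted Rand index across repeats,
reported without a pass threshold. Fragment occupancy divides the number
of cluster members carrying each annotated fragment class (e.g.
solvent-exposed R1, buried R2 substituents) by the cluster size,
averaged over repeats.

## Synthetic study conditions

The generators define the conditions under which the pipeline is
validated:

- **Contact streams**: 14 features, bound sets of 12, 60 frames, an
  egress frame in the second half, loss frames uniform before egress —
  enough bound contacts that the three truncation thresholds are ordered
  strictly.
- **Compound sets**: 94 compounds × 47 features, matching the scale of a
  typical congeneric-series study; occurrences Beta(0.7, 1.6) (skewed
  toward rare contacts, as in real occurrence matrices); Gaussian planted
  weights rescaled so the noise-free label spread is 1.5 log units around
  an intercept of −1, mimicking measured log₁₀(1/k_off) spreads of
  roughly −4…2; label noise SD 0.3 log units; scaffold annotations in the
  proportions 14 outliers / 45 indazoles / 35 others so constrained
  splitting is exercised.
- **Egress times**: 4 replicas × 15 trajectories per compound, log-normal
  with ln-scale spread 0.4; the planted scaling law defaults to slope
  0.39, intercept −0.52, the magnitude of empirical tauRAMD-to-experiment
  scalings for HSP90-scale systems.
- **Blobs** (clustering): 3 × 50 compounds in 4 features, SD 0.08 around
  centres on the unit-cube diagonal — about 17 samples per free mixture
  parameter, the regime where AIC is a consistent selector.
- **Toy complex**: five archetypal contacts placed 40 Å apart so they
  cannot cross-talk; ligand ring carbons are deliberately typed aromatic
  but not apolar so each archetype maps to exactly one feature category.
  Groups jump 15 Å out of their site at their break frame and the whole
  ligand 200 Å at egress, keeping the centre of mass below the 30 Å
  criterion until the scripted event.

What passing these conditions shows: the geometry, truncation, filtering,
statistics, and model-selection machinery are correct against independent
oracles (brute-force scans, closed forms, normal equations, planted
structure). What it does not show: that real RAMD trajectories satisfy
the generators' independence and noise assumptions — real occurrence
matrices are correlated by physics, real egress times are heavier-tailed,
and force-field or pose errors bias whole compound series, none of which
the synthetic conditions emulate.

## Numerical choices and limitations

- Frames are 0-indexed; times ns; coordinates Å; logs base 10 throughout.
- Ties in grid search resolve to the smallest parameter (first minimum in
  ascending grid order); AIC ties to the smallest component count.
- Empty transition parts (truncation criterion never met) exclude the
  trajectory from aggregation with a warning rather than failing a
  compound.
- Per-frame contact typing is O(n_ligand × n_protein) per frame without
  spatial decomposition — adequate for binding-site-scale systems, slow
  for very large complexes.
- Exact numeric reproduction of fingerprints produced by other toolkits
  is not promised: published per-frame bit streams depend on their
  toolkit's unpublished cutoffs; this package's cutoffs are documented
  conventions.
- Time-ordered (sequence-of-events) dissociation models and
  water-mediated contacts are out of scope by design.
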