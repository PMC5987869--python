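# Methods

This note documents the models, procedures, numerical choices, and known
limitations behind `ldpatterns`. Module by module it covers what is
simulated, what is estimated, and what the simulations do and do not show
about real data.

## Synthetic cohort (`ldpatterns.cohort`)

**Task design.** A run alternates 15 s fixation blocks with 15 s format
blocks (dot arrays, Arabic digits, number words). A format block is one
900 ms reference presentation followed by three trials of 300 ms fixation +
4400 ms subtraction item: 900 + 3×(300+4400) ms = 15 s. Four blocks per
format per run give 12 trials per format per run; four runs; TR = 3 s; the
reference magnitude cycles [4 5 4 5] over runs. The number and placement of
fixation blocks is not pinned down by the block-alternation constraint
alone; the simulator's convention is to start and end with fixation (13
fixation + 12 format blocks, 375 s, 125 scans). The format block order is a
seeded balanced permutation: each consecutive triple of format blocks is a
fresh permutation of the three formats, avoiding order confounds.

**Latent amplitude model.** Voxel grids default to 16³ at 2.2 mm isotropic
(the study's acquisition voxel size); an inner box is the "brain", split
into four slab ROIs standing in for lobe masks; label 0 is background.
Within the brain mask, subject *i* of group *g* has per-format amplitudes

    A_i = mu + z_DL(g)·dev_DL + z_DC(g)·dev_DC + eps_i,
    eps_i ~ N(0, sigma_subject²) i.i.d. per voxel,

with indicator z's, and

    dev_DL = delta·(sqrt(rho)·s + sqrt(1−rho)·u_DL)
    dev_DC = delta·(sqrt(rho)·s + sqrt(1−rho)·u_DC)

where (s, u_DL, u_DC) are orthonormal random voxel patterns (QR of a
Gaussian matrix). Consequences used throughout the tests: ‖dev‖ = delta
exactly; the cosine between the two deviations equals `rho_shared` exactly;
`rho_shared = 1` makes the disorders deviate identically, `0` orthogonally.
The comorbid group's deviation defaults to the sum of both (additive
comorbidity, consistent with the behavioral literature's additive-deficit
findings); an averaging rule is available for sensitivity analyses.

**Parameters that matter.**

| parameter | default | meaning |
|---|---|---|
| `n_td/n_dl/n_dc/n_dldc` | 22/14/8/8 | group sizes (total 52) |
| `effect_size_delta` | 8 (map units) | L2 norm of each disorder deviation |
| `rho_shared` | 0.5 | cosine between DL and DC deviations |
| `sigma_subject` | 0.1 | between-subject amplitude noise per voxel |
| `sigma_noise` | 1.0 | AR(1) scan-noise innovation sd |
| `ar1_coef` | 0.3 | lag-1 autocorrelation of scan noise |
| `motion_severity` | 0.05 mm | random-walk step sd (rotations scaled to match arc length at 50 mm) |
| `p_bad_run` | 0.1 | probability a run receives a 3 mm two-transition spike (the study lost ~10% of runs to motion) |

**Forward model.** BOLD = baseline + Σ_format amplitude·x_format(t) +
optional motion coupling + AR(1) noise (stationary initialization). The
format regressors are produced by the *same* routine the first-level GLM
uses, so the noiseless forward→inverse loop recovers amplitudes to machine
precision — verified at 1e-8 in the acceptance tests. This is a design
feature, not an accident: it separates testing of the estimation machinery
from the realism of the forward model.

**Behavior.** Trial-level accuracy / RT / non-response per group×format,
defaults encoding the qualitative direction of the study's findings:
dyscalculia impairs dots most (accuracy down, non-response up), dyslexia
impairs the symbolic formats, all disorder groups respond more slowly than
TD with under-additive comorbid slowing, non-response ordered
dots > digits > words.

**What the simulator does not emulate:** anatomy, spatial autocorrelation of
noise, physiological confounds, stimulus rendering, slice timing,
registration error, and session effects. Passing tests therefore validate
the *estimation and inference machinery* under a known generative model —
they do not certify performance on real scanner data.

## Motion QC (`ldpatterns.motion_qc`)

Scan-to-scan displacements are absolute first differences of the six
realignment parameters, rotations converted to arc length on a 50 mm sphere
(the standard framewise-displacement convention; the source procedure does
not state how rotations enter, so a translations-only mode exists). Two
run-exclusion rules, both strict inequalities against one voxel size
(2.2 mm): the same axis exceeding threshold on two *consecutive*
transitions, and the six-component Euclidean norm exceeding threshold on
any transition. (An alternative reading of "two consecutive scans" — a
single displacement between scans t and t+2 — is available as
`consecutive_mode='span'`.) Subjects keeping fewer than half their runs are
excluded; exactly half is retained. Residual group differences in motion are
checked with one-way ANOVAs on per-subject mean Euclidean motion, cumulative
motion, and retained-run count.

## First level (`ldpatterns.first_level`)

Gaussian smoothing (default FWHM 10 mm, sigma = FWHM/(2√(2 ln 2)) per axis in
voxel units) uses reflective boundaries so constant fields are preserved
exactly and small synthetic grids suffer no rim attenuation. The design
matrix holds one boxcar per format spanning the full block (the reference
presentation is part of the block, matching a model whose boxcars correspond
to the block length), convolved with the canonical double-gamma response
(peak-normalized; `hrf=None` gives raw boxcars for tests), six demeaned
motion regressors, and an intercept. Fixation is the implicit baseline, so
each format beta *is* the format-versus-fixation contrast. Estimation is
ordinary least squares per voxel; no autocorrelation prewhitening is applied
(a limitation: with AR(1) noise the single-run t statistics are mildly
miscalibrated, which is why the t-calibration tests use white noise).
Retained runs are combined by concatenation with per-run intercepts and
per-run motion blocks (averaging per-run contrasts is available); t =
estimate / SE with dof = total scans − rank.

## Group statistics (`ldpatterns.group_stats`)

Per voxel, a 2×2 between-subject factorial model (dyslexia, dyscalculia,
interaction) with Type III sums of squares computed by model comparison on
effect-coded designs — appropriate for the unbalanced 22/14/8/8 cells
(Type I sequential is available). Directional maps are pooled-variance
two-sample t statistics with one-sided p values for the control-vs-disorder
comparisons and pairwise disorder comparisons. Thresholding: voxel-level
Benjamini–Hochberg FDR (q = 0.05, via statsmodels, applied per contrast map)
and uncorrected p < 0.001, both strict, restricted to the in-brain mask so
background voxels never enter the FDR denominator. Degenerate zero-variance
voxels are detected against a relative tolerance (1e-12 of the per-voxel
mean square) and reported as F = ∞, p = 0.

## MVPA (`ldpatterns.mvpa`)

**Pattern matrices** are ROI-restricted contrast estimates (fixed C-order
voxel ordering), mean-centered within each subject; centering makes results
invariant to adding any constant to all of a subject's voxels (tested
exactly).

**One LPOCV pass** over groups balanced to size *n* (larger group subsampled
uniformly without replacement): a random bijection pairs the groups into *n*
disjoint test pairs; each pair is held out while the classifier trains on
the remaining 2(n−1) subjects; the pass accuracy covers all 2n subjects.
This reading of "repeated until each participant was left out once" is the
default; an all-cross-pairs mode exists (`pairing='all_pairs'`). Observed
accuracy is the mean over `n_repetitions` (default 1000) passes, each with a
fresh subsample and pairing.

**Permutation null:** each of `n_permutations` (default 1000) iterations
permutes the balanced label vector once, trains with the permuted labels in
every fold, and scores against the true labels; the significance cutoff is
the 95th percentile (linear interpolation) of the null pass accuracies, and
a cell is significant when the observed mean exceeds it strictly. A
full-relabeling mode (`permute_mode='full'`) exists as a sensitivity switch.
A caveat documented because it is measurable with this package: comparing a
repetition-averaged observed statistic with single-pass null draws makes the
test anticonservative when the voxel-to-subject ratio is large (chance
pattern–label alignment inflates the observed mean but not the permuted
null); at n = 8 per group and 64 voxels the measured false-positive rate for
two exchangeable groups is ≈ 30%. This mirrors the published procedure and
is kept as specified; interpretation of "non-significant" cells is
correspondingly safer than of marginally "significant" ones at small n.

**Generalization:** direction X→Y balances control/X/Y to the common
smallest size, pairs each held-out control subject with one Y subject,
trains controls-vs-X on the remaining subjects, and scores the held-out
control/Y pair with true labels. Any test-pair subject present in the
training pool is excluded from that fold's training set — the leakage
control; it also makes the degenerate Y = X case reduce exactly to ordinary
LPOCV classification (verified within Monte-Carlo error). Both directions
are averaged; the permutation null permutes training labels as above.

**Classifier.** Default: linear soft-margin SVM with unit regularization
(C = 1), squared hinge, regularized intercept — the dominant MVPA choice of
the study's era. Because the resampling procedures fit it ~10⁵–10⁶ times,
fitting runs a numba-compiled dual coordinate-descent solver for this
objective; tests assert its weights match scikit-learn's `LinearSVC`
(liblinear) to 1e-5 with sign-identical decisions. Features are centered on
the training mean before fitting because the regularized intercept otherwise
biases the boundary when both classes share a large offset. Decision scores
of exactly zero go to the first group deterministically. An LDA alternative
(pooled covariance, pseudo-inverse for n < p) is provided.

**Suite layout:** six classification comparisons (TD vs DL+DLDC, TD vs
DC+DLDC, TD vs DL, TD vs DC, TD vs DLDC, DL vs DC) and three generalization
pairs (DL↔DC, DL↔DLDC, DC↔DLDC) per ROI × format, one config for all cells,
per-cell seeded substreams so the table is reproducible and insensitive to
cell order.

## Behavioral statistics (`ldpatterns.behavior`)

Non-response trials (no response within the 4400 ms item limit) are removed
from accuracy and RT aggregation and tallied as per-cell percentages. RT
cells average correct trials (all-scored-trials mode available). Each
measure gets a mixed 2 (dyslexia) × 2 (dyscalculia) × 3 (format, within)
ANOVA: between-subject effects are tested against subjects-within-groups
(df 1, N−4), within-subject effects against the format×subject residual
(df 2, 2(N−4); for N = 52 exactly the 1,48 and 2,96 of the study's design),
with Type III SS by model comparison in each stratum and no sphericity
correction (the source reports uncorrected df). Subjects missing a format
cell are dropped listwise. Pairwise format follow-ups are paired t tests on
marginal means with Bonferroni adjustment p_adj = min(1, m·p).

## Pipeline (`ldpatterns.pipeline`, `config`, `cli`)

A pydantic-validated config (unknown keys rejected; resolved copy echoed to
the output directory) drives simulate → qc → first-level → group → mvpa →
behavior. One global seed derives per-stage substreams by hashing
(seed, stage), so disabling a stage never shifts another stage's randomness.
BOLD runs are synthesized per subject on demand (a full default cohort held
in memory at once would be ~8 GB; streaming keeps it ~20 MB). Each stage
records its outputs with SHA-256 checksums and is skipped on re-run when its
config section, seed, and outputs are unchanged. The default MVPA setting
(1000 repetitions / 1000 permutations over all ROI×format cells) is the
full-scale analysis and takes hours on one core; the tests and examples run
reduced settings.

## Problem sizes and design choices in the verification suite

- Permutation-null chance level: two exchangeable groups of 8, 100 voxels,
  1000 permutation iterations; the null mean is asserted at 50% ± 2 pp.
- Type-I calibrations: 1000+ null voxels for the factorial ANOVA; 1000 null
  replicates for the mixed ANOVA; first-level t tails at ±1.5% on ≥1000
  white-noise voxels.
- Oracle equivalences: BH-FDR vs a literal step-up on 200 random p sets; GLM
  betas vs normal equations at 1e-10; QC decisions vs literal rule
  re-evaluation on 1000 random walks; mixed-ANOVA F vs a hand-computed
  balanced SS decomposition at 1e-8 (with SS conservation).
- Parameter recovery: noiseless forward→GLM at 1e-8; `rho_shared` recovered
  within 0.1 from GLM-recovered group-mean deviations on a ≥10,000-voxel
  grid at near-zero subject noise.
- Qualitative pattern reproduction under the shared-deviation hypothesis
  (`rho_shared = 1`): 20 seeded replicates of four groups × 16 subjects with
  27-voxel patterns, delta = 2 against unit subject noise — a working point
  calibrated to mean TD-vs-disorder accuracy ≈ 0.75 — analysed at 200
  repetitions / 200 permutations. These sizes came from an explicit power
  analysis: with n = 8 per group the permutation test has only ~50–70% power
  at the 0.75 working point and a materially inflated false-positive rate
  for the exchangeable DL-vs-DC cell (see the caveat above), so no n = 8
  condition can make the pattern reproduce reliably; n = 16 with a small
  voxel count keeps the working point while restoring calibration and power.
  A replicate "reproduces the pattern" when the majority of TD-vs-disorder
  cells are significant, DL-vs-DC is not, and at least two of the three
  generalization cells are; ≥90% of replicates must reproduce it (the
  original study's own figures include non-significant TD-vs-DC cells in
  several ROIs, so requiring every cell in every replicate would demand more
  than the real-data pattern shows).

## Known limitations

- No prewhitening in the GLM; AR(1) noise mildly inflates single-run t
  statistics (the betas, which feed the MVPA, are unbiased regardless).
- The permutation scheme's small-sample anticonservatism described above.
- The simulator's noise is spatially white; FDR behavior under spatially
  correlated noise is not characterized here.
- ROI geometry is a toy parcellation (slabs of an inner box), not anatomy.
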