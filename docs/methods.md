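# Methods

## Graph spectral decomposition

The structural connectome is an undirected weighted graph on n cortical
regions (Desikan-Killiany, n = 66: 33 parcels per hemisphere, the
standard atlas list without the insula). Weights are streamline counts,
so the adjacency matrix A is symmetric and nonnegative with zero
diagonal; validation repairs asymmetry only up to a relative tolerance of
1e-8 (by averaging), and anything beyond that is an error rather than
silently symmetrized.

Because A is symmetric, A = VΛVᵀ with orthonormal V and real
eigenvalues sorted ascending. The graph Fourier transform is x̂ = Vᵀx.
The *high* graph-frequency band keeps the K smallest eigenvalues (sorted
indices 0..K−1), the *low* band the K largest — for an adjacency matrix,
large eigenvalues belong to smooth, anatomy-aligned modes, so the
low/high naming is inverted relative to Laplacian intuition. Band
membership is by **sorted index**, not eigenvalue sign or magnitude,
which keeps the definition well-posed for graphs with negative
eigenvalues. K defaults to 10 and is configurable.

Eigenvector signs are fixed deterministically (largest-magnitude entry
positive, ties to the lowest index) so serialized bases reproduce across
runs. Band energies are invariant to sign flips and to rotations within a
degenerate eigenvalue block (filters are subspace projections); the one
genuinely solver-dependent case — a degenerate eigenvalue straddling the
band boundary — is logged as a warning rather than guessed around,
because no convention can make the passed subspace unique there.

## BOLD preprocessing

Fixed order: trim → detrend → band-pass → z-score, enforced by stage
tags (re-applying a stage or skipping forward is allowed; going backwards
is an error).

* **Trim**: floor(18 s / TR) frames; at the study geometry (TR = 2 s,
  154 frames) this is exactly 9 frames, leaving 145.
* **Detrend**: per-region least-squares line (slope + offset).
* **Band-pass**: 0.009–0.1 Hz, hard (brick-wall) real-FFT bin mask with
  inclusive bounds. A hard mask is exactly testable (a sinusoid on an
  in-band bin passes untouched; on an out-of-band bin it vanishes) and
  matches a plain "frequency domain filter" with no stated taper; a
  tapered filter would change band energies only marginally.
* **Z-score**: per region, sample SD (denominator T−1). Either SD
  convention only rescales each region's energies uniformly; one was
  fixed for bit-reproducibility.

Band energy is the ℓ2 norm over time (square root of the sum of
squares). The squared-energy variant is exposed as an option because
downstream linear models are not invariant to the square root.

## Univariate selection and group tests

Per-feature simple regression of NfL on each band energy:
F = (n−2)r²/(1−r²) on (1, n−2) df, computed via scikit-learn's
`f_regression` and verified in tests against an explicit two-model RSS
oracle. Constant features are flagged, not dropped; perfect fits report
F = +inf. The FDR family is all 132 features per cohort (the natural
family for the feature screen); Benjamini–Hochberg step-up via
statsmodels. No covariate enters the univariate screen — the protocol's
F-screen is unadjusted, with age handled downstream by partial
correlation and mediation. Rank-sum group comparisons are exact by
enumeration when the pooled sample is ≤ 12 and tie-free, and use the
tie-corrected normal approximation otherwise.

## PLS protocol

PLS is NIPALS with a univariate response (scikit-learn
`PLSRegression`), inputs and outcome z-scored internally with stored
means/SDs so fitted models can score new cohorts in original units. For
the one-component case used throughout, the fit has the closed form
w ∝ Xᵀy, and the test suite verifies the library fit against it exactly;
the same closed form drives a fully vectorized permutation null, so gate
nulls are bit-identical to refitting, at a small fraction of the cost.

* **Component count**: leave-one-out MSEP minimizer, ties toward fewer;
  the cohort-scale models force one component (small n), exposed as a
  flag.
* **VIP**: VIP_j = sqrt(p·Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a); the
  identity mean(VIP²) = 1 is asserted to 1e-8.
* **Overfit gate**: 5000 outcome permutations (1000 inside CV folds — the
  gate thresholds the null *mean*, which is stable well below 5000
  draws); overfit ⇔ null mean R² > 0.5. The observed-R² permutation count
  uses ≥ (one-sided by construction). Gates require explicit seeds, which
  are recorded in outputs.
* **Threshold sweep**: VIP > t for t in 0.8–2.0 by 0.1 (the grid is
  configurable; the protocol varies the threshold without fixing a grid,
  and this range brackets the conventional VIP > 1 rule). Empty subsets
  are skipped with a log note.
* **Leave-one-out CV**: the sweep reruns on training data only; among
  non-overfit candidates the fold model is the one with the smallest
  absolute error on the held-out subject. That rule consults the held-out
  label, so the resulting Q² is optimistically biased; the package always
  computes a no-leakage variant alongside (candidate chosen by training
  R²) and reports both. On null data the biased rule's Q² centers near
  zero while the no-leakage Q² is clearly negative — the directional gap
  is itself a tested property. Folds with no surviving candidate predict
  the training mean (logged).

Cohort transfer is plain out-of-sample R² using the stored
standardization (may be negative); VIP rank agreement is Kendall tau-b.

## Association analyses

* **Partial correlation**: Pearson on OLS residuals against [1, C]; t on
  n−k−2 df. Residuals that are numerically zero relative to their source
  (e.g. the outcome *is* a covariate) report ρ = 0 rather than the
  correlation of rounding noise.
* **Mediation**: a from M ~ X, b and c′ from Y ~ X + M, c from Y ~ X,
  ab = a·b, so c = c′ + a·b holds exactly. Variables enter in raw units
  (a standardization flag exists); no covariates are assumed by default.
  Significance: case-resampling bootstrap (default 10000 draws,
  vectorized batched normal equations), percentile two-sided p per path,
  with a bias-corrected option behind a flag.
* **Moderation**: OLS of Y on [1, covariates, X, W, X·W]. X and W are
  mean-centered by default for interpretable main effects; the
  interaction coefficient — the replication quantity — is
  translation-invariant, so centering cannot affect it. Simple slopes at
  W = mean ± SD with delta-method SEs. Ill-conditioned designs log a
  warning instead of failing.
* **FDR over declared families**: any set of named tests can be
  corrected jointly; the family membership is written into the output so
  the correction is auditable.

## Synthetic cohorts

Connectomes are stochastic-block graphs (4 modules, within-block Poisson
mean 20, between-block mean 2 — modular and integer-weighted like
streamline counts), resampled up to 10 times to guarantee connectedness.
BOLD is white spectral noise with per-band scales (low 3.0, high 1.5,
mid 1.0) inverse-transformed to region space; for round-trip fixtures the
generator instead plants *exact* per-region band energies by assigning
each planted (region, band) pair a time-orthogonal component along the
band-subspace projection of the region indicator and solving a small
linear system for amplitudes — so the generative truth coincides exactly
with what the feature extractor measures.

Ages are Normal(50, 11²) truncated at 20 years; serum NfL is a linear
function of age and selected standardized band energies plus Gaussian
noise (floored at 0.1 pg/mL). A single planted unit effect against unit
noise gives generative R² = 0.5. Mediation triplets default to paths
(a = −0.05, b = −2.2, c′ = 0.16) on age/energy/NfL scales with residual
SDs of 0.2 (mediator) and 0.3 (outcome) — chosen once so each path's
estimation SE at n = 2000 sits several-fold below a 10% recovery band.
Moderation data default to an interaction of 16.5 on an amygdala-volume
scale (residual SD 30 mm³, moderator SD 3 pg/mL), sized so the
interaction SE at n = 500 is ~3% of the coefficient. All generation is
bit-reproducible from a master seed via spawned `SeedSequence` streams.

The generator makes no attempt at hemodynamic realism, head motion,
spatially correlated noise, or empirical connectome topology; recovery
tests therefore certify the estimators under the assumed linear models,
not robustness to acquisition artifacts.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale: 20-subject cohorts with the
full 132-feature space for CV experiments, 50–200 random subjects for
the energy-partition identity, 5000-draw permutation nulls at the top
level and 500–1000 inside folds, 2000-draw bootstraps for mediation
reporting. Tolerances: exact linear-algebra identities at 1e-8–1e-12;
Monte-Carlo quantities at 3 standard errors; recovery bands of 5–10% as
stated per experiment.

## Known limitations

* The fold-model selection rule is reproduced verbatim including its
  information leak; use `q2_no_leak` for honest generalization estimates.
* The VIP threshold grid and permutation seeds of the original protocol
  are unknown, so cohort-level Q² values are stochastic targets, not
  bit-reproducible ones.
* Whether energies should be computed on z-scored or detrended-only
  series is settled here by the stated preprocessing order (z-score
  last, energies after); the alternative uniformly rescales per-region
  energies.
* Laplacian-based GFT variants, continuous decoupling indices, and
  mid-band analyses beyond the partition check are out of scope.
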