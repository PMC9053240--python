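"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates, per subject: a modular symmetric streamline-count
connectome (stochastic-block means with Poisson draws), BOLD series whose
graph-spectral content has controllable per-band scale (or exactly planted
per-region band energies for round-trip fixtures), ages ~ Normal(50, 11²)
truncated at 20 (matching the study cohorts' age distribution), serum NfL
as a linear function of age and selected standardized band-energy features
plus Gaussian noise, and standalone mediation triplets / moderation
datasets with chosen path and interaction coefficients.

What it does *not* emulate: hemodynamics, head motion, spatial
autocorrelation of real BOLD noise, or empirical connectome topology
beyond modularity — so passing recovery tests demonstrates correctness of
the estimators under the assumed linear models, not robustness to real
acquisition artifacts.

All draws derive from a master seed through ``numpy``'s ``SeedSequence``;
the same seed reproduces a cohort bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from neurogsp._labels import DESIKAN_KILLIANY_66
from neurogsp.band_features import build_feature_table, make_band_filter, to_wide
from neurogsp.bold import BoldSeries
from neurogsp.graph_spectrum import Connectome, SpectralBasis, eigendecompose, \
    validate_connectome


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings for one cohort.

    ``planted`` lists (region, band, beta) effects of standardized band
    energies on serum NfL; ``nfl_noise_sd`` is the residual SD in pg/mL,
    so a single planted beta of 1.0 against noise 1.0 gives generative
    R² = 0.5 for the feature model.
    """

    n_subjects: int = 20
    cohort: str = "HC"
    n_regions: int = 66
    n_timepoints: int = 154
    tr_seconds: float = 2.0
    n_modules: int = 4
    within_mean: float = 20.0
    between_mean: float = 2.0
    band_k: int = 10
    low_scale: float = 3.0
    high_scale: float = 1.5
    mid_scale: float = 1.0
    bold_noise_sd: float = 0.0
    planted: tuple = ()
    age_mean: float = 50.0
    age_sd: float = 11.0
    age_min: float = 20.0
    nfl_intercept: float = 2.0
    nfl_age_beta: float = 0.27
    nfl_noise_sd: float = 1.0
    nfl_floor: float = 0.1

    def __post_init__(self):
        if self.age_sd <= 0 or self.nfl_noise_sd < 0:
            raise ValueError("spread parameters must be positive")
        labels = self.region_labels
        for region, band, _ in self.planted:
            if region not in labels:
                raise ValueError(f"planted region {region!r} not in atlas")
            if band not in ("low", "high"):
                raise ValueError(f"planted band {band!r} invalid")

    @property
    def region_labels(self) -> tuple:
        if self.n_regions == 66:
            return DESIKAN_KILLIANY_66
        return tuple(f"r{i:02d}" for i in range(self.n_regions))


def _spawn(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_connectome(config: SyntheticConfig, seed: int) -> Connectome:
    """Modular symmetric Poisson-weighted connectome, connected, zero diag."""
    rng = np.random.default_rng(seed)
    n = config.n_regions
    modules = np.arange(n) % config.n_modules
    means = np.where(modules[:, None] == modules[None, :],
                     config.within_mean, config.between_mean)
    for attempt in range(10):
        upper = rng.poisson(means).astype(float)
        A = np.triu(upper, k=1)
        A = A + A.T
        n_comp, _ = connected_components(A > 0, directed=False)
        if n_comp == 1:
            return validate_connectome(A, config.region_labels,
                                       subject_id=f"sim{seed}")
    raise RuntimeError("could not generate a connected connectome in 10 tries")


def _solve_planted(basis: SpectralBasis, band_idx, targets):
    """Spectral-space components hitting exact per-region band energies.

    Each planted (region, target) pair of a band gets its own time-
    orthogonal component proportional to the band-subspace projection of
    the region's indicator vector; component amplitudes solve a small
    linear system so the quadrature sum of energies per planted region
    equals its target.
    """
    V_b = basis.eigenvectors[:, band_idx]
    regions = [i for i, _ in targets]
    G = np.stack([V_b @ (V_b.T[:, i]) for i in regions], axis=1)  # n × m
    M = G[regions, :] ** 2                                        # m × m
    t2 = np.array([t for _, t in targets], dtype=float) ** 2
    alpha2 = np.linalg.solve(M, t2)
    if np.any(alpha2 < -1e-12):
        raise ValueError("infeasible planted band-energy targets")
    return G * np.sqrt(np.clip(alpha2, 0, None))[None, :]          # n × m


def gen_bold(basis: SpectralBasis, config: SyntheticConfig, seed: int,
             target_energies=None) -> BoldSeries:
    """BOLD series with band-specific spectral scales or exact planted energies.

    Without targets: spectral coefficients are white over time with SD
    ``high_scale`` on the k smallest-eigenvalue modes, ``low_scale`` on the
    k largest, ``mid_scale`` in between, inverse-transformed to region
    space plus optional white noise; returned at stage ``raw`` for the
    preprocessing pipeline.

    With ``target_energies`` (mapping (region, band) → energy): builds a
    signal whose measured band energies equal the targets exactly at
    ``bold_noise_sd=0``; returned at stage ``zscored`` (the fixture
    bypasses temporal preprocessing, which would rescale the targets).
    """
    rng = np.random.default_rng(seed)
    n, T, k = basis.n, config.n_timepoints, config.band_k
    labels = config.region_labels
    if target_energies is None:
        scales = np.full(n, config.mid_scale)
        scales[:k] = config.high_scale
        scales[n - k:] = config.low_scale
        xhat = rng.standard_normal((n, T)) * scales[:, None]
        x = basis.eigenvectors @ xhat
        if config.bold_noise_sd > 0:
            x = x + rng.standard_normal((n, T)) * config.bold_noise_sd
        return BoldSeries(values=x, tr_seconds=config.tr_seconds,
                          region_labels=labels, subject_id=basis.subject_id,
                          stage="raw")

    by_band = {"low": [], "high": []}
    for (region, band), value in target_energies.items():
        if value < 0:
            raise ValueError("band-energy targets must be nonnegative")
        if value == 0 and config.bold_noise_sd > 0:
            import warnings
            warnings.warn("zero target with nonzero noise is unattainable")
        by_band[band].append((labels.index(region), float(value)))
    x = np.zeros((n, T))
    t_slot = 0
    for band, targets in by_band.items():
        if not targets:
            continue
        idx = np.arange(k) if band == "high" else np.arange(n - k, n)
        comps = _solve_planted(basis, idx, targets)   # n × m
        for m_i in range(comps.shape[1]):
            x[:, t_slot] += comps[:, m_i]
            t_slot += 1
    if config.bold_noise_sd > 0:
        x = x + rng.standard_normal((n, T)) * config.bold_noise_sd
    return BoldSeries(values=x, tr_seconds=config.tr_seconds,
                      region_labels=labels, subject_id=basis.subject_id,
                      stage="zscored")


def gen_subjects(config: SyntheticConfig, seed: int):
    """Per-subject (Connectome, BoldSeries, covariates) triples."""
    rngs = _spawn(seed, config.n_subjects)
    out = []
    for i, rng in enumerate(rngs):
        s1, s2 = rng.integers(2 ** 31, size=2)
        conn = gen_connectome(config, int(s1))
        conn = Connectome(region_labels=conn.region_labels,
                          weights=conn.weights,
                          subject_id=f"{config.cohort}-{i:02d}")
        basis = eigendecompose(conn)
        series = gen_bold(basis, config, int(s2))
        series = replace(series, subject_id=conn.subject_id)
        out.append((conn, series, {"cohort": config.cohort}))
    return out


def gen_outcomes(features_wide: pd.DataFrame, config: SyntheticConfig,
                 seed: int) -> pd.DataFrame:
    """Ages and serum NfL for a cohort given its wide feature table.

    NfL = intercept + β_age·age + Σ_j β_j·z(feature_j) + Normal(0, σ),
    floored at ``nfl_floor`` pg/mL; ages are truncated normal.
    """
    rng = np.random.default_rng(seed)
    n = len(features_wide)
    ages = np.empty(n)
    for i in range(n):
        a = rng.normal(config.age_mean, config.age_sd)
        while a < config.age_min:
            a = rng.normal(config.age_mean, config.age_sd)
        ages[i] = a
    nfl = config.nfl_intercept + config.nfl_age_beta * ages \
        + rng.normal(0, config.nfl_noise_sd, size=n)
    from neurogsp.band_features import feature_name
    for region, band, beta in config.planted:
        col = features_wide[feature_name(band, region)].to_numpy()
        z = (col - col.mean()) / col.std(ddof=1)
        nfl = nfl + beta * z
    nfl = np.maximum(nfl, config.nfl_floor)
    return pd.DataFrame({
        "subject_id": features_wide.index,
        "cohort": config.cohort,
        "age": ages,
        "serum_nfl": nfl,
    }).set_index("subject_id")


def gen_cohort(config: SyntheticConfig, seed: int) -> dict:
    """Full cohort: subjects, tidy/wide band-energy tables, outcome records."""
    ss = np.random.SeedSequence(seed).spawn(2)
    subj_seed = int(ss[0].generate_state(1)[0] % (2 ** 31))
    out_seed = int(ss[1].generate_state(1)[0] % (2 ** 31))
    subjects = gen_subjects(config, subj_seed)
    tidy = build_feature_table(subjects, k=config.band_k)
    wide = to_wide(tidy)
    records = gen_outcomes(wide, config, out_seed)
    return {"subjects": subjects, "features_tidy": tidy,
            "features_wide": wide, "records": records, "config": config}


def gen_two_cohorts(config_a: SyntheticConfig, config_b: SyntheticConfig,
                    seed: int) -> dict:
    """Two independent cohorts (e.g. disjoint planted features) from one seed."""
    ss = np.random.SeedSequence(seed).spawn(2)
    return {
        "A": gen_cohort(config_a, int(ss[0].generate_state(1)[0] % (2 ** 31))),
        "B": gen_cohort(config_b, int(ss[1].generate_state(1)[0] % (2 ** 31))),
    }


def gen_mediation_data(n: int = 2000, a: float = -0.05, b: float = -2.2,
                       c_prime: float = 0.16, seed: int = None,
                       noise_m: float = 0.2, noise_y: float = 0.3,
                       x_mean: float = 50.0, x_sd: float = 11.0,
                       m_intercept: float = 13.0,
                       y_intercept: float = 30.0) -> pd.DataFrame:
    """Mediation triplet X → M → Y with chosen path coefficients.

    Defaults mirror an age (years) → band energy → serum NfL (pg/mL)
    chain; noise SDs are small relative to the path scales so the paths
    are recoverable at moderate n.
    """
    if seed is None:
        raise ValueError("gen_mediation_data requires an explicit seed")
    rng = np.random.default_rng(seed)
    x = rng.normal(x_mean, x_sd, size=n)
    m = m_intercept + a * x + rng.normal(0, noise_m, size=n)
    y = y_intercept + c_prime * x + b * m + rng.normal(0, noise_y, size=n)
    return pd.DataFrame({"x": x, "m": m, "y": y})


def gen_moderation_data(n: int = 500, interaction: float = 16.5,
                        beta_x: float = 30.25, beta_w: float = 8.09,
                        intercept: float = 1680.0, noise_sd: float = 30.0,
                        seed: int = None, x_mean: float = 10.0,
                        x_sd: float = 1.0, w_mean: float = 10.0,
                        w_sd: float = 3.0) -> pd.DataFrame:
    """Moderation dataset Y = β₀ + βx·X̃ + βw·W̃ + βint·X̃·W̃ + noise.

    X̃, W̃ are the centered focal predictor (band energy) and moderator
    (serum NfL); the default coefficient scales follow an amygdala-volume
    (mm³) outcome.
    """
    if seed is None:
        raise ValueError("gen_moderation_data requires an explicit seed")
    rng = np.random.default_rng(seed)
    x = rng.normal(x_mean, x_sd, size=n)
    w = rng.normal(w_mean, w_sd, size=n)
    xc, wc = x - x_mean, w - w_mean
    y = intercept + beta_x * xc + beta_w * wc + interaction * xc * wc \
        + rng.normal(0, noise_sd, size=n)
    return pd.DataFrame({"y": y, "x": x, "w": w})
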