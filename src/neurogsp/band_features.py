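"""Graph-frequency band filters and band-energy features.

A band filter is a diagonal spectral mask F = diag(f(λ0), …, f(λn−1)) with
binary response; applying it to a regional signal x gives y = V F Vᵀ x.
With eigenvalues sorted ascending, the *high* graph-frequency band keeps
the K smallest eigenvalues (sorted indices 0..K−1: rapidly varying modes,
function decoupled from anatomy) and the *low* band keeps the K largest
(indices n−K..n−1: smooth modes, function conforming to anatomy). This
inversion relative to classical Fourier intuition is intrinsic to the
adjacency-based transform. K = 10 throughout the source protocol.

The per-region band energy is the ℓ2 norm over time of the filtered
series, E_i = sqrt(Σ_t y_i(t)²); with both bands over n = 66 regions this
yields the 132-feature predictor table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from neurogsp.bold import BoldSeries, preprocess
from neurogsp.graph_spectrum import Connectome, SpectralBasis, eigendecompose

log = logging.getLogger(__name__)

BANDS = ("low", "high")


class LabelMismatchError(ValueError):
    """A subject's BOLD region ordering disagrees with its connectome."""


@dataclass(frozen=True)
class GraphFilter:
    """Binary spectral mask over the eigenmodes of one subject's basis."""

    response: np.ndarray = field(repr=False)
    band: str
    k: int

    def __post_init__(self):
        r = np.asarray(self.response, dtype=float)
        if not np.all((r == 0) | (r == 1)):
            raise ValueError("filter response must be binary")
        object.__setattr__(self, "response", r)


@dataclass(frozen=True)
class FilteredSeries:
    """Band-filtered regional series y = V F Vᵀ x."""

    values: np.ndarray = field(repr=False)
    band: str
    region_labels: tuple
    subject_id: str = "subject"


def feature_name(band: str, region: str) -> str:
    """Canonical wide-table column name, e.g. ``low__rh_isthmuscingulate``."""
    return f"{band}__{region}"


def make_band_filter(basis: SpectralBasis, band: str, k: int = 10) -> GraphFilter:
    """Build the low/high band mask on sorted eigenvalue indices.

    ``high`` passes sorted indices 0..k−1 (smallest eigenvalues), ``low``
    passes n−k..n−1 (largest). Logs a warning when a degenerate eigenvalue
    straddles the band boundary, because the passed subspace then depends
    on solver ordering.
    """
    n = basis.n
    if not 1 <= k <= n:
        raise ValueError(f"band size k={k} out of range [1, {n}]")
    if band not in BANDS:
        raise ValueError(f"band must be one of {BANDS}, got {band!r}")
    response = np.zeros(n)
    lam = basis.eigenvalues
    if band == "high":
        response[:k] = 1.0
        boundary = (k < n) and np.isclose(lam[k - 1], lam[k], rtol=1e-12, atol=1e-12)
    else:
        response[n - k:] = 1.0
        boundary = (k < n) and np.isclose(lam[n - k - 1], lam[n - k],
                                          rtol=1e-12, atol=1e-12)
    if boundary:
        log.warning(
            "degenerate eigenvalue at the %s-band boundary (k=%d) for "
            "subject %s; band subspace depends on solver ordering",
            band, k, basis.subject_id,
        )
    return GraphFilter(response=response, band=band, k=k)


def apply_filter(s: BoldSeries, basis: SpectralBasis, f: GraphFilter) -> FilteredSeries:
    """Apply y = V F Vᵀ x to every timepoint column of a z-scored series."""
    if s.stage != "zscored":
        raise ValueError(
            f"band filtering expects a 'zscored'-stage series, got {s.stage!r}"
        )
    if s.n_regions != basis.n:
        raise ValueError(
            f"series has {s.n_regions} regions but basis has {basis.n} modes"
        )
    V = basis.eigenvectors
    y = V @ (f.response[:, None] * (V.T @ s.values))
    return FilteredSeries(values=y, band=f.band,
                          region_labels=s.region_labels, subject_id=s.subject_id)


def band_energy(fs: FilteredSeries, squared: bool = False) -> pd.Series:
    """Per-region ℓ2 energy over time, E_i = sqrt(Σ_t y_i(t)²).

    ``squared=True`` returns Σ_t y_i(t)² instead; downstream linear models
    are not invariant to this monotone transform, so the choice is explicit.
    """
    e2 = np.einsum("it,it->i", fs.values, fs.values)
    e = e2 if squared else np.sqrt(e2)
    return pd.Series(e, index=list(fs.region_labels), name=fs.band)


def subject_band_energies(
    connectome: Connectome,
    series: BoldSeries,
    k: int = 10,
    squared: bool = False,
    run_preprocess: bool = True,
) -> pd.DataFrame:
    """Band energies (both bands, all regions) for one subject.

    A ``raw`` series is passed through the full preprocessing pipeline
    first; a ``zscored`` series is used as-is. Region orderings of the
    connectome and series must agree.
    """
    if tuple(connectome.region_labels) != tuple(series.region_labels):
        raise LabelMismatchError(
            f"region labels of connectome and BOLD series disagree for "
            f"subject {connectome.subject_id!r}"
        )
    if series.stage == "raw" and run_preprocess:
        series = preprocess(series)
    basis = eigendecompose(connectome)
    rows = []
    for band in BANDS:
        filt = make_band_filter(basis, band, k)
        e = band_energy(apply_filter(series, basis, filt), squared=squared)
        for region, value in e.items():
            rows.append((connectome.subject_id, region, band, value))
    return pd.DataFrame(rows, columns=["subject_id", "region", "band", "energy"])


def build_feature_table(subjects, k: int = 10, squared: bool = False) -> pd.DataFrame:
    """Tidy band-energy table over a cohort.

    Parameters
    ----------
    subjects : iterable of (Connectome, BoldSeries, covariates)
        ``covariates`` is a mapping; its ``cohort`` entry (default ``""``)
        is carried into the table.
    k : int
        Band size (10 in the source protocol; 2 bands × n regions rows per
        subject, 132 features at n = 66).

    Returns a DataFrame with columns ``subject_id, cohort, region, band,
    energy`` sorted by (subject, region, band).
    """
    frames = []
    for connectome, series, covariates in subjects:
        covariates = dict(covariates or {})
        tbl = subject_band_energies(connectome, series, k=k, squared=squared)
        tbl.insert(1, "cohort", covariates.get("cohort", ""))
        frames.append(tbl)
    if not frames:
        raise ValueError("no subjects supplied")
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["subject_id", "region", "band"],
                           kind="stable").reset_index(drop=True)


def to_wide(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy band-energy table to subject × ``band__region`` columns."""
    wide = tidy.pivot_table(index="subject_id", columns=["band", "region"],
                            values="energy", sort=False)
    wide.columns = [feature_name(band, region) for band, region in wide.columns]
    return wide.sort_index(axis=1).sort_index(axis=0)
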