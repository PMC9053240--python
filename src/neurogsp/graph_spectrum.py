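"""Structural connectomes and the adjacency-based graph Fourier transform.

The white-matter anatomy of a subject is modelled as an undirected weighted
graph G on n cortical regions; edge weights are streamline counts, so the
adjacency matrix A is symmetric and nonnegative with a zero diagonal. Since
A is symmetric it eigendecomposes as A = V Λ Vᵀ with orthonormal V and real
eigenvalues λ0 ≤ λ1 ≤ … ≤ λn−1. The columns of V (eigenmodes) define the
graph Fourier transform (GFT) pair

    x̂ = Vᵀ x,    x = V x̂.

For an adjacency-based GFT, eigenmodes with *large* eigenvalues vary
smoothly over the graph (low graph frequency, function aligned with
anatomy) while eigenmodes with *small/negative* eigenvalues vary rapidly
(high graph frequency, function decoupled from anatomy). Band filters built
on this ordering live in :mod:`neurogsp.band_features`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: Relative tolerance for accepting a connectome matrix as symmetric.
SYMMETRY_RTOL = 1e-8


class ConnectomeError(ValueError):
    """Base class for connectome validation failures."""


class AsymmetryError(ConnectomeError):
    """Matrix asymmetry beyond the relative tolerance."""


class NegativeWeightError(ConnectomeError):
    """A streamline-count weight is negative."""


class NonFiniteError(ConnectomeError):
    """A matrix entry is NaN or infinite."""


class DimensionError(ConnectomeError):
    """Matrix is not square or labels do not match its dimension."""


@dataclass(frozen=True)
class Connectome:
    """A validated structural connectome.

    Attributes
    ----------
    region_labels : tuple of str
        Ordered region names (Desikan-Killiany cortical names at n=66).
    weights : ndarray, shape (n, n)
        Symmetric nonnegative streamline-count weights, zero diagonal.
    subject_id : str
    """

    region_labels: tuple
    weights: np.ndarray = field(repr=False)
    subject_id: str = "subject"

    @property
    def n(self) -> int:
        return len(self.region_labels)


@dataclass(frozen=True)
class SpectralBasis:
    """Eigendecomposition A = V Λ Vᵀ of a connectome adjacency matrix.

    ``eigenvalues`` are sorted ascending; column k of ``eigenvectors`` pairs
    with ``eigenvalues[k]``. The sign of each eigenvector is fixed so that
    its largest-magnitude entry is positive (ties broken by lowest index),
    making serialized bases reproducible across runs; band energies do not
    depend on this convention.
    """

    eigenvalues: np.ndarray = field(repr=False)
    eigenvectors: np.ndarray = field(repr=False)
    subject_id: str = "subject"

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]


def validate_connectome(raw_matrix, labels, subject_id: str = "subject") -> Connectome:
    """Validate a raw weight matrix and return a :class:`Connectome`.

    Small numerical asymmetry (within ``SYMMETRY_RTOL`` relative to the
    largest weight) is repaired by averaging (A + Aᵀ)/2; anything larger is
    an :class:`AsymmetryError`. The diagonal is zeroed.

    Raises
    ------
    DimensionError, NonFiniteError, NegativeWeightError, AsymmetryError
    """
    A = np.array(raw_matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DimensionError(f"expected a square matrix, got shape {A.shape}")
    labels = tuple(str(lb) for lb in labels)
    if len(labels) != A.shape[0]:
        raise DimensionError(
            f"{len(labels)} labels for a {A.shape[0]}x{A.shape[0]} matrix"
        )
    if len(set(labels)) != len(labels):
        raise DimensionError("duplicate region labels")
    if not np.all(np.isfinite(A)):
        bad = np.argwhere(~np.isfinite(A))[0]
        raise NonFiniteError(f"non-finite weight at ({bad[0]}, {bad[1]})")
    scale = max(np.abs(A).max(), 1.0)
    asym = np.abs(A - A.T).max()
    if asym > SYMMETRY_RTOL * scale:
        raise AsymmetryError(
            f"asymmetry {asym:.3g} exceeds {SYMMETRY_RTOL:g} relative tolerance"
        )
    if A.min() < 0:
        bad = np.argwhere(A < 0)[0]
        raise NegativeWeightError(f"negative weight at ({bad[0]}, {bad[1]})")
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    A.setflags(write=False)
    return Connectome(region_labels=labels, weights=A, subject_id=subject_id)


def eigendecompose(c: Connectome) -> SpectralBasis:
    """Compute the spectral basis (ascending eigenvalues, orthonormal V).

    Degenerate eigenvalues are allowed; downstream band filters project onto
    index-defined subspaces, which is well-defined up to rotations within a
    degenerate block (band *energies* are invariant to those rotations
    unless a degeneracy straddles a band boundary, which
    :func:`neurogsp.band_features.make_band_filter` warns about).
    """
    lam, V = np.linalg.eigh(c.weights)
    if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(V))):
        raise ArithmeticError(f"eigendecomposition produced non-finite values "
                              f"for subject {c.subject_id!r}")
    # deterministic sign: largest-|entry| of each column made positive
    anchor = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[anchor, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    V = V * signs
    lam.setflags(write=False)
    V.setflags(write=False)
    return SpectralBasis(eigenvalues=lam, eigenvectors=V, subject_id=c.subject_id)


def gft(x, basis: SpectralBasis, direction: str = "forward") -> np.ndarray:
    """Graph Fourier transform of a signal or an n×T series.

    ``forward`` returns x̂ = Vᵀx (column-wise over timepoints); ``inverse``
    returns x = V x̂. Because V is orthonormal the round trip is exact and
    Parseval holds per timepoint: ‖x̂‖₂ = ‖x‖₂.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != basis.n:
        raise DimensionError(
            f"signal has {x.shape[0]} rows but basis has {basis.n} modes"
        )
    if direction == "forward":
        return basis.eigenvectors.T @ x
    if direction == "inverse":
        return basis.eigenvectors @ x
    raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
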