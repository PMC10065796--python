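"""Multilayer (time-layered) network model and multilayer eigenvector centrality.

The ``N x N x T`` connectivity stack of a seizure is embedded in an
``NT x NT`` symmetric super-adjacency matrix ``A``: diagonal blocks are the
per-window networks, and off-diagonal blocks couple each node to itself at the
two neighbouring time points with a scalar weight ``c`` (ordinal interlayer
coupling).  Multilayer eigenvector centrality (mlEVC) sums the absolute
eigenvalue-weighted top-``T`` eigenvectors of ``A``,

.. math:: v = \\sum_{i=1}^{T} |\\sigma_i \\varphi_i|,

reshaped to ``N x T``: each column tracks a node's centrality through the
seizure.  With ``c = 0`` this reduces to the concatenated single-layer
eigenvector centralities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

from .connectivity import ConnectivitySeries
from .recording import Recording

__all__ = [
    "SuperAdjacency",
    "CentralitySpectrum",
    "MlEVC",
    "build_superadjacency",
    "top_eigenpairs",
    "mlevc",
    "mlevc_from_series",
    "eigenvalue_spectrum",
    "phase_randomized_surrogate",
]

DENSE_LIMIT = 2000  # use a dense solver whenever NT is at most this


@dataclass
class SuperAdjacency:
    """Lazy ``NT x NT`` super-adjacency: layer stack plus coupling weight."""

    blocks: np.ndarray  # (N, N, T)
    c: float

    def __post_init__(self) -> None:
        self.blocks = np.asarray(self.blocks, dtype=float)
        if self.blocks.ndim != 3 or self.blocks.shape[0] != self.blocks.shape[1]:
            raise ValueError("blocks must be (N, N, T)")
        if self.c < 0:
            raise ValueError("coupling must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.blocks.shape[0]

    @property
    def n_layers(self) -> int:
        return self.blocks.shape[2]

    @property
    def size(self) -> int:
        return self.n_nodes * self.n_layers

    def to_sparse(self) -> sp.csr_matrix:
        """Materialize as sparse CSR; super index of node i in layer t is t*N+i."""
        n, T = self.n_nodes, self.n_layers
        diag = sp.block_diag(
            [self.blocks[:, :, t] for t in range(T)], format="csr"
        )
        if T > 1 and self.c > 0:
            coupling = sp.diags(
                [np.full(n * (T - 1), self.c)] * 2, offsets=[n, -n], format="csr"
            )
            return (diag + coupling).tocsr()
        return diag

    def to_dense(self) -> np.ndarray:
        return self.to_sparse().toarray()


@dataclass
class CentralitySpectrum:
    """Top eigenpairs of a super-adjacency, eigenvalues descending."""

    eigvals: np.ndarray  # (k,)
    eigvecs: np.ndarray  # (NT, k), unit columns, sign-canonicalized
    n_nodes: int
    n_layers: int


@dataclass
class MlEVC:
    """``N x T`` multilayer eigenvector centrality."""

    values: np.ndarray
    c: float
    band: tuple[float, float] | None = None
    seizure_id: str = ""
    labels: list[str] = field(default_factory=list)


def build_superadjacency(series: ConnectivitySeries | np.ndarray, c: float) -> SuperAdjacency:
    blocks = series.values if isinstance(series, ConnectivitySeries) else np.asarray(series)
    return SuperAdjacency(blocks, float(c))


def _canonicalize_signs(vecs: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(vecs), axis=0)
    flip = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    flip[flip == 0] = 1.0
    return vecs * flip


def top_eigenpairs(A: SuperAdjacency, k: int | None = None, seed: int = 0) -> CentralitySpectrum:
    """``k`` largest-algebraic eigenpairs of the symmetric super-adjacency.

    Defaults to ``k = T``.  A dense solver is used for ``NT`` up to 2000;
    larger problems use a Lanczos solver with a seeded start vector.
    """
    if k is None:
        k = A.n_layers
    nt = A.size
    if not 1 <= k <= nt:
        raise ValueError(f"k={k} outside [1, {nt}]")
    if nt <= DENSE_LIMIT or k >= nt - 1:
        vals, vecs = np.linalg.eigh(A.to_dense())
        order = np.argsort(vals)[::-1][:k]
        vals, vecs = vals[order], vecs[:, order]
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(nt)
        vals, vecs = eigsh(A.to_sparse(), k=k, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    return CentralitySpectrum(vals, _canonicalize_signs(vecs), A.n_nodes, A.n_layers)


def mlevc(spec: CentralitySpectrum, **meta) -> MlEVC:
    """Sum the absolute eigenvalue-weighted eigenvectors and reshape to N x T.

    Taking the entrywise absolute value of each product also covers negative
    eigenvalues among the top ``T``.
    """
    v = np.abs(spec.eigvecs * spec.eigvals[None, :]).sum(axis=1)
    mat = v.reshape(spec.n_layers, spec.n_nodes).T  # super index t*N + i
    return MlEVC(mat, meta.pop("c", np.nan), **meta)


def mlevc_from_series(
    series: ConnectivitySeries, c: float, seed: int = 0, **meta
) -> MlEVC:
    """Convenience: stack -> super-adjacency -> top-T eigenpairs -> mlEVC."""
    A = build_superadjacency(series, c)
    spec = top_eigenpairs(A, seed=seed)
    return mlevc(spec, c=c, **meta)


def eigenvalue_spectrum(A: SuperAdjacency, n_e: int | None = None) -> np.ndarray:
    """Sorted (descending) leading eigenvalues, for rank-falloff diagnostics."""
    if n_e is None:
        n_e = A.size
    spec = top_eigenpairs(A, k=min(n_e, A.size))
    return spec.eigvals


def phase_randomized_surrogate(rec: Recording, seed: int) -> Recording:
    """Phase-randomized surrogate: each channel keeps its amplitude spectrum
    exactly while phases are drawn uniformly (independently per channel),
    destroying cross-channel phase structure."""
    rng = np.random.default_rng(seed)
    n = rec.n_samples
    spec = np.fft.rfft(rec.data, axis=-1)
    n_bins = spec.shape[-1]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(rec.n_channels, n_bins))
    phases[:, 0] = np.angle(spec[:, 0])  # keep DC
    if n % 2 == 0:
        phases[:, -1] = np.angle(spec[:, -1])  # keep Nyquist bin real
    surr = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n, axis=-1)
    return rec.copy_with(data=surr)
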