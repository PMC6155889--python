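"""Gaussian and anisotropic network models over coarse-grained nodes.

Both models place identical springs (force constant gamma) between every
node pair within a distance cutoff. The GNM works with the N x N Kirchhoff
(graph-Laplacian) matrix of the contact network and predicts isotropic
square fluctuations from its pseudo-inverse,

    <dR_i^2> = (3kT/gamma) [Gamma^+]_ii ,

while the ANM differentiates the pairwise potential

    V = (gamma/2) sum_{ij} (|R_ij| - |R_ij^0|)^2

at the native state into a 3N x 3N Hessian whose low-frequency eigenvectors
are directional collective modes. Cross-correlations are the normalised
covariances built from a chosen number of low modes.

Cutoff defaults follow the coarse-graining level: GNM 20/15/10 A and ANM
30/20/15 A for the one-/two-/three-node representations. Fluctuation units
are 3kT/gamma (relative); only profile shapes and correlations are compared
downstream, so absolute temperature never enters.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import (DisconnectedNetworkWarning, DuplicateNodeError,
                     InvalidArgumentError, InvalidModeError)
from .io import NodeModel

#: default distance cutoffs (A) keyed by (model, representation level)
DEFAULT_CUTOFFS = {
    ("GNM", 1): 20.0, ("GNM", 2): 15.0, ("GNM", 3): 10.0,
    ("ANM", 1): 30.0, ("ANM", 2): 20.0, ("ANM", 3): 15.0,
}

#: rigid-body null-space dimension of a connected network
_EXPECTED_ZERO = {"GNM": 1, "ANM": 6}


@dataclass(frozen=True)
class ENMConfig:
    model: str = "GNM"            # "GNM" | "ANM"
    cutoff: Optional[float] = None  # A; None -> level default
    gamma: float = 1.0            # spring constant (arbitrary units)
    kT_scale: float = 1.0         # value of 3kT/gamma scaling fluctuations
    zero_tol: float = 1e-8        # relative eigenvalue threshold

    def __post_init__(self) -> None:
        if self.model not in ("GNM", "ANM"):
            raise InvalidArgumentError("model must be 'GNM' or 'ANM'")
        if self.cutoff is not None and self.cutoff <= 0:
            raise InvalidArgumentError("cutoff must be positive")
        if self.gamma <= 0:
            raise InvalidArgumentError("gamma must be positive")

    def cutoff_for(self, level: int) -> float:
        if self.cutoff is not None:
            return self.cutoff
        try:
            return DEFAULT_CUTOFFS[(self.model, level)]
        except KeyError:
            raise InvalidArgumentError(
                f"no default cutoff for {self.model} at level {level}")


@dataclass
class ModeSet:
    """Eigen-decomposition of a GNM/ANM matrix or a PCA covariance.

    ``eigenvalues`` holds only the non-zero (non-rigid) spectrum, ascending
    for GNM/ANM and descending (variances) for PCA; ``eigenvectors`` are
    the matching unit-norm columns (length N for GNM, 3N otherwise).
    "Mode 1" always means the first non-zero mode.
    """

    kind: str                      # "GNM" | "ANM" | "PCA"
    eigenvalues: np.ndarray        # (m,)
    eigenvectors: np.ndarray       # (dim, m) columns
    n_zero_excluded: int
    node_meta: list = field(default_factory=list)
    kT_scale: float = 1.0
    #: discarded null-space eigenpairs, kept for completeness checks
    zero_eigenvectors: Optional[np.ndarray] = None

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n_nodes(self) -> int:
        dim = self.eigenvectors.shape[0]
        return dim if self.kind == "GNM" else dim // 3

    def mode(self, index: int) -> np.ndarray:
        """Unit eigenvector of non-zero mode ``index`` (1-based)."""
        self._check_indices([index])
        return self.eigenvectors[:, index - 1]

    def variances(self) -> np.ndarray:
        """Per-mode variance: eigenvalue for PCA, 1/eigenvalue otherwise."""
        if self.kind == "PCA":
            return self.eigenvalues.copy()
        return 1.0 / self.eigenvalues

    def _check_indices(self, indices: Sequence[int]) -> None:
        for k in indices:
            if not 1 <= int(k) <= self.n_modes:
                raise InvalidModeError(
                    f"mode index {k} outside the non-zero spectrum "
                    f"1..{self.n_modes} (zero/rigid modes are excluded)")


@dataclass
class FluctuationProfile:
    """Per-node square fluctuations in units of 3kT/gamma."""

    values: np.ndarray
    modes_used: Union[str, list]
    node_meta: list = field(default_factory=list)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class CorrelationMap:
    """Normalised cross-correlation of node displacements, in [-1, 1]."""

    values: np.ndarray             # (N, N), symmetric, unit diagonal
    modes_used: list = field(default_factory=list)
    node_meta: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# matrix assembly


def _contact_pairs(positions: np.ndarray, cutoff: float) -> np.ndarray:
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(positions) > 1:
        d, _ = tree.query(positions, k=2)
        if d[:, 1].min() <= 0.0:
            raise DuplicateNodeError("two nodes coincide (zero distance)")
    return pairs


def kirchhoff(nodes: NodeModel, config: ENMConfig | None = None) -> np.ndarray:
    """Assemble the GNM Kirchhoff (connectivity) matrix.

    Off-diagonal: -1 for node pairs within the cutoff, 0 otherwise;
    diagonal: minus the off-diagonal row sum (node degree), so every row
    sums exactly to zero.
    """
    config = config or ENMConfig(model="GNM")
    pos = np.asarray(nodes.positions, dtype=float)
    if len(pos) < 2:
        raise InvalidArgumentError("need at least 2 nodes")
    rc = config.cutoff_for(nodes.level)
    pairs = _contact_pairs(pos, rc)
    n = len(pos)
    gamma_m = np.zeros((n, n))
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        gamma_m[i, j] = -1.0
        gamma_m[j, i] = -1.0
    np.fill_diagonal(gamma_m, -gamma_m.sum(axis=1))
    return gamma_m * config.gamma


def hessian(nodes: NodeModel, config: ENMConfig | None = None) -> np.ndarray:
    """Assemble the 3N x 3N ANM Hessian of the pairwise distance potential.

    Each contact pair (i, j) contributes the 3x3 super-element
    -(gamma/|R0|^2) R0 (x) R0 off the diagonal; diagonal super-elements
    are minus the sum of the row's off-diagonal blocks, which makes every
    row sum exactly zero (rigid translations are force-free).
    """
    config = config or ENMConfig(model="ANM")
    pos = np.asarray(nodes.positions, dtype=float)
    if len(pos) < 2:
        raise InvalidArgumentError("need at least 2 nodes")
    rc = config.cutoff_for(nodes.level)
    pairs = _contact_pairs(pos, rc)
    n = len(pos)
    h = np.zeros((3 * n, 3 * n))
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        rij = pos[j] - pos[i]                      # (m, 3)
        d2 = np.einsum("ij,ij->i", rij, rij)
        blocks = -config.gamma * rij[:, :, None] * rij[:, None, :] / \
            d2[:, None, None]                      # (m, 3, 3)
        for (a, b, blk) in zip(i, j, blocks):
            sa, sb = slice(3 * a, 3 * a + 3), slice(3 * b, 3 * b + 3)
            h[sa, sb] += blk
            h[sb, sa] += blk
            h[sa, sa] -= blk
            h[sb, sb] -= blk
    return h


def _component_count(matrix: np.ndarray, kind: str) -> int:
    if kind == "GNM":
        adj = matrix != 0
    else:
        n = matrix.shape[0] // 3
        adj = np.abs(matrix).reshape(n, 3, n, 3).sum(axis=(1, 3)) != 0
    np.fill_diagonal(adj, False)
    return connected_components(adj, directed=False)[0]


def diagonalize(matrix: np.ndarray, kind: str,
                config: ENMConfig | None = None,
                node_meta: Optional[list] = None) -> ModeSet:
    """Full symmetric eigendecomposition with zero-mode bookkeeping.

    Eigenvalues below ``zero_tol`` x lambda_max are flagged as null-space
    (rigid) modes and excluded; the remaining modes are indexed from 1 in
    ascending eigenvalue order. A :class:`DisconnectedNetworkWarning`
    carrying the connected-component count is issued when the zero-mode
    count differs from the connected-network expectation (1 for GNM,
    6 for ANM).
    """
    if kind not in ("GNM", "ANM"):
        raise InvalidArgumentError("kind must be 'GNM' or 'ANM'")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise InvalidArgumentError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise InvalidArgumentError("matrix must be symmetric")
    config = config or ENMConfig(model=kind)
    evals, evecs = scipy.linalg.eigh(matrix)
    lam_max = float(np.abs(evals).max()) or 1.0
    zero = np.abs(evals) < config.zero_tol * lam_max
    n_zero = int(zero.sum())
    expected = _EXPECTED_ZERO[kind]
    if n_zero != expected:
        ncomp = _component_count(matrix, kind)
        warnings.warn(DisconnectedNetworkWarning(
            f"{kind} network has {n_zero} zero modes (expected {expected}); "
            f"{ncomp} connected components", ncomp))
    return ModeSet(kind=kind, eigenvalues=evals[~zero],
                   eigenvectors=evecs[:, ~zero], n_zero_excluded=n_zero,
                   node_meta=list(node_meta or []), kT_scale=config.kT_scale,
                   zero_eigenvectors=evecs[:, zero])


def diagonalize_partial(matrix: np.ndarray, kind: str, n_modes: int,
                        config: ENMConfig | None = None,
                        node_meta: Optional[list] = None) -> ModeSet:
    """Lowest-``n_modes`` eigenpairs via a sparse Lanczos solver.

    Same contract as :func:`diagonalize` restricted to the low end of the
    spectrum; useful when only a few slow modes of a large network are
    needed. Agrees with the dense route mode-for-mode (up to sign).
    """
    import scipy.sparse
    import scipy.sparse.linalg
    config = config or ENMConfig(model=kind)
    expected = _EXPECTED_ZERO[kind]
    k = n_modes + expected
    sp = scipy.sparse.csr_matrix(matrix)
    evals, evecs = scipy.sparse.linalg.eigsh(sp, k=k, sigma=-1e-6,
                                             which="LM")
    order = np.argsort(evals)
    evals, evecs = evals[order], evecs[:, order]
    lam_max = float(scipy.sparse.linalg.eigsh(
        sp, k=1, which="LA", return_eigenvectors=False)[0])
    zero = np.abs(evals) < config.zero_tol * abs(lam_max)
    n_zero = int(zero.sum())
    if n_zero != expected:
        ncomp = _component_count(np.asarray(matrix), kind)
        warnings.warn(DisconnectedNetworkWarning(
            f"{kind} network has {n_zero} zero modes (expected {expected}); "
            f"{ncomp} connected components", ncomp))
    return ModeSet(kind=kind, eigenvalues=evals[~zero],
                   eigenvectors=evecs[:, ~zero], n_zero_excluded=n_zero,
                   node_meta=list(node_meta or []), kT_scale=config.kT_scale,
                   zero_eigenvectors=evecs[:, zero])


# ---------------------------------------------------------------------------
# fluctuations and correlations


def _mode_indices(modes: ModeSet,
                  mode_subset: Union[str, Sequence[int]]) -> np.ndarray:
    if isinstance(mode_subset, str):
        if mode_subset != "all":
            raise InvalidArgumentError(
                "mode_subset must be 'all' or a list of indices")
        return np.arange(1, modes.n_modes + 1)
    idx = np.asarray(list(mode_subset), dtype=int)
    if idx.size == 0:
        raise InvalidArgumentError("empty mode subset")
    modes._check_indices(idx)
    return idx


def _per_node_square(modes: ModeSet, columns: np.ndarray,
                     weights: np.ndarray) -> np.ndarray:
    """sum_k w_k * |v_k[node]|^2 with 3-component grouping for 3N vectors."""
    v = modes.eigenvectors[:, columns]
    if modes.kind == "GNM":
        return (v ** 2) @ weights
    n = v.shape[0] // 3
    return (v.reshape(n, 3, -1) ** 2).sum(axis=1) @ weights


def square_fluctuations(modes: ModeSet,
                        mode_subset: Union[str, Sequence[int]] = "all"
                        ) -> FluctuationProfile:
    """Per-node square fluctuations from a subset of non-zero modes.

    GNM: kT_scale * sum_k (1/lambda_k) u_k[i]^2 (the pseudo-inverse
    diagonal when all modes are used); ANM: same with the squared 3-vector
    norm of each node's eigenvector slice.
    """
    idx = _mode_indices(modes, mode_subset)
    weights = modes.variances()[idx - 1]
    values = modes.kT_scale * _per_node_square(modes, idx - 1, weights)
    used = "all" if isinstance(mode_subset, str) else [int(k) for k in idx]
    return FluctuationProfile(values=values, modes_used=used,
                              node_meta=modes.node_meta)


def cross_correlation(modes: ModeSet, n_modes: int = 20) -> CorrelationMap:
    """Normalised cross-correlation map from the first ``n_modes`` modes.

    The unnormalised covariance is sum_k (1/lambda_k) u_k u_k^T for GNM
    and, for ANM, the trace of each 3x3 super-element of the analogous
    3N x 3N sum; normalising by the diagonal yields C_ij in [-1, 1] with
    C_ii = 1.
    """
    if not 1 <= n_modes <= modes.n_modes:
        raise InvalidArgumentError(
            f"n_modes must be in 1..{modes.n_modes}, got {n_modes}")
    cols = np.arange(n_modes)
    w = modes.variances()[cols]
    v = modes.eigenvectors[:, cols]
    if modes.kind == "GNM":
        cov = (v * w) @ v.T
    else:
        n = v.shape[0] // 3
        v3 = v.reshape(n, 3, -1)
        cov = np.einsum("iak,jak,k->ij", v3, v3, w, optimize=True)
    diag = np.sqrt(np.diag(cov))
    cmap = cov / np.outer(diag, diag)
    cmap = 0.5 * (cmap + cmap.T)
    np.fill_diagonal(cmap, 1.0)
    return CorrelationMap(values=cmap, modes_used=list(range(1, n_modes + 1)),
                          node_meta=modes.node_meta)


def gnm_pseudoinverse_fluctuations(gamma_matrix: np.ndarray,
                                   kT_scale: float = 1.0) -> np.ndarray:
    """Independent route to GNM fluctuations: Moore-Penrose diagonal."""
    return kT_scale * np.diag(np.linalg.pinv(gamma_matrix,
                                             hermitian=True)).copy()


def export_matrix_mtx(matrix: np.ndarray, path) -> None:
    """Dump a matrix in Matrix Market format for external inspection."""
    import scipy.io
    import scipy.sparse
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix))
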