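"""Synthetic conformational ensembles and principal component analysis.

With no deposited trajectory to analyse, ensembles are generated as
mode-directed Gaussian deformations of a reference node model: frame f is

    R_f = R0 + sum_l a_{f,l} v_l + eta_f ,

with a_{f,l} ~ N(0, sigma_l^2) along chosen ANM eigenvectors v_l and
isotropic coordinate noise eta_f ~ N(0, eps^2). This emulates the
statistical structure of an equilibrated MD ensemble (a few dominant
collective directions plus a high-dimensional noise floor) while keeping
the ground truth known, so PCA-versus-ANM comparisons become
parameter-recovery checks.

PCA follows the standard covariance route: frames are iteratively
superposed onto their mean (least-squares rigid fit, no reflection),
and the eigenvectors of the displacement covariance (divisor F) are the
PC modes, ordered by descending variance. The decomposition is computed
through the thin SVD of the F x 3N displacement matrix, which yields the
identical non-null eigenpairs without forming the 3N x 3N matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .errors import (IllConditionedFitError, InsufficientFramesError,
                     InvalidArgumentError, MalformedEnsembleError)
from .enm import ModeSet
from .io import LEVEL_ROLES, NodeModel, read_pdb, select_nodes


@dataclass
class Ensemble:
    """A stack of conformations of one node model."""

    frames: np.ndarray            # (F, N, 3) Angstrom
    node_meta: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InvalidArgumentError("frames must have shape (F, N, 3)")
        if self.frames.shape[0] < 2:
            raise InsufficientFramesError("an ensemble needs >= 2 frames")
        if self.node_meta and len(self.node_meta) != self.frames.shape[1]:
            raise InvalidArgumentError("node_meta does not match frame width")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.frames.shape[1]

    def mean(self) -> np.ndarray:
        return self.frames.mean(axis=0)

    def rmsf(self) -> np.ndarray:
        """Per-node root-mean-square fluctuation about the ensemble mean."""
        d = self.frames - self.mean()
        return np.sqrt((d ** 2).sum(axis=2).mean(axis=0))


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of the mode-directed Gaussian ensemble generator.

    ``mode_amplitudes`` maps 1-based non-zero ANM mode indices to the
    standard deviation (A) of the Gaussian amplitude drawn along that
    mode; ``isotropic_noise`` is the per-coordinate noise floor (A).
    100 frames mirrors a typical snapshot count used for trajectory PCA.
    """

    base: NodeModel
    mode_amplitudes: dict = field(default_factory=dict)
    isotropic_noise: float = 0.0
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.mode_amplitudes.values()):
            raise InvalidArgumentError("mode amplitudes must be >= 0")
        if self.isotropic_noise < 0:
            raise InvalidArgumentError("isotropic_noise must be >= 0")
        if not any(self.mode_amplitudes.values()) and self.isotropic_noise == 0:
            raise InvalidArgumentError(
                "at least one amplitude or the noise level must be positive")
        if self.n_frames < 2:
            raise InvalidArgumentError("n_frames must be >= 2")


def generate_ensemble(spec: EnsembleSpec, modes: ModeSet) -> Ensemble:
    """Draw a reproducible mode-directed Gaussian ensemble.

    Draw order is fixed (modes in ascending index, all frames per mode,
    then the noise block) so a seed pins the ensemble bitwise.
    """
    if modes.kind != "ANM":
        raise InvalidArgumentError("generator requires ANM modes")
    base = np.asarray(spec.base.positions, dtype=float)
    n = base.shape[0]
    if modes.eigenvectors.shape[0] != 3 * n:
        raise InvalidArgumentError(
            "mode vectors do not match the base node model")
    rng = np.random.default_rng(spec.seed)
    disp = np.zeros((spec.n_frames, 3 * n))
    for l in sorted(spec.mode_amplitudes):
        sigma = spec.mode_amplitudes[l]
        amps = rng.normal(0.0, sigma, spec.n_frames)
        disp += np.outer(amps, modes.mode(l))
    frames = base[None, :, :] + disp.reshape(spec.n_frames, n, 3)
    if spec.isotropic_noise > 0:
        frames = frames + rng.normal(0.0, spec.isotropic_noise,
                                     frames.shape)
    return Ensemble(frames=frames, node_meta=list(spec.base.node_meta),
                    provenance={"generator": "mode_gaussian",
                                "mode_amplitudes": dict(spec.mode_amplitudes),
                                "isotropic_noise": spec.isotropic_noise,
                                "seed": spec.seed})


# ---------------------------------------------------------------------------
# superposition


def _kabsch(mobile: np.ndarray, target: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation of ``mobile`` onto ``target``.

    Proper rotation only (determinant +1); both inputs are (N, 3).
    """
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def superpose(ensemble: Ensemble, tol: float = 1e-10,
              max_iter: int = 100,
              reference: Optional[np.ndarray] = None) -> Ensemble:
    """Iteratively superpose all frames onto the running mean structure.

    Every frame is rigid-body fitted (rotation + translation, no
    reflection) to the current mean, the mean is recomputed, and the loop
    repeats until the mean moves by less than ``tol`` A or ``max_iter``
    rounds have run. All nodes enter the fit with equal weight.

    The converged orientation is arbitrary (any global rotation of an
    aligned ensemble is equally aligned); pass ``reference`` coordinates
    (N, 3) to fix it — the converged mean is fitted onto the reference
    and the same transform applied to every frame, which is needed
    whenever frame projections are compared against mode vectors
    expressed in the reference frame.
    """
    frames = ensemble.frames.copy()
    ref0 = frames[0]
    sv = np.linalg.svd(ref0 - ref0.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise IllConditionedFitError(
            "nodes are collinear; rigid fit is degenerate")
    # seeding from frame 0 instead of the raw mean would re-orient an
    # already-aligned ensemble; the mean seed makes the procedure a fixed
    # point on its own output
    mean = frames.mean(axis=0)
    if np.linalg.svd(mean - mean.mean(axis=0),
                     compute_uv=False)[1] < 1e-6 * max(sv[0], 1.0):
        mean = ref0.copy()  # raw mean degenerate (e.g. random rotations)
    for _ in range(max_iter):
        for f in range(frames.shape[0]):
            rot, trans = _kabsch(frames[f], mean)
            frames[f] = frames[f] @ rot.T + trans
        new_mean = frames.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if shift < tol:
            break
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        rot, trans = _kabsch(mean, reference)
        frames = frames @ rot.T + trans
    return Ensemble(frames=frames, node_meta=ensemble.node_meta,
                    provenance={**ensemble.provenance, "superposed": True})


# ---------------------------------------------------------------------------
# PCA


def pca(ensemble: Ensemble, zero_tol: float = 1e-10) -> ModeSet:
    """PC modes of the displacement covariance about the ensemble mean.

    Covariance uses divisor F (population convention); only directions and
    variance fractions are consumed downstream, and both are invariant to
    that choice. Components with negligible variance (below ``zero_tol``
    of the leading one) are dropped from the reported spectrum.
    """
    if ensemble.n_frames < 2:
        raise InsufficientFramesError("PCA needs >= 2 frames")
    f, n = ensemble.n_frames, ensemble.n_nodes
    disp = (ensemble.frames - ensemble.mean()).reshape(f, 3 * n)
    # thin SVD of the displacement matrix == eigendecomposition of the
    # 3N x 3N covariance restricted to its non-null range
    _, s, vt = np.linalg.svd(disp, full_matrices=False)
    variances = s ** 2 / f
    keep = variances > zero_tol * (variances[0] if variances.size else 1.0)
    return ModeSet(kind="PCA", eigenvalues=variances[keep],
                   eigenvectors=vt[keep].T,
                   n_zero_excluded=int((~keep).sum()),
                   node_meta=list(ensemble.node_meta))


def project(ensemble: Ensemble, mode_vector: np.ndarray) -> np.ndarray:
    """Per-frame scalar projections onto a unit 3N mode vector (A)."""
    v = np.asarray(mode_vector, dtype=float).ravel()
    f, n = ensemble.n_frames, ensemble.n_nodes
    if v.shape[0] != 3 * n:
        raise InvalidArgumentError(
            f"mode vector length {v.shape[0]} != 3N = {3 * n}")
    disp = (ensemble.frames - ensemble.mean()).reshape(f, 3 * n)
    return disp @ v


# ---------------------------------------------------------------------------
# multi-model PDB input


def read_ensemble(path, stride: int = 1, level: int = 3) -> Ensemble:
    """Load a multi-model PDB as an ensemble of level-``level`` node sets.

    One frame per MODEL record, subsampled by ``stride``; node selection
    follows the representation-level rules of :mod:`nacage.io`. All models
    must contain the same atoms.
    """
    if stride < 1:
        raise InvalidArgumentError("stride must be >= 1")
    from pathlib import Path
    from .io import _parse_atom_line
    from .structure import Structure

    models: list[list] = []
    current: Optional[list] = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        rec = line[:6].strip()
        if rec == "MODEL":
            current = []
        elif rec == "ENDMDL":
            if current:
                models.append(current)
            current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                current = []  # tolerate single-model files without MODEL
            current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    if not models:
        raise MalformedEnsembleError(f"{path}: no models found")
    counts = {len(m) for m in models}
    if len(counts) != 1:
        raise MalformedEnsembleError(
            f"inconsistent atom counts across models: {sorted(counts)}")
    models = models[::stride]
    nodesets = [select_nodes(Structure(atoms=m), level) for m in models]
    meta0 = nodesets[0].node_meta
    for ns in nodesets[1:]:
        if ns.node_meta != meta0:
            raise MalformedEnsembleError(
                "models select different node sets")
    frames = np.stack([ns.positions for ns in nodesets])
    return Ensemble(frames=frames, node_meta=list(meta0),
                    provenance={"path": str(path), "stride": stride,
                                "level": level})
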