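"""Analyses computed from mode sets.

Covers the comparison toolbox used on the nanocage: square-fluctuation
profile rescaling and correlation across coarse-graining levels, map
correlation, mode overlap O(u, v) = |u . v| and cumulative overlap
CO(m) = sqrt(sum_k O^2), fraction of variance, entropy collectivity,
hinge-site detection from slow GNM modes, per-strand profiles and NMD
export for mode visualization.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .enm import (CorrelationMap, FluctuationProfile, ModeSet,
                  square_fluctuations)
from .errors import (InvalidArgumentError, ParseError,
                     UndefinedCorrelationError, UnsupportedModeKindError)
from .io import NodeModel


# ---------------------------------------------------------------------------
# overlap machinery


def _check_unit(v: np.ndarray, name: str, tol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    norm = float(np.linalg.norm(v))
    if abs(norm - 1.0) > tol:
        raise InvalidArgumentError(f"{name} is not unit norm (|v| = {norm})")
    return v


def overlap(u: np.ndarray, v: np.ndarray) -> float:
    """Absolute dot product of two unit mode vectors.

    The sign of an eigenvector is arbitrary, so the overlap is reported
    signless in [0, 1].
    """
    u = _check_unit(u, "u")
    v = _check_unit(v, "v")
    if u.shape != v.shape:
        raise InvalidArgumentError(
            f"length mismatch: {u.shape[0]} vs {v.shape[0]}")
    return float(abs(np.dot(u, v)))


def cumulative_overlap(mode_vectors: np.ndarray,
                       target: np.ndarray) -> np.ndarray:
    """CO(m) series for m = 1..k over an orthonormal mode set.

    ``mode_vectors`` holds k unit columns; the result is the square root
    of the running sum of squared overlaps with ``target``, clipped at
    1 + 1e-8 (it equals 1 on a complete basis).
    """
    m = np.asarray(mode_vectors, dtype=float)
    if m.ndim != 2:
        raise InvalidArgumentError("mode_vectors must be a (dim, k) matrix")
    gram = m.T @ m
    if not np.allclose(gram, np.eye(m.shape[1]), atol=1e-6):
        raise InvalidArgumentError("mode set is not orthonormal")
    t = _check_unit(target, "target")
    if t.shape[0] != m.shape[0]:
        raise InvalidArgumentError("target length does not match modes")
    co = np.sqrt(np.cumsum((m.T @ t) ** 2))
    return np.minimum(co, 1.0 + 1e-8)


def overlap_map(set_a: ModeSet, set_b: ModeSet, n_modes: int) -> np.ndarray:
    """k x k matrix of |u_i . v_j| between two mode sets."""
    if set_a.eigenvectors.shape[0] != set_b.eigenvectors.shape[0]:
        raise InvalidArgumentError("mode sets live in different dimensions")
    k = min(n_modes, set_a.n_modes, set_b.n_modes)
    a = set_a.eigenvectors[:, :k]
    b = set_b.eigenvectors[:, :k]
    return np.abs(a.T @ b)


# ---------------------------------------------------------------------------
# spectra


def fraction_of_variance(modes: ModeSet) -> np.ndarray:
    """Share of total variance carried by each mode.

    PCA: lambda_k / sum(lambda); GNM/ANM: mode variance is proportional
    to the inverse eigenvalue, so p_k = (1/lambda_k) / sum(1/lambda) over
    the non-zero spectrum.
    """
    if modes.n_modes == 0:
        raise InvalidArgumentError("empty spectrum")
    var = modes.variances()
    return var / var.sum()


def collectivity(mode_vector: np.ndarray,
                 n_nodes: Optional[int] = None) -> float:
    """Information-entropy collectivity kappa in (0, 1].

    With alpha-normalised per-node squared amplitudes p_i (sum p_i = 1),
    kappa = exp(-sum p_i ln p_i) / N: 1 for a uniform mode, 1/N when a
    single node carries all the amplitude. 3N vectors are reduced to
    per-node amplitudes by the 3-component norm first.
    """
    v = np.asarray(mode_vector, dtype=float).ravel()
    if not np.any(v):
        raise InvalidArgumentError("zero mode vector")
    if n_nodes is not None and v.shape[0] == 3 * n_nodes:
        amp2 = (v.reshape(n_nodes, 3) ** 2).sum(axis=1)
    else:
        amp2 = v ** 2
    p = amp2 / amp2.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return float(np.exp(entropy) / p.shape[0])


# ---------------------------------------------------------------------------
# profile comparison


def per_residue_profile(profile: FluctuationProfile) -> np.ndarray:
    """Reduce a per-node profile to per-residue means.

    Profiles at different coarse-graining levels are only comparable per
    residue; nodes are grouped by (strand_id, residue_index) in node
    order.
    """
    if not profile.node_meta:
        return np.asarray(profile.values, dtype=float)
    keys: dict[tuple, int] = {}
    for sid, resi, _, _ in profile.node_meta:
        keys.setdefault((sid, resi), len(keys))
    idx = np.array([keys[(sid, resi)]
                    for sid, resi, _, _ in profile.node_meta])
    return (np.bincount(idx, weights=profile.values)
            / np.bincount(idx))


def rescale_profile(profile: FluctuationProfile,
                    reference: FluctuationProfile) -> FluctuationProfile:
    """Scale a profile so its mean matches the reference mean."""
    if len(profile) != len(reference):
        raise InvalidArgumentError("profiles have different lengths")
    mean = float(np.mean(profile.values))
    ref_mean = float(np.mean(reference.values))
    if mean <= 0 or ref_mean <= 0:
        raise InvalidArgumentError("profile means must be positive")
    return FluctuationProfile(values=profile.values * (ref_mean / mean),
                              modes_used=profile.modes_used,
                              node_meta=profile.node_meta)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant profile")
    return float(np.corrcoef(x, y)[0, 1])


def profile_correlation(a: FluctuationProfile,
                        b: FluctuationProfile) -> float:
    """Pearson correlation of two fluctuation profiles, per residue.

    Each profile is first reduced to per-residue means so one-, two- and
    three-node representations can be compared on a common axis.
    """
    ra, rb = per_residue_profile(a), per_residue_profile(b)
    if ra.shape[0] != rb.shape[0]:
        raise InvalidArgumentError(
            f"profiles cover different residue sets "
            f"({ra.shape[0]} vs {rb.shape[0]})")
    return _pearson(ra, rb)


def map_correlation(a: CorrelationMap, b: CorrelationMap) -> float:
    """Pearson correlation between two maps over the strict upper triangle.

    The diagonal is identically 1 in both maps and would only inflate the
    correlation, so it is excluded.
    """
    if a.values.shape != b.values.shape:
        raise InvalidArgumentError("maps have different shapes")
    iu = np.triu_indices_from(a.values, k=1)
    return _pearson(a.values[iu], b.values[iu])


# ---------------------------------------------------------------------------
# hinge detection


@dataclass
class HingeSet:
    """Hinge residues of one slow GNM mode."""

    mode_index: int
    #: (node_index, strand_id, residue_index, region)
    hinge_nodes: list
    detection_params: dict = field(default_factory=dict)


def _strand_series(node_meta: Sequence, values: np.ndarray
                   ) -> dict[str, list[tuple[int, float, Optional[str]]]]:
    """Per-strand (residue_index, value, region) series in strand order."""
    residues: dict[tuple, list[float]] = {}
    regions: dict[tuple, Optional[str]] = {}
    order: list[tuple] = []
    for (sid, resi, _, region), v in zip(node_meta, values):
        key = (sid, resi)
        if key not in residues:
            residues[key] = []
            order.append(key)
        residues[key].append(float(v))
        regions[key] = region
    strands: dict[str, list] = {}
    for sid, resi in order:
        strands.setdefault(sid, []).append(
            (resi, float(np.mean(residues[(sid, resi)])),
             regions[(sid, resi)]))
    return strands


def detect_hinges(modes: ModeSet,
                  mode_indices: Sequence[int] = (1, 2),
                  window: int = 5, percentile: float = 25.0,
                  circular: bool = True) -> list[HingeSet]:
    """Hinge residues: low-lying strict local minima of slow-mode profiles.

    For each requested GNM mode the single-mode square-fluctuation profile
    is reduced per residue; a residue is a hinge iff it is a strict local
    minimum within +-``window`` residues along its strand and its value
    lies below the ``percentile``-th percentile of the whole profile.
    ``circular`` treats each strand as a closed loop (the cage
    oligonucleotides are covalently closed); linear strands are handled
    with truncated windows at their ends.
    """
    if modes.kind != "GNM":
        raise InvalidArgumentError("hinge detection expects GNM modes")
    if window < 1:
        raise InvalidArgumentError("window must be >= 1")
    if not 0 < percentile < 100:
        raise InvalidArgumentError("percentile must be in (0, 100)")
    out = []
    for mode in mode_indices:
        prof = square_fluctuations(modes, [int(mode)])
        strands = _strand_series(modes.node_meta, prof.values)
        all_values = np.array([v for series in strands.values()
                               for _, v, _ in series])
        threshold = float(np.percentile(all_values, percentile))
        hinges = []
        for sid, series in strands.items():
            n = len(series)
            for i, (resi, v, region) in enumerate(series):
                if v >= threshold:
                    continue
                if circular and n > 2 * window:
                    neighbors = [series[(i + d) % n][1]
                                 for d in range(-window, window + 1) if d]
                else:
                    neighbors = [series[j][1]
                                 for j in range(max(0, i - window),
                                                min(n, i + window + 1))
                                 if j != i]
                if all(v < w for w in neighbors):
                    hinges.append((i, sid, resi, region))
        out.append(HingeSet(mode_index=int(mode), hinge_nodes=hinges,
                            detection_params={"window": window,
                                              "percentile": percentile,
                                              "circular": circular}))
    return out


def hinge_linker_fraction(hinge_sets: Sequence[HingeSet],
                          node_meta: Sequence, max_distance: int = 2,
                          circular: bool = True) -> float:
    """Fraction of hinge residues within ``max_distance`` residues of a
    linker region along their strand."""
    strands = _strand_series(node_meta, np.zeros(len(node_meta)))
    region_by_strand = {sid: [r for _, _, r in series]
                        for sid, series in strands.items()}
    total, near = 0, 0
    for hs in hinge_sets:
        for i, sid, resi, region in hs.hinge_nodes:
            total += 1
            regions = region_by_strand[sid]
            n = len(regions)
            for d in range(-max_distance, max_distance + 1):
                j = (i + d) % n if circular else i + d
                if 0 <= j < n and regions[j] == "linker":
                    near += 1
                    break
    return near / total if total else float("nan")


# ---------------------------------------------------------------------------
# per-strand profiles


def strand_profile(profile: FluctuationProfile, strand_id: str
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue series of one strand: (residue_indices, values)."""
    strands = _strand_series(profile.node_meta, profile.values)
    if strand_id not in strands:
        raise InvalidArgumentError(f"unknown strand {strand_id!r}")
    series = strands[strand_id]
    return (np.array([r for r, _, _ in series]),
            np.array([v for _, v, _ in series]))


# ---------------------------------------------------------------------------
# NMD export


def export_nmd(modes: ModeSet, nodes: NodeModel, path,
               n_modes: int = 20, name: str = "nacage") -> None:
    """Write modes in the plain-text NMD format used by mode viewers.

    Each mode line carries the 1-based index, a scale factor (RMS
    amplitude: 1/sqrt(lambda) for ANM, sqrt(variance) for PCA) and the
    3N vector. GNM modes carry no directions and cannot be exported.
    """
    if modes.kind == "GNM":
        raise UnsupportedModeKindError(
            "GNM modes have no directions; NMD export needs ANM or PCA")
    n_modes = min(n_modes, modes.n_modes)
    coords = np.asarray(nodes.positions, dtype=float).ravel()
    if coords.shape[0] != modes.eigenvectors.shape[0]:
        raise InvalidArgumentError("node model does not match mode vectors")
    lines = ["nmd", f"name {name}"]
    names = " ".join(role for _, _, role, _ in nodes.node_meta)
    resids = " ".join(str(resi) for _, resi, _, _ in nodes.node_meta)
    chains = " ".join(sid for sid, _, _, _ in nodes.node_meta)
    lines.append(f"atomnames {names}")
    lines.append(f"resids {resids}")
    lines.append(f"chainids {chains}")
    lines.append("coordinates " + " ".join(f"{x:.3f}" for x in coords))
    scales = (np.sqrt(modes.eigenvalues) if modes.kind == "PCA"
              else 1.0 / np.sqrt(modes.eigenvalues))
    for k in range(n_modes):
        vec = modes.eigenvectors[:, k]
        lines.append(f"mode {k + 1} {scales[k]:.6g} "
                     + " ".join(f"{x:.6f}" for x in vec))
    Path(path).write_text("\n".join(lines) + "\n")


def read_nmd(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse an NMD file back into (coordinates, scales, mode matrix)."""
    coords = None
    scales, vectors = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "coordinates":
            coords = np.array([float(x) for x in parts[1:]])
        elif parts[0] == "mode":
            scales.append(float(parts[2]))
            vectors.append([float(x) for x in parts[3:]])
    if coords is None or not vectors:
        raise ParseError(f"{path}: not a valid NMD file")
    return coords, np.array(scales), np.array(vectors).T
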