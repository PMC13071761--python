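"""Rigid-body superposition, fluctuation statistics, and common-eigenspace PCA.

The comparative PCA concatenates the Cα coordinates of both ensemble states
(after iterated least-squares alignment to the joint mean structure), builds a
single 3m × 3m covariance matrix and diagonalises it once.  The resulting
eigenvectors form a common reference subspace; individual reduced and
PTM-modified trajectories are projected onto it so that their occupancies of
the collective-motion space can be compared directly, including per-group
centroid shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import StatePair, Trajectory, ValidationError

__all__ = [
    "PCAResult",
    "ModeContribution",
    "kabsch_superpose",
    "align_frames_to_mean",
    "rmsf",
    "radius_of_gyration",
    "combined_pca",
    "mode_residue_contributions",
    "centroid_shift",
]


class DegenerateGeometryError(ValueError):
    """The selected atoms cannot define a unique rigid-body fit."""


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of one frame onto a reference.

    The optimal proper rotation is found over the ``selection`` atom indices
    (all atoms when None) and applied to every atom.  Returns the transformed
    coordinates and the minimum RMSD (nm) over the selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise DegenerateGeometryError("need at least 3 atoms for superposition")
    mob_sel = mobile[sel]
    ref_sel = reference[sel]
    mob_centroid = mob_sel.mean(axis=0)
    ref_centroid = ref_sel.mean(axis=0)
    mob_c = mob_sel - mob_centroid
    ref_c = ref_sel - ref_centroid
    if np.linalg.matrix_rank(mob_c, tol=1e-10) < 2:
        raise DegenerateGeometryError("selected atoms are collinear")
    rotation, _ = Rotation.align_vectors(ref_c, mob_c)
    aligned = rotation.apply(mobile - mob_centroid) + ref_centroid
    rmsd = float(np.sqrt(np.mean(np.sum((aligned[sel] - ref_sel) ** 2, axis=1))))
    return aligned, rmsd


def align_frames_to_mean(
    coords: np.ndarray,
    selection: np.ndarray | None = None,
    n_passes: int = 10,
    tol: float = 1e-12,
) -> np.ndarray:
    """Superpose all frames onto their mean structure, iterated to a fixed point.

    Each pass aligns every frame to the current mean and recomputes the mean;
    iteration stops once the mean moves less than ``tol`` nm (typically after
    2-3 passes).  The first pass uses the first frame as a provisional
    reference, and the converged result is independent of the ensemble's
    initial global orientation up to one overall rotation, which leaves all
    downstream covariance spectra unchanged.
    """
    coords = np.asarray(coords, dtype=float)
    reference = coords[0]
    aligned = coords
    for _ in range(n_passes):
        aligned = np.stack(
            [kabsch_superpose(frame, reference, selection)[0] for frame in aligned]
        )
        new_reference = aligned.mean(axis=0)
        moved = np.abs(new_reference - reference).max()
        reference = new_reference
        if moved < tol:
            break
    return np.stack(
        [kabsch_superpose(frame, reference, selection)[0] for frame in aligned]
    )


def _selected_ca_coords(trajectory: Trajectory, selection: str) -> np.ndarray:
    """(frames, m, 3) Cα coordinates of a named residue selection."""
    keys = trajectory.system.select_residues(selection)
    ca = trajectory.system.ca_indices(keys)
    return trajectory.coordinates[:, ca, :]


def rmsf(
    trajectories: Sequence[Trajectory],
    selection: str,
    fit: bool = True,
) -> np.ndarray:
    """Per-residue root-mean-square fluctuation (nm) over pooled replicas.

    Each replica is aligned to its own mean structure first (when ``fit``),
    then frames are pooled and RMSF_i = sqrt(<|r_i − <r_i>|²>) is taken about
    the pooled mean.
    """
    if not trajectories:
        raise ValidationError("need at least one trajectory")
    blocks = []
    for traj in trajectories:
        coords = _selected_ca_coords(traj, selection)
        if coords.shape[1] == 0:
            raise ValidationError(f"selection {selection!r} is empty")
        do_fit = fit and coords.shape[1] >= 3
        blocks.append(align_frames_to_mean(coords) if do_fit else coords)
    pooled = np.concatenate(blocks, axis=0)
    if pooled.shape[0] < 2:
        raise ValidationError("need at least 2 frames in total")
    dev = pooled - pooled.mean(axis=0)
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def radius_of_gyration(
    frame: np.ndarray,
    masses: np.ndarray | None = None,
    mass_weighted: bool = False,
) -> float:
    """Rg (nm) of one frame; unweighted unless ``mass_weighted``."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValidationError("empty selection")
    if mass_weighted:
        if masses is None:
            raise ValidationError("mass_weighted=True requires masses")
        w = np.asarray(masses, dtype=float)
        if w.sum() <= 0:
            raise ValidationError("total mass must be positive")
    else:
        w = np.ones(len(frame))
    com = np.average(frame, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((frame - com) ** 2, axis=1), weights=w)))


# ---------------------------------------------------------------------------
# Combined-eigenspace PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Eigen-decomposition of the combined covariance plus per-source projections.

    ``eigenvalues`` (nm², descending) and orthonormal ``eigenvectors``
    (columns, length 3m) describe the joint ensemble; ``projections`` maps a
    ``(state, replica)`` source label to a (frames, n_modes) array of
    projections onto the shared modes.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (3m, n_modes), columns orthonormal
    variance_fractions: np.ndarray
    projections: dict[tuple[str, int], np.ndarray]
    mean_structure: np.ndarray  # (m, 3) joint mean after alignment
    residue_keys: list
    total_variance: float

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]


def _canonical_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its largest-magnitude component is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        k = np.argmax(np.abs(out[:, j]))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def combined_pca(
    pair: StatePair,
    selection: str | None = None,
    n_modes: int | None = None,
) -> PCAResult:
    """PCA on the concatenated, aligned frames of both states.

    All replicas of both states are concatenated, aligned to the joint mean
    (two-pass), mean-centred and used to build one covariance matrix whose
    eigenvectors serve as the common subspace; each source trajectory's
    projections are computed against those shared modes.
    """
    selection = selection or pair.selection
    sources = pair.all_trajectories()
    blocks = [_selected_ca_coords(t, selection) for _, _, t in sources]
    m = blocks[0].shape[1]
    if any(b.shape[1] != m for b in blocks):
        raise ValidationError("selection resolves to differing residue counts")
    if m == 0:
        raise ValidationError(f"selection {selection!r} is empty")
    combined = np.concatenate(blocks, axis=0)
    if combined.shape[0] < 2:
        raise ValidationError("need at least 2 frames in total")
    # superposition needs >=3 atoms; tiny selections are analysed as-is
    aligned = align_frames_to_mean(combined) if m >= 3 else combined
    mean = aligned.mean(axis=0)
    flat = (aligned - mean).reshape(len(aligned), 3 * m)
    cov = flat.T @ flat / len(flat)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _canonical_sign(evecs[:, order])
    total = float(np.trace(cov))
    k = n_modes if n_modes is not None else len(evals)
    k = min(k, len(evals))
    fractions = evals / total if total > 0 else np.zeros_like(evals)

    projections: dict[tuple[str, int], np.ndarray] = {}
    offset = 0
    for (state, replica, _), block in zip(sources, blocks):
        segment = aligned[offset : offset + len(block)]
        offset += len(block)
        centred = (segment - mean).reshape(len(segment), 3 * m)
        projections[(state, replica)] = centred @ evecs[:, :k]

    keys = pair.reduced[0].system.select_residues(selection)
    return PCAResult(
        eigenvalues=evals[:k],
        eigenvectors=evecs[:, :k],
        variance_fractions=fractions[:k],
        projections=projections,
        mean_structure=mean,
        residue_keys=list(keys),
        total_variance=total,
    )


@dataclass
class ModeContribution:
    """Normalised per-residue displacement weight of one collective mode."""

    mode: int
    contributions: np.ndarray  # sums to 1
    top_set: list  # residue keys covering the requested cumulative fraction
    fraction: float


def mode_residue_contributions(
    result: PCAResult, mode: int, fraction: float = 0.5
) -> ModeContribution:
    """Per-residue |displacement| weights of a mode and its top-``fraction`` set.

    contribution_i = |(v_x, v_y, v_z)_i| / Σ_j |v_j|; the top set is the
    minimal prefix of residues sorted by descending contribution whose
    cumulative sum reaches the requested fraction (ties broken toward the
    lower residue index).
    """
    if mode >= result.n_modes:
        raise ValidationError(f"mode {mode} not in result (n_modes={result.n_modes})")
    vec = result.eigenvectors[:, mode].reshape(-1, 3)
    magnitudes = np.linalg.norm(vec, axis=1)
    total = magnitudes.sum()
    contributions = magnitudes / total if total > 0 else magnitudes
    # stable sort on (-contribution, index): ties keep the lower index first
    order = np.lexsort((np.arange(len(contributions)), -contributions))
    cumulative = np.cumsum(contributions[order])
    n_top = int(np.searchsorted(cumulative, fraction - 1e-12) + 1)
    top = [result.residue_keys[i] for i in order[:n_top]]
    return ModeContribution(
        mode=mode, contributions=contributions, top_set=top, fraction=fraction
    )


def centroid_shift(
    result: PCAResult,
    grouping: Callable[[tuple[str, int]], str] | dict[tuple[str, int], str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-group PTM-minus-reduced shift of mean projections in PC space.

    ``grouping`` maps a ``(state, replica)`` source label to a group name
    (e.g. a subunit); by default all sources form one group.  Every group must
    have frames in both states.
    """
    if grouping is None:
        group_of = lambda label: "all"
    elif isinstance(grouping, dict):
        group_of = grouping.__getitem__
    else:
        group_of = grouping
    buckets: dict[str, dict[str, list[np.ndarray]]] = {}
    for label, proj in result.projections.items():
        state = label[0]
        buckets.setdefault(group_of(label), {}).setdefault(state, []).append(proj)
    shifts: dict[str, np.ndarray] = {}
    for group, states in buckets.items():
        if "reduced" not in states or "ptm" not in states:
            raise ValidationError(f"group {group!r} is missing one state")
        mean_ptm = np.concatenate(states["ptm"]).mean(axis=0)
        mean_red = np.concatenate(states["reduced"]).mean(axis=0)
        shifts[group] = mean_ptm - mean_red
    return shifts
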