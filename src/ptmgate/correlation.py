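"""Dynamic cross-correlation matrices and the PTM redistribution score.

The DCCM entry for residues i, j is the normalised covariance of their Cα
positional fluctuations,

    C_ij = <dr_i · dr_j> / sqrt(<|dr_i|²> <|dr_j|²>),

computed after removal of overall translation and rotation.  Pairs with
C_ij > 0.2 are classed as strongly correlated and C_ij < −0.2 as strongly
anti-correlated (strict inequalities).  For each residue the directional
coupling is the fraction of strongly correlated partners minus the fraction
of strongly anti-correlated partners; the redistribution score is the change
of that balance between the PTM-modified and reduced ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model_io import Trajectory, ValidationError
from .superpose_pca import _selected_ca_coords, align_frames_to_mean

__all__ = [
    "DCCMatrix",
    "CouplingFractions",
    "RedistributionScore",
    "dccm",
    "coupling_fractions",
    "redistribution_score",
    "write_dccm_csv",
    "write_dccm_long_tsv",
]


@dataclass
class DCCMatrix:
    """Symmetric residue–residue correlation matrix with labels.

    ``zero_fluctuation`` lists residues whose fluctuation variance vanished;
    their off-diagonal entries are set to 0 rather than NaN so that coupling
    fractions stay defined on degenerate inputs.
    """

    labels: list
    values: np.ndarray
    zero_fluctuation: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class CouplingFractions:
    """Per-residue fractions of strongly (anti-)correlated partners."""

    labels: list
    f_plus: np.ndarray
    f_minus: np.ndarray
    threshold: float

    @property
    def directional(self) -> np.ndarray:
        return self.f_plus - self.f_minus


@dataclass
class RedistributionScore:
    """Per-residue change in directional coupling, PTM minus reduced, in [−2, 2]."""

    labels: list
    score: np.ndarray
    threshold: float


def dccm(
    trajectories: Sequence[Trajectory],
    selection: str,
    fit: bool = True,
) -> DCCMatrix:
    """Cross-correlation matrix of Cα fluctuations over pooled replicas.

    Each replica is aligned to its own mean structure (two passes) when
    ``fit`` is on, replicas are pooled by concatenation, and deviations are
    taken from the pooled time-mean.
    """
    if not trajectories:
        raise ValidationError("need at least one trajectory")
    blocks = []
    for traj in trajectories:
        coords = _selected_ca_coords(traj, selection)
        # superposition needs >=3 atoms; tiny selections are used as-is
        do_fit = fit and coords.shape[1] >= 3
        blocks.append(align_frames_to_mean(coords) if do_fit else coords)
    pooled = np.concatenate(blocks, axis=0)
    n_frames, n_res, _ = pooled.shape
    if n_frames < 2:
        raise ValidationError("need at least 2 frames")
    if n_res < 2:
        raise ValidationError("need at least 2 residues")
    dev = pooled - pooled.mean(axis=0)
    # <dr_i . dr_j> as an (n_res, n_res) inner-product average over frames
    inner = np.einsum("fid,fjd->ij", dev, dev) / n_frames
    var = np.diag(inner).copy()
    zero = var <= 0
    denom = np.sqrt(np.where(zero, 1.0, var))
    values = inner / denom[:, None] / denom[None, :]
    if zero.any():
        values[zero, :] = 0.0
        values[:, zero] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip(values, -1.0, 1.0)
    keys = trajectories[0].system.select_residues(selection)
    labels = [f"{c}:{r}" for c, r in keys]
    return DCCMatrix(
        labels=labels,
        values=values,
        zero_fluctuation=[labels[i] for i in np.flatnonzero(zero)],
    )


def coupling_fractions(matrix: DCCMatrix, threshold: float = 0.2) -> CouplingFractions:
    """Fractions of strongly coupled partners per residue (diagonal excluded).

    Strict inequalities at ±threshold; denominators are n − 1 partners.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must be in (0, 1)")
    n = matrix.n
    if n < 2:
        raise ValidationError("need at least 2 residues")
    off = ~np.eye(n, dtype=bool)
    values = matrix.values
    f_plus = ((values > threshold) & off).sum(axis=1) / (n - 1)
    f_minus = ((values < -threshold) & off).sum(axis=1) / (n - 1)
    return CouplingFractions(
        labels=list(matrix.labels),
        f_plus=f_plus,
        f_minus=f_minus,
        threshold=threshold,
    )


def redistribution_score(
    reduced: DCCMatrix, ptm: DCCMatrix, threshold: float = 0.2
) -> RedistributionScore:
    """Change of directional coupling per residue: PTM minus reduced.

    Residue pairing is by label identity; a mismatch raises with the
    offending labels listed.
    """
    if list(reduced.labels) != list(ptm.labels):
        extra_r = sorted(set(reduced.labels) - set(ptm.labels))
        extra_p = sorted(set(ptm.labels) - set(reduced.labels))
        raise ValidationError(
            "residue labels differ between states: "
            f"only-reduced={extra_r}, only-ptm={extra_p}"
        )
    frac_r = coupling_fractions(reduced, threshold)
    frac_p = coupling_fractions(ptm, threshold)
    return RedistributionScore(
        labels=list(reduced.labels),
        score=frac_p.directional - frac_r.directional,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_dccm_csv(matrix: DCCMatrix, path: str | Path) -> None:
    """Square labeled CSV."""
    pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels).to_csv(path)


def write_dccm_long_tsv(matrix: DCCMatrix, path: str | Path) -> None:
    """Long format (res_i, res_j, C_ij), upper triangle including diagonal."""
    rows = []
    for i in range(matrix.n):
        for j in range(i, matrix.n):
            rows.append((matrix.labels[i], matrix.labels[j], matrix.values[i, j]))
    pd.DataFrame(rows, columns=["res_i", "res_j", "C_ij"]).to_csv(
        path, sep="\t", index=False
    )
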