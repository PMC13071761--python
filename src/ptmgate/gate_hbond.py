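"""Gate-distance series, conformational-state classification, and hydrogen bonds.

The pocket entrance ("gate") near the active site is defined by a lower
residue pair (ASP33/ARG37) and an upper pair (GLU241/ARG243); its state is
read off the distance between the two sides.  Distance distributions are
classified by their kernel-density peaks into

* ``closed``    — single peak below 0.4 nm,
* ``open``      — single peak in [0.4, 0.7] nm,
* ``wide_open`` — single peak above 0.7 nm,
* ``open_closed`` — peaks in both the closed and open regions (alternation).

Hydrogen bonds use the geometric criterion: donor–acceptor distance at most
0.35 nm and a deviation-from-linearity angle (hydrogen–donor–acceptor, the
angle at the donor) at most 30°.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde

from .model_io import MolecularSystem, ResidueKey, Trajectory, ValidationError

__all__ = [
    "GateDefinition",
    "GateClassification",
    "HBondCriteria",
    "DEFAULT_BANDS",
    "gate_distance_series",
    "classify_gate",
    "state_occupancy",
    "detect_hbonds",
    "hbond_occupancy",
    "infer_donor_hydrogens",
]

#: Band edges (nm): closed below the first, wide_open above the second.
DEFAULT_BANDS = (0.4, 0.7)

_BACKBONE_NAMES = {
    "N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3",
}


@dataclass(frozen=True)
class GateDefinition:
    """Residue pairs forming the lower and upper sides of the gate."""

    lower: tuple[int, ...] = (33, 37)
    upper: tuple[int, ...] = (241, 243)
    mode: str = "min_sidechain_heavy"

    def __post_init__(self) -> None:
        if set(self.lower) & set(self.upper):
            raise ValidationError("lower and upper gate residues must not overlap")
        if self.mode not in ("min_sidechain_heavy", "centroid_sidechain"):
            raise ValidationError(f"unknown gate distance mode {self.mode!r}")


@dataclass
class GateClassification:
    """KDE peaks, the derived state label, and band occupancies."""

    peaks: list[tuple[float, float]]  # (position nm, density height)
    label: str
    occupancies: dict[str, float]
    bands: tuple[float, float] = DEFAULT_BANDS


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond cutoffs: 0.35 nm and 30° by default."""

    distance_cutoff: float = 0.35  # nm, donor–acceptor
    angle_cutoff: float = 30.0  # degrees, deviation from linearity at the donor

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValidationError("distance cutoff must be positive")
        if not 0.0 < self.angle_cutoff <= 90.0:
            raise ValidationError("angle cutoff must be in (0, 90] degrees")


def _sidechain_heavy_indices(
    system: MolecularSystem, chain: str, resid: int
) -> np.ndarray:
    indices = [
        idx
        for idx in system.residue_atom_indices((chain, resid))
        if system.atoms[idx].element.upper() != "H"
        and system.atoms[idx].name not in _BACKBONE_NAMES
    ]
    if not indices:
        raise ValidationError(
            f"residue {resid} in chain {chain!r} has no side-chain heavy atoms"
        )
    return np.asarray(indices, dtype=int)


def gate_distance_series(
    trajectory: Trajectory,
    gate: GateDefinition = GateDefinition(),
    chain: str | None = None,
) -> np.ndarray:
    """Per-frame distance (nm) between the lower and upper gate atom sets.

    ``min_sidechain_heavy`` takes the minimum over all lower–upper side-chain
    heavy-atom pairs; ``centroid_sidechain`` the distance between the two
    side-chain centroids.
    """
    system = trajectory.system
    chain = chain if chain is not None else system.chain_ids[0]
    lower = np.concatenate(
        [_sidechain_heavy_indices(system, chain, r) for r in gate.lower]
    )
    upper = np.concatenate(
        [_sidechain_heavy_indices(system, chain, r) for r in gate.upper]
    )
    lo = trajectory.coordinates[:, lower, :]
    up = trajectory.coordinates[:, upper, :]
    if gate.mode == "min_sidechain_heavy":
        diff = lo[:, :, None, :] - up[:, None, :, :]
        dist = np.linalg.norm(diff, axis=-1)  # (frames, n_lower, n_upper)
        return dist.min(axis=(1, 2))
    centroid_lo = lo.mean(axis=1)
    centroid_up = up.mean(axis=1)
    return np.linalg.norm(centroid_lo - centroid_up, axis=-1)


def classify_gate(
    series: np.ndarray,
    bands: tuple[float, float] = DEFAULT_BANDS,
    bandwidth: str | float = "silverman",
    peak_rel_height: float = 0.1,
) -> GateClassification:
    """Classify a gate-distance distribution by its density peaks.

    A Gaussian KDE (Silverman bandwidth by default) is evaluated on a fine
    grid; local maxima above ``peak_rel_height`` of the global maximum count
    as peaks.  A closed-band peak together with any peak at or above the
    closed/open boundary labels the series ``open_closed``; otherwise the
    label is that of the band holding the tallest peak.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValidationError("empty distance series")
    lo_band, hi_band = bands
    if np.ptp(series) < 1e-12:
        # degenerate: all frames at one distance
        pos = float(series[0])
        peaks = [(pos, 1.0)]
    else:
        kde = gaussian_kde(series, bw_method=bandwidth)
        pad = 4 * np.std(series)
        grid = np.linspace(series.min() - pad, series.max() + pad, 1024)
        density = kde(grid)
        maxima = argrelmax(density)[0]
        threshold = peak_rel_height * density.max()
        peaks = [
            (float(grid[i]), float(density[i]))
            for i in maxima
            if density[i] >= threshold
        ]
        if not peaks:  # monotone-edge degenerate case
            i = int(np.argmax(density))
            peaks = [(float(grid[i]), float(density[i]))]
    peak_bands = {_band_of(p, bands) for p, _ in peaks}
    if "closed" in peak_bands and len(peak_bands) > 1:
        label = "open_closed"
    else:
        tallest = max(peaks, key=lambda ph: ph[1])
        label = _band_of(tallest[0], bands)
    return GateClassification(
        peaks=peaks,
        label=label,
        occupancies=state_occupancy(series, bands),
        bands=bands,
    )


def _band_of(distance: float, bands: tuple[float, float]) -> str:
    lo, hi = bands
    if distance < lo:
        return "closed"
    if distance <= hi:
        return "open"
    return "wide_open"


def state_occupancy(
    series: np.ndarray, bands: tuple[float, float] = DEFAULT_BANDS
) -> dict[str, float]:
    """Fraction of frames per band: closed [0, 0.4), open [0.4, 0.7], wide_open (0.7, ∞)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValidationError("empty distance series")
    lo, hi = bands
    n = series.size
    closed = float(np.count_nonzero(series < lo)) / n
    open_ = float(np.count_nonzero((series >= lo) & (series <= hi))) / n
    wide = float(np.count_nonzero(series > hi)) / n
    return {"closed": closed, "open": open_, "wide_open": wide}


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def detect_hbonds(
    frame: np.ndarray,
    donors: Sequence[int],
    donor_hydrogens: dict[int, Sequence[int]],
    acceptors: Sequence[int],
    criteria: HBondCriteria = HBondCriteria(),
) -> set[tuple[int, int, int]]:
    """Hydrogen bonds in one frame as (donor, hydrogen, acceptor) index triples.

    A bond requires donor–acceptor distance ≤ cutoff and the angle at the
    donor between the D→H and D→A directions ≤ the angle cutoff.  Every donor
    must have a covalently attached hydrogen listed in ``donor_hydrogens``.
    """
    frame = np.asarray(frame, dtype=float)
    bonds: set[tuple[int, int, int]] = set()
    for d in donors:
        if d not in donor_hydrogens or not donor_hydrogens[d]:
            raise ValidationError(f"donor atom {d} has no attached hydrogen listed")
        for a in acceptors:
            if a == d:
                continue
            da = frame[a] - frame[d]
            r_da = np.linalg.norm(da)
            if r_da > criteria.distance_cutoff or r_da == 0:
                continue
            for h in donor_hydrogens[d]:
                dh = frame[h] - frame[d]
                norm = np.linalg.norm(dh) * r_da
                if norm == 0:
                    continue
                cosang = np.clip(np.dot(dh, da) / norm, -1.0, 1.0)
                if np.degrees(np.arccos(cosang)) <= criteria.angle_cutoff:
                    bonds.add((d, h, a))
    return bonds


def infer_donor_hydrogens(
    system: MolecularSystem,
    frame: np.ndarray,
    residues: Iterable[ResidueKey] | None = None,
    bond_cutoff: float = 0.115,
) -> tuple[list[int], dict[int, list[int]], list[int]]:
    """Polar donors/acceptors inferred from geometry.

    N and O atoms are acceptor candidates; those with a hydrogen within
    ``bond_cutoff`` nm (a covalent N–H/O–H length) in the given frame are
    donors.  Returns (donors, donor→hydrogens, acceptors), restricted to
    ``residues`` when given.
    """
    frame = np.asarray(frame, dtype=float)
    if residues is None:
        atom_pool = range(system.n_atoms)
    else:
        atom_pool = np.concatenate(
            [system.residue_atom_indices(k) for k in residues]
        ).tolist()
    polar = [i for i in atom_pool if system.atoms[i].element.upper() in ("N", "O")]
    hydrogens = [i for i in atom_pool if system.atoms[i].element.upper() == "H"]
    donors: list[int] = []
    mapping: dict[int, list[int]] = {}
    for p in polar:
        attached = [
            h for h in hydrogens if np.linalg.norm(frame[h] - frame[p]) <= bond_cutoff
        ]
        if attached:
            donors.append(p)
            mapping[p] = attached
    return donors, mapping, polar


def hbond_occupancy(
    pair: tuple[ResidueKey, ResidueKey],
    trajectories: Sequence[Trajectory],
    criteria: HBondCriteria = HBondCriteria(),
) -> float:
    """Fraction of pooled frames with ≥1 qualifying bond between two residues.

    Any donor/acceptor combination between the residue pair counts, in either
    direction; frames of all replicas are pooled with equal weight per frame.
    """
    res_a, res_b = pair
    total_frames = 0
    bonded_frames = 0
    for traj in trajectories:
        system = traj.system
        try:
            idx_a = system.residue_atom_indices(res_a)
            idx_b = system.residue_atom_indices(res_b)
        except KeyError as exc:
            raise ValidationError(str(exc)) from exc
        donors, mapping, polar = infer_donor_hydrogens(
            system, traj.coordinates[0], residues=[res_a, res_b]
        )
        set_a, set_b = set(idx_a.tolist()), set(idx_b.tolist())
        if not polar:
            raise ValidationError(
                f"no polar atoms found for residue pair {res_a}–{res_b}"
            )
        for frame in traj.coordinates:
            bonds = detect_hbonds(frame, donors, mapping, polar, criteria)
            hit = any(
                (d in set_a and a in set_b) or (d in set_b and a in set_a)
                for d, _, a in bonds
            )
            bonded_frames += hit
            total_frames += 1
    if total_frames == 0:
        raise ValidationError("no frames supplied")
    return bonded_frames / total_frames
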