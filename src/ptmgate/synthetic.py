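"""Synthetic ensembles with known ground truth for every analysis stage.

Real trajectory ensembles are expensive to produce; the analyses in this
package are validated instead on generated data whose true parameters are
known exactly:

* Gaussian positional fluctuations around a reference structure with a
  prescribed residue–residue correlation structure (the target DCCM is known
  analytically because per-residue couplings are expanded isotropically to
  the three Cartesian components).
* Two-state/three-state Markov gate-distance dynamics with band-specific
  means, whose stationary occupancies are the analytic left eigenvector of
  the transition matrix.
* Hydrogen-bond geometries toggled frame by frame.
* Forward/reverse alchemical work samples from the Gaussian pair
  W_F ~ N(dG + s²/2, s²), W_R ~ N(−dG + s²/2, s²), which satisfies the
  Crooks fluctuation relation P_F(W) = P_R(−W) exp(W − dG) exactly (kT = 1).

Every generator is reproducible: the same seed gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .correlation import coupling_fractions, DCCMatrix
from .free_energy import WorkSamples
from .model_io import (
    Atom,
    MolecularSystem,
    StatePair,
    Trajectory,
    ValidationError,
    write_topology,
    write_trajectory,
)

__all__ = [
    "CorrelationRecipe",
    "FluctuationModel",
    "GateProcess",
    "WorkSamples",
    "make_synthetic_system",
    "make_reference_structure",
    "sample_fluctuation_trajectory",
    "sample_gate_series",
    "embed_gate_in_structure",
    "sample_crooks_work",
    "make_state_pair_fixture",
    "write_fixture_bundle",
]


@dataclass
class CorrelationRecipe:
    """Residue-level fluctuation recipe: per-residue spread and pair couplings.

    ``sd`` is the standard deviation (nm) of each Cartesian component of a
    residue's displacement; ``correlations`` maps 0-based residue-position
    pairs to target correlation coefficients, applied identically to x, y and
    z so the expected DCCM entry equals the recipe value.
    """

    n_residues: int
    sd: float | np.ndarray = 0.05
    correlations: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValidationError("need at least one residue")
        for (i, j), rho in self.correlations.items():
            if not -1.0 <= rho <= 1.0:
                raise ValidationError(f"correlation ({i},{j})={rho} outside [-1, 1]")
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues) or i == j:
                raise ValidationError(f"bad correlation pair ({i},{j})")

    def correlation_matrix(self) -> np.ndarray:
        r = np.eye(self.n_residues)
        for (i, j), rho in self.correlations.items():
            r[i, j] = r[j, i] = rho
        return r

    def residue_covariance(self) -> np.ndarray:
        sd = np.broadcast_to(np.asarray(self.sd, dtype=float), (self.n_residues,))
        cov = self.correlation_matrix() * np.outer(sd, sd)
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValidationError("recipe correlation matrix is not positive semi-definite")
        return cov

    def perturbed(self, changes: dict[tuple[int, int], float]) -> "CorrelationRecipe":
        """A copy with some pair couplings replaced."""
        merged = dict(self.correlations)
        for (i, j), rho in changes.items():
            merged[(min(i, j), max(i, j))] = rho
        return replace(self, correlations=merged)


@dataclass
class FluctuationModel:
    """Gaussian fluctuation generator around a reference structure.

    Either a residue-level ``recipe`` (expanded isotropically to 3D) or a
    full ``covariance`` over the 3m flattened residue coordinates (nm²).
    Displacements are applied rigidly to every atom of a residue, so Cα-based
    statistics see exactly the recipe's correlation structure.  ``ar1``
    introduces optional frame memory (default off: frames are i.i.d.).
    """

    system: MolecularSystem
    reference: np.ndarray  # (n_atoms, 3) nm
    recipe: CorrelationRecipe | None = None
    covariance: np.ndarray | None = None
    seed: int = 0
    ar1: float = 0.0

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.shape != (self.system.n_atoms, 3):
            raise ValidationError("reference shape must be (n_atoms, 3)")
        if (self.recipe is None) == (self.covariance is None):
            raise ValidationError("give exactly one of recipe or covariance")
        if not -1.0 < self.ar1 < 1.0:
            raise ValidationError("ar1 coefficient must be in (-1, 1)")
        if self.recipe is not None and self.recipe.n_residues != self.system.n_residues:
            raise ValidationError("recipe residue count does not match system")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            m = self.system.n_residues
            if cov.shape != (3 * m, 3 * m):
                raise ValidationError("covariance must be (3m, 3m) over residues")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValidationError("covariance must be symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-10:
                raise ValidationError("covariance is not positive semi-definite")
            self.covariance = cov


def _psd_sampler(cov: np.ndarray):
    """Return draw(rng, n) -> (n, dim) samples from N(0, cov), PSD-safe."""
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)

    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        z = rng.standard_normal((n, cov.shape[0]))
        return z @ root.T

    return draw


def sample_fluctuation_trajectory(
    model: FluctuationModel, n_frames: int
) -> Trajectory:
    """Draw frames reference + δ with δ ~ N(0, target covariance)."""
    if n_frames < 2:
        raise ValidationError("need at least 2 frames")
    rng = np.random.default_rng(model.seed)
    m = model.system.n_residues
    if model.recipe is not None:
        cov = model.recipe.residue_covariance()
        draw = _psd_sampler(cov)
        # independent x/y/z draws with the same residue coupling
        disp = np.stack([draw(rng, n_frames) for _ in range(3)], axis=2)  # (f, m, 3)
    else:
        draw = _psd_sampler(model.covariance)
        disp = draw(rng, n_frames).reshape(n_frames, m, 3)
    if model.ar1:
        phi = model.ar1
        scale = np.sqrt(1.0 - phi**2)
        out = np.empty_like(disp)
        out[0] = disp[0]
        for t in range(1, n_frames):
            out[t] = phi * out[t - 1] + scale * disp[t]
        disp = out
    coords = np.repeat(model.reference[None], n_frames, axis=0)
    for r, key in enumerate(model.system.residues):
        idx = model.system.residue_atom_indices(key)
        coords[:, idx, :] += disp[:, r, None, :]
    return Trajectory(system=model.system, coordinates=coords)


# ---------------------------------------------------------------------------
# Gate dynamics
# ---------------------------------------------------------------------------

@dataclass
class GateProcess:
    """First-order Markov gate-distance process with Gaussian emission bands."""

    means: tuple[float, ...]  # nm, one per state
    sds: tuple[float, ...]  # nm
    transition: np.ndarray  # row-stochastic (k, k)
    n_frames: int
    seed: int = 0
    state_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        k = len(self.means)
        if len(self.sds) != k or self.transition.shape != (k, k):
            raise ValidationError("means, sds and transition sizes disagree")
        if np.any(np.asarray(self.sds) < 0):
            raise ValidationError("state sds must be non-negative")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValidationError("transition matrix rows must sum to 1")
        if np.any(self.transition < 0):
            raise ValidationError("transition probabilities must be non-negative")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        w, v = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def sample_gate_series(process: GateProcess) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the hidden Markov path and its emitted distances.

    The initial state is drawn from the stationary distribution so finite
    chains are unbiased estimates of stationary occupancies.  Returns the
    distance series (nm) and the hidden state labels.
    """
    rng = np.random.default_rng(process.seed)
    k = len(process.means)
    pi = process.stationary_distribution()
    cum = np.cumsum(process.transition, axis=1)
    states = np.empty(process.n_frames, dtype=int)
    states[0] = rng.choice(k, p=pi)
    u = rng.random(process.n_frames)
    for t in range(1, process.n_frames):
        states[t] = min(np.searchsorted(cum[states[t - 1]], u[t]), k - 1)
    means = np.asarray(process.means)[states]
    sds = np.asarray(process.sds)[states]
    series = means + sds * rng.standard_normal(process.n_frames)
    return series, states


def embed_gate_in_structure(
    trajectory: Trajectory,
    gate_pair: tuple[int, int],
    series: np.ndarray,
) -> Trajectory:
    """Impose an exact per-frame separation on a designated atom pair.

    The second atom of the pair is moved along the existing pair direction so
    that its distance to the first equals the series value; all other atoms
    are untouched.
    """
    a, b = gate_pair
    if a == b:
        raise ValidationError("gate pair atoms must be distinct")
    series = np.asarray(series, dtype=float)
    if series.shape != (trajectory.n_frames,):
        raise ValidationError("series length must equal frame count")
    coords = trajectory.coordinates.copy()
    vec = coords[:, b] - coords[:, a]
    norm = np.linalg.norm(vec, axis=1, keepdims=True)
    unit = np.where(norm > 0, vec / np.where(norm == 0, 1.0, norm), [0.0, 0.0, 1.0])
    coords[:, b] = coords[:, a] + unit * series[:, None]
    return Trajectory(
        system=trajectory.system,
        coordinates=coords,
        frame_times=trajectory.frame_times,
    )


# ---------------------------------------------------------------------------
# Alchemical work samples
# ---------------------------------------------------------------------------

def sample_crooks_work(
    true_dg: float,
    sigma: float,
    n_forward: int,
    n_reverse: int,
    seed: int = 0,
) -> WorkSamples:
    """Gaussian work pair satisfying the Crooks relation with known ΔG (kT units)."""
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    if n_forward <= 0 or n_reverse <= 0:
        raise ValidationError("sample counts must be positive")
    rng = np.random.default_rng(seed)
    forward = true_dg + sigma**2 / 2.0 + sigma * rng.standard_normal(n_forward)
    reverse = -true_dg + sigma**2 / 2.0 + sigma * rng.standard_normal(n_reverse)
    return WorkSamples(forward=forward, reverse=reverse, true_dg=true_dg)


# ---------------------------------------------------------------------------
# Systems, reference structures, state-pair fixtures
# ---------------------------------------------------------------------------

def make_synthetic_system(
    n_residues: int,
    chain: str = "A",
    resnames: dict[int, str] | None = None,
    extra_atoms: dict[int, list[tuple[str, str]]] | None = None,
    selections: dict | None = None,
) -> MolecularSystem:
    """A coarse system: one Cα per residue plus optional named extra atoms.

    ``resnames`` overrides the default GLY per 1-based residue index;
    ``extra_atoms`` maps a residue index to (atom name, element) pairs, used
    to give gate residues side-chain atoms or H-bond donors/acceptors.
    """
    resnames = resnames or {}
    extra_atoms = extra_atoms or {}
    atoms: list[Atom] = []
    atom_id = 1
    for resid in range(1, n_residues + 1):
        resname = resnames.get(resid, "GLY")
        atoms.append(
            Atom(
                atom_id=atom_id, name="CA", element="C",
                residue_index=resid, residue_name=resname, chain_id=chain,
                mass=12.011,
            )
        )
        atom_id += 1
        for name, element in extra_atoms.get(resid, []):
            atoms.append(
                Atom(
                    atom_id=atom_id, name=name, element=element,
                    residue_index=resid, residue_name=resname, chain_id=chain,
                    mass={"H": 1.008, "N": 14.007, "O": 15.999}.get(element, 12.011),
                )
            )
            atom_id += 1
    selections = dict(selections or {})
    selections.setdefault("all", list(range(1, n_residues + 1)))
    return MolecularSystem(atoms, selections)


def make_reference_structure(
    system: MolecularSystem, seed: int = 0, spacing: float = 0.38
) -> np.ndarray:
    """A compact, non-collinear backbone curve with jitter (nm).

    Residue Cα positions follow a helical curve at the given spacing; extra
    atoms of a residue sit at small fixed offsets from its Cα.
    """
    rng = np.random.default_rng(seed)
    coords = np.zeros((system.n_atoms, 3))
    turn = 2.0 * np.pi / 3.6
    radius = 0.23
    rise = spacing * 0.42
    for r, key in enumerate(system.residues):
        base = np.array(
            [radius * np.cos(turn * r), radius * np.sin(turn * r), rise * r]
        ) + 0.02 * rng.standard_normal(3)
        for k, idx in enumerate(system.residue_atom_indices(key)):
            offset = np.zeros(3) if k == 0 else 0.12 * _unit_offset(k)
            coords[idx] = base + offset
    return coords


def _unit_offset(k: int) -> np.ndarray:
    directions = np.array(
        [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=float
    )
    d = directions[(k - 1) % len(directions)]
    return d / np.linalg.norm(d)


def _recipe_directional(recipe: CorrelationRecipe, threshold: float) -> np.ndarray:
    matrix = DCCMatrix(
        labels=list(range(recipe.n_residues)),
        values=recipe.correlation_matrix(),
        zero_fluctuation=[],
    )
    return coupling_fractions(matrix, threshold).directional


def make_state_pair_fixture(
    base: CorrelationRecipe,
    perturbation: dict[tuple[int, int], float],
    n_frames: int,
    seed: int = 0,
    n_replicas: int = 1,
) -> tuple[StatePair, dict]:
    """A reduced/PTM StatePair with analytically known redistribution truth.

    The reduced state samples the base recipe, the PTM state the perturbed
    one; the ground truth holds the expected per-residue redistribution score
    computed directly on the two generative correlation matrices (threshold
    0.2), plus its sign map.
    """
    perturbed = base.perturbed(perturbation)
    if perturbed.n_residues != base.n_residues:
        raise ValidationError("perturbation must preserve the residue set")
    system = make_synthetic_system(base.n_residues)
    reference = make_reference_structure(system, seed=seed)
    reduced, ptm = [], []
    for rep in range(n_replicas):
        model_r = FluctuationModel(
            system=system, reference=reference, recipe=base, seed=seed + 1000 + rep
        )
        model_p = FluctuationModel(
            system=system, reference=reference, recipe=perturbed,
            seed=seed + 2000 + rep,
        )
        reduced.append(sample_fluctuation_trajectory(model_r, n_frames))
        ptm.append(sample_fluctuation_trajectory(model_p, n_frames))
    pair = StatePair(reduced=reduced, ptm=ptm, selection="all")
    threshold = 0.2
    expected = _recipe_directional(perturbed, threshold) - _recipe_directional(
        base, threshold
    )
    truth = {
        "threshold": threshold,
        "expected_score": expected.tolist(),
        "sign": np.sign(expected).astype(int).tolist(),
        "perturbed_residues": sorted(
            {i for pair_ in perturbation for i in pair_}
        ),
    }
    return pair, truth


def write_fixture_bundle(
    directory: str | Path,
    base: CorrelationRecipe,
    perturbation: dict[tuple[int, int], float],
    n_frames: int = 200,
    n_replicas: int = 2,
    seed: int = 0,
) -> dict:
    """Write a CLI-consumable fixture: topology TSV, multi-model PDBs, truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pair, truth = make_state_pair_fixture(
        base, perturbation, n_frames=n_frames, seed=seed, n_replicas=n_replicas
    )
    system = pair.reduced[0].system
    write_topology(system, directory / "topology.tsv")
    paths: dict[str, list[str]] = {"reduced": [], "ptm": []}
    for state, trajs in (("reduced", pair.reduced), ("ptm", pair.ptm)):
        for i, traj in enumerate(trajs):
            name = f"{state}_rep{i}.pdb"
            write_trajectory(traj, directory / name)
            paths[state].append(name)
    truth_full = {
        "seed": seed,
        "n_frames": n_frames,
        "n_replicas": n_replicas,
        "n_residues": base.n_residues,
        "base_correlations": {f"{i},{j}": v for (i, j), v in base.correlations.items()},
        "perturbation": {f"{i},{j}": v for (i, j), v in perturbation.items()},
        **truth,
    }
    (directory / "ground_truth.json").write_text(json.dumps(truth_full, indent=1))
    (directory / "manifest.json").write_text(
        json.dumps({"topology": "topology.tsv", "trajectories": paths}, indent=1)
    )
    return truth_full
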