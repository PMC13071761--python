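"""Topology and trajectory data model, file I/O, and simulation-plan enumeration.

The in-memory containers used throughout the package:

* :class:`MolecularSystem` — atoms with residue/chain assignment, partial
  charges, Lennard-Jones parameters and masses, plus named residue selections.
* :class:`Trajectory` — a ``(n_frames, n_atoms, 3)`` coordinate array in nm
  tied to one system.
* :class:`StatePair` — matched reduced / PTM-modified replica sets, the unit
  of every comparative analysis.

Units are nm for lengths and kcal/mol for energies everywhere inside the
package; Ångström appears only at the PDB/XYZ file boundary.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "MolecularSystem",
    "Trajectory",
    "StatePair",
    "SystemSpec",
    "TIWindow",
    "PTM_TYPES",
    "DEFAULT_LAMBDA_SCHEDULE",
    "DEFAULT_STAGES",
    "TopologyFormatError",
    "ValidationError",
    "load_topology",
    "write_topology",
    "load_trajectory",
    "write_trajectory",
    "enumerate_ptm_systems",
    "enumerate_ti_windows",
]


class TopologyFormatError(ValueError):
    """A topology stream is syntactically unusable (e.g. missing column)."""


class ValidationError(ValueError):
    """Parsed data violates a model invariant (e.g. duplicate atom id)."""


#: PTM types supported by the experiment-plan enumeration and SystemSpec.
PTM_TYPES = ("reduced", "sulfenylated", "nitrosylated", "glutathionylated", "disulfide")

#: The 13-value coupling-parameter schedule used per decoupling stage.
DEFAULT_LAMBDA_SCHEDULE = (
    0.00, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 0.95, 1.00,
)

#: Electrostatics are decoupled first, then van der Waals / masses / bonded terms.
DEFAULT_STAGES = ("electrostatics", "vdw_bonded")

_TOPOLOGY_COLUMNS = (
    "atom_id", "name", "element", "chain", "resid", "resname",
    "charge", "sigma_nm", "epsilon_kcal", "mass",
)


@dataclass(frozen=True)
class Atom:
    """One atom with force-field parameters.

    ``charge`` in elementary-charge units, ``lj_sigma`` in nm, ``lj_epsilon``
    in kcal/mol, ``mass`` in Da. ``residue_index`` is 1-based and mirrors the
    source topology (no renumbering on load).
    """

    atom_id: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.atom_id < 1:
            raise ValidationError(f"atom_id must be >= 1, got {self.atom_id}")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValidationError(
                f"atom {self.atom_id}: LJ parameters must be non-negative"
            )
        if not self.mass > 0:
            raise ValidationError(f"atom {self.atom_id}: mass must be positive")
        if not np.isfinite(self.charge):
            raise ValidationError(f"atom {self.atom_id}: charge must be finite")


ResidueKey = tuple[str, int]  # (chain_id, residue_index)


class MolecularSystem:
    """An ordered atom list with residue lookup tables and named selections.

    Selections map a label to a set of residues.  A selection entry may be a
    plain residue index (resolved in every chain that has it — convenient for
    single-chain systems and for concatenated global numbering) or a
    ``"chain:resid"`` string for chain-local addressing; both conventions are
    supported because complexes are sometimes numbered per chain and sometimes
    straight through.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        selections: dict[str, Iterable[int | str]] | None = None,
    ) -> None:
        if not atoms:
            raise ValidationError("a MolecularSystem needs at least one atom")
        ids = [a.atom_id for a in atoms]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate atom_id(s): {dupes}")
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        self._residue_atoms: dict[ResidueKey, list[int]] = {}
        for idx, atom in enumerate(self.atoms):
            self._residue_atoms.setdefault(
                (atom.chain_id, atom.residue_index), []
            ).append(idx)
        self._residue_table = {
            key: np.asarray(v, dtype=int) for key, v in self._residue_atoms.items()
        }
        self.selections: dict[str, tuple[ResidueKey, ...]] = {}
        for label, entries in (selections or {}).items():
            self.selections[label] = tuple(self._resolve_entries(label, entries))

    # -- basic queries ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> list[ResidueKey]:
        """Residue keys in first-appearance order."""
        return list(self._residue_table)

    @property
    def n_residues(self) -> int:
        return len(self._residue_table)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.chain_id)
        return list(seen)

    def residue_name(self, key: ResidueKey) -> str:
        return self.atoms[self._residue_table[key][0]].residue_name

    def residue_atom_indices(self, key: ResidueKey) -> np.ndarray:
        """0-based atom indices of one residue."""
        try:
            return self._residue_table[key]
        except KeyError:
            raise KeyError(f"residue {key[1]} in chain {key[0]!r} not in system") from None

    def atom_index(self, chain_id: str, residue_index: int, name: str) -> int:
        for idx in self.residue_atom_indices((chain_id, residue_index)):
            if self.atoms[idx].name == name:
                return idx
        raise KeyError(
            f"no atom named {name!r} in residue {residue_index} chain {chain_id!r}"
        )

    def ca_indices(self, residues: Sequence[ResidueKey] | None = None) -> np.ndarray:
        """0-based indices of Cα atoms, in residue order."""
        keys = self.residues if residues is None else list(residues)
        out = []
        for key in keys:
            for idx in self.residue_atom_indices(key):
                if self.atoms[idx].name == "CA":
                    out.append(idx)
                    break
            else:
                raise KeyError(f"residue {key} has no CA atom")
        return np.asarray(out, dtype=int)

    def cysteine_sites(self) -> list[ResidueKey]:
        return [k for k in self.residues if self.residue_name(k) == "CYS"]

    def masses(self) -> np.ndarray:
        return np.asarray([a.mass for a in self.atoms])

    def charges(self) -> np.ndarray:
        return np.asarray([a.charge for a in self.atoms])

    # -- selections -------------------------------------------------------
    def _resolve_entries(
        self, label: str, entries: Iterable[int | str]
    ) -> list[ResidueKey]:
        resolved: list[ResidueKey] = []
        for entry in entries:
            if isinstance(entry, str) and ":" in entry:
                chain, resid_s = entry.split(":", 1)
                key = (chain, int(resid_s))
                if key not in self._residue_table:
                    raise ValidationError(
                        f"selection {label!r}: residue {entry!r} not in system"
                    )
                resolved.append(key)
            else:
                resid = int(entry)
                hits = [k for k in self._residue_table if k[1] == resid]
                if not hits:
                    raise ValidationError(
                        f"selection {label!r}: residue index {resid} not in system"
                    )
                resolved.extend(hits)
        return resolved

    def select_residues(self, label: str) -> tuple[ResidueKey, ...]:
        try:
            return self.selections[label]
        except KeyError:
            raise KeyError(f"no selection named {label!r}") from None

    def selection_atom_indices(self, label: str) -> np.ndarray:
        keys = self.select_residues(label)
        return np.concatenate([self.residue_atom_indices(k) for k in keys])


@dataclass
class Trajectory:
    """Coordinate frames (nm) tied to one MolecularSystem."""

    system: MolecularSystem
    coordinates: np.ndarray  # (n_frames, n_atoms, 3) nm
    frame_times: np.ndarray | None = None  # ps, strictly increasing

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError(
                f"coordinates must be (n_frames, n_atoms, 3), got {self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != self.system.n_atoms:
            raise ValidationError(
                f"coordinate array has {self.coordinates.shape[1]} atoms but the "
                f"system has {self.system.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("non-finite coordinates")
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames, dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ValidationError("frame_times length must equal frame count")
            if np.any(np.diff(self.frame_times) <= 0):
                raise ValidationError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class StatePair:
    """Matched reduced / PTM-modified replica sets over one shared selection."""

    reduced: list[Trajectory]
    ptm: list[Trajectory]
    selection: str

    def __post_init__(self) -> None:
        if not self.reduced or not self.ptm:
            raise ValidationError("both states need at least one replica")
        counts = {
            len(t.system.selection_atom_indices(self.selection))
            for t in [*self.reduced, *self.ptm]
        }
        if len(counts) != 1:
            raise ValidationError(
                f"selection {self.selection!r} resolves to differing atom counts "
                f"across trajectories: {sorted(counts)}"
            )

    def all_trajectories(self) -> list[tuple[str, int, Trajectory]]:
        """(state, replica_index, trajectory) triples, reduced first."""
        out = [("reduced", i, t) for i, t in enumerate(self.reduced)]
        out += [("ptm", i, t) for i, t in enumerate(self.ptm)]
        return out


@dataclass(frozen=True)
class SystemSpec:
    """One simulated case: a PTM site (or pair, for a disulfide) and replica."""

    ptm_type: str
    site: int | tuple[int, int] | None = None
    replica: int = 1

    def __post_init__(self) -> None:
        if self.ptm_type not in PTM_TYPES:
            raise ValidationError(f"unknown ptm_type {self.ptm_type!r}")
        if self.replica < 1:
            raise ValidationError("replica must be >= 1")
        if self.ptm_type == "reduced":
            if self.site is not None:
                raise ValidationError("a reduced baseline has no PTM site")
        elif self.ptm_type == "disulfide":
            if (
                not isinstance(self.site, tuple)
                or len(self.site) != 2
                or self.site[0] == self.site[1]
            ):
                raise ValidationError("a disulfide needs a pair of distinct sites")
        else:
            if not isinstance(self.site, int):
                raise ValidationError(f"{self.ptm_type} needs a single residue site")


@dataclass(frozen=True)
class TIWindow:
    """One λ state of a two-stage alchemical decoupling schedule."""

    stage: str
    lambda_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_value <= 1.0:
            raise ValidationError(f"lambda must be in [0, 1], got {self.lambda_value}")


# ---------------------------------------------------------------------------
# Topology I/O
# ---------------------------------------------------------------------------

def load_topology(source) -> MolecularSystem:
    """Read a topology table (TSV or JSON) into a MolecularSystem.

    TSV needs the header columns ``atom_id name element chain resid resname
    charge sigma_nm epsilon_kcal mass``; JSON is ``{"atoms": [...],
    "selections": {label: [resid, ...]}}`` with the same per-atom keys.
    A sibling ``<name>.selections.json`` next to a TSV path is picked up
    automatically.
    """
    selections: dict | None = None
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        if path.suffix != ".json":
            sidecar = path.with_suffix(".selections.json")
            if sidecar.exists():
                selections = json.loads(sidecar.read_text())
    elif hasattr(source, "read"):
        text = source.read()
    else:
        raise TypeError("source must be a path or a text stream")

    stripped = text.lstrip()
    if stripped.startswith("{"):
        payload = json.loads(text)
        rows = payload.get("atoms")
        if rows is None:
            raise TopologyFormatError("JSON topology is missing the 'atoms' key")
        frame = pd.DataFrame(rows)
        selections = payload.get("selections", selections)
    else:
        frame = pd.read_csv(_io.StringIO(text), sep="\t")

    missing = [c for c in _TOPOLOGY_COLUMNS if c not in frame.columns]
    if missing:
        raise TopologyFormatError(f"topology is missing column(s): {missing}")

    atoms = [
        Atom(
            atom_id=int(row.atom_id),
            name=str(row.name_),
            element=str(row.element),
            residue_index=int(row.resid),
            residue_name=str(row.resname),
            chain_id=str(row.chain),
            charge=float(row.charge),
            lj_sigma=float(row.sigma_nm),
            lj_epsilon=float(row.epsilon_kcal),
            mass=float(row.mass),
        )
        for row in frame.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    return MolecularSystem(atoms, selections)


def write_topology(system: MolecularSystem, path: str | Path) -> None:
    """Write the TSV form (and a selections sidecar if any selections exist)."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "atom_id": [a.atom_id for a in system.atoms],
            "name": [a.name for a in system.atoms],
            "element": [a.element for a in system.atoms],
            "chain": [a.chain_id for a in system.atoms],
            "resid": [a.residue_index for a in system.atoms],
            "resname": [a.residue_name for a in system.atoms],
            "charge": [a.charge for a in system.atoms],
            "sigma_nm": [a.lj_sigma for a in system.atoms],
            "epsilon_kcal": [a.lj_epsilon for a in system.atoms],
            "mass": [a.mass for a in system.atoms],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
    if system.selections:
        sidecar = path.with_suffix(".selections.json")
        payload = {
            label: [f"{c}:{r}" for c, r in keys]
            for label, keys in system.selections.items()
        }
        sidecar.write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Trajectory I/O (multi-model PDB is the canonical interchange; XYZ optional)
# ---------------------------------------------------------------------------

def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        return "pdb"
    if suffix == ".xyz":
        return "xyz"
    raise ValueError(f"cannot infer trajectory format from {path.name!r}")


def load_trajectory(
    source: str | Path,
    system: MolecularSystem,
    fmt: str | None = None,
) -> Trajectory:
    """Read a multi-model PDB or XYZ file; Å in the file become nm in memory."""
    path = Path(source)
    fmt = _detect_format(path, fmt)
    if fmt == "pdb":
        pdb = PDBFile.read(str(path))
        coords_ang = pdb.get_coord(model=None)  # (models, atoms, 3) Å
        if coords_ang.ndim == 2:
            coords_ang = coords_ang[None]
    elif fmt == "xyz":
        coords_ang = _read_xyz(path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    if coords_ang.shape[0] == 0:
        raise ValidationError(f"{path.name}: no frames found")
    for i, frame in enumerate(coords_ang):
        if frame.shape[0] != system.n_atoms:
            raise ValidationError(
                f"{path.name}: frame {i} has {frame.shape[0]} atoms, "
                f"system has {system.n_atoms}"
            )
    return Trajectory(system=system, coordinates=np.asarray(coords_ang) / 10.0)


def write_trajectory(
    trajectory: Trajectory, path: str | Path, fmt: str | None = None
) -> None:
    """Write nm coordinates as an Å multi-model PDB or XYZ file."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    coords_ang = trajectory.coordinates * 10.0
    system = trajectory.system
    if fmt == "pdb":
        atoms = bst.AtomArray(system.n_atoms)
        atoms.chain_id = np.array([a.chain_id for a in system.atoms])
        atoms.res_id = np.array([a.residue_index for a in system.atoms])
        atoms.res_name = np.array([a.residue_name for a in system.atoms])
        atoms.atom_name = np.array([a.name for a in system.atoms])
        atoms.element = np.array([a.element.upper() for a in system.atoms])
        atoms.hetero = np.zeros(system.n_atoms, dtype=bool)
        stack = bst.from_template(atoms, coords_ang.astype(np.float32))
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    elif fmt == "xyz":
        _write_xyz(path, coords_ang, [a.element for a in system.atoms])
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def _read_xyz(path: Path) -> np.ndarray:
    """Parse a (possibly multi-frame) XYZ file into an (frames, atoms, 3) Å array."""
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValidationError(
                f"{path.name}: expected an atom count at line {pos + 1}"
            ) from exc
        block = lines[pos + 2 : pos + 2 + n_atoms]
        if len(block) < n_atoms:
            raise ValidationError(f"{path.name}: truncated frame at line {pos + 1}")
        coords = np.array(
            [[float(x) for x in line.split()[1:4]] for line in block]
        )
        frames.append(coords)
        pos += 2 + n_atoms
    if not frames:
        raise ValidationError(f"{path.name}: no frames found")
    return np.stack(frames)


def _write_xyz(path: Path, coords_ang: np.ndarray, elements: list[str]) -> None:
    with open(path, "w") as fh:
        for i, frame in enumerate(coords_ang):
            fh.write(f"{len(elements)}\nframe {i}\n")
            for element, (x, y, z) in zip(elements, frame):
                fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Experiment-plan enumeration
# ---------------------------------------------------------------------------

def enumerate_ptm_systems(
    system: MolecularSystem,
    ptm_types: Iterable[str],
    replicas: int = 1,
) -> list[SystemSpec]:
    """Enumerate the per-site PTM simulation plan.

    One spec per (cysteine site × PTM type) plus one fully reduced baseline,
    each expanded into ``replicas`` copies; replicas expand last, so the
    baseline counts as one system.  With 11 cysteines, 3 PTM types and one
    replica this yields the 34-system plan; with 3 replicas, 102 cases.
    """
    types = [t for t in dict.fromkeys(ptm_types)]
    if not types:
        raise ValidationError("ptm_types must be non-empty")
    for t in types:
        if t not in PTM_TYPES:
            raise ValidationError(f"unsupported ptm_type {t!r}")
        if t == "disulfide":
            raise ValidationError(
                "disulfide systems need explicit residue pairs and are not "
                "enumerated per single site"
            )
    if replicas < 1:
        raise ValidationError("replicas must be >= 1")
    sites = [resid for _, resid in system.cysteine_sites()]
    if not sites:
        warnings.warn(
            "system has no cysteines: plan contains the reduced baseline only",
            stacklevel=2,
        )
    systems: list[SystemSpec] = [SystemSpec(ptm_type="reduced")]
    for site in sites:
        for ptm_type in types:
            if ptm_type == "reduced":
                continue
            systems.append(SystemSpec(ptm_type=ptm_type, site=site))
    plan: list[SystemSpec] = []
    for spec in systems:
        for replica in range(1, replicas + 1):
            plan.append(
                SystemSpec(ptm_type=spec.ptm_type, site=spec.site, replica=replica)
            )
    return plan


def enumerate_ti_windows(
    schedule: Sequence[float] = DEFAULT_LAMBDA_SCHEDULE,
    stages: Sequence[str] = DEFAULT_STAGES,
) -> list[TIWindow]:
    """Expand a λ schedule across decoupling stages (electrostatics first).

    The default schedule is the 13-window ladder 0.00, 0.05, 0.10, then steps
    of 0.10 up to 0.90, 0.95, 1.00 — 26 windows over the two stages.
    """
    schedule = list(schedule)
    if not schedule or schedule[0] != 0.0 or schedule[-1] != 1.0:
        raise ValidationError("schedule must start at 0.0 and end at 1.0")
    if np.any(np.diff(schedule) <= 0):
        raise ValidationError("schedule must be strictly increasing")
    if not stages:
        raise ValidationError("at least one stage required")
    return [
        TIWindow(stage=stage, lambda_value=float(lam))
        for stage in stages
        for lam in schedule
    ]
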