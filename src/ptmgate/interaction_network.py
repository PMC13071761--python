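"""Residue–residue nonbonded energies and layered allosteric flow graphs.

Pair energies are direct frame-averaged sums over all atom pairs between two
residues: Coulomb with a uniform dielectric, k_e q_a q_b / (eps r), plus
Lennard-Jones 12-6 with Lorentz–Berthelot combination rules.  Pairs whose
mean total energy exceeds ±10 kcal/mol (strictly) are "strong" interactions;
strong edges linking regulator regions, intermediate enzyme residues, and
gate residues are assembled into a layered flow graph per gate state, with
edges categorised by the charge character of the partners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .model_io import MolecularSystem, ResidueKey, Trajectory, ValidationError

__all__ = [
    "PairEnergy",
    "COULOMB_CONSTANT",
    "NEGATIVE_RESIDUES",
    "POSITIVE_RESIDUES",
    "pair_nonbonded_energy",
    "strong_interactions",
    "classify_edge",
    "build_flow_graph",
    "write_graphml",
    "write_flow_json",
]

#: Coulomb constant in kcal·Å / (mol·e²).
COULOMB_CONSTANT = 332.0636

NEGATIVE_RESIDUES = frozenset({"ASP", "GLU"})
POSITIVE_RESIDUES = frozenset({"ARG", "LYS"})


@dataclass
class PairEnergy:
    """Frame-averaged nonbonded interaction between two residues (kcal/mol)."""

    residue_i: ResidueKey
    residue_j: ResidueKey
    resname_i: str
    resname_j: str
    coulomb: float
    lj: float
    n_frames: int

    @property
    def total(self) -> float:
        return self.coulomb + self.lj


def pair_nonbonded_energy(
    system: MolecularSystem,
    trajectories: Sequence[Trajectory],
    residue_i: ResidueKey,
    residue_j: ResidueKey,
    dielectric: float = 1.0,
    cutoff: float | None = None,
) -> PairEnergy:
    """Mean Coulomb + LJ energy between two residues over pooled frames.

    All atom pairs between the residues are summed (inter-residue pairs have
    no bonded exclusions).  ``cutoff`` (nm), when given, skips atom pairs
    beyond it; the default sums every pair.
    """
    if residue_i == residue_j:
        raise ValidationError("residues must be distinct")
    idx_i = system.residue_atom_indices(residue_i)
    idx_j = system.residue_atom_indices(residue_j)
    q = system.charges()
    sigma = np.asarray([a.lj_sigma for a in system.atoms])
    epsilon = np.asarray([a.lj_epsilon for a in system.atoms])

    qq = q[idx_i][:, None] * q[idx_j][None, :]
    sig_ab = 0.5 * (sigma[idx_i][:, None] + sigma[idx_j][None, :])
    eps_ab = np.sqrt(epsilon[idx_i][:, None] * epsilon[idx_j][None, :])

    coulomb_sum = 0.0
    lj_sum = 0.0
    n_frames = 0
    for traj in trajectories:
        if traj.system is not system and traj.system.n_atoms != system.n_atoms:
            raise ValidationError("trajectory does not match the system")
        for frame in traj.coordinates:
            diff = frame[idx_i][:, None, :] - frame[idx_j][None, :, :]
            r = np.linalg.norm(diff, axis=-1)  # nm
            if np.any(r == 0):
                raise ValidationError("coincident atoms between residue pair")
            mask = np.ones_like(r, dtype=bool) if cutoff is None else (r <= cutoff)
            coulomb_sum += float(
                np.sum((COULOMB_CONSTANT * qq / (dielectric * r * 10.0))[mask])
            )
            with np.errstate(divide="ignore"):
                sr6 = np.where(sig_ab > 0, (sig_ab / r) ** 6, 0.0)
            lj_sum += float(np.sum((4.0 * eps_ab * (sr6**2 - sr6))[mask]))
            n_frames += 1
    return PairEnergy(
        residue_i=residue_i,
        residue_j=residue_j,
        resname_i=system.residue_name(residue_i),
        resname_j=system.residue_name(residue_j),
        coulomb=coulomb_sum / n_frames,
        lj=lj_sum / n_frames,
        n_frames=n_frames,
    )


def strong_interactions(
    energies: Iterable[PairEnergy], threshold: float = 10.0
) -> list[PairEnergy]:
    """Keep pairs with |mean total energy| strictly above the threshold."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    return [e for e in energies if e.total > threshold or e.total < -threshold]


def classify_edge(
    resname_i: str, resname_j: str, his_positive: bool = False
) -> str:
    """Charge category of a residue pair.

    ``like_charged`` when both carry the same charge sign, ``oppositely_charged``
    for a salt-bridge-like pair, ``polar_charged`` when exactly one partner is
    charged, ``other`` when neither is.  Histidine counts as uncharged unless
    ``his_positive``.
    """
    positive = POSITIVE_RESIDUES | ({"HIS"} if his_positive else frozenset())

    def sign(name: str) -> int:
        name = name.upper()
        if name in NEGATIVE_RESIDUES:
            return -1
        if name in positive:
            return 1
        return 0

    s_i, s_j = sign(resname_i), sign(resname_j)
    if s_i and s_j:
        return "like_charged" if s_i == s_j else "oppositely_charged"
    if s_i or s_j:
        return "polar_charged"
    return "other"


def build_flow_graph(
    opca_regions: dict[str, Sequence[ResidueKey]],
    opca_g6pdh_edges: Sequence[PairEnergy],
    g6pdh_gate_edges: Sequence[PairEnergy],
    gate_residues: Sequence[ResidueKey],
    gate_state_by_subunit: dict[str, str],
    his_positive: bool = False,
) -> dict[str, nx.DiGraph]:
    """Layered regulator→intermediate→gate graphs grouped by gate state.

    Subunits are grouped into ``open_closed``, ``closed`` and ``open_wide``
    (open or wide_open) gate-state classes.  Within each group the
    intermediate layer holds enzyme residues that interact strongly with a
    gate residue of a subunit in the group — whether or not a regulator
    region also reaches them (limited-regulator-involvement paths keep their
    gate edge only).  Edge inputs are expected pre-filtered by
    :func:`strong_interactions`; every edge carries its mean energy and
    charge category.
    """
    gate_set = set(gate_residues)
    region_of: dict[ResidueKey, str] = {}
    for region, residues in opca_regions.items():
        for key in residues:
            region_of[key] = region
    for key in gate_set:
        if key[0] not in gate_state_by_subunit:
            raise ValidationError(
                f"gate residue {key} is in subunit {key[0]!r} with no gate state"
            )

    def group_of(state: str) -> str:
        if state == "open_closed":
            return "open_closed"
        if state == "closed":
            return "closed"
        return "open_wide"

    graphs = {
        name: nx.DiGraph(gate_state_group=name)
        for name in ("open_closed", "closed", "open_wide")
    }

    def node_id(key: ResidueKey) -> str:
        return f"{key[0]}:{key[1]}"

    # gate edges define the groups and the intermediate layer
    intermediates_by_group: dict[str, set[ResidueKey]] = {g: set() for g in graphs}
    for edge in g6pdh_gate_edges:
        if edge.residue_j in gate_set:
            inter, gate, iname, gname = (
                edge.residue_i, edge.residue_j, edge.resname_i, edge.resname_j,
            )
        elif edge.residue_i in gate_set:
            inter, gate, iname, gname = (
                edge.residue_j, edge.residue_i, edge.resname_j, edge.resname_i,
            )
        else:
            continue
        group = group_of(gate_state_by_subunit[gate[0]])
        graph = graphs[group]
        graph.add_node(node_id(inter), layer="g6pdh_intermediate", resname=iname)
        graph.add_node(node_id(gate), layer="gate", resname=gname)
        graph.add_edge(
            node_id(inter),
            node_id(gate),
            energy=edge.total,
            category=classify_edge(iname, gname, his_positive),
        )
        intermediates_by_group[group].add(inter)

    # regulator-region edges attach to intermediates already in a group
    for edge in opca_g6pdh_edges:
        if edge.residue_i in region_of:
            src, dst, sname, dname = (
                edge.residue_i, edge.residue_j, edge.resname_i, edge.resname_j,
            )
        elif edge.residue_j in region_of:
            src, dst, sname, dname = (
                edge.residue_j, edge.residue_i, edge.resname_j, edge.resname_i,
            )
        else:
            continue
        for group, intermediates in intermediates_by_group.items():
            if dst in intermediates:
                graph = graphs[group]
                graph.add_node(
                    node_id(src),
                    layer="opca_region",
                    resname=sname,
                    region=region_of[src],
                )
                graph.add_edge(
                    node_id(src),
                    node_id(dst),
                    energy=edge.total,
                    category=classify_edge(sname, dname, his_positive),
                )
    return {name: g for name, g in graphs.items() if g.number_of_edges() > 0}


def write_graphml(graphs: dict[str, nx.DiGraph], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, graph in graphs.items():
        nx.write_graphml(graph, directory / f"flow_{name}.graphml")


def write_flow_json(graphs: dict[str, nx.DiGraph], path: str | Path) -> None:
    """Layered JSON description: per group, nodes with layers and typed edges."""
    payload = {}
    for name, graph in graphs.items():
        payload[name] = {
            "nodes": [
                {"id": n, **graph.nodes[n]} for n in sorted(graph.nodes)
            ],
            "edges": [
                {"source": u, "target": v, **graph.edges[u, v]}
                for u, v in sorted(graph.edges)
            ],
        }
    Path(path).write_text(json.dumps(payload, indent=1))
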