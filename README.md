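# ptmgate

Comparative trajectory analysis of how redox post-translational modifications
(PTMs) on a regulatory protein reshape the dynamics of the enzyme it
controls.  The motivating system is the cyanobacterial OpcA–G6PDH complex:
OpcA is a redox-sensitive activator of glucose-6-phosphate dehydrogenase,
and thiol modifications of its cysteines (sulfenylation, S-nitrosylation,
S-glutathionylation, disulfides) tune a molecular *gate* at the G6PDH active
site between closed (< 0.4 nm), open (0.4–0.7 nm) and wide-open (> 0.7 nm)
conformations.

The package takes matched **reduced** and **PTM-modified** coordinate
ensembles (multi-model PDB or XYZ plus a TSV topology with charges and
Lennard-Jones parameters) and computes:

* per-residue RMSF and radius of gyration;
* dynamic cross-correlation matrices
  C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) and the per-residue
  **redistribution score** (f⁺−f⁻)_PTM − (f⁺−f⁻)_reduced at |C_ij| > 0.2;
* **common-eigenspace PCA**: one covariance from the concatenated, aligned
  Cα frames of both states, with per-state projections, centroid shifts,
  and top-50% per-residue mode contributions;
* gate-distance series, KDE-peak state classification, band occupancies,
  and geometric hydrogen-bond occupancy (D–A ≤ 0.35 nm, angle ≤ 30°);
* residue-pair nonbonded energies (Coulomb + Lennard-Jones,
  k_e = 332.0636 kcal·Å/(mol·e²)), strong-interaction selection at
  ±10 kcal/mol, and layered regulator → enzyme → gate flow graphs;
* **Bennett acceptance ratio** free energies per λ window, chained over the
  two-stage 13-window schedule, relative binding free energies
  (ΔΔG = ΔG_protein − ΔG_water) and per-PTM-type L1 summaries.

A synthetic-data module generates ensembles with analytic ground truth
(Gaussian fluctuations with prescribed residue–residue correlations, Markov
gate dynamics, toggled H-bond geometries, Crooks-consistent work samples),
so every stage is validated without running MD.  See `docs/methods.md` for
the models and numerical choices.

## Worked example

Generate a fixture in which the PTM flips one residue pair's coupling from
+0.6 to −0.6, then compare the two states:

```python
import json
from ptmgate.cli import run_simulate, run_compare, AnalysisConfig

truth = run_simulate(
    {"n_residues": 10, "sd": 0.05,
     "base_correlations": {"0,1": 0.6},
     "perturbation": {"0,1": -0.6},
     "n_frames": 120, "n_replicas": 2, "seed": 7},
    "fixture",
)
manifest = json.load(open("fixture/manifest.json"))
report = run_compare(AnalysisConfig(
    topology="fixture/topology.tsv",
    trajectories=manifest["trajectories"],
    output_dir="out",
))
print(report["redistribution"])
print(report["pca"]["variance_fractions"][:2])
```

prints

```
{'threshold': 0.2, 'mean_abs_score': 0.1111..., 'max_abs_score': 0.3333...}
[0.0587..., 0.0569...]
```

The two perturbed residues each lose their one strongly correlated partner
out of nine, so their expected redistribution score is −2/9 ≈ −0.22; at 240
frames per state the measured scores scatter around that (the fixture's
ground-truth JSON records the expected values exactly).  With
near-isotropic fluctuations no single collective mode dominates, so the
leading variance fractions stay small.  The same
pipeline runs from a shell:

```sh
ptmgate simulate --spec spec.json --out fixture/
ptmgate compare --config config.json
ptmgate free-energy --protein protein.csv --water water.csv --out fe.json
```

plus standalone `gate`, `pca`, `dccm` and `network` stage commands.

The enumeration helpers reproduce the experiment-plan arithmetic for an
11-cysteine target with three thiol PTM types:

```python
from ptmgate import enumerate_ptm_systems, enumerate_ti_windows
len(enumerate_ptm_systems(system, ["sulfenylated", "nitrosylated",
                                   "glutathionylated"], replicas=1))  # 34
len(enumerate_ti_windows())                                           # 26
```

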