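# edgepore

Trajectory-analysis toolkit for quantifying how membrane-inserted β-sheet
oligomers permeabilize phospholipid bilayers, plus the rule-based machinery to
build the β-sandwich oligomer models themselves and a synthetic-trajectory
generator so the whole pipeline is verifiable without an MD engine.

## What it computes

- **Polar transmembrane defect coordinate ξ** — the fraction of 0.1 nm slices
  across a 2.8 nm hydrophobic slab occupied by at least one lipid- or
  water-oxygen atom (1 = continuous pore, 0 = intact membrane), per frame,
  total and per β-strand edge; its exact-counting distribution p(ξ) and the
  free-energy transform −RT·ln p (T = 300 K, R = 0.0083145 kJ/mol/K).
- **Partial density profiles** along the membrane normal (water, polar lipid
  groups, phosphates, K⁺, Cl⁻), binned relative to the lipid center of mass,
  replicate-averaged with SEM.
- **Residue contact maps** — heavy-atom contact frequencies (0.5 nm cutoff)
  between protein residues and lipid head groups / water / ions.
- **Ion coordination** — first-hydration-shell composition (0.35 nm cutoff) as
  a function of bilayer depth, membrane crossing events, and permeation
  free-energy profiles via Boltzmann inversion of the ion density.
- **Stability metrics** — least-squares superposition RMSD over mainchain+Cβ
  masks, dihedral-based β-structure content, and RMSD pooling with the 0.6 nm
  non-conducting boundary.
- **Model building** — the `<SizeWord>-<k>pe-<composition>` identifier
  grammar, rigid-body assembly of β-sandwich octamers from a tetramer sheet
  (face-to-face antiparallel or face-to-back parallel packing), and strand
  deletion to derive truncation isoforms.
- **Synthetic data** — planted bilayer/sheet/ion systems whose ground truth
  (ξ, contacts, shell counts, crossings) is recovered exactly by the analyses.

## File formats

- Multi-MODEL **PDB** (Å on disk, nm in memory).
- **frame_table** (`.ftb`) — tab-separated text: one `#FRAME t=<ps>
  box=<lx> <ly> <lz>` header per frame followed by rows
  `atom_index name residue_name residue_number chain role subrole x y z`
  (nm).  Writing uses shortest round-trip float formatting, so a
  write/read cycle is bit exact.
- Model **sidecar** JSON describing chains, strands (β1/β2/β3 with residue
  spans) and edges; it feeds the per-edge defect analysis.

The membrane normal is the third box axis; distances use the minimum-image
convention under an orthorhombic box.

## CLI

```sh
edgepore config --show-defaults          # every analysis constant
edgepore synth   --out-dir fixtures/ --seed 1
edgepore defect  --traj rep0.ftb --sidecar model.json --out defect.tsv
edgepore density --traj rep0.ftb --select water_O --out density.tsv
edgepore contacts --traj rep0.ftb --residues 9-21 --out contacts.tsv
edgepore ions    --traj rep0.ftb --species K --out coord.tsv
edgepore rmsd    --traj rep0.ftb --reference start.pdb --out rmsd.tsv
edgepore build   --packing face_to_face_AP --out-prefix sandwich
edgepore run     --traj rep0.ftb --traj rep1.ftb --sidecar model.json --out-dir report/
```

All subcommands accept `--config <yaml>`; defaults follow the analysis
protocol (100 ps sampling stride, first 500 ns discarded, 0.5 / 0.35 / 1.0 nm
cutoffs, 300 K).  `edgepore run` writes a TSV report bundle plus a
`manifest.json` with config and file hashes; identical inputs give
byte-identical outputs.

## Layout

```
src/edgepore/
  trajectory.py   data model, PDB/frame_table IO, atom selections
  defects.py      slice grid, ξ, distributions, free energy
  density.py      axial density profiles
  contacts.py     residue contact frequencies
  ions.py         shell composition, crossings, permeation ΔG
  metrics.py      superposition RMSD, β content, pooling
  builder.py      model grammar, sandwich assembly, strand deletion
  synth.py        synthetic systems with planted ground truth
  pipeline.py     end-to-end orchestration
  cli.py          click CLI
tests/            unit, property (hypothesis) and acceptance suites
```
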