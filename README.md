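# waternet

Hydrogen-bonded water-ring analysis for MD snapshot coordinates.

`waternet` detects closed rings (trimers through hexamers, R3–R6) of
hydrogen-bonded water molecules in PDB coordinate frames, maps ring centers
of mass onto named binding-site regions, and scores two kinds of similarity:

* **ring-cloud vs. ligand shape similarity** — an alignment-free 12-moment
  shape descriptor (distance-distribution moments to four reference points)
  compared with `S = 1 / (1 + mean |Δmoment|)`;
* **binding-site similarity** — spatially consistent element-typed atom
  matching between two pockets, scored Tanimoto-like as
  `n_match / (n_site1 + n_site2 − n_match)`.

Hydrogen bonds are decided energetically: two rigid 3-site waters are bonded
when their interaction energy (nine Coulomb site–site terms plus one
oxygen–oxygen Lennard-Jones term, default charges −0.834 e / +0.417 e,
A = 582000 kcal·Å¹²/mol, C = 595 kcal·Å⁶/mol) is at or below
−2.25 kcal/mol. Rings are the chordless simple cycles of the resulting
graph, enumerated exactly and reported once each in canonical order.

## Library overview

| module | contents |
| --- | --- |
| `waternet.structures_io` | PDB snapshot parsing/writing (multi-MODEL → one frame each), water/ligand recognition by residue name, region-config loading |
| `waternet.water_networks` | pair energy, H-bond graph, chordless-cycle ring enumeration, ring centers of mass, per-frame analysis, ring table / COM-PDB export |
| `waternet.site_regions` | spherical region specs, ring-COM assignment, per-region count + percentage tables |
| `waternet.shape_similarity` | 12-moment shape descriptors, similarity score, ring-cloud vs. ligand percentage |
| `waternet.site_similarity` | binding-site loading and rigid-matching similarity |
| `waternet.fixtures` | deterministic synthetic inputs: planted hydrogen-bonded rings, noise waters, toy ligands |
| `waternet.cli` | `waternet` command-line entry point |

```python
from waternet import analyze_frames, distribution, load_region_spec, parse_frames

frames = parse_frames("snapshots.pdb")          # multi-MODEL PDB
rings = analyze_frames(frames)                  # list of WaterRing with COMs
table = distribution(rings, load_region_spec("regions.cfg"))
print(table.pretty())
```

## Command line

```sh
# generate a synthetic box: 2 planted R3 + 1 R6 per frame, 10 frames
waternet fixtures --ring R3:8,8,8 --ring R3:8,22,8 --ring R6:22,15,20 \
    --n-noise 12 --n-frames 10 --seed 42 --ligand rod:10 --out-dir demo

# enumerate rings -> demo/rings.csv + demo/ring_coms.pdb
waternet rings --frames demo/frames.pdb --out-dir demo

# per-region distribution table (counts + percentages)
waternet distribution --frames demo/frames.pdb --regions demo/regions.cfg

# ring-cloud vs. ligand shape similarity (percentage)
waternet shape --ring-coms demo/ring_coms.pdb --ligand demo/ligand.pdb

# binding-site similarity between two pocket PDBs
waternet sitesim --site1 a.pdb --site2 b.pdb --residues1 1,2,3 --residues2 1,2,3
```

The region config is a flat text file, one region per line:

```
# name center_x center_y center_z radius   (Å)
A 8.0 8.0 8.0 4.0
B 8.0 22.0 8.0 4.0
```

Energetic and geometric knobs (`--criterion`, `--cutoff`, `--minimum-image`,
`--com-mode`, charges/LJ coefficients) are exposed on the relevant
subcommands; defaults match the values above.

## Tests

```sh
python -m pytest tests/
```

The suite cross-checks every equation against independent brute-force
oracles (plain-loop energy summation, networkx cycle enumeration, direct
moment summation, exhaustive rigid matching) and verifies planted-ring
recovery from the synthetic generator. One acceptance case
(`compound4-E`) intentionally stays red: its expected value of 34.2% cannot
be produced by any per-entry rounding of 14/41 (100·14/41 = 34.146… → 34.1);
see the decisions notes accompanying this build.

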