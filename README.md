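# conformetrics

Conformational-descriptor analyses for peptide monomer and fibril
ensembles, built around the 42-residue amyloid-beta peptide
(author numbering Asp1..Ala42):

- **Secondary-structure timelines** — per-residue/per-frame {H, E, C}
  labels from rebuilt amide hydrogens and Kabsch–Sander hydrogen-bond
  energies, with pooled alpha-helix / beta-sheet content percentages.
- **Hydrogen-bond frequency tables** — geometric donor–acceptor
  detection aggregated to residue pairs; "average frequency" (af) is the
  percentage of frames in which a pair is bonded, with the >= 10%
  turn-contact filter.
- **RMSD clustering and U-shape statistics** — deterministic GROMOS
  greedy clustering of the all-to-all best-fit RMSD matrix; cluster
  representatives are classified by a three-condition geometric U-shape
  test (arm-axis angle, inter-arm distance, turn direction reversal) and
  the U-shape percentage is the population-weighted sum over U clusters.
- **Contact maps and radius-of-gyration series.**
- **Fibril compactness distances** — the five CA-based descriptors on
  geometrically ordered strand stacks (D_HC: Gly33 strand 3↔8; D_VC:
  Phe19–Val39 per core strand, averaged; D_HE: Gln15 strand 3↔8; D_VE:
  Glu11–Val39 averaged; D_IS: adjacent core-strand His14 pairs), plus
  fan-motion amplitude (max − min of D_VE) and the leading-mode variance
  fraction from CA coordinate PCA.
- **Synthetic ground truth** — ideal helices/strands from internal
  coordinates, U-shaped hairpins, coil ensembles, scripted hydrogen-bond
  schedules, and S-shaped fibril stacks with programmable rise,
  fan-opening hinge schedules (solved to hit per-frame D_VE targets),
  strand dissociation, and Gaussian noise. Every generated trajectory
  ships with a machine-readable log of its programmed ground truth.

Input/output is multi-model PDB (one MODEL per frame); analyses emit a
JSON report (thresholds echoed, config hashed) plus TSV/CSV tables.
Fixed seed + fixed config ⇒ byte-identical outputs.

## CLI

```sh
# Generate a synthetic monomer ensemble (PDB + ground-truth TSV):
conformetrics generate --config examples/monomer.yaml --out run/gen

# Monomer report: SS content, HB contacts, U-shape %, RoG:
conformetrics monomer --in run/gen/trajectory.pdb --out run/mono

# Fibril report: five distances, fan amplitude, PCA mode-1 fraction:
conformetrics fibril --in fibril.pdb --out run/fib --core-margin 2
```

Config files are YAML; every threshold has a CLI override
(`--hb-dist`, `--hb-angle`, `--cluster-cutoff`, `--u-angle`,
`--u-contact`, `--core-margin`). Example generator configs:

```yaml
# monomer ensemble
kind: monomer
n_frames: 200
weights: {u: 0.75, extended: 0.25}
noise: 1.0
seed: 7
contacts:
  - {donor_res: 23, acceptor_res: 26, fraction: 0.92}
```

```yaml
# fibril stack with a fan-opening schedule
kind: fibril
n_strands: 10
rise: 4.8
n_frames: 100
dve_schedule: {start: 32.0, stop: 22.0}
noise: 0.5
seed: 7
```

## Package layout

| module | contents |
| --- | --- |
| `conformetrics.structio` | multi-model PDB reader/writer, selections |
| `conformetrics.geometry` | Kabsch superposition, RMSD matrices, RoG, PCA |
| `conformetrics.secstruct` | amide-H placement, KS energies, {H,E,C} timelines |
| `conformetrics.hbonds` | geometric H-bond detection, af tables, 10% filter |
| `conformetrics.shape_cluster` | GROMOS clustering, U-shape test, contact maps |
| `conformetrics.fibril_metrics` | strand ordering, five distances, fan motion |
| `conformetrics.synthetic` | ground-truth generators |
| `conformetrics.pipeline` / `.cli` | reports, provenance, CLI |
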