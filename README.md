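# aiiconn

Skeleton-based retinal connectomics analysis: quantify the synaptic
input/output structure of AII amacrine cells and their presynaptic
amacrine-cell axons from Knossos/webKnossos NML skeleton tracings.

The package provides:

- **`aiiconn.skeleton_io`** — NML read/write with validation (forests
  only, cycles rejected, nothing silently dropped), a documented synapse
  comment grammar `syn:<ribbon|conv>:<in|out>:<TYPE>[:<id>]`, physical
  coordinate conversion for anisotropic voxels, cable length, tree
  geodesics, and SWC export.
- **`aiiconn.geometry`** — total-least-squares fitting of the ON/OFF
  starburst (SAC/ChAT) planes, rigid tilt correction, and normalized
  IPL depth (OFF plane = 0, ON plane = 1, increasing toward the GCL;
  re-anchorable to percent-IPL), plus laminar-zone assignment.
- **`aiiconn.connectome`** — typed synapse tables built from paired or
  one-sided annotations (partner-id matching with greedy proximity
  fallback), per-cell input/output tallies by partner type and
  compartment, cross-cell mean ± SD summaries, axon→target convergence
  (both the per-presynaptic-skeleton and per-connected-pair means), and
  ribbon dyad composition.
- **`aiiconn.spatial_stats`** — nearest-neighbor synapse distances
  (Euclidean or along-arbor geodesic, grouped by postsynaptic cell),
  ECDF / median / fraction-within, stratification-depth profiles with
  exact mass conservation, a rule-based ON cone-bipolar subtype
  classifier, and en-passant ribbon cluster statistics.
- **`aiiconn.synthetic_data`** — a seeded generator of synthetic
  skeleton volumes (tilted SAC planes, AII/RB/axon morphologies,
  two-sided synapse annotations with configurable target and dyad
  mixtures) with full ground truth, plus fixtures encoding published
  per-cell synapse counts.
- **`aiiconn.cli`** — the `aiiconn` command with `validate`,
  `simulate`, `fixtures`, `pipeline`, `profile`, and `classify`
  subcommands.

## CLI quick start

```sh
# generate a synthetic volume with known ground truth
aiiconn simulate --seed 1 --out scratch/sim

# validate any NML file
aiiconn validate scratch/sim/volume.nml

# full pipeline: depth frame, synapse table, tallies, NN stats, report
aiiconn pipeline scratch/sim/volume.nml --truth scratch/sim/truth.json \
    --out scratch/run

# published-table count fixtures as TSV
aiiconn fixtures --out scratch/fixtures
```

`pipeline` writes `frame.json` (the fitted SAC planes and depth
convention), `synapses.tsv`, per-cell tally TSVs, `convergence.tsv`,
`nn_distances.tsv`, a Markdown report, and `run_config.json` with a
hash of the resolved configuration.

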