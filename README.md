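# ribobind

Analysis toolkit for characterizing protein–RNA interactions across three
experimental readout classes, with seeded synthetic-data generators so every
stage can be exercised without external data.

## Stages

- **`ribobind.rip_enrichment`** — RIP-seq enrichment calling from
  per-replicate fragment-count tables: FPKM computation, strict
  RIP-vs-control positive calls, a stringent class (fold change > 2 in ≥ 2
  replicates, with a configurable pseudocount for zero-control transcripts),
  replicate-overlap Venn summaries, intron-coverage classification
  (co- vs post-transcriptional binding), and RIP-qPCR ΔΔCt fold enrichment /
  percent-input math.
- **`ribobind.mst_binding`** — microscale-thermophoresis dilution-series
  analysis: trace normalization, extraction of the T-jump (1.25 s after
  IR-on), thermophoresis (last 1 s of the 30 s IR-on window) and
  back-diffusion (2.5 s after IR-off) readouts, 1:1 mass-action isotherm
  fitting with ligand depletion for Kd per readout, and roughness-based
  irregularity detection that reports the thermophoresis Kd as `n.d.` for
  aggregating samples.
- **`ribobind.dock_surface`** — docked-pose ensemble processing: PDB
  ingestion, exact k-d-tree minimum distances, removal of poses binding
  within 5 Å of a terminal nucleotide, removal of poses clashing (< 2.5 Å)
  with partner chains of a reference complex, and per-residue RNA
  contact-frequency maps (< 5 Å, any atom) over the retained poses, with
  optional B-factor-encoded PDB output.
- **`ribobind.synthetic_data`** — generators: negative-binomial RIP/control
  counts with planted binders and exon/intron read allocation,
  piecewise-exponential MST traces whose amplitudes follow the mass-action
  binding curve (with an aggregation mode), and rigid-body RNA pose
  ensembles with planted filter violations and a controllable contact
  hotspot. All generators are deterministic given a seed.

## CLI

```bash
# simulate, then analyze, a RIP-seq count dataset
ribobind sim rip --seed 1 --out rip_data/
ribobind rip-enrich --counts rip_data/counts.tsv \
    --transcripts rip_data/transcripts.tsv \
    --library-sizes rip_data/library_sizes.tsv \
    --reads rip_data/reads.bed --pseudocount 0.1 --out rip_out/

# simulate and fit an MST dilution series
ribobind mst-sim --kd 8.7e-7 --noise 0.002 --seed 1 --out mst_data/
ribobind mst-fit --series mst_data/manifest.yaml --readout all --out mst_out/

# filter a docked-pose ensemble and map the contact surface
ribobind sim poses --seed 1 --out pose_data/
ribobind dock-surface --receptor pose_data/receptor.pdb \
    --poses pose_data/poses --reference pose_data/reference_complex.pdb \
    --terminal-a 5 --clash-a 2.5 --contact-a 5 --out dock_out/
```

`rip-enrich` also accepts `--gtf` for standard GTF transcript models
(1-based inclusive coordinates, converted internally to 0-based half-open).

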