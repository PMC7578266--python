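# osteoblast

Toolkit for comparing biomaterial surfaces by the tyrosine-kinome
activity profile of cells grown on them, measured on a 144-spot
peptide microarray with technical replicates.

The analysis pipeline:

1. **Ingest** (`osteoblast.chip_io`) — read the chip layout and
   per-group replicate intensity tables, drop the internal
   positive-control peptide (`ART_003_EAI(pY)AAPFAKKKXC`), floor
   negative background-subtracted signals to zero.
2. **Reliability scoring** (`osteoblast.reliability`) — per spot,
   compute P1 = sd/mean and P2 = mean/median across replicates, band
   each High/Medium/Low (P1 High < 0.20, Medium < 0.50; P2 High in
   (0.80, 1.20), Medium in (0.70, 1.40)) and combine them into the
   integer SR score, 1 (worst) to 6 (best).
3. **Common-spot selection** — spots at the same SR level in both
   groups of a comparison.
4. **Differential phosphorylation** (`osteoblast.diffphos`) — joint
   quantile normalization of the two groups' replicate columns,
   two-sided Student's t-test (pooled variance; Welch optional),
   fold change = test mean / control mean, up/down calls at alpha.
5. **Chi similarity** (`osteoblast.similarity`) — for each group pair,
   `chi = sqrt( mean_i ((I0[i] - It[i]) / (1 - |s0[i] - st[i]|))^2 )`
   over the common spots, with per-spot means/sds taken on the
   normalized intensities rescaled by the pair's global maximum
   (guaranteeing a positive denominator). Lower chi = more similar
   surfaces.
6. **Network comparison** (`osteoblast.network_compare`) — undirected
   protein networks from edge-list TSVs, degree / betweenness /
   closeness centralities, top-decile node selection, Venn-style
   cross-network partitions, and the substrate/site export consumed by
   an external kinase-site predictor.

`osteoblast.synthgen` generates synthetic chips with known ground
truth (quality classes by target CV, per-spot fold effects, optional
negative background values) so every stage is testable offline.

## CLI

```sh
# synthesize a demo chip
osteoblast synth --seed 1 --out fixtures/

# stage by stage
osteoblast ingest --layout fixtures/layout.tsv --intensities fixtures/intensities.tsv \
    --out dataset.json
osteoblast score --dataset dataset.json --out scores.tsv
osteoblast diff  --dataset dataset.json --scores scores.tsv \
    --control control --test test --sr 6 --alpha 0.05 --out diff.tsv
osteoblast chi   --dataset dataset.json --scores scores.tsv --sr 6 --out chi.tsv
osteoblast net   --edges string_edges.tsv --edges-b other_edges.tsv \
    --diff diff.tsv --out netdir/

# or everything at once from a YAML config
osteoblast run --config run.yaml --layout fixtures/layout.tsv \
    --intensities fixtures/intensities.tsv
```

`run.yaml` example:

```yaml
control_group: control
test_groups: [test]
sr_level: 6
alpha: 0.05
output_dir: out
```

Outputs are TSV/CSV tables (SR histogram, per-spot scores, common-spot
lists, differential and volcano tables, pairwise chi matrix) plus a
JSON manifest recording config, input hashes and per-stage spot counts.

## Notes

* The sample standard deviation (n−1) is used everywhere.
* Band boundary points (0.20/0.50 for P1; 0.70/0.80/1.20/1.40 for P2)
  resolve to the wider band: the High bands are open intervals as
  printed and Medium absorbs their endpoints.
* Negative-flooring is the only background correction applied.
* No multiple-testing correction by default (`--bh` enables
  Benjamini–Hochberg).
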