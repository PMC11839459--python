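# lesionphylo

Detection and characterization of somatic mutations generated by
**persistent DNA lesions** in high-resolution somatic phylogenies.

A DNA lesion that survives several cell cycles can template a different
base at each replication. In a phylogeny of single-cell-derived
genomes this leaves two recognizable footprints:

* **MAVs** (multi-allelic variants) — two different mutant alleles at
  the same genomic position, in clades close enough to share a single
  lesion-bearing lineage; classified *simple* / *separated* /
  *unrelated* from the orientation of their assigned branches.
* **PVVs** (phylogeny-violating variants) — the same mutant allele in
  two or more subclades separated by a wild-type subclade, inconsistent
  with a single acquisition event; detected by beta-binomial
  overdispersion of variant-read counts within/outside the assigned
  clade, then resolved into a lesion node, lesion path and repair/loss
  node. The branch-length sum between lesion and repair node is the
  **MMLD** (minimum molecular lesion duration).

The package implements the full analysis pipeline on top of those
calls: read-pair phasing against nearby heterozygous SNPs and
read-based LOH exclusion; null simulations of independent co-occurring
mutations and somatic reversion (sharing the detection code paths);
96-channel spectra, MAV pair-profiles and expected artefact signatures;
molecular-time lesion timing; per-branch lesion-segregation (strand
asymmetry) tests; a stem-cell population simulator with lesion
implantation and rejection-ABC inference of mean lesion duration and
per-cell lesion prevalence; and a fully seeded synthetic-data generator
with machine-readable ground truth.

## Inputs

* rooted Newick tree, branch lengths in mutation counts (molecular time)
* variant table TSV: `chrom  pos  ref  alt  vclass` (`SNV`/`indel`/`MNV`)
* MTR/DEP matrices (variants × samples) as TSV, or a VCF with AD fields
* optional: het-SNP table and read-pair observation table for phasing,
  96-channel reference signatures, genome trinucleotide frequencies

## CLI

```sh
lesionphylo validate     --tree T.nwk --variants V.tsv --mtr M.tsv --dep D.tsv
lesionphylo detect-mav   --tree T.nwk --variants V.tsv --mtr M.tsv --dep D.tsv --out run1
lesionphylo detect-pvv   --tree T.nwk --variants V.tsv --mtr M.tsv --dep D.tsv --out run1
lesionphylo simulate-null --kind mav|pvv|reversion --tree T.nwk --reps 10000 --seed 1
lesionphylo signatures   --mode observed|expected-mav|expected-pvv|expected-reversion ...
lesionphylo timing       --tree T.nwk --variants V.tsv --mtr M.tsv --dep D.tsv
lesionphylo segregation  --branch-mutations muts.tsv
lesionphylo synth        --preset adult-hspc --seed 1 --outdir synthetic/
lesionphylo run-all      --tree T.nwk --variants V.tsv --mtr M.tsv --dep D.tsv
```

Exit codes: 0 success, 2 validation error, 3 computation error.

Python API: one module per pipeline stage (`phylo_model`,
`mav_detection`, `pvv_detection`, `phasing_loh`, `null_simulations`,
`signature_analysis`, `lesion_timing`, `abc_duration`,
`lesion_segregation`, `synthetic_data`), shared thresholds in
`lesionphylo.PipelineConfig`.

```python
from lesionphylo.synthetic_data import generate_dataset
from lesionphylo.pvv_detection import detect_pvvs

ds = generate_dataset("adult-hspc", seed=11)
calls = [c for c in detect_pvvs(ds.tree, ds.counts) if c.status == "pass"]
```

## Tests

```sh
python -m pytest -q tests/
```

The suite includes brute-force oracles (exhaustive branch-likelihood
scans, adjacency-list MAV classification, dense 2-D beta-binomial grid
search, exact pair enumeration for the null model), property tests, and
`tests/test_acceptance.py` with one test per acceptance criterion —
including a reduced-scale ABC coverage experiment (populations of 2,000
cells, 12-point duration grid, ≥20 seeded repetitions). The full run
takes roughly 10 minutes on one CPU.

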