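# dtamix

Joint drug–target binding-affinity regression and protein binding-region
prediction with token-mixing sequence encoders, implemented in pure
NumPy (including a small reverse-mode autodiff engine — no deep-learning
framework required).

The model consumes four raw views of a drug–protein pair — residue-token and
k-mer-token index maps for the protein, a functional-class circular
fingerprint and a bond-graph for the drug — encodes each with residual
token-mixing blocks, fuses the two views per entity with a convolutional
gate, and decodes the pair with a drug-derived sliding kernel whose
per-residue response vector both localizes the binding region and feeds the
affinity head. Training is multi-task: mean squared error on affinities plus
a rectified Wing loss on the response vector against site annotations.

## CLI

```sh
# generate a synthetic benchmark (FASTA + TSVs + manifest)
dtamix simulate --out data/ --n-proteins 50 --n-drugs 10 --n-pairs 200 --seed 0

# encode all inputs to a tensor container
dtamix featurize --proteins data/proteins.fasta --drugs data/drugs.tsv \
    --affinities data/affinities.tsv --sites data/sites.tsv \
    --preset desk --out feat/

# train one cross-validation fold
dtamix train --proteins data/proteins.fasta --drugs data/drugs.tsv \
    --affinities data/affinities.tsv --sites data/sites.tsv \
    --preset desk --epochs 100 --fold 0 --seed 0 --checkpoint model.npz

# predict affinities + binding regions at scales S = 5, 10, 15
dtamix predict --proteins data/proteins.fasta --drugs data/drugs.tsv \
    --affinities data/affinities.tsv --checkpoint model.npz --out pred.tsv

# score predictions (CI, MSE, rm2, optional AUPR and region hit accuracy)
dtamix evaluate --predictions pred.tsv --affinities data/affinities.tsv \
    --sites data/sites.tsv --out metrics.tsv
```

Presets: `davis` / `kiba` carry the published full-scale hyper-parameters
(protein length 1200, channels 100/75/75, stacked encoder depths);
`desk` is a small configuration that trains in minutes on one CPU. Any
field can be overridden with a YAML/JSON file passed via `--config`.

## Data formats

- proteins: FASTA (unknown residues mapped to `X`)
- drugs: TSV with columns `drug_id`, `smiles`
- affinities: TSV with `drug_id`, `protein_id`, `affinity`
  (pKd for Davis-style data — see `dtamix.data_io.kd_to_pkd` — or KIBA score)
- binding sites: BED-like TSV `protein_id`, `start`, `end`
  (0-based, half-open residue coordinates)

## Package layout

- `dtamix.nn` — minimal autodiff Tensor, layers (affine, linear, embedding,
  grouped 1-D conv, 2-D conv, batch norm, dropout) and AdamW
- `dtamix.data_io` — FASTA/TSV/BED-like readers and writers, pKd transform,
  5-fold cross-validation splits
- `dtamix.featurize` — residue/k-mer token encodings, fingerprints,
  molecular graphs
- `dtamix.bio_blocks` — token-mixing encoder blocks (MLP-style for drugs,
  large-kernel-convolution style for proteins)
- `dtamix.fusion` — gated two-branch feature fusion
- `dtamix.mix_decoder` — drug-kernel sampling, response vector,
  binding-region prediction, self-enhancement, cross-attention, pooling,
  affinity head
- `dtamix.objectives` — MSE, rectified Wing loss, site-label embedding,
  joint multi-task loss
- `dtamix.metrics` — concordance index, rm², AUPR, region hit accuracy
- `dtamix.simulate` — synthetic dataset generator with planted motif sites
- `dtamix.train` / `dtamix.cli` — training loop, checkpointing, prediction,
  command-line interface
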