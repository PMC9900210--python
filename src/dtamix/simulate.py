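"""Synthetic benchmark generator.

Produces datasets with the statistical structure the model assumes: random
protein sequences with exactly one planted motif (the annotated binding
site), drugs drawn from a fixed pool of small valid SMILES, and affinities
driven by drug-class / motif-class compatibility plus Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data_io import (AA_ALPHABET, AffinitySample, DrugRecord, ProteinRecord,
                      write_affinities, write_fasta, write_sites,
                      write_smiles_table)

__all__ = ["SimConfig", "SimulatedDataset", "generate_dataset",
           "oracle_affinity", "write_dataset", "SMILES_POOL"]

# small drug-like molecules; cycled when n_drugs exceeds the pool
SMILES_POOL = [
    "CCO", "CC(=O)O", "c1ccccc1", "c1ccncc1", "CC(C)O", "CCN(CC)CC",
    "CC(=O)Nc1ccc(O)cc1", "c1ccc2ccccc2c1", "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "OC(=O)c1ccccc1O", "Clc1ccccc1", "CCOC(=O)C", "CN1CCC[C@H]1c1cccnc1",
    "Cc1ccccc1N", "OCC1OC(O)C(O)C(O)C1O", "CC(=O)OC1=CC=CC=C1C(=O)O",
    "NC(=O)c1ccccc1", "COc1ccc(CC=C)cc1", "CC1=CC(=O)C=CC1=O",
    "O=C(O)CCc1ccccc1",
]


@dataclass
class SimConfig:
    n_proteins: int = 50
    n_drugs: int = 10
    n_pairs: int = 200
    protein_length_range: tuple[int, int] = (80, 180)
    motif_length: int = 8
    n_motif_classes: int = 4
    affinity_base: float = 5.0
    affinity_gain: float = 2.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        self.protein_length_range = tuple(self.protein_length_range)
        lo, hi = self.protein_length_range
        if self.motif_length > lo:
            raise ValueError(
                f"motif_length {self.motif_length} exceeds min protein length {lo}")
        if self.n_pairs > self.n_proteins * self.n_drugs:
            raise ValueError("n_pairs exceeds n_proteins * n_drugs")
        if self.n_motif_classes < 1 or lo < 1 or hi < lo:
            raise ValueError("invalid simulation configuration")


@dataclass
class SimulatedDataset:
    proteins: list[ProteinRecord]
    drugs: list[DrugRecord]
    samples: list[AffinitySample]
    motifs: list[str]                  # one consensus motif per class
    protein_classes: dict[str, int]
    drug_classes: dict[str, int]
    config: SimConfig


def _motif_patterns(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    # draw distinct consensus strings; redraw on collision
    seen: set[str] = set()
    motifs = []
    while len(motifs) < cfg.n_motif_classes:
        m = "".join(rng.choice(list(AA_ALPHABET), size=cfg.motif_length))
        if m not in seen:
            seen.add(m)
            motifs.append(m)
    return motifs


def _compat(drug_class: int, motif_class: int) -> float:
    return 1.0 if drug_class == motif_class else 0.0


def oracle_affinity(drug_class: int, motif_class: int, cfg: SimConfig) -> float:
    """Noiseless planted affinity for a (drug class, motif class) pair."""
    value = cfg.affinity_base + cfg.affinity_gain * _compat(drug_class,
                                                            motif_class)
    return float(np.clip(value, 4.0, 10.0))


def generate_dataset(cfg: SimConfig) -> SimulatedDataset:
    rng = np.random.default_rng(cfg.seed)
    motifs = _motif_patterns(cfg, rng)
    alphabet = list(AA_ALPHABET)

    proteins: list[ProteinRecord] = []
    protein_classes: dict[str, int] = {}
    lo, hi = cfg.protein_length_range
    for i in range(cfg.n_proteins):
        pid = f"P{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(alphabet, size=length))
        klass = int(rng.integers(cfg.n_motif_classes))
        start = int(rng.integers(0, length - cfg.motif_length + 1))
        seq[start:start + cfg.motif_length] = list(motifs[klass])
        proteins.append(ProteinRecord(
            id=pid, sequence="".join(seq),
            sites=[(start, start + cfg.motif_length)]))
        protein_classes[pid] = klass

    drugs: list[DrugRecord] = []
    drug_classes: dict[str, int] = {}
    for j in range(cfg.n_drugs):
        did = f"D{j:04d}"
        drugs.append(DrugRecord(id=did,
                                smiles=SMILES_POOL[j % len(SMILES_POOL)]))
        drug_classes[did] = j % cfg.n_motif_classes

    all_pairs = [(d.id, p.id) for p in proteins for d in drugs]
    chosen = rng.choice(len(all_pairs), size=cfg.n_pairs, replace=False)
    samples = []
    for idx in sorted(chosen):
        did, pid = all_pairs[idx]
        value = (cfg.affinity_base
                 + cfg.affinity_gain * _compat(drug_classes[did],
                                               protein_classes[pid])
                 + rng.normal(0.0, cfg.noise_sd))
        samples.append(AffinitySample(drug_id=did, protein_id=pid,
                                      affinity=float(np.clip(value, 4.0, 10.0))))
    return SimulatedDataset(proteins=proteins, drugs=drugs, samples=samples,
                            motifs=motifs, protein_classes=protein_classes,
                            drug_classes=drug_classes, config=cfg)


def write_dataset(data: SimulatedDataset, outdir: str | Path) -> None:
    """FASTA + drugs/affinities/sites TSV + a JSON manifest of the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "proteins.fasta", data.proteins)
    write_smiles_table(outdir / "drugs.tsv", data.drugs)
    write_affinities(outdir / "affinities.tsv", data.samples)
    write_sites(outdir / "sites.tsv",
                {p.id: p.sites for p in data.proteins if p.sites})
    manifest = {"config": asdict(data.config), "motifs": data.motifs,
                "protein_classes": data.protein_classes,
                "drug_classes": data.drug_classes}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
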