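"""Readers/writers for the external formats, the pKd transform and CV splits.

Formats: FASTA for proteins (via Biopython), tab-separated tables with a
header row for drugs / affinities / predictions, and a 3-column BED-like
table (0-based, half-open residue coordinates) for binding-site intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from rdkit import Chem

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_AA = "X"

__all__ = [
    "ProteinRecord", "DrugRecord", "AffinitySample", "DatasetSplit",
    "FormatError", "read_fasta", "write_fasta", "read_smiles_table",
    "write_smiles_table", "read_sites", "write_sites", "read_affinities",
    "write_affinities", "kd_to_pkd", "make_cv_splits", "merge_intervals",
    "assemble_dataset", "AA_ALPHABET", "UNKNOWN_AA",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    sites: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        self.sites = merge_intervals([tuple(iv) for iv in self.sites])
        for start, end in self.sites:
            if start < 0 or end > len(self.sequence):
                raise FormatError(
                    f"protein {self.id!r}: site ({start}, {end}) outside "
                    f"[0, {len(self.sequence)})")


@dataclass
class DrugRecord:
    id: str
    smiles: str

    def __post_init__(self):
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None or mol.GetNumAtoms() == 0:
            raise FormatError(f"drug {self.id!r}: unparseable SMILES {self.smiles!r}")


@dataclass
class AffinitySample:
    drug_id: str
    protein_id: str
    affinity: float

    def __post_init__(self):
        if not math.isfinite(self.affinity):
            raise FormatError(
                f"pair ({self.drug_id}, {self.protein_id}): non-finite affinity")


@dataclass
class DatasetSplit:
    train_indices: np.ndarray
    valid_indices: np.ndarray
    test_indices: np.ndarray
    fold: int
    seed: int


def _clean_sequence(raw: str) -> str:
    seq = raw.upper()
    return "".join(c if c in AA_ALPHABET else UNKNOWN_AA for c in seq)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """One record per FASTA entry; sequences upper-cased, unknown → 'X'."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA entry with empty header")
        seq = _clean_sequence(str(rec.seq))
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(path: str | Path, proteins: list[ProteinRecord]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins],
        str(path), "fasta")


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def read_smiles_table(path: str | Path) -> list[DrugRecord]:
    df = _read_table(path, ["drug_id", "smiles"])
    dupes = df["drug_id"][df["drug_id"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate drug id(s) {sorted(set(dupes))}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(DrugRecord(id=row.drug_id, smiles=row.smiles))
        except FormatError as exc:
            raise FormatError(f"{path}: line {row_no}: {exc}") from exc
    return records


def write_smiles_table(path: str | Path, drugs: list[DrugRecord]) -> None:
    pd.DataFrame({"drug_id": [d.id for d in drugs],
                  "smiles": [d.smiles for d in drugs]}
                 ).to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED-like TSV (protein_id, start, end) → merged intervals per protein."""
    df = _read_table(path, ["protein_id", "start", "end"])
    raw: dict[str, list[tuple[int, int]]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        start, end = int(row.start), int(row.end)
        if start < 0 or start >= end:
            raise FormatError(
                f"{path}: line {row_no}: bad interval ({start}, {end})")
        raw.setdefault(row.protein_id, []).append((start, end))
    return {pid: merge_intervals(ivs) for pid, ivs in raw.items()}


def write_sites(path: str | Path, sites: dict[str, list[tuple[int, int]]]) -> None:
    rows = [(pid, s, e) for pid, ivs in sites.items() for s, e in ivs]
    pd.DataFrame(rows, columns=["protein_id", "start", "end"]
                 ).to_csv(path, sep="\t", index=False)


def read_affinities(path: str | Path) -> list[AffinitySample]:
    df = _read_table(path, ["drug_id", "protein_id", "affinity"])
    samples = [AffinitySample(r.drug_id, r.protein_id, float(r.affinity))
               for r in df.itertuples(index=False)]
    seen: set[tuple[str, str]] = set()
    for s in samples:
        key = (s.drug_id, s.protein_id)
        if key in seen:
            raise FormatError(f"{path}: duplicate pair {key}")
        seen.add(key)
    return samples


def write_affinities(path: str | Path, samples: list[AffinitySample]) -> None:
    pd.DataFrame({"drug_id": [s.drug_id for s in samples],
                  "protein_id": [s.protein_id for s in samples],
                  "affinity": [s.affinity for s in samples]}
                 ).to_csv(path, sep="\t", index=False)


def kd_to_pkd(kd_nM: float) -> float:
    """Dissociation constant in nM → pKd = −log10(Kd / 1e9)."""
    if kd_nM <= 0:
        raise ValueError(f"Kd must be positive, got {kd_nM}")
    return -math.log10(kd_nM / 1e9)


def assemble_dataset(proteins: list[ProteinRecord], drugs: list[DrugRecord],
                     samples: list[AffinitySample],
                     sites: dict[str, list[tuple[int, int]]] | None = None,
                     ) -> tuple[list[ProteinRecord], list[DrugRecord],
                                list[AffinitySample]]:
    """Attach site annotations and check referential integrity of the triples."""
    pmap = {p.id: p for p in proteins}
    dmap = {d.id: d for d in drugs}
    if sites:
        for pid, ivs in sites.items():
            if pid in pmap:
                pmap[pid] = ProteinRecord(pid, pmap[pid].sequence, list(ivs))
    for s in samples:
        if s.drug_id not in dmap:
            raise FormatError(f"affinity references unknown drug {s.drug_id!r}")
        if s.protein_id not in pmap:
            raise FormatError(f"affinity references unknown protein {s.protein_id!r}")
    return list(pmap.values()), drugs, samples


def make_cv_splits(n_samples: int, test_fraction: float = 1 / 6,
                   seed: int = 0, n_folds: int = 5) -> list[DatasetSplit]:
    """One fixed held-out test set + ``n_folds``-fold partition of the rest.

    Every pool index lands in exactly one validation fold; folds differ in
    size by at most one. Deterministic in ``seed``.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    n_test = int(round(n_samples * test_fraction))
    n_pool = n_samples - n_test
    if n_pool < n_folds:
        raise ValueError(
            f"pool of {n_pool} samples too small for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_samples)
    test = np.sort(order[:n_test])
    pool = order[n_test:]
    folds = np.array_split(pool, n_folds)
    splits = []
    for k, fold in enumerate(folds):
        valid = np.sort(fold)
        train = np.sort(np.concatenate([f for i, f in enumerate(folds) if i != k]))
        splits.append(DatasetSplit(train_indices=train, valid_indices=valid,
                                   test_indices=test, fold=k, seed=seed))
    return splits
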