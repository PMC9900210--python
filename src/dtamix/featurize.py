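"""Raw model inputs: residue/k-mer token indices for proteins, functional-class
circular fingerprints and padded molecular graphs for drugs."""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .data_io import AA_ALPHABET, UNKNOWN_AA

PAD_INDEX = 0
AA_VOCAB = {aa: i + 1 for i, aa in enumerate(AA_ALPHABET + UNKNOWN_AA)}
AA_VOCAB_SIZE = len(AA_VOCAB) + 1  # + pad
WE_PAD, WE_OOV = 0, 1

_ELEMENTS = ["C", "N", "O", "S", "F", "P", "Cl", "Br", "I"]
ATOM_FEATURE_DIM = len(_ELEMENTS) + 1 + 7 + 3  # element one-hot+other, degree, flags

__all__ = [
    "ProteinInput", "DrugInput", "encode_protein_aae", "encode_protein_we",
    "build_we_vocab", "encode_drug_fcfp", "smiles_to_graph", "decode_aae",
    "AA_VOCAB", "AA_VOCAB_SIZE", "PAD_INDEX", "WE_PAD", "WE_OOV",
    "ATOM_FEATURE_DIM",
]


@dataclass
class ProteinInput:
    aae: np.ndarray    # (L_P,) int token indices
    we: np.ndarray     # (L_P,) int k-mer indices
    mask: np.ndarray   # (L_P,) bool, True on real residues


@dataclass
class DrugInput:
    fingerprint: np.ndarray    # (n_bits,) 0/1
    atom_features: np.ndarray  # (L_D, ATOM_FEATURE_DIM)
    adj: np.ndarray            # (L_D, L_D) binary, unit diagonal on real atoms
    n_atoms: int


def encode_protein_aae(sequence: str, l_p: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue indices over the 22-symbol vocabulary, padded/truncated."""
    if not sequence:
        raise ValueError("empty sequence")
    idx = np.full(l_p, PAD_INDEX, dtype=np.int64)
    mask = np.zeros(l_p, dtype=bool)
    n = min(len(sequence), l_p)
    idx[:n] = [AA_VOCAB.get(c, AA_VOCAB[UNKNOWN_AA]) for c in sequence[:n]]
    mask[:n] = True
    return idx, mask


def decode_aae(indices: np.ndarray) -> str:
    rev = {i: aa for aa, i in AA_VOCAB.items()}
    return "".join(rev[i] for i in indices if i != PAD_INDEX)


def build_we_vocab(sequences: list[str], k: int = 3,
                   max_size: int = 4096) -> dict[str, int]:
    """Most-frequent k-mers (ties broken lexicographically); 0=pad, 1=OOV."""
    if not sequences:
        raise ValueError("need at least one sequence")
    counts: Counter[str] = Counter()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            counts[seq[i:i + k]] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:max_size]
    return {token: i + 2 for i, (token, _) in enumerate(ranked)}


def encode_protein_we(sequence: str, k: int, vocab: dict[str, int],
                      l_p: int) -> np.ndarray:
    """Overlapping k-mer indices (stride 1), padded/truncated to ``l_p``."""
    idx = np.full(l_p, WE_PAD, dtype=np.int64)
    n_tokens = len(sequence) - k + 1
    if n_tokens <= 0:
        warnings.warn(f"sequence shorter than k={k}; word encoding is all-pad",
                      stacklevel=2)
        return idx
    for i in range(min(n_tokens, l_p)):
        idx[i] = vocab.get(sequence[i:i + k], WE_OOV)
    return idx


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def encode_drug_fcfp(smiles: str, radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    """Functional-class circular fingerprint folded to ``n_bits`` as 0/1."""
    mol = _parse(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits,
        atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen())
    fp = gen.GetFingerprint(mol)
    return np.asarray(fp, dtype=np.float64)


def _atom_row(atom: Chem.Atom) -> np.ndarray:
    row = np.zeros(ATOM_FEATURE_DIM)
    symbol = atom.GetSymbol()
    row[_ELEMENTS.index(symbol) if symbol in _ELEMENTS else len(_ELEMENTS)] = 1.0
    degree = min(atom.GetDegree(), 6)
    row[len(_ELEMENTS) + 1 + degree] = 1.0
    base = len(_ELEMENTS) + 1 + 7
    row[base] = float(atom.GetIsAromatic())
    row[base + 1] = float(atom.GetFormalCharge())
    row[base + 2] = float(atom.IsInRing())
    return row


def smiles_to_graph(smiles: str, l_d: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Heavy-atom features + bond adjacency (unit diagonal), zero-padded.

    Molecules with more than ``l_d`` heavy atoms are truncated with a warning.
    """
    mol = _parse(smiles)
    n_heavy = mol.GetNumAtoms()
    if n_heavy > l_d:
        warnings.warn(
            f"molecule has {n_heavy} heavy atoms, truncating to {l_d}",
            stacklevel=2)
    n = min(n_heavy, l_d)
    features = np.zeros((l_d, ATOM_FEATURE_DIM))
    adj = np.zeros((l_d, l_d))
    for i in range(n):
        features[i] = _atom_row(mol.GetAtomWithIdx(i))
        adj[i, i] = 1.0
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i < n and j < n:
            adj[i, j] = adj[j, i] = 1.0
    return features, adj, n
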