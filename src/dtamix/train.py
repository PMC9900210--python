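"""Training/prediction orchestration: featurized dataset assembly, the epoch
loop with early stopping, checkpointing and batched inference."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig, TrainConfig
from .data_io import AffinitySample, DrugRecord, ProteinRecord
from .featurize import (build_we_vocab, encode_drug_fcfp, encode_protein_aae,
                        encode_protein_we, smiles_to_graph)
from .metrics import mse
from .mix_decoder import predict_binding_region
from .model import DTAModel
from .nn import AdamW
from .objectives import embed_site_labels, joint_loss

logger = logging.getLogger("dtamix")

__all__ = ["FeaturizedDataset", "TrainResult", "train", "predict",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class FeaturizedDataset:
    """Pre-encoded tensors for every protein/drug plus per-pair label data."""

    cfg: ModelConfig
    vocab: dict[str, int]
    protein_ids: list[str]
    drug_ids: list[str]
    aae: np.ndarray          # (n_prot, L_P)
    we: np.ndarray           # (n_prot, L_P)
    fingerprints: np.ndarray  # (n_drug, fcfp_bits)
    atoms: np.ndarray        # (n_drug, L_D, F_atom)
    adj: np.ndarray          # (n_drug, L_D, L_D)
    pair_protein: np.ndarray  # (n_pairs,) int
    pair_drug: np.ndarray    # (n_pairs,) int
    affinity: np.ndarray     # (n_pairs,)
    labels: np.ndarray       # (n_pairs, L_P) site label vectors
    site_mask: np.ndarray    # (n_pairs,) bool — pair has annotations
    sites: list[list[tuple[int, int]]] = field(default_factory=list)

    @classmethod
    def build(cls, proteins: list[ProteinRecord], drugs: list[DrugRecord],
              samples: list[AffinitySample], cfg: ModelConfig,
              vocab: dict[str, int] | None = None) -> "FeaturizedDataset":
        if vocab is None:
            vocab = build_we_vocab([p.sequence for p in proteins], cfg.we_k,
                                   cfg.we_vocab_size)
        pindex = {p.id: i for i, p in enumerate(proteins)}
        dindex = {d.id: i for i, d in enumerate(drugs)}
        aae = np.zeros((len(proteins), cfg.l_p), dtype=np.int64)
        we = np.zeros((len(proteins), cfg.l_p), dtype=np.int64)
        for i, p in enumerate(proteins):
            aae[i], _ = encode_protein_aae(p.sequence, cfg.l_p)
            we[i] = encode_protein_we(p.sequence, cfg.we_k, vocab, cfg.l_p)
        fps = np.zeros((len(drugs), cfg.fcfp_bits))
        adj = np.zeros((len(drugs), cfg.l_d, cfg.l_d))
        atom_rows = []
        for j, d in enumerate(drugs):
            fps[j] = encode_drug_fcfp(d.smiles, cfg.fcfp_radius, cfg.fcfp_bits)
            a, m, _ = smiles_to_graph(d.smiles, cfg.l_d)
            atom_rows.append(a)
            adj[j] = m
        atoms = np.stack(atom_rows)
        n = len(samples)
        pair_p = np.array([pindex[s.protein_id] for s in samples])
        pair_d = np.array([dindex[s.drug_id] for s in samples])
        affinity = np.array([s.affinity for s in samples])
        labels = np.zeros((n, cfg.l_p))
        site_mask = np.zeros(n, dtype=bool)
        sites = []
        for k, s in enumerate(samples):
            prot = proteins[pindex[s.protein_id]]
            sites.append(list(prot.sites))
            if prot.sites:
                labels[k] = embed_site_labels(prot.sites, s.affinity, cfg.l_p)
                site_mask[k] = True
        return cls(cfg=cfg, vocab=vocab,
                   protein_ids=[p.id for p in proteins],
                   drug_ids=[d.id for d in drugs], aae=aae, we=we,
                   fingerprints=fps, atoms=atoms, adj=adj,
                   pair_protein=pair_p, pair_drug=pair_d, affinity=affinity,
                   labels=labels, site_mask=site_mask, sites=sites)

    def __len__(self) -> int:
        return len(self.affinity)

    def batch(self, idx: np.ndarray) -> dict[str, np.ndarray]:
        p, d = self.pair_protein[idx], self.pair_drug[idx]
        return {"aae": self.aae[p], "we": self.we[p],
                "fingerprint": self.fingerprints[d], "atoms": self.atoms[d],
                "adj": self.adj[d], "affinity": self.affinity[idx],
                "labels": self.labels[idx], "site_mask": self.site_mask[idx]}


@dataclass
class TrainResult:
    model: DTAModel
    best_state: dict[str, np.ndarray]
    history: list[dict[str, float]]
    best_epoch: int
    best_valid_mse: float


def _check_finite(value: float, stage: str) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite loss at stage {stage!r}")


def _forward_loss(model: DTAModel, batch: dict[str, np.ndarray]):
    pred, s = model(batch)
    cfg = model.cfg
    return joint_loss(pred, batch["affinity"], s, batch["labels"],
                      lambda_br=cfg.loss.lambda_br, params=cfg.loss,
                      site_mask=batch["site_mask"]), pred


def train(dataset: FeaturizedDataset, model_cfg: ModelConfig,
          train_cfg: TrainConfig, train_idx: np.ndarray,
          valid_idx: np.ndarray) -> TrainResult:
    """Epoch loop with AdamW, early stopping on validation MSE.

    Fully deterministic given ``train_cfg.seed`` (model init, batch order and
    dropout masks all derive from it).
    """
    model_cfg = replace(model_cfg, dropout=train_cfg.dropout)
    model = DTAModel(model_cfg, seed=train_cfg.seed)
    opt = AdamW(model.parameters(), lr=train_cfg.lr,
                weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed + 1)
    history: list[dict[str, float]] = []
    best_state = model.state_dict()
    best_valid = float("inf")
    best_epoch = -1
    bad_epochs = 0
    for epoch in range(train_cfg.epochs):
        model.train()
        order = rng.permutation(train_idx)
        total, count = 0.0, 0
        for lo in range(0, len(order), train_cfg.batch_size):
            idx = order[lo:lo + train_cfg.batch_size]
            batch = dataset.batch(idx)
            loss, _ = _forward_loss(model, batch)
            _check_finite(loss.item(), f"epoch {epoch} train loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
            count += len(idx)
        train_loss = total / max(count, 1)
        valid_mse = _evaluate_mse(model, dataset, valid_idx,
                                  train_cfg.batch_size)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "valid_mse": valid_mse})
        logger.info("epoch %d: train_loss=%.5f valid_mse=%.5f", epoch,
                    train_loss, valid_mse)
        if valid_mse < best_valid:
            best_valid = valid_mse
            best_state = model.state_dict()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= train_cfg.patience:
                logger.info("early stop at epoch %d", epoch)
                break
    model.load_state_dict(best_state)
    return TrainResult(model=model, best_state=best_state, history=history,
                       best_epoch=best_epoch, best_valid_mse=best_valid)


def _evaluate_mse(model: DTAModel, dataset: FeaturizedDataset,
                  idx: np.ndarray, batch_size: int) -> float:
    if len(idx) == 0:
        return float("nan")
    preds = predict_array(model, dataset, idx, batch_size)[0]
    return mse(preds, dataset.affinity[idx])


def predict_array(model: DTAModel, dataset: FeaturizedDataset,
                  idx: np.ndarray, batch_size: int = 16
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode forward over ``idx``: (affinities, response matrix)."""
    model.eval()
    preds, responses = [], []
    for lo in range(0, len(idx), batch_size):
        batch = dataset.batch(np.asarray(idx)[lo:lo + batch_size])
        pred, s = model(batch)
        preds.append(pred.data)
        responses.append(s.data)
    model.train()
    return np.concatenate(preds), np.concatenate(responses)


def predict(model: DTAModel, dataset: FeaturizedDataset, idx: np.ndarray,
            scales: tuple[int, ...] = (5, 10, 15),
            batch_size: int = 16) -> pd.DataFrame:
    """Per-pair predictions: affinity, response peak, interval per scale."""
    idx = np.asarray(idx)
    preds, responses = predict_array(model, dataset, idx, batch_size)
    rows = []
    for k, i in enumerate(idx):
        s = responses[k]
        peak = int(np.argmax(s))
        row = {"drug_id": dataset.drug_ids[dataset.pair_drug[i]],
               "protein_id": dataset.protein_ids[dataset.pair_protein[i]],
               "pred_affinity": preds[k], "peak": peak,
               "peak_score": float(s[peak])}
        for scale in scales:
            start, end = predict_binding_region(s, scale)
            row[f"start_s{scale}"] = start
            row[f"end_s{scale}"] = end
        rows.append(row)
    return pd.DataFrame(rows)


def save_checkpoint(path: str | Path, model: DTAModel,
                    vocab: dict[str, int]) -> None:
    """Single-file checkpoint: npz of parameters + embedded JSON config."""
    meta = json.dumps({"config": model.cfg.to_dict(), "vocab": vocab})
    buf = {name: value for name, value in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **buf)


def load_checkpoint(path: str | Path) -> tuple[DTAModel, dict[str, int]]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = ModelConfig.from_dict(meta["config"])
    model = DTAModel(cfg, seed=0)
    model.load_state_dict(state)
    return model, meta["vocab"]
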