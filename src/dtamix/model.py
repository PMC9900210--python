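"""Full model assembly: embeddings → encoders → fusion → decoder."""

from __future__ import annotations

import numpy as np

from .bio_blocks import DrugEncoder, ProteinEncoder
from .config import ModelConfig
from .featurize import AA_VOCAB_SIZE, ATOM_FEATURE_DIM
from .fusion import ChannelAlign, ElemFeatureFusion
from .mix_decoder import MixDecoder
from .nn import Embedding, Linear, Module, Tensor

__all__ = ["DTAModel"]


class DTAModel(Module):
    """Predicts (binding affinity, per-residue response vector) for a batch.

    Protein branch: residue-token and k-mer-token index maps are embedded,
    encoded by separate convolutional token-mixer stacks and fused.
    Drug branch: the folded fingerprint is projected and broadcast along the
    atom axis; atom features are projected and smoothed once over the bond
    graph; both are encoded by MLP token-mixer stacks and fused.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.aae_embed = Embedding(AA_VOCAB_SIZE, cfg.c_p, rng)
        self.we_embed = Embedding(cfg.we_vocab_size + 2, cfg.c_p, rng)
        self.protein_enc_aae = ProteinEncoder(cfg, rng)
        self.protein_enc_we = ProteinEncoder(cfg, rng)
        self.align_p1 = ChannelAlign(cfg.c_p, cfg.c_s, rng)
        self.align_p2 = ChannelAlign(cfg.c_p, cfg.c_s, rng)
        self.fuse_protein = ElemFeatureFusion(cfg.c_s, cfg.kernel_2d, rng,
                                              cfg.share_fc1)

        self.fp_proj = Linear(cfg.fcfp_bits, cfg.c_d, rng)
        self.atom_proj = Linear(ATOM_FEATURE_DIM, cfg.c_d, rng)
        self.drug_enc_fp = DrugEncoder(cfg, rng)
        self.drug_enc_graph = DrugEncoder(cfg, rng)
        self.align_d1 = ChannelAlign(cfg.c_d, cfg.c_s, rng)
        self.align_d2 = ChannelAlign(cfg.c_d, cfg.c_s, rng)
        self.fuse_drug = ElemFeatureFusion(cfg.c_s, cfg.kernel_2d, rng,
                                           cfg.share_fc1)

        self.decoder = MixDecoder(cfg, rng)

    # -- branches -------------------------------------------------------------
    def protein_features(self, aae: np.ndarray, we: np.ndarray) -> Tensor:
        x1 = self.protein_enc_aae(self.aae_embed(aae))
        x2 = self.protein_enc_we(self.we_embed(we))
        return self.fuse_protein(self.align_p1(x1), self.align_p2(x2))

    def drug_features(self, fingerprint: np.ndarray, atoms: np.ndarray,
                      adj: np.ndarray) -> Tensor:
        b = fingerprint.shape[0]
        cfg = self.cfg
        fp = self.fp_proj(Tensor(fingerprint)).reshape(b, 1, cfg.c_d)
        x1 = fp + Tensor(np.zeros((cfg.l_d, cfg.c_d)))  # broadcast over atoms
        # one hop of mean aggregation over the bond graph (adj has self-loops)
        deg = np.maximum(adj.sum(axis=-1, keepdims=True), 1.0)
        x2 = Tensor(adj / deg) @ self.atom_proj(Tensor(atoms))
        x1 = self.drug_enc_fp(x1)
        x2 = self.drug_enc_graph(x2)
        return self.fuse_drug(self.align_d1(x1), self.align_d2(x2))

    def forward(self, batch: dict[str, np.ndarray]) -> tuple[Tensor, Tensor]:
        fp_map = self.protein_features(batch["aae"], batch["we"])
        fd_map = self.drug_features(batch["fingerprint"], batch["atoms"],
                                    batch["adj"])
        return self.decoder(fp_map, fd_map, batch["adj"])
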