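"""Per-visit field encoders: token embeddings plus a set-semantics transformer.

Each of a visit's three fields (diagnoses, drugs, symptoms) is encoded
independently: tokens are embedded -- diagnosis/drug tokens from the
ontology-attention leaf table (or a plain lookup table when knowledge
enhancement is ablated), symptom tokens from a learned dictionary table,
special tokens from their own learned vectors -- and run through a
multi-layer transformer.  No positional encodings are added (a field is a
set, not a sequence) and padded positions are excluded from attention, so
the [CLS]-state visit embedding is invariant to token order and padding.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Parameter, Tensor, concatenate, layer_norm, softmax
from .ontology import GraphAttentionEmbedding
from .records import SPECIALS, TokenizedVisit, Vocabulary

FIELDS = ("d", "m", "s")


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the visit encoder (defaults: 2 layers, 4 heads)."""

    width: int = 64
    layers: int = 2
    heads: int = 4
    ff_width: int | None = None  # defaults to 2 * width
    gat_heads: int = 4
    share_field_weights: bool = False
    use_ontology: bool = True  # False = plain leaf-code lookup (knowledge ablated)

    def __post_init__(self):
        if self.width % self.heads:
            raise ValueError("width must be divisible by heads")

    @property
    def ff(self) -> int:
        return self.ff_width or 2 * self.width


def _normal(rng: np.random.Generator, *shape: int, scale: float) -> np.ndarray:
    return rng.normal(0.0, scale, size=shape)


class TransformerBlock:
    """Post-norm transformer layer with masked multi-head self-attention."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator, tag: str):
        l, h = cfg.width, cfg.heads
        s = 1.0 / np.sqrt(l)
        self.heads = h
        self.head_dim = l // h
        self.Wq = Parameter(_normal(rng, l, l, scale=s), name=f"{tag}.Wq")
        self.Wk = Parameter(_normal(rng, l, l, scale=s), name=f"{tag}.Wk")
        self.Wv = Parameter(_normal(rng, l, l, scale=s), name=f"{tag}.Wv")
        self.Wo = Parameter(_normal(rng, l, l, scale=s), name=f"{tag}.Wo")
        self.ff1 = Parameter(_normal(rng, l, cfg.ff, scale=s), name=f"{tag}.ff1")
        self.ff1_b = Parameter(np.zeros(cfg.ff))
        self.ff2 = Parameter(_normal(rng, cfg.ff, l, scale=1.0 / np.sqrt(cfg.ff)))
        self.ff2_b = Parameter(np.zeros(l))
        self.ln1_g = Parameter(np.ones(l))
        self.ln1_b = Parameter(np.zeros(l))
        self.ln2_g = Parameter(np.ones(l))
        self.ln2_b = Parameter(np.zeros(l))

    @property
    def parameters(self) -> list[Parameter]:
        return [self.Wq, self.Wk, self.Wv, self.Wo, self.ff1, self.ff1_b,
                self.ff2, self.ff2_b, self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b]

    def __call__(self, x: Tensor, valid: np.ndarray) -> Tensor:
        B, S, l = x.shape
        h, dk = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:  # (B,S,l) -> (B,h,S,dk)
            return t.reshape(B, S, h, dk).transpose(0, 2, 1, 3)

        q, k, v = split(x @ self.Wq), split(x @ self.Wk), split(x @ self.Wv)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))  # (B,h,S,S)
        key_mask = valid[:, None, None, :]
        att = softmax(scores, axis=-1, mask=np.broadcast_to(key_mask, scores.shape))
        mixed = (att @ v).transpose(0, 2, 1, 3).reshape(B, S, l) @ self.Wo
        x = layer_norm(x + mixed, self.ln1_g, self.ln1_b)
        ff = ((x @ self.ff1 + self.ff1_b).relu()) @ self.ff2 + self.ff2_b
        return layer_norm(x + ff, self.ln2_g, self.ln2_b)


class FieldTransformer:
    """Stack of transformer blocks; returns the [CLS] (position 0) state."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator, tag: str):
        self.blocks = [TransformerBlock(cfg, rng, f"{tag}.layer{i}")
                       for i in range(cfg.layers)]

    @property
    def parameters(self) -> list[Parameter]:
        return [p for b in self.blocks for p in b.parameters]

    def __call__(self, x: Tensor, valid: np.ndarray) -> Tensor:
        for block in self.blocks:
            x = block(x, valid)
        return x[:, 0, :]  # aggregate sequence representation at [CLS]


class TokenEmbedder:
    """Maps one field's token-index rows to embedding rows.

    Diagnosis/drug code rows come from the ontology-attention table (or a
    plain learned lookup under the knowledge ablation); symptom rows from a
    learned dictionary table; the four special tokens have their own learned
    vectors.  An additive perturbation on the code table (used by the
    adversarial training step) can be injected per call.
    """

    def __init__(self, field: str, vocab: Vocabulary, cfg: EncoderConfig,
                 rng: np.random.Generator,
                 gat: GraphAttentionEmbedding | None = None):
        self.field = field
        self.vocab = vocab
        self.last_code_table: Tensor | None = None
        l = cfg.width
        self.specials = Parameter(_normal(rng, len(SPECIALS), l, scale=1.0 / np.sqrt(l)),
                                  name=f"{field}.specials")
        self.gat = gat
        if gat is not None:
            if gat.embed_dim != l:
                raise ValueError("ontology embedding width must match encoder width")
            # vocabulary code i -> row of the GAT leaf table
            self._rows = np.array([gat.leaf_row(c) for c in vocab.codes], dtype=np.intp)
            self.lookup = None
        else:
            self._rows = np.arange(vocab.n_codes, dtype=np.intp)
            self.lookup = Parameter(_normal(rng, max(vocab.n_codes, 1), l,
                                            scale=1.0 / np.sqrt(l)),
                                    name=f"{field}.lookup")

    @property
    def parameters(self) -> list[Parameter]:
        own = [self.specials] if self.lookup is None else [self.specials, self.lookup]
        return own  # GAT parameters are owned by the network (shared across fields)

    def code_table(self, perturbation: np.ndarray | None = None) -> Tensor:
        """The (n_codes, width) embedding table for real codes.

        The returned tensor is remembered as ``last_code_table`` so a caller
        can read the gradient of a loss with respect to the code embeddings
        (the quantity the adversarial perturbation is computed from).
        """
        base = self.gat.embed_all_leaves().take(self._rows) if self.gat is not None \
            else self.lookup.take(self._rows)
        self.last_code_table = base
        if perturbation is not None:
            base = base + Tensor(perturbation)
        return base

    def __call__(self, tokens: np.ndarray,
                 perturbation: np.ndarray | None = None) -> Tensor:
        """Embed an integer token matrix (..., S) -> (..., S, width)."""
        full = concatenate([self.specials, self.code_table(perturbation)], axis=0)
        return full.take(tokens)


class VisitEncoder:
    """The three field encoders plus their token embedders.

    Field encoders share hyperparameters; weights are separate by default
    (``share_field_weights=True`` collapses them to one stack).
    """

    def __init__(self, vocabularies: tuple[Vocabulary, Vocabulary, Vocabulary],
                 cfg: EncoderConfig, rng: np.random.Generator,
                 diag_gat: GraphAttentionEmbedding | None,
                 drug_gat: GraphAttentionEmbedding | None):
        self.cfg = cfg
        dvoc, mvoc, svoc = vocabularies
        self.embedders = {
            "d": TokenEmbedder("d", dvoc, cfg, rng, diag_gat),
            "m": TokenEmbedder("m", mvoc, cfg, rng, drug_gat),
            "s": TokenEmbedder("s", svoc, cfg, rng, None),
        }
        if cfg.share_field_weights:
            shared = FieldTransformer(cfg, rng, "enc")
            self.transformers = {f: shared for f in FIELDS}
        else:
            self.transformers = {f: FieldTransformer(cfg, rng, f"enc.{f}")
                                 for f in FIELDS}

    @property
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for f in FIELDS:
            params.extend(self.embedders[f].parameters)
        seen: set[int] = set()
        for f in FIELDS:
            for p in self.transformers[f].parameters:
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def token_embeddings(self, tokens: np.ndarray, field: str,
                         perturbation: np.ndarray | None = None) -> Tensor:
        return self.embedders[field](tokens, perturbation)

    def encode_field(self, tokens: np.ndarray, valid: np.ndarray, field: str,
                     perturbation: np.ndarray | None = None) -> Tensor:
        """Encode a (B, S) token batch to (B, width) visit embeddings."""
        if tokens.ndim != 2:
            raise ValueError("expected a (batch, positions) token matrix")
        cls_idx = self.embedders[field].vocab.index("[CLS]")
        if not np.all(tokens[:, 0] == cls_idx):
            raise ValueError("every sequence must start with [CLS]")
        x = self.token_embeddings(tokens, field, perturbation)
        return self.transformers[field](x, valid)

    def encode_visits(self, batch: Sequence[TokenizedVisit],
                      perturbations: Mapping[str, np.ndarray] | None = None,
                      ) -> dict[str, Tensor]:
        """Encode a batch of tokenized visits to the three (B, width) fields."""
        perturbations = perturbations or {}
        out: dict[str, Tensor] = {}
        for f in FIELDS:
            tokens = np.stack([tv.field(f) for tv in batch])
            valid = np.stack([tv.valid[f] for tv in batch])
            out[f] = self.encode_field(tokens, valid, f, perturbations.get(f))
        return out


def encode_visit(encoder: VisitEncoder, visit: TokenizedVisit) -> dict[str, np.ndarray]:
    """Convenience single-visit encoding; returns plain arrays v_d, v_m, v_s."""
    out = encoder.encode_visits([visit])
    return {f: out[f].data[0] for f in FIELDS}
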