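"""The Omicsformer network.

Per-omics self-attention encoders produce low-dimensional sample
embeddings H^(i); these are concatenated and passed through a second
attention block ("fusion") that reduces the joint representation to a
fixed width d_mul; a softmax head classifies samples; affine decoders map
each H^(i) back to the input space for the reconstruction objective.

Attention here runs across the *samples* of a batch — QK^T is n x n — so
a sample's embedding depends on the batch it is embedded with.  The
package trains and predicts with full-batch attention (each split as one
batch), which keeps every output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import (
    affine_forward,
    attention_forward,
    attention_scale,
    init_matrix,
    softmax_rows,
)
from .dataio import MultiOmicsDataset


@dataclass
class AttentionBlockParams:
    """Learnable Q/K/V projections of one self-attention block."""

    W_Q: np.ndarray
    W_K: np.ndarray
    W_V: np.ndarray
    scale_dim: int
    scale_mode: str = "sqrt"  # "sqrt" -> /sqrt(d); "linear" -> /d

    def __post_init__(self) -> None:
        if not (self.W_Q.shape == self.W_K.shape == self.W_V.shape):
            raise ValueError("W_Q, W_K, W_V must share shape")
        if self.scale_dim != self.W_Q.shape[1]:
            raise ValueError("scale_dim must equal the projection width")

    @property
    def d_in(self) -> int:
        return self.W_Q.shape[0]

    @property
    def d_out(self) -> int:
        return self.W_Q.shape[1]

    @property
    def scale(self) -> float:
        return attention_scale(self.scale_dim, self.scale_mode)


@dataclass
class Affine:
    W: np.ndarray
    b: np.ndarray


@dataclass
class OmicsformerModel:
    """All learnable parameters plus the dimension record.

    ``blocks[i]`` encodes layer i (d_i -> d_hidden_i), ``decoders[i]``
    maps back (d_hidden_i -> d_i), ``fusion`` attends over the
    concatenation (sum d_hidden -> d_mul), ``head`` is the affine
    classifier (d_mul -> n_classes).
    """

    blocks: list[AttentionBlockParams]
    decoders: list[Affine]
    fusion: AttentionBlockParams
    head: Affine
    layer_names: list[str]
    n_classes: int
    seed: int
    history: dict = field(default_factory=dict)
    # training batch stored at the end of finetuning; new samples are
    # embedded jointly with it so their attention context is the cohort
    # the model was trained on (kNN-style transductive scoring)
    reference: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(self.blocks) != len(self.decoders) or len(self.blocks) != len(self.layer_names):
            raise ValueError("blocks, decoders and layer_names must align")
        if self.fusion.d_in != sum(b.d_out for b in self.blocks):
            raise ValueError("fusion input width must equal sum of hidden widths")

    # -- construction --------------------------------------------------

    @classmethod
    def initialize(
        cls,
        layer_dims: dict[str, int],
        n_classes: int,
        d_hidden: int = 64,
        d_mul: int = 32,
        seed: int = 0,
        scale_mode: str = "sqrt",
    ) -> "OmicsformerModel":
        """Seeded scaled-normal initialization of every parameter."""
        rng = np.random.default_rng(seed)
        blocks, decoders = [], []
        for name, d in layer_dims.items():
            dh = min(d_hidden, d)
            blocks.append(
                AttentionBlockParams(
                    init_matrix(rng, d, dh),
                    init_matrix(rng, d, dh),
                    init_matrix(rng, d, dh),
                    scale_dim=dh,
                    scale_mode=scale_mode,
                )
            )
            decoders.append(Affine(init_matrix(rng, dh, d), np.zeros(d)))
        d_cat = sum(b.d_out for b in blocks)
        fusion = AttentionBlockParams(
            init_matrix(rng, d_cat, d_mul),
            init_matrix(rng, d_cat, d_mul),
            init_matrix(rng, d_cat, d_mul),
            scale_dim=d_mul,
            scale_mode=scale_mode,
        )
        head = Affine(init_matrix(rng, d_mul, n_classes), np.zeros(n_classes))
        return cls(blocks, decoders, fusion, head, list(layer_dims), n_classes, seed)

    # -- parameter bookkeeping -----------------------------------------

    def parameters(self) -> list[np.ndarray]:
        """Flat parameter list in a fixed order (shared with gradients)."""
        out = []
        for blk, dec in zip(self.blocks, self.decoders):
            out += [blk.W_Q, blk.W_K, blk.W_V, dec.W, dec.b]
        out += [self.fusion.W_Q, self.fusion.W_K, self.fusion.W_V]
        out += [self.head.W, self.head.b]
        return out

    def copy(self) -> "OmicsformerModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def _to_arrays(self):
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        if self.reference is not None:
            for i, r in enumerate(self.reference):
                arrays[f"ref{i}"] = r
        config = {
            "has_reference": self.reference is not None,
            "layer_names": self.layer_names,
            "layer_dims": [b.d_in for b in self.blocks],
            "hidden_dims": [b.d_out for b in self.blocks],
            "d_mul": self.fusion.d_out,
            "n_classes": self.n_classes,
            "seed": self.seed,
            "scale_mode": self.fusion.scale_mode,
        }
        return arrays, config

    @classmethod
    def _from_arrays(cls, arrays, config):
        model = cls.initialize(
            dict(zip(config["layer_names"], config["layer_dims"])),
            config["n_classes"],
            d_hidden=max(config["hidden_dims"]),
            d_mul=config["d_mul"],
            seed=config["seed"],
            scale_mode=config["scale_mode"],
        )
        for i, p in enumerate(model.parameters()):
            p[...] = arrays[f"p{i}"]
        if config.get("has_reference"):
            model.reference = [
                arrays[f"ref{i}"] for i in range(len(model.blocks))
            ]
        return model


# -- forward operations ----------------------------------------------------


def self_attention(X: np.ndarray, params: AttentionBlockParams) -> np.ndarray:
    """H = rowsoftmax(X W_Q (X W_K)^T / scale) X W_V, attention over samples."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != params.d_in:
        raise ValueError(
            f"input width {X.shape[1]} does not match block d_in {params.d_in}"
        )
    H, _ = attention_forward(X, params.W_Q, params.W_K, params.W_V, params.scale)
    return H


def encode_all(dataset: MultiOmicsDataset, model: OmicsformerModel) -> list[np.ndarray]:
    """One n x d_hidden_i embedding per omics layer."""
    if dataset.n_layers != len(model.blocks):
        raise ValueError(
            f"dataset has {dataset.n_layers} layers, model expects {len(model.blocks)}"
        )
    out = []
    for layer, blk in zip(dataset.layers, model.blocks):
        if np.isnan(layer.values).any():
            raise ValueError(f"layer {layer.omics_name!r} contains missing values")
        out.append(self_attention(layer.values, blk))
    return out


def concat_representations(H_list: list[np.ndarray]) -> np.ndarray:
    """Column-wise concatenation of per-omics embeddings, in layer order."""
    n = H_list[0].shape[0]
    for H in H_list[1:]:
        if H.shape[0] != n:
            raise ValueError("row-count mismatch across representations")
    return np.concatenate(H_list, axis=1)


def fuse(H_mul: np.ndarray, model: OmicsformerModel) -> np.ndarray:
    """Fixed-width fused representation H_F via the fusion attention block."""
    return self_attention(H_mul, model.fusion)


def classify(H_F: np.ndarray, model: OmicsformerModel) -> np.ndarray:
    """Per-sample class probabilities from the softmax head."""
    logits = affine_forward(H_F, model.head.W, model.head.b)
    return softmax_rows(logits)


def decode(H: np.ndarray, model: OmicsformerModel, i) -> np.ndarray:
    """Reconstruct layer ``i`` (index or name) from its embedding."""
    if isinstance(i, str):
        if i not in model.layer_names:
            raise KeyError(f"unknown omics layer {i!r}")
        i = model.layer_names.index(i)
    if not 0 <= i < len(model.decoders):
        raise KeyError(f"unknown omics layer index {i}")
    dec = model.decoders[i]
    return affine_forward(H, dec.W, dec.b)


def forward(
    dataset: MultiOmicsDataset, model: OmicsformerModel
) -> dict[str, object]:
    """Full forward pass; returns embeddings, fused rep, probabilities and
    reconstructions in one dict."""
    H_list = encode_all(dataset, model)
    H_mul = concat_representations(H_list)
    H_F = fuse(H_mul, model)
    P = classify(H_F, model)
    X_hat = [decode(H, model, i) for i, H in enumerate(H_list)]
    return {"H_list": H_list, "H_mul": H_mul, "H_F": H_F, "proba": P, "X_hat": X_hat}


def predict_proba(
    dataset: MultiOmicsDataset,
    model: OmicsformerModel,
    reference: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Class probabilities for new samples, scored against the reference.

    Because attention runs across the samples of a batch, a lone new
    sample carries no context; predictions therefore embed the query
    batch jointly with the stored training batch (``model.reference``,
    set at the end of finetuning) and read off the query rows.  Attention
    is permutation-equivariant, so each query's output is independent of
    the order of rows in the call.  Without a reference this falls back
    to embedding the query batch alone.
    """
    ref = reference if reference is not None else model.reference
    if ref is None:
        return forward(dataset, model)["proba"]
    n_query = dataset.n_samples
    H_list = []
    for lay, blk, r in zip(dataset.layers, model.blocks, ref):
        if np.isnan(lay.values).any():
            raise ValueError(f"layer {lay.omics_name!r} contains missing values")
        X = np.concatenate([np.asarray(r, dtype=float), lay.values], axis=0)
        H_list.append(self_attention(X, blk))
    H_F = fuse(concat_representations(H_list), model)
    return classify(H_F, model)[-n_query:]


def predict(
    dataset: MultiOmicsDataset,
    model: OmicsformerModel,
    reference: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Predicted class indices (argmax of the softmax head)."""
    return np.argmax(predict_proba(dataset, model, reference), axis=1)
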