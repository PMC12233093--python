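"""The two trainable encoders of the joint molecule-spectrum space.

The molecular encoder runs several rounds of graph convolution over the
heavy-atom graph (edge features concatenated into messages), pools nodes
with an elementwise max, and maps through a 2-layer MLP head into the
d-dimensional joint space.  The spectral encoder is a 3-layer MLP over the
1000-bin transformed spectrum vector.  Both emit vectors of the same
dimension d so cross-modal cosine similarity is meaningful.

Embeddings are deliberately NOT length-normalized here; normalization
happens inside cosine computations, which keeps dot-product scoring a
distinct, meaningful ablation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .chem import EDGE_FEATURE_DIM, NODE_FEATURE_DIM, MoleculeGraph
from .spectra import N_BINS, BinnedSpectrum


@dataclass
class EncoderParams:
    """Architecture hyperparameters shared by both encoders.

    ``embed_dim`` is the joint-space dimension d; the molecular head is a
    fixed 2-layer MLP and the spectral encoder a fixed 3-layer MLP.
    """

    gcn_layers: int = 3
    hidden_dim: int = 256
    embed_dim: int = 256
    activation: str = "relu"
    dropout_rate: float = 0.1
    use_edge_features: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.gcn_layers < 1 or self.hidden_dim < 1 or self.embed_dim < 1:
            raise ValueError("layer counts and dimensions must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")


@dataclass
class Embedding:
    """A point in the joint space, tagged with its modality and source."""

    vector: np.ndarray
    role: Literal["molecule", "spectrum"]
    source_id: str = ""

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding contains non-finite entries")


Weights = dict[str, Tensor]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_weights(p: EncoderParams) -> Weights:
    """Seeded Glorot-uniform initialization of both encoders' parameters."""
    rng = np.random.default_rng(p.seed)
    w: Weights = {}
    h, d = p.hidden_dim, p.embed_dim
    msg_extra = EDGE_FEATURE_DIM if p.use_edge_features else 0
    f_in = NODE_FEATURE_DIM
    for i in range(p.gcn_layers):
        w[f"gcn{i}_Wself"] = Tensor(_glorot(rng, f_in, h), requires_grad=True)
        w[f"gcn{i}_Wmsg"] = Tensor(_glorot(rng, f_in + msg_extra, h), requires_grad=True)
        w[f"gcn{i}_b"] = Tensor(np.zeros(h), requires_grad=True)
        f_in = h
    w["mol_W1"] = Tensor(_glorot(rng, h, h), requires_grad=True)
    w["mol_b1"] = Tensor(np.zeros(h), requires_grad=True)
    w["mol_W2"] = Tensor(_glorot(rng, h, d), requires_grad=True)
    w["mol_b2"] = Tensor(np.zeros(d), requires_grad=True)
    w["spec_W1"] = Tensor(_glorot(rng, N_BINS, h), requires_grad=True)
    w["spec_b1"] = Tensor(np.zeros(h), requires_grad=True)
    w["spec_W2"] = Tensor(_glorot(rng, h, h), requires_grad=True)
    w["spec_b2"] = Tensor(np.zeros(h), requires_grad=True)
    w["spec_W3"] = Tensor(_glorot(rng, h, d), requires_grad=True)
    w["spec_b3"] = Tensor(np.zeros(d), requires_grad=True)
    return w


def _dropout(t: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or rate <= 0.0:
        return t
    mask = (rng.random(t.shape) >= rate) / (1.0 - rate)
    return t * Tensor(mask)


def _batch_graphs(graphs: Sequence[MoleculeGraph]):
    """Disjoint union of molecule graphs for one batched forward pass."""
    nodes, efeats, srcs, dsts, seg = [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        if g.n_nodes == 0:
            raise ValueError("cannot encode an empty molecule graph")
        nodes.append(g.node_features)
        efeats.append(g.edge_features)
        srcs.append(g.edge_index[0] + offset)
        dsts.append(g.edge_index[1] + offset)
        seg.append(np.full(g.n_nodes, gi))
        offset += g.n_nodes
    return (
        np.concatenate(nodes, axis=0),
        np.concatenate(efeats, axis=0),
        np.concatenate(srcs),
        np.concatenate(dsts),
        np.concatenate(seg),
        offset,
    )


def encode_molecules(
    graphs: Sequence[MoleculeGraph],
    weights: Weights,
    p: EncoderParams,
    dropout_rng: np.random.Generator | None = None,
) -> Tensor:
    """Encode a batch of molecule graphs; returns a (batch, d) Tensor.

    Pass ``dropout_rng`` only during training; evaluation is deterministic.
    """
    X, E, src, dst, seg, n_nodes = _batch_graphs(graphs)
    if X.shape[1] != NODE_FEATURE_DIM:
        raise ValueError(
            f"node feature width {X.shape[1]} != expected {NODE_FEATURE_DIM}"
        )
    h = Tensor(X)
    efeat = Tensor(E)
    # degree normalization as in the Kipf-Welling convolution; isolated
    # nodes (single-atom molecules) simply keep their self term
    inv_deg = 1.0 / np.maximum(np.bincount(dst, minlength=n_nodes), 1)[:, None]
    for i in range(p.gcn_layers):
        if len(src) > 0:
            neigh = ad.gather(h, src)
            if p.use_edge_features:
                neigh = ad.concat([neigh, efeat], axis=1)
            msg = neigh @ weights[f"gcn{i}_Wmsg"]
            agg = ad.segment_sum(msg, dst, n_nodes) * Tensor(inv_deg)
        else:  # edgeless batch (single-atom molecules): self term only
            agg = Tensor(np.zeros((n_nodes, p.hidden_dim)))
        out = (h @ weights[f"gcn{i}_Wself"] + agg + weights[f"gcn{i}_b"]).relu()
        # residual once widths match: keeps lower-hop structure visible
        # to the max-pool readout in deeper stacks
        h = out + h if i > 0 else out
        h = _dropout(h, p.dropout_rate, dropout_rng)
    pooled = ad.segment_max(h, seg, len(graphs))
    z = (pooled @ weights["mol_W1"] + weights["mol_b1"]).relu()
    z = _dropout(z, p.dropout_rate, dropout_rng)
    return z @ weights["mol_W2"] + weights["mol_b2"]


def encode_spectra(
    binned: np.ndarray,
    weights: Weights,
    p: EncoderParams,
    dropout_rng: np.random.Generator | None = None,
) -> Tensor:
    """Encode a (batch, 1000) matrix of binned spectra into (batch, d)."""
    binned = np.atleast_2d(np.asarray(binned, dtype=float))
    if binned.shape[1] != N_BINS:
        raise ValueError(f"binned input width {binned.shape[1]} != {N_BINS}")
    z = (Tensor(binned) @ weights["spec_W1"] + weights["spec_b1"]).relu()
    z = _dropout(z, p.dropout_rate, dropout_rng)
    z = (z @ weights["spec_W2"] + weights["spec_b2"]).relu()
    z = _dropout(z, p.dropout_rate, dropout_rng)
    return z @ weights["spec_W3"] + weights["spec_b3"]


def encode_molecule(g: MoleculeGraph, p: EncoderParams, weights: Weights,
                    source_id: str = "") -> Embedding:
    vec = encode_molecules([g], weights, p).data[0]
    return Embedding(vector=vec, role="molecule", source_id=source_id)


def encode_spectrum(b: BinnedSpectrum, p: EncoderParams, weights: Weights) -> Embedding:
    vec = encode_spectra(b.values[None, :], weights, p).data[0]
    return Embedding(vector=vec, role="spectrum", source_id=b.source_id)


# ---------------------------------------------------------------------------
# checkpointing

def save_weights(weights: Weights, p: EncoderParams, path: str | Path) -> None:
    """Single-file archive with an embedded config header."""
    arrays = {k: t.data for k, t in weights.items()}
    header = json.dumps({"params": asdict(p), "format": 1})
    np.savez(path, __config__=np.array(header), **arrays)


def load_weights(path: str | Path) -> tuple[Weights, EncoderParams]:
    """Load a checkpoint, verifying shapes against its own config header."""
    with np.load(path, allow_pickle=False) as arc:
        if "__config__" not in arc:
            raise ValueError(f"{path}: not a jestr checkpoint (no config header)")
        header = json.loads(str(arc["__config__"]))
        p = EncoderParams(**header["params"])
        weights = {
            k: Tensor(arc[k], requires_grad=True) for k in arc.files if k != "__config__"
        }
    expected = init_weights(p)
    for k, t in expected.items():
        if k not in weights:
            raise ValueError(f"{path}: missing parameter {k!r}")
        if weights[k].shape != t.shape:
            raise ValueError(
                f"{path}: shape mismatch for {k!r}: "
                f"{weights[k].shape} vs expected {t.shape}"
            )
    return weights, p
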