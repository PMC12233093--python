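"""Dataset splitting, batch assembly and the optimization loop.

Splits are structure-disjoint: molecules are grouped by the first InChIKey
block and whole groups (with all their spectra) go to one side, so no
connectivity-identical structure appears in both train and test.

During the fine-tuning phase each spectrum in a batch carries ``kaug``
regularization candidates of its target, taken sequentially from the
target's Tanimoto-descending candidate list through a wrapping per-target
cursor — hardest decoys first, the rest cycled in over successive epochs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import objective as obj
from . import _autodiff as ad
from .chem import CandidateSet, Molecule, MoleculeGraph, featurize_molecule
from .encoders import EncoderParams, Weights, encode_molecules, encode_spectra, init_weights
from .objective import ObjectiveConfig
from .spectra import Spectrum, bin_all

log = logging.getLogger(__name__)


@dataclass
class PairedDataset:
    """Matched (spectrum, molecule) pairs with lookup tables.

    A molecule has one structural view but may own several spectra measured
    under different instrument conditions; every spectrum maps to exactly
    one molecule.
    """

    pairs: list[tuple[str, str]]
    spectra: dict[str, Spectrum]
    molecules: dict[str, Molecule]
    candidate_sets: dict[str, CandidateSet] = field(default_factory=dict)

    def __post_init__(self):
        for sid, mid in self.pairs:
            if mid not in self.molecules:
                raise ValueError(f"pair references unknown molecule {mid!r}")
            if sid not in self.spectra:
                raise ValueError(f"pair references unknown spectrum {sid!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    def molecule_ids(self) -> list[str]:
        return sorted({mid for _, mid in self.pairs})


@dataclass
class TrainingConfig:
    batch_size: int = 32
    kaug: int = 8
    epochs: int = 100
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    lr_decay: bool = False  # cosine decay of the learning rate over epochs
    seed: int = 0
    unique_molecules_per_batch: bool = False
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    encoder: EncoderParams = field(default_factory=EncoderParams)


@dataclass
class Batch:
    spectrum_ids: list[str]
    molecule_ids: list[str]
    candidates: list[list[Molecule]]  # per spectrum; empty in phase 1


class CandidateCursor:
    """Per-target wrapping position into the Tanimoto-sorted candidate list."""

    def __init__(self):
        self._pos: dict[str, int] = {}

    def take(self, cset: CandidateSet, kaug: int) -> list[Molecule]:
        cands = cset.candidates
        if not cands or kaug == 0:
            return []
        pos = self._pos.get(cset.target_id, 0)
        out = [cands[(pos + i) % len(cands)] for i in range(kaug)]
        self._pos[cset.target_id] = (pos + kaug) % len(cands)
        return out


def split_structure_disjoint(
    ds: PairedDataset, test_fraction: float, seed: int
) -> tuple[PairedDataset, PairedDataset]:
    """Partition by InChIKey connectivity groups; spectra follow molecules."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    groups: dict[str, list[str]] = {}
    for mid in {m for _, m in ds.pairs}:
        groups.setdefault(ds.molecules[mid].inchikey_block1, []).append(mid)
    if len(groups) < 2:
        raise ValueError("need at least 2 structure groups to split")
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n_mols = sum(len(v) for v in groups.values())
    target = test_fraction * n_mols
    test_keys: set[str] = set()
    count = 0
    for key in keys:
        if count >= target:
            break
        test_keys.add(key)
        count += len(groups[key])

    def subset(pred) -> PairedDataset:
        pairs = [
            (s, m) for s, m in ds.pairs
            if pred(ds.molecules[m].inchikey_block1)
        ]
        mids = {m for _, m in pairs}
        sids = {s for s, _ in pairs}
        return PairedDataset(
            pairs=pairs,
            spectra={k: v for k, v in ds.spectra.items() if k in sids},
            molecules={k: v for k, v in ds.molecules.items() if k in mids},
            candidate_sets={k: v for k, v in ds.candidate_sets.items() if k in mids},
        )

    return subset(lambda k: k not in test_keys), subset(lambda k: k in test_keys)


def make_batches(
    train: PairedDataset,
    cfg: TrainingConfig,
    epoch: int,
    cursor: CandidateCursor,
) -> list[Batch]:
    """Shuffled batches for one epoch (1-based), short final batch allowed.

    In the regularization phase each spectrum carries the next ``kaug``
    candidates of its target from the cursor; targets with empty candidate
    sets contribute none and are simply skipped by the regularization term.
    """
    if not train.pairs:
        raise ValueError("cannot batch an empty training set")
    rng = np.random.default_rng([cfg.seed, epoch])
    order = rng.permutation(len(train.pairs))
    pairs = [train.pairs[i] for i in order]
    if cfg.unique_molecules_per_batch:
        pairs = _defer_duplicates(pairs, cfg.batch_size)
    _, beta = obj.schedule_weights(epoch, cfg.epochs, cfg.objective)
    batches = []
    for lo in range(0, len(pairs), cfg.batch_size):
        chunk = pairs[lo : lo + cfg.batch_size]
        cands: list[list[Molecule]] = []
        for _, mid in chunk:
            cset = train.candidate_sets.get(mid)
            if beta > 0 and cset is not None:
                cands.append(cursor.take(cset, cfg.kaug))
            else:
                cands.append([])
        batches.append(
            Batch(
                spectrum_ids=[s for s, _ in chunk],
                molecule_ids=[m for _, m in chunk],
                candidates=cands,
            )
        )
    return batches


def _defer_duplicates(pairs, batch_size):
    """Reorder so a molecule appears at most once per batch where possible."""
    out, pending = [], list(pairs)
    while pending:
        seen, batch, rest = set(), [], []
        for p in pending:
            if len(batch) < batch_size and p[1] not in seen:
                seen.add(p[1])
                batch.append(p)
            else:
                rest.append(p)
        out += batch
        pending = rest
    return out


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: Weights, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay  # decoupled (AdamW-style)
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def rebind(self, params: Weights) -> "Adam":
        """Copy of this optimizer state bound to a new parameter dict
        (used when branching fine-tuning variants off one checkpoint)."""
        other = Adam(params, lr=self.lr, betas=self.betas, eps=self.eps,
                     weight_decay=self.weight_decay)
        other.t = self.t
        other.m = {k: v.copy() for k, v in self.m.items()}
        other.v = {k: v.copy() for k, v in self.v.items()}
        return other

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )


@dataclass
class TrainingReport:
    epochs: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)


class _GraphCache:
    def __init__(self):
        self._cache: dict[str, MoleculeGraph] = {}

    def get(self, m: Molecule) -> MoleculeGraph:
        g = self._cache.get(m.molecule_id)
        if g is None:
            g = self._cache[m.molecule_id] = featurize_molecule(m)
        return g


def train(
    ds: PairedDataset,
    cfg: TrainingConfig,
    weights: Weights | None = None,
    start_epoch: int = 1,
    graph_cache: "_GraphCache | None" = None,
    optimizer: Adam | None = None,
    return_optimizer: bool = False,
):
    """Minimize the scheduled total loss over the paired dataset.

    Deterministic under a fixed seed/config (single-threaded NumPy).
    ``weights``/``start_epoch``/``optimizer`` allow resuming, which the
    ablation suite uses to branch fine-tuning variants off a shared
    phase-1 state with continuous optimizer moments.  Candidates are
    encoded by the same molecular encoder with gradients on.
    """
    if not ds.pairs:
        raise ValueError("training requires a non-empty paired dataset")
    if weights is None:
        weights = init_weights(cfg.encoder)
    if optimizer is None:
        optimizer = Adam(weights, lr=cfg.learning_rate,
                         weight_decay=cfg.weight_decay)
    elif optimizer.params is not weights:
        optimizer = optimizer.rebind(weights)
    # re-play optimizer step count when resuming so schedules stay aligned
    cache = graph_cache or _GraphCache()
    binned, sids = bin_all(ds.spectra.values())
    row_of = {sid: i for i, sid in enumerate(sids)}
    cursor = CandidateCursor()
    report = TrainingReport()

    for epoch in range(start_epoch, cfg.epochs + 1):
        if cfg.lr_decay:
            # cosine decay with a floor so the late fine-tuning phase
            # (regularization epochs) can still move the weights
            frac = 0.5 * (1.0 + math.cos(math.pi * (epoch - 1) / cfg.epochs))
            optimizer.lr = cfg.learning_rate * max(frac, 0.1)
        alpha, beta = obj.schedule_weights(epoch, cfg.epochs, cfg.objective)
        batches = make_batches(ds, cfg, epoch, cursor)
        lc_sum = lr_sum = 0.0
        n_lr = 0
        for bi, batch in enumerate(batches):
            drop_rng = np.random.default_rng([cfg.seed, epoch, bi, 7])
            spec = encode_spectra(
                binned[[row_of[s] for s in batch.spectrum_ids]],
                weights, cfg.encoder, dropout_rng=drop_rng,
            )
            mols = encode_molecules(
                [cache.get(ds.molecules[m]) for m in batch.molecule_ids],
                weights, cfg.encoder, dropout_rng=drop_rng,
            )
            lc = obj.batch_loss(spec, mols, cfg.objective)
            lr_val = 0.0
            if beta > 0:
                flat: list[Molecule] = []
                owners: list[int] = []
                keep_rows = [i for i, c in enumerate(batch.candidates) if c]
                for new_i, i in enumerate(keep_rows):
                    flat += batch.candidates[i]
                    owners += [new_i] * len(batch.candidates[i])
                if flat:
                    cand = encode_molecules(
                        [cache.get(m) for m in flat], weights, cfg.encoder,
                        dropout_rng=drop_rng,
                    )
                    spec_kept = ad.gather(spec, np.array(keep_rows))
                    lr_t = obj.regularization_loss(spec_kept, cand, owners=owners)
                    loss = lc * alpha + lr_t * beta
                    lr_val = float(lr_t.data)
                    n_lr += 1
                else:
                    loss = lc * alpha
            else:
                loss = lc * alpha
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bi}: training diverged"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            lc_sum += float(lc.data)
            lr_sum += lr_val
        report.epochs.append(
            {
                "epoch": epoch,
                "loss_contrastive": lc_sum / len(batches),
                "loss_regularization": lr_sum / max(n_lr, 1),
                "alpha": alpha,
                "beta": beta,
            }
        )
        log.info(
            "epoch %d/%d Lc=%.4f Lr=%.4f alpha=%.2f beta=%.2f",
            epoch, cfg.epochs, report.epochs[-1]["loss_contrastive"],
            report.epochs[-1]["loss_regularization"], alpha, beta,
        )
    if return_optimizer:
        return weights, report, optimizer
    return weights, report
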