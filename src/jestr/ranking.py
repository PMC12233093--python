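"""Inference-time candidate ranking and evaluation.

For a query spectrum the target and every formula-matched candidate are
embedded with the molecular encoder, scored against the spectrum embedding
by cosine similarity (or raw dot product, as an ablation), and sorted
descending.  rank@k is the percentage of queries whose target lands at
position k or better; one trial per query spectrum.

Ties are resolved pessimistically: the target's rank counts every
competitor scoring greater than OR equal to it, so score collisions can
never inflate rank@1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .chem import CandidateSet, Molecule
from .encoders import Embedding, EncoderParams, Weights, encode_molecules
from .training import PairedDataset, _GraphCache
from .spectra import bin_all
from .encoders import encode_spectra

Score = Literal["cosine", "dotproduct"]


@dataclass
class RankingResult:
    spectrum_id: str
    target_id: str
    scored_candidates: list[tuple[str, float]]  # descending score
    target_rank: int


@dataclass
class EvaluationReport:
    results: list[RankingResult]
    rank_at_k: dict[int, float]
    rank_curve: list[float]
    matching_mean: float | None = None
    candidate_mean: float | None = None
    histogram: dict | None = None

    def to_tsv(self, path: str | Path) -> None:
        """Rank curve as a two-column TSV (k, rank@k percentage)."""
        lines = ["k\trank_at_k_pct"] + [
            f"{k}\t{v:.4f}" for k, v in enumerate(self.rank_curve, start=1)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rank_at_k": {str(k): v for k, v in self.rank_at_k.items()},
            "rank_curve": self.rank_curve,
            "matching_mean": self.matching_mean,
            "candidate_mean": self.candidate_mean,
            "histogram": self.histogram,
            "results": [asdict(r) for r in self.results],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _scores(z_spec: np.ndarray, mol_vecs: np.ndarray, score: Score) -> np.ndarray:
    if score == "dotproduct":
        return mol_vecs @ z_spec
    zn = z_spec / np.linalg.norm(z_spec)
    norms = np.linalg.norm(mol_vecs, axis=1)
    return (mol_vecs @ zn) / np.where(norms == 0, 1.0, norms)


def rank_candidates(
    z_spec: Embedding | np.ndarray,
    target: Molecule,
    cset: CandidateSet,
    weights: Weights,
    params: EncoderParams,
    score: Score = "cosine",
    graph_cache: _GraphCache | None = None,
    spectrum_id: str = "",
) -> RankingResult:
    """Score target + candidates against the spectrum and rank them.

    The target is injected into the scored pool, so every ranking contains
    exactly one true answer.  An empty candidate set yields target_rank 1
    (degenerate trial).
    """
    zs = np.asarray(getattr(z_spec, "vector", z_spec), dtype=float).ravel()
    cache = graph_cache or _GraphCache()
    pool = [target] + [c for c in cset.candidates if c.molecule_id != target.molecule_id]
    vecs = encode_molecules([cache.get(m) for m in pool], weights, params).data
    s = _scores(zs, vecs, score)
    target_score = s[0]
    # pessimistic: competitors >= target all outrank it
    rank = 1 + int(np.sum(s[1:] >= target_score))
    order = np.argsort(-s, kind="stable")
    scored = [(pool[i].molecule_id, float(s[i])) for i in order]
    return RankingResult(
        spectrum_id=spectrum_id or getattr(z_spec, "source_id", ""),
        target_id=target.molecule_id,
        scored_candidates=scored,
        target_rank=rank,
    )


def rank_at_k(results: Sequence[RankingResult], k: int) -> float:
    """Percentage of queries whose target ranks at position k or better."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not results:
        raise ValueError("rank_at_k requires at least one result")
    hits = sum(1 for r in results if r.target_rank <= k)
    return 100.0 * hits / len(results)


def relative_improvement(a: float, b: float) -> float:
    """Relative gain of a over b in percent: 100 * (a - b) / b."""
    if b == 0:
        raise ZeroDivisionError("relative improvement undefined for zero baseline")
    return 100.0 * (a - b) / b


def evaluate(
    ds: PairedDataset,
    weights: Weights,
    params: EncoderParams,
    score: Score = "cosine",
    ks: Sequence[int] = (1, 5, 20),
    max_k_curve: int = 20,
    per_molecule: bool = False,
) -> EvaluationReport:
    """Rank every (spectrum, molecule) pair of ``ds`` against its candidates.

    ``per_molecule=True`` aggregates by molecule instead (best spectrum per
    molecule counts as the molecule's trial); the default treats each query
    spectrum as one trial.
    """
    cache = _GraphCache()
    binned, sids = bin_all(ds.spectra.values())
    row_of = {sid: i for i, sid in enumerate(sids)}
    spec_vecs = encode_spectra(binned, weights, params).data
    results = []
    match_cos, cand_cos = [], []
    for sid, mid in ds.pairs:
        target = ds.molecules[mid]
        cset = ds.candidate_sets.get(mid) or CandidateSet(mid, [], "formula")
        zs = spec_vecs[row_of[sid]]
        res = rank_candidates(
            zs, target, cset, weights, params, score=score,
            graph_cache=cache, spectrum_id=sid,
        )
        results.append(res)
        if score == "cosine":  # scores are cosines; reuse for diagnostics
            cos = dict(res.scored_candidates)
            match_cos.append(cos[mid])
            cand_cos += [v for m, v in cos.items() if m != mid]

    trials = results
    if per_molecule:
        best: dict[str, RankingResult] = {}
        for r in trials:
            cur = best.get(r.target_id)
            if cur is None or r.target_rank < cur.target_rank:
                best[r.target_id] = r
        trials = list(best.values())

    hist = np.histogram(cand_cos, bins=50, range=(-1.0, 1.0)) if cand_cos else None
    return EvaluationReport(
        results=trials,
        rank_at_k={k: rank_at_k(trials, k) for k in ks},
        rank_curve=[rank_at_k(trials, k) for k in range(1, max_k_curve + 1)],
        matching_mean=float(np.mean(match_cos)) if match_cos else None,
        candidate_mean=float(np.mean(cand_cos)) if cand_cos else None,
        histogram=None if hist is None else {
            "counts": hist[0].tolist(), "edges": hist[1].tolist()
        },
    )


def similarity_distributions(
    ds: PairedDataset,
    weights: Weights,
    params: EncoderParams,
    bins: int = 50,
) -> dict:
    """Empirical cosine distributions for matched pairs vs spectrum-candidate
    pairs (the non-matching pool restricted to formula-matched candidates)."""
    cache = _GraphCache()
    binned, sids = bin_all(ds.spectra.values())
    row_of = {sid: i for i, sid in enumerate(sids)}
    spec_vecs = encode_spectra(binned, weights, params).data
    match, nonmatch = [], []
    for sid, mid in ds.pairs:
        zs = spec_vecs[row_of[sid]]
        zsn = zs / max(np.linalg.norm(zs), 1e-12)
        tgt_vec = encode_molecules(
            [cache.get(ds.molecules[mid])], weights, params
        ).data[0]
        match.append(float(tgt_vec @ zsn / max(np.linalg.norm(tgt_vec), 1e-12)))
        cset = ds.candidate_sets.get(mid)
        if cset and cset.candidates:
            vecs = encode_molecules(
                [cache.get(m) for m in cset.candidates], weights, params
            ).data
            norms = np.maximum(np.linalg.norm(vecs, axis=1), 1e-12)
            nonmatch += list((vecs @ zsn) / norms)
    out = {
        "matching_mean": float(np.mean(match)),
        "matching_n": len(match),
        "candidate_mean": float(np.mean(nonmatch)) if nonmatch else None,
        "candidate_n": len(nonmatch),
    }
    mh = np.histogram(match, bins=bins, range=(-1.0, 1.0))
    out["matching_hist"] = {"counts": mh[0].tolist(), "edges": mh[1].tolist()}
    if nonmatch:
        ch = np.histogram(nonmatch, bins=bins, range=(-1.0, 1.0))
        out["candidate_hist"] = {"counts": ch[0].tolist(), "edges": ch[1].tolist()}
    return out
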