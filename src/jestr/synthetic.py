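"""Seeded generator of self-contained molecule/spectrum datasets.

The generator emulates the statistical structure of a spectral library
paired with formula-matched decoys:

* molecules are assembled from a small grammar of substructure fragments;
  molecules built from the same fragment multiset are formula isomers, so
  the universe naturally contains isomer families that serve as
  formula-keyed candidate sets (true hard negatives, no external database);
* each molecule owns several spectral "views" (different instrument
  conditions) produced by an in-silico fragmenter: up to ``cut_depth``
  acyclic single bonds are cut, each connected fragment yields a peak at
  its protonated monoisotopic mass, with log-normal intensity noise,
  per-fragment dropout, and uniform noise peaks.

Fragmentation here is graph-combinatorial, not physical: no bond energies,
rearrangements, ring openings or isotope envelopes.  What it preserves is
the one thing the model needs — a learnable, structure-determined mapping
from molecule to peak pattern that differs between formula isomers.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem import (
    CandidateSet,
    Molecule,
    build_candidate_store,
    make_candidate_set,
    parse_molecule,
    write_candidate_sets_tsv,
    write_molecules_tsv,
)
from .spectra import Peak, Spectrum, write_spectra
from .training import PairedDataset, split_structure_disjoint

log = logging.getLogger(__name__)

PROTON_MASS = 1.00728  # [M+H]+ adduct shift, Da
_H_MASS = 1.00782503207

#: attachable substructure groups; blocks within a group are themselves
#: formula isomers, so assemblies of one group-multiset form a formula
#: family whose members range from same-skeleton (hard decoys, high
#: Tanimoto) to rearranged-skeleton (realistic decoys, low Tanimoto) —
#: mirroring the similarity spread of database candidate sets
DEFAULT_GRAMMAR: tuple[tuple[str, ...], ...] = (
    ("CCO", "COC"),            # C2H6O: ethanol / dimethyl ether
    ("CCN", "CNC"),            # C2H7N: ethylamine / dimethylamine
    ("CC(C)C", "CCCC"),        # C4H10: isobutane / n-butane
    ("c1ccccc1",),             # benzene
    ("CC(=O)O", "OCC=O"),      # C2H4O2: acetic acid / glycolaldehyde
    ("CS",),                   # methanethiol
    ("CCCl",),                 # chloroethyl
    ("C1CCNCC1", "C=CCCCN"),   # C5H11N: piperidine / pent-4-enylamine
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give a universe of ~300 molecules in formula-isomer families
    of ~8, two spectral views per molecule, mild intensity noise and 10%
    fragment dropout — a regime where the spectrum-structure mapping is
    learnable but decoys are genuinely hard (same formula, shared
    substructures).
    """

    n_molecules: int = 300
    fragment_grammar: tuple = DEFAULT_GRAMMAR  # groups of isomeric blocks
    max_heavy_atoms: int = 25
    fragments_per_molecule: tuple[int, int] = (2, 4)
    isomers_per_family: int = 8
    spectra_per_molecule: tuple[int, int] = (2, 2)
    cut_depth: int = 2
    noise_peaks: tuple[int, int] = (0, 3)
    intensity_noise_cv: float = 0.25
    dropout_prob: float = 0.1
    test_fraction: float = 0.2
    seed: int = 0


@dataclass
class SyntheticDataset:
    molecules: list[Molecule]
    dataset: PairedDataset
    train: PairedDataset
    test: PairedDataset
    config: GeneratorConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_spectra(self.dataset.spectra.values(), out / "spectra.mgf")
        write_molecules_tsv(self.molecules, out / "molecules.tsv")
        write_candidate_sets_tsv(
            self.dataset.candidate_sets.values(), out / "candidates.tsv"
        )
        (out / "split.json").write_text(
            json.dumps(
                {
                    "train_molecules": self.train.molecule_ids(),
                    "test_molecules": self.test.molecule_ids(),
                },
                indent=2,
            )
        )
        (out / "manifest.json").write_text(
            json.dumps({"generator": asdict(self.config)}, indent=2, default=list)
        )


def _free_valence_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def _join(base: Chem.Mol, frag: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
    """Bond a random free-valence atom of ``frag`` to one of ``base``."""
    a_opts = _free_valence_atoms(base)
    b_opts = _free_valence_atoms(frag)
    if not a_opts or not b_opts:
        return None
    a = int(rng.choice(a_opts))
    b = int(rng.choice(b_opts))
    combined = Chem.RWMol(Chem.CombineMols(base, frag))
    combined.AddBond(a, base.GetNumAtoms() + b, Chem.BondType.SINGLE)
    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def generate_universe(cfg: GeneratorConfig) -> list[Molecule]:
    """Assemble a deduplicated universe of grammar-built molecules.

    Fragment multisets are sampled first and several distinct connectivity
    isomers are built per multiset, so formula families of useful size
    arise by construction.  Deduplication is by InChIKey connectivity
    block.  If the attempt budget runs out a partial universe is returned
    with a warning.
    """
    if not cfg.fragment_grammar:
        raise ValueError("fragment grammar must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    # accept flat SMILES tuples too: each block becomes its own group
    raw_groups = [
        (g,) if isinstance(g, str) else tuple(g) for g in cfg.fragment_grammar
    ]
    groups: list[list[Chem.Mol]] = []
    for grp in raw_groups:
        mols = []
        for smi in grp:
            m = Chem.MolFromSmiles(smi)
            if m is None:
                raise ValueError(f"unparsable grammar fragment {smi!r}")
            mols.append(m)
        groups.append(mols)

    universe: list[Molecule] = []
    seen_keys: set[str] = set()
    budget = cfg.n_molecules * 200
    attempts = 0
    lo, hi = cfg.fragments_per_molecule
    while len(universe) < cfg.n_molecules and attempts < budget:
        n_frag = int(rng.integers(lo, hi + 1))
        multiset = sorted(int(i) for i in rng.integers(0, len(groups), size=n_frag))
        min_atoms = sum(groups[i][0].GetNumAtoms() for i in multiset)
        if min_atoms > cfg.max_heavy_atoms:
            attempts += 1
            continue
        family_found = 0
        for _ in range(cfg.isomers_per_family * 6):
            attempts += 1
            if family_found >= cfg.isomers_per_family or len(universe) >= cfg.n_molecules:
                break
            # isomeric block choice within each group keeps the formula fixed
            picks = [groups[i][int(rng.integers(len(groups[i])))] for i in multiset]
            order = rng.permutation(len(picks))
            mol = Chem.Mol(picks[order[0]])
            ok = True
            for j in order[1:]:
                nxt = _join(mol, picks[j], rng)
                if nxt is None:
                    ok = False
                    break
                mol = nxt
            if not ok:
                continue
            parsed = parse_molecule(Chem.MolToSmiles(mol), f"M{len(universe):04d}")
            if parsed.inchikey_block1 in seen_keys:
                continue
            seen_keys.add(parsed.inchikey_block1)
            universe.append(parsed)
            family_found += 1
    if len(universe) < cfg.n_molecules:
        warnings.warn(
            f"universe generation reached attempt budget: "
            f"{len(universe)}/{cfg.n_molecules} molecules"
        )
    return universe


def _atom_masses(mol: Chem.Mol) -> np.ndarray:
    pt = Chem.GetPeriodicTable()
    return np.array(
        [
            pt.GetMostCommonIsotopeMass(a.GetSymbol()) + _H_MASS * a.GetTotalNumHs()
            for a in mol.GetAtoms()
        ]
    )


def _fragment_masses(mol: Chem.Mol, cut_depth: int) -> list[float]:
    """Masses of connected fragments from cutting <= cut_depth acyclic
    single bonds; each distinct atom subset contributes once."""
    masses = _atom_masses(mol)
    n = mol.GetNumAtoms()
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        for b in mol.GetBonds()
        if not b.IsInRing() and b.GetBondType() == Chem.BondType.SINGLE
    ]
    adj_full = [[] for _ in range(n)]
    for i, (u, v) in enumerate(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    ):
        adj_full[u].append((v, i))
        adj_full[v].append((u, i))
    all_bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    cuttable = [i for i, b in enumerate(all_bonds) if all_bonds[i] in bonds]

    seen: set[frozenset[int]] = set()
    out: list[float] = []
    for depth in range(1, cut_depth + 1):
        for combo in itertools.combinations(cuttable, depth):
            cut = set(combo)
            comp = [-1] * n
            c = 0
            for start in range(n):
                if comp[start] != -1:
                    continue
                stack = [start]
                comp[start] = c
                while stack:
                    u = stack.pop()
                    for v, bi in adj_full[u]:
                        if bi in cut or comp[v] != -1:
                            continue
                        comp[v] = c
                        stack.append(v)
                c += 1
            if c == 1:
                continue
            for ci in range(c):
                atoms = frozenset(i for i in range(n) if comp[i] == ci)
                if len(atoms) == n or atoms in seen:
                    continue
                seen.add(atoms)
                out.append(float(masses[list(atoms)].sum()))
    return out


def simulate_spectrum(
    m: Molecule, cfg: GeneratorConfig, condition_seed: int
) -> Spectrum:
    """One in-silico [M+H]+ spectrum of ``m`` under one instrument condition.

    Deterministic in (molecule, config seed, condition_seed); different
    condition seeds share the fragment masses but differ in intensities,
    dropout and noise — distinct-but-correlated views.
    """
    mol = m.to_mol()
    rng = np.random.default_rng(
        [cfg.seed, condition_seed, zlib.crc32(m.smiles.encode()) & 0x7FFFFFFF]
    )
    sigma = float(np.sqrt(np.log(1.0 + cfg.intensity_noise_cv**2)))
    precursor = float(_atom_masses(mol).sum()) + PROTON_MASS
    peaks = [Peak(precursor, 999.0 * float(rng.lognormal(0.0, sigma)))]
    for fmass in _fragment_masses(mol, cfg.cut_depth):
        if rng.random() < cfg.dropout_prob:
            continue
        peaks.append(
            Peak(fmass + PROTON_MASS, 300.0 * float(rng.lognormal(0.0, sigma)))
        )
    n_noise = int(rng.integers(cfg.noise_peaks[0], cfg.noise_peaks[1] + 1))
    for _ in range(n_noise):
        if precursor <= 50.0:
            break
        peaks.append(
            Peak(float(rng.uniform(50.0, precursor)), float(rng.uniform(1.0, 30.0)))
        )
    return Spectrum(
        spectrum_id=f"{m.molecule_id}_v{condition_seed}",
        peaks=peaks,
        molecule_id=m.molecule_id,
        adduct="[M+H]+",
        precursor_mz=precursor,
    )


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Universe + spectra + formula-keyed candidate sets + disjoint split."""
    universe = generate_universe(cfg)
    store = build_candidate_store(universe)
    candidate_sets: dict[str, CandidateSet] = {
        m.molecule_id: make_candidate_set(store, m, key_type="formula")
        for m in universe
    }
    rng = np.random.default_rng([cfg.seed, 1])
    spectra: dict[str, Spectrum] = {}
    pairs: list[tuple[str, str]] = []
    lo, hi = cfg.spectra_per_molecule
    for m in universe:
        n_views = int(rng.integers(lo, hi + 1))
        for v in range(n_views):
            s = simulate_spectrum(m, cfg, condition_seed=v)
            spectra[s.spectrum_id] = s
            pairs.append((s.spectrum_id, m.molecule_id))
    full = PairedDataset(
        pairs=pairs,
        spectra=spectra,
        molecules={m.molecule_id: m for m in universe},
        candidate_sets=candidate_sets,
    )
    train, test = split_structure_disjoint(full, cfg.test_fraction, seed=cfg.seed)
    return SyntheticDataset(
        molecules=universe, dataset=full, train=train, test=test, config=cfg
    )
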