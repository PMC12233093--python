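"""Molecule handling: parsing, graph featurization, fingerprints, candidates.

Candidate retrieval mirrors the annotation setting: for a target molecule
the decoy set is every known structure sharing its molecular formula (or
falling in a ppm window around its monoisotopic mass).  Retrieval runs
against a local :class:`CandidateStore` built from a molecule collection.
Candidate sets are sorted by descending ECFP Tanimoto similarity to the
target, which is what lets regularization pick the hardest decoys first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

# one-hot atom-type vocabulary: common metabolome elements plus a catch-all
ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Se", "Si")
CHIRAL_TAGS = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)
BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
BOND_STEREO = (
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
)

# atom type (12+other) + mass + valence + in-ring + charge + radicals
# + chirality (3+other) + degree + H count + aromatic
NODE_FEATURE_DIM = (len(ELEMENTS) + 1) + 5 + (len(CHIRAL_TAGS) + 1) + 3
# bond type (4+other) + in-ring + conjugated + stereo (5+other)
EDGE_FEATURE_DIM = (len(BOND_TYPES) + 1) + 2 + (len(BOND_STEREO) + 1)

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""


@dataclass(frozen=True)
class Molecule:
    """A parsed, canonicalized small molecule.

    ``inchikey_block1`` (first 14 InChIKey characters, the connectivity
    hash) is the identity used for deduplication and structure-disjoint
    splitting.
    """

    molecule_id: str
    smiles: str
    formula: str
    inchikey_block1: str
    monoisotopic_mass: float

    def to_mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class MoleculeGraph:
    """Featurized heavy-atom graph consumed by the molecular encoder.

    ``edge_index`` lists each bond once per direction (2, 2*n_bonds);
    ``edge_features`` rows align with ``edge_index`` columns.
    """

    node_features: np.ndarray
    edge_features: np.ndarray
    edge_index: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


@dataclass(frozen=True)
class Fingerprint:
    """ECFP (Morgan radius 2) bit vector, 2048 bits."""

    bits: np.ndarray  # uint8 0/1

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.uint8))


@dataclass
class CandidateSet:
    """Formula- or mass-matched decoys for one target, Tanimoto-descending."""

    target_id: str
    candidates: list[Molecule]
    key_type: Literal["formula", "mass"]
    tanimoto_scores: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)


def parse_molecule(smiles: str, molecule_id: str) -> Molecule:
    """Parse and canonicalize a SMILES string into a :class:`Molecule`."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"cannot parse SMILES {smiles!r} (id {molecule_id!r})")
    inchikey = Chem.MolToInchiKey(mol)
    return Molecule(
        molecule_id=molecule_id,
        smiles=Chem.MolToSmiles(mol),
        formula=rdMolDescriptors.CalcMolFormula(mol),
        inchikey_block1=inchikey[:14],
        monoisotopic_mass=Descriptors.ExactMolWt(mol),
    )


def _one_hot(value, vocab) -> list[float]:
    row = [0.0] * (len(vocab) + 1)
    try:
        row[vocab.index(value)] = 1.0
    except ValueError:
        row[-1] = 1.0
    return row


def featurize_molecule(m: Molecule | Chem.Mol) -> MoleculeGraph:
    """Build the heavy-atom graph with per-atom and per-bond features.

    Hydrogens are implicit: they appear only through each heavy atom's
    hydrogen-count feature.  A single-atom molecule yields one node and an
    empty edge set.
    """
    mol = m.to_mol() if isinstance(m, Molecule) else m
    nodes = []
    for atom in mol.GetAtoms():
        row = _one_hot(atom.GetSymbol(), ELEMENTS)
        row.append(atom.GetMass() / 100.0)  # keep magnitudes near unity
        row.append(float(atom.GetTotalValence()))
        row.append(float(atom.IsInRing()))
        row.append(float(atom.GetFormalCharge()))
        row.append(float(atom.GetNumRadicalElectrons()))
        row += _one_hot(atom.GetChiralTag(), CHIRAL_TAGS)
        row.append(float(atom.GetDegree()))
        row.append(float(atom.GetTotalNumHs()))
        row.append(float(atom.GetIsAromatic()))
        nodes.append(row)

    src, dst, efeat = [], [], []
    for bond in mol.GetBonds():
        row = _one_hot(bond.GetBondType(), BOND_TYPES)
        row.append(float(bond.IsInRing()))
        row.append(float(bond.GetIsConjugated()))
        row += _one_hot(bond.GetStereo(), BOND_STEREO)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        src += [i, j]
        dst += [j, i]
        efeat += [row, row]

    return MoleculeGraph(
        node_features=np.array(nodes, dtype=float).reshape(len(nodes), NODE_FEATURE_DIM),
        edge_features=np.array(efeat, dtype=float).reshape(len(efeat), EDGE_FEATURE_DIM),
        edge_index=np.array([src, dst], dtype=int).reshape(2, len(src)),
    )


def fingerprint(m: Molecule | Chem.Mol) -> Fingerprint:
    mol = m.to_mol() if isinstance(m, Molecule) else m
    arr = np.zeros(2048, dtype=np.uint8)
    fp = _FP_GEN.GetFingerprint(mol)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return Fingerprint(bits=arr)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a AND b| / |a OR b|; 0 for two empty sets."""
    if a.bits.shape != b.bits.shape:
        raise ValueError(
            f"fingerprint width mismatch: {a.bits.shape} vs {b.bits.shape}"
        )
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        return 0.0
    return int(np.sum(a.bits & b.bits)) / union


class CandidateStore:
    """Local index of molecules by formula and by monoisotopic mass.

    Stands in for database retrieval (e.g. PubChem-by-formula) so candidate
    generation is self-contained and reproducible.
    """

    def __init__(self, molecules: Iterable[Molecule]):
        self.molecules: dict[str, Molecule] = {}
        self._by_formula: dict[str, list[Molecule]] = {}
        for mol in molecules:
            if mol.molecule_id in self.molecules:
                raise ValueError(f"duplicate molecule_id {mol.molecule_id!r}")
            self.molecules[mol.molecule_id] = mol
            self._by_formula.setdefault(mol.formula, []).append(mol)
        ordered = sorted(self.molecules.values(), key=lambda m: m.monoisotopic_mass)
        self._mass_sorted = ordered
        self._masses = np.array([m.monoisotopic_mass for m in ordered], dtype=float)

    def __len__(self) -> int:
        return len(self.molecules)

    def __contains__(self, molecule_id: str) -> bool:
        return molecule_id in self.molecules

    def by_formula(self, formula: str) -> list[Molecule]:
        return list(self._by_formula.get(formula, []))

    def by_mass(self, mass: float, tolerance_ppm: float = 10.0) -> list[Molecule]:
        """Molecules within +-tolerance_ppm of ``mass`` (window on mass itself)."""
        half = mass * tolerance_ppm * 1e-6
        lo = int(np.searchsorted(self._masses, mass - half, side="left"))
        hi = int(np.searchsorted(self._masses, mass + half, side="right"))
        return self._mass_sorted[lo:hi]


def build_candidate_store(molecules: Iterable[Molecule]) -> CandidateStore:
    return CandidateStore(molecules)


def make_candidate_set(
    store: CandidateStore,
    target: Molecule,
    key_type: Literal["formula", "mass"] = "formula",
    tolerance_ppm: float = 10.0,
) -> CandidateSet:
    """Retrieve the target's decoys and sort them hardest-first.

    The target itself is excluded; ordering is descending Tanimoto to the
    target with ascending molecule_id as the deterministic tie-break.
    """
    if target.molecule_id not in store:
        raise ValueError(f"target {target.molecule_id!r} not present in store")
    if key_type == "formula":
        pool = store.by_formula(target.formula)
    elif key_type == "mass":
        pool = store.by_mass(target.monoisotopic_mass, tolerance_ppm)
    else:
        raise ValueError(f"unknown key_type {key_type!r}")
    pool = [m for m in pool if m.molecule_id != target.molecule_id]
    if not pool:
        log.warning("no candidates found for target %s", target.molecule_id)
        return CandidateSet(target.molecule_id, [], key_type, [])
    fp_t = fingerprint(target)
    scored = [(tanimoto(fp_t, fingerprint(m)), m) for m in pool]
    scored.sort(key=lambda sm: (-sm[0], sm[1].molecule_id))
    return CandidateSet(
        target_id=target.molecule_id,
        candidates=[m for _, m in scored],
        key_type=key_type,
        tanimoto_scores=[s for s, _ in scored],
    )


# ---------------------------------------------------------------------------
# file formats

def read_molecules_tsv(path: str | Path) -> list[Molecule]:
    """Read a molecule table with columns ``molecule_id`` and ``smiles``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"molecule_id", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(f"molecule TSV missing columns: {sorted(missing)}")
    return [parse_molecule(r.smiles, r.molecule_id) for r in df.itertuples()]


def write_molecules_tsv(molecules: Sequence[Molecule], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "molecule_id": [m.molecule_id for m in molecules],
            "smiles": [m.smiles for m in molecules],
        }
    ).to_csv(path, sep="\t", index=False)


def read_molecules_sdf(path: str | Path, id_prop: str = "_Name") -> list[Molecule]:
    """Read molecules from an SDF file; ids from ``id_prop`` or positional."""
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            log.warning("unparsable SDF record %d skipped", i)
            continue
        mid = mol.GetProp(id_prop) if mol.HasProp(id_prop) and mol.GetProp(id_prop) else f"sdf_{i}"
        out.append(parse_molecule(Chem.MolToSmiles(mol), mid))
    return out


def write_candidate_sets_tsv(
    candidate_sets: Iterable[CandidateSet], path: str | Path
) -> None:
    """One row per (target, candidate) pair, candidate order preserved."""
    import pandas as pd

    rows = []
    for cs in candidate_sets:
        for mol in cs.candidates:
            rows.append((cs.target_id, mol.molecule_id, mol.smiles, cs.key_type))
    pd.DataFrame(
        rows, columns=["target_id", "candidate_id", "candidate_smiles", "key_type"]
    ).to_csv(path, sep="\t", index=False)


def read_candidate_sets_tsv(path: str | Path) -> dict[str, CandidateSet]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, CandidateSet] = {}
    for tid, grp in df.groupby("target_id", sort=False):
        cands = [
            parse_molecule(r.candidate_smiles, r.candidate_id)
            for r in grp.itertuples()
        ]
        key_type = grp.key_type.iloc[0] if "key_type" in grp else "formula"
        out[str(tid)] = CandidateSet(str(tid), cands, key_type)  # type: ignore[arg-type]
    return out
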