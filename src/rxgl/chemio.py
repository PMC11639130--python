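"""Molecule and reaction ingestion.

Parses SMILES into molecular graphs via RDKit, computes the two feature
families the model consumes — per-atom one-hot blocks (element, formal
charge, aromaticity, attached-hydrogen count) and the 39-dimensional
functional-group count vector — and handles reaction/property dataset
files and train/valid/test splitting.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit parse noise; errors surface as exceptions

N_FUNCTIONAL_GROUPS = 39

# charge one-hot covers -2..+2 plus an overflow bucket
CHARGE_VOCAB = (-2, -1, 0, 1, 2)
# attached-H one-hot covers 0..4 plus an overflow bucket
HCOUNT_VOCAB = (0, 1, 2, 3, 4)


class SmilesParseError(ValueError):
    """Raised when RDKit cannot sanitize a SMILES string."""


@dataclass(frozen=True)
class MolecularGraph:
    """Atoms with one-hot feature rows and undirected bond edges.

    Hydrogens are implicit: they appear only through the H-count feature
    block, never as nodes. Bonds carry no features.
    """

    atom_features: np.ndarray  # |V| x F0, 0/1 entries
    edges: tuple[tuple[int, int], ...]  # unordered pairs, i < j, no duplicates

    @property
    def num_atoms(self) -> int:
        return self.atom_features.shape[0]


@dataclass(frozen=True)
class Molecule:
    canonical_smiles: str
    graph: MolecularGraph
    fg_vector: np.ndarray  # length-39 non-negative integer counts
    bond_count: int
    ring_count: int

    def __post_init__(self):
        if self.fg_vector.shape != (N_FUNCTIONAL_GROUPS,):
            raise ValueError(
                f"fg_vector must have length {N_FUNCTIONAL_GROUPS}, "
                f"got {self.fg_vector.shape}"
            )

    def __hash__(self):
        return hash(self.canonical_smiles)

    def __eq__(self, other):
        return (
            isinstance(other, Molecule)
            and self.canonical_smiles == other.canonical_smiles
        )


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: a set of reactants transformed into a set of products.

    Molecules are deduplicated by canonical SMILES within each side;
    stoichiometry is deliberately ignored (sides are sets).
    """

    reactants: tuple[Molecule, ...]
    products: tuple[Molecule, ...]
    label: int | None = None

    def __post_init__(self):
        if not self.reactants or not self.products:
            raise ValueError("both reaction sides must be non-empty")

    @property
    def reactant_smiles(self) -> tuple[str, ...]:
        return tuple(m.canonical_smiles for m in self.reactants)

    @property
    def product_smiles(self) -> tuple[str, ...]:
        return tuple(m.canonical_smiles for m in self.products)

    def to_reaction_smiles(self) -> str:
        return ".".join(self.reactant_smiles) + ">>" + ".".join(self.product_smiles)

    @property
    def delta_bonds(self) -> int:
        """Change in total bond count from reactant side to product side."""
        return sum(m.bond_count for m in self.products) - sum(
            m.bond_count for m in self.reactants
        )

    @property
    def delta_rings(self) -> int:
        """Change in total ring count from reactant side to product side."""
        return sum(m.ring_count for m in self.products) - sum(
            m.ring_count for m in self.reactants
        )


@dataclass
class DatasetSplit:
    train: list
    valid: list
    test: list
    seed: int = 0

    def __iter__(self):
        yield from (self.train, self.valid, self.test)


# ---------------------------------------------------------------------------
# functional-group patterns
# ---------------------------------------------------------------------------


def default_fg_pattern_path() -> Path:
    return Path(importlib.resources.files("rxgl") / "data" / "functional_groups.tsv")


def load_fg_patterns(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Load the functional-group catalog as (name, SMARTS) pairs.

    The default file carries the standard 39-group fragment catalog; a
    custom file must follow the same ``name\\tSMARTS`` TSV layout.
    """
    path = default_fg_pattern_path() if path is None else Path(path)
    rows: list[tuple[str, str]] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("//"):
            continue
        name, smarts = line.split("\t")[:2]
        smarts = smarts.strip()
        rows.append((name, smarts))
    return rows


class _FgMatcher:
    """Compiled functional-group SMARTS queries (module-level cache)."""

    _cache: dict[str, list] = {}

    @classmethod
    def get(cls, path: str | Path | None = None):
        key = str(path or default_fg_pattern_path())
        if key not in cls._cache:
            patterns = load_fg_patterns(path)
            cls._cache[key] = [Chem.MolFromSmarts(s) for _, s in patterns]
        return cls._cache[key]


def featurize_functional_groups(
    mol: Chem.Mol, fg_patterns_path: str | Path | None = None
) -> np.ndarray:
    """Count matches of each functional-group pattern in a molecule.

    Entry *k* is the number of (unique) substructure matches of pattern
    *k*; a molecule without any catalog group maps to the zero vector.
    """
    queries = _FgMatcher.get(fg_patterns_path)
    counts = np.zeros(len(queries), dtype=np.int64)
    for k, q in enumerate(queries):
        counts[k] = len(mol.GetSubstructMatches(q))
    return counts


# ---------------------------------------------------------------------------
# atom featurization
# ---------------------------------------------------------------------------


@dataclass
class FeatureVocab:
    """Frozen vocabularies for the four one-hot atom-feature blocks.

    The element list is fit from a corpus before training; elements seen
    later map to a reserved "unknown" slot, as do out-of-range charges
    and H counts. Feature width F0 = |elements|+1 + |charges|+1 + 2 +
    |hcounts|+1.
    """

    elements: tuple[str, ...] = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
    charges: tuple[int, ...] = CHARGE_VOCAB
    hcounts: tuple[int, ...] = HCOUNT_VOCAB
    _elem_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._elem_index = {e: i for i, e in enumerate(self.elements)}

    @property
    def width(self) -> int:
        return (
            len(self.elements) + 1 + len(self.charges) + 1 + 2 + len(self.hcounts) + 1
        )

    @classmethod
    def from_corpus(cls, smiles_iter: Iterable[str]) -> "FeatureVocab":
        seen: set[str] = set()
        for smi in smiles_iter:
            mol = _mol_from_smiles(smi)
            for atom in mol.GetAtoms():
                seen.add(atom.GetSymbol())
        return cls(elements=tuple(sorted(seen)))


def featurize_atoms(mol: Chem.Mol, vocab: FeatureVocab) -> np.ndarray:
    """One-hot atom features: element | charge | aromaticity | H count.

    Every row has exactly four ones, one per block; out-of-vocabulary
    values land in each block's reserved overflow slot.
    """
    n_elem = len(vocab.elements) + 1
    n_chg = len(vocab.charges) + 1
    n_h = len(vocab.hcounts) + 1
    out = np.zeros((mol.GetNumAtoms(), n_elem + n_chg + 2 + n_h), dtype=np.float64)
    chg_index = {c: i for i, c in enumerate(vocab.charges)}
    h_index = {h: i for i, h in enumerate(vocab.hcounts)}
    for i, atom in enumerate(mol.GetAtoms()):
        e = vocab._elem_index.get(atom.GetSymbol(), n_elem - 1)
        c = chg_index.get(atom.GetFormalCharge(), n_chg - 1)
        a = 1 if atom.GetIsAromatic() else 0
        h = h_index.get(atom.GetTotalNumHs(), n_h - 1)
        out[i, e] = 1.0
        out[i, n_elem + c] = 1.0
        out[i, n_elem + n_chg + a] = 1.0
        out[i, n_elem + n_chg + 2 + h] = 1.0
    return out


# ---------------------------------------------------------------------------
# molecule / reaction parsing
# ---------------------------------------------------------------------------


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def parse_molecule(
    smiles: str,
    vocab: FeatureVocab | None = None,
    fg_patterns_path: str | Path | None = None,
) -> Molecule:
    """Parse a SMILES string into a fully featurized :class:`Molecule`.

    Canonicalization is idempotent: parsing the canonical SMILES again
    yields a structurally identical molecule.
    """
    mol = _mol_from_smiles(smiles)
    vocab = vocab or FeatureVocab()
    edges = sorted(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    graph = MolecularGraph(
        atom_features=featurize_atoms(mol, vocab), edges=tuple(edges)
    )
    return Molecule(
        canonical_smiles=Chem.MolToSmiles(mol),
        graph=graph,
        fg_vector=featurize_functional_groups(mol, fg_patterns_path),
        bond_count=mol.GetNumBonds(),
        ring_count=mol.GetRingInfo().NumRings(),
    )


def _parse_side(side: str, vocab: FeatureVocab | None) -> tuple[Molecule, ...]:
    mols: dict[str, Molecule] = {}
    for token in side.split("."):
        m = parse_molecule(token, vocab=vocab)
        mols.setdefault(m.canonical_smiles, m)  # dedupe within a side
    return tuple(mols.values())


def parse_reaction_smiles(
    line: str, vocab: FeatureVocab | None = None, label: int | None = None
) -> ReactionRecord:
    if ">>" not in line:
        raise ValueError(f"missing '>>' separator in reaction SMILES: {line!r}")
    lhs, rhs = line.split(">>", 1)
    if not lhs.strip() or not rhs.strip():
        raise ValueError(f"empty reaction side in: {line!r}")
    return ReactionRecord(
        reactants=_parse_side(lhs.strip(), vocab),
        products=_parse_side(rhs.strip(), vocab),
        label=label,
    )


def read_reaction_file(
    path: str | Path,
    vocab: FeatureVocab | None = None,
    drop_identity: bool = True,
) -> tuple[list[ReactionRecord], list[str]]:
    """Read a reaction-SMILES file, one reaction per line.

    Lines are ``reactants>>products`` with molecules joined by ``.`` and
    an optional tab-separated integer class label. Returns the valid
    records in file order together with per-line error messages for
    lines that failed to parse. Reactions whose two sides canonicalize
    to the same molecule set are dropped (they carry no transformation),
    reported in the error list as warnings.
    """
    records: list[ReactionRecord] = []
    errors: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        label = None
        if len(parts) > 1:
            try:
                label = int(parts[1])
            except ValueError:
                errors.append(f"line {lineno}: non-integer label {parts[1]!r}")
                continue
        try:
            rec = parse_reaction_smiles(parts[0], vocab=vocab, label=label)
        except (ValueError, SmilesParseError) as exc:
            errors.append(f"line {lineno}: {exc}")
            continue
        if drop_identity and set(rec.reactant_smiles) == set(rec.product_smiles):
            errors.append(
                f"line {lineno}: warning: identity reaction dropped "
                f"({rec.to_reaction_smiles()})"
            )
            continue
        records.append(rec)
    return records, errors


def write_reaction_file(records: Sequence[ReactionRecord], path: str | Path) -> None:
    lines = []
    for rec in records:
        line = rec.to_reaction_smiles()
        if rec.label is not None:
            line += f"\t{rec.label}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n")


def read_property_file(path: str | Path) -> pd.DataFrame:
    """Read a molecule property CSV with columns ``smiles,label``."""
    df = pd.read_csv(path)
    missing = {"smiles", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"property file missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_dataset(
    records: Sequence, ratios: tuple[int, int, int] = (8, 1, 1), seed: int = 0
) -> DatasetSplit:
    """Random, seed-deterministic train/valid/test partition.

    Sizes follow `ratios` (default 8:1:1) with the training fold
    absorbing the rounding remainder; the partition is exhaustive and
    disjoint.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    n = len(records)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    total = sum(ratios)
    n_valid = max(1, int(round(n * ratios[1] / total)))
    n_test = max(1, int(round(n * ratios[2] / total)))
    if n_valid + n_test >= n:
        raise ValueError("not enough records for the requested ratios")
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = perm[:n_test]
    valid_idx = perm[n_test : n_test + n_valid]
    train_idx = perm[n_test + n_valid :]
    pick = lambda idx: [records[i] for i in sorted(idx)]
    return DatasetSplit(
        train=pick(train_idx), valid=pick(valid_idx), test=pick(test_idx), seed=seed
    )
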