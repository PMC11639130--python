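"""Synthetic reaction corpora for testing and desk-scale experiments.

Reactions are assembled from template families whose bond/ring-count
changes are constant by construction:

* esterification-like (family 0): alcohol + acid → ester, joining the
  alkyl and acyl fragments, ΔNB = 0 and ΔNR = 0 with implicit
  hydrogens;
* ring-opening (family 1): a nitrile-anchored ring ``N#CC1<body>C1``
  opens into the chain ``N#CC<body>C`` — one bond and one ring fewer,
  ΔNB = −1, ΔNR = −1. The nitrile anchor guarantees a non-trivial
  functional-group vector for every ring and chain (an all-carbon ring
  would otherwise embed as a zero vector in the reaction view).

Product sides are unique across reactions by default, so the
reaction-aware graph is a disjoint union of per-reaction stars; a
controllable number of reaction pairs is then given a shared single-atom
by-product (water, ammonia, ...), creating the second-order
neighborhoods that shared products induce. Single-atom by-products have
zero bonds and rings, so family signatures stay constant.

The template grammar guarantees RDKit-parseable SMILES and non-trivial
functional-group count vectors without any reaction-enumeration engine;
chemical realism (thermodynamics, atom mapping) is not a goal.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import product as iter_product
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chemio import (
    FeatureVocab,
    ReactionRecord,
    parse_reaction_smiles,
    write_reaction_file,
)

#: single-atom by-products used to create controlled product overlap
BYPRODUCT_POOL = ("O", "N", "S", "P", "F", "Cl", "Br", "I")


@dataclass
class FixtureSpec:
    n_molecules: int = 60  # target universe size (pool budget)
    n_reactions: int = 8
    max_side_size: int = 2
    overlap_degree: int = 0  # reaction pairs sharing a by-product
    family_count: int = 2  # 1 = esterification only, 2 = + ring-opening
    seed: int = 0

    def __post_init__(self):
        if min(self.n_molecules, self.n_reactions, self.max_side_size) < 1:
            raise ValueError("spec sizes must be positive")
        if self.n_molecules < 4:
            raise ValueError("need at least 4 molecules")
        if self.family_count not in (1, 2):
            raise ValueError("family_count must be 1 or 2")
        if self.overlap_degree < 0 or self.overlap_degree > self.n_reactions:
            raise ValueError("overlap_degree must be in [0, n_reactions]")
        if self.max_side_size < 2:
            raise ValueError("esterification reactions need side size >= 2")


@dataclass
class MoleculeUniverse:
    alcohols: list[str]  # alkyl + "O"
    acids: list[str]  # acyl + "C(=O)O"
    rings: list[str]  # "N#CC1<body>C1"
    ring_products: dict[str, str]  # ring smiles -> opened-chain smiles
    ester_parts: dict[str, tuple[str, str]]  # alcohol/acid -> fragments

    @property
    def all_smiles(self) -> list[str]:
        return self.alcohols + self.acids + self.rings


def _canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # template grammar should never produce this
        raise ValueError(f"template produced invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _alkyl_variants(max_len: int):
    """Linear and singly-methyl-branched alkyl SMILES fragments."""
    for n in range(1, max_len + 1):
        yield "C" * n
    for n in range(3, max_len + 1):
        for pos in range(1, n - 1):
            yield "C" * pos + "C(C)" + "C" * (n - pos - 1)


def _ring_bodies(max_len: int):
    """Ring body strings over a C/O/N alphabet (ring = N#CC1<body>C1)."""
    for n in range(1, max_len + 1):
        for combo in iter_product("CON", repeat=n):
            yield "".join(combo)


def generate_molecule_universe(spec: FixtureSpec) -> MoleculeUniverse:
    """Deterministic template universe large enough for `spec`.

    Pools are enumerated in a fixed order and deduplicated by canonical
    SMILES, so a given spec always yields the byte-identical universe.
    """
    budget = spec.n_molecules
    # the budget is a floor: pools grow further if the requested reaction
    # count demands it (ester supply is the product of two pools, ring
    # supply is linear)
    n_ester_needed = spec.n_reactions - spec.n_reactions // 2 * (spec.family_count - 1)
    n_ring_needed = spec.n_reactions // 2 if spec.family_count == 2 else 0
    if spec.overlap_degree == 0:
        # disjoint-star topology: every alcohol/acid used at most once
        side = n_ester_needed
    else:
        side = int(np.ceil(np.sqrt(max(n_ester_needed, 1))))
    n_alc = max(2, budget // 3, side)
    n_acid = max(2, budget // 3, side)
    n_ring = max(2, budget - 2 * (budget // 3), n_ring_needed)

    alcohols, ester_parts = [], {}
    seen = set()
    for alkyl in _alkyl_variants(12):
        smi = _canonical(alkyl + "O")
        if smi not in seen:
            seen.add(smi)
            alcohols.append(smi)
            ester_parts[smi] = ("alkyl", alkyl)
        if len(alcohols) >= n_alc:
            break

    acids = []
    for acyl in _alkyl_variants(12):
        smi = _canonical(acyl + "C(=O)O")
        if smi not in seen:
            seen.add(smi)
            acids.append(smi)
            ester_parts[smi] = ("acyl", acyl)
        if len(acids) >= n_acid:
            break

    rings, ring_products = [], {}
    for body in _ring_bodies(9):
        smi = _canonical("N#CC1" + body + "C1")
        if smi not in seen:
            seen.add(smi)
            rings.append(smi)
            ring_products[smi] = _canonical("N#CC" + body + "C")
        if len(rings) >= n_ring:
            break

    return MoleculeUniverse(
        alcohols=alcohols,
        acids=acids,
        rings=rings,
        ring_products=ring_products,
        ester_parts=ester_parts,
    )


def _ester_smiles(universe: MoleculeUniverse, alcohol: str, acid: str) -> str:
    _, alkyl = universe.ester_parts[alcohol]
    _, acyl = universe.ester_parts[acid]
    return _canonical(alkyl + "OC(=O)" + acyl)


def generate_reaction_set(
    spec: FixtureSpec,
    universe: MoleculeUniverse | None = None,
    vocab: FeatureVocab | None = None,
) -> list[ReactionRecord]:
    """Assemble a reaction corpus from the template families.

    Reactions alternate between the requested families; each record's
    label is its family index, giving downstream tests a class signal
    with a known (ΔNB, ΔNR) signature. `overlap_degree` reaction pairs
    are then given a shared single-atom by-product (cycling through a
    small pool, so very large overlap degrees may chain extra pairs
    together via a reused by-product).
    """
    universe = universe or generate_molecule_universe(spec)
    rng = np.random.default_rng(spec.seed)

    if spec.overlap_degree == 0:
        # molecule-disjoint reactions: the reaction-aware graph becomes a
        # disjoint union of per-reaction stars
        alcohols = [universe.alcohols[i] for i in rng.permutation(len(universe.alcohols))]
        acids = [universe.acids[i] for i in rng.permutation(len(universe.acids))]
        ester_pairs = list(zip(alcohols, acids))
    else:
        ester_pairs = [(a, b) for a in universe.alcohols for b in universe.acids]
        ester_pairs = [ester_pairs[i] for i in rng.permutation(len(ester_pairs))]
    ring_list = [universe.rings[i] for i in rng.permutation(len(universe.rings))]

    families = [i % spec.family_count for i in range(spec.n_reactions)]
    n_ester = families.count(0)
    n_ring = families.count(1)
    if n_ester > len(ester_pairs) or n_ring > len(ring_list):
        raise ValueError(
            f"spec infeasible: needs {n_ester} esterifications / {n_ring} "
            f"ring-openings but universe offers {len(ester_pairs)} / {len(ring_list)}"
        )

    lines: list[tuple[str, int]] = []
    ei = ri = 0
    for fam in families:
        if fam == 0:
            alcohol, acid = ester_pairs[ei]
            ei += 1
            lines.append((f"{alcohol}.{acid}>>{_ester_smiles(universe, alcohol, acid)}", 0))
        else:
            ring = ring_list[ri]
            ri += 1
            lines.append((f"{ring}>>{universe.ring_products[ring]}", 1))

    # inject product overlap: shared by-product on chosen reaction pairs
    if spec.overlap_degree:
        n = len(lines)
        all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        if spec.overlap_degree > len(all_pairs):
            raise ValueError("overlap_degree exceeds the number of reaction pairs")
        picks = rng.choice(len(all_pairs), size=spec.overlap_degree, replace=False)
        extras: dict[int, set[str]] = {}
        for k, p in enumerate(sorted(picks)):
            i, j = all_pairs[p]
            by = BYPRODUCT_POOL[k % len(BYPRODUCT_POOL)]
            extras.setdefault(i, set()).add(by)
            extras.setdefault(j, set()).add(by)
        for i, extra in extras.items():
            smi, fam = lines[i]
            lhs, rhs = smi.split(">>")
            rhs = ".".join([rhs, *sorted(extra)])
            lines[i] = (f"{lhs}>>{rhs}", fam)

    records = [
        parse_reaction_smiles(smi, vocab=vocab, label=fam) for smi, fam in lines
    ]
    return records


def write_fixture(records: list[ReactionRecord], path: str | Path) -> None:
    write_reaction_file(records, path)


def fixture_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# golden fixtures
# ---------------------------------------------------------------------------

GOLDEN_SPECS: dict[str, FixtureSpec] = {
    "tiny": FixtureSpec(n_molecules=12, n_reactions=8, overlap_degree=2, seed=7),
    "small": FixtureSpec(n_molecules=120, n_reactions=200, overlap_degree=20, seed=11),
    "medium": FixtureSpec(n_molecules=900, n_reactions=2000, overlap_degree=200, seed=13),
}

#: sha256 of the serialized golden corpora (frozen; regeneration must match)
GOLDEN_CHECKSUMS: dict[str, str] = {
    "tiny": "ced44abdc393fc60912a18beab39aafc01cf18dd066490d4d25b2aa908c2a650",
    "small": "4b622a21b2d5dd8fc1c1dd2e9790dca90da444ca1f08f20217f96930f33a3d9c",
    "medium": "474c4c7f5a23880cd12cd01effca60c1c9657016af3139c762ff880ad2e82a2d",
}


def golden_fixture_path(name: str) -> Path:
    import importlib.resources

    return Path(importlib.resources.files("rxgl") / "data" / "fixtures" / f"{name}.txt")


def generate_golden_fixture(name: str, path: str | Path) -> list[ReactionRecord]:
    """Regenerate a golden corpus from its frozen spec and write it out."""
    records = generate_reaction_set(GOLDEN_SPECS[name])
    write_fixture(records, path)
    return records


def load_golden_fixture(
    name: str, vocab: FeatureVocab | None = None
) -> list[ReactionRecord]:
    """Load a golden corpus: shipped file if present, regenerated otherwise.

    The tiny and small corpora ship as files; the medium one is
    regenerated on demand from its frozen spec (it is deterministic and
    checksum-frozen like the others).
    """
    from .chemio import read_reaction_file

    path = golden_fixture_path(name)
    if path.exists():
        records, errors = read_reaction_file(path, vocab=vocab)
        if errors:
            raise ValueError(f"golden fixture {name} failed to load: {errors[:3]}")
        return records
    return generate_reaction_set(GOLDEN_SPECS[name], vocab=vocab)
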