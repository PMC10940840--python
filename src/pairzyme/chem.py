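"""Atom-mapped reaction parsing and substrate-product pair extraction.

A reaction with atom-to-atom mapping (AAM) carries, on every mapped atom, an
integer map number linking a product atom to the substrate atom it derives
from.  From one mapped reaction we emit every (substrate A, product C) pair
in which *strictly more than half* of C's heavy atoms derive from A; pairs
involving single-atom species (e.g. H+) or ubiquitous cofactors (ATP, NAD+,
...) are then filtered out.  The surviving pair is the reaction surrogate
scored by the promiscuity model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# rdkit is chatty on valence warnings; errors are raised by us explicitly
RDLogger.DisableLog("rdApp.warning")


class ReactionParseError(ValueError):
    """A reaction SMILES (or one of its molecules) could not be parsed."""


class ReactionValidationError(ValueError):
    """A parsed reaction violates an atom-map invariant."""


UNMAPPED = "unmapped"


@dataclass(frozen=True)
class MappedMolecule:
    """One molecule of a mapped reaction, with per-atom map numbers."""

    smiles: str
    atoms: tuple  # of (element symbol, atom-map number >= 0, is_heavy flag)
    role: str  # "substrate" | "product"

    @property
    def heavy_map_numbers(self) -> list[int]:
        return [m for (_s, m, heavy) in self.atoms if heavy]

    @property
    def n_heavy(self) -> int:
        return sum(1 for (_s, _m, heavy) in self.atoms if heavy)


@dataclass(frozen=True)
class MappedReaction:
    reaction_id: str
    substrates: tuple
    products: tuple
    ec_numbers: tuple = ()

    def __post_init__(self):
        sub_maps = _side_nonzero_maps(self.substrates, "substrates")
        _side_nonzero_maps(self.products, "products")
        for i, prod in enumerate(self.products):
            seen = set()
            for (_s, m, heavy) in prod.atoms:
                if heavy and m > 0:
                    if m in seen:
                        raise ReactionValidationError(
                            f"reaction {self.reaction_id}: map {m} duplicated "
                            f"within product {i}"
                        )
                    seen.add(m)
        # every nonzero product map occurs at most once among substrates:
        # guaranteed by substrate-side uniqueness checked above
        del sub_maps


@dataclass(frozen=True)
class SubstrateProductPair:
    """An (A, C) pair with the fraction of C's heavy atoms derived from A."""

    substrate_smiles: str
    product_smiles: str
    provenance_fraction: float
    reaction_id: str

    def key(self) -> str:
        return pair_to_reaction_smiles(self)


def _side_nonzero_maps(mols: Sequence[MappedMolecule], side: str) -> set[int]:
    seen: set[int] = set()
    for mol in mols:
        for (_sym, m, heavy) in mol.atoms:
            if heavy and m > 0:
                if m in seen:
                    raise ReactionValidationError(
                        f"map number {m} duplicated among {side} "
                        f"(molecule {mol.smiles!r})"
                    )
                seen.add(m)
    return seen


def _mol_from_smiles(smiles: str, what: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise ReactionParseError(f"cannot parse {what}: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES with atom-map numbers stripped (stereo preserved)."""
    mol = _mol_from_smiles(smiles, "molecule")
    return strip_maps_canonical(mol)


def strip_maps_canonical(mol: Chem.Mol) -> str:
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def _mapped_molecule(smiles: str, role: str) -> MappedMolecule:
    mol = _mol_from_smiles(smiles, f"{role} molecule")
    atoms = tuple(
        (a.GetSymbol(), a.GetAtomMapNum(), a.GetAtomicNum() > 1)
        for a in mol.GetAtoms()
    )
    if not atoms:
        # e.g. "[H+]" sanitizes to a molecule whose only atom is hydrogen;
        # rdkit keeps it as one (non-heavy) atom, so an empty atom list means
        # a truly empty molecule string
        raise ReactionParseError(f"empty molecule in {role}: {smiles!r}")
    return MappedMolecule(smiles=smiles, atoms=atoms, role=role)


def parse_mapped_reaction(
    line: str,
    reaction_id: str = "",
    ec: Optional[Iterable[str]] = None,
) -> MappedReaction:
    """Parse one atom-mapped reaction SMILES line.

    Accepts ``subs>>prods`` or the three-field form ``subs>agents>prods``;
    agents are dropped with a warning (they are neither substrates nor
    products for pair extraction).
    """
    line = line.strip()
    parts = line.split(">")
    if len(parts) == 3:
        subs_field, agents_field, prods_field = parts
        if agents_field:
            logger.warning(
                "reaction %s: dropping agents field %r", reaction_id, agents_field
            )
    else:
        raise ReactionParseError(
            f"reaction {reaction_id}: expected exactly one '>>' "
            f"(or two '>') in {line!r}"
        )
    substrates = tuple(
        _mapped_molecule(s, "substrate") for s in subs_field.split(".") if s
    )
    products = tuple(
        _mapped_molecule(s, "product") for s in prods_field.split(".") if s
    )
    if not substrates or not products:
        raise ReactionParseError(
            f"reaction {reaction_id}: needs at least one substrate and one product"
        )
    return MappedReaction(
        reaction_id=reaction_id,
        substrates=substrates,
        products=products,
        ec_numbers=tuple(ec or ()),
    )


def atom_provenance(rxn: MappedReaction, product_index: int):
    """Assign every heavy atom of one product to its source substrate.

    Returns a list, one entry per heavy atom of the product, holding either
    the index of the unique substrate containing that atom's map number or
    the string ``"unmapped"`` (map number 0 or absent from the substrates).
    """
    if not 0 <= product_index < len(rxn.products):
        raise IndexError(f"product index {product_index} out of range")
    map_to_sub: dict[int, int] = {}
    for si, sub in enumerate(rxn.substrates):
        for m in sub.heavy_map_numbers:
            if m > 0:
                map_to_sub[m] = si
    out = []
    for (_sym, m, heavy) in rxn.products[product_index].atoms:
        if not heavy:
            continue
        out.append(map_to_sub.get(m, UNMAPPED) if m > 0 else UNMAPPED)
    return out


def extract_pairs(
    rxn: MappedReaction, threshold: float = 0.5
) -> list[SubstrateProductPair]:
    """Emit substrate-product pairs passing the strict provenance rule.

    For every (substrate A, product C) combination the provenance fraction is
    (heavy atoms of C mapped to A) / (heavy atoms of C); the pair is kept iff
    the fraction is strictly greater than ``threshold``.  Unmapped atoms
    count in the denominator only.
    """
    pairs: list[SubstrateProductPair] = []
    for pi, prod in enumerate(rxn.products):
        n_heavy = prod.n_heavy
        if n_heavy == 0:
            logger.warning(
                "reaction %s: product %d has no heavy atoms, skipped",
                rxn.reaction_id, pi,
            )
            continue
        prov = atom_provenance(rxn, pi)
        counts = [0] * len(rxn.substrates)
        for src in prov:
            if src != UNMAPPED:
                counts[src] += 1
        prod_canon = strip_maps_canonical(_mol_from_smiles(prod.smiles, "product"))
        for si, sub in enumerate(rxn.substrates):
            frac = counts[si] / n_heavy
            if frac > threshold:
                pairs.append(
                    SubstrateProductPair(
                        substrate_smiles=strip_maps_canonical(
                            _mol_from_smiles(sub.smiles, "substrate")
                        ),
                        product_smiles=prod_canon,
                        provenance_fraction=frac,
                        reaction_id=rxn.reaction_id,
                    )
                )
    return pairs


def _n_heavy_atoms(smiles: str) -> int:
    return _mol_from_smiles(smiles, "molecule").GetNumHeavyAtoms()


def filter_pairs(
    pairs: Sequence[SubstrateProductPair],
    cofactors: Optional[set[str]] = None,
) -> list[SubstrateProductPair]:
    """Drop pairs with a single-heavy-atom or cofactor substrate/product.

    ``cofactors`` holds canonical, map-free SMILES; when omitted, the packaged
    default list (ATP, ADP, NAD(P)(H), CoA, common inorganics, ...) is used.
    Order of survivors is preserved; the operation is idempotent.
    """
    if cofactors is None:
        cofactors = default_cofactors()
    out = []
    for p in pairs:
        if _n_heavy_atoms(p.substrate_smiles) <= 1:
            continue
        if _n_heavy_atoms(p.product_smiles) <= 1:
            continue
        if p.substrate_smiles in cofactors or p.product_smiles in cofactors:
            continue
        out.append(p)
    return out


def pair_to_reaction_smiles(pair: SubstrateProductPair) -> str:
    """Deterministic ``A>>C`` string with canonical components (dedup key)."""
    return f"{canonical_smiles(pair.substrate_smiles)}>>" \
           f"{canonical_smiles(pair.product_smiles)}"


def load_cofactors(path: Union[str, Path, None] = None) -> set[str]:
    """Load a cofactor list (one SMILES per line, '#' comments) canonicalized."""
    if path is None:
        text = (
            resources.files("pairzyme").joinpath("data/cofactors.smi").read_text()
        )
    else:
        text = Path(path).read_text()
    out = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(canonical_smiles(line))
    return out


_DEFAULT_COFACTORS: Optional[set[str]] = None


def default_cofactors() -> set[str]:
    global _DEFAULT_COFACTORS
    if _DEFAULT_COFACTORS is None:
        _DEFAULT_COFACTORS = load_cofactors(None)
    return _DEFAULT_COFACTORS


# ---------------------------------------------------------------------------
# tabular I/O


def read_reactions_tsv(path: Union[str, Path]) -> list[MappedReaction]:
    """Read a reactions TSV: reaction_id, mapped_rxn_smiles, ec_numbers.

    ``ec_numbers`` is semicolon-separated and may be empty or absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    rxns = []
    for _, row in df.iterrows():
        ecs = [e for e in str(row.get("ec_numbers", "")).split(";") if e]
        rxns.append(
            parse_mapped_reaction(
                row["mapped_rxn_smiles"], reaction_id=str(row["reaction_id"]), ec=ecs
            )
        )
    return rxns


def write_pairs_tsv(pairs: Sequence[SubstrateProductPair], path) -> None:
    pd.DataFrame(
        [
            {
                "reaction_id": p.reaction_id,
                "substrate_smiles": p.substrate_smiles,
                "product_smiles": p.product_smiles,
                "provenance_fraction": p.provenance_fraction,
            }
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[SubstrateProductPair]:
    df = pd.read_csv(path, sep="\t", dtype={"reaction_id": str})
    return [
        SubstrateProductPair(
            substrate_smiles=row.substrate_smiles,
            product_smiles=row.product_smiles,
            provenance_fraction=float(row.provenance_fraction),
            reaction_id=str(row.reaction_id),
        )
        for row in df.itertuples()
    ]
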