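"""Molecular structure ingestion as hydrogen-suppressed labeled graphs.

Structures arrive as SMILES strings or SDF (MOL V2000) records, are parsed
with RDKit, and are reduced to a minimal heavy-atom graph: atoms carry an
element symbol and an aromatic flag, bonds carry a bond-order class.  That
graph is the sole substrate for the edge-adjacency descriptor engine — no
3D geometry, charges or isotopes enter the descriptor values.

Bond weighting schemes
----------------------
Three schemes are supported, selected by name:

``none``
    every bond weighs 1.0 (the plain line-graph adjacency).
``bo``
    conventional bond orders: single 1.0, aromatic 1.5, double 2.0,
    triple 3.0.  The aromatic weight is Kekulé-independent by design.
``ri``
    a resonance-integral-style weight keyed on (bond class, element pair),
    normalised so that an aromatic C–C bond (the benzene reference) weighs
    exactly 1.0.  The shipped table is an explicit, overridable stand-in
    built from Hückel-type heteroatom scaling factors; it can be replaced
    wholesale from a plain-text config file (see :func:`load_ri_table`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "WeightScheme",
    "SmilesParseError",
    "MultiFragmentError",
    "WeightTableError",
    "BO_WEIGHTS",
    "RI_DEFAULT_TABLE",
    "parse_smiles",
    "load_sdf",
    "load_smiles_file",
    "bond_weight",
    "load_ri_table",
]

logger = logging.getLogger(__name__)

# RDKit's C++-level parse chatter is redundant with the structured errors
# raised here.
RDLogger.DisableLog("rdApp.error")

BOND_ORDERS = ("single", "double", "triple", "aromatic")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the input."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        self.detail = detail
        msg = f"cannot parse SMILES {smiles!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class MultiFragmentError(ValueError):
    """Raised for disconnected (multi-fragment) structures.

    Eigen-descriptors of disconnected line graphs are ambiguous, so
    disconnected inputs are rejected rather than silently reduced to the
    largest fragment.
    """


class WeightTableError(KeyError):
    """Raised when a weight table has no entry for a bond."""


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    aromatic: bool = False


@dataclass(frozen=True)
class Bond:
    """A heavy-atom bond.

    ``atoms`` is the unordered endpoint pair stored as a sorted tuple;
    ``elements`` caches the endpoint element symbols so weight lookup does
    not need the parent graph.
    """

    index: int
    atoms: tuple[int, int]
    order: str
    elements: tuple[str, str] = ("C", "C")

    def __post_init__(self):
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order {self.order!r}")
        if self.atoms[0] == self.atoms[1]:
            raise ValueError("bond endpoints must be distinct")
        object.__setattr__(self, "atoms", tuple(sorted(self.atoms)))
        object.__setattr__(self, "elements", tuple(sorted(self.elements)))


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed connected molecular graph."""

    atoms: list[Atom]
    bonds: list[Bond]

    def __post_init__(self):
        n = len(self.atoms)
        if [a.index for a in self.atoms] != list(range(n)):
            raise ValueError("atom indices must be contiguous from 0")
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.atoms[0] < n and 0 <= b.atoms[1] < n):
                raise ValueError(f"bond {b.index} references missing atom")
            if b.atoms in seen:
                raise ValueError(f"duplicate bond between atoms {b.atoms}")
            seen.add(b.atoms)
        if n > 1 and not self._connected():
            raise MultiFragmentError(
                "graph is disconnected; multi-fragment structures are not supported"
            )

    def _connected(self) -> bool:
        adj: dict[int, list[int]] = {a.index: [] for a in self.atoms}
        for b in self.bonds:
            i, j = b.atoms
            adj[i].append(j)
            adj[j].append(i)
        stack, seen = [0], {0}
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


# --------------------------------------------------------------------------
# RDKit conversion

_RDKIT_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


def _from_rdkit(mol: "Chem.Mol") -> MolecularGraph:
    mol = Chem.RemoveHs(mol)
    if len(Chem.GetMolFrags(mol)) > 1:
        raise MultiFragmentError(
            "multi-fragment structure (use one connected molecule per record)"
        )
    atoms = [
        Atom(a.GetIdx(), a.GetSymbol(), a.GetIsAromatic())
        for a in mol.GetAtoms()
    ]
    bonds = []
    for k, b in enumerate(mol.GetBonds()):
        order = _RDKIT_ORDER.get(b.GetBondType())
        if order is None:
            raise ValueError(f"unsupported bond type {b.GetBondType()}")
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append(
            Bond(k, (i, j), order, (atoms[i].element, atoms[j].element))
        )
    return MolecularGraph(atoms, bonds)


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed graph.

    Aromaticity perception follows RDKit's default model.  Multi-fragment
    SMILES (``"C.C"``) raise :class:`MultiFragmentError`; syntax or
    valence failures raise :class:`SmilesParseError` naming the input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        detail = ""
        raw = Chem.MolFromSmiles(smiles, sanitize=False)
        if raw is not None:
            problems = Chem.DetectChemistryProblems(raw)
            if problems:
                detail = problems[0].Message()
        raise SmilesParseError(smiles, detail)
    return _from_rdkit(mol)


def load_smiles_file(path: str | Path) -> list[tuple[str, MolecularGraph]]:
    """Read a SMILES file: one record per line, optional tab-separated id."""
    records: list[tuple[str, MolecularGraph]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        rec_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
        records.append((rec_id, parse_smiles(smiles)))
    return records


def load_sdf(path: str | Path) -> list[tuple[str, MolecularGraph]]:
    """Load an SDF / MOL V2000 file, skipping unparseable records.

    Returns ``(record id, graph)`` pairs; the id is the molecule title or
    ``record<N>`` when untitled.  Skipped records are logged with a final
    summary count.  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        logger.warning("SDF file %s is empty", path)
        return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    out: list[tuple[str, MolecularGraph]] = []
    skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            logger.warning("SDF record %d in %s unparseable; skipped", i, path)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        out.append((name or f"record{i}", _from_rdkit(mol)))
    if skipped:
        logger.warning("%d of %d SDF records skipped", skipped, skipped + len(out))
    if not out and not skipped:
        logger.warning("SDF file %s contained no records", path)
    return out


# --------------------------------------------------------------------------
# Bond weighting

BO_WEIGHTS: Mapping[str, float] = {
    "single": 1.0,
    "aromatic": 1.5,
    "double": 2.0,
    "triple": 3.0,
}

# Hückel-style heteroatom scaling factors relative to a C-C pi bond.
_RI_PAIR_FACTOR: dict[frozenset, float] = {
    frozenset({"C"}): 1.0,
    frozenset({"C", "N"}): 0.9,
    frozenset({"C", "O"}): 0.8,
    frozenset({"C", "S"}): 0.7,
    frozenset({"C", "P"}): 0.6,
    frozenset({"C", "F"}): 0.7,
    frozenset({"C", "Cl"}): 0.4,
    frozenset({"C", "Br"}): 0.3,
    frozenset({"C", "I"}): 0.25,
    frozenset({"N"}): 0.8,
    frozenset({"N", "O"}): 0.7,
    frozenset({"N", "S"}): 0.6,
    frozenset({"O"}): 0.6,
    frozenset({"O", "S"}): 0.5,
    frozenset({"O", "P"}): 0.5,
    frozenset({"S"}): 0.5,
}

# Class factors chosen so the benzene aromatic C-C bond is the unit
# reference; sigma-only single bonds carry a reduced conjugative weight.
_RI_CLASS_FACTOR = {"single": 0.5, "aromatic": 1.0, "double": 1.1, "triple": 1.2}


def _build_ri_table() -> dict[tuple[str, tuple[str, str]], float]:
    table = {}
    for order, cf in _RI_CLASS_FACTOR.items():
        for pair, pf in _RI_PAIR_FACTOR.items():
            elems = tuple(sorted(pair)) if len(pair) == 2 else (min(pair), min(pair))
            table[(order, elems)] = round(cf * pf, 6)
    return table


#: Default resonance-integral weight table:
#: ``(bond class, sorted element pair) -> weight``; aromatic ("C","C") == 1.0.
RI_DEFAULT_TABLE: dict[tuple[str, tuple[str, str]], float] = _build_ri_table()


@dataclass(frozen=True)
class WeightScheme:
    """A named bond weighting scheme (``none`` | ``bo`` | ``ri``).

    For ``ri`` an explicit table may be supplied; all weights must be
    positive.
    """

    name: str
    table: Mapping | None = None

    def __post_init__(self):
        if self.name not in ("none", "bo", "ri"):
            raise ValueError(f"unknown weight scheme {self.name!r}")
        if self.table is not None and any(w <= 0 for w in self.table.values()):
            raise ValueError("all weights must be > 0")

    @classmethod
    def coerce(cls, scheme: "WeightScheme | str | None") -> "WeightScheme":
        if scheme is None:
            return cls("none")
        if isinstance(scheme, str):
            return cls(scheme)
        return scheme


def bond_weight(bond: Bond, scheme: WeightScheme | str = "none") -> float:
    """Weight of a single bond under the given scheme."""
    scheme = WeightScheme.coerce(scheme)
    if scheme.name == "none":
        return 1.0
    if scheme.name == "bo":
        table = scheme.table or BO_WEIGHTS
        return float(table[bond.order])
    table = scheme.table or RI_DEFAULT_TABLE
    key = (bond.order, bond.elements)
    try:
        return float(table[key])
    except KeyError:
        raise WeightTableError(
            f"no ri weight for element pair {bond.elements[0]}-{bond.elements[1]} "
            f"({bond.order} bond)"
        ) from None


def load_ri_table(path: str | Path) -> dict[tuple[str, tuple[str, str]], float]:
    """Load a resonance-integral weight table from a plain-text config.

    Format: one entry per line, ``<bond class> <elem1> <elem2> <weight>``,
    ``#`` comments allowed, e.g. ``aromatic C N 0.9``.
    """
    table: dict[tuple[str, tuple[str, str]], float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'class elem1 elem2 weight'")
        order, e1, e2, w = parts
        if order not in BOND_ORDERS:
            raise ValueError(f"{path}:{lineno}: unknown bond class {order!r}")
        weight = float(w)
        if weight <= 0:
            raise ValueError(f"{path}:{lineno}: weights must be > 0")
        table[(order, tuple(sorted((e1, e2))))] = weight
    return table
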