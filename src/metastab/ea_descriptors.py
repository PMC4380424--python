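"""Edge-adjacency spectral descriptors.

The edge adjacency matrix (EA) of a molecule is a symmetric matrix over its
bonds: entry (i, j) is nonzero exactly when bonds i and j share an atom.
Unweighted, it is the adjacency matrix of the molecular line graph.  With a
bond weighting scheme w, the off-diagonal entries become sqrt(w_i * w_j) —
a symmetric convention that guarantees a real spectrum — and the augmented
variant (AEA) additionally places the bond weights on the diagonal.

Descriptors are simple spectral functionals of these matrices, named with a
Dragon-style grammar::

    {Eig<nn> | SpMax | SpDiam}_{EA | AEA}[(bo | ri)]

where ``SpMax`` is the largest eigenvalue, ``SpDiam`` the spectral diameter
(lambda_max - lambda_min), and ``Eig<nn>`` the nn-th largest eigenvalue
(1-indexed; zero-padded when nn exceeds the bond count, so small molecules
still yield complete descriptor vectors).  An absent parenthesis suffix
means the unweighted matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_graph import MolecularGraph, WeightScheme, bond_weight

__all__ = [
    "EdgeAdjacencyMatrix",
    "DescriptorVector",
    "DescriptorNameError",
    "edge_adjacency_matrix",
    "spectral_descriptors",
    "parse_descriptor_name",
    "compute_named",
    "family_names",
    "descriptor_table",
    "MAX_EIG_INDEX",
]

#: Highest Eig<nn> index emitted by default (Eig01 ... Eig15).
MAX_EIG_INDEX = 15

_NAME_RE = re.compile(
    r"^(?P<stat>SpMax|SpDiam|Eig(?P<nn>\d{2}))_(?P<kind>EA|AEA)"
    r"(?:\((?P<scheme>bo|ri)\))?$"
)


class DescriptorNameError(ValueError):
    """Raised for a descriptor name that does not parse under the grammar."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(
            f"descriptor name {name!r} does not match "
            "{Eig<nn>|SpMax|SpDiam}_{EA|AEA}[(bo|ri)]"
        )


@dataclass
class EdgeAdjacencyMatrix:
    """A (possibly augmented) weighted edge adjacency matrix."""

    entries: np.ndarray
    augmented: bool
    scheme: WeightScheme

    @property
    def size(self) -> int:
        return self.entries.shape[0]

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending (real: the matrix is symmetric)."""
        return np.sort(np.linalg.eigvalsh(self.entries))[::-1]


@dataclass
class DescriptorVector:
    values: dict[str, float]
    compound_id: str | None = None


def edge_adjacency_matrix(
    graph: MolecularGraph,
    scheme: WeightScheme | str = "none",
    augmented: bool = False,
) -> EdgeAdjacencyMatrix:
    """Build the EA (or AEA) matrix of a molecular graph.

    Off-diagonal entry (i, j) is sqrt(w_i * w_j) when bonds i != j share an
    atom, else 0; the diagonal is 0 (EA) or the bond weight (AEA).
    """
    if graph.n_bonds < 1:
        raise ValueError("descriptor computation requires at least one bond")
    scheme = WeightScheme.coerce(scheme)
    w = np.array([bond_weight(b, scheme) for b in graph.bonds])
    m = graph.n_bonds
    mat = np.zeros((m, m))
    endpoints = [set(b.atoms) for b in graph.bonds]
    for i in range(m):
        for j in range(i + 1, m):
            if endpoints[i] & endpoints[j]:
                mat[i, j] = mat[j, i] = np.sqrt(w[i] * w[j])
    if augmented:
        mat[np.diag_indices(m)] = w
    return EdgeAdjacencyMatrix(mat, augmented, scheme)


def spectral_descriptors(
    matrix: EdgeAdjacencyMatrix, max_eig: int = MAX_EIG_INDEX
) -> dict[str, float]:
    """SpMax, SpDiam and Eig01..Eig<max_eig> of one matrix.

    Eigenvalues beyond the matrix size pad with 0.0 so descriptor tables
    stay rectangular across molecules of different size.
    """
    ev = matrix.eigenvalues()
    out = {"SpMax": float(ev[0]), "SpDiam": float(ev[0] - ev[-1])}
    for nn in range(1, max_eig + 1):
        out[f"Eig{nn:02d}"] = float(ev[nn - 1]) if nn <= len(ev) else 0.0
    return out


def parse_descriptor_name(name: str) -> tuple[str, int | None, bool, str]:
    """Parse a descriptor name into (stat, eig index, augmented, scheme).

    ``stat`` is ``SpMax``/``SpDiam``/``Eig``; the eig index is None for the
    Sp* statistics; ``augmented`` is True for AEA; scheme is ``none`` when
    no suffix is present.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise DescriptorNameError(name)
    nn = m.group("nn")
    if nn is not None and int(nn) == 0:
        raise DescriptorNameError(name)
    stat = "Eig" if nn is not None else m.group("stat")
    return (
        stat,
        int(nn) if nn is not None else None,
        m.group("kind") == "AEA",
        m.group("scheme") or "none",
    )


def compute_named(
    graph: MolecularGraph,
    names: Sequence[str],
    compound_id: str | None = None,
    ri_table: Mapping | None = None,
) -> DescriptorVector:
    """Compute the requested named descriptors for one molecule.

    Each name is routed to the correct matrix variant and weight scheme;
    eigendecompositions are cached per (variant, scheme).  Values are kept
    at full precision; round only at reporting time.
    """
    parsed = [(name, parse_descriptor_name(name)) for name in names]
    cache: dict[tuple[bool, str], np.ndarray] = {}
    values: dict[str, float] = {}
    for name, (stat, nn, augmented, scheme_name) in parsed:
        key = (augmented, scheme_name)
        if key not in cache:
            scheme = WeightScheme(
                scheme_name, ri_table if scheme_name == "ri" else None
            )
            cache[key] = edge_adjacency_matrix(graph, scheme, augmented).eigenvalues()
        ev = cache[key]
        if stat == "SpMax":
            values[name] = float(ev[0])
        elif stat == "SpDiam":
            values[name] = float(ev[0] - ev[-1])
        else:
            values[name] = float(ev[nn - 1]) if nn <= len(ev) else 0.0
    return DescriptorVector(values, compound_id)


def family_names(max_eig: int = MAX_EIG_INDEX) -> list[str]:
    """All descriptor names of the EA family (the ``--family ea-all`` set)."""
    names = []
    for kind in ("EA", "AEA"):
        for scheme in ("", "(bo)", "(ri)"):
            for stat in (
                ["SpMax", "SpDiam"] + [f"Eig{nn:02d}" for nn in range(1, max_eig + 1)]
            ):
                names.append(f"{stat}_{kind}{scheme}")
    return names


def descriptor_table(
    graphs: Iterable[tuple[str, MolecularGraph]],
    names: Sequence[str] | None = None,
    ri_table: Mapping | None = None,
) -> pd.DataFrame:
    """Descriptor table: one row per compound, one column per descriptor."""
    names = list(names) if names is not None else family_names()
    rows, ids = [], []
    for cid, graph in graphs:
        vec = compute_named(graph, names, cid, ri_table)
        rows.append(vec.values)
        ids.append(cid)
    return pd.DataFrame(rows, index=pd.Index(ids, name="compound_id"), columns=names)
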