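"""Independent brute-force oracles used to validate the production metrics.

These deliberately avoid the code paths they check: the MCS oracle
enumerates connected bond subgraphs and tests monomorphic embedding with
networkx, and the cosine oracle works on explicit on-bit sets.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
from networkx.algorithms.isomorphism import GraphMatcher
from rdkit import Chem


def _to_graph(smiles: str) -> nx.Graph:
    mol = Chem.MolFromSmiles(smiles)
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetSymbol(), in_ring=atom.IsInRing())
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            order=str(bond.GetBondType()),
            in_ring=bond.IsInRing(),
        )
    return g


def _node_match(a: dict, b: dict) -> bool:
    return a["element"] == b["element"] and a["in_ring"] == b["in_ring"]


def _edge_match(a: dict, b: dict) -> bool:
    return a["order"] == b["order"] and a["in_ring"] == b["in_ring"]


def _connected_edge_subsets(g: nx.Graph):
    edges = list(g.edges)
    for size in range(len(edges), 0, -1):
        for subset in combinations(edges, size):
            sub = g.edge_subgraph(subset)
            if nx.is_connected(sub):
                yield sub


def brute_force_mcs_atoms(ref_smiles: str, pred_smiles: str) -> int:
    """Atom count of the maximum common connected edge subgraph.

    Matching respects element, bond order, and ring membership of both
    atoms and bonds. A common substructure must contain at least one bond;
    returns 0 when none exists.
    """
    g_ref = _to_graph(ref_smiles)
    g_pred = _to_graph(pred_smiles)
    small, large = (
        (g_ref, g_pred) if g_ref.number_of_edges() <= g_pred.number_of_edges() else (g_pred, g_ref)
    )
    best = 0
    for sub in _connected_edge_subsets(small):
        if sub.number_of_nodes() <= best:
            continue
        matcher = GraphMatcher(large, sub, node_match=_node_match, edge_match=_edge_match)
        if matcher.subgraph_is_monomorphic():
            best = sub.number_of_nodes()
    return best


def cosine_from_bitsets(bits_a: set[int], bits_b: set[int]) -> float:
    """Cosine of two binary vectors via explicit set arithmetic."""
    if not bits_a or not bits_b:
        return 0.0
    return len(bits_a & bits_b) / math.sqrt(len(bits_a) * len(bits_b))
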