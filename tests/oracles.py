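"""Independent brute-force oracles used by the test suite.

Every oracle here recomputes a quantity by direct enumeration, staying
independent of the library code paths it checks (no shared shortest-path,
pruning, ranking or metric logic).
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations

import numpy as np
from rdkit import Chem


def bfs_distances(n_nodes: int, edges, source: int) -> list:
    """Single-source shortest paths by plain breadth-first search."""
    adj = {i: [] for i in range(n_nodes)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    dist = [None] * n_nodes
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if dist[w] is None:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def signature_bruteforce(n_nodes, edges, labels, grid, class_pairs) -> np.ndarray:
    """Cumulative pharmacophore-pair counts by explicit pair enumeration."""
    dist_rows = [bfs_distances(n_nodes, edges, s) for s in range(n_nodes)]
    values = np.zeros((len(grid), len(class_pairs)), dtype=int)
    pair_index = {p: j for j, p in enumerate(class_pairs)}
    for u in range(n_nodes):
        for v in range(u + 1, n_nodes):
            d = dist_rows[u][v]
            supported = {
                tuple(sorted((a, b))) for a in labels[u] for b in labels[v]
            }
            for i, c in enumerate(grid):
                if d <= c:
                    for p in supported:
                        values[i, pair_index[p]] += 1
    return values


def auc_concordance(y, scores) -> float:
    """AUC as the exhaustive fraction of concordant positive/negative pairs,
    ties counted one half."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def ks_statistic_enumeration(x, y) -> float:
    """Two-sample KS sup-distance by evaluating both ECDFs on the pooled grid."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


def confusion_formula(tp, fp, fn, tn) -> dict:
    """MCC / F1 / balanced accuracy straight from their defining formulas."""
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = num / den if den > 0 else 0.0
    f1 = (2 * tp) / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    sens = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    spec = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    return {"MCC": mcc, "F1": f1, "BACC": (sens + spec) / 2}


def connected_atom_subsets(mol: Chem.Mol, max_atoms: int) -> set:
    """All connected atom-index subsets up to max_atoms, by filtering every
    combination for connectedness."""
    n = mol.GetNumAtoms()
    adj = {a.GetIdx(): {nb.GetIdx() for nb in a.GetNeighbors()} for a in mol.GetAtoms()}

    def connected(subset) -> bool:
        subset = set(subset)
        start = next(iter(subset))
        seen = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for w in adj[u] & subset:
                if w not in seen:
                    seen.add(w)
                    queue.append(w)
        return seen == subset

    out = set()
    for k in range(1, min(max_atoms, n) + 1):
        for subset in combinations(range(n), k):
            if connected(subset):
                out.add(frozenset(subset))
    return out


def exhaustive_fragment_hits(focus_mols, complement_mols, min_support, max_atoms) -> dict:
    """Oracle miner: enumerate every connected substructure of every focus
    molecule by subset enumeration, then count molecule-level presence with
    substructure matching.  Returns {canonical pattern: (a, c)} for patterns
    meeting the focus support threshold."""
    patterns = set()
    for mol in focus_mols:
        for subset in connected_atom_subsets(mol, max_atoms):
            try:
                patterns.add(
                    Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(subset), canonical=True)
                )
            except Exception:
                continue
    min_count = math.ceil(min_support * len(focus_mols))
    hits = {}
    for smi in patterns:
        query = Chem.MolFromSmarts(smi)
        if query is None:
            continue
        a = sum(1 for m in focus_mols if m.HasSubstructMatch(query))
        if a >= min_count:
            c = sum(1 for m in complement_mols if m.HasSubstructMatch(query))
            hits[smi] = (a, c)
    return hits
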