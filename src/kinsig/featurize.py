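"""Graph-based molecular signatures and the physicochemical descriptor block.

A molecule is modelled as an undirected, unweighted heavy-atom graph whose
nodes carry (possibly empty) sets of pharmacophore labels: hydrogen-bond
acceptor/donor, positively/negatively ionizable, aromatic, hydrophobe.  The
signature of a molecule is, for each unordered pair of pharmacophore classes
and each graph-distance cutoff, the cumulative count of atom pairs of those
classes whose shortest-path distance (in bonds) does not exceed the cutoff.
Scanning the cutoff grid therefore yields a coarse cumulative distance
distribution per class pair -- a compact, atom-order-invariant encoding of
molecular geometry and interaction chemistry.

The descriptor block complements the signature with whole-molecule
physicochemical properties (log p, TPSA, hydrogen-bond counts, flexibility,
ring and halogen counts, selected functional-group frequencies).  Its
registry is fixed and versioned so feature matrices remain alignable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Fragments, Lipinski, rdMolDescriptors
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .chem_io import LabeledDataset, Molecule

logger = logging.getLogger(__name__)

PHARMACOPHORE_CLASSES = (
    "Acceptor",
    "Aromatic",
    "Donor",
    "Hydrophobe",
    "NegIonizable",
    "PosIonizable",
)
#: the 21 unordered class pairs, same-class pairs included
CLASS_PAIRS = tuple(combinations_with_replacement(PHARMACOPHORE_CLASSES, 2))
#: default cutoff grid: graph distances of 1..10 bonds
DEFAULT_GRID = tuple(range(1, 11))

DESCRIPTOR_REGISTRY_VERSION = "1"


class ConfigurationError(ValueError):
    """Invalid grid, registry or definitions configuration."""


class GraphError(ValueError):
    """Molecular graph precondition violated (e.g. disconnected input)."""


class UndefinedStatisticError(ValueError):
    """A statistical comparison is undefined for the given samples."""


# ---------------------------------------------------------------------------
# pharmacophore definitions


@dataclass(frozen=True)
class PharmacophoreDefinitions:
    """Compiled pharmacophore SMARTS patterns, loaded from a versioned file."""

    version: str
    patterns: dict  # class name -> tuple of compiled SMARTS queries
    source_text: str

    @property
    def checksum(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()


def load_pharmacophore_definitions(path=None) -> PharmacophoreDefinitions:
    """Load pharmacophore SMARTS definitions (packaged file by default)."""
    if path is None:
        text = (
            resources.files("kinsig").joinpath("data/pharmacophores.smarts").read_text()
        )
    else:
        text = Path(path).read_text()
    version = "unversioned"
    patterns: dict = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip()
        if line.startswith("# version:"):
            version = line.split(":", 1)[1].strip()
        if not line or line.startswith("#"):
            continue
        try:
            cls, smarts = line.split("\t", 1)
        except ValueError as exc:
            raise ConfigurationError(
                f"malformed definitions line {lineno}: {line!r}"
            ) from exc
        if cls not in PHARMACOPHORE_CLASSES:
            raise ConfigurationError(f"unknown pharmacophore class {cls!r}")
        query = Chem.MolFromSmarts(smarts.strip())
        if query is None:
            raise ConfigurationError(f"invalid SMARTS on line {lineno}: {smarts!r}")
        patterns.setdefault(cls, []).append(query)
    missing = [c for c in PHARMACOPHORE_CLASSES if c not in patterns]
    if missing:
        raise ConfigurationError(f"definitions missing classes: {missing}")
    return PharmacophoreDefinitions(
        version=version,
        patterns={c: tuple(v) for c, v in patterns.items()},
        source_text=text,
    )


_DEFAULT_DEFS: Optional[PharmacophoreDefinitions] = None


def default_definitions() -> PharmacophoreDefinitions:
    global _DEFAULT_DEFS
    if _DEFAULT_DEFS is None:
        _DEFAULT_DEFS = load_pharmacophore_definitions()
    return _DEFAULT_DEFS


# ---------------------------------------------------------------------------
# molecular graph


@dataclass(frozen=True)
class MolecularGraph:
    """Undirected, unweighted heavy-atom graph with optional per-node
    pharmacophore label sets.  May be built from a molecule or constructed
    directly (e.g. toy graphs in tests)."""

    n_nodes: int
    edges: tuple
    labels: Optional[tuple] = None  # tuple of frozensets, len n_nodes
    mol: Optional[Chem.Mol] = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        for u, v in self.edges:
            if u == v:
                raise GraphError(f"self-loop on node {u}")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise GraphError(f"edge ({u},{v}) out of range")
        if len({frozenset(e) for e in self.edges}) != len(self.edges):
            raise GraphError("multi-edge in graph")
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise GraphError("labels length mismatch")


def build_graph(m: Molecule) -> MolecularGraph:
    """Heavy-atom graph of a molecule: atoms are nodes, bonds are edges.

    The input must be a single covalent component; strip salts first.
    """
    frags = Chem.GetMolFrags(m.mol)
    if len(frags) > 1:
        raise GraphError(
            f"{m.smiles_canonical!r} has {len(frags)} fragments; "
            "apply strip_to_largest_fragment first"
        )
    edges = tuple(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in m.mol.GetBonds()
    )
    return MolecularGraph(n_nodes=m.heavy_atom_count, edges=edges, mol=m.mol)


def assign_pharmacophores(
    g: MolecularGraph, defs: Optional[PharmacophoreDefinitions] = None
) -> MolecularGraph:
    """Annotate every node with its (possibly empty) pharmacophore label set.

    Labels come from the versioned SMARTS definition file; an atom may carry
    several labels (e.g. a hydroxyl oxygen is both donor and acceptor).
    """
    if g.mol is None:
        raise GraphError("graph has no underlying molecule to match against")
    defs = defs or default_definitions()
    label_sets = [set() for _ in range(g.n_nodes)]
    for cls, queries in defs.patterns.items():
        for query in queries:
            for match in g.mol.GetSubstructMatches(query, uniquify=True):
                for idx in match:
                    label_sets[idx].add(cls)
    return MolecularGraph(
        n_nodes=g.n_nodes,
        edges=g.edges,
        labels=tuple(frozenset(s) for s in label_sets),
        mol=g.mol,
    )


def all_pairs_shortest_paths(g: MolecularGraph) -> np.ndarray:
    """Integer matrix of shortest-path bond distances between all node pairs."""
    n = g.n_nodes
    if n == 1:
        return np.zeros((1, 1), dtype=int)
    rows = [u for u, v in g.edges] + [v for u, v in g.edges]
    cols = [v for u, v in g.edges] + [u for u, v in g.edges]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    if np.isinf(dist).any():
        raise GraphError("graph is disconnected")
    return dist.astype(int)


# ---------------------------------------------------------------------------
# signatures


@dataclass(frozen=True)
class SignatureVector:
    """Cumulative pharmacophore-pair distance counts.

    ``values[i, j]`` is the number of unordered atom pairs supporting class
    pair ``CLASS_PAIRS[j]`` at shortest-path distance <= ``grid[i]``.
    """

    grid: tuple
    values: np.ndarray  # shape (len(grid), 21), non-negative ints

    @property
    def names(self) -> list:
        return [
            f"sig_{a}:{b}_d{c}" for c in self.grid for (a, b) in CLASS_PAIRS
        ]

    @property
    def flat(self) -> np.ndarray:
        return self.values.reshape(-1)

    def to_series(self) -> pd.Series:
        return pd.Series(self.flat, index=self.names)


def _validate_grid(grid) -> tuple:
    grid = tuple(grid)
    if not grid:
        raise ConfigurationError("cutoff grid is empty")
    if any(int(c) != c or c <= 0 for c in grid):
        raise ConfigurationError(f"grid must be positive integers: {grid}")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ConfigurationError(f"grid must be strictly increasing: {grid}")
    return tuple(int(c) for c in grid)


def csm_signature(g: MolecularGraph, grid: Iterable[int] = DEFAULT_GRID) -> SignatureVector:
    """Cumulative pharmacophore-pair distance signature of a labelled graph.

    For every unordered atom pair {u, v} and every unordered class pair
    (A, B) supported by the pair's label sets (A in labels(u), B in labels(v)
    or vice versa), the pair contributes once to every cutoff c >= d(u, v).
    Same-class pairs are counted once per atom pair; an atom pair with
    multi-label atoms contributes to every class pair its labels support.
    """
    grid = _validate_grid(grid)
    if g.labels is None:
        raise GraphError("assign_pharmacophores before computing signatures")
    dist = all_pairs_shortest_paths(g)
    pair_index = {p: j for j, p in enumerate(CLASS_PAIRS)}
    # raw histogram over distances, then cumulative over the grid
    max_d = int(dist.max()) if g.n_nodes > 1 else 0
    hist = np.zeros((max_d + 1, len(CLASS_PAIRS)), dtype=int)
    for u in range(g.n_nodes):
        lu = g.labels[u]
        if not lu:
            continue
        for v in range(u + 1, g.n_nodes):
            lv = g.labels[v]
            if not lv:
                continue
            d = dist[u, v]
            supported = {tuple(sorted((a, b))) for a in lu for b in lv}
            for p in supported:
                hist[d, pair_index[p]] += 1
    cum = np.cumsum(hist, axis=0)
    values = np.zeros((len(grid), len(CLASS_PAIRS)), dtype=int)
    for i, c in enumerate(grid):
        values[i] = cum[min(c, max_d)]
    return SignatureVector(grid=grid, values=values)


def signature_for_molecule(
    m: Molecule,
    grid: Iterable[int] = DEFAULT_GRID,
    defs: Optional[PharmacophoreDefinitions] = None,
) -> SignatureVector:
    """Convenience: build, label and sign a molecule in one call."""
    return csm_signature(assign_pharmacophores(build_graph(m), defs), grid)


# ---------------------------------------------------------------------------
# descriptor block

DESCRIPTOR_NAMES = (
    "MolLogP",
    "TPSA",
    "HBD",
    "HBA",
    "RotatableBonds",
    "RingCount",
    "PEOE_VSA12",
    "FCount",
    "Hydrophobe_Count",
    "fr_sulfonamide",
    "fr_urea",
    "fr_pyrrole",
    "fr_Ar_N",
)


def _hydrophobe_count(mol: Chem.Mol, defs: PharmacophoreDefinitions) -> int:
    atoms = set()
    for query in defs.patterns["Hydrophobe"]:
        for match in mol.GetSubstructMatches(query, uniquify=True):
            atoms.update(match)
    return len(atoms)


def descriptor_block(
    m: Molecule, defs: Optional[PharmacophoreDefinitions] = None
) -> dict:
    """Compute the fixed, ordered descriptor registry for one molecule.

    A descriptor that fails on an exotic structure is flagged as NaN with a
    warning; the molecule is retained.
    """
    defs = defs or default_definitions()
    mol = m.mol
    funcs = {
        "MolLogP": lambda: Crippen.MolLogP(mol),
        "TPSA": lambda: rdMolDescriptors.CalcTPSA(mol),
        "HBD": lambda: Lipinski.NumHDonors(mol),
        "HBA": lambda: Lipinski.NumHAcceptors(mol),
        "RotatableBonds": lambda: rdMolDescriptors.CalcNumRotatableBonds(mol),
        "RingCount": lambda: rdMolDescriptors.CalcNumRings(mol),
        "PEOE_VSA12": lambda: Descriptors.PEOE_VSA12(mol),
        "FCount": lambda: sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "F"),
        "Hydrophobe_Count": lambda: _hydrophobe_count(mol, defs),
        "fr_sulfonamide": lambda: Fragments.fr_sulfonamd(mol),
        "fr_urea": lambda: Fragments.fr_urea(mol),
        "fr_pyrrole": lambda: Fragments.fr_Nhpyrrole(mol),
        "fr_Ar_N": lambda: Fragments.fr_Ar_N(mol),
    }
    out = {}
    for name in DESCRIPTOR_NAMES:
        try:
            out[name] = float(funcs[name]())
        except Exception as exc:  # pragma: no cover - exotic-atom fallback
            logger.warning(
                "descriptor %s failed for %s: %s", name, m.smiles_canonical, exc
            )
            out[name] = math.nan
    return out


def registry_checksum(
    grid: Iterable[int] = DEFAULT_GRID,
    defs: Optional[PharmacophoreDefinitions] = None,
) -> str:
    """Checksum identifying the full feature configuration (signature grid,
    descriptor registry, pharmacophore definitions).  Models refuse to score
    feature matrices built under a different checksum."""
    defs = defs or default_definitions()
    payload = json.dumps(
        {
            "descriptors": list(DESCRIPTOR_NAMES),
            "registry_version": DESCRIPTOR_REGISTRY_VERSION,
            "grid": list(_validate_grid(grid)),
            "pharmacophores": defs.checksum,
            "classes": list(PHARMACOPHORE_CLASSES),
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# rule-of-thumb drug-likeness flags


def ro5_veber_flags(d: dict) -> dict:
    """Drug-likeness flags over a descriptor mapping.

    Thresholds: HBA <= 10, HBD < 5 (strict), log p < 5 (strict), rotatable
    bonds <= 10, TPSA < 140 A^2 (strict).  ``all_pass`` is their conjunction.
    """
    flags = {
        "hba_le_10": d["HBA"] <= 10,
        "hbd_lt_5": d["HBD"] < 5,
        "logp_lt_5": d["MolLogP"] < 5,
        "rotatable_le_10": d["RotatableBonds"] <= 10,
        "tpsa_lt_140": d["TPSA"] < 140,
    }
    flags["all_pass"] = all(flags.values())
    return flags


# ---------------------------------------------------------------------------
# distribution comparisons


def compare_distributions(x, y, method: str = "ks"):
    """Two-sample comparison of a feature between labelled groups.

    ``ks`` returns the Kolmogorov-Smirnov sup-distance D in [0, 1] with the
    asymptotic p-value; ``welch_t`` returns Welch's t with the two-sided
    p-value under Welch-Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UndefinedStatisticError("both samples must be non-empty")
    if method == "ks":
        res = stats.ks_2samp(x, y, method="asymp")
        return float(res.statistic), float(res.pvalue)
    if method == "welch_t":
        if x.size < 2 or y.size < 2:
            raise UndefinedStatisticError("welch_t requires >= 2 points per sample")
        if np.var(x) == 0 and np.var(y) == 0:
            raise UndefinedStatisticError(
                "welch_t undefined for two constant samples (zero variance)"
            )
        res = stats.ttest_ind(x, y, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise ConfigurationError(f"unknown method {method!r}; use 'ks' or 'welch_t'")


# ---------------------------------------------------------------------------
# dataset featurisation


@dataclass
class FeatureMatrix:
    """Feature matrix (signature block then descriptor block) plus the
    configuration needed to reproduce or align it."""

    X: pd.DataFrame
    grid: tuple
    registry_version: str
    checksum: str
    dropped: list


def feature_names(grid: Iterable[int] = DEFAULT_GRID) -> list:
    grid = _validate_grid(grid)
    sig = [f"sig_{a}:{b}_d{c}" for c in grid for (a, b) in CLASS_PAIRS]
    return sig + list(DESCRIPTOR_NAMES)


def featurize_molecule(
    m: Molecule,
    grid: Iterable[int] = DEFAULT_GRID,
    defs: Optional[PharmacophoreDefinitions] = None,
) -> np.ndarray:
    sig = signature_for_molecule(m, grid, defs)
    desc = descriptor_block(m, defs)
    return np.concatenate([sig.flat.astype(float), [desc[n] for n in DESCRIPTOR_NAMES]])


def featurize_dataset(
    ds: LabeledDataset,
    grid: Iterable[int] = DEFAULT_GRID,
    defs: Optional[PharmacophoreDefinitions] = None,
) -> FeatureMatrix:
    """Featurize every molecule of a dataset; row order matches the dataset.

    Rows whose featurisation fails are dropped and recorded in ``dropped``
    (original positions), so callers can realign labels.
    """
    if len(ds) == 0:
        raise ConfigurationError("cannot featurize an empty dataset")
    grid = _validate_grid(grid)
    defs = defs or default_definitions()
    rows, index, dropped = [], [], []
    for i, mol in enumerate(ds.molecules):
        try:
            rows.append(featurize_molecule(mol, grid, defs))
            index.append(i)
        except Exception as exc:
            dropped.append(i)
            logger.warning("featurisation failed for row %d: %s", i, exc)
    X = pd.DataFrame(np.vstack(rows), index=index, columns=feature_names(grid))
    return FeatureMatrix(
        X=X,
        grid=grid,
        registry_version=DESCRIPTOR_REGISTRY_VERSION,
        checksum=registry_checksum(grid, defs),
        dropped=dropped,
    )


def write_feature_matrix(fm: FeatureMatrix, csv_path) -> Path:
    """Write the matrix as CSV with a JSON sidecar describing grid, registry
    version and pharmacophore-definition checksum."""
    csv_path = Path(csv_path)
    fm.X.to_csv(csv_path, index_label="row")
    sidecar = csv_path.with_suffix(csv_path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "grid": list(fm.grid),
                "registry_version": fm.registry_version,
                "checksum": fm.checksum,
                "n_rows": int(fm.X.shape[0]),
                "n_columns": int(fm.X.shape[1]),
                "dropped_rows": fm.dropped,
            },
            indent=2,
        )
    )
    return csv_path
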