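"""Discriminative substructure mining between a focus and a complement set.

Connected substructures are grown atom by atom inside the focus molecules
(an exhaustive grow-and-prune miner: start from single atoms, extend by one
bond, deduplicate via canonical fragment SMILES, and prune fragments whose
focus support falls below the threshold -- support is anti-monotone, so no
frequent fragment is missed).  Each surviving fragment gets a 2x2
presence/absence contingency table against the complement set and an odds
ratio

    OR = (a/b) / (c/d)

where a/b are the focus molecules containing/not containing the fragment and
c/d the same for the complement.  Support is molecule-level (a fragment is
counted once per molecule however many times it embeds), and matching uses
substructure (monomorphism) semantics: the canonical fragment SMILES is
interpreted as a SMARTS query.

A fragment absent from the complement has infinite odds ratio; the optional
Haldane-Anscombe correction (+0.5 to every cell) gives a finite estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

from rdkit import Chem

from .chem_io import Molecule

logger = logging.getLogger(__name__)

#: hard bound on fragment size; the exhaustive miner is meant for desk-scale
#: analyses and larger patterns explode combinatorially
MAX_ATOMS_SAFETY_BOUND = 12


class PatternError(ValueError):
    """An invalid substructure pattern."""


class EnrichmentError(ValueError):
    """Invalid mining configuration or degenerate contingency table."""


@dataclass(frozen=True)
class FragmentPattern:
    """A connected substructure in SMILES/SMARTS line notation."""

    pattern: str
    atom_count: int

    @classmethod
    def from_string(cls, pattern: str) -> "FragmentPattern":
        query = _compile(pattern)
        return cls(pattern=pattern, atom_count=query.GetNumAtoms())


@lru_cache(maxsize=100_000)
def _compile(pattern: str) -> Chem.Mol:
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise PatternError(f"invalid substructure pattern {pattern!r}")
    return query


def _as_mol(m) -> Chem.Mol:
    return m.mol if isinstance(m, Molecule) else m


def contains_fragment(m, f) -> bool:
    """Molecule-level presence: true iff the pattern is a substructure of the
    molecule (counted once per molecule regardless of embedding count)."""
    pattern = f.pattern if isinstance(f, FragmentPattern) else str(f)
    return _as_mol(m).HasSubstructMatch(_compile(pattern))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 presence/absence counts: a/b in the focus set, c/d in the
    complement set."""

    a: int  # focus, containing
    b: int  # focus, not containing
    c: int  # complement, containing
    d: int  # complement, not containing

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EnrichmentError("contingency counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise EnrichmentError("both focus and complement sets must be non-empty")

    @property
    def support_focus(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def support_complement(self) -> float:
        return self.c / (self.c + self.d)


def fragment_contingency(f, focus: Sequence, complement: Sequence) -> ContingencyTable:
    """Count molecule-level fragment presence in the two sets."""
    if len(focus) == 0 or len(complement) == 0:
        raise EnrichmentError("focus and complement sets must be non-empty")
    a = sum(1 for m in focus if contains_fragment(m, f))
    c = sum(1 for m in complement if contains_fragment(m, f))
    return ContingencyTable(a=a, b=len(focus) - a, c=c, d=len(complement) - c)


@dataclass(frozen=True)
class OddsRatio:
    value: float  # math.inf when infinite
    infinite: bool
    haldane: bool


def odds_ratio(t: ContingencyTable, haldane: bool = False) -> OddsRatio:
    """Odds ratio (a/b) / (c/d) of a contingency table.

    A fragment present in every focus molecule (b = 0) or absent from the
    complement (c = 0) has odds ratio tending to infinity, returned as an
    infinite flag.  A fragment absent from both sets (a = c = 0) is
    undefined.  With ``haldane`` a 0.5 pseudo-count is added to every cell,
    always yielding a finite value.
    """
    if t.a == 0 and t.c == 0:
        raise EnrichmentError("pattern absent from both sets; odds ratio undefined")
    if haldane:
        a, b, c, d = t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5
        return OddsRatio(value=(a / b) / (c / d), infinite=False, haldane=True)
    if t.b == 0 or t.c == 0:
        return OddsRatio(value=math.inf, infinite=True, haldane=False)
    if t.a == 0 or t.d == 0:
        return OddsRatio(value=0.0, infinite=False, haldane=False)
    return OddsRatio(value=(t.a / t.b) / (t.c / t.d), infinite=False, haldane=False)


@dataclass(frozen=True)
class FragmentHit:
    """A mined fragment with its counts, supports and odds ratio."""

    pattern: FragmentPattern
    table: ContingencyTable
    odds: OddsRatio

    @property
    def support_focus(self) -> float:
        return self.table.support_focus

    @property
    def support_complement(self) -> float:
        return self.table.support_complement

    def sort_key(self):
        # infinite odds ratios first; among them, the more discriminative
        # fragment (lower complement support, then higher focus support)
        # ranks higher.  Finite hits rank by value then focus support.
        if self.odds.infinite:
            return (0, self.support_complement, -self.support_focus, self.pattern.pattern)
        return (1, -self.odds.value, -self.support_focus, self.pattern.pattern)


def _fragment_smiles(mol: Chem.Mol, atoms) -> Optional[str]:
    try:
        return Chem.MolFragmentToSmiles(mol, atomsToUse=list(atoms), canonical=True)
    except Exception:  # pragma: no cover - rare kekulisation corner cases
        return None


def _match_count(pattern: str, mols) -> int:
    try:
        query = _compile(pattern)
    except PatternError:  # pragma: no cover
        return 0
    return sum(1 for m in mols if m.HasSubstructMatch(query))


def mine_fragments(
    focus: Sequence,
    complement: Sequence,
    min_support_focus: float = 0.3,
    max_atoms: int = 10,
    haldane: bool = False,
) -> list:
    """Enumerate all connected substructures of up to ``max_atoms`` atoms that
    occur in at least ``ceil(min_support_focus * |focus|)`` focus molecules.

    Growth starts from single atoms and extends one bond at a time inside the
    focus molecules; canonical fragment SMILES deduplicate equivalent
    subgraphs, and supersets of infrequent fragments are never expanded
    (support-based pruning, valid because molecule-level support is
    anti-monotone under substructure matching).  Hits are ranked by odds
    ratio (infinite first), then focus support.
    """
    if not (0 < min_support_focus <= 1):
        raise EnrichmentError("min_support_focus must lie in (0, 1]")
    if max_atoms < 2:
        raise EnrichmentError("max_atoms must be >= 2")
    if max_atoms > MAX_ATOMS_SAFETY_BOUND:
        raise EnrichmentError(
            f"max_atoms={max_atoms} exceeds the safety bound "
            f"{MAX_ATOMS_SAFETY_BOUND} (combinatorial blow-up guard)"
        )
    if len(focus) == 0 or len(complement) == 0:
        raise EnrichmentError("focus and complement sets must be non-empty")
    focus_mols = [_as_mol(m) for m in focus]
    complement_mols = [_as_mol(m) for m in complement]
    min_count = math.ceil(min_support_focus * len(focus_mols))

    # level 1: single atoms
    embeddings: dict = {}  # canonical fragment -> {mol_idx: set(frozenset(atom idx))}
    for mi, mol in enumerate(focus_mols):
        for atom in mol.GetAtoms():
            smi = _fragment_smiles(mol, [atom.GetIdx()])
            if smi is None:
                continue
            embeddings.setdefault(smi, {}).setdefault(mi, set()).add(
                frozenset([atom.GetIdx()])
            )

    frequent: dict = {}  # canonical fragment -> (atom_count, focus match count)
    level = 1
    while embeddings and level <= max_atoms:
        # match-based focus support for pruning and reporting
        kept = {}
        for smi, embs in embeddings.items():
            count = _match_count(smi, focus_mols)
            if count >= min_count:
                frequent[smi] = (level, count)
                kept[smi] = embs
        if level == max_atoms:
            break
        # extend each surviving embedding by one bond
        next_embeddings: dict = {}
        for smi, embs in kept.items():
            for mi, atom_sets in embs.items():
                mol = focus_mols[mi]
                for atoms in atom_sets:
                    for idx in atoms:
                        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                            j = nb.GetIdx()
                            if j in atoms:
                                continue
                            new_atoms = frozenset(atoms | {j})
                            new_smi = _fragment_smiles(mol, new_atoms)
                            if new_smi is None:
                                continue
                            next_embeddings.setdefault(new_smi, {}).setdefault(
                                mi, set()
                            ).add(new_atoms)
        embeddings = next_embeddings
        level += 1

    hits = []
    for smi, (atom_count, a) in frequent.items():
        c = _match_count(smi, complement_mols)
        table = ContingencyTable(
            a=a, b=len(focus_mols) - a, c=c, d=len(complement_mols) - c
        )
        hits.append(
            FragmentHit(
                pattern=FragmentPattern(pattern=smi, atom_count=atom_count),
                table=table,
                odds=odds_ratio(table, haldane=haldane),
            )
        )
    hits.sort(key=FragmentHit.sort_key)
    return hits


def pairwise_enrichment(
    groups: dict,
    min_group_size: int = 5,
    min_support_focus: float = 0.3,
    max_atoms: int = 10,
    haldane: bool = False,
) -> dict:
    """Run the miner for every ordered pair of labelled groups.

    Groups below ``min_group_size`` are skipped with a warning (tiny classes
    do not support an unbiased enrichment analysis).  Returns a dict mapping
    (focus_name, complement_name) to the ranked hit list.
    """
    if len(groups) < 2:
        raise EnrichmentError("need at least two groups")
    usable = {}
    for name, mols in groups.items():
        if len(mols) < min_group_size:
            logger.warning(
                "group %r has %d molecules (< %d); skipped from enrichment",
                name,
                len(mols),
                min_group_size,
            )
        else:
            usable[name] = mols
    reports = {}
    for focus_name, focus in usable.items():
        for comp_name, comp in usable.items():
            if focus_name == comp_name:
                continue
            reports[(focus_name, comp_name)] = mine_fragments(
                focus,
                comp,
                min_support_focus=min_support_focus,
                max_atoms=max_atoms,
                haldane=haldane,
            )
    return reports


def hits_to_rows(hits: Sequence[FragmentHit]) -> list:
    """Flatten hits into report rows (used by the CSV writer and CLI)."""
    rows = []
    for h in hits:
        rows.append(
            {
                "pattern": h.pattern.pattern,
                "atom_count": h.pattern.atom_count,
                "a": h.table.a,
                "b": h.table.b,
                "c": h.table.c,
                "d": h.table.d,
                "support_focus": h.support_focus,
                "support_complement": h.support_complement,
                "odds_ratio": "" if h.odds.infinite else h.odds.value,
                "infinite_flag": h.odds.infinite,
            }
        )
    return rows
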