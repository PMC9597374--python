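"""Molecule parsing, canonicalisation and labelled-dataset I/O.

Molecules enter the pipeline as SMILES strings, either one per line
(``.smi``, with an optional whitespace-delimited identifier) or as a CSV
column next to a label column.  Three label kinds are supported:

* ``binary`` -- inhibitor / non-inhibitor flag derived from an IC50 cut-off,
* ``pki``    -- continuous pK_i (-log10 of the inhibition constant, molar),
  optionally with a censoring mask for qualified ("<" / ">") measurements,
* ``type``   -- binding-mode class, one of ``I``, ``I1/2``, ``II``,
  ``allosteric``.

All molecules are canonicalised on load; salts and mixtures should be
reduced to their largest covalent fragment with
:func:`strip_to_largest_fragment` before featurisation, which requires a
connected heavy-atom graph.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

# RDKit reports parse failures on its own logger; we surface them as
# exceptions with context instead.
RDLogger.DisableLog("rdApp.error")

logger = logging.getLogger(__name__)

TYPE_VOCABULARY = ("I", "I1/2", "II", "allosteric")
LABEL_KINDS = ("binary", "pki", "type")


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed."""


class DatasetError(ValueError):
    """A dataset file is malformed, empty, or violates the label schema."""


@dataclass(frozen=True)
class Molecule:
    """A parsed small molecule.

    ``smiles_canonical`` is RDKit's canonical form with implicit hydrogens;
    ``heavy_atom_count`` counts non-hydrogen atoms only.
    """

    smiles_input: str
    smiles_canonical: str
    heavy_atom_count: int
    _mol: Chem.Mol = field(repr=False, compare=False)

    @property
    def mol(self) -> Chem.Mol:
        return self._mol


def _paren_hint(s: str) -> Optional[int]:
    """Best-effort position of the first unbalanced bracket, for error context."""
    for open_ch, close_ch in (("(", ")"), ("[", "]")):
        depth = 0
        for i, ch in enumerate(s):
            if ch == open_ch:
                depth += 1
            elif ch == close_ch:
                depth -= 1
                if depth < 0:
                    return i
        if depth > 0:
            return s.rindex(open_ch)
    return None


def parse_smiles(s: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Raises :class:`SmilesParseError` for empty or unparseable input, with the
    offending string (and a bracket-position hint where detectable).
    """
    if not isinstance(s, str) or not s.strip():
        raise SmilesParseError("empty SMILES string")
    text = s.strip()
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        pos = _paren_hint(text)
        ctx = f" (unbalanced bracket near position {pos})" if pos is not None else ""
        raise SmilesParseError(f"unparseable SMILES {text!r}{ctx}")
    return Molecule(
        smiles_input=s,
        smiles_canonical=Chem.MolToSmiles(mol),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        _mol=mol,
    )


def canonical_smiles(s: str) -> str:
    """Canonical form of a SMILES string (idempotent)."""
    return parse_smiles(s).smiles_canonical


def strip_to_largest_fragment(m: Molecule) -> Molecule:
    """Keep the covalently connected component with the most heavy atoms.

    Ties are broken by larger molecular weight, then by lexicographically
    smaller canonical SMILES, so the result is deterministic.
    """
    frags = Chem.GetMolFrags(m.mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return m
    ranked = sorted(
        frags,
        key=lambda f: (
            -f.GetNumHeavyAtoms(),
            -Descriptors.MolWt(f),
            Chem.MolToSmiles(f),
        ),
    )
    best = ranked[0]
    return Molecule(
        smiles_input=m.smiles_input,
        smiles_canonical=Chem.MolToSmiles(best),
        heavy_atom_count=best.GetNumHeavyAtoms(),
        _mol=best,
    )


@dataclass
class DatasetSchema:
    """Column mapping for CSV datasets: the SMILES column plus exactly one
    label column of a declared kind."""

    smiles: str = "smiles"
    label: Optional[str] = "label"
    kind: Optional[str] = None  # one of LABEL_KINDS, required when label set
    censored: Optional[str] = None  # optional boolean column for pki datasets
    id: Optional[str] = None


@dataclass
class LabeledDataset:
    """Parsed molecules with aligned labels.

    ``labels`` may be ``None`` for unlabeled screening input (``.smi`` files).
    ``censored_mask`` marks qualified pK_i measurements stored at their
    numeric bound.
    """

    molecules: list
    labels: Optional[list] = None
    label_kind: Optional[str] = None
    censored_mask: Optional[list] = None
    ids: Optional[list] = None
    n_dropped: int = 0

    def __post_init__(self):
        if self.labels is not None:
            if len(self.labels) != len(self.molecules):
                raise DatasetError("molecules and labels differ in length")
            if self.label_kind not in LABEL_KINDS:
                raise DatasetError(f"unknown label kind {self.label_kind!r}")
            if self.label_kind == "type":
                bad = sorted({l for l in self.labels if l not in TYPE_VOCABULARY})
                if bad:
                    raise DatasetError(
                        f"type labels outside vocabulary {TYPE_VOCABULARY}: {bad}"
                    )
        if self.censored_mask is not None and len(self.censored_mask) != len(
            self.molecules
        ):
            raise DatasetError("censored_mask length mismatch")
        if self.ids is not None and len(self.ids) != len(self.molecules):
            raise DatasetError("ids length mismatch")

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def smiles(self) -> list:
        return [m.smiles_canonical for m in self.molecules]


def _coerce_label(raw: str, kind: str):
    if kind == "binary":
        v = str(raw).strip().lower()
        if v in ("0", "false", "no"):
            return 0
        if v in ("1", "true", "yes"):
            return 1
        raise DatasetError(f"binary label must be 0/1, got {raw!r}")
    if kind == "pki":
        try:
            return float(raw)
        except (TypeError, ValueError) as exc:
            raise DatasetError(f"pK_i label must be numeric, got {raw!r}") from exc
    if kind == "type":
        v = str(raw).strip()
        if v not in TYPE_VOCABULARY:
            raise DatasetError(
                f"type label {v!r} outside closed vocabulary {TYPE_VOCABULARY}"
            )
        return v
    raise DatasetError(f"unknown label kind {kind!r}")


def _read_smi(path: Path) -> LabeledDataset:
    molecules, ids, dropped = [], [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            tokens = line.split()
            try:
                molecules.append(parse_smiles(tokens[0]))
            except SmilesParseError as exc:
                dropped += 1
                logger.warning("dropping line %d of %s: %s", lineno, path, exc)
                continue
            ids.append(tokens[1] if len(tokens) > 1 else str(lineno))
    if not molecules:
        raise DatasetError(f"no valid molecules in {path}")
    return LabeledDataset(molecules=molecules, ids=ids, n_dropped=dropped)


def read_dataset(path, schema: Optional[DatasetSchema] = None) -> LabeledDataset:
    """Read a ``.smi`` or CSV dataset.

    Rows with invalid SMILES are dropped and logged (``n_dropped`` records the
    count).  Duplicate canonical SMILES with conflicting labels keep the first
    occurrence with a warning.  A missing schema column raises
    :class:`DatasetError`, as does an empty result.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    if path.suffix.lower() == ".smi":
        return _read_smi(path)

    schema = schema or DatasetSchema()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fieldnames = reader.fieldnames or []
        for col in (schema.smiles, schema.label, schema.censored, schema.id):
            if col is not None and col not in fieldnames:
                raise DatasetError(f"missing column {col!r} in {path} ({fieldnames})")
        if schema.label is not None and schema.kind not in LABEL_KINDS:
            raise DatasetError(
                f"schema.kind must be one of {LABEL_KINDS} when a label column is set"
            )
        molecules, labels, mask, ids = [], [], [], []
        seen = {}  # canonical smiles -> label of first occurrence
        dropped = 0
        for rowno, row in enumerate(reader, 1):
            try:
                mol = parse_smiles(row[schema.smiles])
            except SmilesParseError as exc:
                dropped += 1
                logger.warning("dropping row %d of %s: %s", rowno, path, exc)
                continue
            label = (
                _coerce_label(row[schema.label], schema.kind)
                if schema.label is not None
                else None
            )
            key = mol.smiles_canonical
            if key in seen and label is not None and seen[key] != label:
                logger.warning(
                    "duplicate molecule %s with conflicting label %r "
                    "(keeping first occurrence %r)",
                    key,
                    label,
                    seen[key],
                )
                dropped += 1
                continue
            seen.setdefault(key, label)
            molecules.append(mol)
            if schema.label is not None:
                labels.append(label)
            if schema.censored is not None:
                mask.append(str(row[schema.censored]).strip().lower() in ("1", "true", "yes"))
            ids.append(row[schema.id] if schema.id is not None else str(rowno))
    if not molecules:
        raise DatasetError(f"no valid rows in {path}")
    return LabeledDataset(
        molecules=molecules,
        labels=labels if schema.label is not None else None,
        label_kind=schema.kind if schema.label is not None else None,
        censored_mask=mask if schema.censored is not None else None,
        ids=ids,
        n_dropped=dropped,
    )


def dataset_from_smiles(
    smiles: Sequence[str],
    labels=None,
    label_kind: Optional[str] = None,
    censored_mask=None,
    ids=None,
) -> LabeledDataset:
    """Build a dataset directly from SMILES strings (used by the synthetic
    generator and in tests)."""
    return LabeledDataset(
        molecules=[parse_smiles(s) for s in smiles],
        labels=list(labels) if labels is not None else None,
        label_kind=label_kind,
        censored_mask=list(censored_mask) if censored_mask is not None else None,
        ids=list(ids) if ids is not None else None,
    )


def write_dataset(ds: LabeledDataset, path) -> Path:
    """Write a dataset to CSV (canonical SMILES).  Reading it back with the
    matching schema reproduces SMILES and labels exactly."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["id", "smiles"]
        if ds.labels is not None:
            header.append("label")
        if ds.censored_mask is not None:
            header.append("censored")
        writer.writerow(header)
        for i, mol in enumerate(ds.molecules):
            row = [ds.ids[i] if ds.ids is not None else str(i), mol.smiles_canonical]
            if ds.labels is not None:
                row.append(ds.labels[i])
            if ds.censored_mask is not None:
                row.append(int(ds.censored_mask[i]))
            writer.writerow(row)
    return path
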