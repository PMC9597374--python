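"""Combined two-stage screening of candidate molecules.

A molecule passes the screen when two independent criteria agree, from crude
to refined:

1. the binary classifier calls it an inhibitor, and
2. the regressor predicts a moderately high potency, pK_i >= 5.5
   (inclusive boundary).

Both criteria are required; the final call is their conjunction, so raising
the pK_i cut-off can only shrink the screen-in set.  Binding-mode votes from
the four binary type classifiers are reported for every molecule, including
screen-outs, so the two outputs can be read side by side.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .chem_io import Molecule
from .featurize import (
    DEFAULT_GRID,
    PharmacophoreDefinitions,
    featurize_molecule,
    registry_checksum,
)
from .learn import TypeClassifierSet

logger = logging.getLogger(__name__)

DEFAULT_PKI_CUTOFF = 5.5


class ChecksumMismatchError(ValueError):
    """Models and featuriser disagree on the feature configuration."""


class ScreeningError(ValueError):
    """Invalid screening input or output."""


@dataclass
class ModelBundle:
    """Trained models plus the feature configuration they were built under."""

    classifier: object
    regressor: object
    type_models: Optional[TypeClassifierSet] = None
    grid: tuple = DEFAULT_GRID
    registry_checksum: str = ""
    defs: Optional[PharmacophoreDefinitions] = None

    def __post_init__(self):
        if not self.registry_checksum:
            self.registry_checksum = registry_checksum(self.grid, self.defs)


@dataclass
class ScreeningDecision:
    molecule_id: str
    smiles: str
    classifier_label: str  # "inhibitor" or "non-inhibitor"
    predicted_pki: float
    pki_pass: bool
    final_call: str  # "screen-in" or "screen-out"
    type_votes: Optional[dict] = None
    final_type: Optional[str] = None
    tie_flag: bool = False
    error: Optional[str] = None


def screen_compounds(
    molecules: Sequence[Molecule],
    bundle: ModelBundle,
    pki_cutoff: float = DEFAULT_PKI_CUTOFF,
    ids: Optional[Sequence[str]] = None,
) -> list:
    """Apply the trained models and emit one decision per molecule.

    The bundle's registry checksum must match the current feature
    configuration, otherwise scoring is refused with both checksums.  A
    molecule whose featurisation fails yields an error record and the run
    continues.
    """
    current = registry_checksum(bundle.grid, bundle.defs)
    if current != bundle.registry_checksum:
        raise ChecksumMismatchError(
            f"feature registry mismatch: models built under "
            f"{bundle.registry_checksum[:12]}..., current configuration is "
            f"{current[:12]}..."
        )
    ids = list(ids) if ids is not None else [str(i) for i in range(len(molecules))]
    decisions = []
    rows, ok_idx = [], []
    for i, mol in enumerate(molecules):
        try:
            rows.append(featurize_molecule(mol, bundle.grid, bundle.defs))
            ok_idx.append(i)
        except Exception as exc:
            logger.warning("featurisation failed for %s: %s", ids[i], exc)
            decisions.append(
                ScreeningDecision(
                    molecule_id=ids[i],
                    smiles=mol.smiles_canonical,
                    classifier_label="error",
                    predicted_pki=float("nan"),
                    pki_pass=False,
                    final_call="screen-out",
                    error=str(exc),
                )
            )
    if rows:
        X = np.vstack(rows)
        labels = np.asarray(bundle.classifier.predict(X)).astype(int)
        pki = np.asarray(bundle.regressor.predict(X), dtype=float)
        type_preds = bundle.type_models.predict(X) if bundle.type_models else None
        for row_i, i in enumerate(ok_idx):
            is_inhibitor = bool(labels[row_i] == 1)
            pki_pass = bool(pki[row_i] >= pki_cutoff)
            tp = type_preds[row_i] if type_preds is not None else None
            decisions.append(
                ScreeningDecision(
                    molecule_id=ids[i],
                    smiles=molecules[i].smiles_canonical,
                    classifier_label="inhibitor" if is_inhibitor else "non-inhibitor",
                    predicted_pki=float(pki[row_i]),
                    pki_pass=pki_pass,
                    final_call="screen-in" if (is_inhibitor and pki_pass) else "screen-out",
                    type_votes=tp.votes if tp else None,
                    final_type=tp.final_type if tp else None,
                    tie_flag=tp.tie_flag if tp else False,
                )
            )
    order = {mid: k for k, mid in enumerate(ids)}
    decisions.sort(key=lambda d: order[d.molecule_id])
    return decisions


REPORT_COLUMNS = (
    "molecule_id",
    "smiles",
    "classifier_label",
    "predicted_pki",
    "pki_pass",
    "final_call",
    "final_type",
    "tie_flag",
    "error",
)


def decision_report(
    decisions: Sequence[ScreeningDecision],
    path,
    pki_cutoff: float = DEFAULT_PKI_CUTOFF,
    fmt: str = "csv",
) -> Path:
    """Write decisions to CSV (with a commented config header) or JSON."""
    if not decisions:
        raise ScreeningError("cannot write an empty decision report")
    path = Path(path)
    config = {"package_version": __version__, "pki_cutoff": pki_cutoff}
    if fmt == "json":
        payload = {
            "config": config,
            "decisions": [
                {c: getattr(d, c) for c in REPORT_COLUMNS} for d in decisions
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path
    if fmt != "csv":
        raise ScreeningError(f"unknown report format {fmt!r}")
    with open(path, "w", newline="") as fh:
        fh.write(f"# config: {json.dumps(config, sort_keys=True)}\n")
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for d in decisions:
            writer.writerow([getattr(d, c) for c in REPORT_COLUMNS])
    return path
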