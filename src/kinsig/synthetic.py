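"""Synthetic SMILES datasets with controllable planted structure.

Real CDK2 bioactivity datasets cannot be redistributed here, so every
pipeline stage is exercised on grammar-generated molecules instead: a
scaffold (aromatic or saturated ring) with one or two substituents drawn
from a small vocabulary.  The grammar guarantees chemical validity and,
because the planted marker groups never occur in the base vocabulary,
exact control over substructure prevalence.

The label models emulate the structure of the curated datasets:

* binary   -- unbalanced inhibitor flag (63.6% positives by default) whose
  positive class carries a planted fragment at controllable prevalence, or,
  alternatively, labels drawn from a logistic odds model where fragment
  presence multiplies the odds by a prescribed odds ratio;
* continuous -- pK_i peaked near 5, shifted by a fragment effect, with an
  optional left-censored floor at 5.1 emulating qualified measurements;
* four_class -- binding-mode labels at the published 1425/394/190/47
  imbalance, each class marked by its own planted group, with a
  configurable confusion rate.

Everything is seeded; there is no global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .chem_io import LabeledDataset, dataset_from_smiles, parse_smiles

# ---------------------------------------------------------------------------
# grammar

#: scaffold templates; slot 0 is substituted in parentheses, slot 1 is
#: appended to the ring-closure atom
AROMATIC_SCAFFOLDS = (
    "c1cc({0})ccc1{1}",  # benzene
    "c1cc({0})cnc1{1}",  # pyridine
    "c1cc({0})oc1{1}",  # furan
)
SATURATED_SCAFFOLDS = (
    "C1CC({0})CCC1{1}",  # cyclohexane
    "C1CC({0})CNC1{1}",  # piperidine
)
ALL_SCAFFOLDS = AROMATIC_SCAFFOLDS + SATURATED_SCAFFOLDS

#: substituent vocabulary; deliberately free of sulfur, nitriles, ureas and
#: CF3 so the planted marker groups below are fully controllable
BASE_SUBSTITUENTS = (
    "",
    "C",
    "CC",
    "CCC",
    "C(C)C",
    "O",
    "OC",
    "OCC",
    "N",
    "NC",
    "N(C)C",
    "F",
    "Cl",
    "CO",
    "CCO",
)

#: default planted marker: a primary sulfonamide on an aromatic carbon
DEFAULT_PLANTED_SUBSTITUENT = "S(N)(=O)=O"
DEFAULT_PLANTED_PATTERN = "NS(=O)(=O)c"

#: one orthogonal marker group per binding-mode class
CLASS_FRAGMENTS = {
    "I": ("C#N", "C#N"),  # nitrile
    "I1/2": ("S(C)(=O)=O", "CS(=O)(=O)c"),  # methylsulfonyl
    "II": ("NC(N)=O", "NC(=O)N"),  # urea
    "allosteric": ("C(F)(F)F", "FC(F)F"),  # trifluoromethyl
}

#: censoring bound for qualified pK_i measurements
DEFAULT_CENSOR_BOUND = 5.1


class GenerationError(ValueError):
    """The requested fixture cannot be generated under the grammar."""


def _fill(template: str, sub0: str, sub1: str) -> str:
    out = template.replace("({0})", f"({sub0})" if sub0 else "")
    return out.replace("{1}", sub1)


def _random_molecule(
    rng: np.random.Generator, planted: Optional[str] = None
) -> str:
    """One grammar molecule; a planted substituent always lands on slot 1 of
    an aromatic scaffold so aromatic-attachment patterns stay detectable."""
    if planted is not None:
        template = AROMATIC_SCAFFOLDS[rng.integers(len(AROMATIC_SCAFFOLDS))]
        sub1 = planted
    else:
        template = ALL_SCAFFOLDS[rng.integers(len(ALL_SCAFFOLDS))]
        sub1 = BASE_SUBSTITUENTS[rng.integers(len(BASE_SUBSTITUENTS))]
    sub0 = BASE_SUBSTITUENTS[rng.integers(len(BASE_SUBSTITUENTS))]
    smiles = _fill(template, sub0, sub1)
    parse_smiles(smiles)  # grammar guarantees validity; fail loudly if not
    return smiles


def _exact_count_mask(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean mask with exactly round(fraction * n) True entries, shuffled."""
    k = int(round(fraction * n))
    if not (0 <= k <= n):
        raise GenerationError(f"fraction {fraction} infeasible for n={n}")
    mask = np.zeros(n, dtype=bool)
    mask[:k] = True
    rng.shuffle(mask)
    return mask


# ---------------------------------------------------------------------------
# label models


@dataclass(frozen=True)
class BinaryLabelModel:
    """Inhibitor / non-inhibitor labels.

    With ``odds`` unset, class labels are assigned first (``positive_fraction``
    positives, matching the 63.6%/36.4% imbalance of curated CDK2 data) and
    the planted fragment is grafted into each class at its prevalence; an
    optional flip rate then corrupts labels.  With ``odds`` set, fragment
    presence is sampled at ``presence_rate`` and labels are drawn from a
    logistic odds model where presence multiplies the baseline odds by
    ``odds`` -- the sampling model under which a mined odds ratio estimates
    ``odds``.
    """

    positive_fraction: float = 0.636
    flip_rate: float = 0.0
    odds: Optional[float] = None
    baseline_odds: float = 0.8
    presence_rate: float = 0.3


@dataclass(frozen=True)
class ContinuousLabelModel:
    """pK_i = baseline + effect * fragment_present + Gaussian(0, sigma);
    the ``censor_fraction`` smallest values are floored at ``censor_bound``
    and flagged in the censoring mask."""

    baseline: float = 5.0
    effect: float = 1.5
    sigma: float = 0.4
    presence_rate: float = 0.5
    censor_fraction: float = 0.0
    censor_bound: float = DEFAULT_CENSOR_BOUND


@dataclass(frozen=True)
class FourClassLabelModel:
    """Binding-mode labels at the published class imbalance; each class
    plants its own marker group, swapped for a random other class's marker at
    the confusion rate."""

    proportions: tuple = (1425 / 2056, 394 / 2056, 190 / 2056, 47 / 2056)
    confusion_rate: float = 0.0


LabelModel = Union[BinaryLabelModel, ContinuousLabelModel, FourClassLabelModel]

CLASS_ORDER = ("I", "I1/2", "II", "allosteric")


@dataclass(frozen=True)
class FixtureSpec:
    """Full recipe for a synthetic dataset."""

    n_molecules: int
    label_model: LabelModel = field(default_factory=BinaryLabelModel)
    planted_substituent: str = DEFAULT_PLANTED_SUBSTITUENT
    planted_pattern: str = DEFAULT_PLANTED_PATTERN
    fragment_prevalence_positive: float = 0.5
    fragment_prevalence_negative: float = 0.05
    seed: int = 0


@dataclass
class GeneratedMolecules:
    """Molecules plus the generation ground truth."""

    smiles: list
    fragment_present: Optional[list] = None  # binary / continuous fixtures
    true_class: Optional[list] = None  # four-class fixtures
    planted_pattern: Optional[str] = None


def _class_counts(rng, n, proportions) -> np.ndarray:
    counts = np.floor(np.asarray(proportions) * n).astype(int)
    remainder = n - counts.sum()
    # distribute the rounding remainder to the largest fractional parts
    fracs = np.asarray(proportions) * n - counts
    for idx in np.argsort(-fracs)[:remainder]:
        counts[idx] += 1
    return counts


def generate_molecules(spec: FixtureSpec) -> GeneratedMolecules:
    """Generate the molecules (and ground truth) for a fixture.

    Fragment prevalences are hit exactly (up to rounding) rather than in
    expectation, so generated sets respect the prescribed proportions even at
    moderate n.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_molecules
    if n < 1:
        raise GenerationError("n_molecules must be >= 1")
    model = spec.label_model

    if isinstance(model, FourClassLabelModel):
        counts = _class_counts(rng, n, model.proportions)
        classes = np.repeat(np.array(CLASS_ORDER, dtype=object), counts)
        rng.shuffle(classes)
        smiles, markers = [], []
        for cls in classes:
            marker_cls = cls
            if model.confusion_rate > 0 and rng.random() < model.confusion_rate:
                others = [c for c in CLASS_ORDER if c != cls]
                marker_cls = others[rng.integers(len(others))]
            smiles.append(_random_molecule(rng, CLASS_FRAGMENTS[marker_cls][0]))
            markers.append(marker_cls)
        return GeneratedMolecules(
            smiles=smiles, true_class=list(classes), planted_pattern=None
        )

    if isinstance(model, BinaryLabelModel) and model.odds is not None:
        present = _exact_count_mask(rng, n, model.presence_rate)
    elif isinstance(model, BinaryLabelModel):
        positive = _exact_count_mask(rng, n, model.positive_fraction)
        present = np.zeros(n, dtype=bool)
        for is_pos, prevalence in (
            (True, spec.fragment_prevalence_positive),
            (False, spec.fragment_prevalence_negative),
        ):
            idx = np.flatnonzero(positive == is_pos)
            sub_mask = _exact_count_mask(rng, idx.size, prevalence)
            present[idx[sub_mask]] = True
        # stash the class assignment for generate_labels via the truth object
        gen = GeneratedMolecules(
            smiles=[
                _random_molecule(
                    rng, spec.planted_substituent if present[i] else None
                )
                for i in range(n)
            ],
            fragment_present=present.tolist(),
            planted_pattern=spec.planted_pattern,
        )
        gen._positive = positive  # type: ignore[attr-defined]
        return gen
    else:  # continuous
        present = _exact_count_mask(rng, n, model.presence_rate)

    smiles = [
        _random_molecule(rng, spec.planted_substituent if present[i] else None)
        for i in range(n)
    ]
    return GeneratedMolecules(
        smiles=smiles,
        fragment_present=present.tolist(),
        planted_pattern=spec.planted_pattern,
    )


def generate_labels(gen: GeneratedMolecules, spec: FixtureSpec) -> LabeledDataset:
    """Attach labels to generated molecules according to the label model."""
    rng = np.random.default_rng([spec.seed, 1])
    n = len(gen.smiles)
    model = spec.label_model

    if isinstance(model, FourClassLabelModel):
        return dataset_from_smiles(gen.smiles, labels=gen.true_class, label_kind="type")

    present = np.asarray(gen.fragment_present, dtype=bool)

    if isinstance(model, BinaryLabelModel):
        if model.odds is not None:
            odds = np.where(present, model.baseline_odds * model.odds, model.baseline_odds)
            labels = (rng.random(n) < odds / (1 + odds)).astype(int)
        else:
            labels = getattr(gen, "_positive").astype(int)
            if model.flip_rate > 0:
                flips = _exact_count_mask(rng, n, model.flip_rate)
                labels = np.where(flips, 1 - labels, labels)
        return dataset_from_smiles(gen.smiles, labels=labels.tolist(), label_kind="binary")

    # continuous pK_i
    pki = model.baseline + model.effect * present + rng.normal(0.0, model.sigma, n)
    mask = np.zeros(n, dtype=bool)
    n_censor = int(np.floor(model.censor_fraction * n))
    if n_censor > 0:
        idx = np.argsort(pki)[:n_censor]
        pki[idx] = model.censor_bound
        mask[idx] = True
    return dataset_from_smiles(
        gen.smiles,
        labels=pki.tolist(),
        label_kind="pki",
        censored_mask=mask.tolist(),
    )


def generate_dataset(spec: FixtureSpec):
    """Convenience: molecules + labels + ground truth in one call."""
    gen = generate_molecules(spec)
    ds = generate_labels(gen, spec)
    truth = {
        "planted_pattern": gen.planted_pattern,
        "fragment_present": gen.fragment_present,
        "true_class": gen.true_class,
        "seed": spec.seed,
    }
    return ds, truth


def write_ground_truth(truth: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth, indent=2))
    return path
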