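"""Terminal molecular rewards: drug-likeness (QED) and synthetic accessibility.

The fine-tuning objective is a weighted sum of per-property scores of the
*completed* molecule,

    R(p) = sum_l w_l p_l,

with p_q the raw QED score in [0, 1] and p_s the rescaled negative
synthetic-accessibility score

    p_s = -(SA - 1) / 9  in  [-1, 0],

so both properties live on comparable scales and lower SA (easier
synthesis) means higher reward.  Property scores exist only for finished
strings, so per-step rewards are zero everywhere except the final step;
an invalid molecule earns a terminal reward of 0.

QED comes from RDKit; the SA score is the Ertl-Schuffenhauer
fragment-contribution heuristic shipped in RDKit's contrib tree (scale 1
easy to 10 hard).  Additional terminal rewards can be registered by name
(tests use simple structural toy rewards this way).
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import QED

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module)

from .codecs import Scheme, canonical_smiles  # noqa: E402

__all__ = [
    "PropertyVector",
    "RewardWeights",
    "RewardValue",
    "qed_term",
    "sa_score",
    "sa_rescale",
    "composite_reward",
    "score_molecule",
    "register_property",
    "property_fn",
    "PROPERTY_REGISTRY",
]


@dataclass(frozen=True)
class PropertyVector:
    values: dict[str, float]

    def __post_init__(self):
        v = self.values
        if "qed" in v and not 0.0 <= v["qed"] <= 1.0:
            raise ValueError("QED term outside [0, 1]")
        if "sa" in v and not -1.0 <= v["sa"] <= 0.0:
            raise ValueError("rescaled SA term outside [-1, 0]")


@dataclass(frozen=True)
class RewardWeights:
    w: dict[str, float]

    def __post_init__(self):
        if not any(x != 0.0 for x in self.w.values()):
            raise ValueError("at least one weight must be nonzero")

    @classmethod
    def qed_sa(cls, w_q: float, w_s: float) -> "RewardWeights":
        """The (w_q, w_s) convention: both applied with +1 sign to the
        already-negated SA term."""
        return cls(w={"qed": w_q, "sa": w_s})


@dataclass(frozen=True)
class RewardValue:
    terminal: float
    n_steps: int

    @property
    def per_step(self) -> np.ndarray:
        out = np.zeros(self.n_steps)
        if self.n_steps:
            out[-1] = self.terminal
        return out


def qed_term(mol: Chem.Mol) -> float:
    """Raw QED drug-likeness in [0, 1] (RDKit reference implementation)."""
    if mol is None:
        raise ValueError("invalid molecule")
    return float(QED.qed(mol))


def sa_score(mol: Chem.Mol) -> float:
    """Ertl-Schuffenhauer synthetic accessibility, 1 (easy) to 10 (hard)."""
    if mol is None:
        raise ValueError("invalid molecule")
    return float(sascorer.calculateScore(mol))


def sa_rescale(sa_raw: float) -> float:
    """Map the SA scale [1, 10] onto [0, -1]: p_s = -(SA - 1) / 9."""
    if not 1.0 <= sa_raw <= 10.0:
        raise ValueError(f"SA score {sa_raw} outside [1, 10]")
    return -(sa_raw - 1.0) / 9.0 + 0.0  # + 0.0 normalises -0.0


def composite_reward(p: PropertyVector, w: RewardWeights) -> float:
    """Weighted sum over the named properties."""
    missing = set(w.w) - set(p.values)
    if missing:
        raise KeyError(f"properties missing from vector: {sorted(missing)}")
    return float(sum(wl * p.values[name] for name, wl in w.w.items()))


PROPERTY_REGISTRY: dict = {}


def register_property(name: str):
    """Register a terminal property scorer ``f(mol) -> float`` by name."""

    def deco(fn):
        PROPERTY_REGISTRY[name] = fn
        return fn

    return deco


register_property("qed")(qed_term)


@register_property("sa")
def _rescaled_sa(mol: Chem.Mol) -> float:
    return sa_rescale(min(10.0, max(1.0, sa_score(mol))))


def property_fn(name: str):
    return PROPERTY_REGISTRY[name]


def score_molecule(core: str, scheme: Scheme, w: RewardWeights,
                   n_steps: int = 0) -> tuple[RewardValue, PropertyVector]:
    """Terminal-only reward of a finished string (0 if it is invalid)."""
    smiles = canonical_smiles(core, scheme) if core else None
    if smiles is None:
        return RewardValue(0.0, n_steps), PropertyVector(values={})
    mol = Chem.MolFromSmiles(smiles)
    values = {name: PROPERTY_REGISTRY[name](mol) for name in w.w}
    p = PropertyVector(values=values)
    return RewardValue(composite_reward(p, w), n_steps), p
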