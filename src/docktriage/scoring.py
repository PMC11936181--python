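"""Weighted multi-target/anti-target scoring, ranking and threshold filtering.

A compound is screened against a panel of targets whose inhibition is
desired (here the MAPK kinases ERK2, JNK2, p38 and the NFkB subunit p65)
and an anti-target whose inhibition is undesirable (IkBa, whose
degradation releases NFkB — a compound binding it strongly would promote,
not suppress, inflammatory signalling). The score of a compound is a
signed weighted sum of its representative binding energies,

    score = sum_t w_t * E_t     (kcal/mol-weighted, no normalisation)

with negative weights penalising anti-target affinity: since binding
energies are negative-favourable, subtracting E_antitarget rewards weak
anti-target binders. Compounds are ranked ascending (lowest score =
strongest combined on-target affinity). Preset schemes:

* ``score1`` — E_ERK2 + E_JNK2 + E_p38 + 3*E_p65 − E_IkBa
  (equal weight to the MAPK and NFkB pathways, then to proteins within
  each pathway, hence the 3 on p65);
* ``score2`` — E_ERK2 + E_JNK2 + E_p38 + E_p65 − E_IkBa
  (equal weight to the five proteins directly).

Independently of scoring, a per-target threshold filter retains compounds
binding every target strictly below a cutoff (default −7 kcal/mol) while
binding the anti-target at or above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ScoreScheme",
    "RankedCompound",
    "ThresholdSpec",
    "DEFAULT_TARGETS",
    "ANTITARGET",
    "SCORE1",
    "SCORE2",
    "compute_score",
    "rank_compounds",
    "threshold_filter",
    "load_scheme",
]

#: Canonical target panel: four desired targets then the anti-target.
DEFAULT_TARGETS: tuple[str, ...] = ("ERK2", "JNK2", "p38", "p65", "IkBa")
ANTITARGET: str = "IkBa"


@dataclass(frozen=True)
class ScoreScheme:
    """Named mapping of target id to signed, dimensionless weight."""

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = dict(self.weights)
        for t, v in w.items():
            v = float(v)
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"scheme {self.name!r}: non-finite weight for {t}")
            w[t] = v
        object.__setattr__(self, "weights", w)


SCORE1 = ScoreScheme(
    "score1", {"ERK2": 1.0, "JNK2": 1.0, "p38": 1.0, "p65": 3.0, "IkBa": -1.0}
)
SCORE2 = ScoreScheme(
    "score2", {"ERK2": 1.0, "JNK2": 1.0, "p38": 1.0, "p65": 1.0, "IkBa": -1.0}
)

_PRESETS = {"score1": SCORE1, "score2": SCORE2}


def load_scheme(spec: str) -> ScoreScheme:
    """Resolve a preset name or a YAML file of target → weight."""
    if spec in _PRESETS:
        return _PRESETS[spec]
    with open(spec) as fh:
        weights = yaml.safe_load(fh)
    if not isinstance(weights, dict):
        raise ValueError(f"scheme file {spec}: expected a mapping")
    return ScoreScheme(name=spec, weights={str(k): float(v) for k, v in weights.items()})


@dataclass(frozen=True)
class RankedCompound:
    compound_id: str
    score: float
    rank: int


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-target energy-cutoff filter specification.

    A compound passes iff its energy is strictly below ``target_cutoff``
    on every desired target and at or above it on the anti-target.
    """

    target_cutoff: float = -7.0
    target_ids: tuple[str, ...] = ("ERK2", "JNK2", "p38", "p65")
    antitarget_id: str = ANTITARGET

    def __post_init__(self) -> None:
        if self.antitarget_id in self.target_ids:
            raise ValueError("anti-target must be disjoint from targets")


def compute_score(row: Mapping[str, float], scheme: ScoreScheme) -> float:
    """Weighted sum of one compound's energies under a scheme.

    ``row`` maps target id to representative energy (kcal/mol) and must
    cover every target the scheme names.
    """
    total = 0.0
    for target, weight in scheme.weights.items():
        if target not in row:
            raise KeyError(f"no energy for target {target!r}")
        total += weight * float(row[target])
    return total


def rank_compounds(
    matrix: pd.DataFrame, scheme: ScoreScheme
) -> list[RankedCompound]:
    """Score every compound and rank ascending (rank 1 = lowest score).

    Ties are broken by ascending compound id for cross-platform
    determinism. An empty matrix yields an empty list.
    """
    missing = set(scheme.weights) - set(matrix.columns)
    if missing:
        raise KeyError(f"matrix lacks scheme targets: {sorted(missing)}")
    if matrix.empty:
        return []
    weights = pd.Series(scheme.weights)
    scores = matrix[weights.index].mul(weights, axis=1).sum(axis=1)
    order = sorted(scores.index, key=lambda cid: (scores[cid], str(cid)))
    return [
        RankedCompound(compound_id=str(cid), score=float(scores[cid]), rank=i)
        for i, cid in enumerate(order, start=1)
    ]


def threshold_filter(
    matrix: pd.DataFrame, spec: ThresholdSpec = ThresholdSpec()
) -> set[str]:
    """Compounds passing the target/anti-target energy cutoffs.

    Retained iff E_t < cutoff (strict) for every desired target t AND
    E_antitarget >= cutoff (non-strict). The two conditions partition
    exactly at the cutoff; comparisons are exact (energies are reported
    at 0.1 kcal/mol granularity, so no epsilon is applied).
    """
    needed = set(spec.target_ids) | {spec.antitarget_id}
    missing = needed - set(matrix.columns)
    if missing:
        raise KeyError(f"matrix lacks filter columns: {sorted(missing)}")
    on_target = (matrix[list(spec.target_ids)] < spec.target_cutoff).all(axis=1)
    off_anti = matrix[spec.antitarget_id] >= spec.target_cutoff
    return {str(c) for c in matrix.index[on_target & off_anti]}
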