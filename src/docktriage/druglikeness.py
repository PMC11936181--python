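"""Lipinski rule-of-5 evaluation from tabulated molecular descriptors.

The rule of 5 is a drug-likeness heuristic over four descriptors:
molecular weight (<= 500 g/mol), LogP (<= 5), hydrogen-bond donor count
(<= 5) and hydrogen-bond acceptor count (<= 10). Descriptors are ingested
from a table (database values such as PubChem's XLogP3), not computed
from structures. Boundaries are inclusive — a descriptor exactly at its
threshold is compliant — which is the canonical reading and the one that
reproduces published violation counts (e.g. an acceptor count of exactly
10 counts as no violation). A compound is drug-like when it violates no
rule; the common "at most one violation" relaxation is available via
``max_violations``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MolecularDescriptors",
    "LipinskiResult",
    "lipinski_violations",
    "evaluate_library",
    "read_descriptor_table",
]

#: Rule code -> (descriptor attribute, inclusive upper bound).
RULES: dict[str, tuple[str, float]] = {
    "MW": ("molecular_weight", 500.0),
    "LogP": ("logp", 5.0),
    "HBD": ("hbd_count", 5.0),
    "HBA": ("hba_count", 10.0),
}


@dataclass(frozen=True)
class MolecularDescriptors:
    """Rule-of-5 inputs for one compound.

    molecular_weight in g/mol (> 0); logp dimensionless (XLogP3-style);
    hbd_count / hba_count non-negative integers.
    """

    compound_id: str
    molecular_weight: float
    logp: float
    hbd_count: int
    hba_count: int

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.compound_id}: non-positive molecular weight")
        if self.hbd_count < 0 or self.hba_count < 0:
            raise ValueError(f"{self.compound_id}: negative H-bond count")


@dataclass(frozen=True)
class LipinskiResult:
    compound_id: str
    violated_rules: frozenset[str]
    violation_count: int
    druglike: bool


def lipinski_violations(
    desc: MolecularDescriptors, *, max_violations: int = 0
) -> LipinskiResult:
    """Evaluate the four rules for one compound.

    A rule is violated iff the descriptor strictly exceeds its threshold
    (values exactly at the threshold are compliant). ``druglike`` is true
    when violation_count <= max_violations; the default 0 is the strict
    "violates no rules" classification.
    """
    violated = frozenset(
        code
        for code, (attr, bound) in RULES.items()
        if getattr(desc, attr) > bound
    )
    return LipinskiResult(
        compound_id=desc.compound_id,
        violated_rules=violated,
        violation_count=len(violated),
        druglike=len(violated) <= max_violations,
    )


def evaluate_library(
    table: pd.DataFrame, *, max_violations: int = 0
) -> pd.DataFrame:
    """Evaluate the rule of 5 for every row of a descriptor table.

    ``table`` needs columns compound_id, molecular_weight, logp,
    hbd_count, hba_count; compound ids must be unique. Returns one row
    per input row, order preserved, with columns compound_id,
    violated_rules (comma-joined codes in MW/LogP/HBD/HBA order),
    violation_count and druglike.
    """
    if table.empty:
        return pd.DataFrame(
            columns=["compound_id", "violated_rules", "violation_count", "druglike"]
        )
    if table["compound_id"].duplicated().any():
        dup = table.loc[table["compound_id"].duplicated(), "compound_id"].iloc[0]
        raise ValueError(f"duplicate compound_id {dup!r} in descriptor table")
    rows = []
    for rec in table.itertuples(index=False):
        res = lipinski_violations(
            MolecularDescriptors(
                compound_id=str(rec.compound_id),
                molecular_weight=float(rec.molecular_weight),
                logp=float(rec.logp),
                hbd_count=int(rec.hbd_count),
                hba_count=int(rec.hba_count),
            ),
            max_violations=max_violations,
        )
        rows.append(
            {
                "compound_id": res.compound_id,
                "violated_rules": ",".join(
                    c for c in RULES if c in res.violated_rules
                ),
                "violation_count": res.violation_count,
                "druglike": res.druglike,
            }
        )
    return pd.DataFrame(rows)


def read_descriptor_table(path) -> pd.DataFrame:
    """Read a descriptor CSV with the evaluate_library column contract."""
    df = pd.read_csv(path)
    needed = {"compound_id", "molecular_weight", "logp", "hbd_count", "hba_count"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"descriptor table missing columns: {sorted(missing)}")
    return df
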