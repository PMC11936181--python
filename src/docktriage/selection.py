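"""Candidate selection from a ranked screen plus curated annotations.

The selection procedure narrows a score-ranked compound list in three
steps: take the top N by rank, keep compounds annotated (from literature
curation) as anti-inflammatory, then drop compounds flagged as already
known to act against the disease — those validate the screen but are not
novel candidates. Each compound receives exactly one audit reason code.
Annotation flags are curated inputs, never computed here; ADMET,
bioactivity and toxicity columns ride along as uninterpreted pass-through
strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .scoring import RankedCompound

__all__ = ["SelectionReport", "select_candidates", "merge_report", "read_annotations"]

REASON_CODES = ("selected", "excluded", "not_anti_inflammatory", "not_top_n")


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of the top-N / anti-inflammatory / exclusion funnel.

    Orders are inherited from the ranking; final_ids is a subset of
    anti_inflammatory_ids, itself a subset of top_n_ids. ``audit`` maps
    every ranked compound to exactly one reason code.
    """

    top_n_ids: tuple[str, ...]
    anti_inflammatory_ids: tuple[str, ...]
    final_ids: tuple[str, ...]
    audit: dict[str, str]


def select_candidates(
    ranked: Sequence[RankedCompound],
    annotations: pd.DataFrame,
    top_n: int = 10,
) -> SelectionReport:
    """Apply the selection funnel to a ranked list.

    ``annotations`` needs columns compound_id, anti_inflammatory,
    excluded_known_anti_oa (boolean); every top-N compound must have an
    annotation row. The anti-inflammatory filter is applied before the
    exclusion filter; with these two operators the final set does not
    depend on the order, but the audit codes do, so the order is fixed:
    a compound both non-anti-inflammatory and excluded is audited as
    ``not_anti_inflammatory``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if annotations["compound_id"].duplicated().any():
        dup = annotations.loc[
            annotations["compound_id"].duplicated(), "compound_id"
        ].iloc[0]
        raise ValueError(f"duplicate annotation row for {dup!r}")
    ann = annotations.set_index(annotations["compound_id"].astype(str))

    ordered = sorted(ranked, key=lambda rc: rc.rank)
    top = [rc.compound_id for rc in ordered[:top_n]]
    missing = [cid for cid in top if cid not in ann.index]
    if missing:
        raise KeyError(f"no annotation for top-{top_n} compounds: {missing}")

    anti_inf = [cid for cid in top if bool(ann.at[cid, "anti_inflammatory"])]
    final = [
        cid for cid in anti_inf if not bool(ann.at[cid, "excluded_known_anti_oa"])
    ]

    audit: dict[str, str] = {}
    for rc in ordered:
        cid = rc.compound_id
        if cid not in top:
            audit[cid] = "not_top_n"
        elif cid not in anti_inf:
            audit[cid] = "not_anti_inflammatory"
        elif cid not in final:
            audit[cid] = "excluded"
        else:
            audit[cid] = "selected"
    return SelectionReport(
        top_n_ids=tuple(top),
        anti_inflammatory_ids=tuple(anti_inf),
        final_ids=tuple(final),
        audit=audit,
    )


def merge_report(
    report: SelectionReport,
    lipinski: pd.DataFrame,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the final per-candidate table.

    One row per selected compound, in selection order, joining the
    rule-of-5 results with the annotation table; pass-through columns are
    copied verbatim. Missing side-table rows are an error.
    """
    cols = ["compound_id", "violation_count", "violated_rules", "druglike"]
    if report.final_ids == ():
        passthrough = [
            c for c in annotations.columns
            if c not in ("compound_id", "anti_inflammatory", "excluded_known_anti_oa")
        ]
        return pd.DataFrame(columns=cols + passthrough)
    lip = lipinski.set_index(lipinski["compound_id"].astype(str))
    ann = annotations.set_index(annotations["compound_id"].astype(str))
    for cid in report.final_ids:
        if cid not in lip.index:
            raise KeyError(f"no rule-of-5 result for selected compound {cid!r}")
        if cid not in ann.index:
            raise KeyError(f"no annotation for selected compound {cid!r}")
    rows = []
    passthrough = [
        c for c in annotations.columns
        if c not in ("compound_id", "anti_inflammatory", "excluded_known_anti_oa")
    ]
    for cid in report.final_ids:
        row = {
            "compound_id": cid,
            "violation_count": int(lip.at[cid, "violation_count"]),
            "violated_rules": lip.at[cid, "violated_rules"],
            "druglike": bool(lip.at[cid, "druglike"]),
        }
        for c in passthrough:
            row[c] = ann.at[cid, c]
        rows.append(row)
    return pd.DataFrame(rows)


def read_annotations(path) -> pd.DataFrame:
    """Read an annotation CSV (boolean literals true/false accepted)."""
    df = pd.read_csv(path)
    needed = {"compound_id", "anti_inflammatory", "excluded_known_anti_oa"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    for col in ("anti_inflammatory", "excluded_known_anti_oa"):
        df[col] = (
            df[col]
            .map(lambda v: str(v).strip().lower() in ("true", "1", "yes"))
            .astype(bool)
        )
    return df
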