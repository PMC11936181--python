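"""Packaged reference tables.

Ships two small curated CSVs:

* the 51-compound screening panel with literature-curated
  anti-inflammatory and known-anti-OA exclusion flags, PubChem CIDs, and
  pass-through ADMET / bioactivity / toxicity annotations for the five
  compounds that were carried into in-vitro testing (flags for compounds
  outside the screen's top ten never enter the selection procedure and
  are set false). Chryseriol and Chrysoeriol share a PubChem CID but are
  kept as distinct compound ids — inputs are never silently
  deduplicated; see :func:`load_panel_annotations`.
* the published molecular descriptors (MW, XLogP3, H-bond donor and
  acceptor counts) of the five selected compounds, the inputs to the
  rule-of-5 evaluation.
"""

from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

from .selection import read_annotations

__all__ = ["load_selected_descriptors", "load_panel_annotations"]


def _data_path(name: str):
    return resources.files("docktriage.data").joinpath(name)


def load_selected_descriptors() -> pd.DataFrame:
    """Descriptor table for the five selected compounds."""
    with resources.as_file(_data_path("descriptors_selected.csv")) as p:
        return pd.read_csv(p)


def load_panel_annotations(*, dedupe_cid: bool = False) -> pd.DataFrame:
    """Annotation table for the 51-compound screening panel.

    Two panel members share a PubChem CID; they are distinct rows. With
    ``dedupe_cid`` the later duplicate-CID row is dropped (explicit
    opt-in); by default a warning is emitted and all rows are kept.
    """
    with resources.as_file(_data_path("annotations_51.csv")) as p:
        df = read_annotations(p)
    dup = df["pubchem_cid"].duplicated()
    if dup.any():
        cids = sorted(df.loc[dup, "pubchem_cid"].unique())
        if dedupe_cid:
            df = df[~dup].reset_index(drop=True)
        else:
            warnings.warn(
                f"panel contains distinct compounds sharing PubChem CID(s) {cids}; "
                "pass dedupe_cid=True to drop later duplicates",
                stacklevel=2,
            )
    return df
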