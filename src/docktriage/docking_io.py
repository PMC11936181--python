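"""Docking-output ingestion and energy-matrix assembly.

A docking engine emits, for each compound-target pair, a set of candidate
bound configurations (poses), each carrying a predicted binding energy in
kcal/mol (negative = more favourable). This module parses those outputs
— either pose-annotated PDBQT files with ``REMARK VINA RESULT`` lines, or
plain long-format energy tables — reduces each pair's pose energies to a
single representative energy (minimum by default, mean as an alternative),
and assembles the dense compound x target energy matrix the scoring stage
consumes. It also applies the Ramachandran-based structure-quality rule
used to vet receptor models before docking.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "DockingRun",
    "RamachandranSummary",
    "ParseError",
    "parse_pose_file",
    "parse_energy_table",
    "representative_energy",
    "build_energy_matrix",
    "classify_model_quality",
    "write_pose_file",
    "write_energy_matrix",
    "read_energy_matrix",
]

RESULT_TAG = "REMARK VINA RESULT:"

ReductionMode = Literal["minimum", "mean"]


class ParseError(ValueError):
    """Raised when a docking output file cannot be interpreted."""


@dataclass(frozen=True)
class DockingRun:
    """Pose energies for one compound docked against one target.

    Parameters
    ----------
    compound_id, target_id
        Identifiers for the ligand and the receptor.
    configuration_energies
        Binding energy of each docked configuration, kcal/mol, in file
        order. Non-empty; all finite. Typically 10-20 poses per pair but
        any positive count is accepted.
    """

    compound_id: str
    target_id: str
    configuration_energies: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        energies = tuple(float(e) for e in self.configuration_energies)
        if not energies:
            raise ValueError(
                f"{self.compound_id}/{self.target_id}: no configuration energies"
            )
        if not all(math.isfinite(e) for e in energies):
            raise ValueError(
                f"{self.compound_id}/{self.target_id}: non-finite energy"
            )
        object.__setattr__(self, "configuration_energies", energies)


@dataclass(frozen=True)
class RamachandranSummary:
    """Percentage of residues in the most-favoured Ramachandran region."""

    protein_id: str
    pct_most_favored: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_most_favored <= 100.0):
            raise ValueError(
                f"{self.protein_id}: pct_most_favored {self.pct_most_favored} "
                "outside [0, 100]"
            )


def _as_lines(stream: str | IO[str] | Path) -> tuple[Iterable[str], str]:
    if isinstance(stream, Path):
        return stream.read_text().splitlines(), str(stream)
    if isinstance(stream, str):
        return stream.splitlines(), "<string>"
    name = getattr(stream, "name", "<stream>")
    return stream.read().splitlines(), str(name)


def parse_pose_file(stream: str | IO[str] | Path) -> list[float]:
    """Extract per-configuration binding energies from a pose file.

    Only ``REMARK VINA RESULT:`` lines are interpreted (one per MODEL
    block); the first numeric field on each is the binding energy in
    kcal/mol. All other PDBQT content — atoms, torsions, other remarks —
    is ignored: this stage consumes energies, not geometry.

    Returns the energies in file order.

    Raises
    ------
    ParseError
        If no result line is present, or a result line's energy field is
        not numeric (the error names the file and line number).
    """
    lines, name = _as_lines(stream)
    energies: list[float] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.lstrip().startswith(RESULT_TAG):
            continue
        fields = line.split(RESULT_TAG, 1)[1].split()
        if not fields:
            raise ParseError(f"{name}:{lineno}: result line has no energy field")
        try:
            energies.append(float(fields[0]))
        except ValueError as exc:
            raise ParseError(
                f"{name}:{lineno}: malformed energy field {fields[0]!r}"
            ) from exc
    if not energies:
        raise ParseError(f"{name}: no '{RESULT_TAG}' line found")
    return energies


def write_pose_file(run: DockingRun, path: Path | None = None) -> str:
    """Serialise a run in the pose-file dialect `parse_pose_file` reads.

    One MODEL/ENDMDL block per configuration; round-trips losslessly
    through :func:`parse_pose_file` (energies written with full repr
    precision).
    """
    buf = io.StringIO()
    for i, e in enumerate(run.configuration_energies, start=1):
        buf.write(f"MODEL {i}\n")
        buf.write(f"{RESULT_TAG}    {e!r}    0.000    0.000\n")
        buf.write("ENDMDL\n")
    text = buf.getvalue()
    if path is not None:
        path.write_text(text)
    return text


_TABLE_COLUMNS = {"compound_id", "target_id", "energy_kcal_mol"}


def parse_energy_table(
    source: str | IO[str] | Path, *, sep: str | None = None
) -> list[DockingRun]:
    """Read a long-format compound/target/configuration energy table.

    Expected columns: ``compound_id``, ``target_id``, ``energy_kcal_mol``
    and optionally ``configuration_index`` (absent: file order within
    each pair is kept). TSV or CSV; the delimiter is sniffed unless
    ``sep`` is given. Returns one :class:`DockingRun` per (compound,
    target) pair with energies ordered by configuration index.

    Raises
    ------
    ParseError
        On missing columns, non-numeric energies, or duplicate
        (compound, target, configuration) triples.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    try:
        df = pd.read_csv(source, sep=sep, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read energy table: {exc}") from exc
    missing = _TABLE_COLUMNS - set(df.columns)
    if missing:
        raise ParseError(f"energy table missing columns: {sorted(missing)}")
    energies = pd.to_numeric(df["energy_kcal_mol"], errors="coerce")
    bad = energies.isna() | ~energies.map(math.isfinite)
    if bad.any():
        row = int(bad.idxmax()) + 2  # header is row 1
        raise ParseError(f"non-numeric energy at table row {row}")
    df = df.assign(energy_kcal_mol=energies)
    if "configuration_index" not in df.columns:
        df = df.assign(configuration_index=df.groupby(
            ["compound_id", "target_id"], sort=False
        ).cumcount())
    dup = df.duplicated(["compound_id", "target_id", "configuration_index"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["compound_id", "target_id", "configuration_index"]]
        raise ParseError(
            "duplicate (compound, target, configuration): "
            f"({key.iloc[0]}, {key.iloc[1]}, {key.iloc[2]})"
        )
    runs = []
    for (cid, tid), grp in df.groupby(["compound_id", "target_id"], sort=True):
        grp = grp.sort_values("configuration_index")
        runs.append(
            DockingRun(str(cid), str(tid), tuple(grp["energy_kcal_mol"]))
        )
    return runs


def read_energy_matrix_xlsx(path: Path, *, sheet: int | str = 0) -> pd.DataFrame:
    """Read a compound x target representative-energy sheet from XLSX.

    Tolerant reader for deposited score sheets: expects a header row that
    names the target proteins, first column holding compound names. Rows
    or columns that are entirely empty are dropped.
    """
    df = pd.read_excel(path, sheet_name=sheet, index_col=0)
    df = df.dropna(axis=0, how="all").dropna(axis=1, how="all")
    df.index = df.index.astype(str)
    df.columns = [str(c).strip() for c in df.columns]
    return df.astype(float)


def representative_energy(run: DockingRun, mode: ReductionMode = "minimum") -> float:
    """Reduce a run's pose energies to one representative value.

    ``minimum`` (default) keeps the most favourable pose — the most
    stable predicted binding model; ``mean`` averages over all poses, a
    summary of the whole ensemble of candidate binding modes. Ties for
    the minimum resolve to the first occurrence (irrelevant to the scalar
    value).
    """
    if mode == "minimum":
        return min(run.configuration_energies)
    if mode == "mean":
        return sum(run.configuration_energies) / len(run.configuration_energies)
    raise ValueError(f"unknown reduction mode {mode!r}")


def build_energy_matrix(
    runs: Sequence[DockingRun],
    compounds: Sequence[str],
    targets: Sequence[str],
    mode: ReductionMode = "minimum",
) -> pd.DataFrame:
    """Assemble the dense compound x target representative-energy matrix.

    Every requested (compound, target) pair must be covered by exactly
    one run; missing pairs are a hard error listing all of them, since
    the downstream score formulas need an energy for every target. Runs
    for pairs outside the requested index are dropped with a warning.
    Input run order is irrelevant.

    Returns a DataFrame with compounds as the row index (in the requested
    order) and targets as columns, values in kcal/mol.
    """
    compounds = [str(c) for c in compounds]
    targets = [str(t) for t in targets]
    if len(set(compounds)) != len(compounds):
        raise ValueError("duplicate compound ids in requested index")
    wanted = {(c, t) for c in compounds for t in targets}
    seen: dict[tuple[str, str], float] = {}
    for run in runs:
        key = (run.compound_id, run.target_id)
        if key not in wanted:
            warnings.warn(f"dropping run for unrequested pair {key}", stacklevel=2)
            continue
        if key in seen:
            raise ValueError(f"multiple runs for pair {key}")
        seen[key] = representative_energy(run, mode)
    missing = sorted(wanted - seen.keys())
    if missing:
        raise ValueError(f"missing (compound, target) pairs: {missing}")
    data = {t: [seen[(c, t)] for c in compounds] for t in targets}
    return pd.DataFrame(data, index=pd.Index(compounds, name="compound_id"))


def write_energy_matrix(matrix: pd.DataFrame, path: Path) -> None:
    """Write the matrix as TSV, compounds as rows, 4-decimal fixed point."""
    matrix.to_csv(path, sep="\t", float_format="%.4f")


def read_energy_matrix(path: Path) -> pd.DataFrame:
    """Read a matrix written by :func:`write_energy_matrix`."""
    return pd.read_csv(path, sep="\t", index_col=0)


def classify_model_quality(summary: RamachandranSummary) -> str:
    """Classify a receptor model from its Ramachandran summary.

    A structure is a ``good`` quality model iff strictly more than 90% of
    its residues fall in the most-favoured regions of the Ramachandran
    plot; exactly 90% is ``not_good``.
    """
    return "good" if summary.pct_most_favored > 90.0 else "not_good"
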