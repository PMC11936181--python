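"""Seeded synthetic screening benchmarks and assay plates.

Generates inputs with the statistical structure the triage pipeline
assumes, so every stage — parsing, matrix assembly, scoring, filtering,
selection, assay statistics — can be exercised and calibrated without
any external data:

* a compound library docked against a five-protein panel (four targets
  plus the anti-target), with per-pose energies drawn i.i.d. Gaussian
  around a library-wide mean, and optional *planted hits* whose pair
  means are shifted down on the targets and up on the anti-target so
  that recovery through the full pipeline is a testable event;
* the matching pose-file tree in the PDBQT dialect the parser reads;
* plate assays with planted group means and Gaussian well noise.

Decoys share one marginal energy distribution across all five proteins,
so the anti-target penalty term is exercised non-trivially rather than
passed by construction. All generators take a mandatory integer seed and
are fully deterministic under it; randomness flows through a single
``numpy.random.Generator`` with no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .docking_io import DockingRun, write_pose_file
from .scoring import DEFAULT_TARGETS, ANTITARGET

__all__ = [
    "PlantedHit",
    "LibrarySpec",
    "PlateGroup",
    "PlateSpec",
    "generate_library",
    "generate_pose_files",
    "generate_assay_plates",
]


@dataclass(frozen=True)
class PlantedHit:
    """A compound whose pair-mean energies are offset from the library's.

    ``target_offset`` (kcal/mol, typically negative) shifts the mean pose
    energy on every desired target; ``antitarget_offset`` (typically
    positive, default +3) shifts it on the anti-target, keeping the hit's
    anti-target *minimum over poses* above the usual −7 kcal/mol
    selectivity bound: with pose energies N(−3, 1) the per-pose tail
    below −7 is about 3e-5, so even the minimum of 20 poses stays above
    the bound in >99.9% of screens.
    """

    compound_id: str
    target_offset: float
    antitarget_offset: float = 3.0


@dataclass(frozen=True)
class LibrarySpec:
    """Conditions for one synthetic screen.

    Defaults emulate a 51-compound x 5-protein screen: pose energies
    N(−6, 1) kcal/mol, 10 or 20 configurations per pair (docking engines
    are commonly run with one of those two pose counts). ``seed`` is
    mandatory — no implicit entropy.
    """

    seed: int
    n_compounds: int = 51
    targets: tuple[str, ...] = DEFAULT_TARGETS
    antitarget: str = ANTITARGET
    configs_choices: tuple[int, ...] = (10, 20)
    energy_mean: float = -6.0
    energy_sd: float = 1.0
    planted_hits: tuple[PlantedHit, ...] = ()

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if self.energy_sd <= 0:
            raise ValueError("energy_sd must be > 0")
        if self.antitarget not in self.targets:
            raise ValueError("anti-target must be one of the panel targets")
        ids = [h.compound_id for h in self.planted_hits]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate planted compound ids")


def _compound_ids(spec: LibrarySpec) -> list[str]:
    hit_ids = [h.compound_id for h in spec.planted_hits]
    n_decoys = spec.n_compounds - len(hit_ids)
    if n_decoys < 0:
        raise ValueError("more planted hits than compounds")
    width = len(str(spec.n_compounds))
    decoys = [f"decoy{str(i + 1).zfill(width)}" for i in range(n_decoys)]
    return hit_ids + decoys


def generate_library(
    spec: LibrarySpec,
) -> tuple[list[DockingRun], pd.DataFrame, pd.DataFrame, dict]:
    """Generate one seeded screen: runs, descriptors, annotations, truth.

    Per (compound, target) pair, pose energies are drawn i.i.d.
    N(energy_mean + offset, energy_sd), where the offset is zero for
    decoys and the planted hit's target/anti-target offset otherwise.
    Planted hits are annotated anti-inflammatory and not excluded; decoy
    annotation flags are random (30% anti-inflammatory, 5% excluded).
    Descriptors are drawn from loose drug-like ranges and only feed the
    rule-of-5 stage.

    Returns ``(runs, descriptors, annotations, ground_truth)`` where
    ground_truth records the planted hit ids in intended rank order
    (most negative total target offset first). Same seed, same spec —
    byte-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    compounds = _compound_ids(spec)
    offsets = {
        h.compound_id: {
            t: (h.antitarget_offset if t == spec.antitarget else h.target_offset)
            for t in spec.targets
        }
        for h in spec.planted_hits
    }
    runs: list[DockingRun] = []
    for cid in compounds:
        for t in spec.targets:
            n_cfg = int(rng.choice(spec.configs_choices))
            mu = spec.energy_mean + offsets.get(cid, {}).get(t, 0.0)
            energies = rng.normal(mu, spec.energy_sd, size=n_cfg)
            runs.append(DockingRun(cid, t, tuple(np.round(energies, 4))))

    n = len(compounds)
    descriptors = pd.DataFrame(
        {
            "compound_id": compounds,
            "molecular_weight": np.round(rng.uniform(150.0, 600.0, size=n), 2),
            "logp": np.round(rng.normal(2.0, 1.5, size=n), 2),
            "hbd_count": rng.poisson(2.0, size=n),
            "hba_count": rng.poisson(5.0, size=n),
        }
    )
    is_hit = np.array([cid in offsets for cid in compounds])
    anti_inf = rng.random(n) < 0.30
    excluded = rng.random(n) < 0.05
    anti_inf[is_hit] = True
    excluded[is_hit] = False
    annotations = pd.DataFrame(
        {
            "compound_id": compounds,
            "anti_inflammatory": anti_inf,
            "excluded_known_anti_oa": excluded,
        }
    )
    ranked_hits = sorted(
        spec.planted_hits, key=lambda h: (h.target_offset, h.compound_id)
    )
    ground_truth = {
        "seed": spec.seed,
        "planted_hits": [h.compound_id for h in ranked_hits],
        "offsets": {
            h.compound_id: {
                "target_offset": h.target_offset,
                "antitarget_offset": h.antitarget_offset,
            }
            for h in spec.planted_hits
        },
    }
    return runs, descriptors, annotations, ground_truth


def generate_pose_files(
    runs: Sequence[DockingRun],
    directory: Path,
    overwrite: bool = False,
) -> list[Path]:
    """Write one pose file per run into ``directory``.

    Files are named ``<compound>__<target>.pdbqt`` and round-trip
    losslessly through the pose parser. Existing files are an error
    unless ``overwrite``; serialisation is deterministic given the runs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for run in runs:
        path = directory / f"{run.compound_id}__{run.target_id}.pdbqt"
        if path.exists() and not overwrite:
            raise FileExistsError(f"refusing to overwrite {path}")
        write_pose_file(run, path)
        paths.append(path)
    return paths


@dataclass(frozen=True)
class PlateGroup:
    """One treatment (or control) group on a synthetic plate."""

    label: str
    concentration: str | float
    true_mean: float
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError(f"group {self.label!r}: need >= 2 replicates")


@dataclass(frozen=True)
class PlateSpec:
    """Conditions for one synthetic assay plate (Gaussian well noise)."""

    seed: int
    groups: tuple[PlateGroup, ...]
    noise_sd: float = 0.02
    assay_kind: str = "viability_450nm"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.groups:
            raise ValueError("plate needs at least one group")


def generate_assay_plates(spec: PlateSpec) -> tuple[pd.DataFrame, dict]:
    """Generate well-level optical densities for a plate spec.

    Each replicate OD is drawn N(group true_mean, noise_sd). Returns a
    long-format frame (group, concentration, replicate, od) plus the
    ground truth (true means per group) for recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for g in spec.groups:
        ods = rng.normal(g.true_mean, spec.noise_sd, size=g.n_replicates)
        for i, od in enumerate(ods, start=1):
            rows.append(
                {
                    "group": g.label,
                    "concentration": g.concentration,
                    "replicate": i,
                    "od": float(od),
                }
            )
    truth = {
        "seed": spec.seed,
        "assay_kind": spec.assay_kind,
        "true_means": {g.label: g.true_mean for g in spec.groups},
        "noise_sd": spec.noise_sd,
    }
    return pd.DataFrame(rows), truth
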