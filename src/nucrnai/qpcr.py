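"""Relative-quantification qPCR: ddCT fold changes and multigenerational
heritable-silencing profiles.

dCT = mean(CT target) - mean(CT reference) within a condition;
ddCT = dCT(treated) - dCT(control); fold change = 2 ** (-ddCT).
Technical replicates are aggregated by arithmetic mean of CT before
differencing.  No amplification-efficiency correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROLES = ("target", "reference")
CONDITIONS = ("treated", "control")
GENERATIONS = ("P0", "F1", "F2", "F3")

__all__ = [
    "QpcrPlate",
    "HeritableProfile",
    "ddct_fold_change",
    "assemble_profile",
    "read_plate_csv",
    "write_plate_csv",
]


@dataclass
class QpcrPlate:
    """CT triplicates for (target, reference) x (treated, control).

    ``ct`` maps (role, condition) to an array of >= 3 technical-replicate
    CT values, all finite and positive.
    """

    ct: dict[tuple[str, str], np.ndarray]
    generation: str | None = None
    genotype: str | None = None
    analyte: str = "mRNA"

    def __post_init__(self) -> None:
        for role in ROLES:
            for cond in CONDITIONS:
                if (role, cond) not in self.ct:
                    raise ValueError(f"plate missing condition ({role}, {cond})")
        self.ct = {k: np.asarray(v, dtype=np.float64) for k, v in self.ct.items()}
        for key, vals in self.ct.items():
            if vals.size < 3:
                raise ValueError(f"condition {key} has {vals.size} replicates; need >= 3")
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                raise ValueError(f"condition {key} has non-finite or non-positive CT values")


@dataclass
class HeritableProfile:
    """Per-generation fold change (treated normalized to control) for one
    genotype and analyte; generations ordered P0 -> F3, missing ones flagged
    rather than interpolated."""

    genotype: str | None
    analyte: str
    fold_changes: dict[str, float]
    missing: tuple[str, ...] = field(default_factory=tuple)

    @property
    def series(self) -> list[tuple[str, float]]:
        return [(g, self.fold_changes[g]) for g in GENERATIONS if g in self.fold_changes]


def ddct_fold_change(plate: QpcrPlate) -> float:
    """Fold change 2^(-ddCT) of the target in treated vs control."""
    dct = {
        cond: float(np.mean(plate.ct[("target", cond)]) - np.mean(plate.ct[("reference", cond)]))
        for cond in CONDITIONS
    }
    ddct = dct["treated"] - dct["control"]
    return float(2.0 ** (-ddct))


def assemble_profile(plates: Iterable[QpcrPlate]) -> HeritableProfile:
    """Order per-generation plates into a P0->F3 fold-change series."""
    plates = list(plates)
    if not plates:
        raise ValueError("no plates supplied")
    folds: dict[str, float] = {}
    for plate in plates:
        gen = plate.generation
        if gen not in GENERATIONS:
            raise ValueError(f"unknown generation {gen!r}; expected one of {GENERATIONS}")
        if gen in folds:
            raise ValueError(f"duplicate generation {gen!r}")
        folds[gen] = ddct_fold_change(plate)
    missing = tuple(g for g in GENERATIONS if g not in folds)
    return HeritableProfile(
        genotype=plates[0].genotype,
        analyte=plates[0].analyte,
        fold_changes={g: folds[g] for g in GENERATIONS if g in folds},
        missing=missing,
    )


# ------------------------------------------------------------------------ IO
def write_plate_csv(plate: QpcrPlate, path: str | Path) -> None:
    """Long format: condition, role, replicate, ct (plus metadata columns)."""
    rows = []
    for (role, cond), vals in sorted(plate.ct.items()):
        for i, ct in enumerate(vals, start=1):
            rows.append(
                {
                    "condition": cond,
                    "role": role,
                    "replicate": i,
                    "ct": ct,
                    "generation": plate.generation or "",
                    "genotype": plate.genotype or "",
                    "analyte": plate.analyte,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> QpcrPlate:
    df = pd.read_csv(path)
    required = {"condition", "role", "replicate", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: plate CSV needs columns {sorted(required)}")
    ct: dict[tuple[str, str], np.ndarray] = {}
    for (role, cond), sub in df.groupby(["role", "condition"]):
        ct[(str(role), str(cond))] = sub.sort_values("replicate")["ct"].to_numpy()
    meta = df.iloc[0]
    return QpcrPlate(
        ct=ct,
        generation=(str(meta["generation"]) or None) if "generation" in df.columns and pd.notna(meta.get("generation")) and str(meta.get("generation")) else None,
        genotype=(str(meta["genotype"]) or None) if "genotype" in df.columns and pd.notna(meta.get("genotype")) and str(meta.get("genotype")) else None,
        analyte=str(meta["analyte"]) if "analyte" in df.columns and pd.notna(meta.get("analyte")) else "mRNA",
    )


def write_profiles_tsv(profiles: Sequence[HeritableProfile], path: str | Path) -> None:
    rows = []
    for prof in profiles:
        for gen, fold in prof.series:
            rows.append(
                {
                    "genotype": prof.genotype or "",
                    "analyte": prof.analyte,
                    "generation": gen,
                    "fold_change": fold,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
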