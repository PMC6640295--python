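"""Classify genes into life-stage expression groups.

A gene is *present* in a tissue when its MAS5-style presence score reaches
the threshold (default 0.9); all other expression values are regarded as
zero.  Genes reliably present only on the pollen side are pollen-specific,
only on the sporophyte side sporophyte-specific, on both sides shared, and
nowhere not expressed.  A gene's expression level is the highest level over
the tissues where it is present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

POLLEN = "pollen"
SPOROPHYTE = "sporophyte"

CLASSES = ("pollen_specific", "sporophyte_specific", "shared", "not_expressed")

#: sporophyte cell types admitted to the single-tissue comparison group
DEFAULT_SINGLE_CELL_TYPES = ("guard_cell", "xylem", "root_hair")


@dataclass(frozen=True)
class ExpressionProfile:
    gene_id: str
    tissues: Mapping[str, tuple[float, float]]  # tissue -> (level, presence)
    life_stage_class: str
    sporophyte_tissue_count: int
    sporophyte_tissues: tuple[str, ...]
    expression_level: float


def classify_life_stage(
    gene_id: str,
    tissues: Mapping[str, tuple[float, float]],
    tissue_sides: Mapping[str, str],
    threshold: float = 0.9,
) -> ExpressionProfile:
    """Classify one gene from its per-tissue (level, presence) pairs."""
    pollen_present = []
    sporo_present = []
    level = 0.0
    for tissue, (lev, presence) in tissues.items():
        side = tissue_sides.get(tissue)
        if side not in (POLLEN, SPOROPHYTE):
            raise KeyError(f"tissue {tissue!r} has no pollen/sporophyte side")
        if presence >= threshold:
            if lev <= 0:
                raise ValueError(
                    f"{gene_id}/{tissue}: presence {presence} >= {threshold} "
                    "but expression level is zero"
                )
            level = max(level, lev)
            (pollen_present if side == POLLEN else sporo_present).append(tissue)
    if pollen_present and not sporo_present:
        cls = "pollen_specific"
    elif sporo_present and not pollen_present:
        cls = "sporophyte_specific"
    elif pollen_present and sporo_present:
        cls = "shared"
    else:
        cls = "not_expressed"
        level = 0.0
    return ExpressionProfile(
        gene_id=gene_id,
        tissues=dict(tissues),
        life_stage_class=cls,
        sporophyte_tissue_count=len(sporo_present),
        sporophyte_tissues=tuple(sorted(sporo_present)),
        expression_level=level,
    )


def merge_pollen_tube(
    expression: pd.DataFrame,
    tube_a: str,
    tube_b: str,
    merged_name: str = "pollen_tube",
) -> pd.DataFrame:
    """Combine two pollen-tube columns into one, taking the elementwise
    maximum of level and presence per gene; absent entries count as (0, 0)."""
    present = set(expression["tissue"])
    for t in (tube_a, tube_b):
        if t not in present:
            raise KeyError(f"tissue {t!r} not in expression table")
    tubes = expression[expression["tissue"].isin([tube_a, tube_b])]
    rest = expression[~expression["tissue"].isin([tube_a, tube_b])]
    merged = (
        tubes.groupby("gene_id", as_index=False)[["level", "presence"]]
        .max()
        .assign(tissue=merged_name)
    )
    out = pd.concat([rest, merged[["gene_id", "tissue", "level", "presence"]]])
    return out.sort_values(["gene_id", "tissue"], kind="stable").reset_index(drop=True)


def classify_table(
    expression: pd.DataFrame,
    tissue_sides: Mapping[str, str],
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Classify every gene of a long-form expression table.

    Returns a frame with columns gene_id, life_stage_class,
    sporophyte_tissue_count, sporophyte_tissues (comma-joined),
    expression_level.  Gene x tissue pairs absent from the table are
    treated as (0, 0), so they never count as present.
    """
    rows = []
    for gene_id, sub in expression.groupby("gene_id", sort=True):
        tissues = {
            t: (float(l), float(p))
            for t, l, p in zip(sub["tissue"], sub["level"], sub["presence"])
        }
        prof = classify_life_stage(str(gene_id), tissues, tissue_sides, threshold)
        rows.append(
            (
                prof.gene_id,
                prof.life_stage_class,
                prof.sporophyte_tissue_count,
                ",".join(prof.sporophyte_tissues),
                prof.expression_level,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "life_stage_class",
            "sporophyte_tissue_count",
            "sporophyte_tissues",
            "expression_level",
        ],
    )


def select_comparison_groups(
    profiles: pd.DataFrame,
    grouping: str,
    single_cell_types: Iterable[str] = DEFAULT_SINGLE_CELL_TYPES,
    broad_min_tissues: int = 5,
) -> dict[str, set[str]]:
    """Gene-id sets for a two-group comparison.

    pollen_vs_sporophyte: all pollen-specific vs all sporophyte-specific.
    pollen_vs_single_tissue: pollen-specific vs sporophyte genes present in
    exactly one sporophytic tissue drawn from ``single_cell_types``.
    pollen_vs_broad: pollen-specific vs sporophyte genes present in at
    least ``broad_min_tissues`` sporophytic tissues.
    """
    pollen = set(profiles.loc[profiles["life_stage_class"] == "pollen_specific", "gene_id"])
    sporo = profiles[profiles["life_stage_class"] == "sporophyte_specific"]
    if grouping == "pollen_vs_sporophyte":
        other = set(sporo["gene_id"])
    elif grouping == "pollen_vs_single_tissue":
        cell_types = set(single_cell_types)
        mask = (sporo["sporophyte_tissue_count"] == 1) & sporo[
            "sporophyte_tissues"
        ].isin(cell_types)
        other = set(sporo.loc[mask, "gene_id"])
    elif grouping == "pollen_vs_broad":
        other = set(sporo.loc[sporo["sporophyte_tissue_count"] >= broad_min_tissues, "gene_id"])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return {"pollen": pollen, "other": other}


def chromosome_distribution_test(
    group_counts: Mapping[str, int],
    all_counts: Mapping[str, int],
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of a gene group's chromosome distribution
    against the all-genes distribution.

    Expected count per chromosome is the group total apportioned by the
    all-genes proportions; df = number of chromosomes - 1.
    """
    chroms = sorted(all_counts)
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes")
    obs = np.array([group_counts.get(c, 0) for c in chroms], dtype=float)
    allv = np.array([all_counts[c] for c in chroms], dtype=float)
    if obs.sum() <= 0:
        raise ValueError("empty gene group")
    expected = obs.sum() * allv / allv.sum()
    zero = [c for c, e in zip(chroms, expected) if e == 0]
    if zero:
        raise ValueError(f"expected count zero on chromosome(s) {zero}")
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return float(chi2), len(chroms) - 1, float(p)
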