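"""Membership-module partition and Jaccard set similarity.

Every target in the union of the three universes (two formulas, one
approved-drug set) is assigned to exactly one of seven membership modules
determined by its flag triple. The module counts drive the contingency
table of the validation battery, and pairwise Jaccard indices quantify how
similar two datasets are at the ingredient and target level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MODULE_LABELS, SourceDataset, module_label

CONTINGENCY_ROWS = ("gxbd_specific", "xzd_specific", "overlapping")
CONTINGENCY_COLS = ("not_drug_target", "drug_target")


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|, with J(∅, ∅) defined as 0."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


@dataclass
class ModulePartition:
    """Assignment of every target symbol to one membership module."""

    assignment: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {label: 0 for label in MODULE_LABELS}
        for label in self.assignment.values():
            out[label] += 1
        return out

    def members(self, label: str) -> set[str]:
        return {s for s, l in self.assignment.items() if l == label}

    @property
    def formula_targets(self) -> set[str]:
        return {s for s, l in self.assignment.items() if l != "drug_only"}

    def is_drug_target(self, symbol: str) -> bool:
        return self.assignment[symbol] in (
            "common_drug", "xzd_only_drug", "gxbd_only_drug", "drug_only",
        )


@dataclass
class ContingencyTable:
    """Modules x drug-target status observed counts (formula targets only)."""

    observed: np.ndarray
    row_labels: tuple[str, ...] = CONTINGENCY_ROWS
    col_labels: tuple[str, ...] = CONTINGENCY_COLS

    @property
    def row_totals(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.observed.sum())


def partition_targets(
    xzd_targets: set[str], gxbd_targets: set[str], drug_targets: set[str]
) -> ModulePartition:
    """Label every symbol in the union by its membership combination."""
    assignment = {}
    for sym in xzd_targets | gxbd_targets | drug_targets:
        assignment[sym] = module_label(
            sym in xzd_targets, sym in gxbd_targets, sym in drug_targets
        )
    return ModulePartition(assignment=assignment)


def module_contingency(partition: ModulePartition) -> ContingencyTable:
    """3x2 table of formula-membership class vs drug-target status.

    Rows: second-formula-specific, first-formula-specific, overlapping;
    columns: not drug-targeted / drug-targeted. Drug-only targets are
    excluded — they have no formula membership.
    """
    c = partition.counts
    observed = np.array(
        [
            [c["gxbd_only_nodrug"], c["gxbd_only_drug"]],
            [c["xzd_only_nodrug"], c["xzd_only_drug"]],
            [c["common_nodrug"], c["common_drug"]],
        ],
        dtype=int,
    )
    return ContingencyTable(observed=observed)


def similarity_report(
    xzd: SourceDataset, gxbd: SourceDataset, drugs: SourceDataset
) -> pd.DataFrame:
    """Pairwise formula similarity table.

    One row per comparison level: raw source ids, canonical compounds (only
    when both formulas share a compound namespace, else ``n/a``), all
    targets, drug-targeted target subsets, non-drug-targeted subsets; plus
    the drug-targeted fraction within each formula-membership class.
    """
    drug_u = drugs.target_universe
    xzd_u, gxbd_u = xzd.target_universe, gxbd.target_universe

    rows = []

    def add(level, a, b, value=None):
        rows.append(
            {
                "level": level,
                "n_xzd": len(a) if a is not None else np.nan,
                "n_gxbd": len(b) if b is not None else np.nan,
                "n_intersection": len(a & b) if a is not None else np.nan,
                "jaccard": jaccard(a, b) if value is None else value,
            }
        )

    add("source_ids", set(xzd.links), set(gxbd.links))
    shared_ns = (
        xzd.compound_namespace is not None
        and xzd.compound_namespace == gxbd.compound_namespace
    )
    if shared_ns:
        add("compounds", set(xzd.links), set(gxbd.links))
    else:
        rows.append(
            {"level": "compounds", "n_xzd": np.nan, "n_gxbd": np.nan,
             "n_intersection": np.nan, "jaccard": np.nan}
        )
    add("targets", xzd_u, gxbd_u)
    add("targets_drug", xzd_u & drug_u, gxbd_u & drug_u)
    add("targets_nodrug", xzd_u - drug_u, gxbd_u - drug_u)
    df = pd.DataFrame(rows)

    part = partition_targets(xzd_u, gxbd_u, drug_u)
    c = part.counts
    fractions = []
    for cls, drug_n, total in (
        ("xzd_specific", c["xzd_only_drug"], c["xzd_only_drug"] + c["xzd_only_nodrug"]),
        ("gxbd_specific", c["gxbd_only_drug"], c["gxbd_only_drug"] + c["gxbd_only_nodrug"]),
        ("overlapping", c["common_drug"], c["common_drug"] + c["common_nodrug"]),
    ):
        fractions.append(
            {"class": cls, "drug_targeted": drug_n, "class_size": total,
             "fraction": drug_n / total if total else np.nan}
        )
    df.attrs["drug_target_fractions"] = pd.DataFrame(fractions)
    return df
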