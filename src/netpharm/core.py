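"""Domain types and gene-symbol normalization.

Every entity in the pipeline is keyed by a *target symbol* (an HGNC-style
gene symbol) or a *source id* (an ingredient or drug identifier). Symbols
are normalized once, at the input boundary, so that all downstream set
arithmetic is case- and whitespace-insensitive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


class SymbolError(ValueError):
    """Raised when a raw symbol normalizes to the empty string."""


def normalize_symbol(raw: str) -> str:
    """Normalize a raw gene-symbol string.

    Uppercases, strips surrounding whitespace and removes internal
    whitespace. Normalization is idempotent. Raises :class:`SymbolError`
    if nothing is left.
    """
    if raw is None:
        raise SymbolError("symbol is missing")
    out = _WS.sub("", str(raw)).upper()
    if not out:
        raise SymbolError(f"symbol {raw!r} is empty after normalization")
    return out


@dataclass
class SourceDataset:
    """A named set of source entities (ingredients or drugs) and their targets.

    Parameters
    ----------
    name : str
        Dataset label, e.g. ``"XZD"`` or ``"DRUGS"``.
    role : str
        Either ``"formula"`` or ``"drug_set"``.
    links : dict
        Mapping ``source_id -> set of normalized target symbols``. Every
        source must have a non-empty target set.
    labels : dict
        Mapping ``source_id -> display label``.
    compound_namespace : str or None
        Identifier of the compound namespace the source ids live in, when
        ids are canonical across datasets (enables ingredient-level
        similarity); ``None`` for opaque per-dataset ids.
    """

    name: str
    role: str
    links: dict[str, set[str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    compound_namespace: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("formula", "drug_set"):
            raise ValueError(f"unknown role {self.role!r}")
        for sid, targets in self.links.items():
            if not sid:
                raise ValueError("empty source_id")
            if not targets:
                raise ValueError(f"source {sid!r} has an empty target set")

    @property
    def n_sources(self) -> int:
        return len(self.links)

    @property
    def target_universe(self) -> set[str]:
        out: set[str] = set()
        for targets in self.links.values():
            out |= targets
        return out

    @property
    def n_targets(self) -> int:
        return len(self.target_universe)


MODULE_LABELS = (
    "common_nodrug",
    "common_drug",
    "xzd_only_nodrug",
    "xzd_only_drug",
    "gxbd_only_nodrug",
    "gxbd_only_drug",
    "drug_only",
)


def module_label(in_xzd: bool, in_gxbd: bool, in_drug: bool) -> str:
    """Map a membership-flag triple to its module label.

    The seven labels correspond to the non-empty regions of the three-set
    membership diagram over {first formula, second formula, drug set}.
    """
    if in_xzd and in_gxbd:
        return "common_drug" if in_drug else "common_nodrug"
    if in_xzd:
        return "xzd_only_drug" if in_drug else "xzd_only_nodrug"
    if in_gxbd:
        return "gxbd_only_drug" if in_drug else "gxbd_only_nodrug"
    if in_drug:
        return "drug_only"
    raise ValueError("target belongs to no dataset")
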