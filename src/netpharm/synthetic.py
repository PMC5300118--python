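"""Synthetic bipartite interaction data with exact membership-module counts.

The generator emulates the structure of curated drug-target tables: three
overlapping target universes (two formula target sets and one approved-drug
target set) with many-to-many source-to-target links. Module cardinalities
— the sizes of the seven regions of the three-set membership diagram — are
specified exactly and recovered exactly by the partition stage, which makes
the whole pipeline testable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MODULE_LABELS, SourceDataset

DATASETS = ("XZD", "GXBD", "DRUGS")

# which membership-diagram regions feed each dataset's target universe
_REGIONS = {
    "XZD": ("common_nodrug", "common_drug", "xzd_only_nodrug", "xzd_only_drug"),
    "GXBD": ("common_nodrug", "common_drug", "gxbd_only_nodrug", "gxbd_only_drug"),
    "DRUGS": ("common_drug", "xzd_only_drug", "gxbd_only_drug", "drug_only"),
}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic three-dataset scenario.

    ``module_sizes`` gives the exact cardinality of each of the seven
    membership combinations; ``n_sources`` the number of source entities
    per dataset; ``out_degree_range`` the inclusive (kmin, kmax) range each
    source's out-degree is drawn from.
    """

    module_sizes: dict[str, int]
    n_sources: dict[str, int]
    out_degree_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {d: (1, 10) for d in DATASETS}
    )
    seed: int = 0

    def target_set_size(self, dataset: str) -> int:
        return sum(self.module_sizes[r] for r in _REGIONS[dataset])

    def validate(self) -> None:
        for label in MODULE_LABELS:
            if self.module_sizes.get(label, 0) < 0:
                raise ValueError(f"negative module size for {label!r}")
        unknown = set(self.module_sizes) - set(MODULE_LABELS)
        if unknown:
            raise ValueError(f"unknown module labels {sorted(unknown)}")
        for d in DATASETS:
            size = self.target_set_size(d)
            n = self.n_sources.get(d, 0)
            kmin, kmax = self.out_degree_range.get(d, (1, 1))
            if size == 0:
                continue
            if n <= 0:
                raise ValueError(f"{d}: targets configured but no sources")
            if kmin < 1 or kmax < kmin:
                raise ValueError(f"{d}: invalid out-degree range ({kmin}, {kmax})")
            if kmax > size:
                raise ValueError(f"{d}: kmax {kmax} exceeds target-set size {size}")
            if n * kmax < size:
                raise ValueError(
                    f"{d}: infeasible — {n} sources with kmax {kmax} "
                    f"cannot cover {size} targets"
                )


def study_config(seed: int = 0) -> SyntheticConfig:
    """The study-sized configuration.

    Two formulas with 214 and 178 targets overlapping in 164 symbols, a
    240-symbol approved-drug target set intersecting them in 50 + 12
    symbols, 787 and 179 formula ingredients, and 60 drug entities (the
    number of drugs is a free parameter of the scenario). Formula
    out-degrees span 1-40 targets, drug out-degrees 1-10.
    """
    return SyntheticConfig(
        module_sizes={
            "common_nodrug": 114,
            "common_drug": 50,
            "xzd_only_nodrug": 38,
            "xzd_only_drug": 12,
            "gxbd_only_nodrug": 14,
            "gxbd_only_drug": 0,
            "drug_only": 178,
        },
        n_sources={"XZD": 787, "GXBD": 179, "DRUGS": 60},
        out_degree_range={"XZD": (1, 40), "GXBD": (1, 40), "DRUGS": (1, 10)},
        seed=seed,
    )


_PREFIX = {"XZD": "X", "GXBD": "G", "DRUGS": "D"}


def generate(
    config: SyntheticConfig,
) -> tuple[SourceDataset, SourceDataset, SourceDataset]:
    """Generate the three datasets for ``config``, reproducibly from its seed.

    Symbols ``T0001``... are assigned to membership regions with exactly
    the configured cardinalities. Each source draws an out-degree uniformly
    from its dataset's range and samples that many targets uniformly
    without replacement from the dataset's allowed target set; any allowed
    target left untouched is then attached to a uniformly chosen source
    (coverage repair), so each realized target universe equals its
    configured set exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    total = sum(config.module_sizes.get(label, 0) for label in MODULE_LABELS)
    symbols = [f"T{i + 1:04d}" for i in range(total)]
    regions: dict[str, list[str]] = {}
    pos = 0
    for label in MODULE_LABELS:
        k = config.module_sizes.get(label, 0)
        regions[label] = symbols[pos:pos + k]
        pos += k

    datasets = []
    for name in DATASETS:
        allowed = [s for r in _REGIONS[name] for s in regions[r]]
        role = "drug_set" if name == "DRUGS" else "formula"
        if not allowed:
            datasets.append(SourceDataset(name=name, role=role))
            continue
        n = config.n_sources[name]
        kmin, kmax = config.out_degree_range[name]
        source_ids = [f"{_PREFIX[name]}{i + 1:04d}" for i in range(n)]
        links: dict[str, set[str]] = {}
        allowed_arr = np.array(allowed)
        for sid in source_ids:
            k = int(rng.integers(kmin, kmax + 1))
            picked = rng.choice(allowed_arr, size=k, replace=False)
            links[sid] = set(picked.tolist())
        covered = set().union(*links.values())
        orphans = [s for s in allowed if s not in covered]
        for sym in orphans:
            sid = source_ids[int(rng.integers(0, n))]
            links[sid].add(sym)
        labels = {sid: f"{name.lower()}-{sid}" for sid in source_ids}
        datasets.append(
            SourceDataset(name=name, role=role, links=links, labels=labels)
        )
    return tuple(datasets)
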