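"""End-to-end orchestration: simulate/load → build → partition → centrality → stats → report.

A pipeline run is configured by a :class:`PipelineConfig` (file datasets or
a synthetic scenario, never both), writes a bundle of tabular outputs plus
a checksummed manifest into one directory, and is byte-identical across
repeated runs at a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as npio
from .centrality import centrality_table, rank_targets
from .network import build_bipartite, integrate_master, network_summary, project_targets
from .partition import module_contingency, partition_targets, similarity_report
from .stats import validation_battery
from .synthetic import SyntheticConfig, generate, study_config

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the exit log."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``datasets`` (list of ``{name, role, path}`` entries)
    and ``synthetic`` (a :class:`SyntheticConfig`, or the string
    ``"study-sized"`` in config files) is active.
    """

    out_dir: Path
    datasets: list[dict] | None = None
    synthetic: SyntheticConfig | None = None
    top_k: int = 10
    t_variant: str = "pooled"
    include_drug_layer: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if (self.datasets is None) == (self.synthetic is None):
            raise ValueError("exactly one of datasets / synthetic must be given")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError(f"unknown t-test variant {self.t_variant!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {"out", "datasets", "synthetic", "top_k", "t_variant",
                 "include_drug_layer", "seed", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        synth = raw.get("synthetic")
        if synth == "study-sized":
            synth = study_config(seed=int(raw.get("seed", 0)))
        elif isinstance(synth, dict):
            synth = SyntheticConfig(
                module_sizes=dict(synth["module_sizes"]),
                n_sources=dict(synth["n_sources"]),
                out_degree_range={
                    k: tuple(v) for k, v in synth.get(
                        "out_degree_range", {"XZD": (1, 10), "GXBD": (1, 10), "DRUGS": (1, 10)}
                    ).items()
                },
                seed=int(raw.get("seed", synth.get("seed", 0))),
            )
        return cls(
            out_dir=Path(raw.get("out", "netpharm_out")),
            datasets=raw.get("datasets"),
            synthetic=synth,
            top_k=int(raw.get("top_k", 10)),
            t_variant=raw.get("t_variant", "pooled"),
            include_drug_layer=bool(raw.get("include_drug_layer", False)),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _load_datasets(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        return generate(cfg.synthetic)
    out = {}
    for entry in cfg.datasets:
        ds = npio.read_interaction_table(entry["path"], entry["name"], entry["role"])
        out[entry["name"]] = ds
    missing = {"XZD", "GXBD", "DRUGS"} - set(out)
    if missing:
        raise ValueError(f"missing dataset entries: {sorted(missing)}")
    return out["XZD"], out["GXBD"], out["DRUGS"]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and write the bundle; returns the bundle directory."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("load")
        xzd, gxbd, drugs = _load_datasets(cfg)
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    try:
        if cfg.synthetic is not None:
            stage("write-datasets")
            for ds, fname in ((xzd, "xzd.tsv"), (gxbd, "gxbd.tsv"), (drugs, "drugs.tsv")):
                npio.write_interaction_table(ds, out / fname)
                files.append(out / fname)
    except Exception as exc:
        raise PipelineError("write-datasets", exc) from exc

    try:
        stage("build")
        bgs = {ds.name: build_bipartite(ds) for ds in (xzd, gxbd, drugs)}
        tps = {name: project_targets(bg) for name, bg in bgs.items()}
        universes = (xzd.target_universe, gxbd.target_universe, drugs.target_universe)
        master = integrate_master(tps["XZD"], tps["GXBD"], tps["DRUGS"], universes)
        npio.write_graphml(master, out / "master.graphml")
        files.append(out / "master.graphml")
        npio.write_edge_table(master, out / "master_edges.tsv")
        files.append(out / "master_edges.tsv")
        for name, tp in tps.items():
            p = out / f"tp_{name.lower()}_edges.tsv"
            npio.write_edge_table(tp, p)
            files.append(p)
        summaries = {name: network_summary(tp) for name, tp in tps.items()}
        summaries["master"] = network_summary(master)
        (out / "network_summary.json").write_text(
            json.dumps(_jsonable(summaries), indent=2, sort_keys=True) + "\n"
        )
        files.append(out / "network_summary.json")
    except Exception as exc:
        raise PipelineError("build", exc) from exc

    try:
        stage("partition")
        part = partition_targets(*universes)
        rows = [
            {
                "symbol": s,
                "in_xzd": int(s in universes[0]),
                "in_gxbd": int(s in universes[1]),
                "in_drug": int(s in universes[2]),
                "module": part.assignment[s],
            }
            for s in sorted(part.assignment)
        ]
        pd.DataFrame(rows).to_csv(out / "partition.csv", index=False)
        files.append(out / "partition.csv")
        sim = similarity_report(xzd, gxbd, drugs)
        sim.to_csv(out / "similarity.csv", index=False, float_format="%.6f")
        files.append(out / "similarity.csv")
        sim.attrs["drug_target_fractions"].to_csv(
            out / "drug_target_fractions.csv", index=False, float_format="%.6f"
        )
        files.append(out / "drug_target_fractions.csv")
    except Exception as exc:
        raise PipelineError("partition", exc) from exc

    try:
        stage("centrality")
        g_formula = master.formula_graph(include_drug_layer=cfg.include_drug_layer)
        cent = centrality_table(g_formula)
        # auxiliary: how many formula ingredients act on each target
        n_ing = {s: 0 for s in cent.index}
        for bg in (bgs["XZD"], bgs["GXBD"]):
            for src, tgt in bg.edges:
                if tgt in n_ing:
                    n_ing[tgt] += 1
        cent_out = cent.copy()
        cent_out["n_ingredients"] = [n_ing[s] for s in cent.index]
        cent_out["module"] = [part.assignment[s] for s in cent.index]
        cent_out.to_csv(out / "centrality.csv", float_format="%.6f")
        files.append(out / "centrality.csv")

        ranked = rank_targets(cent, k=cfg.top_k)
        rows = []
        for i in range(cfg.top_k):
            rows.append(
                {
                    "rank": i + 1,
                    "by_degree": ranked.by_degree[i] if i < len(ranked.by_degree) else "",
                    "by_betweenness": ranked.by_betweenness[i] if i < len(ranked.by_betweenness) else "",
                    "by_closeness": ranked.by_closeness[i] if i < len(ranked.by_closeness) else "",
                    "consensus": ranked.consensus[i] if i < len(ranked.consensus) else "",
                }
            )
        pd.DataFrame(rows).to_csv(out / "ranked_targets.csv", index=False)
        files.append(out / "ranked_targets.csv")
    except Exception as exc:
        raise PipelineError("centrality", exc) from exc

    try:
        stage("stats")
        report = validation_battery(part, cent, t_variant=cfg.t_variant)
        payload = {
            key: _jsonable(
                {
                    "statistic": res.statistic,
                    "df": list(res.df),
                    "p_value": res.p_value,
                    "auxiliaries": res.auxiliaries,
                    "error": res.error,
                }
            )
            for key, res in report.items()
        }
        (out / "validation.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        files.append(out / "validation.json")
    except Exception as exc:
        raise PipelineError("stats", exc) from exc

    try:
        stage("manifest")
        cfg_dict = asdict(cfg)
        cfg_dict["out_dir"] = str(cfg.out_dir)
        manifest = {
            "config": _jsonable(cfg_dict),
            "seed": cfg.seed,
            "checksums": {p.name: _sha256(p) for p in sorted(files)},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        raise PipelineError("manifest", exc) from exc

    stage("done")
    return out


BUNDLE_FILES = (
    "network_summary.json", "partition.csv", "similarity.csv",
    "drug_target_fractions.csv", "centrality.csv", "ranked_targets.csv",
    "validation.json",
)


def report(bundle_dir: str | Path) -> str:
    """One-page text summary of a bundle; missing files are listed as absent."""
    bundle = Path(bundle_dir)
    lines = [f"netpharm report — bundle {bundle}", "=" * 60]
    absent = [f for f in BUNDLE_FILES if not (bundle / f).exists()]

    if (bundle / "network_summary.json").exists():
        summ = json.loads((bundle / "network_summary.json").read_text())
        lines.append("Networks:")
        for name in sorted(summ):
            s = summ[name]
            lines.append(
                f"  {name}: {s['n_vertices']} vertices, {s['n_edges']} edges,"
                f" {s['n_isolated']} isolated"
            )
    if (bundle / "partition.csv").exists():
        part = pd.read_csv(bundle / "partition.csv")
        counts = part["module"].value_counts().sort_index()
        lines.append("Module counts:")
        for label, n in counts.items():
            lines.append(f"  {label}: {n}")
        lines.append(f"  total: {len(part)}")
    if (bundle / "similarity.csv").exists():
        sim = pd.read_csv(bundle / "similarity.csv")
        lines.append("Similarity (Jaccard):")
        for _, row in sim.iterrows():
            ji = "n/a" if pd.isna(row["jaccard"]) else f"{row['jaccard']:.4f}"
            lines.append(f"  {row['level']}: {ji}")
    if (bundle / "validation.json").exists():
        val = json.loads((bundle / "validation.json").read_text())
        lines.append("Validation battery:")
        chi = val.get("chi_square_modules", {})
        if chi.get("error") is None and chi.get("statistic") is not None:
            aux = chi["auxiliaries"]
            lines.append(
                f"  chi-square: {chi['statistic']:.3f}, df={int(chi['df'][0])},"
                f" p={chi['p_value']:.3f}; min expected {aux['min_expected']:.1f};"
                f" {aux['n_cells_expected_lt_5']} cell(s)"
                f" ({aux['pct_cells_expected_lt_5']:.1f}%) with expected < 5"
            )
        for key in sorted(val):
            if key == "chi_square_modules":
                continue
            res = val[key]
            if res.get("error"):
                lines.append(f"  {key}: ERROR — {res['error']}")
            else:
                lines.append(
                    f"  {key}: stat={res['statistic']:.3f}, p={res['p_value']:.3f}"
                )
    if (bundle / "ranked_targets.csv").exists():
        ranked = pd.read_csv(bundle / "ranked_targets.csv")
        lines.append("Top targets (consensus):")
        lines.append("  " + ", ".join(str(s) for s in ranked["consensus"].dropna()))
    if absent:
        lines.append("Absent bundle files: " + ", ".join(absent))
    return "\n".join(lines) + "\n"
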