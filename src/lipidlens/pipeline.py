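"""End-to-end orchestration: annotate -> DE/PCA -> select -> ROC -> network.

A single root seed derives per-stage seeds by fixed offsets, so one number
reproduces every stage. All tabular outputs are TSV with a comment header
recording the stage, package version and parameters; a JSON manifest
records input hashes, seeds, parameter values and the files each stage
produced. Two runs with equal configs produce byte-identical tabular
outputs. On a stage failure the stage's partially written files keep a
``.partial`` suffix and the error names the stage and cause.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import AbundanceTable
from .diffabund import LEVELS, de_by_level, hier_cluster, pca, preprocess
from .network import (
    GeneLipidTable,
    build_graph,
    filter_generic_nodes,
    layout_coordinates,
    map_lipids_to_genes,
    node_table,
)
from .nomenclature import BiophysRuleTable, annotate_table, parse_lipid_name
from .rocscreen import evaluate_feature
from .stability import ferns_importance_backend, stability_protocol

__all__ = [
    "PipelineConfig",
    "InputValidationError",
    "StageError",
    "validate_inputs",
    "run_all",
]

logger = logging.getLogger("lipidlens")

# fixed per-stage seed offsets from the root seed
_SEED_OFFSETS = {"stability": 1, "roc": 2, "network": 3}


class InputValidationError(ValueError):
    """Raised with the full list of input problems, one message per issue."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    abundance_path: str
    metadata_path: str
    out_dir: str
    alpha: float = 0.05
    fc_threshold: float = 1.0
    levels: tuple[str, ...] = ("species", "class", "total_fa")
    r1: int = 100
    r2: int = 100
    subsample_fraction: float = 0.70
    n_ferns: int = 1000
    fern_depth: int = 3
    max_iter: int = 100
    p_threshold: float = 0.01
    auc_min: float = 0.80
    sens_min: float = 0.70
    spec_min: float = 0.80
    network_table_path: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        problems = []
        if not 0 < self.alpha < 1:
            problems.append(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fc_threshold < 1:
            problems.append(f"fc_threshold must be >= 1, got {self.fc_threshold}")
        if not 0 < self.subsample_fraction < 1:
            problems.append(
                f"subsample_fraction must be in (0, 1), got {self.subsample_fraction}"
            )
        if self.r1 < 1 or self.r2 < 1:
            problems.append("r1 and r2 must be positive")
        if not 0 < self.p_threshold < 1:
            problems.append(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        for gate in ("auc_min", "sens_min", "spec_min"):
            if not 0 <= getattr(self, gate) <= 1:
                problems.append(f"{gate} must be in [0, 1]")
        unknown = [lv for lv in self.levels if lv not in LEVELS]
        if unknown:
            problems.append(f"unknown DE levels: {unknown}")
        for path_attr in ("abundance_path", "metadata_path"):
            if not Path(getattr(self, path_attr)).exists():
                problems.append(f"{path_attr} does not exist: {getattr(self, path_attr)}")
        if self.network_table_path and not Path(self.network_table_path).exists():
            problems.append(f"network_table_path does not exist: {self.network_table_path}")
        if problems:
            raise InputValidationError(problems)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "levels" in data:
            data["levels"] = tuple(data["levels"])
        return cls(**data)


def validate_inputs(abundance_path: str | Path, metadata_path: str | Path) -> AbundanceTable:
    """Read and validate the abundance/metadata pair.

    Checks unique sample ids, metadata coverage, binary group labels,
    parseability of every lipid column name (all failures listed, not just
    the first) and non-negativity. Shorthand dialects (Unicode minus,
    numeric oxygen suffix) are accepted with a logged warning.
    """
    problems: list[str] = []
    abundance = pd.read_csv(abundance_path)
    metadata = pd.read_csv(metadata_path)
    if "sample_id" not in abundance.columns:
        raise InputValidationError(["abundance table lacks a sample_id column"])
    if "sample_id" not in metadata.columns or "group" not in metadata.columns:
        raise InputValidationError(["metadata needs sample_id and group columns"])

    dup = abundance["sample_id"][abundance["sample_id"].duplicated()].tolist()
    if dup:
        problems.append(f"duplicated sample ids: {sorted(set(dup))}")
    meta = metadata.set_index("sample_id")["group"]
    missing = [s for s in abundance["sample_id"] if s not in meta.index]
    if missing:
        problems.append(f"samples missing from metadata: {missing}")
    groups = set(meta.unique())
    if not groups <= {"case", "control"} or len(groups) != 2:
        problems.append(
            f"group labels must be exactly {{'case', 'control'}}, got {sorted(groups)}"
        )
    species = [c for c in abundance.columns if c != "sample_id"]
    for name in species:
        try:
            s = parse_lipid_name(name)
        except Exception as exc:
            problems.append(f"unparseable lipid column {name!r}: {exc}")
            continue
        if s.canonical_name != name:
            logger.warning(
                "lipid name %r accepted as dialect of %r", name, s.canonical_name
            )
    values = abundance[species].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        problems.append(f"non-numeric values in columns: {bad}")
    else:
        neg = values.lt(0)
        if neg.any().any():
            for col in values.columns[neg.any()]:
                rows = abundance.loc[neg[col], "sample_id"].tolist()
                problems.append(f"negative values in {col!r} for samples {rows}")
    if problems:
        raise InputValidationError(problems)
    frame = abundance.set_index("sample_id")[species].astype(float)
    return AbundanceTable(abundance=frame, groups=meta.reindex(frame.index))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class _StageWriter:
    """Writes a stage's TSVs to .partial names, promoted on stage success."""

    def __init__(self, out_dir: Path, stage: str, params: dict):
        self.out_dir = out_dir
        self.stage = stage
        self.params = params
        self.pending: list[tuple[Path, Path]] = []

    def write(self, frame: pd.DataFrame, filename: str, index: bool = False) -> Path:
        final = self.out_dir / filename
        partial = self.out_dir / (filename + ".partial")
        header = (
            f"# stage: {self.stage}\n# lipidlens version: {__version__}\n"
            f"# params: {json.dumps(self.params, sort_keys=True)}\n"
        )
        with open(partial, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=index, lineterminator="\n")
        self.pending.append((partial, final))
        return final

    def promote(self) -> list[str]:
        names = []
        for partial, final in self.pending:
            os.replace(partial, final)
            names.append(final.name)
        return names


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    table = validate_inputs(config.abundance_path, config.metadata_path)
    manifest: dict = {
        "lipidlens_version": __version__,
        "inputs": {
            "abundance": {"path": str(config.abundance_path), "sha256": _sha256(config.abundance_path)},
            "metadata": {"path": str(config.metadata_path), "sha256": _sha256(config.metadata_path)},
        },
        "parameters": asdict(config),
        "seeds": {
            "root": config.seed,
            **{k: config.seed + v for k, v in _SEED_OFFSETS.items()},
        },
        "stages": [],
    }

    state: dict = {}

    def stage(name: str, fn) -> None:
        writer = _StageWriter(out_dir, name, {"seed": config.seed})
        try:
            fn(writer)
        except Exception as exc:  # noqa: BLE001 - report stage and cause
            raise StageError(name, exc) from exc
        manifest["stages"].append({"name": name, "outputs": writer.promote()})
        logger.info("stage %s complete", name)

    def s_annotate(w: _StageWriter) -> None:
        annot = annotate_table(table.species, BiophysRuleTable.default())
        state["annot"] = annot
        w.write(annot, "annotation.tsv")

    def s_de(w: _StageWriter) -> None:
        transformed, deltas = preprocess(table)
        state["transformed"] = transformed
        de_frames = {}
        for level in config.levels:
            frame = de_by_level(
                table, state["annot"], level, alpha=config.alpha,
                fc_threshold=config.fc_threshold,
            )
            de_frames[level] = frame
            w.write(frame, f"de_{level}.tsv")
        state["de"] = de_frames
        if "species" in de_frames:
            volcano = de_frames["species"][["feature_id", "log2fc", "adj_p", "significant"]].copy()
            import numpy as np

            volcano["neg_log10_adj_p"] = -np.log10(volcano["adj_p"].clip(lower=1e-300))
            w.write(volcano, "volcano.tsv")

    def s_pca(w: _StageWriter) -> None:
        result = pca(state["transformed"])
        w.write(result.scores.rename_axis("sample_id"), "pca_scores.tsv", index=True)
        w.write(result.loadings.rename_axis("species"), "pca_loadings.tsv", index=True)
        explained = pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(result.explained_fraction))],
                "explained_fraction": result.explained_fraction,
            }
        )
        w.write(explained, "pca_explained.tsv")
        clust = hier_cluster(state["transformed"])
        orders = pd.DataFrame(
            {
                "axis": ["sample"] * len(clust.sample_order) + ["feature"] * len(clust.feature_order),
                "position": list(range(len(clust.sample_order))) + list(range(len(clust.feature_order))),
                "label": clust.sample_order + clust.feature_order,
            }
        )
        w.write(orders, "cluster_orders.tsv")

    def s_stability(w: _StageWriter) -> None:
        result = stability_protocol(
            state["transformed"],
            table.groups.values,
            R1=config.r1,
            R2=config.r2,
            subsample_fraction=config.subsample_fraction,
            base_seed=config.seed + _SEED_OFFSETS["stability"],
            backend=ferns_importance_backend(config.n_ferns, config.fern_depth),
            max_iter=config.max_iter,
            p_threshold=config.p_threshold,
        )
        state["stability"] = result
        w.write(result.table.rename_axis("feature"), "stability.tsv", index=True)

    def s_roc(w: _StageWriter) -> None:
        features = state["stability"].stable_features()
        reports = []
        for i, f in enumerate(features):
            report = evaluate_feature(
                f,
                table.group_values(f, "case"),
                table.group_values(f, "control"),
                seed=config.seed + _SEED_OFFSETS["roc"] + i,
            )
            reports.append(
                {
                    "feature": f,
                    "auc": report.auc,
                    "ci_low": report.ci_low,
                    "ci_high": report.ci_high,
                    "threshold": report.threshold,
                    "sensitivity": report.sensitivity,
                    "specificity": report.specificity,
                    "direction": report.direction,
                    "passes_gates": report.passes_gates(
                        config.auc_min, config.sens_min, config.spec_min
                    ),
                }
            )
        columns = [
            "feature", "auc", "ci_low", "ci_high", "threshold",
            "sensitivity", "specificity", "direction", "passes_gates",
        ]
        w.write(pd.DataFrame(reports, columns=columns), "roc.tsv")

    def s_network(w: _StageWriter) -> None:
        de_species = state["de"].get("species")
        significant = (
            de_species.loc[de_species["significant"], "feature_id"].tolist()
            if de_species is not None
            else []
        )
        gl_table = (
            GeneLipidTable.from_tsv(config.network_table_path)
            if config.network_table_path
            else GeneLipidTable.default()
        )
        edges = filter_generic_nodes(map_lipids_to_genes(significant, gl_table))
        graph = build_graph(edges)
        coords = layout_coordinates(graph, seed=config.seed + _SEED_OFFSETS["network"])
        w.write(pd.DataFrame(edges, columns=["gene", "lipid"]), "network_edges.tsv")
        w.write(node_table(graph, coords), "network_nodes.tsv")

    stage("annotate", s_annotate)
    stage("differential_abundance", s_de)
    stage("pca_clustering", s_pca)
    stage("stability_selection", s_stability)
    stage("roc_screening", s_roc)
    stage("gene_lipid_network", s_network)

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
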