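"""Pipeline orchestration: normalize → patterns → enrich → cohort.

A :class:`PipelineConfig` (usually loaded from a YAML file) names the input
files and analysis parameters; :func:`run_full_pipeline` executes the stages
in order, writes every tabular output with a provenance header (tool
version, config hash, seed), and records a JSON manifest listing each output
file and its row count.  Reruns with the same config produce byte-identical
tabular outputs; only the manifest timestamp differs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (candidate_biomarkers, hierarchical_cluster,
                     log_cap_transform, read_design)
from .enrichment import neglog_p_matrix, ora, read_gmt
from .patterns import (DirectionParams, DoseDesign, PatternCode,
                       call_directions_table, kmeans_profiles,
                       match_clusters_to_patterns, matches_to_frame,
                       standardize_profiles)
from .quant import SpikeKey, normalize_to_spike, read_quant_table

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline",
           "read_pattern_table"]

log = logging.getLogger("glycopattern")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and underlying cause."""

    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Declarative configuration for a full pipeline run."""

    quant: str
    out_dir: str
    baseline_sample: str
    treated_samples: list[str]
    gmt: str | None = None
    tissue: str | None = None
    tissue_design: str | None = None
    cell_patterns: str | None = None
    spike_ids: list[str] = field(default_factory=lambda: ["BSA_SPIKE"])
    reference_sample: str = "first"
    spa_index: int = -1
    fold_threshold: float = 1.5
    missing_policy: str = "drop-protein"
    k: int = 27
    n_init: int = 10
    seed: int = 17
    alpha: float = 0.05
    min_term_size: int = 3
    min_log10_fc: float = 0.5
    require_pairs: bool = False
    pseudo_intensity: float = 1.0
    cap: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(data) - known
        if stray:
            raise ValueError(f"unknown configuration keys: {sorted(stray)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @property
    def design(self) -> DoseDesign:
        return DoseDesign(baseline_sample=self.baseline_sample,
                          treated_samples=tuple(self.treated_samples),
                          spa_index=self.spa_index)

    @property
    def direction_params(self) -> DirectionParams:
        return DirectionParams(fold_threshold=self.fold_threshold,
                               missing_policy=self.missing_policy)


def read_pattern_table(path) -> dict[str, PatternCode]:
    """Read a per-protein pattern table (protein_id, pattern, ...)."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"protein_id", "pattern"} <= set(frame.columns):
        raise ValueError("pattern table needs 'protein_id' and 'pattern' columns")
    return {pid: PatternCode.from_string(p)
            for pid, p in zip(frame["protein_id"], frame["pattern"])}


def _write_frame(frame: pd.DataFrame, path: Path, header: str,
                 index: bool = True) -> int:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        frame.to_csv(fh, sep="\t", index=index, na_rep="", float_format="%.10g")
    return len(frame)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; return (and write) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = (f"glycopattern {__version__} | config_hash={config.config_hash} "
              f"| seed={config.seed}")
    manifest: dict = {
        "tool": "glycopattern",
        "version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "status": "ok",
        "stages": {},
    }

    def record(stage: str, outputs: dict[str, int], status: str = "ok") -> None:
        manifest["stages"][stage] = {"status": status, "outputs": outputs}

    def fail(stage: str, exc: BaseException):
        for info in manifest["stages"].values():
            info["status"] = "stale" if info["status"] == "ok" else info["status"]
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        record(stage, {}, status="failed")
        manifest["created"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, exc) from exc

    # ---- normalize ----------------------------------------------------
    stage = "normalize"
    try:
        log.info("stage %s", stage)
        table = read_quant_table(config.quant)
        spike_present = [s for s in config.spike_ids if s in table.index]
        if spike_present:
            key = SpikeKey(spike_present, reference_sample=config.reference_sample)
            table = normalize_to_spike(table, key)
        else:
            log.warning("no spike rows found; table left unnormalized")
        path = out_dir / "normalized.tsv"
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            table.to_csv(fh, sep="\t", na_rep="", float_format="%.10g")
        record(stage, {"normalized.tsv": len(table)})
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail(stage, exc)

    # ---- patterns -----------------------------------------------------
    stage = "patterns"
    try:
        log.info("stage %s", stage)
        design = config.design
        params = config.direction_params
        pattern_table = call_directions_table(table, design, params)
        standardized = standardize_profiles(table, design,
                                            pseudo_intensity=config.pseudo_intensity)
        model = kmeans_profiles(standardized, k=config.k, seed=config.seed,
                                n_init=config.n_init)
        matches = match_clusters_to_patterns(model, table, design, params)
        match_frame = matches_to_frame(matches)
        assign = model.assignments.to_frame()
        outputs = {
            "patterns.tsv": _write_frame(pattern_table, out_dir / "patterns.tsv",
                                         header),
            "cluster_assignments.tsv": _write_frame(
                assign, out_dir / "cluster_assignments.tsv", header),
            "cluster_matches.tsv": _write_frame(
                match_frame, out_dir / "cluster_matches.tsv", header),
        }
        record(stage, outputs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- enrich -------------------------------------------------------
    stage = "enrich"
    try:
        log.info("stage %s", stage)
        if not config.gmt or not Path(config.gmt).exists():
            raise FileNotFoundError(f"annotation GMT file not found: {config.gmt}")
        collection = read_gmt(config.gmt)
        universe = set(pattern_table.index)
        spa_query = set(pattern_table.index[pattern_table["spa_associated"]])
        spa_result = ora(spa_query, universe, collection,
                         min_term_size=config.min_term_size, alpha=config.alpha)
        per_cluster = {}
        for m in matches:
            if not m.spa_associated or m.empty:
                continue
            members = set(model.members(m.cluster_id)) & universe
            if not members:
                continue
            per_cluster[f"c{m.cluster_id}"] = ora(
                members, universe, collection,
                min_term_size=config.min_term_size, alpha=config.alpha)
        matrix = neglog_p_matrix(per_cluster, alpha=config.alpha)
        outputs = {
            "enrichment_spa.tsv": _write_frame(
                spa_result, out_dir / "enrichment_spa.tsv",
                header + " | p upper-tail hypergeometric, neglog10_p base 10",
                index=False),
            "enrichment_neglog10p.tsv": _write_frame(
                matrix, out_dir / "enrichment_neglog10p.tsv",
                header + " | -log10(p) where p < alpha else 0"),
        }
        record(stage, outputs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- cohort -------------------------------------------------------
    stage = "cohort"
    if config.tissue is None:
        record(stage, {}, status="skipped")
    else:
        try:
            log.info("stage %s", stage)
            tissue = read_quant_table(config.tissue)
            if config.tissue_design is None:
                raise ValueError("tissue_design is required with a tissue table")
            design_c = read_design(config.tissue_design)
            if config.cell_patterns:
                cell_patterns = read_pattern_table(config.cell_patterns)
            else:
                cell_patterns = {
                    pid: PatternCode.from_string(p)
                    for pid, p in zip(pattern_table.index,
                                      pattern_table["pattern"])}
            candidates = candidate_biomarkers(
                cell_patterns, tissue, design_c,
                min_log10_fc=config.min_log10_fc,
                require_pairs=config.require_pairs,
                pseudo_intensity=config.pseudo_intensity)
            capped = log_cap_transform(tissue, cap=config.cap)
            # rows constant on the display scale carry no clustering signal
            variable = capped.loc[capped.std(axis=1) > 0]
            dendro = hierarchical_cluster(variable, axis="rows")
            (out_dir / "protein_dendrogram.nwk").write_text(
                dendro.to_newick() + "\n")
            outputs = {
                "candidates.tsv": _write_frame(
                    candidates, out_dir / "candidates.tsv", header),
                "heatmap_matrix.tsv": _write_frame(
                    capped, out_dir / "heatmap_matrix.tsv",
                    header + f" | log10 display scale capped at {config.cap}"),
                "protein_dendrogram.nwk": len(dendro.leaf_order),
                "dendrogram_merges.tsv": _write_frame(
                    dendro.to_frame(), out_dir / "dendrogram_merges.tsv",
                    header, index=False),
            }
            record(stage, outputs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    manifest["created"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
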