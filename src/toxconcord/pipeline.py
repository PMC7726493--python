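"""End-to-end orchestration: matrix in, report bundle out.

``run_pipeline`` chains the analysis stages -- differential expression per
compound-vs-control contrast, up/down gene lists, Venn partition, pairwise
and three-way overlap ratios with a Monte-Carlo exceedance probability,
genome-wide fold-change concordance, top-variance PCA, and IC50 estimation
for any supplied concentration-response curves -- and writes every result as
TSV/JSON plus a machine-readable manifest (config, seed, package versions,
SHA-256 checksums) into the output directory.

Defaults mirror the analysis settings the statistics were designed around:
fold-change threshold 1.5, FDR level 0.05, PCA on the 1000 highest-variance
probes, overlap universe = all probes of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .matrix import ExpressionMatrix, read_matrix, write_gene_list
from .diffexpr import de_table, write_de_table, called_sets
from .overlap import (
    GeneSetCollection,
    OverlapSummary,
    UndefinedRatioError,
    monte_carlo_null,
    overlap_ratio_pairwise,
    overlap_ratio_threeway,
    summaries_to_frame,
    venn_partition,
)
from .concordance import pairwise_concordance, format_p
from .pca import pca, select_top_variance
from .dose_response import estimate_ic50, read_curve

logger = logging.getLogger("toxconcord")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    matrix_path: str
    sample_sheet_path: str
    output_dir: str
    control: str = "control"
    dose_response_paths: dict[str, str] = field(default_factory=dict)
    fc_threshold: float = 1.5
    alpha: float = 0.05
    pca_top_k: int = 1000
    universe: str = "all"  # "all" probes or "expressed" subset
    expressed_min_mean: float = 5.0
    monte_carlo_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.universe not in ("all", "expressed"):
            raise ValueError("universe must be 'all' or 'expressed'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _universe_probes(matrix: ExpressionMatrix, config: PipelineConfig) -> pd.Index:
    if config.universe == "all":
        return matrix.probe_ids
    expressed = matrix.values.mean(axis=1) >= config.expressed_min_mean
    return matrix.probe_ids[expressed]


def _overlap_rows(
    sets: dict[str, set], universe_size: int, direction: str,
    reps: int, seed: int,
) -> dict[str, dict]:
    """Pairwise + three-way overlap summaries for one call direction.

    Empty sets make the ratio undefined; such rows carry NaN statistics and
    an explicit marker naming the empty set(s).
    """
    names = list(sets)
    rows: dict[str, dict] = {}

    def _row(selected: list[str], k: int) -> dict:
        sizes = [len(sets[n]) for n in selected]
        observed = len(set.intersection(*(sets[n] for n in selected)))
        base = {f"n{i+1}": s for i, s in enumerate(sizes)}
        base.update(k=k, N=universe_size, observed=observed)
        empty = [n for n, s in zip(selected, sizes) if s == 0]
        if empty:
            base.update(
                expected=np.nan, overlap_ratio=np.nan,
                note=f"undefined: n_i = 0 for {','.join(empty)}",
            )
            return base
        if k == 2:
            summary = overlap_ratio_pairwise(*sizes, observed, universe_size)
        else:
            summary = overlap_ratio_threeway(*sizes, observed, universe_size)
        base.update(
            expected=summary.expected, overlap_ratio=summary.ratio, note=""
        )
        if k == 3:
            null = monte_carlo_null(
                *sizes[:2], universe_size, n3=sizes[2],
                reps=reps, seed=seed, observed=observed,
            )
            # Monte-Carlo extension beyond the analytic ratio
            base["mc_exceedance_p"] = null.exceedance
        return base

    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rows[f"{a}&{b} {direction}"] = _row([a, b], 2)
    if len(names) == 3:
        rows[f"{'&'.join(names)} {direction}"] = _row(names, 3)
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle.

    Returns the manifest dict (also written as ``manifest.json``).  Any
    stage failure aborts with a :class:`PipelineStageError`; the stages
    completed so far are flagged in the manifest on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": asdict(config),
        "seed": config.seed,
        "stages_completed": [],
        "outputs": {},
    }
    stage = "load"
    try:
        matrix = read_matrix(config.matrix_path, config.sample_sheet_path)
        compounds = [t for t in matrix.treatments if t != config.control]
        if config.control not in matrix.treatments:
            raise ValueError(f"control label {config.control!r} not in sample sheet")
        universe = _universe_probes(matrix, config)
        manifest["n_probes"] = matrix.n_probes
        manifest["universe_size"] = len(universe)
        manifest["stages_completed"].append(stage)

        stage = "diffexpr"
        tables = {}
        for compound in compounds:
            de = de_table(
                matrix, compound, config.control,
                fc_threshold=config.fc_threshold, alpha=config.alpha,
            )
            tables[compound] = de
            write_de_table(de, out / f"de_{compound}.tsv")
            for direction, ids in called_sets(de).items():
                write_gene_list(sorted(ids), out / f"{compound}_{direction}.txt")
        manifest["de_counts"] = {
            c: {"up": int((t["call"] == "up").sum()),
                "down": int((t["call"] == "down").sum())}
            for c, t in tables.items()
        }
        manifest["stages_completed"].append(stage)

        stage = "overlap"
        universe_set = set(universe)
        rows: dict[str, dict] = {}
        venn_frames = []
        for direction in ("up", "down"):
            sets = {
                c: called_sets(t)[direction] & universe_set
                for c, t in tables.items()
            }
            rows.update(_overlap_rows(
                sets, len(universe), direction,
                reps=config.monte_carlo_reps, seed=config.seed,
            ))
            if len(sets) == 3:
                regions = venn_partition(
                    GeneSetCollection(universe_set, sets)
                )
                venn_frames.append(
                    pd.Series(regions, name=direction)
                )
        overlap_frame = pd.DataFrame.from_dict(rows, orient="index")
        overlap_frame.index.name = "comparison"
        overlap_frame.to_csv(out / "overlap_summary.tsv", sep="\t")
        if venn_frames:
            venn = pd.concat(venn_frames, axis=1)
            venn.index.name = "region"
            venn.to_csv(out / "venn_regions.tsv", sep="\t")
        manifest["stages_completed"].append(stage)

        stage = "concordance"
        if len(compounds) >= 2:
            profiles = {c: t["log2fc"] for c, t in tables.items()}
            r, p = pairwise_concordance(profiles)
            r.to_csv(out / "concordance_R.tsv", sep="\t")
            p_formatted = p.map(format_p)
            p_formatted.to_csv(out / "concordance_p.tsv", sep="\t")
        manifest["stages_completed"].append(stage)

        stage = "pca"
        top = select_top_variance(matrix, min(config.pca_top_k, matrix.n_probes))
        result = pca(matrix.subset_probes(top))
        coords = result.coordinates.copy()
        coords.insert(0, "treatment", matrix.samples["treatment"].values)
        coords.index.name = "sample_id"
        coords.to_csv(out / "pca_coordinates.tsv", sep="\t")
        pd.Series(
            result.percent_variance,
            index=coords.columns[1:],
            name="percent_variance",
        ).to_csv(out / "pca_variance.tsv", sep="\t")
        manifest["pca_pc1_pct"] = float(result.percent_variance[0])
        manifest["stages_completed"].append(stage)

        stage = "ic50"
        if config.dose_response_paths:
            ic50_rows = []
            for name, path in config.dose_response_paths.items():
                res = estimate_ic50(read_curve(path))
                ic50_rows.append(
                    {"curve": name, "status": res.status,
                     "ic50_uM": res.ic50, "a": res.a, "b": res.b}
                )
            pd.DataFrame(ic50_rows).to_csv(
                out / "ic50.tsv", sep="\t", index=False
            )
        manifest["stages_completed"].append(stage)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineStageError(stage, exc) from exc

    manifest["outputs"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir())
        if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete: %d stages", len(manifest["stages_completed"]))
    return manifest
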