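"""End-to-end orchestration: QC -> expression -> selectivity -> deconvolution
-> paired antibodies -> (optional) antigen structure stage.

The pipeline is a thin composition of the stage modules; it owns only file
layout, the run configuration, logging and the run manifest (config hash +
seed + package versions) that makes a run reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    AssayMatrix,
    read_antibody_manifest,
    read_gpcr_library,
    read_mfi_table,
    read_sample_manifest,
    validate_panel,
)
from .deconvolution import deconvolve, events_table
from .expression import assess_expression, coupling_qc, expression_summary, filter_bead_counts
from .pairs import pair_correlations, pair_summary, pairs_table
from .selectivity import (
    classify_all,
    rz_long_table,
    summarize_classifications,
    threshold_sweep,
)
from .structure import (
    antigen_profile,
    compare_groups,
    extract_residue_annotations,
    profiles_frame,
    read_structure_model,
)


@dataclass
class RunConfig:
    """Run configuration; defaults are the screen's published operating point."""

    antibody_manifest: str = "antibodies.tsv"
    sample_manifest: str = "samples.tsv"
    mfi: str = "mfi.tsv"
    bead_counts: str = "bead_counts.tsv"
    library_fasta: str = "library.fasta"
    library_meta: str = "library_meta.tsv"
    coupling_mfi: str = "coupling_mfi.tsv"
    coupling_counts: str = "coupling_counts.tsv"
    structure_dir: str | None = None

    k: float = 12.0  # SD multiplier over the density peak
    min_events: int = 32  # bead-count floor per cell
    alpha: float = 0.05  # expression significance level
    ratio_cut: float = 2.0  # twofold abundance line
    evalue_cut: float = 1.0  # homology boundary
    coupling_floor: float = 1000.0
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")
        for name in ("min_events", "alpha", "ratio_cut", "evalue_cut"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory results of one pipeline run."""

    config: RunConfig
    mask: pd.DataFrame
    failed_beads: list
    expression: list
    expression_table: pd.DataFrame
    profiles: dict
    annotations: list
    classification_table: pd.DataFrame
    sweep: pd.DataFrame
    crossreact: list
    pairs: list
    pair_stats: dict
    antigen_stats: pd.DataFrame | None = None
    log: list = field(default_factory=list)


def run_stages(
    matrix: AssayMatrix,
    coupling: AssayMatrix,
    antibodies,
    samples,
    library,
    config: RunConfig,
    sweep_grid=tuple(range(0, 31, 2)),
) -> RunResult:
    """Run every analysis stage on in-memory inputs."""
    log: list = []

    report = validate_panel(antibodies, samples, library)
    if not report.ok:
        raise ValueError("panel validation failed: " + "; ".join(report.violations))

    masked, mask = filter_bead_counts(matrix, config.min_events)
    for s, b in zip(*np.where(mask.to_numpy())):
        log.append(f"masked cell sample={mask.index[s]} bead={mask.columns[b]} (low bead count)")

    anti_gpcr = [ab for ab in antibodies if not ab.is_control]
    failed_beads = coupling_qc(coupling, [ab.bead_id for ab in anti_gpcr], config.coupling_floor)
    for b in failed_beads:
        log.append(f"excluded bead {b} (coupling below {config.coupling_floor})")

    expression = assess_expression(masked, samples, antibodies, library, alpha=config.alpha)
    expr_table = expression_summary(expression, library)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        profiles, annotations = classify_all(
            masked, antibodies, samples, excluded_beads=failed_beads, k=config.k
        )
        sweep = threshold_sweep(
            profiles,
            [ab for ab in anti_gpcr if ab.bead_id not in failed_beads],
            samples,
            sweep_grid,
        )
        crossreact = deconvolve(
            annotations,
            profiles,
            expression,
            library,
            antibodies,
            samples,
            ratio_cut=config.ratio_cut,
            evalue_cut=config.evalue_cut,
        )
        pairs = pair_correlations(profiles, antibodies)
    log.extend(str(w.message) for w in caught)

    class_table = summarize_classifications(annotations, antibodies)
    stats = pair_summary(pairs, annotations, antibodies)
    return RunResult(
        config=config,
        mask=mask,
        failed_beads=failed_beads,
        expression=expression,
        expression_table=expr_table,
        profiles=profiles,
        annotations=annotations,
        classification_table=class_table,
        sweep=sweep,
        crossreact=crossreact,
        pairs=pairs,
        pair_stats=stats,
        log=log,
    )


def _antigen_stage(result: RunResult, antibodies, config: RunConfig) -> pd.DataFrame | None:
    """Optional structural stage: needs per-antibody model files in structure_dir."""
    if config.structure_dir is None:
        return None
    sdir = Path(config.structure_dir)
    if not sdir.is_dir():
        warnings.warn(f"structure directory {sdir} not found; antigen stage skipped")
        return None
    category = {a.antibody_id: a.category for a in result.annotations}
    profiles = []
    for ab in antibodies:
        if ab.is_control or ab.antigen_start is None:
            continue
        path = None
        for ext in (".pdb", ".cif"):
            cand = sdir / f"{ab.antibody_id}{ext}"
            if cand.exists():
                path = cand
                break
        if path is None:
            continue
        model = read_structure_model(path)
        annotations = extract_residue_annotations(model)
        profiles.append(
            antigen_profile(annotations, (ab.antigen_start, ab.antigen_end), ab.antibody_id)
        )
    if not profiles:
        warnings.warn("no structure models matched any antibody; antigen stage skipped")
        return None
    frame = profiles_frame(profiles, category)
    return compare_groups(frame)


def run_pipeline(config: RunConfig, indir=".") -> RunResult:
    """Load inputs from disk, run all stages, write the report bundle."""
    indir = Path(indir)
    antibodies = read_antibody_manifest(indir / config.antibody_manifest)
    samples = read_sample_manifest(indir / config.sample_manifest)
    library = read_gpcr_library(indir / config.library_fasta, indir / config.library_meta)
    matrix = read_mfi_table(indir / config.mfi, indir / config.bead_counts, antibodies, samples)
    coupling = read_mfi_table(indir / config.coupling_mfi, indir / config.coupling_counts, antibodies)

    result = run_stages(matrix, coupling, antibodies, samples, library, config)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result.antigen_stats = _antigen_stage(result, antibodies, config)
    result.log.extend(str(w.message) for w in caught)

    write_outputs(result, antibodies, samples)
    return result


def write_outputs(result: RunResult, antibodies, samples) -> None:
    """Write the TSV/JSON report bundle with fixed float formatting."""
    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    result.expression_table.to_csv(outdir / "expression_summary.tsv", sep="\t", index=False)
    result.classification_table.to_csv(
        outdir / "classification_summary.tsv", sep="\t", index=False
    )
    result.sweep.to_csv(outdir / "threshold_sweep.tsv", sep="\t", index=False)

    category = {a.antibody_id: a.category for a in result.annotations}
    prof_rows = [
        {
            "antibody_id": ab_id,
            "median_mfi": p.median_mfi,
            "mad_mfi": p.mad_mfi,
            "density_peak": p.density_peak,
            "sigma_neg": p.sigma_neg,
            "threshold": p.threshold,
            "category": category.get(ab_id, ""),
        }
        for ab_id, p in sorted(result.profiles.items())
    ]
    pd.DataFrame(prof_rows).to_csv(
        outdir / "antibody_profiles.tsv", sep="\t", index=False, float_format="%.6g"
    )
    ann_rows = [
        {
            "antibody_id": a.antibody_id,
            "category": a.category,
            "on_target_mean_rz": a.on_target_mean_rz,
            "threshold": a.threshold,
            "offtargets": ";".join(e.gpcr_id for e in a.offtarget_events),
        }
        for a in result.annotations
    ]
    pd.DataFrame(ann_rows).to_csv(
        outdir / "annotations.tsv", sep="\t", index=False, float_format="%.6g"
    )
    events_table(result.crossreact).to_csv(
        outdir / "crossreact_events.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pairs_table(result.pairs).to_csv(
        outdir / "pairs.tsv", sep="\t", index=False, float_format="%.6g"
    )
    (outdir / "pair_summary.json").write_text(json.dumps(_jsonable(result.pair_stats), indent=1))
    rz_long_table(result.profiles, samples).to_csv(
        outdir / "rz_long.tsv", sep="\t", index=False, float_format="%.6g"
    )
    if result.antigen_stats is not None:
        result.antigen_stats.to_csv(
            outdir / "antigen_stats.tsv", sep="\t", index=False, float_format="%.6g"
        )
    manifest = {
        "package": "sbaval",
        "version": __version__,
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "k": result.config.k,
        "n_antibodies_scored": len(result.profiles),
        "n_beads_excluded": len(result.failed_beads),
        "n_cells_masked": int(result.mask.to_numpy().sum()),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "run.log").write_text("\n".join(result.log) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def mark_partial(outdir) -> None:
    """Suffix every existing output file with .partial after a failed run."""
    outdir = Path(outdir)
    if not outdir.is_dir():
        return
    for f in outdir.iterdir():
        if f.is_file() and not f.name.endswith(".partial"):
            f.rename(f.with_name(f.name + ".partial"))
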