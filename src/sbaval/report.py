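"""Static report exports (the file-based replacement for interactive browsing).

Everything is derived from the TSV bundle a pipeline run writes: long-format
robust-Z data for beeswarm plots, a per-panel cross-reactivity heatmap matrix
(threshold exceedance per antibody x construct; zero where nothing crossed
the threshold), paired-antibody panel data, and a Markdown summary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def build_heatmap(rz_long: pd.DataFrame) -> pd.DataFrame:
    """Antibody x construct matrix of max(rz - threshold, 0) over samples.

    Mock wells are excluded; a panel with no above-threshold binding yields
    an all-zero matrix, not an error.
    """
    df = rz_long[rz_long["construct"] != "MOCK"].copy()
    df["exceedance"] = np.maximum(df["rz"] - df["threshold"], 0.0).fillna(0.0)
    mat = df.pivot_table(
        index="antibody_id", columns="construct", values="exceedance", aggfunc="max", fill_value=0.0
    )
    return mat


def write_report(results_dir, outdir=None) -> Path:
    """Assemble the static report from a run's output bundle."""
    results_dir = Path(results_dir)
    outdir = results_dir / "report" if outdir is None else Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rz_long = pd.read_csv(results_dir / "rz_long.tsv", sep="\t")
    rz_long.to_csv(outdir / "beeswarm.tsv", sep="\t", index=False)
    build_heatmap(rz_long).to_csv(outdir / "heatmap.tsv", sep="\t")

    pairs_path = results_dir / "pairs.tsv"
    if pairs_path.exists():
        pd.read_csv(pairs_path, sep="\t").to_csv(outdir / "pair_panel.tsv", sep="\t", index=False)

    lines = ["# SBA selectivity run summary", ""]
    for title, name in [
        ("Expression", "expression_summary.tsv"),
        ("Selectivity classification", "classification_summary.tsv"),
    ]:
        path = results_dir / name
        if path.exists():
            lines.append(f"## {title}")
            lines.append("")
            lines.append(pd.read_csv(path, sep="\t").to_markdown(index=False))
            lines.append("")
    (outdir / "summary.md").write_text("\n".join(lines))
    return outdir
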