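"""Assay QC and per-construct expression assessment against mock.

Two QC gates precede any scoring: cells backed by too few bead events are
masked, and antibody beads whose coupling-control signal is low are excluded
outright.  Expression of each construct is then judged from the epitope-tag
capture bead (FLAG capture / 1D4 detection; HA capture for frizzled
constructs): log2 MFI values are compared against the panel's mock wells by a
one-way ANOVA gate followed by Dunnett's multiple-comparison contrasts to
mock, and a construct is called *supported* only when its Dunnett p-value is
below alpha **and** its mean lies above the mock mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MOCK, SUBFAMILIES, AssayMatrix

#: Floor applied to MFI before log2 so zeros stay finite while order is kept.
LOG_FLOOR = 1.0


@dataclass
class ExpressionResult:
    gpcr_id: str
    subfamily: str
    log2_levels: np.ndarray  # over QC-passing samples of the construct
    mock_log2_levels: np.ndarray
    anova_p: float
    dunnett_p: float  # NaN when not computable (<2 replicates)
    status: str  # supported | uncertain

    @property
    def mean_log2(self) -> float:
        return float(np.mean(self.log2_levels)) if self.log2_levels.size else math.nan

    @property
    def mean_linear(self) -> float:
        """Mean tag-capture level on the linear scale (for expression ratios)."""
        if not self.log2_levels.size:
            return math.nan
        return float(np.mean(2.0 ** self.log2_levels))


def filter_bead_counts(matrix: AssayMatrix, min_events: int = 32):
    """Mask MFI cells whose bead count is below ``min_events``.

    Returns the masked matrix (MFI -> NaN in masked cells) and the boolean
    mask frame (True = masked).  Masked cells are treated as missing by every
    downstream stage, never imputed.
    """
    mask = matrix.bead_count < min_events
    mfi = matrix.mfi.where(~mask)
    return AssayMatrix(mfi, matrix.bead_count.copy()), mask


def coupling_qc(coupling: AssayMatrix, bead_ids, floor: float = 1000.0) -> list:
    """Beads whose median coupling-control signal falls below ``floor``.

    ``coupling`` is the dedicated anti-rabbit-detection run measuring how
    much antibody each bead actually carries; flagged beads are excluded from
    all scoring.
    """
    failed = []
    for b in bead_ids:
        if float(coupling.mfi[b].median()) < floor:
            failed.append(b)
    return failed


def _log2(values: np.ndarray) -> np.ndarray:
    return np.log2(np.maximum(np.asarray(values, dtype=float), LOG_FLOOR))


def capture_bead_for(panel: str, n_tag: str, antibodies) -> int:
    """Bead id of the panel's capture-tag control bead (anti-FLAG / anti-HA)."""
    role = f"anti-{n_tag}"
    for ab in antibodies:
        if ab.subfamily_panel == panel and ab.target_id == role:
            return ab.bead_id
    raise KeyError(f"no {role} bead in panel {panel}")


def assess_expression(matrix: AssayMatrix, samples, antibodies, library, alpha: float = 0.05):
    """Two-stage expression test: panel-level ANOVA gate, then Dunnett to mock.

    Within each panel, constructs sharing a capture tag form one stratum;
    the stratum is first tested by ordinary one-way ANOVA (constructs + mock)
    at ``alpha``, and only if that gate fires are per-construct Dunnett
    contrasts against mock evaluated.  Constructs with fewer than two
    QC-passing replicates are reported *uncertain* with a NaN p-value.
    """
    lib = {g.gpcr_id: g for g in library}
    results = []
    panels = sorted({s.panel for s in samples}, key=SUBFAMILIES.index)
    for panel in panels:
        panel_constructs = sorted(
            {s.construct for s in samples if s.panel == panel and not s.is_mock}
        )
        tags = sorted({lib[c].n_tag for c in panel_constructs})
        for tag in tags:
            bead = capture_bead_for(panel, tag, antibodies)
            col = matrix.mfi[bead]
            mock_vals = _log2(
                col.loc[[s.sample_id for s in samples if s.panel == panel and s.is_mock]]
                .dropna()
                .to_numpy()
            )
            stratum = [c for c in panel_constructs if lib[c].n_tag == tag]
            groups, usable = {}, []
            for c in stratum:
                vals = _log2(
                    col.loc[[s.sample_id for s in samples if s.construct == c]]
                    .dropna()
                    .to_numpy()
                )
                groups[c] = vals
                if vals.size >= 2:
                    usable.append(c)
            if usable and mock_vals.size >= 2:
                anova_p = float(
                    stats.f_oneway(*[groups[c] for c in usable], mock_vals).pvalue
                )
                dunnett = stats.dunnett(
                    *[groups[c] for c in usable], control=mock_vals
                )
                dunnett_p = dict(zip(usable, np.asarray(dunnett.pvalue, dtype=float)))
            else:
                anova_p, dunnett_p = math.nan, {}
            for c in stratum:
                vals = groups[c]
                p = dunnett_p.get(c, math.nan)
                supported = (
                    not math.isnan(anova_p)
                    and anova_p < alpha
                    and not math.isnan(p)
                    and p < alpha
                    and vals.size > 0
                    and float(np.mean(vals)) > float(np.mean(mock_vals))
                )
                results.append(
                    ExpressionResult(
                        gpcr_id=c,
                        subfamily=lib[c].subfamily,
                        log2_levels=vals,
                        mock_log2_levels=mock_vals,
                        anova_p=anova_p,
                        dunnett_p=p,
                        status="supported" if supported else "uncertain",
                    )
                )
    return results


def expression_summary(results, library) -> pd.DataFrame:
    """Per-subfamily counts and percent expressed (one decimal) + total row."""
    by_fam = {}
    for r in results:
        by_fam.setdefault(r.subfamily, []).append(r)
    rows = []
    total_n = total_k = 0
    for fam in SUBFAMILIES:
        fam_lib = [g for g in library if g.subfamily == fam]
        if not fam_lib:
            continue
        rs = by_fam.get(fam, [])
        if not rs:
            warnings.warn(f"subfamily {fam} has no expression results; row omitted")
            continue
        n = len(rs)
        k = sum(1 for r in rs if r.status == "supported")
        total_n += n
        total_k += k
        rows.append({"Subfamily": fam, "GPCRs (N)": n, "Expressed (%)": round(100.0 * k / n, 1)})
    rows.append(
        {
            "Subfamily": "Total",
            "GPCRs (N)": total_n,
            "Expressed (%)": round(100.0 * total_k / total_n, 1) if total_n else math.nan,
        }
    )
    return pd.DataFrame(rows)
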