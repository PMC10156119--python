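"""Per-antibody robust Z-scoring, data-driven thresholds and selectivity calls.

Each antibody's MFI vector across the samples of its panel is rescaled to
robust Z-scores (R.Z)::

    rz_i = (x_i - median(x)) / (1.4826 * MAD(x))

a per-antibody scaling that is resistant to the very binding events it is
meant to expose.  The bulk of each R.Z distribution is background; its mode
is located by a Gaussian kernel density estimate, the spread of the negative
(non-binding) population is estimated from the lower half of the
distribution mirrored around that mode, and the antibody-specific selectivity
threshold is set ``k`` such SDs above the mode (default k = 12, chosen where
the on-target count plateaus in the threshold sweep).

An antibody is *on-target* when the mean R.Z of samples containing its
intended receptor exceeds the threshold and no sample containing any other
receptor does; a single unintended sample above the threshold makes it
cross-reactive (co- or off-target); an antibody above threshold nowhere is
*no-target*.  Mock wells belong to the background population and can never
constitute an off-target event.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import SUBFAMILIES, AssayMatrix

DEFAULT_K = 12.0

CATEGORIES = ("on_target", "co_target", "off_target", "no_target")


class DegenerateDistributionError(ValueError):
    """MAD of an antibody's MFI vector is zero; no silent fallback."""


def robust_z(values, label: str | None = None) -> np.ndarray:
    """Robust Z-scores (x - median) / (1.4826 * MAD); NaN-preserving.

    Requires at least 3 finite values.  A zero MAD raises
    :class:`DegenerateDistributionError` naming the antibody.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 3:
        raise ValueError(f"robust_z needs >=3 finite values, got {finite.size}")
    med = float(np.median(finite))
    mad = float(np.median(np.abs(finite - med)))
    if mad == 0.0:
        who = f" for antibody {label}" if label else ""
        raise DegenerateDistributionError(f"MAD is zero{who}: degenerate distribution")
    return (x - med) / (1.4826 * mad)


def _silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9 * min(sd, IQR/1.349) * n^(-1/5)."""
    sd = float(np.std(values, ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * spread * values.size ** (-0.2)


def density_peak(rz, grid_size: int = 512) -> float:
    """Mode of a Gaussian KDE of the R.Z values on a fixed grid over [min, max]."""
    vals = np.asarray(rz, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("density_peak needs at least one finite value")
    if np.ptp(vals) == 0.0:
        return float(vals[0])
    h = _silverman_bandwidth(vals)
    sd = float(np.std(vals, ddof=1))
    if h <= 0 or sd <= 0:
        return float(np.median(vals))
    kde = stats.gaussian_kde(vals, bw_method=h / sd)
    grid = np.linspace(vals.min(), vals.max(), grid_size)
    return float(grid[int(np.argmax(kde(grid)))])


#: Minimum points at or below the peak for a stable reflected-tail estimate;
#: a median over fewer distances is dominated by peak-location noise.
MIN_TAIL_POINTS = 10


def negative_sd(rz, peak: float) -> float:
    """SD of the negative population: reflected-lower-tail robust estimate.

    True binding inflates only the upper tail, so the spread of the
    non-binding population is estimated as 1.4826 x median(|r - peak|) over
    the values at or below the peak (the lower half mirrored around it).
    Too few such points (< MIN_TAIL_POINTS, including the degenerate < 3
    case) falls back to the full-vector MAD-based SD with a warning.
    """
    vals = np.asarray(rz, dtype=float)
    vals = vals[np.isfinite(vals)]
    lower = vals[vals <= peak]
    estimate = 1.4826 * float(np.median(np.abs(lower - peak))) if lower.size else 0.0
    if lower.size < MIN_TAIL_POINTS or estimate == 0.0:
        warnings.warn(
            f"only {lower.size} points at or below the density peak; "
            "falling back to full-vector MAD-based SD"
        )
        med = np.median(vals)
        return 1.4826 * float(np.median(np.abs(vals - med)))
    return estimate


@dataclass
class RZProfile:
    """Robust-Z profile of one antibody plus its selectivity threshold."""

    antibody_id: str
    rz: pd.Series  # indexed by sample_id; NaN where QC-masked
    median_mfi: float
    mad_mfi: float
    density_peak: float
    sigma_neg: float
    k: float = DEFAULT_K

    @property
    def threshold(self) -> float:
        return self.threshold_at(self.k)

    def threshold_at(self, k: float) -> float:
        return self.density_peak + k * self.sigma_neg


@dataclass
class OffTargetEvent:
    gpcr_id: str
    n_samples_above: int
    max_rz: float


@dataclass
class SelectivityAnnotation:
    antibody_id: str
    category: str  # one of CATEGORIES
    on_target_mean_rz: float
    threshold: float
    offtarget_events: list = field(default_factory=list)


def rz_profile(matrix: AssayMatrix, antibody, samples, k: float = DEFAULT_K) -> RZProfile:
    """Build the R.Z profile of one antibody over its panel's samples.

    QC-masked cells (NaN MFI) are excluded from median/MAD and remain NaN in
    the profile; they never contribute to classification.
    """
    panel_ids = [s.sample_id for s in samples if s.panel == antibody.subfamily_panel]
    x = matrix.mfi.loc[panel_ids, antibody.bead_id]
    rz = pd.Series(
        robust_z(x.to_numpy(), label=antibody.antibody_id), index=x.index, name=antibody.antibody_id
    )
    finite = x.to_numpy()[np.isfinite(x.to_numpy())]
    med = float(np.median(finite))
    mad = float(np.median(np.abs(finite - med)))
    peak = density_peak(rz.to_numpy())
    sigma = negative_sd(rz.to_numpy(), peak)
    return RZProfile(
        antibody_id=antibody.antibody_id,
        rz=rz,
        median_mfi=med,
        mad_mfi=mad,
        density_peak=peak,
        sigma_neg=sigma,
        k=k,
    )


def classify_antibody(profile: RZProfile, samples, target_id: str, k: float | None = None) -> SelectivityAnnotation:
    """Four-way selectivity call for one antibody.

    on = mean R.Z over samples containing the target above threshold;
    cross = any single sample containing a different construct above
    threshold (mock wells can never trigger it).  Categories:
    on & !cross -> on_target; on & cross -> co_target;
    !on & cross -> off_target; neither -> no_target.
    """
    threshold = profile.threshold_at(profile.k if k is None else k)
    construct_of = {s.sample_id: s.construct for s in samples}
    rz = profile.rz.dropna()

    target_vals = [v for sid, v in rz.items() if construct_of.get(sid) == target_id]
    if not target_vals:
        raise ValueError(
            f"no QC-passing samples expressing target {target_id!r} in the panel "
            f"of antibody {profile.antibody_id} (design flaw, not no_target)"
        )
    on_mean = float(np.mean(target_vals))
    on_flag = on_mean > threshold

    events = {}
    for sid, v in rz.items():
        g = construct_of.get(sid)
        if g is None or g == target_id or g == "MOCK":
            continue
        if v > threshold:
            ev = events.setdefault(g, [0, -math.inf])
            ev[0] += 1
            ev[1] = max(ev[1], float(v))
    cross_flag = bool(events)

    if on_flag and not cross_flag:
        category = "on_target"
    elif on_flag and cross_flag:
        category = "co_target"
    elif cross_flag:
        category = "off_target"
    else:
        category = "no_target"
    return SelectivityAnnotation(
        antibody_id=profile.antibody_id,
        category=category,
        on_target_mean_rz=on_mean,
        threshold=threshold,
        offtarget_events=[
            OffTargetEvent(g, n, mx) for g, (n, mx) in sorted(events.items())
        ],
    )


def classify_all(
    matrix: AssayMatrix,
    antibodies,
    samples,
    excluded_beads=(),
    k: float = DEFAULT_K,
):
    """Profiles + annotations for every QC-passing anti-GPCR antibody."""
    excluded = set(excluded_beads)
    profiles, annotations = {}, []
    for ab in antibodies:
        if ab.is_control or ab.bead_id in excluded:
            continue
        prof = rz_profile(matrix, ab, samples, k=k)
        profiles[ab.antibody_id] = prof
        annotations.append(classify_antibody(prof, samples, ab.target_id))
    return profiles, annotations


def threshold_sweep(profiles: dict, antibodies, samples, k_grid) -> pd.DataFrame:
    """Counts of each category as a function of the SD multiplier k.

    Profiles are computed once; only the threshold moves with k.  Used to
    justify the default k = 12 (where the on-target count plateaus).
    """
    target_of = {ab.antibody_id: ab.target_id for ab in antibodies}
    rows = []
    for k in k_grid:
        counts = dict.fromkeys(CATEGORIES, 0)
        for ab_id, prof in profiles.items():
            ann = classify_antibody(prof, samples, target_of[ab_id], k=k)
            counts[ann.category] += 1
        rows.append(
            {
                "k": k,
                "on_target": counts["on_target"],
                "co_target": counts["co_target"],
                "off_target": counts["off_target"],
                "no_target": counts["no_target"],
                "cross_reactive": counts["co_target"] + counts["off_target"],
            }
        )
    return pd.DataFrame(rows)


def _pct1(k: int, n: int) -> float:
    return round(100.0 * k / n, 1) if n else math.nan


def int_percent(k: int, n: int) -> int:
    """Integer percentage as printed in narrative text: one-decimal value,
    then half-up to the nearest integer (so 19.5% prints as 20%)."""
    p = round(100.0 * k / n, 1)
    return int(math.floor(p + 0.5))


def summarize_classifications(annotations, manifest) -> pd.DataFrame:
    """Per-subfamily and total category counts with one-decimal percentages."""
    panel_of = {ab.antibody_id: ab.subfamily_panel for ab in manifest}
    rows = []
    by_fam = {}
    for ann in annotations:
        by_fam.setdefault(panel_of[ann.antibody_id], []).append(ann)
    fams = [f for f in SUBFAMILIES if f in by_fam]
    for fam in fams + ["Total"]:
        anns = by_fam.get(fam, []) if fam != "Total" else annotations
        n = len(anns)
        counts = {c: sum(1 for a in anns if a.category == c) for c in CATEGORIES}
        rows.append(
            {
                "Subfamily": fam,
                "Abs (N)": n,
                "On-target (%)": _pct1(counts["on_target"], n),
                "Co-target (%)": _pct1(counts["co_target"], n),
                "Off-target (%)": _pct1(counts["off_target"], n),
                "No target (%)": _pct1(counts["no_target"], n),
            }
        )
    return pd.DataFrame(rows)


def remaining_breakdown(annotations) -> dict:
    """Breakdown of non-on-target antibodies, integer percentages."""
    rest = [a for a in annotations if a.category != "on_target"]
    n = len(rest)
    if n == 0:
        return {"n": 0, "co_target_pct": math.nan, "off_target_pct": math.nan, "no_target_pct": math.nan}
    counts = {c: sum(1 for a in rest if a.category == c) for c in CATEGORIES[1:]}
    return {
        "n": n,
        "co_target_pct": int_percent(counts["co_target"], n),
        "off_target_pct": int_percent(counts["off_target"], n),
        "no_target_pct": int_percent(counts["no_target"], n),
    }


def rz_long_table(profiles: dict, samples) -> pd.DataFrame:
    """Long-format R.Z export (antibody, sample, construct, rz) for plotting."""
    construct_of = {s.sample_id: s.construct for s in samples}
    rows = []
    for ab_id, prof in profiles.items():
        for sid, v in prof.rz.items():
            rows.append(
                {
                    "antibody_id": ab_id,
                    "sample_id": sid,
                    "construct": construct_of.get(sid, ""),
                    "rz": v,
                    "threshold": prof.threshold,
                }
            )
    return pd.DataFrame(rows)
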