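"""Agreement between paired antibodies raised against a common target.

Independent antibodies recognising the same receptor should rank samples
similarly; Pearson correlation of their robust-Z profiles over shared
QC-passing samples quantifies that agreement, and the summary counts how
many multi-antibody targets are actually recognised by at least two of
their antibodies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .selectivity import int_percent


@dataclass
class PairResult:
    target_id: str
    antibody_a: str
    antibody_b: str
    pearson_r: float
    n_samples: int


def pair_correlations(profiles: dict, manifest) -> list:
    """Pearson r over shared samples for every unordered pair sharing a target.

    Correlations use the per-antibody robust-Z vectors (each antibody's own
    scaling), restricted to samples where both profiles pass QC; pairs with
    fewer than 3 shared samples are skipped with a warning.
    """
    by_target = {}
    for ab in manifest:
        if ab.is_control or ab.antibody_id not in profiles:
            continue
        by_target.setdefault(ab.target_id, []).append(ab.antibody_id)
    results = []
    for target, ab_ids in sorted(by_target.items()):
        for i, a in enumerate(ab_ids):
            for b in ab_ids[i + 1 :]:
                ra, rb = profiles[a].rz, profiles[b].rz
                joined = pd.concat([ra, rb], axis=1, keys=["a", "b"]).dropna()
                if len(joined) < 3:
                    warnings.warn(
                        f"pair ({a}, {b}) shares only {len(joined)} QC-passing samples; skipped"
                    )
                    continue
                if joined["a"].std() == 0 or joined["b"].std() == 0:
                    warnings.warn(f"pair ({a}, {b}) has a constant profile; skipped")
                    continue
                r = float(stats.pearsonr(joined["a"], joined["b"]).statistic)
                results.append(PairResult(target, a, b, r, len(joined)))
    return results


def pair_summary(pairs, annotations, manifest) -> dict:
    """Headline counts: multi-antibody targets, targets recognised by >=2 antibodies.

    'Recognised' counts on_target and co_target calls (both detect the
    intended receptor above threshold).  Percentages are integers (half-up
    from the one-decimal value); NA when there is no denominator.
    """
    category = {a.antibody_id: a.category for a in annotations}
    by_target = {}
    for ab in manifest:
        if ab.is_control or ab.antibody_id not in category:
            continue
        by_target.setdefault(ab.target_id, []).append(ab.antibody_id)

    n_targets = len(by_target)
    multi = {t: ids for t, ids in by_target.items() if len(ids) >= 2}
    recognised2 = [
        t
        for t, ids in multi.items()
        if sum(1 for i in ids if category[i] in ("on_target", "co_target")) >= 2
    ]
    rs = [p.pearson_r for p in pairs]
    return {
        "n_targets": n_targets,
        "n_multi_ab_targets": len(multi),
        "pct_multi_ab_targets": int_percent(len(multi), n_targets) if n_targets else math.nan,
        "n_recognised_by_2plus": len(recognised2),
        "pct_recognised_by_2plus": int_percent(len(recognised2), len(multi)) if multi else math.nan,
        "n_pairs": len(pairs),
        "mean_r": float(np.mean(rs)) if rs else math.nan,
        "median_r": float(np.median(rs)) if rs else math.nan,
    }


def pairs_table(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_id": p.target_id,
                "antibody_a": p.antibody_a,
                "antibody_b": p.antibody_b,
                "pearson_r": p.pearson_r,
                "n_samples": p.n_samples,
            }
            for p in pairs
        ],
        columns=["target_id", "antibody_a", "antibody_b", "pearson_r", "n_samples"],
    )
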