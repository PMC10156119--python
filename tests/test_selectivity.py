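"""Robust Z-scoring, threshold estimation and the four-way selectivity rule."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import sbaval as sv
from sbaval.selectivity import (
    DegenerateDistributionError,
    RZProfile,
    int_percent,
    remaining_breakdown,
)


def test_robust_z_hand_arithmetic():
    rz = sv.robust_z([10, 12, 11, 13, 200])
    # median 12, MAD 1 -> rz(200) = 188 / 1.4826
    assert rz[-1] == pytest.approx(188 / 1.4826, abs=1e-6)
    assert rz[-1] == pytest.approx(126.80, abs=0.01)
    assert rz[1] == 0.0  # the median element


def test_robust_z_degenerate_names_antibody():
    with pytest.raises(DegenerateDistributionError, match="AB42"):
        sv.robust_z([5, 5, 5, 5], label="AB42")


def test_robust_z_affine_invariance():
    rng = np.random.default_rng(11)
    for _ in range(50):
        y = rng.normal(size=20)
        a, c = rng.uniform(0.1, 10), rng.uniform(-5, 5)
        assert np.allclose(sv.robust_z(a * y + c), sv.robust_z(y), atol=1e-9)


def test_density_peak_behaviour():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(10000)
    assert abs(sv.density_peak(x)) < 0.1
    assert sv.density_peak(np.full(10, 3.5)) == 3.5
    bimodal = np.concatenate([rng.standard_normal(9500), rng.normal(50, 1, 500)])
    assert abs(sv.density_peak(bimodal)) < 0.2


def test_negative_sd_estimator():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(10000)
    peak = sv.density_peak(x)
    sigma = sv.negative_sd(x, peak)
    assert 0.9 < sigma < 1.1
    # symmetric data: the mirrored upper-tail estimate agrees within 5%
    # in expectation (resampling over independent draws)
    lowers, uppers = [], []
    for _ in range(30):
        y = rng.standard_normal(10000)
        pk = sv.density_peak(y)
        lowers.append(sv.negative_sd(y, pk))
        uppers.append(1.4826 * np.median(np.abs(y[y >= pk] - pk)))
    assert abs(np.mean(lowers) / np.mean(uppers) - 1.0) < 0.05
    # upper-tail contamination leaves the estimator unchanged
    contaminated = np.concatenate([x, rng.normal(80, 2, 300)])
    assert sv.negative_sd(contaminated, peak) == sv.negative_sd(x, peak)


def _profile(rz_by_sample, peak=0.0, sigma=1.0, k=12.0):
    return RZProfile(
        antibody_id="AB1",
        rz=pd.Series(rz_by_sample),
        median_mfi=100.0,
        mad_mfi=5.0,
        density_peak=peak,
        sigma_neg=sigma,
        k=k,
    )


def _samples(constructs):
    return [
        sv.SampleRecord(sid, g, i + 1, 1, "rhodopsin_alpha")
        for i, (sid, g) in enumerate(constructs.items())
    ]


def test_classification_rule_four_ways():
    samples = _samples({"t1": "T", "t2": "T", "o1": "O", "m1": "MOCK"})
    # threshold = 0 + 12*1 = 12
    cases = [
        ({"t1": 30, "t2": 30, "o1": 5, "m1": 0}, "on_target"),
        ({"t1": 30, "t2": 30, "o1": 25, "m1": 0}, "co_target"),
        ({"t1": 5, "t2": 5, "o1": 25, "m1": 0}, "off_target"),
        ({"t1": 5, "t2": 5, "o1": 5, "m1": 0}, "no_target"),
    ]
    for rz, expected in cases:
        ann = sv.classify_antibody(_profile(rz), samples, "T")
        assert ann.category == expected, expected
    co = sv.classify_antibody(_profile(cases[1][0]), samples, "T")
    assert co.offtarget_events[0].gpcr_id == "O"
    assert co.offtarget_events[0].max_rz == 25
    on = sv.classify_antibody(_profile(cases[0][0]), samples, "T")
    assert on.offtarget_events == []


def test_mock_never_triggers_cross_reactivity():
    samples = _samples({"t1": "T", "o1": "O", "m1": "MOCK"})
    ann = sv.classify_antibody(_profile({"t1": 30, "o1": 5, "m1": 99}), samples, "T")
    assert ann.category == "on_target"


def test_masked_samples_are_ignored():
    samples = _samples({"t1": "T", "o1": "O", "o2": "O", "m1": "MOCK"})
    rz = {"t1": 30.0, "o1": math.nan, "o2": 5.0, "m1": 0.0}
    ann = sv.classify_antibody(_profile(rz), samples, "T")
    assert ann.category == "on_target"


def test_missing_target_samples_is_an_error():
    samples = _samples({"o1": "O", "m1": "MOCK"})
    with pytest.raises(ValueError, match="design flaw"):
        sv.classify_antibody(_profile({"o1": 5, "m1": 0}), samples, "T")


def test_scaling_mfi_preserves_profile_and_category(dataset, run_result):
    """Multiplying one antibody's MFI by a positive constant changes nothing."""
    ab = next(a for a in dataset.antibodies if not a.is_control)
    masked, _ = sv.filter_bead_counts(dataset.matrix)
    scaled = masked.copy()
    scaled.mfi[ab.bead_id] = scaled.mfi[ab.bead_id] * 37.5
    p1 = sv.rz_profile(masked, ab, dataset.samples)
    p2 = sv.rz_profile(scaled, ab, dataset.samples)
    assert np.allclose(p1.rz.dropna(), p2.rz.dropna())
    a1 = sv.classify_antibody(p1, dataset.samples, ab.target_id)
    a2 = sv.classify_antibody(p2, dataset.samples, ab.target_id)
    assert a1.category == a2.category


def test_partition_is_exhaustive_and_exclusive(run_result, dataset):
    scored = {a.antibody_id for a in run_result.annotations}
    expected = {
        a.antibody_id
        for a in dataset.antibodies
        if not a.is_control and a.bead_id not in run_result.failed_beads
    }
    assert scored == expected
    assert all(a.category in sv.selectivity.CATEGORIES for a in run_result.annotations)


def test_threshold_sweep_monotonicity(run_result, dataset):
    sweep = run_result.sweep
    # antibodies with any sample above threshold = co+off+on contributions;
    # the count of antibodies with >= 1 sample above is non-increasing in k
    above = (
        sweep["on_target"] + sweep["co_target"] + sweep["off_target"]
    )  # no_target = nothing above
    assert (above.diff().dropna() <= 0).all()
    # per antibody, the set of samples above threshold shrinks as k grows
    for prof in list(run_result.profiles.values())[:10]:
        counts = [(prof.rz.dropna() > prof.threshold_at(k)).sum() for k in (0, 4, 8, 12, 20)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_threshold_sweep_k0_leaves_no_silent_antibody(run_result):
    row0 = run_result.sweep[run_result.sweep["k"] == 0].iloc[0]
    assert row0["no_target"] == 0
    k12 = run_result.sweep[run_result.sweep["k"] == 12]["cross_reactive"].iloc[0]
    k4 = run_result.sweep[run_result.sweep["k"] == 4]["cross_reactive"].iloc[0]
    assert k12 <= k4


def _fake_annotations(counts):
    anns, i = [], 0
    for cat, n in counts.items():
        for _ in range(n):
            i += 1
            anns.append(sv.SelectivityAnnotation(f"AB{i}", cat, 0.0, 10.0))
    return anns


def test_summary_percentages_from_printed_counts():
    counts = {"on_target": 248, "co_target": 15, "off_target": 31, "no_target": 113}
    anns = _fake_annotations(counts)
    manifest = [
        sv.AntibodyRecord(a.antibody_id, 1000 + i, "X", "rhodopsin_alpha")
        for i, a in enumerate(anns)
    ]
    lib = [sv.GPCRRecord("X", "rhodopsin_alpha", "ACDEF")]
    table = sv.summarize_classifications(anns, manifest)
    total = table[table["Subfamily"] == "Total"].iloc[0]
    assert total["Abs (N)"] == 407
    assert [
        total["On-target (%)"], total["Co-target (%)"],
        total["Off-target (%)"], total["No target (%)"],
    ] == [60.9, 3.7, 7.6, 27.8]

    rest = remaining_breakdown(anns)
    assert rest["n"] == 159
    assert (rest["co_target_pct"], rest["off_target_pct"], rest["no_target_pct"]) == (9, 20, 71)

    all_on = _fake_annotations({"on_target": 10})
    manifest10 = [
        sv.AntibodyRecord(a.antibody_id, 2000 + i, "X", "rhodopsin_alpha")
        for i, a in enumerate(all_on)
    ]
    t2 = sv.summarize_classifications(all_on, manifest10)
    row = t2[t2["Subfamily"] == "Total"].iloc[0]
    assert row["On-target (%)"] == 100.0 and row["No target (%)"] == 0.0


def test_int_percent_half_up_from_one_decimal():
    assert int_percent(31, 159) == 20  # 19.497 -> 19.5 -> 20
    assert int_percent(15, 159) == 9
    assert int_percent(116, 205) == 57
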