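"""Bead-count masking, coupling QC and the mock-contrast expression test."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import sbaval as sv


def _matrix(mfi, counts, beads):
    index = pd.Index([f"S{i}" for i in range(len(mfi))], name="sample_id")
    return sv.AssayMatrix(
        pd.DataFrame(np.asarray(mfi, dtype=float), index=index, columns=beads),
        pd.DataFrame(np.asarray(counts, dtype=int), index=index, columns=beads),
    )


def test_filter_bead_counts_masks_exact_cells():
    m = _matrix([[10, 20], [30, 40], [50, 60]], [[50, 50], [31, 50], [50, 50]], [1, 2])
    masked, mask = sv.filter_bead_counts(m, min_events=32)
    assert mask.to_numpy().sum() == 1
    assert bool(mask.iloc[1, 0])
    assert math.isnan(masked.mfi.iloc[1, 0])
    assert masked.mfi.iloc[0, 0] == 10

    same, mask0 = sv.filter_bead_counts(m, min_events=0)
    assert not mask0.to_numpy().any()
    assert same.mfi.equals(m.mfi)


def test_coupling_qc_flags_low_beads():
    coupling = _matrix([[5000, 999], [5000, 999], [5000, 999]], [[100] * 2] * 3, [1, 2])
    assert sv.coupling_qc(coupling, [1, 2], floor=1000) == [2]
    assert sv.coupling_qc(coupling, [1, 2], floor=0) == []
    assert sv.coupling_qc(coupling, [1], floor=1000) == []


def _expression_fixture(construct_mult, sigma=0.05, n=4, seed=0):
    """One panel, one construct vs mock, measured on the anti-FLAG bead."""
    rng = np.random.default_rng(seed)
    library = [sv.GPCRRecord("GPR_A", "rhodopsin_alpha", "ACDEFGHIKLMNPQRSTVWY" * 5)]
    antibodies = [sv.AntibodyRecord("CTRL", 900, "anti-FLAG", "rhodopsin_alpha")]
    samples = [sv.SampleRecord(f"A.b{i}", "GPR_A", i, 1, "rhodopsin_alpha") for i in range(1, n + 1)]
    samples += [sv.SampleRecord(f"M.b{i}", "MOCK", i, 1, "rhodopsin_alpha") for i in range(1, 5)]
    mock_level = 100.0
    vals = []
    for s in samples:
        base = mock_level * (construct_mult if not s.is_mock else 1.0)
        vals.append(base * math.exp(rng.normal(0, sigma)))
    matrix = _matrix([[v] for v in vals], [[100]] * len(vals), [900])
    matrix.mfi.index = pd.Index([s.sample_id for s in samples], name="sample_id")
    matrix.bead_count.index = matrix.mfi.index
    return matrix, samples, antibodies, library


def test_construct_equal_to_mock_not_supported():
    matrix, samples, antibodies, library = _expression_fixture(1.0)
    (res,) = sv.assess_expression(matrix, samples, antibodies, library)
    assert res.status == "uncertain"
    assert res.dunnett_p > 0.05


def test_strong_construct_supported():
    matrix, samples, antibodies, library = _expression_fixture(100.0, sigma=0.01)
    (res,) = sv.assess_expression(matrix, samples, antibodies, library)
    assert res.status == "supported"
    assert res.dunnett_p < 0.001
    assert res.mean_log2 > float(np.mean(res.mock_log2_levels))


def test_single_replicate_is_uncertain_with_na():
    matrix, samples, antibodies, library = _expression_fixture(100.0, n=1)
    (res,) = sv.assess_expression(matrix, samples, antibodies, library)
    assert res.status == "uncertain"
    assert math.isnan(res.dunnett_p)


def test_supported_implies_mean_above_mock(run_result):
    for r in run_result.expression:
        if r.status == "supported":
            assert r.mean_log2 > float(np.mean(r.mock_log2_levels))


def test_no_failures_and_strong_expression_mostly_supported():
    """With failure probability 0, >=95% of constructs are supported (20 seeds)."""
    rates = []
    for seed in range(1, 21):
        config = sv.SimulationConfig(seed=seed, failure_probs={})
        ds = sv.generate_dataset(config)
        masked, _ = sv.filter_bead_counts(ds.matrix)
        results = sv.assess_expression(masked, ds.samples, ds.antibodies, ds.library)
        rates.append(np.mean([r.status == "supported" for r in results]))
    assert np.mean(rates) >= 0.95


def test_expression_summary_percentages():
    """Printed-count check: 182 supported of 215 -> 84.7% total."""
    per_fam = {
        "rhodopsin_alpha": (59, 55),
        "rhodopsin_beta": (21, 18),
        "rhodopsin_gamma": (51, 44),
        "rhodopsin_delta": (46, 34),
        "GSAF": (29, 25),
        "other": (9, 6),
    }
    library, results = [], []
    for fam, (n, k) in per_fam.items():
        for i in range(n):
            gid = f"{fam}_{i}"
            library.append(sv.GPCRRecord(gid, fam, "ACDEFGHIK"))
            results.append(
                sv.ExpressionResult(
                    gid, fam, np.array([1.0]), np.array([0.0]), 0.01,
                    0.01 if i < k else 0.5,
                    "supported" if i < k else "uncertain",
                )
            )
    table = sv.expression_summary(results, library)
    total = table[table["Subfamily"] == "Total"].iloc[0]
    assert total["GPCRs (N)"] == 215
    assert total["Expressed (%)"] == 84.7
    # percentages are counts-consistent per subfamily
    for fam, (n, k) in per_fam.items():
        row = table[table["Subfamily"] == fam].iloc[0]
        assert row["Expressed (%)"] == round(100.0 * k / n, 1)

    all_sup = [r for r in results if r.status == "supported"]
    lib_sup = [g for g in library if any(r.gpcr_id == g.gpcr_id for r in all_sup[:20])]
    t2 = sv.expression_summary(all_sup[:20], lib_sup)
    assert t2[t2["Subfamily"] == "Total"]["Expressed (%)"].iloc[0] == 100.0


def test_empty_subfamily_row_omitted_with_warning():
    library = [sv.GPCRRecord("A1", "rhodopsin_alpha", "ACDEF"), sv.GPCRRecord("B1", "other", "ACDEF")]
    results = [
        sv.ExpressionResult("A1", "rhodopsin_alpha", np.array([1.0]), np.array([0.0]), 0.01, 0.01, "supported")
    ]
    with pytest.warns(UserWarning, match="other"):
        table = sv.expression_summary(results, library)
    assert "other" not in set(table["Subfamily"])
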