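"""Generator behaviour: determinism, planted structure, signal model limits."""

import math
import warnings

import numpy as np
import pytest

import sbaval as sv
from sbaval.pipeline import RunConfig, run_stages
from sbaval.simulate import make_samples, segment_span


def _segment(record, config):
    start, end = segment_span(config)
    return record.sequence[start - 1 : end]


def test_same_seed_byte_identical_files(tmp_path):
    config = sv.SimulationConfig(seed=7)
    sv.generate_dataset(config, outdir=tmp_path / "a")
    sv.generate_dataset(sv.SimulationConfig(seed=7), outdir=tmp_path / "b")
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


def test_shared_segment_homology_structure():
    config = sv.SimulationConfig(seed=3, mutation_rate=0.0)
    library = sv.simulate_library(config)
    by_fam = {}
    for g in library:
        by_fam.setdefault(g.subfamily, []).append(g)
    # mutation rate 0: segments identical within a subfamily
    for fam, members in by_fam.items():
        segs = {_segment(g, config) for g in members}
        assert len(segs) == 1, fam
    # no shared ancestral segment across subfamilies
    across = {_segment(members[0], config) for members in by_fam.values()}
    assert len(across) == len(by_fam)


def test_failure_probability_one_matches_mock():
    config = sv.SimulationConfig(
        seed=5, failure_probs={f: 1.0 for f in sv.simulate.SUBFAMILIES}
    )
    library = sv.simulate_library(config)
    samples = make_samples(config, library)
    levels = sv.simulate_expression(config, library, samples)
    construct_levels = [v for (g, s), v in levels.items() if g != "MOCK"]
    mock_levels = [v for (g, s), v in levels.items() if g == "MOCK"]
    ratio = np.mean(construct_levels) / np.mean(mock_levels)
    assert 0.7 < ratio < 1.4


def test_sigma_e_zero_gives_equal_replicates():
    config = sv.SimulationConfig(seed=5, sigma_e=0.0, failure_probs={})
    library = sv.simulate_library(config)
    samples = make_samples(config, library)
    levels = sv.simulate_expression(config, library, samples)
    vals = {v for (g, s), v in levels.items() if g != "MOCK"}
    assert len(vals) == 1


def test_expression_fold_monte_carlo():
    """Mean expressed level / mean mock level ~ configured fold (n = 10,000)."""
    config = sv.SimulationConfig(
        seed=11,
        n_gpcrs_per_subfamily={"rhodopsin_alpha": 500},
        n_mock_per_panel=10000,
        n_bio_replicates=20,
        failure_probs={},
    )
    library = sv.simulate_library(config)
    samples = make_samples(config, library)
    levels = sv.simulate_expression(config, library, samples)
    expressed = [v for (g, s), v in levels.items() if g != "MOCK"]
    mock = [v for (g, s), v in levels.items() if g == "MOCK"]
    assert len(expressed) >= 10000
    fold = np.mean(expressed) / np.mean(mock)
    assert abs(fold - config.expression_fold) / config.expression_fold < 0.10


def test_signal_model_closed_form_and_saturation():
    config = sv.SimulationConfig(seed=2, sigma_n=0.0, dropout_rate=0.0)
    ds = sv.generate_dataset(config)
    levels = ds.truth.sample_levels
    ab = next(
        a for a in ds.antibodies
        if not a.is_control and ds.truth.antibodies[a.antibody_id].planted_class == "on"
    )
    truth = ds.truth.antibodies[ab.antibody_id]
    for s in ds.samples:
        expected = config.background
        if not s.is_mock:
            expected += truth.affinities.get(s.construct, 0.0) * levels[s.sample_id]
        expected = min(config.saturation, expected)
        assert ds.matrix.mfi.loc[s.sample_id, ab.bead_id] == pytest.approx(expected)

    # planted no-binders: every MFI within noise of the background
    none_ab = next(
        a for a in ds.antibodies
        if not a.is_control and ds.truth.antibodies[a.antibody_id].planted_class == "none"
    )
    col = ds.matrix.mfi[none_ab.bead_id]
    assert np.allclose(col, config.background)

    # affinity * level >> saturation caps at S
    big = sv.SimulationConfig(seed=2, sigma_n=0.0, a_on=1e9, dropout_rate=0.0)
    ds_big = sv.generate_dataset(big)
    ab_big = next(
        a for a in ds_big.antibodies
        if not a.is_control and ds_big.truth.antibodies[a.antibody_id].planted_class == "on"
    )
    target_samples = [s.sample_id for s in ds_big.samples if s.construct == ab_big.target_id]
    assert np.allclose(ds_big.matrix.mfi.loc[target_samples, ab_big.bead_id], big.saturation)


def test_all_none_fractions_classify_no_target():
    config = sv.SimulationConfig(seed=1, class_fractions={"on": 0, "co": 0, "off": 0, "none": 1})
    ds = sv.generate_dataset(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_stages(
            ds.matrix, ds.coupling, ds.antibodies, ds.samples, ds.library, RunConfig(seed=1)
        )
    assert all(a.category == "no_target" for a in res.annotations)


def test_on_target_rz_monotone_in_affinity():
    """Raising on-target affinity never lowers mean on-target R.Z (20 seeds)."""
    def mean_on_rz(a_on, seed):
        ds = sv.generate_dataset(sv.SimulationConfig(seed=seed, a_on=a_on))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_stages(
                ds.matrix, ds.coupling, ds.antibodies, ds.samples, ds.library, RunConfig(seed=seed)
            )
        vals = [
            ann.on_target_mean_rz
            for ann in res.annotations
            if ds.truth.antibodies[ann.antibody_id].planted_class == "on"
        ]
        return float(np.mean(vals))

    lows = [mean_on_rz(5.0, s) for s in range(1, 21)]
    highs = [mean_on_rz(20.0, s) for s in range(1, 21)]
    assert np.mean(highs) >= np.mean(lows)


def test_ground_truth_affinity_invariants(dataset):
    for ab_id, t in dataset.truth.antibodies.items():
        if t.planted_class == "on":
            assert len(t.affinities) == 1
        if t.planted_class == "none":
            assert t.affinities == {}
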