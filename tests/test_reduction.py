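"""Averaging windows, background subtraction, LOQ and filter rules."""

import numpy as np
import pytest

from conftest import make_run
from ptrvoc.reduction import (
    ExclusionEntry,
    ExclusionList,
    ReductionConfig,
    average_background,
    average_sample_window,
    build_feature_matrix,
    compute_loq,
    default_exclusion_list,
    read_peak_table_csv,
    reduce_run,
    write_peak_table_csv,
    write_reduced_tsv,
    read_reduced_tsv,
)

CFG = ReductionConfig()


def test_sample_window_constant_trace():
    run = make_run(np.zeros((60, 1)), np.full((100, 1), 5.0), [100.0])
    assert average_sample_window(run, "100.000", CFG) == 5.0


def test_sample_window_is_cycles_21_to_80():
    # sample-block value at cycle t equals t -> mean over cycles 21..80 is 50.5
    run = make_run(np.zeros((60, 1)), np.arange(1, 101, dtype=float)[:, None], [100.0])
    assert average_sample_window(run, "100.000", CFG) == 50.5


def test_sample_window_matches_direct_summation(rng):
    trace = 10.0 * np.exp(-1e-3 * np.arange(200)) + rng.normal(0, 0.1, 200)
    run = make_run(np.zeros((60, 1)), trace[:, None], [100.0])
    assert average_sample_window(run, "100.000", CFG) == pytest.approx(
        sum(trace[20:80]) / 60.0, abs=1e-12
    )


def test_sample_window_too_short():
    run = make_run(np.zeros((60, 1)), np.zeros((79, 1)), [100.0])
    with pytest.raises(ValueError, match="shorter"):
        average_sample_window(run, "100.000", CFG)


def test_background_mean_and_population_sd():
    # 30 cycles at -1 and 30 at +1 in the final window: mean 0, population SD 1
    bg = np.concatenate([-np.ones(30), np.ones(30)])[:, None]
    run = make_run(bg, np.zeros((80, 1)), [100.0])
    mean, sd = average_background(run, "100.000", CFG)
    assert mean == 0.0
    assert sd == 1.0


def test_background_uses_last_window():
    bg = np.concatenate([np.full(40, 100.0), np.zeros(60)])[:, None]
    run = make_run(bg, np.zeros((80, 1)), [100.0])
    mean, _sd = average_background(run, "100.000", CFG)
    assert mean == 0.0


def test_background_sd_estimator_unbiased(rng):
    sds = []
    for _ in range(1000):
        bg = rng.normal(0, 0.3, (60, 1))
        run = make_run(bg, np.zeros((80, 1)), [100.0])
        sds.append(average_background(run, "100.000", CFG)[1])
    assert np.mean(sds) == pytest.approx(0.3, rel=0.02)


@pytest.mark.parametrize("sd, expected", [(0.0, 0.0), (1.0, 10.0), (0.37, 3.7)])
def test_loq_is_ten_times_background_sd(sd, expected):
    assert compute_loq(sd, CFG) == pytest.approx(expected)


def test_loq_rejects_negative_sd():
    with pytest.raises(ValueError):
        compute_loq(-0.1, CFG)


def _toy_run(values_by_mz):
    mzs = list(values_by_mz)
    sample = np.tile(np.array([values_by_mz[mz] for mz in mzs]), (100, 1))
    return make_run(np.zeros((60, len(mzs))), sample, mzs)


def test_reduce_run_hand_enumerated_filters():
    run = _toy_run({15.0: 5.0, 305.0: 5.0, 50.0: -0.1, 63.024: 20.0, 137.060: 5.0})
    reduced = reduce_run(run, CFG)
    assert reduced.retained_ids == ["63.024", "137.060"]
    assert reduced.table.at["15.000", "flags"] == frozenset({"out_of_range"})
    assert reduced.table.at["305.000", "flags"] == frozenset({"out_of_range"})
    assert "negative" in reduced.table.at["50.000", "flags"]


def test_mz_bounds_are_inclusive():
    reduced = reduce_run(_toy_run({15.993: 5.0, 300.066: 5.0}), CFG)
    assert reduced.retained_ids == ["15.993", "300.066"]


def test_all_zero_run_retains_nothing():
    run = make_run(np.zeros((60, 3)), np.zeros((100, 3)), [50.0, 60.0, 70.0])
    reduced = reduce_run(run, CFG)
    assert reduced.retained_ids == []


def test_exclusion_list_matching():
    cfg = ReductionConfig(exclusion=default_exclusion_list())
    reduced = reduce_run(_toy_run({19.018: 50.0, 19.030: 50.0}), cfg)
    assert "excluded" in reduced.table.at["19.018", "flags"]
    assert reduced.table.at["19.030", "retained"]
    with pytest.raises(ValueError):
        ExclusionEntry(19.018, tolerance=0.0, reason="bad")


def test_retained_iff_no_flags_and_constant_offset_invariance(rng):
    run = _random_run(rng)
    reduced = reduce_run(run, CFG)
    assert (reduced.table["retained"] == (reduced.table["flags"] == frozenset())).all()
    # adding a constant to both blocks of a channel leaves net_conc unchanged
    shifted = make_run(
        run.background.to_numpy() + 3.7,
        run.sample.to_numpy() + 3.7,
        run.channel_mz.to_numpy(),
        sample_id=run.sample_id,
    )
    shifted_reduced = reduce_run(shifted, CFG)
    assert np.allclose(
        reduced.table["net_conc"], shifted_reduced.table["net_conc"], atol=1e-10
    )


def _random_run(rng, n_channels=6, sample_id="r"):
    mzs = np.round(rng.uniform(10.0, 310.0, n_channels), 3)
    bg = rng.normal(0, 0.3, (70, n_channels))
    sm = rng.normal(rng.uniform(-1, 4, n_channels), 0.3, (120, n_channels))
    return make_run(bg, sm, mzs, sample_id=sample_id)


def brute_force_reduce(run, cfg):
    """Straight-line reference: python loops over the written rules."""
    out = {}
    for cid in run.channels:
        sm = list(run.sample[cid])
        bg = list(run.background[cid])[-cfg.background_window:]
        sample_mean = sum(sm[cfg.skip_cycles : cfg.skip_cycles + cfg.sample_window]) / cfg.sample_window
        bg_mean = sum(bg) / len(bg)
        bg_sd = (sum((x - bg_mean) ** 2 for x in bg) / len(bg)) ** 0.5
        net = sample_mean - bg_mean
        mz = float(run.channel_mz[cid])
        flags = set()
        if net <= 0:
            flags.add("negative")
        if net < cfg.loq_factor * bg_sd:
            flags.add("below_loq")
        if not (cfg.mz_min <= mz <= cfg.mz_max):
            flags.add("out_of_range")
        if any(abs(mz - e.mz) <= e.tolerance for e in cfg.exclusion.entries):
            flags.add("excluded")
        out[cid] = (net, frozenset(flags))
    return out


def test_reduce_run_equals_brute_force_reference():
    rng = np.random.default_rng(99)
    for _ in range(100):
        run = _random_run(rng)
        reduced = reduce_run(run, CFG)
        oracle = brute_force_reduce(run, CFG)
        for cid, (net, flags) in oracle.items():
            assert reduced.table.at[cid, "net_conc"] == pytest.approx(net, abs=1e-10)
            assert reduced.table.at[cid, "flags"] == flags


def test_filter_monotonicity(rng):
    run = _random_run(rng, n_channels=12)
    base = set(reduce_run(run, ReductionConfig(loq_factor=5.0)).retained_ids)
    stricter = set(reduce_run(run, ReductionConfig(loq_factor=20.0)).retained_ids)
    assert stricter <= base
    narrow = set(reduce_run(run, ReductionConfig(mz_min=50.0, mz_max=200.0)).retained_ids)
    wide = set(reduce_run(run, ReductionConfig(mz_min=10.0, mz_max=400.0)).retained_ids)
    assert narrow <= wide


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------


def _reduced(sample_id, values_by_mz):
    run = _toy_run(values_by_mz)
    run.sample_id = sample_id
    return reduce_run(run, CFG)


def test_feature_matrix_shared_channels_no_fill():
    a = _reduced("a", {63.0: 5.0, 70.0: 2.0})
    b = _reduced("b", {63.0: 6.0, 70.0: 3.0})
    fm = build_feature_matrix([a, b, _reduced("c", {63.0: 4.0, 70.0: 1.0})])
    assert list(fm.values.columns) == ["63.000", "70.000"]
    assert fm.values.loc["a", "63.000"] == pytest.approx(5.0)


def test_feature_matrix_fill_in_uses_net_value():
    a = _reduced("a", {63.0: 5.0, 70.0: 2.0})
    b = _reduced("b", {63.0: 6.0, 70.0: -0.5})  # 70 filtered in b (negative)
    c = _reduced("c", {63.0: 6.0, 70.0: 2.5})
    fm = build_feature_matrix([a, b, c])
    assert "70.000" in fm.values.columns
    assert fm.values.loc["b", "70.000"] == pytest.approx(-0.5)


def test_feature_matrix_union_size_oracle(rng):
    tables = [_random_and_reduce(rng, f"s{i}") for i in range(5)]
    fm = build_feature_matrix(tables)
    union = set()
    for t in tables:
        union |= set(t.retained_ids)
    assert fm.values.shape[1] == len(union)


def _random_and_reduce(rng, sample_id):
    return reduce_run(_random_run(rng, n_channels=8, sample_id=sample_id), CFG)


def test_feature_matrix_rejects_duplicate_sample_ids():
    a = _reduced("a", {63.0: 5.0, 70.0: 2.0})
    with pytest.raises(ValueError, match="duplicate"):
        build_feature_matrix([a, a])


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------


def test_peak_table_csv_round_trip(tmp_path, rng):
    run = _random_run(rng)
    path = tmp_path / "peaks.csv"
    write_peak_table_csv(run, path)
    header = path.read_text(encoding="utf-8").splitlines()[0]
    assert header == "sample_id,segment,cycle,mz,concentration_ppb"
    (back,) = read_peak_table_csv(path)
    assert sorted(back.channels) == sorted(run.channels)
    for cid in run.channels:  # reader orders channels by ascending m/z
        assert np.allclose(back.sample[cid], run.sample[cid])
        assert np.allclose(back.background[cid], run.background[cid])


def test_reduced_tsv_round_trip(tmp_path, rng):
    reduced = reduce_run(_random_run(rng), CFG)
    path = tmp_path / "reduced.tsv"
    write_reduced_tsv(reduced, path)
    back = read_reduced_tsv(path)
    assert back.sample_id == reduced.sample_id
    assert list(back.table["flags"]) == list(reduced.table["flags"])
    assert np.allclose(back.table["net_conc"], reduced.table["net_conc"])
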