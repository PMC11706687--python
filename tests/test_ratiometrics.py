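"""Ratio images, masked zone means and Welch statistics vs textbook formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phroot.image_io import CHANNEL_ROLES, MultiChannelImage, SampleRecord
from phroot.ratiometrics import (
    RatioImage,
    compute_ratio_image,
    group_statistics,
    measures_frame,
    welch_t_test,
    zone_mean_ratio,
)
from phroot.synthetic import SyntheticConfig, generate_sample


def make_image(fl405, fl458):
    zeros = np.zeros_like(np.asarray(fl405))
    return MultiChannelImage(
        np.stack([fl405, zeros, fl458, zeros]), channel_roles=CHANNEL_ROLES
    )


def test_ratio_of_proportional_channels_is_constant():
    fl405 = np.full((4, 4), 100.0)
    out = compute_ratio_image(make_image(fl405, 2 * fl405))
    assert np.all(out.X == 2.0) and out.valid.all()


def test_zero_denominator_marks_pixel_invalid():
    fl405 = np.array([[0.0, 10.0], [5.0, 0.0]])
    fl458 = np.array([[3.0, 20.0], [10.0, 7.0]])
    out = compute_ratio_image(make_image(fl405, fl458))
    assert out.valid.tolist() == [[False, True], [True, False]]
    assert out.X[0, 1] == 2.0 and out.X[1, 0] == 2.0


def test_noise_free_synthetic_zone_is_flat():
    sample = generate_sample(
        SyntheticConfig(image_size=64, noise_sd=0.0, seed=8), "Col-0", "mock"
    )
    ratio = compute_ratio_image(sample.image)
    mz = ratio.X[sample.mask.labels == 4]
    assert np.all(mz == 1.5)


def test_zone_mean_examples():
    X = np.array([[1.0, 2.0], [3.0, 6.0]])
    valid = np.ones((2, 2), dtype=bool)
    mask = np.ones((2, 2), dtype=int) * 2  # all EEZ
    m = zone_mean_ratio(RatioImage(X, valid), mask, "EEZ", sample_id="s")
    assert m.mean_ratio == pytest.approx(3.0) and m.n_pixels == 4
    # invalid pixel excluded from the masked mean
    X2 = np.array([[1.0, 2.0], [3.0, 4.0]])
    valid2 = np.array([[False, True], [True, True]])
    mask2 = np.array([[2, 2], [0, 0]])
    m2 = zone_mean_ratio(RatioImage(X2, valid2), mask2, "EEZ")
    assert m2.mean_ratio == pytest.approx(2.0) and m2.n_pixels == 1
    # zone without valid pixels is flagged missing
    m3 = zone_mean_ratio(RatioImage(X2, valid2), mask2, "MZ")
    assert m3.missing and np.isnan(m3.mean_ratio)
    with pytest.raises(ValueError):
        zone_mean_ratio(RatioImage(X2, valid2), np.zeros((3, 3), dtype=int), "EEZ")
    with pytest.raises(ValueError):
        zone_mean_ratio(RatioImage(X2, valid2), mask2, "cortex")


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    values=st.lists(st.floats(0.1, 5.0), min_size=4, max_size=30),
    order_seed=st.integers(0, 10**6),
)
def test_zone_mean_bounded_and_order_invariant(values, order_seed):
    side = int(np.ceil(np.sqrt(len(values))))
    X = np.zeros((side, side))
    X.ravel()[: len(values)] = values
    valid = np.zeros((side, side), dtype=bool)
    valid.ravel()[: len(values)] = True
    mask = np.full((side, side), 3)
    m = zone_mean_ratio(RatioImage(X, valid), mask, "LEZ")
    assert min(values) - 1e-12 <= m.mean_ratio <= max(values) + 1e-12
    rng = np.random.default_rng(order_seed)
    perm = rng.permutation(side * side)
    X2 = X.ravel()[perm].reshape(side, side)
    valid2 = valid.ravel()[perm].reshape(side, side)
    m2 = zone_mean_ratio(RatioImage(X2, valid2), mask, "LEZ")
    assert m2.mean_ratio == pytest.approx(m.mean_ratio, rel=1e-12)


# --- Welch -----------------------------------------------------------------

def welch_oracle(a, b):
    """Textbook Welch formulas, independent of the implementation path."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def test_welch_hand_example():
    t, df, p = welch_t_test([1, 2, 3], [2, 4, 6])
    t0, df0, p0 = welch_oracle([1, 2, 3], [2, 4, 6])
    assert t == pytest.approx(t0, abs=1e-10)
    assert df == pytest.approx(df0, abs=1e-10)
    assert p == pytest.approx(p0, abs=1e-10)


def test_welch_symmetry_properties():
    rng = np.random.default_rng(0)
    a = rng.normal(size=8)
    t, _, p = welch_t_test(a, a + 0.0)
    assert t == pytest.approx(0.0) and p == pytest.approx(1.0)
    b = rng.normal(1.0, 2.0, size=12)
    t_ab, df_ab, p_ab = welch_t_test(a, b)
    t_ba, df_ba, p_ba = welch_t_test(b, a)
    assert t_ab == pytest.approx(-t_ba)
    assert df_ab == pytest.approx(df_ba) and p_ab == pytest.approx(p_ba)


def test_welch_matches_oracle_on_random_groups():
    rng = np.random.default_rng(123)
    for _ in range(100):
        a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 25))
        b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 25))
        t, df, p = welch_t_test(a, b)
        t0, df0, p0 = welch_oracle(a, b)
        assert abs(t - t0) < 1e-10 and abs(df - df0) < 1e-10 and abs(p - p0) < 1e-10


def test_welch_preconditions():
    with pytest.raises(ValueError):
        welch_t_test([1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        welch_t_test([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        welch_t_test([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])


# --- group statistics ------------------------------------------------------

def _measures_and_records(rng, effect=0.0):
    records, measures = [], []
    from phroot.ratiometrics import ZoneMeasure

    for line, treatment, shift in [
        ("Col-0", "mock", 0.0),
        ("Col-0", "BL", effect),
        ("bri1-301", "mock", 0.0),
        ("bri1-301", "BL", 0.0),
    ]:
        for k in range(6):
            sid = f"{line}_{treatment}_{k}"
            records.append(SampleRecord(sid, line, treatment, "x.tif"))
            for zone in ("EEZ", "MZ"):
                measures.append(
                    ZoneMeasure(sid, zone, 2.0 + shift + rng.normal(0, 0.02), 100)
                )
    return measures, records


def test_group_statistics_detects_wildtype_effect():
    rng = np.random.default_rng(5)
    measures, records = _measures_and_records(rng, effect=-0.4)
    comps = group_statistics(measures, records)
    by_key = {(c.zone, c.group_a, c.group_b): c for c in comps}
    wt = by_key[("EEZ", ("Col-0", "mock"), ("Col-0", "BL"))]
    mut = by_key[("EEZ", ("bri1-301", "mock"), ("bri1-301", "BL"))]
    assert wt.p_value < 0.05 < mut.p_value
    assert wt.summary_a["n"] == 6 and "median" in wt.summary_a


def test_group_statistics_identical_groups_give_zero_t():
    from phroot.ratiometrics import ZoneMeasure

    records, measures = [], []
    for line in ("Col-0", "bri1-301"):
        for k in range(4):
            sid = f"{line}_mock_{k}"
            records.append(SampleRecord(sid, line, "mock", "x.tif"))
            measures.append(ZoneMeasure(sid, "MZ", [1.0, 1.5, 2.0, 2.5][k], 10))
    comps = group_statistics(
        measures, records, comparisons=[(("Col-0", "mock"), ("bri1-301", "mock"))]
    )
    assert comps[0].t_statistic == pytest.approx(0.0)


def test_group_statistics_error_paths():
    from phroot.ratiometrics import ZoneMeasure

    records = [SampleRecord("s1", "Col-0", "mock", "x.tif")]
    with pytest.raises(ValueError, match="unknown sample"):
        group_statistics([ZoneMeasure("ghost", "MZ", 1.0, 5)], records)
    with pytest.raises(ValueError, match="unknown groups"):
        group_statistics(
            [ZoneMeasure("s1", "MZ", 1.0, 5)],
            records,
            comparisons=[(("Ler", "mock"), ("Col-0", "mock"))],
        )


def test_measures_frame_layout():
    from phroot.ratiometrics import ZoneMeasure

    records = [SampleRecord("s1", "Col-0", "mock", "x.tif")]
    frame = measures_frame([ZoneMeasure("s1", "MZ", 1.4, 10)], records)
    assert list(frame.columns) == [
        "sample_id", "line", "treatment", "zone", "mean_ratio", "n_pixels",
    ]
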