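"""Background estimation, on/off calling and channel interference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twocolorqc import (
    NEGATIVE_CONTROL,
    SimConfig,
    build_matrix,
    call_expressed,
    channel_interference,
    fit_background,
    generate_dataset,
)
from twocolorqc.io_agilent import FeatureTable
from twocolorqc.synthetic import ArrayBias


def _control_table(values, array_id="arr", extra_probes=()):
    probes = [NEGATIVE_CONTROL] * len(values) + [p for p, _ in extra_probes]
    sig = list(values) + [s for _, s in extra_probes]
    ctype = [-1] * len(values) + [0] * len(extra_probes)
    frame = pd.DataFrame(
        {
            "feature_index": range(len(probes)),
            "probe_name": probes,
            "control_type": ctype,
            "g_median_signal": sig,
            "r_median_signal": sig,
        }
    )
    return FeatureTable(array_id=array_id, frame=frame)


def test_identical_controls_give_their_value():
    t = _control_table([2.0**6.0] * 153)
    bg = fit_background(t)
    assert bg.per_array["arr"] == pytest.approx(6.0, abs=1e-12)
    assert len(bg.pooled) == 153


def test_two_controls_average():
    t = _control_table([2.0**5.8, 2.0**6.0])
    assert fit_background(t).per_array["arr"] == pytest.approx(5.9, abs=1e-12)


def test_missing_controls_fatal_names_probe():
    t = _control_table([100.0], extra_probes=[("P1", 500.0)])
    with pytest.raises(ValueError, match=r"3xSLv1"):
        fit_background(t)


def test_background_recovers_generator_truth():
    cfg = SimConfig(n_probes=300, n_replicate_probes=20, n_arrays=4, seed=13,
                    array_bias=tuple(ArrayBias() for _ in range(4)))
    ds = generate_dataset(cfg)
    bg = fit_background(ds.tables, channel="Cy5")
    se = cfg.background_sd / np.sqrt(cfg.negative_control_count)
    for stat in bg.per_array:
        assert abs(stat - cfg.background_log2) < 5 * se


def test_call_curve_boundaries_and_strictness():
    values = pd.Series([6.0] * 50, index=[f"P{i}" for i in range(50)])
    curve = call_expressed(values, 6.0, [0.0, 1e9])
    assert curve.fraction_on[0] == 0.0  # strict inequality at threshold 0
    assert curve.fraction_on[1] == 0.0
    below = call_expressed(values, 6.0, [-1e9])
    assert below.fraction_on[0] == 1.0


def test_call_curve_matches_brute_force_and_is_monotone():
    rng = np.random.default_rng(14)
    values = pd.Series(rng.normal(7, 1, size=400),
                       index=[f"P{i}" for i in range(400)])
    thresholds = np.linspace(-2, 3, 21)
    curve = call_expressed(values, 6.0, thresholds)
    for t, f in zip(curve.thresholds, curve.fraction_on):
        brute = sum(1 for v in values if v > 6.0 + t) / len(values)
        assert f == pytest.approx(brute, abs=1e-12)
    assert (np.diff(curve.fraction_on) <= 1e-12).all()


def test_unsorted_thresholds_rejected():
    with pytest.raises(ValueError, match="ascending"):
        call_expressed(np.array([1.0]), 0.0, [1.0, 0.5])


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_call_curve_monotone_property(seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(6, 1.5, size=100)
    curve = call_expressed(values, 6.0, np.linspace(-4, 4, 33))
    assert (np.diff(curve.fraction_on) <= 1e-12).all()


def test_call_sensitivity_specificity_match_noise_model():
    """At threshold 0.5 the on-call of known expressed / non-expressed probes
    follows the binomial predictions of the generator's noise model."""
    cfg = SimConfig(seed=19)
    ds = generate_dataset(cfg)
    m5, _ = build_matrix(ds.tables, "Cy5")
    from twocolorqc.normalize import normalize_matrix

    n5, _ = normalize_matrix(m5, "loess")
    bg = fit_background(n5)
    expr = ds.truth.probes["expressed"]
    tech, _ = cfg.tech_bio_split()
    on_frac_expr, on_frac_off, exp_expr, exp_off = [], [], [], []
    for array_id in n5.array_ids[:5]:
        col = n5.data[array_id].drop(NEGATIVE_CONTROL)
        on = col > bg.per_array[array_id] + 0.5
        on_frac_expr.append(on[expr[expr].index].mean())
        on_frac_off.append(on[expr[~expr].index].mean())
        margin = ds.truth.probes["mean_cy5"] - bg.per_array[array_id] - 0.5
        p_on_expr = stats.norm.sf(-margin[expr] / cfg.noise_sd_cy5)
        p_on_off = stats.norm.sf(-margin[~expr] / tech)
        exp_expr.append(p_on_expr.mean())
        exp_off.append(p_on_off.mean())
    # 95% binomial CI half-widths plus a small allowance for the
    # normalization residual the closed form does not model
    n_e, n_o = expr.sum(), (~expr).sum()
    tol_e = 2 * np.sqrt(0.05 * 0.95 / n_e) + 0.02
    tol_o = 2 * np.sqrt(0.1 * 0.9 / n_o) + 0.02
    assert np.mean(on_frac_expr) == pytest.approx(np.mean(exp_expr), abs=tol_e)
    assert np.mean(on_frac_off) == pytest.approx(np.mean(exp_off), abs=tol_o)


# -- channel interference ----------------------------------------------------


def test_identical_differences_fully_correlated():
    d = pd.Series(np.linspace(0, 6, 300))
    table = channel_interference(d, d.copy())
    top = table[table["bin"] == "top50"].iloc[0]
    assert top["correlation"] == pytest.approx(1.0, abs=1e-9)
    big = table[table["bin"] == "(4.0, inf]"].iloc[0]
    assert big["correlation"] == pytest.approx(1.0, abs=1e-9)


def test_independent_differences_uncorrelated():
    rng = np.random.default_rng(15)
    d5 = pd.Series(rng.uniform(0, 6, size=5000))
    d3 = pd.Series(rng.normal(0, 0.3, size=5000))
    table = channel_interference(d5, d3)
    for _, row in table.iterrows():
        if row["count"] >= 100:
            assert abs(row["correlation"]) < 4 / np.sqrt(row["count"])


def test_interference_only_at_large_signal_changes():
    """Cy3 follows Cy5 only above 4 log2 units: the top bin shows the
    coupling, the smallest bin does not."""
    rng = np.random.default_rng(16)
    # heavy-tailed stimulation indices so the top-50 subset spans a wide range
    d5 = pd.Series(np.minimum(0.5 + rng.exponential(1.2, size=6000), 8.0))
    d3 = pd.Series(rng.normal(0, 0.15, size=6000))
    high = d5 > 4
    d3[high] = 0.3 * d5[high] + rng.normal(0, 0.15, size=int(high.sum()))
    table = channel_interference(d5, d3).set_index("bin")
    assert table.loc["(4.0, inf]", "correlation"] > 0.5
    assert abs(table.loc["(2.5, 3.0]", "correlation"]) < 0.15
    assert table.loc["(4.0, inf]", "slope"] == pytest.approx(0.3, abs=0.05)
    assert table.loc["top50", "correlation"] > 0.3


def test_sparse_bin_reports_nan_not_error():
    d5 = pd.Series([0.1, 0.2, 5.0])
    d3 = pd.Series([0.0, 0.1, 0.2])
    table = channel_interference(d5, d3, bins=[(4.0, np.inf)], top_n=2)
    assert np.isnan(table.iloc[0]["correlation"])
    assert table.iloc[0]["count"] == 1


def test_overlapping_bins_rejected():
    d = pd.Series(np.linspace(0, 5, 10))
    with pytest.raises(ValueError, match="disjoint"):
        channel_interference(d, d, bins=[(1.0, 3.0), (2.0, 4.0)])
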