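import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitotherm import stats as mstats
from mitotherm import synth


def _two_line(x, bp, s1, s2, y0):
    y = y0 + s1 * (x - x[0])
    post = x > bp
    y_bp = y0 + s1 * (bp - x[0])
    y = np.where(post, y_bp + s2 * (x - bp), y)
    return y


# --------------------------------------------------------------------------
# segmented regression
# --------------------------------------------------------------------------

def test_segmented_exact_recovery():
    x = np.arange(18.0, 32.5, 0.5)
    y = _two_line(x, 25.0, 2.0, -8.0, 60.0)
    fit = mstats.segmented_fit(x, y, n_boot=0)
    assert fit.breakpoint == pytest.approx(25.0, abs=1e-6)
    assert fit.slope_left == pytest.approx(2.0, abs=1e-8)
    assert fit.slope_right == pytest.approx(-8.0, abs=1e-8)
    assert fit.r2 == pytest.approx(1.0)
    assert not fit.no_break


def test_segmented_no_break_on_line():
    x = np.arange(0.0, 10.0)
    fit = mstats.segmented_fit(x, 3.0 + 2.0 * x, n_boot=0)
    assert fit.no_break


def test_segmented_needs_five_points():
    with pytest.raises(ValueError):
        mstats.segmented_fit([1, 2, 3, 4], [1, 2, 3, 4], n_boot=0)


def _oracle_breakpoint(x, y, step=0.002):
    """Exhaustive fixed-breakpoint SSE scan (independent implementation)."""
    grid = np.arange(x[1], x[-2] + step / 2, step)
    best_c, best_sse = grid[0], np.inf
    for c in grid:
        X = np.column_stack([np.ones_like(x), x,
                             np.clip(x - c, 0.0, None)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ coef) ** 2))
        if sse < best_sse:
            best_c, best_sse = c, sse
    return best_c


def test_segmented_matches_scan_oracle():
    rng = np.random.default_rng(12)
    x = np.arange(18.0, 32.5, 0.5)
    y = _two_line(x, 26.3, 2.0, -8.0, 60.0) + rng.normal(0, 2.0, x.size)
    fit = mstats.segmented_fit(x, y, grid_step=0.01, n_boot=0)
    assert abs(fit.breakpoint - _oracle_breakpoint(x, y)) <= 0.01


def test_segmented_noisy_within_bootstrap_se():
    rng = np.random.default_rng(7)
    x = np.arange(18.0, 32.5, 0.5)
    y = _two_line(x, 25.0, 2.0, -8.0, 60.0) + rng.normal(0, 2.0, x.size)
    fit = mstats.segmented_fit(x, y, n_boot=500, seed=1)
    assert fit.breakpoint_se > 0
    assert abs(fit.breakpoint - 25.0) <= 2.0 * fit.breakpoint_se


def test_segmented_bootstrap_seeded():
    rng = np.random.default_rng(7)
    x = np.arange(18.0, 32.5, 0.5)
    y = _two_line(x, 25.0, 2.0, -8.0, 60.0) + rng.normal(0, 2.0, x.size)
    a = mstats.segmented_fit(x, y, n_boot=200, seed=3)
    b = mstats.segmented_fit(x, y, n_boot=200, seed=3)
    assert a.breakpoint_se == b.breakpoint_se


# --------------------------------------------------------------------------
# 4PL dose-response
# --------------------------------------------------------------------------

def _pl4(x, bottom, top, c, h):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((c - x) * h))


def test_dose_response_zero_noise_recovery():
    x = np.repeat(np.array([15.0, 17.5, 20.0, 25.0, 27.5, 30.0, 32.5]), 4)
    y = _pl4(x, 3.0, 4.6, 19.97, -0.3)
    fit = mstats.dose_response_breakpoint(x, y, "inhibition")
    assert fit.breakpoint == pytest.approx(19.97, rel=1e-6)
    assert fit.bottom == pytest.approx(3.0, rel=1e-5)
    assert fit.top == pytest.approx(4.6, rel=1e-5)
    assert fit.hill == pytest.approx(-0.3, rel=1e-5)
    assert fit.r2 == pytest.approx(1.0)


def test_dose_response_stimulation():
    x = np.array([15.0, 17.5, 20.0, 25.0, 27.5, 30.0, 32.5])
    y = _pl4(x, 2.5, 9.0, 29.96, 0.45)
    fit = mstats.dose_response_breakpoint(x, y, "stimulation")
    assert fit.breakpoint == pytest.approx(29.96, rel=1e-6)
    assert fit.hill > 0


def test_dose_response_shift_equivariance():
    x = np.array([15.0, 17.5, 20.0, 25.0, 27.5, 30.0, 32.5])
    rng = np.random.default_rng(5)
    y = _pl4(x, 3.0, 4.6, 22.0, -0.3) + rng.normal(0, 0.05, x.size)
    f1 = mstats.dose_response_breakpoint(x, y, "inhibition")
    f2 = mstats.dose_response_breakpoint(x, y + 10.0, "inhibition")
    assert f2.breakpoint == pytest.approx(f1.breakpoint, abs=1e-5)
    assert f2.bottom == pytest.approx(f1.bottom + 10.0, abs=1e-4)


def test_dose_response_degenerate_and_errors():
    x = np.array([15.0, 17.5, 20.0, 25.0, 27.5])
    fit = mstats.dose_response_breakpoint(x, np.full(5, 3.0), "inhibition")
    assert fit.degenerate and "DEGENERATE" in fit.flags
    with pytest.raises(ValueError):
        mstats.dose_response_breakpoint(x[:4], np.arange(4.0), "inhibition")
    with pytest.raises(ValueError):
        mstats.dose_response_breakpoint(x, np.arange(5.0), "sideways")
    with pytest.raises(ValueError):
        mstats.dose_response_breakpoint(x - 20.0, np.arange(5.0),
                                        "inhibition", log_dose=True)


def test_dose_response_log_dose():
    x = np.array([1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0])
    y = _pl4(np.log10(x), 1.0, 5.0, 1.0, -1.2)     # inflection at 10 units
    fit = mstats.dose_response_breakpoint(x, y, "inhibition", log_dose=True)
    assert fit.breakpoint == pytest.approx(10.0, rel=1e-5)


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

def test_one_sample_t_branches():
    t, p, sig = mstats.one_sample_t([1.0, 1.0, 1.0], 1.0)
    assert (t, p, sig) == (0.0, 1.0, False)
    t, p, sig = mstats.one_sample_t([2.0, 2.0, 2.0], 1.0)
    assert t == np.inf and p == 0.0 and sig
    vals = [0.03, 0.08, 0.05, 0.06]
    t, p, sig = mstats.one_sample_t(vals, 0.0)
    t_ref, p_ref = sps.ttest_1samp(vals, 0.0)
    assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)
    with pytest.raises(ValueError):
        mstats.one_sample_t([1.0, 2.0], 0.0)


def test_anova_hand_computed_f():
    # SSB = 6, SSW = 4, df = (1, 4) -> F = 6
    res = mstats.anova_tukey({"a": [0.0, 1.0, 2.0], "b": [2.0, 3.0, 4.0]})
    assert res["F"] == pytest.approx(6.0)
    assert res["p"] == pytest.approx(float(sps.f.sf(6.0, 1, 4)))


def test_anova_letters():
    rng = np.random.default_rng(2)
    groups = {"cold": rng.normal(10, 0.1, 6),
              "warm": rng.normal(10.05, 0.1, 6),
              "hot": rng.normal(20, 0.1, 6)}
    res = mstats.anova_tukey(groups)
    lt = res["letters"]
    assert set(lt["cold"]) & set(lt["warm"])          # share a letter
    assert not set(lt["cold"]) & set(lt["hot"])       # differ
    assert res["significant"]


def test_anova_errors_and_identical_groups():
    with pytest.raises(ValueError):
        mstats.anova_tukey({"only": [1.0, 2.0]})
    with pytest.raises(ValueError):
        mstats.anova_tukey({"a": [1.0], "b": [1.0, 2.0]})
    res = mstats.anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0]})
    assert not res["significant"]
    assert set(res["letters"]["a"]) & set(res["letters"]["b"])


def test_two_factor_anova():
    rng = np.random.default_rng(3)
    rows = []
    for a in ("ctl", "exp"):
        for b in (15.0, 25.0):
            mu = 10.0 + (5.0 if a == "exp" else 0.0) + 0.2 * b
            rows += [(a, b, mu + rng.normal(0, 0.5)) for _ in range(5)]
    df = pd.DataFrame(rows, columns=["group", "temp", "y"])
    tab = mstats.two_factor_anova(df, "y", "group", "temp")
    assert {"C(A)", "C(B)", "C(A):C(B)", "Residual"} <= set(tab.index)
    assert tab.loc["C(A)", "PR(>F)"] < 0.001


def test_fold_change_exact_means():
    df = pd.DataFrame({
        "group": ["control"] * 2 + ["experimental"] * 2,
        "internal_standard": [1.0, 1.0, 1.0, 1.0],
        "lactate": [106.61, 106.61, 142.39, 142.39],
    })
    out = mstats.fold_change_table(df)
    assert out.loc["lactate", "fold"] == pytest.approx(142.39 / 106.61)
    assert out.loc["lactate", "percent_change"] == pytest.approx(33.56,
                                                                 abs=0.01)


def test_fold_change_internal_standard_invariance():
    df = synth.gen_metabolite_table({"lactate": (100.0, 130.0)},
                                    cv=0.05, n_per_group=6, seed=8)
    out1 = mstats.fold_change_table(df)
    df2 = df.copy()
    scale = np.linspace(0.5, 2.0, len(df2))     # per-sample gain drift
    df2["lactate"] *= scale
    df2["internal_standard"] *= scale
    out2 = mstats.fold_change_table(df2)
    assert out2.loc["lactate", "fold"] == pytest.approx(
        out1.loc["lactate", "fold"], rel=1e-9)


def test_fold_change_flags_and_errors():
    df = pd.DataFrame({
        "group": ["control"] * 2 + ["experimental"] * 2,
        "internal_standard": [1.0, 1.0, 1.0, 1.0],
        "x": [0.0, 0.0, 1.0, 2.0],
    })
    out = mstats.fold_change_table(df)
    assert out.loc["x", "flag"] == "ZERO_CONTROL"
    with pytest.raises(ValueError):
        mstats.fold_change_table(df.drop(columns="internal_standard"))
    with pytest.raises(ValueError):
        mstats.fold_change_table(df.iloc[[0, 2]])
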