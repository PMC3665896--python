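"""Breakpoint inference and group statistics.

Two breakpoint estimators are provided:

* :func:`segmented_fit` — a continuous two-segment linear regression
  (Arrhenius-break style).  The breakpoint is found by an SSE scan over a
  candidate grid followed by a bounded 1-D refinement, its standard error
  by a seeded nonparametric bootstrap, and the existence of a break is
  decided by an F-test of the two-segment model against a single line.

* :func:`dose_response_breakpoint` — a four-parameter logistic (4PL)
  fitted with temperature as the dose axis.  The reported "breakpoint" is
  the fitted inflection.  ``direction`` constrains the sign of the hill
  slope: ``inhibition`` for a response falling with temperature,
  ``stimulation`` for one rising with it.

Plus the small-group statistics used around them: one-sample t-tests,
one-way ANOVA with Tukey HSD and a compact letter display, and metabolite
fold-change tables normalized to an internal standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


# --------------------------------------------------------------------------
# segmented (two-line continuous) regression
# --------------------------------------------------------------------------

@dataclass
class SegmentedFit:
    breakpoint: float
    slope_left: float
    slope_right: float
    intercept_left: float
    intercept_right: float
    breakpoint_se: float
    r2: float
    sse: float
    no_break: bool
    p_break: float


def _two_line_sse(x, y, c):
    """Least-squares fit of y = a + b*x + d*(x-c)+ at fixed breakpoint c."""
    hinge = np.clip(x - c, 0.0, None)
    X = np.column_stack([np.ones_like(x), x, hinge])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def _sse_scan(x, y, grid):
    """SSE of the hinge model at every candidate breakpoint (vectorized).

    Solves the 3x3 normal equations per candidate on mean-centred x; a
    tiny ridge keeps degenerate bootstrap resamples solvable.
    """
    xm = x.mean()
    xc = x - xm
    H = np.clip(xc[None, :] - (grid - xm)[:, None], 0.0, None)
    n = x.size
    s1h = H.sum(axis=1)
    sxh = H @ xc
    shh = np.einsum("ij,ij->i", H, H)
    A = np.empty((grid.size, 3, 3))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = xc.sum()
    A[:, 1, 1] = xc @ xc
    A[:, 0, 2] = A[:, 2, 0] = s1h
    A[:, 1, 2] = A[:, 2, 1] = sxh
    A[:, 2, 2] = shh
    ridge = 1e-12 * (A[:, 0, 0] + A[:, 1, 1] + A[:, 2, 2])
    A[:, 0, 0] += ridge
    A[:, 1, 1] += ridge
    A[:, 2, 2] += ridge
    yc = y - y.mean()           # centring y improves SSE conditioning
    B = np.empty((grid.size, 3))
    B[:, 0] = yc.sum()
    B[:, 1] = xc @ yc
    B[:, 2] = H @ yc
    coef = np.linalg.solve(A, B[..., None])[..., 0]
    sse = yc @ yc - np.einsum("ij,ij->i", coef, B)
    return np.clip(sse, 0.0, None)


def _best_breakpoint(x, y, grid_step, refine=True):
    lo, hi = x[1], x[-2]
    if hi <= lo:
        lo, hi = x[0], x[-1]
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    sses = _sse_scan(x, y, grid)
    i = int(np.argmin(sses))
    c0 = grid[i]
    if refine:
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        if b > a:
            res = optimize.minimize_scalar(
                lambda c: _two_line_sse(x, y, c)[0],
                bounds=(a, b), method="bounded",
                options={"xatol": 1e-10})
            if res.fun <= sses[i] + 1e-15:
                c0 = float(res.x)
    return c0


def segmented_fit(x, y, grid_step: float = 0.1, n_boot: int = 1000,
                  seed: int = 0, alpha: float = 0.05) -> SegmentedFit:
    """Fit a continuous two-segment line; breakpoint by SSE scan + refine.

    ``no_break`` is set when the two-segment model fails to beat a single
    line by an F-test at ``alpha`` (2 extra parameters).  Breakpoint SE is
    from ``n_boot`` seeded pair-resampling bootstrap replicates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = x.size
    if n < 5:
        raise ValueError("segmented_fit needs at least 5 points")

    c = _best_breakpoint(x, y, grid_step)
    sse2, coef = _two_line_sse(x, y, c)
    a, b, d = coef
    # single-line comparison
    X1 = np.column_stack([np.ones_like(x), x])
    coef1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    r1 = y - X1 @ coef1
    sse1 = float(r1 @ r1)
    sst = float(np.sum((y - y.mean()) ** 2))

    eps = 1e-12 * max(sst, 1.0)
    if sse2 < eps:
        no_break, p_break = (sse1 < eps), (1.0 if sse1 < eps else 0.0)
    else:
        df2 = n - 4
        F = ((sse1 - sse2) / 2.0) / (sse2 / df2)
        p_break = float(sps.f.sf(max(F, 0.0), 2, df2))
        no_break = p_break > alpha

    rng = np.random.default_rng(seed)
    if n_boot > 0 and not no_break:
        bps = np.empty(n_boot)
        for k in range(n_boot):
            idx = np.sort(rng.integers(0, n, n))
            xb, yb = x[idx], y[idx]
            if np.unique(xb).size < 4:
                bps[k] = c
                continue
            bps[k] = _best_breakpoint(xb, yb, grid_step, refine=False)
        se = float(np.std(bps, ddof=1))
    else:
        se = float("nan")

    r2 = 1.0 - sse2 / sst if sst > 0 else 1.0
    return SegmentedFit(
        breakpoint=float(c), slope_left=float(b), slope_right=float(b + d),
        intercept_left=float(a), intercept_right=float(a - d * c),
        breakpoint_se=se, r2=float(r2), sse=sse2,
        no_break=bool(no_break), p_break=float(p_break),
    )


# --------------------------------------------------------------------------
# four-parameter logistic dose-response on the temperature axis
# --------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    breakpoint: float          # fitted inflection, same units as x
    bottom: float
    top: float
    hill: float
    breakpoint_se: float
    bottom_se: float
    top_se: float
    hill_se: float
    r2: float
    degenerate: bool = False
    flags: list[str] = field(default_factory=list)


def _pl4(x, bottom, top, c, h):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((c - x) * h))


def dose_response_breakpoint(temps, response, direction: str = "inhibition",
                             log_dose: bool = False) -> DoseResponseFit:
    """Fit y = bottom + (top-bottom)/(1 + 10^((c-x)*h)) on the dose axis.

    ``direction='inhibition'`` constrains h < 0 (response falls with the
    dose), ``'stimulation'`` constrains h > 0.  With ``log_dose`` the fit
    runs on log10(x) and the inflection is transformed back.
    """
    if direction not in ("inhibition", "stimulation"):
        raise ValueError(f"unknown direction {direction!r}")
    x = np.asarray(temps, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.unique(x).size < 5:
        raise ValueError("dose_response_breakpoint needs >= 5 dose levels")
    if log_dose:
        if np.any(x <= 0):
            raise ValueError("log dose axis requires positive doses")
        x = np.log10(x)

    scale = max(abs(float(np.mean(y))), float(np.ptp(y)), 1e-300)
    if np.ptp(y) <= 1e-9 * scale:
        return DoseResponseFit(np.nan, float(y.mean()), float(y.mean()),
                               np.nan, np.nan, np.nan, np.nan, np.nan,
                               np.nan, degenerate=True, flags=["DEGENERATE"])

    # per-dose means guide the initial values
    xu = np.unique(x)
    ymeans = np.array([y[x == xi].mean() for xi in xu])
    step = float(np.median(np.diff(xu)))
    span = xu[-1] - xu[0]
    lo_y, hi_y = float(ymeans.min()), float(ymeans.max())
    half = 0.5 * (lo_y + hi_y)
    # crossing point of the mean curve as the inflection guess
    c0 = float(xu[int(np.argmin(np.abs(ymeans - half)))])
    if direction == "inhibition":
        h0, hlo, hhi = -1.0 / max(span / 4, step), -8.0 / step, -1e-3
        top0, bot0 = float(ymeans[0]), float(ymeans[-1])
    else:
        h0, hlo, hhi = 1.0 / max(span / 4, step), 1e-3, 8.0 / step
        top0, bot0 = float(ymeans[-1]), float(ymeans[0])
    amp = hi_y - lo_y
    bounds = ([lo_y - 2 * amp, lo_y - 2 * amp, xu[0] - step, hlo],
              [hi_y + 2 * amp, hi_y + 2 * amp, xu[-1] + step, hhi])
    p0 = [bot0, top0, c0, np.clip(h0, hlo, hhi)]
    try:
        popt, pcov = optimize.curve_fit(_pl4, x, y, p0=p0, bounds=bounds,
                                        maxfev=20000)
    except RuntimeError:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                               np.nan, np.nan, np.nan, np.nan,
                               degenerate=True, flags=["FIT_FAILED"])
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = y - _pl4(x, *popt)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
    c = popt[2]
    c_se = perr[2]
    if log_dose:
        c = 10.0 ** c
        c_se = c * np.log(10.0) * c_se  # delta method
    return DoseResponseFit(
        breakpoint=float(c), bottom=float(popt[0]), top=float(popt[1]),
        hill=float(popt[3]), breakpoint_se=float(c_se),
        bottom_se=float(perr[0]), top_se=float(perr[1]),
        hill_se=float(perr[3]), r2=float(r2),
    )


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

def one_sample_t(values, mu0: float = 0.0, alpha: float = 0.05):
    """Two-sided one-sample t-test; returns (t, p, significant)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("one_sample_t needs n >= 3")
    if np.std(v, ddof=1) == 0.0:
        if v[0] == mu0:
            return 0.0, 1.0, False
        return float(np.sign(v[0] - mu0) * np.inf), 0.0, True
    t, p = sps.ttest_1samp(v, mu0)
    return float(t), float(p), bool(p <= alpha)


def _compact_letters(names, differ):
    """Insert-and-absorb compact letter display.

    ``differ[frozenset((a, b))]`` is True when groups a and b are
    significantly different; in the result, groups sharing no letter
    differ at the test's alpha.
    """
    sets: list[set] = [set(names)]
    for pair, is_diff in differ.items():
        if not is_diff:
            continue
        a, b = tuple(pair)
        for s in list(sets):
            if a in s and b in s:
                sets.remove(s)
                sets.extend([s - {a}, s - {b}])
        # absorb: drop sets contained in another
        sets = [s for i, s in enumerate(sets)
                if s and not any(s < t or (s == t and i > j)
                                 for j, t in enumerate(sets) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {n: set() for n in names}
    for s, letter in zip(sets, alphabet):
        for n in s:
            letters[n].add(letter)
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def anova_tukey(groups: dict, alpha: float = 0.05):
    """One-way ANOVA with Tukey HSD and compact letter display.

    ``groups`` maps group name to an array of observations (each n >= 2).
    Returns a dict with F, p, the pairwise Tukey table and per-group
    letters; groups sharing no letter differ at ``alpha``.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(names) < 2:
        raise ValueError("anova_tukey needs >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    F, p = sps.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[n] * a.size for n, a in zip(names, arrays)])
    differ = {frozenset((a, b)): False
              for i, a in enumerate(names) for b in names[i + 1:]}
    if np.std(values, ddof=1) > 0 and not np.isnan(F):
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        tukey = pd.DataFrame(tk.summary().data[1:],
                             columns=tk.summary().data[0])
        for row in tukey.itertuples(index=False):
            differ[frozenset((row.group1, row.group2))] = bool(row.reject)
    else:
        tukey = pd.DataFrame()
        F, p = 0.0, 1.0
    letters = _compact_letters(names, differ)
    return {"F": float(F), "p": float(p), "tukey": tukey,
            "letters": letters,
            "significant": bool(p <= alpha)}


def two_factor_anova(df: pd.DataFrame, response: str, factor_a: str,
                     factor_b: str) -> pd.DataFrame:
    """Crossed two-factor fixed-effects ANOVA with interaction."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    d = df.rename(columns={response: "y", factor_a: "A", factor_b: "B"})
    model = smf.ols("y ~ C(A) * C(B)", data=d).fit()
    return anova_lm(model, typ=2)


def fold_change_table(table: pd.DataFrame, group_col: str = "group",
                      control: str = "control",
                      experimental: str = "experimental",
                      internal_standard: str = "internal_standard",
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-metabolite experimental/control fold changes.

    Abundances are first normalized per sample to the internal-standard
    column; fold = mean(experimental) / mean(control); percent change is
    100*(fold - 1); significance by two-sided Welch t-test.
    """
    if internal_standard not in table.columns:
        raise ValueError("internal standard column missing")
    metabolites = [c for c in table.columns
                   if c not in (group_col, internal_standard)]
    norm = table[metabolites].div(table[internal_standard], axis=0)
    norm[group_col] = table[group_col].values
    ctl = norm[norm[group_col] == control]
    exp = norm[norm[group_col] == experimental]
    if len(ctl) < 2 or len(exp) < 2:
        raise ValueError("both groups need n >= 2")
    rows = []
    for m in metabolites:
        mc, me = ctl[m].mean(), exp[m].mean()
        if mc == 0:
            rows.append((m, np.nan, np.nan, np.nan, False, "ZERO_CONTROL"))
            continue
        fold = me / mc
        t, p = sps.ttest_ind(exp[m], ctl[m], equal_var=False)
        rows.append((m, fold, 100.0 * (fold - 1.0), float(p),
                     bool(p <= alpha), ""))
    return pd.DataFrame(rows, columns=["metabolite", "fold",
                                       "percent_change", "p",
                                       "significant", "flag"]
                        ).set_index("metabolite")
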