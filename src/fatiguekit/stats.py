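"""Within-subject inferential statistics and effect sizes.

Classical univariate repeated-measures ANOVA (subject as blocking factor,
each within effect tested against its own effect-by-subject interaction),
paired t-tests with Bonferroni correction and Cohen's d on the difference
scores, and Pearson/Spearman correlations.  Degrees of freedom are reported
uncorrected (no sphericity adjustment), matching the convention of reporting
e.g. F(2, 58) for a three-level factor over 30 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "RMAnovaResult",
    "PairedTestResult",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "paired_tests",
    "correlations",
]


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


@dataclass
class RMAnovaResult:
    effects: dict[str, EffectResult]

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "effect": name,
                "F": e.F,
                "df_num": e.df_num,
                "df_den": e.df_den,
                "p": e.p,
                "partial_eta_sq": e.partial_eta_sq,
            }
            for name, e in self.effects.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedTestResult:
    pair: tuple[str, str]
    t: float
    df: int
    p_raw: float
    p_bonf: float
    cohens_d: float


def _as_table(data: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns]
    arr = np.asarray(data, dtype=float)
    return arr, [str(j) for j in range(arr.shape[1])]


def _effect(ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> EffectResult:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err == 0.0:
        f = 0.0 if ms_eff == 0.0 else float("inf")
    else:
        f = ms_eff / ms_err
    p = float(sps.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
    denom = ss_eff + ss_err
    np2 = ss_eff / denom if denom > 0 else 0.0
    return EffectResult(
        F=float(f), df_num=df_eff, df_den=df_err, p=p,
        partial_eta_sq=float(np2), ss_effect=float(ss_eff), ss_error=float(ss_err),
    )


def rm_anova_oneway(
    data: pd.DataFrame | np.ndarray, effect_name: str = "condition"
) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Decomposes total variation into condition, subject and residual sums of
    squares; F = MS_condition / MS_residual with (k-1, (n-1)(k-1)) df and
    partial eta-squared SS_effect / (SS_effect + SS_error).  The table must be
    complete (no NaN) with at least two subjects and two conditions.
    """
    y, _ = _as_table(data)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need a complete table with >= 2 subjects and >= 2 conditions")
    if np.any(~np.isfinite(y)):
        raise ValueError("table contains missing cells; no imputation is performed")
    n, k = y.shape
    grand = y.mean()
    ss_cond = n * float(np.sum((y.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((y.mean(axis=1) - grand) ** 2))
    ss_tot = float(np.sum((y - grand) ** 2))
    ss_err = ss_tot - ss_cond - ss_subj
    # cancellation guard: sums of squares are non-negative by construction
    tiny = 1e-12 * max(ss_tot, 1e-300)
    ss_cond = 0.0 if ss_cond < tiny else ss_cond
    ss_err = 0.0 if ss_err < tiny else ss_err
    return RMAnovaResult({effect_name: _effect(ss_cond, k - 1, ss_err, (n - 1) * (k - 1))})


def rm_anova_twoway(
    cube: np.ndarray, factor_names: tuple[str, str] = ("A", "B")
) -> RMAnovaResult:
    """Two-way fully within-subject ANOVA on an (n_subjects, a, b) array.

    Each effect is tested against its own interaction with subjects:
    F_A = MS_A / MS_{A x S}, F_B = MS_B / MS_{B x S},
    F_{AxB} = MS_{AxB} / MS_{AxB x S} (one observation per cell).
    """
    y = np.asarray(cube, dtype=float)
    if y.ndim != 3 or y.shape[0] < 2 or y.shape[1] < 2 or y.shape[2] < 2:
        raise ValueError("need an (n>=2, a>=2, b>=2) array")
    if np.any(~np.isfinite(y)):
        raise ValueError("cube contains missing cells; no imputation is performed")
    n, a, b = y.shape
    g = y.mean()
    m_s = y.mean(axis=(1, 2))  # subject means
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)  # (n, a)
    m_sb = y.mean(axis=1)  # (n, b)
    m_ab = y.mean(axis=0)  # (a, b)

    ss_a = n * b * float(np.sum((m_a - g) ** 2))
    ss_b = n * a * float(np.sum((m_b - g) ** 2))
    ss_as = b * float(np.sum((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2))
    ss_bs = a * float(np.sum((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2))
    ss_ab = n * float(np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2))
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - g
    )
    ss_abs = float(np.sum(resid**2))

    name_a, name_b = factor_names
    return RMAnovaResult(
        {
            name_a: _effect(ss_a, a - 1, ss_as, (n - 1) * (a - 1)),
            name_b: _effect(ss_b, b - 1, ss_bs, (n - 1) * (b - 1)),
            f"{name_a} x {name_b}": _effect(
                ss_ab, (a - 1) * (b - 1), ss_abs, (n - 1) * (a - 1) * (b - 1)
            ),
        }
    )


def paired_tests(
    data: pd.DataFrame | np.ndarray,
    comparisons: list[tuple[str, str]] | None = None,
    m: int | None = None,
) -> list[PairedTestResult]:
    """Follow-up paired t-tests with Bonferroni correction.

    ``comparisons`` lists column pairs (default: all pairwise, in column
    order); the Bonferroni family size ``m`` defaults to the number of
    comparisons.  Cohen's d is mean(diff) / sd(diff).
    """
    y, cols = _as_table(data)
    if comparisons is None:
        comparisons = [(cols[i], cols[j]) for i in range(len(cols)) for j in range(i + 1, len(cols))]
    if m is None:
        m = len(comparisons)
    out = []
    for a, b in comparisons:
        ia, ib = cols.index(str(a)), cols.index(str(b))
        da = y[:, ia]
        db = y[:, ib]
        if da.size < 2:
            raise ValueError("paired test needs at least 2 subjects")
        diff = da - db
        sd = float(np.std(diff, ddof=1))
        if sd == 0.0:
            t, p, d = 0.0, 1.0, 0.0
        else:
            res = sps.ttest_rel(da, db)
            t, p = float(res.statistic), float(res.pvalue)
            d = float(np.mean(diff) / sd)
        out.append(
            PairedTestResult(
                pair=(str(a), str(b)),
                t=t,
                df=da.size - 1,
                p_raw=p,
                p_bonf=min(1.0, m * p),
                cohens_d=d,
            )
        )
    return out


def correlations(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> tuple[float, float]:
    """Pearson r or Spearman rho with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
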