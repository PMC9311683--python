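"""Group summaries, planned contrasts and the 4 x 2 mixed-design ANOVA.

The analysis pipeline mirrors a standard experimental-psychology report:
per-condition means and SDs of block accuracy (sample SD, n-1 denominator),
pairwise and repeated-measures-marginal mean differences with
Bonferroni-adjusted pooled-variance t intervals, and a mixed ANOVA with one
between-subject factor (condition) and a two-level within-subject factor
(block). With two within levels the mixed ANOVA decomposes exactly into two
ordinary least-squares fits — subject means for the between part, block
differences for the within part — which this module delegates to
statsmodels with Type III sums of squares (unweighted marginal means, the
convention of mainstream ANOVA software for unbalanced groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

BLOCKS = ("block1", "block2")

#: Planned contrast weights on the canonical condition order (block-difference
#: scale): within experiment 1, within experiment 2, experiment 1 vs 2.
DEFAULT_CONTRASTS: Tuple[Tuple[str, Dict[str, float]], ...] = (
    ("confirmation vs violation",
     {"confirmation": 1.0, "violation": -1.0}),
    ("violation_inhibiting vs violation_enhancing",
     {"violation_inhibiting": 1.0, "violation_enhancing": -1.0}),
    ("experiment1 vs experiment2",
     {"confirmation": 0.5, "violation": 0.5,
      "violation_inhibiting": -0.5, "violation_enhancing": -0.5}),
)


@dataclass
class GroupSummary:
    """Per (condition x block) mean, sample SD and n of accuracy (%)."""

    table: pd.DataFrame  # columns: condition, block, mean, sd, n

    @classmethod
    def from_participants(cls, df: pd.DataFrame) -> "GroupSummary":
        if df.empty:
            raise ValueError("no participants to summarise")
        rows = []
        for cond, sub in df.groupby("condition", sort=False):
            for block in BLOCKS:
                col = f"accuracy_{block}"
                vals = sub[col].to_numpy(dtype=float)
                if vals.size == 0:
                    raise ValueError(f"empty cell: {cond} x {block}")
                rows.append({
                    "condition": cond, "block": block,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n": int(vals.size),
                })
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_means(
        cls,
        means: Mapping[str, Tuple[float, float]],
        sds: Optional[Mapping[str, Tuple[float, float]]] = None,
        ns: Optional[Mapping[str, int]] = None,
    ) -> "GroupSummary":
        """Build a summary from printed (block1, block2) group means, e.g. to
        rerun worked-example contrasts from a published table."""
        rows = []
        for cond, (m1, m2) in means.items():
            for block, m in zip(BLOCKS, (m1, m2)):
                sd = sds[cond][BLOCKS.index(block)] if sds else np.nan
                rows.append({
                    "condition": cond, "block": block, "mean": float(m),
                    "sd": float(sd), "n": int(ns[cond]) if ns else 0,
                })
        return cls(pd.DataFrame(rows))

    def mean(self, condition: str, block: str) -> float:
        t = self.table
        sel = t[(t["condition"] == condition) & (t["block"] == block)]
        if sel.empty:
            raise KeyError(f"no cell {condition!r} x {block!r}")
        return float(sel["mean"].iloc[0])

    def conditions(self) -> List[str]:
        return list(dict.fromkeys(self.table["condition"]))


def summarize_cohort(data: Union[pd.DataFrame, Iterable]) -> GroupSummary:
    """Table-shaped accuracy summary from a per-participant frame or a list
    of participant records. Excluded participants are omitted."""
    if not isinstance(data, pd.DataFrame):
        from .experiment import records_to_frame
        data = records_to_frame(data)
    if "excluded" in data.columns:
        data = data[data["excluded"] == 0]
    return GroupSummary.from_participants(data)


@dataclass(frozen=True)
class ContrastResult:
    label: str
    m_diff: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_adjusted: Optional[float] = None
    method: str = "none"

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.m_diff <= self.ci_high):
                raise ValueError("CI must bracket the mean difference")


def bonferroni_adjust(
    p_values: Sequence[float], family_size: Optional[int] = None
) -> np.ndarray:
    """min(1, p * m); order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else p.size
    return np.minimum(1.0, p * m)


def _pooled_t_interval(
    a: np.ndarray, b: np.ndarray, family_size: int, confidence: float = 0.95
) -> Tuple[float, float, float, float]:
    """Pooled-variance two-sample t difference with a Bonferroni-adjusted CI.

    Returns (diff, ci_low, ci_high, p_adjusted)."""
    na, nb = a.size, b.size
    diff = float(a.mean() - b.mean())
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se = float(np.sqrt(sp2 * (1 / na + 1 / nb)))
    if se == 0:
        p_adj = 0.0 if diff != 0 else 1.0
        return diff, diff, diff, p_adj
    tstat = diff / se
    p_raw = 2 * scipy.stats.t.sf(abs(tstat), df)
    alpha_adj = (1 - confidence) / family_size
    tcrit = scipy.stats.t.ppf(1 - alpha_adj / 2, df)
    return (diff, diff - tcrit * se, diff + tcrit * se,
            float(min(1.0, p_raw * family_size)))


def posthoc_mean_difference(
    summary: GroupSummary,
    group_a: str,
    group_b: str,
    block: str,
    raw: Optional[pd.DataFrame] = None,
    family_size: int = 6,
) -> ContrastResult:
    """Mean accuracy difference (group_a - group_b) in one block.

    From summary means alone only the point difference is available; with a
    raw per-participant frame a pooled-variance t CI and Bonferroni-adjusted
    p over ``family_size`` pairwise comparisons (6 for four groups) are added.
    """
    m_diff = summary.mean(group_a, block) - summary.mean(group_b, block)
    label = f"{group_a} vs {group_b} ({block})"
    if raw is None:
        return ContrastResult(label, m_diff)
    col = f"accuracy_{block}"
    a = raw.loc[raw["condition"] == group_a, col].to_numpy(dtype=float)
    b = raw.loc[raw["condition"] == group_b, col].to_numpy(dtype=float)
    diff, lo, hi, p_adj = _pooled_t_interval(a, b, family_size)
    return ContrastResult(label, diff, lo, hi, p_adj, method="bonferroni")


def marginal_mean_difference(
    summary: GroupSummary,
    group_a: str,
    group_b: str,
    raw: Optional[pd.DataFrame] = None,
    family_size: int = 6,
) -> ContrastResult:
    """Between-group difference of accuracies averaged over both blocks
    (the repeated-measures marginal means)."""
    ma = np.mean([summary.mean(group_a, b) for b in BLOCKS])
    mb = np.mean([summary.mean(group_b, b) for b in BLOCKS])
    label = f"{group_a} vs {group_b} (marginal)"
    if raw is None:
        return ContrastResult(label, float(ma - mb))
    subj = raw[["accuracy_block1", "accuracy_block2"]].mean(axis=1)
    a = subj[raw["condition"] == group_a].to_numpy(dtype=float)
    b = subj[raw["condition"] == group_b].to_numpy(dtype=float)
    diff, lo, hi, p_adj = _pooled_t_interval(a, b, family_size)
    return ContrastResult(label, diff, lo, hi, p_adj, method="bonferroni")


def _safe_f(ss_effect: float, df1: int, ss_error: float, df2: int) -> Tuple[float, float]:
    """F and p with the degenerate cases pinned: 0/0 -> F = 0, x/0 -> inf."""
    if ss_effect <= 0:
        return 0.0, 1.0
    if ss_error <= 0:
        return float("inf"), 0.0
    f = (ss_effect / df1) / (ss_error / df2)
    return float(f), float(scipy.stats.f.sf(f, df1, df2))


def _eta_sq_p(ss_effect: float, ss_error: float) -> float:
    if ss_effect <= 0:
        return 0.0
    return float(ss_effect / (ss_effect + ss_error))


class MixedAnova:
    """Mixed-design ANOVA model: condition (between) x block (within, 2 levels).

    Built from a wide per-participant frame with ``condition``,
    ``accuracy_block1`` and ``accuracy_block2`` columns; ``fit()`` returns a
    :class:`MixedAnovaResults`.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        group: str = "condition",
        dv_block1: str = "accuracy_block1",
        dv_block2: str = "accuracy_block2",
        contrasts: Optional[Sequence[Tuple[str, Dict[str, float]]]] = None,
    ) -> None:
        for col in (group, dv_block1, dv_block2):
            if col not in data.columns:
                raise ValueError(f"missing column: {col!r}")
        counts = data[group].value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"singular design: fewer than 2 participants in {small}")
        self.data = data.reset_index(drop=True)
        self.group = group
        self.dv_block1 = dv_block1
        self.dv_block2 = dv_block2
        if contrasts is None:
            labels = set(data[group])
            contrasts = tuple(
                (name, w) for name, w in DEFAULT_CONTRASTS
                if set(w) <= labels
            )
        self.contrasts = tuple(contrasts)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "MixedAnova":
        return cls(data, **kwargs)

    def fit(self) -> "MixedAnovaResults":
        df = self.data
        g = df[self.group].astype(str)
        b1 = df[self.dv_block1].to_numpy(dtype=float)
        b2 = df[self.dv_block2].to_numpy(dtype=float)
        subj_mean = 0.5 * (b1 + b2)
        diff = b2 - b1
        n_total = len(df)
        n_groups = g.nunique()
        df_err = n_total - n_groups

        work = pd.DataFrame({"g": g, "s": subj_mean, "d": diff})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # typ-3 anova warns on 0-SS corner cases
            fit_d = smf.ols("d ~ C(g, Sum)", data=work).fit()
            aov_d = sm.stats.anova_lm(fit_d, typ=3)
            fit_s = smf.ols("s ~ C(g, Sum)", data=work).fit()
            aov_s = sm.stats.anova_lm(fit_s, typ=3)

        # canonical repeated-measures scale: within terms are OLS-on-d SS / 2,
        # between terms are OLS-on-subject-means SS * 2 (two within levels)
        ss_time = float(aov_d.loc["Intercept", "sum_sq"]) / 2.0
        ss_inter = float(aov_d.loc["C(g, Sum)", "sum_sq"]) / 2.0
        ss_werr = float(fit_d.ssr) / 2.0
        ss_cond = float(aov_s.loc["C(g, Sum)", "sum_sq"]) * 2.0
        ss_berr = float(fit_s.ssr) * 2.0

        # Degenerate designs: statsmodels reports NaN type-III SS when a term
        # is rank-deficient (e.g. an exactly-zero response), and float noise
        # can leave ~1e-30 residuals. Sanitise both so the definitional
        # limits (F = 0 or inf, eta^2 = 0 or 1) come out cleanly.
        terms = [ss_time, ss_inter, ss_werr, ss_cond, ss_berr]
        terms = [0.0 if not np.isfinite(ss) else ss for ss in terms]
        snap = 1e-12 * max(1.0, sum(terms))
        ss_time, ss_inter, ss_werr, ss_cond, ss_berr = (
            0.0 if ss < snap else ss for ss in terms
        )

        rows = []
        for effect, ss, df1, ss_err in (
            ("time", ss_time, 1, ss_werr),
            ("condition", ss_cond, n_groups - 1, ss_berr),
            ("time:condition", ss_inter, n_groups - 1, ss_werr),
        ):
            f, p = _safe_f(ss, df1, ss_err, df_err)
            rows.append({
                "effect": effect, "ss": ss, "ss_error": ss_err,
                "df1": df1, "df2": df_err, "F": f, "p": p,
                "eta_sq_p": _eta_sq_p(ss, ss_err),
            })
        anova_table = pd.DataFrame(rows).set_index("effect")

        # planned contrasts on the block-difference scores, pooled error
        gm = work.groupby("g")["d"].mean()
        gn = work.groupby("g")["d"].size()
        mse_d = fit_d.ssr / df_err if df_err > 0 else 0.0
        crows = []
        for name, weights in self.contrasts:
            L = float(sum(w * gm[lab] for lab, w in weights.items()))
            scale = float(sum(w**2 / gn[lab] for lab, w in weights.items()))
            ss_c = (L**2 / scale) / 2.0 if scale > 0 else 0.0
            f, p = _safe_f(ss_c, 1, ss_werr, df_err)
            crows.append({
                "contrast": name, "estimate": L, "F": f,
                "df1": 1, "df2": df_err, "p": p,
                "eta_sq_p": _eta_sq_p(ss_c, ss_werr),
            })
        contrast_table = pd.DataFrame(crows)
        return MixedAnovaResults(self, anova_table, contrast_table)


@dataclass
class MixedAnovaResults:
    """Fitted mixed-ANOVA effects and planned contrasts."""

    model: MixedAnova
    anova_table: pd.DataFrame
    contrast_table: pd.DataFrame

    def summary(self) -> str:
        lines = ["Mixed-design ANOVA (condition x block)", ""]
        tab = self.anova_table.copy()
        lines.append(tab.to_string(
            float_format=lambda x: f"{x:.4f}", columns=["ss", "df1", "df2", "F", "p", "eta_sq_p"]
        ))
        if len(self.contrast_table):
            lines += ["", "Planned contrasts (block-difference scores)", ""]
            lines.append(self.contrast_table.to_string(
                index=False, float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)


def mixed_anova(
    data: pd.DataFrame,
    group: str = "condition",
    dv_block1: str = "accuracy_block1",
    dv_block2: str = "accuracy_block2",
    contrasts: Optional[Sequence[Tuple[str, Dict[str, float]]]] = None,
) -> MixedAnovaResults:
    """Convenience wrapper: build and fit :class:`MixedAnova`."""
    return MixedAnova(data, group, dv_block1, dv_block2, contrasts).fit()


def manipulation_check_summary(
    data: pd.DataFrame,
    columns: Sequence[str] = ("post_block1", "prediction_block2", "post_block2"),
    group: str = "condition",
) -> pd.DataFrame:
    """Per-condition M (SD) of self-assessment items (pass-through data).

    Single-participant cells get SD = NaN and a warning — the dispersion is
    undefined there.
    """
    for col in columns:
        if col not in data.columns:
            raise ValueError(f"missing column: {col!r}")
    rows = []
    for cond, sub in data.groupby(group, sort=False):
        row: Dict[str, object] = {"condition": cond, "n": len(sub)}
        for col in columns:
            vals = sub[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(vals.mean())
            if vals.size > 1:
                row[f"{col}_sd"] = float(vals.std(ddof=1))
            else:
                warnings.warn(f"single observation in {cond!r}: SD undefined")
                row[f"{col}_sd"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
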