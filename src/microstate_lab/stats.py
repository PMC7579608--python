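"""Group statistics for the 2 x 2 mixed design.

One between-subject factor (group) and one within-subject factor
(recording condition), analyzed per microstate class and parameter with a
classical repeated-measures ANOVA: the group effect is tested against
subjects-within-groups, condition and the interaction against the
condition x subjects-within-groups error term. Effect size is partial eta
squared; "observed power" is the retrospective noncentral-F convention
(noncentrality λ = F·df1) reported by common statistics packages — a
monotone transform of the p-value, reported for comparability, not a
design-stage power estimate.

Significant interactions are decomposed into four simple-effect contrasts
(paired t within each group, two-sample t within each condition) at a
Bonferroni-corrected α of 0.05/4 = 0.0125.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sstats

__all__ = [
    "MixedAnova",
    "MixedAnovaResults",
    "observed_power",
    "posthoc_bonferroni",
    "log_transform_correlate",
    "correlate_covariates",
]

POSTHOC_ALPHA = 0.05 / 4  # Bonferroni over the four simple-effect contrasts


def _finite_t(t, p):
    """Resolve degenerate t statistics: zero-variance, zero-mean data is a
    certain null (t=0, p=1); zero-variance nonzero differences stay at the
    certain-rejection limit scipy already returns (|t|=inf, p=0)."""
    t, p = float(t), float(p)
    if np.isnan(t):
        return 0.0, 1.0
    return t, p


def observed_power(
    f: float, df1: int, df2: int, alpha: float = 0.05
) -> float:
    """Retrospective power of an observed F test.

    Uses the noncentral-F tail with noncentrality ``λ = F·df1``:
    ``P(F'(df1, df2, λ) > F_crit(α))``. At F=0 this degrades to the α-level
    false-positive floor.
    """
    if f < 0 or df1 < 1 or df2 < 1:
        raise ValueError("need F >= 0 and dfs >= 1")
    fcrit = sstats.f.isf(alpha, df1, df2)
    lam = f * df1
    if lam == 0:  # central case; scipy's ncf is unreliable at zero noncentrality
        return float(sstats.f.sf(fcrit, df1, df2))
    return float(sstats.ncf.sf(fcrit, df1, df2, lam))


class MixedAnova:
    """2 x 2 mixed-design ANOVA model for a tidy table of one dependent variable.

    Parameters
    ----------
    data
        Long-format DataFrame with one row per subject x within-level.
    dv, between, within, subject
        Column names. Exactly two levels of ``between`` and ``within`` are
        supported; subjects missing either within-level are rejected (no
        imputation).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str = "value",
        between: str = "group",
        within: str = "condition",
        subject: str = "participant",
    ) -> None:
        data = data[[subject, between, within, dv]].copy()
        if data[dv].isna().any():
            raise ValueError("missing dependent-variable values")
        if data[between].nunique() != 2 or data[within].nunique() != 2:
            raise ValueError("only 2 x 2 designs are supported")
        counts = data.groupby(subject)[within].nunique()
        if (counts != 2).any():
            bad = counts.index[counts != 2].tolist()
            raise ValueError(f"incomplete within-subject data for {bad}")
        if data.groupby([subject, within]).size().max() > 1:
            raise ValueError("duplicate rows per subject x condition")
        self.data = data
        self.dv, self.between, self.within, self.subject = dv, between, within, subject

    def fit(self, alpha: float = 0.05) -> "MixedAnovaResults":
        df_subj = self.data[self.subject].nunique() - 2
        if np.ptp(self.data[self.dv].to_numpy()) == 0:
            # degenerate all-equal data: every effect is exactly null
            effects = {
                name: {
                    "F": 0.0,
                    "df1": 1,
                    "df2": df_subj,
                    "p": 1.0,
                    "partial_eta_sq": 0.0,
                    "observed_power": observed_power(0.0, 1, max(df_subj, 1), alpha),
                }
                for name in ("group", "condition", "interaction")
            }
        else:
            # private dv name: pingouin melts internally and rejects dv
            # columns that collide with its reserved names
            work = self.data.rename(columns={self.dv: "_dv_"})
            aov = pg.mixed_anova(
                data=work,
                dv="_dv_",
                within=self.within,
                subject=self.subject,
                between=self.between,
                correction=False,
            ).set_index("Source")
            name_map = {
                self.between: "group",
                self.within: "condition",
                "Interaction": "interaction",
            }
            effects = {}
            for src, name in name_map.items():
                row = aov.loc[src]
                f = float(row["F"])
                df1, df2 = int(row["DF1"]), int(row["DF2"])
                effects[name] = {
                    "F": f,
                    "df1": df1,
                    "df2": df2,
                    "p": float(row["p_unc"]),
                    "partial_eta_sq": float(row["np2"]),
                    "observed_power": observed_power(f, df1, df2, alpha),
                }
        cells = (
            self.data.groupby([self.between, self.within])[self.dv]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        return MixedAnovaResults(self, alpha, effects, cells)


@dataclass(frozen=True)
class MixedAnovaResults:
    """Fitted effects of the 2 x 2 mixed ANOVA."""

    model: MixedAnova = field(repr=False)
    alpha: float
    effects: dict = field(repr=False)
    cell_stats: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append({"effect": name, **e})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "2 x 2 mixed ANOVA "
            f"(between: {self.model.between}, within: {self.model.within})",
            f"{'effect':>22} {'df':>8} {'F':>9} {'Sig.':>8} "
            f"{'partial η²':>11} {'obs. power':>11}",
        ]
        for name, e in self.effects.items():
            lines.append(
                f"{name:>22} {e['df1']:>3}, {e['df2']:<3} {e['F']:>9.3f} "
                f"{e['p']:>8.3f} {e['partial_eta_sq']:>11.3f} "
                f"{e['observed_power']:>11.3f}"
            )
        lines.append("")
        lines.append("cell means:")
        for _, row in self.cell_stats.iterrows():
            lines.append(
                f"  {row[self.model.between]:>6} {row[self.model.within]:>4}: "
                f"{row['mean']:.3f} (SD {row['std']:.3f}, n={int(row['count'])})"
            )
        return "\n".join(lines)


def posthoc_bonferroni(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "condition",
    subject: str = "participant",
    alpha: float = POSTHOC_ALPHA,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Four simple-effect contrasts decomposing a group x condition interaction.

    Within each group: paired t between the two conditions; within each
    condition: two-sample t between the groups (pooled variance by
    default). Significance is judged at the Bonferroni-corrected ``alpha``
    (0.05/4 = 0.0125 for the four contrasts).
    """
    groups = sorted(data[between].unique())
    conds = sorted(data[within].unique())
    if len(groups) != 2 or len(conds) != 2:
        raise ValueError("posthoc decomposition expects a 2 x 2 design")
    wide = data.pivot_table(
        index=[subject, between], columns=within, values=dv
    ).reset_index()
    rows = []
    for g in groups:
        sub = wide[wide[between] == g]
        if len(sub) < 2:
            raise ValueError(f"need >= 2 subjects per cell (group {g})")
        t, p = _finite_t(*sstats.ttest_rel(sub[conds[0]], sub[conds[1]]))
        diff = float(sub[conds[0]].mean() - sub[conds[1]].mean())
        rows.append(
            {
                "contrast": f"{g}: {conds[0]} vs {conds[1]}",
                "type": "paired",
                "t": float(t),
                "df": len(sub) - 1,
                "p_raw": float(p),
                "mean_diff": diff,
                "significant": bool(p < alpha),
            }
        )
    for c in conds:
        a = wide[wide[between] == groups[0]][c]
        b = wide[wide[between] == groups[1]][c]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >= 2 subjects per cell (condition {c})")
        t, p = _finite_t(*sstats.ttest_ind(a, b, equal_var=equal_var))
        rows.append(
            {
                "contrast": f"{c}: {groups[0]} vs {groups[1]}",
                "type": "independent",
                "t": float(t),
                "df": len(a) + len(b) - 2,
                "p_raw": float(p),
                "mean_diff": float(a.mean() - b.mean()),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def log_transform_correlate(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of a log(x+1)-transformed covariate with a parameter.

    The transform tames the right skew typical of psychometric scores; the
    covariate must be non-negative. Returns (r, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.any(x < 0):
        raise ValueError("covariate must be non-negative for log(x+1)")
    xt = np.log1p(x)
    if np.std(xt) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = sstats.pearsonr(xt, y)
    return float(r), float(p)


def correlate_covariates(
    covariates: pd.DataFrame,
    y: pd.Series,
    names: list[str],
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """log(x+1) Pearson correlations for a declared covariate family.

    Bonferroni-corrects over the family: each test is judged at
    ``family_alpha / len(names)``.
    """
    alpha = family_alpha / len(names)
    rows = []
    for name in names:
        merged = pd.concat([covariates[name], y], axis=1).dropna()
        r, p = log_transform_correlate(
            merged[name].to_numpy(), merged.iloc[:, 1].to_numpy()
        )
        rows.append(
            {
                "covariate": name,
                "n": len(merged),
                "r": r,
                "p_raw": p,
                "alpha_corrected": alpha,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
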