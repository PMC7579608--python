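"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (cell-mean
arithmetic, exhaustive search, series expansions) so that they share no
code path with the implementations they check.
"""

import itertools

import numpy as np
from scipy import stats as sstats


def mixed_anova_bruteforce(df, dv="value", between="group", within="condition",
                           subject="participant"):
    """Classical 2x2 mixed-design sums-of-squares decomposition via means.

    Balanced within-factor (every subject has both conditions); equal group
    sizes assumed. Returns per-effect dicts with SS, df and F.
    """
    groups = sorted(df[between].unique())
    conds = sorted(df[within].unique())
    subjects = sorted(df[subject].unique())
    y = {
        (r[subject], r[within]): r[dv] for _, r in df.iterrows()
    }
    group_of = dict(zip(df[subject], df[between]))
    n_c = len(conds)
    grand = np.mean(list(y.values()))
    subj_mean = {s: np.mean([y[(s, c)] for c in conds]) for s in subjects}
    group_mean = {
        g: np.mean([subj_mean[s] for s in subjects if group_of[s] == g])
        for g in groups
    }
    cond_mean = {
        c: np.mean([y[(s, c)] for s in subjects]) for c in conds
    }
    cell_mean = {
        (g, c): np.mean([y[(s, c)] for s in subjects if group_of[s] == g])
        for g in groups
        for c in conds
    }
    n_g = {g: sum(1 for s in subjects if group_of[s] == g) for g in groups}

    ss_group = n_c * sum(n_g[g] * (group_mean[g] - grand) ** 2 for g in groups)
    ss_between_subj = n_c * sum((subj_mean[s] - grand) ** 2 for s in subjects)
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = sum(
        len(subjects) * (cond_mean[c] - grand) ** 2 for c in conds
    )
    ss_inter = sum(
        n_g[g]
        * (cell_mean[(g, c)] - group_mean[g] - cond_mean[c] + grand) ** 2
        for g in groups
        for c in conds
    )
    ss_within = sum(
        (y[(s, c)] - subj_mean[s]) ** 2 for s in subjects for c in conds
    )
    ss_err_within = ss_within - ss_cond - ss_inter

    df_subj = sum(n_g[g] - 1 for g in groups)
    out = {}
    for name, ss_eff, ss_err, df_err in (
        ("group", ss_group, ss_subj_within, df_subj),
        ("condition", ss_cond, ss_err_within, df_subj),
        ("interaction", ss_inter, ss_err_within, df_subj),
    ):
        f = (ss_eff / 1.0) / (ss_err / df_err)
        out[name] = {
            "SS": ss_eff,
            "df1": 1,
            "df2": df_err,
            "F": f,
            "partial_eta_sq": ss_eff / (ss_eff + ss_err),
            "p": float(sstats.f.sf(f, 1, df_err)),
        }
    out["_total"] = {
        "SS_total": float(
            sum((v - grand) ** 2 for v in y.values())
        ),
        "components": ss_group + ss_subj_within + ss_cond + ss_inter + ss_err_within,
    }
    return out


def noncentral_f_tail_series(crit, df1, df2, lam, n_terms=400):
    """P(F'(df1, df2, lam) > crit) via the Poisson mixture of central F laws.

    A noncentral chi-square(df1, lam) is a Poisson(lam/2) mixture of central
    chi-squares with df1 + 2j dofs, so the noncentral F tail is the matching
    mixture of rescaled central F tails.
    """
    j = np.arange(n_terms)
    w = sstats.poisson.pmf(j, lam / 2.0)
    tails = sstats.f.sf(crit * df1 / (df1 + 2 * j), df1 + 2 * j, df2)
    return float(np.sum(w * tails))


def sort_by_exhaustive_search(maps, normative):
    """Reference label assignment: try all permutations with np.corrcoef."""
    k = maps.shape[0]
    best, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(
            abs(np.corrcoef(maps[perm[j]], normative[j])[0, 1]) for j in range(k)
        )
        if score > best_score + 1e-12:
            best_score, best = score, perm
    return best, best_score
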