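"""Group-comparison and correlation statistics for tissue endpoints.

The battery mirrors common practice for engineered-tissue dose-response
designs: a normality/homoscedasticity gate (Shapiro-Wilk per group, Levene
across groups) routes each endpoint to one-way ANOVA with Tukey HSD
(parametric) or the tie-corrected Kruskal-Wallis test with the Conover-Iman
post-hoc on ranks (nonparametric).  Pairwise outcomes are condensed into a
compact letter display: groups sharing a letter are not significantly
different at alpha.  Correlations across endpoints use Spearman's rho with
Bonferroni adjustment over all tested pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "CorrelationMatrix",
    "validate_table",
    "extract_groups",
    "normality_gate",
    "anova_tukey",
    "kruskal_conover",
    "conover_pairwise",
    "spearman_matrix",
    "compact_letters",
    "compare",
]

ALPHA_DEFAULT = 0.05


@dataclass
class GroupComparison:
    """Omnibus + pairwise result for one endpoint across groups."""

    method: str  # "anova_tukey" | "kruskal_conover"
    statistic: float  # F or H
    p_value: float
    pairwise_p: pd.DataFrame  # symmetric, unit diagonal
    letters: dict[str, str]
    alpha: float = ALPHA_DEFAULT
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "groups": list(self.pairwise_p.columns),
            "pairwise_p": self.pairwise_p.to_numpy().tolist(),
            "letters": self.letters,
            "warnings": self.warnings,
        }


@dataclass
class CorrelationMatrix:
    """Spearman rho across variables with raw and Bonferroni-adjusted p."""

    variables: list[str]
    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    n_pairs_tested: int


def validate_table(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    min_per_group: int = 3,
) -> None:
    """Check a long-format table is fit for group testing.

    Requires no missing group labels or values, >= 2 groups and at least
    ``min_per_group`` values in every group.
    """
    if group_col not in table or value_col not in table:
        raise ValueError(f"table needs columns {group_col!r} and {value_col!r}")
    if table[group_col].isna().any():
        raise ValueError("missing group labels")
    if table[value_col].isna().any():
        raise ValueError("missing values in the value column")
    counts = table.groupby(group_col, sort=False)[value_col].count()
    if len(counts) < 2:
        raise ValueError(f"need >= 2 groups, got {len(counts)}")
    small = counts[counts < min_per_group]
    if len(small):
        raise ValueError(
            f"groups below n={min_per_group}: {dict(small)}"
        )


def extract_groups(
    table, value_col: str = "value", group_col: str = "group"
) -> tuple[list[str], list[np.ndarray]]:
    """Accept a long DataFrame or a mapping label -> array; return labels, arrays."""
    if isinstance(table, pd.DataFrame):
        labels = list(dict.fromkeys(table[group_col]))
        arrays = [
            table.loc[table[group_col] == g, value_col].to_numpy(dtype=float)
            for g in labels
        ]
    else:
        labels = list(table)
        arrays = [np.asarray(table[g], dtype=float) for g in labels]
    return labels, arrays


def normality_gate(table, alpha: float = ALPHA_DEFAULT) -> tuple[str, dict]:
    """Route to "parametric" or "nonparametric" testing.

    Parametric iff every group passes Shapiro-Wilk at ``alpha`` AND Levene's
    test across groups passes at ``alpha``.  A zero-variance group forces the
    nonparametric route with a warning (Shapiro-Wilk is undefined there).
    """
    labels, arrays = extract_groups(table)
    detail: dict = {"alpha": alpha, "shapiro_p": {}, "levene_p": None, "warnings": []}
    for g, a in zip(labels, arrays):
        if len(a) < 3:
            raise ValueError(f"group {g!r} has n={len(a)} < 3")
        if np.ptp(a) == 0:
            detail["warnings"].append(f"group {g!r} has zero variance")
            detail["route"] = "nonparametric"
            return "nonparametric", detail
        detail["shapiro_p"][g] = float(stats.shapiro(a).pvalue)
    detail["levene_p"] = float(stats.levene(*arrays).pvalue)
    parametric = all(p > alpha for p in detail["shapiro_p"].values()) and (
        detail["levene_p"] > alpha
    )
    route = "parametric" if parametric else "nonparametric"
    detail["route"] = route
    return route, detail


def anova_tukey(table, alpha: float = ALPHA_DEFAULT) -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise comparisons and letters."""
    labels, arrays = extract_groups(table)
    if len(labels) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; ANOVA undefined")
    f_res = stats.f_oneway(*arrays)
    k = len(labels)
    pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    if np.all([np.array_equal(a, arrays[0]) for a in arrays]) or f_res.statistic == 0:
        # zero between-group variance: Tukey p-values are all 1
        pass
    else:
        group_codes = np.concatenate(
            [np.full(len(a), i) for i, a in enumerate(arrays)]
        )
        hsd = pairwise_tukeyhsd(pooled, group_codes, alpha=alpha)
        for (i, j), p in zip(
            itertools.combinations(range(k), 2), np.atleast_1d(hsd.pvalues)
        ):
            pmat.iloc[i, j] = pmat.iloc[j, i] = float(p)
    letters = compact_letters(pmat, alpha=alpha)
    stat = float(f_res.statistic)
    p = float(f_res.pvalue)
    if stat == 0.0:
        p = 1.0
    return GroupComparison("anova_tukey", stat, p, pmat, letters, alpha)


def conover_pairwise(arrays: list[np.ndarray], h_statistic: float) -> np.ndarray:
    """Conover-Iman pairwise t tests on pooled ranks.

    Uses average ranks for ties, the pooled rank variance S^2, the
    (N-1-H)/(N-k) shrinkage and a t distribution with N-k degrees of
    freedom; returns the symmetric matrix of two-sided unadjusted p-values.
    """
    k = len(arrays)
    sizes = np.array([len(a) for a in arrays])
    n_total = int(sizes.sum())
    ranks = stats.rankdata(np.concatenate(arrays))
    mean_ranks = []
    pos = 0
    for n in sizes:
        mean_ranks.append(ranks[pos : pos + n].mean())
        pos += n
    mean_ranks = np.array(mean_ranks)
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    df = n_total - k
    scale = s2 * (n_total - 1 - h_statistic) / df
    pmat = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            p = 0.0 if mean_ranks[i] != mean_ranks[j] else 1.0
        else:
            t = abs(mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.t.sf(t, df)
        pmat[i, j] = pmat[j, i] = min(1.0, p)
    return pmat


def kruskal_conover(
    table, alpha: float = ALPHA_DEFAULT, p_adjust: str | None = None
) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis omnibus with the Conover-Iman post-hoc.

    ``p_adjust`` may be None (unadjusted pairwise p, the conventional
    default for this post-hoc) or any method accepted by
    ``statsmodels.stats.multitest.multipletests`` (e.g. "holm").
    """
    labels, arrays = extract_groups(table)
    if len(labels) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    warnings: list[str] = []
    n_total = sum(len(a) for a in arrays)
    if n_total < 5:
        warnings.append("total n < 5: chi-square approximation unreliable")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; ranks are degenerate")
    h_res = stats.kruskal(*arrays)
    h, p = float(h_res.statistic), float(h_res.pvalue)
    pmat_arr = conover_pairwise(arrays, h)
    if p_adjust is not None:
        k = len(labels)
        iu = np.triu_indices(k, 1)
        adj = multipletests(pmat_arr[iu], method=p_adjust)[1]
        pmat_arr[iu] = adj
        pmat_arr[(iu[1], iu[0])] = adj
    pmat = pd.DataFrame(pmat_arr, index=labels, columns=labels)
    letters = compact_letters(pmat, alpha=alpha)
    return GroupComparison("kruskal_conover", h, p, pmat, letters, alpha, warnings)


def compact_letters(pairwise_p, alpha: float = ALPHA_DEFAULT) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Produces the minimal-style letter assignment in which two groups share
    at least one letter iff their pairwise p >= alpha.
    """
    if isinstance(pairwise_p, pd.DataFrame):
        labels = list(pairwise_p.columns)
        pmat = pairwise_p.to_numpy()
    else:
        pmat = np.asarray(pairwise_p, dtype=float)
        labels = [str(i) for i in range(pmat.shape[0])]
    if pmat.shape[0] != pmat.shape[1] or not np.allclose(pmat, pmat.T):
        raise ValueError("pairwise_p must be a symmetric square matrix")
    k = len(labels)
    columns: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if pmat[i, j] >= alpha:
            continue
        new_columns: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                new_columns.append(col - {i})
                new_columns.append(col - {j})
            else:
                new_columns.append(col)
        # absorb: drop empty columns, duplicates and strict subsets
        uniq: list[set[int]] = []
        for col in new_columns:
            if col and col not in uniq:
                uniq.append(col)
        columns = [c for c in uniq if not any(c < o for o in uniq)]
    columns.sort(key=lambda c: (min(c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in labels}
    for idx, col in enumerate(columns):
        ch = alphabet[idx] if idx < len(alphabet) else f"({idx})"
        for member in sorted(col):
            letters[labels[member]] += ch
    return letters


def spearman_matrix(data: pd.DataFrame, min_n: int = 3) -> CorrelationMatrix:
    """Pairwise Spearman rho over the columns of a wide table.

    rho is the Pearson correlation of average-ranked data; raw p uses the t
    approximation; Bonferroni multiplies by the number of unique off-diagonal
    pairs actually tested.  Pairs with fewer than ``min_n`` complete
    observations or a constant variable are recorded missing (NaN).
    """
    variables = list(data.columns)
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p_raw = pd.DataFrame(np.full((k, k), np.nan), index=variables, columns=variables)
    np.fill_diagonal(p_raw.values, 0.0)
    tested = []
    for i, j in itertools.combinations(range(k), 2):
        sub = data.iloc[:, [i, j]].dropna()
        x, y = sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)
        if len(sub) < min_n or np.ptp(x) == 0 or np.ptp(y) == 0:
            rho.iloc[i, j] = rho.iloc[j, i] = np.nan
            continue
        res = stats.spearmanr(x, y)
        rho.iloc[i, j] = rho.iloc[j, i] = float(res.statistic)
        p_raw.iloc[i, j] = p_raw.iloc[j, i] = float(res.pvalue)
        tested.append((i, j))
    m = len(tested)
    p_adj = p_raw.copy()
    for i, j in tested:
        p_adj.iloc[i, j] = p_adj.iloc[j, i] = min(1.0, m * p_raw.iloc[i, j])
    return CorrelationMatrix(variables, rho, p_raw, p_adj, n_pairs_tested=m)


def compare(
    table,
    alpha: float = ALPHA_DEFAULT,
    method: str = "auto",
    p_adjust: str | None = None,
) -> GroupComparison:
    """Run the gated battery on one endpoint.

    ``method`` is "auto" (normality gate decides), "anova" or "kw"; the gate
    is advisory and either branch may be forced.
    """
    if method == "auto":
        route, detail = normality_gate(table, alpha=alpha)
        method = "anova" if route == "parametric" else "kw"
        result = (
            anova_tukey(table, alpha=alpha)
            if method == "anova"
            else kruskal_conover(table, alpha=alpha, p_adjust=p_adjust)
        )
        result.warnings.extend(detail.get("warnings", []))
        return result
    if method == "anova":
        return anova_tukey(table, alpha=alpha)
    if method == "kw":
        return kruskal_conover(table, alpha=alpha, p_adjust=p_adjust)
    raise ValueError(f"unknown method {method!r}")
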