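"""Group statistics for the stage × genotype design.

Every biomarker in this pipeline is compared across a two-factor design —
genotype (3xTg vs non-transgenic) crossed with disease stage (pre-, early-,
late-symptomatic) — with a two-way ANOVA followed by Holm–Šidák step-down
multiple comparisons, and aggregate volumes in the retina are correlated
with those in the hippocampus by Pearson's r.

The ANOVA is computed from sums of squares of nested least-squares fits
(Type II for unbalanced designs: each main effect is adjusted for the
other, the interaction for both), with F p-values from the F distribution.
The Holm–Šidák adjustment sorts the m raw p-values ascending and sets
``p_adj(i) = max_{j<=i} min(1, 1 - (1 - p(j))^(m - j + 1))``, reported in
the original order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatResult",
    "two_way_anova",
    "pairwise_comparisons",
    "holm_sidak",
    "pearson_r",
]


@dataclass
class StatResult:
    """ANOVA table plus optional pairwise-comparison table."""

    anova: pd.DataFrame  # index: effect; columns: sum_sq, df, F, p
    pairwise: pd.DataFrame | None = None
    r: float | None = None
    n: int | None = None


def _design_matrices(a_codes: np.ndarray, b_codes: np.ndarray,
                     n_a: int, n_b: int) -> dict[str, np.ndarray]:
    """Full-rank (treatment-coded) design blocks: intercept, A, B, AB."""
    n = len(a_codes)
    intercept = np.ones((n, 1))
    A = np.zeros((n, n_a - 1))
    for lvl in range(1, n_a):
        A[a_codes == lvl, lvl - 1] = 1.0
    B = np.zeros((n, n_b - 1))
    for lvl in range(1, n_b):
        B[b_codes == lvl, lvl - 1] = 1.0
    AB = np.einsum("ij,ik->ijk", A, B).reshape(n, -1)
    return {"1": intercept, "A": A, "B": B, "AB": AB}


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "stage",
    pairwise: bool = True,
) -> StatResult:
    """Two-way ANOVA with interaction (Type II sums of squares).

    ``data`` holds one observation per row.  Every cell of the A × B
    design must be nonempty (with replication somewhere) for the
    interaction to be estimable; empty cells raise an error naming them.
    """
    y = data[value].to_numpy(dtype=float)
    a_levels, a_codes = np.unique(data[factor_a].to_numpy(), return_inverse=True)
    b_levels, b_codes = np.unique(data[factor_b].to_numpy(), return_inverse=True)
    n_a, n_b = len(a_levels), len(b_levels)
    if n_a < 2 or n_b < 2:
        raise ValueError(f"both factors need >= 2 levels; got {n_a} x {n_b}")

    counts = np.zeros((n_a, n_b), dtype=int)
    np.add.at(counts, (a_codes, b_codes), 1)
    if (counts == 0).any():
        empty = [(str(a_levels[i]), str(b_levels[j]))
                 for i, j in zip(*np.nonzero(counts == 0))]
        raise ValueError(f"design has empty cells, effects inestimable: {empty}")

    X = _design_matrices(a_codes, b_codes, n_a, n_b)
    rss_full = _rss(y, np.hstack([X["1"], X["A"], X["B"], X["AB"]]))
    rss_ab = _rss(y, np.hstack([X["1"], X["A"], X["B"]]))
    rss_a = _rss(y, np.hstack([X["1"], X["A"]]))
    rss_b = _rss(y, np.hstack([X["1"], X["B"]]))

    # Type II: each main effect adjusted for the other main effect;
    # the interaction adjusted for both.
    ss_a = rss_b - rss_ab
    ss_b = rss_a - rss_ab
    ss_ab = rss_ab - rss_full

    df_a = n_a - 1
    df_b = n_b - 1
    df_ab = df_a * df_b
    df_res = len(y) - n_a * n_b
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom; need replicates within cells")
    mse = rss_full / df_res
    # degenerate data (zero total variance): every F is 0 by convention
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2) * len(y):
        mse = 0.0
        ss_a = ss_b = ss_ab = 0.0

    rows = []
    for name, ss, df in ((factor_a, ss_a, df_a), (factor_b, ss_b, df_b),
                         (f"{factor_a}:{factor_b}", ss_ab, df_ab)):
        ss = max(ss, 0.0)
        F = (ss / df) / mse if mse > 0 else 0.0
        p = float(stats.f.sf(F, df, df_res)) if mse > 0 else 1.0
        rows.append({"effect": name, "sum_sq": ss, "df": df, "F": F, "p": p})
    rows.append({"effect": "residual", "sum_sq": rss_full, "df": df_res,
                 "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows).set_index("effect")

    pw = pairwise_comparisons(data, value, factor_a, factor_b,
                              mse=mse, df_res=df_res) if pairwise else None
    return StatResult(anova=table, pairwise=pw, n=len(y))


def pairwise_comparisons(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "stage",
    mse: float | None = None,
    df_res: int | None = None,
) -> pd.DataFrame:
    """Post-hoc cell-mean comparisons with Holm–Šidák adjustment.

    Two labelled comparison families are emitted, mirroring the two
    questions the design answers: ``A_within_B`` (genotype differences at
    each stage) and ``B_within_A`` (stage differences within each
    genotype).  Adjustment is applied within each family.  t statistics
    use the pooled residual variance of the full two-way model.
    """
    if mse is None or df_res is None:
        res = two_way_anova(data, value, factor_a, factor_b)
        mse = float(res.anova.loc["residual", "sum_sq"] / res.anova.loc["residual", "df"])
        df_res = int(res.anova.loc["residual", "df"])

    groups = data.groupby([factor_a, factor_b])[value]
    means = groups.mean()
    ns = groups.size()
    a_levels = sorted(data[factor_a].unique())
    b_levels = sorted(data[factor_b].unique())

    rows = []
    fam_pvals: dict[str, list[float]] = {}

    def compare(family, label_1, label_2, key1, key2):
        m1, m2 = means[key1], means[key2]
        n1, n2 = ns[key1], ns[key2]
        se = np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se if se > 0 else 0.0
        p = float(2 * stats.t.sf(abs(t), df_res)) if se > 0 else 1.0
        rows.append({"family": family, "group_1": label_1, "group_2": label_2,
                     "mean_1": m1, "mean_2": m2, "t": t, "p_raw": p})
        fam_pvals.setdefault(family, []).append(p)

    for b in b_levels:
        for i, a1 in enumerate(a_levels):
            for a2 in a_levels[i + 1:]:
                compare(f"{factor_a}_within_{factor_b}",
                        f"{a1}|{b}", f"{a2}|{b}", (a1, b), (a2, b))
    for a in a_levels:
        for i, b1 in enumerate(b_levels):
            for b2 in b_levels[i + 1:]:
                compare(f"{factor_b}_within_{factor_a}",
                        f"{a}|{b1}", f"{a}|{b2}", (a, b1), (a, b2))

    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for family, pvals in fam_pvals.items():
        adj = holm_sidak(pvals)
        table.loc[table["family"] == family, "p_adj"] = adj
    return table


def holm_sidak(pvalues) -> np.ndarray:
    """Holm–Šidák step-down adjusted p-values, in the input order.

    Sort the m raw p-values ascending; the i-th (1-based) gets the Šidák
    correction for the m − i + 1 remaining hypotheses, with a running
    maximum enforcing monotonicity:
    ``p_adj(i) = max_{j<=i} min(1, 1 − (1 − p(j))^(m − j + 1))``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError(f"p-values must lie in [0, 1], got {p}")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k = m - np.arange(m)  # m, m-1, ..., 1
    stepwise = 1.0 - np.power(1.0 - sorted_p, k)
    adj_sorted = np.minimum(np.maximum.accumulate(stepwise), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1D vectors, got {x.shape}, {y.shape}")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
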