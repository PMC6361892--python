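"""Group-level univariate statistics and brain-behaviour correlations.

Covers the cohort-table analyses around the connectivity pipeline: the
normality/homogeneity dispatcher between Student's t and Mann-Whitney U,
Mann-Whitney with exact or tie-corrected asymptotic p and the rank-biserial
style effect size r = z/sqrt(N), Pearson chi-square on 2x2 sex tables
(no continuity correction), Spearman rank correlations with single-max
winsorising, Benjamini-Hochberg FDR, and restricted-and-repetitive-behaviour
(RRB) subtype scores summed from interview item "ever" scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "GROUPS",
    "choose_test",
    "mann_whitney",
    "mw_z_from_u",
    "chi_square_2x2",
    "spearman",
    "winsorize_max",
    "bh_fdr",
    "default_rrb_item_sets",
    "rrb_subtype_scores",
    "correlation_analysis",
]

#: outcome groups: low familial risk; high risk with typical, atypical, or ASD outcome
GROUPS = ("LR", "HR-TD", "HR-Atyp", "HR-ASD")


@dataclass
class TestResult:
    """A univariate test with its effect size.

    ``statistic`` names the test statistic (``t``, ``U``, ``chi2``, ``rho``);
    ``z`` is the normal-approximation score where applicable; ``effect_r``
    is z/sqrt(N) for rank tests.
    """

    statistic: str
    value: float
    p: float
    z: float | None = None
    p_mode: str = "asymptotic"
    tails: int = 2
    effect_r: float | None = None
    n1: int | None = None
    n2: int | None = None
    extra: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, SPSS-output style
        parts = [f"{self.statistic} = {self.value:.4g}"]
        if self.z is not None:
            parts.append(f"z = {self.z:.3f}")
        parts.append(f"{self.p_mode} {self.tails}-tailed p = {self.p:.4g}")
        if self.effect_r is not None:
            parts.append(f"r = {self.effect_r:.2f}")
        return "TestResult(" + ", ".join(parts) + ")"


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def choose_test(values_a, values_b, alpha: float = 0.05) -> str:
    """Dispatch between the t-test and Mann-Whitney U.

    Student's t is chosen only when a Shapiro-Wilk test in *both* groups and
    a Levene test across groups all fail to reject at ``alpha``; otherwise
    (including any zero-variance group, with a warning) the non-parametric
    Mann-Whitney U is used.
    """
    a, b = _clean(values_a), _clean(values_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least three observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant group; forcing Mann-Whitney", stacklevel=2)
        return "mann-whitney"
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    lev = stats.levene(a, b, center="mean").pvalue
    return "t-test" if (sw_a > alpha and sw_b > alpha and lev > alpha) else "mann-whitney"


def mw_z_from_u(u: float, n1: int, n2: int) -> tuple[float, float]:
    """Normal-approximation z and effect size r from a U statistic (no ties).

    z = (U - n1*n2/2) / sqrt(n1*n2*(n1+n2+1)/12);  r = z / sqrt(n1+n2).
    """
    mu = n1 * n2 / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (u - mu) / sd
    return float(z), float(z / np.sqrt(n1 + n2))


def mann_whitney(
    values_a,
    values_b,
    tails: int = 2,
    p_mode: str = "auto",
    exact_threshold: int = 400,
) -> TestResult:
    """Mann-Whitney U for group A vs group B.

    U is reported for group A.  ``p_mode='exact'`` enumerates the tie-free
    null distribution of U (two-tailed p doubles the smaller tail, which for
    the symmetric U null equals summing both tails); with ties present exact
    mode falls back to the tie-corrected normal approximation with a warning.
    ``'auto'`` uses exact when there are no ties and n1*n2 <= exact_threshold.
    The z score and r = z/sqrt(N) always come from the (tie-corrected) normal
    approximation, without continuity correction.
    """
    a, b = _clean(values_a), _clean(values_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if p_mode not in ("auto", "exact", "asymptotic"):
        raise ValueError("p_mode must be 'auto', 'exact' or 'asymptotic'")
    use_exact = p_mode == "exact" or (p_mode == "auto" and n1 * n2 <= exact_threshold)
    if use_exact and has_ties:
        if p_mode == "exact":
            warnings.warn("ties present; exact p unavailable, using asymptotic", stacklevel=2)
        use_exact = False

    alternative = "two-sided" if tails == 2 else "less"
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    # tie-corrected normal approximation
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    t = counts[counts > 1].astype(float)
    var = n1 * n2 / 12.0 * ((n + 1) - (t**3 - t).sum() / (n * (n - 1)))
    z = 0.0 if var <= 0 else (u1 - n1 * n2 / 2.0) / np.sqrt(var)
    if use_exact:
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="exact")
        p, mode = float(res.pvalue), "exact"
    else:
        p = 2 * stats.norm.sf(abs(z)) if tails == 2 else stats.norm.cdf(z)
        p, mode = float(min(p, 1.0)), "asymptotic"
    return TestResult(
        statistic="U",
        value=float(u1),
        p=max(p, np.finfo(float).tiny),
        z=float(z),
        p_mode=mode,
        tails=tails,
        effect_r=float(z / np.sqrt(n)),
        n1=n1,
        n2=n2,
    )


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square on a 2x2 count table, 1 df, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return TestResult(
        statistic="chi2", value=float(chi2), p=float(p), p_mode="asymptotic",
        tails=2, extra={"dof": int(dof)},
    )


def spearman(x, y) -> TestResult:
    """Spearman rank correlation, pairwise-complete, two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least three complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in ranks; rho undefined")
    rho, p = stats.spearmanr(x, y)
    return TestResult(
        statistic="rho", value=float(rho), p=float(p), p_mode="asymptotic",
        tails=2, n1=len(x),
    )


def winsorize_max(values) -> np.ndarray:
    """Replace every occurrence of the maximum by the next-largest distinct value.

    Bounds the influence of the single most extreme observation on rank
    correlations; all-equal input is returned unchanged.  Idempotent only in
    the sense of repeated single application on the already-winsorised data
    replacing nothing new when the new maximum is shared by >= 2 values from
    distinct originals; a second application continues down the order
    statistics.
    """
    v = np.asarray(values, dtype=float).copy()
    if len(v) < 2:
        raise ValueError("need at least two values")
    m = np.nanmax(v)
    below = v[v < m]
    if below.size == 0:
        return v
    v[v == m] = below.max()
    return v


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level ``q``.

    Returns (reject flags, adjusted p-values).
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def default_rrb_item_sets() -> dict[str, list[str]]:
    """Bundled, editable subtype -> ADI-R item mapping (literature-derived)."""
    import yaml
    from importlib import resources

    text = resources.files("alphaconn").joinpath("data/rrb_subtypes.yaml").read_text()
    return {str(k): [str(i) for i in v] for k, v in yaml.safe_load(text).items()}


def rrb_subtype_scores(item_table: pd.DataFrame, item_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Sum interview item "ever" scores into RRB subtype scores per subject.

    ``item_sets`` maps a subtype name (e.g. Repetitive Motor Behaviours,
    Insistence on Sameness, Circumscribed Interests) to its item columns; the
    sets must be disjoint and non-empty, and every item must exist in
    ``item_table``.  A subject missing any item of a subtype gets a missing
    subtype score; other subtypes are still computed.
    """
    seen: set[str] = set()
    for name, items in item_sets.items():
        if not items:
            raise ValueError(f"subtype '{name}' has an empty item set")
        unknown = [i for i in items if i not in item_table.columns]
        if unknown:
            raise ValueError(f"unknown item id(s) in subtype '{name}': {unknown}")
        dup = seen.intersection(items)
        if dup:
            raise ValueError(f"item(s) {sorted(dup)} appear in more than one subtype")
        seen.update(items)
    out = {}
    for name, items in item_sets.items():
        out[name] = item_table[items].sum(axis=1, skipna=False)
    return pd.DataFrame(out, index=item_table.index)


def correlation_analysis(
    cohort: pd.DataFrame,
    group_filter: list[str] | None,
    measures: dict[str, str],
    scales: list[str],
    fdr_q: float | None = None,
    winsorize: bool = False,
) -> pd.DataFrame:
    """Spearman correlations of connectivity summaries with trait scales.

    ``measures`` maps a display name to a cohort column holding a
    connectivity summary (e.g. global vs selected-edge dbWPLI); ``scales``
    lists trait columns.  Rows are every measure x scale pair.  When
    ``fdr_q`` is given the whole table is treated as one non-a-priori family
    and Benjamini-Hochberg flags are appended; when None (a-priori
    hypotheses) p-values are left uncorrected.
    """
    df = cohort if group_filter is None else cohort[cohort["group"].isin(group_filter)]
    if len(df) < 4:
        raise ValueError(f"only {len(df)} subjects after group filter; need >= 4")
    rows = []
    for mname, mcol in measures.items():
        x = df[mcol].to_numpy(dtype=float)
        if winsorize:
            x = winsorize_max(x)
        for scale in scales:
            if scale not in df.columns:
                raise ValueError(f"trait scale '{scale}' not in cohort table")
            res = spearman(x, df[scale].to_numpy(dtype=float))
            rows.append(
                {"measure": mname, "scale": scale, "rho": res.value, "p": res.p, "n": res.n1}
            )
    table = pd.DataFrame(rows)
    if fdr_q is not None:
        reject, p_adj = bh_fdr(table["p"].to_numpy(), q=fdr_q)
        table["p_fdr"] = p_adj
        table["significant_fdr"] = reject
    return table
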