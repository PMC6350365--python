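"""Between-arm statistics for tumor-volume data.

Endpoint tests (one-way ANOVA / Kruskal-Wallis on end volumes or per-animal
growth rates), the rank-based two-factor Scheirer-Ray-Hare test, repeated
measures models (mixed-design ANOVA, linear mixed model) and a growth-curve
permutation test that compares whole trajectories between arm pairs.

Tumor growth in xenografts is near-exponential, and engrafted tumors start
treatment at heterogeneous volumes, so endpoint comparisons default to a
per-animal log-growth rate rather than the raw terminal volume: the rate
"rectifies" unequal baselines away.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .trial_data import TrialDataset, TrialDataError

__all__ = [
    "TestResult",
    "PairwiseResult",
    "endpoint_values",
    "one_way_test",
    "scheirer_ray_hare",
    "mixed_anova",
    "fit_lmm",
    "permutation_curve_test",
    "adjust_pvalues",
]

EXHAUSTIVE_LIMIT = 20_000


@dataclass
class TestResult:
    """Outcome of a between-arm test: statistic, df, p, optional per-term table."""

    method: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    terms: pd.DataFrame | None = None
    params: pd.DataFrame | None = None  # full coefficient table where meaningful
    notes: str = ""


@dataclass
class PairwiseResult:
    """All-pairs permutation test outcome."""

    pairs: pd.DataFrame  # arm_a, arm_b, statistic, n_perm, exhaustive, p_raw, p_adjusted
    n_permutations: int
    seed: int | None
    adjust_method: str
    notes: str = ""


# ---------------------------------------------------------------------------
# endpoints


def _common_days(df: pd.DataFrame) -> np.ndarray:
    """Days on which every animal in ``df`` was measured."""
    sets = [set(g["day"]) for _, g in df.groupby(["tumor_id", "arm", "animal_id"])]
    common = set.intersection(*sets) if sets else set()
    return np.sort(np.array(sorted(common), dtype=float))


def endpoint_values(
    ds: TrialDataset,
    endpoint: str = "growth_rate",
    growth_method: str = "slope_log",
) -> pd.DataFrame:
    """Reduce each animal's trajectory to a scalar endpoint.

    ``end_volume`` is the volume at the animals' last shared measurement day
    (falling back to each animal's own last day when no day is shared).
    ``growth_rate`` fits a per-day rate:

    - ``slope_log``: least-squares slope of ln(volume) vs day (uses every
      timepoint; the default),
    - ``ratio_log``: ln(V_end / V_0) / (t_end - t_0),
    - ``diff``: (V_end - V_0) / (t_end - t_0).

    Animals that cannot support the method (fewer than 2 timepoints, or a
    non-positive volume under a log method) are excluded and listed in
    ``attrs["excluded"]``.
    """
    if endpoint not in ("end_volume", "growth_rate"):
        raise TrialDataError(f"unknown endpoint {endpoint!r}")
    if growth_method not in ("slope_log", "ratio_log", "diff"):
        raise TrialDataError(f"unknown growth method {growth_method!r}")
    df = ds.records
    rows: list[tuple] = []
    excluded: list[tuple] = []

    if endpoint == "end_volume":
        for tumor, tdf in df.groupby("tumor_id"):
            common = _common_days(tdf)
            end_day = common.max() if common.size else None
            for (arm, animal), g in tdf.groupby(["arm", "animal_id"]):
                g = g.sort_values("day")
                day = end_day if end_day is not None else g["day"].iloc[-1]
                sel = g[g["day"] == day]
                rows.append((tumor, arm, animal, float(sel["volume"].iloc[-1])))
    else:
        for (tumor, arm, animal), g in df.groupby(["tumor_id", "arm", "animal_id"]):
            g = g.sort_values("day")
            t = g["day"].to_numpy(float)
            v = g["volume"].to_numpy(float)
            if len(t) < 2:
                excluded.append((tumor, arm, animal, "fewer than 2 timepoints"))
                continue
            if growth_method in ("slope_log", "ratio_log") and np.any(v <= 0):
                excluded.append((tumor, arm, animal, "non-positive volume"))
                continue
            if growth_method == "slope_log":
                rate = float(np.polyfit(t, np.log(v), 1)[0])
            elif growth_method == "ratio_log":
                rate = float(np.log(v[-1] / v[0]) / (t[-1] - t[0]))
            else:
                rate = float((v[-1] - v[0]) / (t[-1] - t[0]))
            rows.append((tumor, arm, animal, rate))

    out = pd.DataFrame(rows, columns=["tumor_id", "arm", "animal_id", "value"])
    out.attrs["endpoint"] = endpoint
    out.attrs["growth_method"] = growth_method
    out.attrs["excluded"] = excluded
    return out


# ---------------------------------------------------------------------------
# one-way tests


def one_way_test(values_by_arm: dict[str, np.ndarray], parametric: bool = True) -> TestResult:
    """One-way fixed-effects ANOVA, or Kruskal-Wallis when ``parametric=False``.

    The Kruskal-Wallis H uses mid-ranks and the usual tie correction, with the
    p-value from a chi-square on k-1 df.  A fully constant dataset has no
    parametric F (error) while the rank test degenerates to H=0, p=1.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_arm.values()]
    if len(groups) < 2:
        raise TrialDataError("one_way_test needs at least 2 arms")
    k = len(groups)
    allv = np.concatenate(groups)
    if parametric:
        if any(len(g) < 2 for g in groups):
            raise TrialDataError("parametric ANOVA needs >= 2 values per arm")
        if np.ptp(allv) == 0:
            raise TrialDataError("all values identical: F undefined")
        f, p = stats.f_oneway(*groups)
        return TestResult(
            method="one_way_anova",
            statistic=float(f),
            df=(float(k - 1), float(len(allv) - k)),
            p_value=float(p),
        )
    notes = ""
    if any(len(g) < 3 for g in groups):
        notes = "some arms have < 3 values: chi-square approximation is coarse"
    if np.ptp(allv) == 0:
        return TestResult("kruskal_wallis", 0.0, (float(k - 1),), 1.0, notes=notes)
    h, p = stats.kruskal(*groups)
    return TestResult(
        method="kruskal_wallis",
        statistic=float(h),
        df=(float(k - 1),),
        p_value=float(p),
        notes=notes,
    )


def scheirer_ray_hare(
    values: np.ndarray, factor_a: np.ndarray, factor_b: np.ndarray
) -> TestResult:
    """Scheirer-Ray-Hare rank test: a two-factor extension of Kruskal-Wallis.

    All N observations are mid-ranked together; two-way ANOVA sums of squares
    are computed on the ranks and each is divided by MS_total = SS_total/(N-1)
    to give an H statistic referred to chi-square on the factor's usual df.
    Using the empirical MS_total of the mid-ranks makes the tie correction
    automatic, so a single-level second factor reproduces Kruskal-Wallis
    (tie-corrected) exactly.

    Every cell of the A-by-B grid must be occupied; incomplete designs are
    rejected.
    """
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not (len(values) == len(factor_a) == len(factor_b)):
        raise TrialDataError("values and factors must have equal length")
    n = len(values)
    if n == 0:
        raise TrialDataError("empty data")
    a_levels = np.unique(factor_a)
    b_levels = np.unique(factor_b)
    for a in a_levels:
        for b in b_levels:
            if not np.any((factor_a == a) & (factor_b == b)):
                raise TrialDataError(f"empty cell ({a!r}, {b!r}): incomplete design")

    r = stats.rankdata(values)  # mid-ranks
    grand = r.mean()
    ss_total = float(np.sum((r - grand) ** 2))
    if ss_total == 0.0:
        terms = pd.DataFrame(
            {
                "term": ["A", "B", "A:B"],
                "statistic": [0.0, 0.0, 0.0],
                "df": [len(a_levels) - 1, len(b_levels) - 1,
                       (len(a_levels) - 1) * (len(b_levels) - 1)],
                "p": [1.0, 1.0, 1.0],
            }
        )
        return TestResult("scheirer_ray_hare", 0.0, (float(terms["df"].iloc[0]),), 1.0,
                          terms=terms, notes="constant values")

    def ss_factor(fac: np.ndarray) -> float:
        return float(
            sum(
                np.sum(fac == lev) * (r[fac == lev].mean() - grand) ** 2
                for lev in np.unique(fac)
            )
        )

    ss_a = ss_factor(factor_a)
    ss_b = ss_factor(factor_b)
    ss_cells = float(
        sum(
            np.sum(m) * (r[m].mean() - grand) ** 2
            for a in a_levels
            for b in b_levels
            if np.any(m := (factor_a == a) & (factor_b == b))
        )
    )
    ss_ab = ss_cells - ss_a - ss_b
    ms_total = ss_total / (n - 1)

    rows = []
    for term, ss, df in (
        ("A", ss_a, len(a_levels) - 1),
        ("B", ss_b, len(b_levels) - 1),
        ("A:B", ss_ab, (len(a_levels) - 1) * (len(b_levels) - 1)),
    ):
        h = ss / ms_total
        p = float(stats.chi2.sf(h, df)) if df > 0 else float("nan")
        rows.append((term, float(h), int(df), p))
    terms = pd.DataFrame(rows, columns=["term", "statistic", "df", "p"])
    lead = terms.iloc[0]
    return TestResult(
        method="scheirer_ray_hare",
        statistic=float(lead["statistic"]),
        df=(float(lead["df"]),),
        p_value=float(lead["p"]),
        terms=terms,
    )


# ---------------------------------------------------------------------------
# repeated-measures models


def _balanced_long(ds: TrialDataset, tumor_id: str | None) -> pd.DataFrame:
    df = ds.records
    if tumor_id is not None:
        df = df[df["tumor_id"] == tumor_id]
    if df.empty:
        raise TrialDataError(f"no data for tumor {tumor_id!r}")
    common = _common_days(df)
    if common.size < 2:
        raise TrialDataError("fewer than 2 measurement days shared by all animals")
    out = df[df["day"].isin(common)].copy()
    out["subject"] = out["tumor_id"] + "/" + out["arm"] + "/" + out["animal_id"]
    return out


def mixed_anova(ds: TrialDataset, tumor_id: str | None = None) -> TestResult:
    """Mixed-design (split-plot) ANOVA: arm between subjects, day within.

    Animals are restricted to the days every animal shares; animals within an
    arm are then required to form a balanced complete layout.  Sums of
    squares are the classical split-plot decomposition: the arm effect is
    tested against subjects-within-arm, day and arm-by-day against the
    day-by-subject residual.  A term whose sum of squares is exactly zero
    reports F = 0 even when its error stratum is also degenerate.
    Greenhouse-Geisser corrected p-values for the within terms ride along in
    the term table when sphericity estimation succeeds.
    """
    df = _balanced_long(ds, tumor_id)
    per_arm = df.groupby("arm")["subject"].nunique()
    if (per_arm < 2).any():
        small = list(per_arm[per_arm < 2].index)
        raise TrialDataError(f"arm(s) with < 2 animals: {small}")
    if per_arm.nunique() != 1:
        raise TrialDataError(
            "unequal animals per arm: mixed-design ANOVA needs a balanced layout"
        )
    a = df["arm"].nunique()
    n = int(per_arm.iloc[0])
    d = df["day"].nunique()

    grand = df["volume"].mean()
    m_arm = df.groupby("arm")["volume"].mean()
    m_day = df.groupby("day")["volume"].mean()
    m_subj = df.groupby(["arm", "subject"])["volume"].mean()
    m_cell = df.groupby(["arm", "day"])["volume"].mean()

    ss_arm = n * d * float(((m_arm - grand) ** 2).sum())
    ss_subj = d * float(
        ((m_subj - m_subj.index.get_level_values("arm").map(m_arm)) ** 2).sum()
    )
    ss_day = a * n * float(((m_day - grand) ** 2).sum())
    inter = (
        m_cell
        - m_cell.index.get_level_values("arm").map(m_arm)
        - m_cell.index.get_level_values("day").map(m_day)
        + grand
    )
    ss_inter = n * float((inter**2).sum())
    resid = (
        df["volume"]
        - df.set_index(["arm", "day"]).index.map(m_cell)
        - df.set_index(["arm", "subject"]).index.map(m_subj)
        + df["arm"].map(m_arm)
    )
    ss_err = float((resid**2).sum())

    df_arm, df_subj = a - 1, a * (n - 1)
    df_day, df_inter = d - 1, (a - 1) * (d - 1)
    df_err = a * (n - 1) * (d - 1)

    def f_and_p(ss, dfn, ss_e, dfe):
        if ss <= 1e-12 * max(ss_arm + ss_subj + ss_day + ss_inter + ss_err, 1.0):
            return 0.0, 1.0
        ms, ms_e = ss / dfn, ss_e / dfe
        if ms_e == 0:
            return float("inf"), 0.0
        f = ms / ms_e
        return f, float(stats.f.sf(f, dfn, dfe))

    f_arm, p_arm = f_and_p(ss_arm, df_arm, ss_subj, df_subj)
    f_day, p_day = f_and_p(ss_day, df_day, ss_err, df_err)
    f_int, p_int = f_and_p(ss_inter, df_inter, ss_err, df_err)
    terms = pd.DataFrame(
        {
            "term": ["arm", "day", "Interaction"],
            "statistic": [f_arm, f_day, f_int],
            "DF1": [df_arm, df_day, df_inter],
            "DF2": [df_subj, df_err, df_err],
            "p": [p_arm, p_day, p_int],
        }
    )
    terms["p_gg"] = _gg_corrected_p(df)
    return TestResult(
        method="mixed_anova",
        statistic=f_arm,
        df=(float(df_arm), float(df_subj)),
        p_value=p_arm,
        terms=terms,
    )


def _gg_corrected_p(df: pd.DataFrame) -> list[float]:
    """Greenhouse-Geisser corrected p per term (NaN where not applicable)."""
    try:
        import pingouin as pg

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.mixed_anova(
                data=df, dv="volume", within="day", subject="subject",
                between="arm", correction=True,
            )
        gg = next((c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns), None)
        if gg is None:
            return [np.nan] * 3
        by = dict(zip(aov["Source"], aov[gg]))
        return [np.nan, by.get("day", np.nan), by.get("Interaction", np.nan)]
    except Exception:
        return [np.nan] * 3


def fit_lmm(
    ds: TrialDataset,
    tumor_id: str | None = None,
    response_scale: str = "log",
    random: str = "intercept_slope",
) -> TestResult:
    """Linear mixed model for repeated tumor volumes.

    Fixed effects: day, arm and day-by-arm with the vehicle arm as reference;
    random intercept (and random slope in ``day`` when
    ``random="intercept_slope"``) per animal; REML estimation.  The default
    response is ln(volume + 1), which keeps regressing tumors with zero
    volumes in the model.

    The per-arm ``day:arm`` coefficient is the treatment's change in log
    growth rate relative to vehicle and is reported with a Wald z and p per
    arm; an omnibus Wald chi-square over all arm-involving fixed effects is
    the headline p-value.  A singular random-effects fit triggers an automatic
    refit with a random intercept only (noted in the result).
    """
    import statsmodels.formula.api as smf

    if response_scale not in ("log", "raw"):
        raise TrialDataError(f"unknown response scale {response_scale!r}")
    if random not in ("intercept", "intercept_slope"):
        raise TrialDataError(f"unknown random spec {random!r}")
    df = ds.records if tumor_id is None else ds.records[ds.records["tumor_id"] == tumor_id]
    if df.empty:
        raise TrialDataError(f"no data for tumor {tumor_id!r}")
    control = ds.resolve_control()
    arms = sorted(df["arm"].unique())
    if len(arms) < 2:
        raise TrialDataError("LMM needs >= 2 arms")
    notes = []
    if df["day"].nunique() < 3:
        notes.append("fewer than 3 timepoints: growth-rate contrasts are weakly identified")
    work = df.copy()
    work["subject"] = work["tumor_id"] + "/" + work["arm"] + "/" + work["animal_id"]
    work["y"] = np.log1p(work["volume"]) if response_scale == "log" else work["volume"]
    formula = f"y ~ day * C(arm, Treatment('{control}'))"

    def _fit(re_formula):
        model = smf.mixedlm(formula, data=work, groups=work["subject"], re_formula=re_formula)
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell", "cg"):
                res = model.fit(reml=True, method=method, maxiter=200)
                if res.converged:
                    break
        return res

    def _singular(res) -> bool:
        eig = np.linalg.eigvalsh(res.cov_re)
        return bool(eig.min() <= 1e-10 * max(eig.max(), 1e-12))

    re_formula = "~day" if random == "intercept_slope" else "~1"
    res = _fit(re_formula)
    if random == "intercept_slope" and (not res.converged or _singular(res)):
        res = _fit("~1")
        notes.append("random slope variance singular: refit with random intercept only")
    if not res.converged:
        raise TrialDataError("LMM did not converge; check data scaling and design")

    rows = []
    arm_param_names = []
    for name in res.fe_params.index:
        if "C(arm" in name:
            arm_param_names.append(name)
        if name.startswith("day:C(arm"):
            label = name.split("[T.")[-1].rstrip("]")
            est = float(res.fe_params[name])
            se = float(res.bse_fe[name])
            z = est / se
            rows.append((label, est, se, z, 2 * float(stats.norm.sf(abs(z)))))
    contrasts = pd.DataFrame(
        rows, columns=["arm", "estimate", "se", "z", "p"]
    )
    params = pd.DataFrame(
        {
            "name": res.fe_params.index,
            "estimate": res.fe_params.values,
            "se": res.bse_fe.values,
        }
    )
    # omnibus Wald test on every fixed effect involving arm
    constraint = ", ".join(f"{n} = 0" for n in arm_param_names)
    wald = res.wald_test(constraint, scalar=True)
    return TestResult(
        method="lmm",
        statistic=float(wald.statistic),
        df=(float(wald.df_denom if hasattr(wald, "df_denom") else len(arm_param_names)),),
        p_value=float(wald.pvalue),
        terms=contrasts,
        params=params,
        notes="; ".join(notes),
    )


# ---------------------------------------------------------------------------
# growth-curve permutation test


def _group1_indices(
    n: int, n1: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Index sets assigned to group 1 under permutation of animal labels.

    Enumerates all C(n, n1) assignments when that count is within
    ``EXHAUSTIVE_LIMIT``; otherwise draws ``n_perm`` random assignments.
    """
    n_total = math.comb(n, n1)
    if n_total <= EXHAUSTIVE_LIMIT:
        return np.array(list(combinations(range(n), n1)), dtype=int), True
    idx = np.empty((n_perm, n1), dtype=int)
    for i in range(n_perm):
        idx[i] = rng.permutation(n)[:n1]
    return idx, False


def _pooled_t_stats(pool: np.ndarray, idx: np.ndarray, n1: int) -> np.ndarray:
    """Per-day pooled-variance t for each group-1 index set.

    ``pool``: (n, d) animal-by-day matrix; ``idx``: (m, n1) group-1 rows.
    Returns (m, d).  A day with zero pooled within-group variance gives 0
    when the group means agree and +/-inf when they differ.
    """
    n, _ = pool.shape
    n2 = n - n1
    total_s = pool.sum(axis=0)
    total_ss = (pool**2).sum(axis=0)
    s1 = pool[idx].sum(axis=1)          # (m, d)
    ss1 = (pool**2)[idx].sum(axis=1)
    m1 = s1 / n1
    m2 = (total_s - s1) / n2
    ssw = (ss1 - n1 * m1**2) + ((total_ss - ss1) - n2 * m2**2)
    sp2 = np.maximum(ssw, 0.0) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def _ranksum_z_stats(pool: np.ndarray, idx: np.ndarray, n1: int) -> np.ndarray:
    """Per-day tie-corrected rank-sum z for each group-1 index set.

    Mid-ranks per day are fixed under relabeling, so the statistic is a sum
    over the group-1 rows of a precomputed rank matrix.
    """
    n, d = pool.shape
    n2 = n - n1
    ranks = np.empty_like(pool)
    var = np.empty(d)
    for j in range(d):
        ranks[:, j] = stats.rankdata(pool[:, j])
        _, counts = np.unique(pool[:, j], return_counts=True)
        tie = (counts**3 - counts).sum() / ((n - 1) * n)
        var[j] = n1 * n2 / 12.0 * ((n + 1) - tie)
    w = ranks[idx].sum(axis=1)  # (m, d)
    mu = n1 * (n + 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (w - mu) / np.sqrt(var)
    return np.nan_to_num(z, nan=0.0)


def _zero_variance_days(pool: np.ndarray, idx_obs: np.ndarray, stat: str) -> np.ndarray:
    """Mask of days where the observed two-sample statistic is undefined."""
    n1 = idx_obs.size
    if stat == "mean_wilcox":
        return np.array([np.unique(col).size == 1 for col in pool.T])
    g1 = pool[idx_obs]
    mask = np.ones(pool.shape[0], dtype=bool)
    mask[idx_obs] = False
    g2 = pool[mask]
    return (np.ptp(g1, axis=0) == 0) & (np.ptp(g2, axis=0) == 0)


def _pair_pvalue(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    stat: str,
    n_perm: int,
    rng: np.random.Generator,
    smooth: bool,
) -> tuple[float, float, int, bool, str]:
    """Permutation p for one arm pair.

    ``mat_a``/``mat_b``: (n_animals, n_days) volume matrices on shared days.
    Whole trajectories move between arms together.  Returns
    (observed statistic, p_raw, n_used, exhaustive, note).
    """
    n1 = mat_a.shape[0]
    pool = np.vstack([mat_a, mat_b])
    n = pool.shape[0]
    statfun = _pooled_t_stats if stat == "mean_t" else _ranksum_z_stats

    idx_obs = np.arange(n1)
    skip = _zero_variance_days(pool, idx_obs, stat)
    note = ""
    if skip.any():
        note = f"{int(skip.sum())} day(s) skipped: no within-group variance"
    if skip.all():
        raise TrialDataError("statistic undefined on every shared day")
    keep = ~skip

    idx, exhaustive = _group1_indices(n, n1, n_perm, rng)
    per_day = statfun(pool[:, keep], idx, n1)
    obs = statfun(pool[:, keep], idx_obs[None], n1)[0]
    s_obs = float(np.abs(obs.mean()))
    s_perm = np.abs(per_day.mean(axis=1))
    # relative slack: assignments tied with the observed one up to fp error count
    hits = int(np.sum(s_perm >= s_obs - 1e-9 * max(1.0, s_obs)))
    m = idx.shape[0]
    p = (hits + 1) / (m + 1) if (smooth and not exhaustive) else hits / m
    return s_obs, float(min(p, 1.0)), m, exhaustive, note


def permutation_curve_test(
    ds: TrialDataset,
    tumor_id: str | None = None,
    stat: str = "mean_t",
    n_perm: int = 1000,
    seed: int | None = None,
    adjust: str = "holm",
    smooth: bool = False,
) -> PairwiseResult:
    """Growth-curve permutation test between every pair of arms.

    For each arm pair a two-sample statistic (pooled-variance t, or a
    tie-corrected rank-sum z for ``stat="mean_wilcox"``) is computed at every
    day the two arms share and averaged over days.  Animal labels are then
    permuted — whole trajectories move together — and the raw p-value is the
    proportion of relabelings whose absolute mean statistic reaches the
    observed one.  When the number of distinct assignments is at most 20,000
    the null is enumerated exhaustively (the p-value is then exact);
    otherwise ``n_perm`` Monte-Carlo relabelings are drawn from ``seed``.
    P-values are adjusted across all pairs (Holm by default).
    """
    if stat not in ("mean_t", "mean_wilcox"):
        raise TrialDataError(f"unknown statistic {stat!r}")
    df = ds.records if tumor_id is None else ds.records[ds.records["tumor_id"] == tumor_id]
    if df.empty:
        raise TrialDataError(f"no data for tumor {tumor_id!r}")
    rng = np.random.default_rng(seed)
    arms = sorted(df["arm"].unique())
    if len(arms) < 2:
        raise TrialDataError("need >= 2 arms")

    # animal -> day -> volume pivots per arm
    pivots = {
        arm: df[df["arm"] == arm]
        .pivot_table(index="animal_id", columns="day", values="volume")
        .sort_index()
        for arm in arms
    }
    rows = []
    for a, b in combinations(arms, 2):
        pa, pb = pivots[a], pivots[b]
        days = sorted(set(pa.columns) & set(pb.columns))
        if not days:
            raise TrialDataError(f"arms {a!r} and {b!r} share no measurement days")
        ma = pa[days].dropna().to_numpy(float)
        mb = pb[days].dropna().to_numpy(float)
        if ma.shape[0] < 2 or mb.shape[0] < 2:
            raise TrialDataError(f"pair ({a!r}, {b!r}) needs >= 2 animals per arm")
        s_obs, p_raw, n_used, exhaustive, note = _pair_pvalue(
            ma, mb, stat, n_perm, rng, smooth
        )
        rows.append((a, b, s_obs, n_used, exhaustive, p_raw, note))
    pairs = pd.DataFrame(
        rows,
        columns=["arm_a", "arm_b", "statistic", "n_perm", "exhaustive", "p_raw", "note"],
    )
    pairs["p_adjusted"] = adjust_pvalues(pairs["p_raw"].to_numpy(), method=adjust)
    return PairwiseResult(
        pairs=pairs,
        n_permutations=n_perm,
        seed=seed,
        adjust_method=adjust,
    )


def adjust_pvalues(p, method: str = "holm") -> np.ndarray:
    """Multiplicity adjustment (holm, bonferroni or BH), order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise TrialDataError("p-values must lie in [0, 1]")
    key = {"holm": "holm", "bonferroni": "bonferroni", "BH": "fdr_bh", "bh": "fdr_bh"}
    if method not in key:
        raise TrialDataError(f"unknown adjustment {method!r}")
    return multipletests(p, method=key[method])[1]
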