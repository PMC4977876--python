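"""Downstream phenotype-tumor statistics.

Covers the descriptive and inferential analyses that follow QTL mapping:
mouse BMI (weight / nasal-anal length squared, g/cm^2) and per-sex mean
centering; Spearman correlation grids of phenotype against biweekly
papilloma counts; top-vs-bottom-quartile Mann-Whitney contrasts;
phenotype x sex interaction linear models; marker-genotype burden
associations with BMI-allele congruency; Cox proportional-hazards and
log-rank analysis of carcinoma-free survival; delta-delta-Ct relative
quantification of qPCR data; and an exact conditional (Fisher-type) test
for ordinal 0-3 inflammation scores across treatment groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING


def compute_bmi(weight: np.ndarray, length: np.ndarray) -> np.ndarray:
    """BMI in g/cm^2 from weight (g) and nasal-anal length (cm)."""
    w = np.asarray(weight, float)
    l = np.asarray(length, float)
    if (l <= 0).any():
        raise ValueError("length must be positive")
    return w / l ** 2


def mean_center_by_sex(values: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Subtract the per-sex mean; each sex's centered mean is exactly 0."""
    v = np.asarray(values, float)
    out = v.copy()
    for s in np.unique(np.asarray(sex)):
        m = np.asarray(sex) == s
        out[m] = v[m] - np.nanmean(v[m])
    return out


# ---------------------------------------------------------------------------
# Correlation grid and quartile contrasts
# ---------------------------------------------------------------------------

def phenotype_tumor_correlations(pheno: pd.DataFrame, phenotypes: list,
                                 count_columns: list,
                                 strata: tuple = ("all", "M", "F")
                                 ) -> pd.DataFrame:
    """Spearman rho/p for each phenotype x count timepoint x sex stratum."""
    rows = []
    sex = pheno["sex"].to_numpy()
    for stratum in strata:
        m = np.ones(len(pheno), bool) if stratum == "all" else sex == stratum
        for p in phenotypes:
            x = pheno.loc[m, p].to_numpy(float)
            for c in count_columns:
                y = pheno.loc[m, c].to_numpy(float)
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                    rho, pv = np.nan, np.nan
                else:
                    rho, pv = stats.spearmanr(x[ok], y[ok])
                rows.append({"phenotype": p, "timepoint": c,
                             "stratum": stratum, "rho": rho, "p": pv,
                             "n": int(ok.sum())})
    return pd.DataFrame(rows)


def quartile_groups(values: np.ndarray):
    """Top/bottom quartile masks using type-7 quantiles.

    Membership: v >= Q3 (top), v <= Q1 (bottom)."""
    v = np.asarray(values, float)
    q1, q3 = np.quantile(v, [0.25, 0.75])
    return v >= q3, v <= q1


@dataclass
class QuartileContrast:
    sex: str
    top_mean: float
    bottom_mean: float
    top_ci: tuple
    bottom_ci: tuple
    u_statistic: float
    p: float
    n_top: int
    n_bottom: int


def quartile_contrast(pheno_values: np.ndarray, counts: np.ndarray,
                      sex: np.ndarray) -> dict:
    """Per-sex top-vs-bottom-quartile burden contrast (Mann-Whitney U).

    The U test is exact for small groups (both <= 20, no ties) and
    normal-approximate otherwise; group means come with normal 95% CIs.
    """
    out = {}
    v = np.asarray(pheno_values, float)
    c = np.asarray(counts, float)
    sx = np.asarray(sex)
    for s in ("M", "F"):
        m = (sx == s) & np.isfinite(v) & np.isfinite(c)
        if m.sum() < 4:
            raise ValueError(f"fewer than 4 individuals for sex {s}")
        top, bottom = quartile_groups(v[m])
        ct, cb = c[m][top], c[m][bottom]
        if len(ct) == 0 or len(cb) == 0:
            raise ValueError("empty quartile group")
        u, p = mann_whitney(ct, cb)
        out[s] = QuartileContrast(
            s, float(ct.mean()), float(cb.mean()),
            _mean_ci(ct), _mean_ci(cb), u, p, len(ct), len(cb))
    return out


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple:
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.inf
    return (float(x.mean() - half), float(x.mean() + half))


def mann_whitney(x: np.ndarray, y: np.ndarray, exact_max_n: int = 20):
    """Mann-Whitney U; exact when both samples are small and tie-free."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    method = "auto"
    if max(len(x), len(y)) <= exact_max_n and \
            len(np.unique(np.concatenate([x, y]))) == len(x) + len(y):
        method = "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Interaction model and marker-burden association
# ---------------------------------------------------------------------------

def interaction_model(counts: np.ndarray, phenotype: np.ndarray,
                      sex: np.ndarray):
    """OLS counts ~ phenotype * sex; returns (p_interaction, fit summary).

    The interaction p is the t/F test of the phenotype x sex coefficient.
    """
    y = np.asarray(counts, float)
    x = np.asarray(phenotype, float)
    male = (np.asarray(sex) == "M").astype(float)
    ok = np.isfinite(y) & np.isfinite(x)
    if len(np.unique(male[ok])) < 2:
        raise ValueError("both sexes required")
    X = np.column_stack([np.ones(ok.sum()), x[ok], male[ok],
                         x[ok] * male[ok]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design")
    coef, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    resid = y[ok] - X @ coef
    df = ok.sum() - X.shape[1]
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    t = coef[3] / np.sqrt(cov[3, 3])
    p = float(2 * stats.t.sf(abs(t), df))
    return p, {"coef": coef, "t_interaction": float(t), "df": int(df)}


def marker_burden_association(genotype: np.ndarray, counts: np.ndarray,
                              sex: np.ndarray, bmi_direction: int) -> dict:
    """Genotype-burden Mann-Whitney per stratum + allele congruency.

    Congruent when the allele that raises BMI (``bmi_direction`` = sign of
    the HET effect on BMI) also raises papilloma burden in the combined
    stratum.
    """
    g = np.asarray(genotype)
    y = np.asarray(counts, float)
    sx = np.asarray(sex)
    res = {}
    for stratum in ("all", "M", "F"):
        m = np.ones(len(g), bool) if stratum == "all" else sx == stratum
        m &= (g != MISSING) & np.isfinite(y)
        het, hom = y[m & (g == 1)], y[m & (g == 0)]
        if len(het) == 0 or len(hom) == 0:
            raise ValueError("genotype has a single class in stratum "
                             + stratum)
        _, p = mann_whitney(het, hom)
        res[stratum] = {"p": p,
                        "het_effect": float(het.mean() - hom.mean())}
    burden_sign = 1 if res["all"]["het_effect"] >= 0 else -1
    res["congruent"] = bool(burden_sign == int(np.sign(bmi_direction)))
    return res


# ---------------------------------------------------------------------------
# Survival: Cox proportional hazards (Breslow ties) and log-rank
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    beta: float
    hr: float
    ci: tuple
    se: float
    p_wald: float
    p_logrank: float | None
    converged: bool
    monotone: bool              # likelihood maximized at the boundary


def carcinoma_survival(time: np.ndarray, event: np.ndarray,
                       covariate: np.ndarray) -> CoxResult:
    """Cox PH fit (Newton-Raphson, Breslow ties) plus two-group log-rank.

    The log-rank p is reported when the covariate is two-valued; the Wald
    CI is ``exp(beta +/- 1.96 se)``.  A constant covariate returns HR = 1
    with p = 1.  Monotone likelihood (risk sets perfectly separated) is
    flagged and the boundary estimate returned.
    """
    t = np.asarray(time, float)
    d = np.asarray(event, int)
    x = np.asarray(covariate, float)
    ok = np.isfinite(t) & np.isfinite(x)
    t, d, x = t[ok], d[ok], x[ok]
    if d.sum() < 1:
        raise ValueError("need at least one event")
    levels = np.unique(x)
    if len(levels) == 1:
        return CoxResult(0.0, 1.0, (1.0, 1.0), np.inf, 1.0, 1.0, True, False)
    xc = x - x.mean()
    beta, converged, monotone = 0.0, False, False
    for _ in range(50):
        u, i = _cox_score_info(beta, t, d, xc)
        if i <= 0:
            monotone = True
            break
        step = u / i
        step = np.clip(step, -2.0, 2.0)
        beta += step
        if abs(step) < 1e-10:
            converged = True
            break
        if abs(beta) > 15:
            monotone = True
            break
    _, info = _cox_score_info(beta, t, d, xc)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p_wald = float(2 * stats.norm.sf(abs(z)))
    ci = (float(np.exp(beta - 1.959963985 * se)),
          float(np.exp(beta + 1.959963985 * se)))
    p_lr = logrank_test(t, d, x == levels.max()) if len(levels) == 2 else None
    return CoxResult(float(beta), float(np.exp(beta)), ci, se, p_wald,
                     p_lr, converged, monotone)


def cox_partial_loglik(beta: float, time, event, covariate) -> float:
    """Breslow partial log-likelihood for a single covariate."""
    t = np.asarray(time, float)
    d = np.asarray(event, int)
    x = np.asarray(covariate, float)
    ll = 0.0
    for tt in np.unique(t[d == 1]):
        at_risk = t >= tt
        dead = (t == tt) & (d == 1)
        ll += float(beta * x[dead].sum()
                    - dead.sum() * np.log(np.exp(beta * x[at_risk]).sum()))
    return ll


def _cox_score_info(beta, t, d, x):
    score, info = 0.0, 0.0
    ebx = np.exp(beta * x)
    for tt in np.unique(t[d == 1]):
        at_risk = t >= tt
        dead = (t == tt) & (d == 1)
        w = ebx[at_risk]
        s0 = w.sum()
        s1 = (w * x[at_risk]).sum()
        s2 = (w * x[at_risk] ** 2).sum()
        m = dead.sum()
        score += x[dead].sum() - m * s1 / s0
        info += m * (s2 / s0 - (s1 / s0) ** 2)
    return float(score), float(info)


def logrank_test(time, event, group) -> float:
    """Two-group log-rank p (standard hypergeometric O-E form)."""
    t = np.asarray(time, float)
    d = np.asarray(event, int)
    g = np.asarray(group).astype(bool)
    o_minus_e, var = 0.0, 0.0
    for tt in np.unique(t[d == 1]):
        at_risk = t >= tt
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        dead = (t == tt) & (d == 1)
        m = dead.sum()
        o1 = (dead & g).sum()
        e1 = m * n1 / n
        o_minus_e += o1 - e1
        if n > 1:
            var += m * (n1 / n) * (1 - n1 / n) * (n - m) / (n - 1)
    if var <= 0:
        return 1.0
    chi2 = o_minus_e ** 2 / var
    return float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# qPCR delta-delta Ct
# ---------------------------------------------------------------------------

def ddct_analysis(ct: pd.DataFrame, reference_gene: str,
                  control_group: str, target_genes=None) -> pd.DataFrame:
    """Delta-delta-Ct relative quantification against a control group.

    Per sample, dCt = Ct(target) - Ct(reference); per group,
    ddCt = mean dCt(group) - mean dCt(control) and the relative quantity
    is 2^(-ddCt).  Group-vs-control significance is a Welch t-test on the
    per-sample dCt values.  Because the reference Ct cancels within each
    sample, adding any constant to all Ct values leaves RQ unchanged.
    """
    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    targets = (sorted(set(ct["gene"]) - {reference_gene})
               if target_genes is None else list(target_genes))
    if control_group not in set(ct["group"]):
        raise ValueError(f"control group {control_group!r} absent")
    rows = []
    for gene in targets:
        sub = ct[ct["gene"] == gene].copy()
        missing_ref = set(sub["sample"]) - set(ref.index)
        if missing_ref:
            raise ValueError(f"samples without reference Ct: "
                             f"{sorted(missing_ref)}")
        sub["dct"] = sub["ct"].to_numpy() - ref.loc[sub["sample"]].to_numpy()
        ctrl = sub.loc[sub["group"] == control_group, "dct"].to_numpy()
        for group, gsub in sub.groupby("group", sort=True):
            dct = gsub["dct"].to_numpy()
            ddct = float(dct.mean() - ctrl.mean())
            if group == control_group:
                p = 1.0
            else:
                p = float(stats.ttest_ind(dct, ctrl, equal_var=False).pvalue)
            rows.append({"gene": gene, "group": group, "ddct": ddct,
                         "rq": float(2.0 ** (-ddct)), "p": p,
                         "n": len(dct)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exact conditional test for ordinal score tables
# ---------------------------------------------------------------------------

def ordinal_score_test(scores: np.ndarray, groups: np.ndarray,
                       max_tables: int = 2_000_000, seed: int = 0,
                       n_mc: int = 100_000) -> float:
    """Fisher-type exact p for a groups x score contingency table.

    Scores must lie in {0,1,2,3}.  The p value sums the conditional
    (multivariate hypergeometric) probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's.  Enumeration is exhaustive up to ``max_tables`` tables; larger
    problems fall back to a seeded Monte-Carlo permutation estimate.
    """
    s = np.asarray(scores, int)
    g = np.asarray(groups)
    if not set(np.unique(s)) <= {0, 1, 2, 3}:
        raise ValueError("scores must lie in {0,1,2,3}")
    glevels = np.unique(g)
    for gl in glevels:
        if (g == gl).sum() == 0:
            raise ValueError("empty group")
    cats = np.unique(s)
    table = np.array([[(s[g == gl] == c).sum() for c in cats]
                      for gl in glevels], dtype=int)
    return fisher_exact_rxc(table, max_tables=max_tables, seed=seed,
                            n_mc=n_mc)


def fisher_exact_rxc(table: np.ndarray, max_tables: int = 2_000_000,
                     seed: int = 0, n_mc: int = 100_000) -> float:
    """Exact conditional test for an r x c table with fixed margins."""
    table = np.asarray(table, int)
    if (table < 0).any():
        raise ValueError("negative cell counts")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if row.min() == 0 or (col == table.sum()).any():
        return 1.0
    logp_obs = _table_logprob(table)
    bound = _count_bound(row, col)
    if bound <= max_tables:
        total = _enumerate_p(row, col, logp_obs)
        return float(min(total, 1.0))
    return _mc_p(table, logp_obs, seed, n_mc)


def _table_logprob(table: np.ndarray) -> float:
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    lp = (sum(lgamma(r + 1) for r in row) + sum(lgamma(c + 1) for c in col)
          - lgamma(n + 1) - sum(lgamma(v + 1) for v in table.ravel()))
    return float(lp)


def _count_bound(row, col) -> float:
    # loose upper bound on the number of tables with the given margins
    bound = 1.0
    for r in row[:-1]:
        for c in col[:-1]:
            bound *= min(r, c) + 1
    return bound


def _enumerate_p(row, col, logp_obs, tol=1e-7):
    """Sum P(table) over tables with P <= P_obs (recursion over rows)."""
    r, c = len(row), len(col)
    total = 0.0

    def fill(i, remaining_col, logp):
        nonlocal total
        if i == r - 1:
            lp = logp - sum(lgamma(v + 1) for v in remaining_col)
            if lp <= logp_obs + tol:
                total += np.exp(lp)
            return
        for cells in _compositions(row[i], remaining_col):
            lp = logp - sum(lgamma(v + 1) for v in cells)
            fill(i + 1, remaining_col - np.array(cells), lp)

    base = (sum(lgamma(x + 1) for x in row) + sum(lgamma(x + 1) for x in col)
            - lgamma(sum(row) + 1))
    fill(0, np.array(col), base)
    return total


def _compositions(total, caps):
    """All ways to split `total` into len(caps) cells bounded by caps."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for v in range(min(total, caps[0]) + 1):
        for rest in _compositions(total - v, caps[1:]):
            yield (v,) + rest


def _mc_p(table, logp_obs, seed, n_mc, tol=1e-7):
    rng = np.random.default_rng(seed)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    pool = np.repeat(np.arange(len(col)), col)
    hits = 0
    edges = np.cumsum(row)[:-1]
    for _ in range(n_mc):
        rng.shuffle(pool)
        parts = np.split(pool, edges)
        tb = np.array([[np.count_nonzero(p == j) for j in range(len(col))]
                       for p in parts])
        if _table_logprob(tb) <= logp_obs + tol:
            hits += 1
    return (hits + 1) / (n_mc + 1)
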