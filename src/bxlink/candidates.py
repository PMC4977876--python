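"""Two-route candidate-gene identification for a phenotype QTL.

Route 1 (sequence): genes physically inside the QTL's marker-bounded
region that carry at least one protein-altering strain difference
(non-synonymous, nonsense, frameshift, or splice-site variant).

Route 2 (expression): genes differentially expressed between genotype
groups at the marker nearest the QTL peak (SAM-style moderated d statistic
with permutation FDR), whose own expression QTL has LOD >= 3 and a Bayes
credible interval overlapping the phenotype QTL's interval.

The union is then tested for gene-phenotype association with an
empirical-Bayes moderated t (FDR across the union), re-tested with the
peak-marker genotype as covariate, and checked for sign congruency of the
QTL->phenotype, QTL->expression and expression->phenotype relationships.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .genotypes import HET, HOM, MISSING, X_CHROM
from .qtlscan import GenoProbGrid, QTLPeak, bayes_interval, scanone_hk

#: Variant consequence classes that qualify a gene for the sequence route.
DELETERIOUS_CLASSES = frozenset({
    "nonsynonymous", "nonsense", "frameshift_del", "frameshift_ins",
    "splice"})

KNOWN_CLASSES = DELETERIOUS_CLASSES | {"synonymous", "noncoding"}


# ---------------------------------------------------------------------------
# Route 1: sequence
# ---------------------------------------------------------------------------

def snp_route(variants: pd.DataFrame, peak: QTLPeak,
              gene_positions: pd.DataFrame) -> list[str]:
    """Genes in the QTL's physical bounds with >=1 protein-altering variant.

    ``gene_positions`` needs columns gene, chrom, mb (gene start);
    inclusion uses the gene start against [left_mb, right_mb].
    Synonymous and non-coding variants never qualify.
    """
    if not np.isfinite([peak.left_mb, peak.right_mb]).all():
        raise ValueError("QTL peak lacks physical bounds")
    unknown = set(variants["consequence"]) - KNOWN_CLASSES
    if unknown:
        raise ValueError(f"unknown consequence classes: {sorted(unknown)}")
    pos = gene_positions.set_index("gene")
    hits = set()
    bad = variants[variants["consequence"].isin(DELETERIOUS_CLASSES)]
    for gene in bad["gene"].unique():
        if gene not in pos.index:
            continue
        row = pos.loc[gene]
        if (str(row["chrom"]) == peak.chrom
                and peak.left_mb <= float(row["mb"]) <= peak.right_mb):
            hits.add(gene)
    return sorted(hits)


# ---------------------------------------------------------------------------
# SAM d statistic with permutation FDR
# ---------------------------------------------------------------------------

def sam_d_statistic(x: np.ndarray, groups: np.ndarray, s0: float | None = None):
    """Two-group SAM statistic d = (mean1 - mean2) / (s + s0) per gene.

    ``x``: genes x samples; ``groups``: 0/1 labels.  ``s`` is the pooled
    standard error of the mean difference.  When ``s0`` is None it is
    chosen by the standard recipe: over candidate values at the 0,5,...,100
    percentiles of ``s``, pick the one minimizing the coefficient of
    variation of the median absolute deviation of d across s-percentile
    windows.  Returns ``(d, s, s0)``.
    """
    g1 = groups == np.unique(groups)[0]
    g2 = ~g1
    n1, n2 = int(g1.sum()), int(g2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each genotype group needs at least 2 samples")
    m1 = x[:, g1].mean(axis=1)
    m2 = x[:, g2].mean(axis=1)
    ss = (((x[:, g1] - m1[:, None]) ** 2).sum(axis=1)
          + ((x[:, g2] - m2[:, None]) ** 2).sum(axis=1))
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    if s0 is None:
        s0 = _choose_s0(m1 - m2, s)
    d = (m1 - m2) / (s + s0)
    return d, s, s0


def _choose_s0(diff: np.ndarray, s: np.ndarray) -> float:
    """Fudge constant minimizing the CV of d's spread across s windows."""
    qs = np.percentile(s, np.arange(0, 101, 5))
    cands = np.unique(qs)
    edges = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = 0.0, np.inf
    for s0 in cands:
        d = diff / (s + s0)
        mads = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (s >= lo) & (s <= hi)
            if m.sum() >= 2:
                dm = d[m]
                mads.append(np.median(np.abs(dm - np.median(dm))) * 1.4826)
        mads = np.array(mads)
        if len(mads) < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads) / np.mean(mads)
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_d_multiclass(x: np.ndarray, groups: np.ndarray,
                     s0: float | None = None):
    """Multi-class SAM statistic (non-negative, F-like) for >2 groups."""
    labels = np.unique(groups)
    n = x.shape[1]
    ns = np.array([(groups == g).sum() for g in labels])
    if (ns < 2).any():
        raise ValueError("each group needs at least 2 samples")
    grand = x.mean(axis=1)
    between = np.zeros(x.shape[0])
    within = np.zeros(x.shape[0])
    for g, ng in zip(labels, ns):
        xg = x[:, groups == g]
        mg = xg.mean(axis=1)
        between += ng * (mg - grand) ** 2
        within += ((xg - mg[:, None]) ** 2).sum(axis=1)
    k = len(labels)
    r = np.sqrt(between * (ns.sum() / np.prod(ns)) / n)
    s = np.sqrt((1.0 / (n - k)) * within * np.sum(1.0 / ns))
    if s0 is None:
        s0 = float(np.median(s))
    return r / (s + s0), s, s0


def de_vs_marker(expression: pd.DataFrame, genotype_at_marker: np.ndarray,
                 sex: np.ndarray | None = None, x_chrom: bool = False,
                 n_perm: int = 100, alpha: float = 0.05, seed: int = 0
                 ) -> pd.DataFrame:
    """Differential expression versus genotype at the QTL peak marker.

    Autosomes use the two-group d statistic (HOM vs HET); on the X the
    four sex-specific genotype classes (AA/AB/AY/BY) are kept distinct via
    the multi-class statistic.  The FDR is permutation-based: per-gene q is
    the median, over label permutations, of the count of permuted |d|
    exceeding the gene's |d|, divided by the observed count at that cutoff
    (monotonicity enforced).  Returns DataFrame(gene, d, q, flagged).
    """
    rng = np.random.default_rng(seed)
    g = np.asarray(genotype_at_marker)
    ok = g != MISSING
    x = expression.to_numpy(float)[:, ok]
    g = g[ok]
    if x_chrom:
        if sex is None:
            raise ValueError("X-chromosome analysis needs sex")
        labels = np.char.add(np.asarray(sex)[ok].astype(str),
                             g.astype(int).astype(str))
        d, s, s0 = sam_d_multiclass(x, labels)
        stat = d       # already non-negative
        def perm_stat(p):
            return sam_d_multiclass(x, labels[p], s0=s0)[0]
    else:
        d, s, s0 = sam_d_statistic(x, g)
        stat = np.abs(d)
        def perm_stat(p):
            return np.abs(sam_d_statistic(x, g[p], s0=s0)[0])
    n = x.shape[1]
    order = np.argsort(stat)[::-1]
    sorted_stat = stat[order]
    exceed = np.zeros((n_perm, len(stat)))
    for b in range(n_perm):
        p = rng.permutation(n)
        ps = perm_stat(p)
        # count permuted stats >= each observed cutoff
        exceed[b] = len(ps) - np.searchsorted(np.sort(ps), sorted_stat,
                                              side="left")
    false = np.median(exceed, axis=0)
    observed = np.arange(1, len(stat) + 1)
    q_sorted = np.minimum(false / observed, 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(len(stat))
    q[order] = q_sorted
    return pd.DataFrame({"gene": expression.index, "d": d, "q": q,
                         "flagged": q <= alpha})


# ---------------------------------------------------------------------------
# Route 2: eQTL
# ---------------------------------------------------------------------------

@dataclass
class EqtlResult:
    gene: str
    chrom: str
    pos_cm: float
    lod: float
    left_cm: float
    right_cm: float
    is_candidate: bool
    direction: int


def eqtl_route(expression_gene: np.ndarray, probs: GenoProbGrid,
               phenotype_peak: QTLPeak, gene: str = "",
               lod_min: float = 3.0) -> EqtlResult:
    """Scan one gene's expression genome-wide and test interval overlap.

    The gene is an expression-route candidate iff its genome-maximum eQTL
    peak has LOD >= ``lod_min`` (boundary inclusive) and its Bayes 95%
    credible interval overlaps the phenotype QTL's interval on the same
    chromosome.
    """
    scan = scanone_hk(probs, expression_gene)
    row = scan.peak()
    chrom = str(row["chrom"])
    l_cm, p_cm, r_cm, *_ = bayes_interval(scan, chrom)
    overlap = (chrom == phenotype_peak.chrom
               and l_cm <= phenotype_peak.right_cm
               and r_cm >= phenotype_peak.left_cm)
    lod = float(row["lod"])
    y = np.asarray(expression_gene, float)
    cp = probs.chroms[chrom]
    j = int(np.argmin(np.abs(cp.pos_cm - p_cm)))
    gvec = cp.p_het[:, j]
    okm = np.isfinite(y)
    cov = float(((gvec[okm] - gvec[okm].mean()) * (y[okm] - y[okm].mean())).mean())
    return EqtlResult(gene, chrom, p_cm, lod, l_cm, r_cm,
                      bool(lod >= lod_min and overlap), 1 if cov >= 0 else -1)


# ---------------------------------------------------------------------------
# Gene-phenotype association (moderated t, FDR, genotype adjustment)
# ---------------------------------------------------------------------------

def _fit_fdist_moments(s2: np.ndarray, df: float):
    """Fit the scaled-F prior (d0, s0^2) to sample variances.

    Method of moments on log sample variances: with z = log s^2,
    E z = log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2) and
    Var z = psi'(df/2) + psi'(d0/2).  The trigamma equation is solved by
    Newton iteration; a non-positive excess variance means no shrinkage
    information (d0 = inf).
    """
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2) + np.log(df / 2)
    if len(e) < 2:
        return np.inf, float(np.exp(np.mean(e)))   # no shrinkage info
    target = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if target <= 1e-12:
        return np.inf, float(np.exp(np.mean(e)))
    # solve trigamma(d0/2) = target
    x = 0.5 + 1.0 / target
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri - target
        if abs(dif) < 1e-12:
            break
        x -= dif / special.polygamma(2, x)
        x = max(x, 1e-6)
    d0 = 2 * x
    s02 = float(np.exp(np.mean(e) + special.digamma(x) - np.log(x)))
    return float(d0), s02


def moderated_association(expression: pd.DataFrame, phenotype: np.ndarray
                          ) -> pd.DataFrame:
    """Per-gene moderated t of expression ~ phenotype.

    Ordinary per-gene OLS slopes are combined with an empirical-Bayes
    shrunken residual variance (scaled-F prior fitted across genes by
    method of moments on log variances); the moderated t has df + d0
    degrees of freedom.  Returns DataFrame(gene, slope, t, p_raw).
    """
    y = np.asarray(phenotype, float)
    ok = np.isfinite(y)
    X = np.column_stack([np.ones(ok.sum()), y[ok]])
    E = expression.to_numpy(float)[:, ok]
    if (E.var(axis=1) <= 1e-20).any():
        raise ValueError("zero-variance gene in expression matrix")
    n = ok.sum()
    xtx_inv = np.linalg.inv(X.T @ X)
    B = E @ X @ xtx_inv.T                  # genes x 2
    resid = E - B @ X.T
    df = n - 2
    s2 = np.maximum((resid ** 2).sum(axis=1) / df, 1e-300)
    d0, s02 = _fit_fdist_moments(s2, df)
    if np.isinf(d0):
        s2_post, df_total = s2, df
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_post * xtx_inv[1, 1])
    t = B[:, 1] / se
    p = 2 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame({"gene": expression.index, "slope": B[:, 1],
                         "t": t, "p_raw": p})


def phenotype_association(expression: pd.DataFrame, phenotype: np.ndarray,
                          genotype_at_peak: np.ndarray | None = None,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Moderated association + BH FDR + genotype-adjusted confirmation.

    Genes passing the FDR on the raw moderated p are refit with the peak-
    marker genotype as a covariate; the ordinary phenotype-term p of that
    fit decides at ``alpha``.  Returns DataFrame(gene, slope, p_raw, q_raw,
    p_adjusted, significant).
    """
    res = moderated_association(expression, phenotype)
    res["q_raw"] = multipletests(res["p_raw"], method="fdr_bh")[1]
    p_adj = np.full(len(res), np.nan)
    y = np.asarray(phenotype, float)
    if genotype_at_peak is not None:
        g = np.asarray(genotype_at_peak, float)
        ok = np.isfinite(y) & (g != MISSING)
        X = np.column_stack([np.ones(ok.sum()), y[ok], g[ok]])
        xtx_inv = np.linalg.inv(X.T @ X)
        df = ok.sum() - 3
        for i in np.flatnonzero((res["q_raw"] <= alpha).to_numpy()):
            e = expression.to_numpy(float)[i, ok]
            b = xtx_inv @ X.T @ e
            r = e - X @ b
            s2 = float(r @ r) / df
            tstat = b[1] / np.sqrt(s2 * xtx_inv[1, 1])
            p_adj[i] = 2 * stats.t.sf(abs(tstat), df)
    else:
        p_adj[(res["q_raw"] <= alpha).to_numpy()] = \
            res.loc[res["q_raw"] <= alpha, "p_raw"]
    res["p_adjusted"] = p_adj
    res["significant"] = (res["q_raw"] <= alpha) & (res["p_adjusted"] <= alpha)
    return res


# ---------------------------------------------------------------------------
# Congruency and assembly
# ---------------------------------------------------------------------------

CONGRUENT, INCONGRUENT, NOT_EVALUABLE = ("congruent", "incongruent",
                                         "not_evaluable")


def congruency_check(qtl_direction, eqtl_direction, gene_phenotype_sign
                     ) -> str:
    """Sign consistency of QTL->phenotype, QTL->expression, expr->phenotype.

    Congruent iff sign(HET on phenotype) * sign(HET on expression) equals
    sign(expression-phenotype correlation).  Any missing or zero sign makes
    the triple not evaluable.  Flipping all three signs preserves the flag.
    """
    signs = [qtl_direction, eqtl_direction, gene_phenotype_sign]
    if any(s is None or s == 0 or (isinstance(s, float) and not np.isfinite(s))
           for s in signs):
        return NOT_EVALUABLE
    s1, s2, s3 = (int(np.sign(s)) for s in signs)
    return CONGRUENT if s1 * s2 == s3 else INCONGRUENT


def assemble_candidates(snp_genes: list, eqtl_results: list,
                        association: pd.DataFrame,
                        gene_positions: pd.DataFrame,
                        qtl_direction: int, stratum: str = "all",
                        de_stats: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Merge the two routes into the final annotated candidate table.

    A gene is a hit when its phenotype association survived the genotype
    adjustment and, where the sign triple is evaluable (expression route),
    the triple is congruent.  Ordering is (chromosome, Mb, gene),
    deterministic.
    """
    pos = gene_positions.set_index("gene")
    assoc = association.set_index("gene")
    de = None if de_stats is None else de_stats.set_index("gene")
    eqtl = {r.gene: r for r in eqtl_results}
    rows = []
    for gene in sorted(set(snp_genes) | set(eqtl)):
        routes = []
        if gene in snp_genes:
            routes.append("sequence")
        er = eqtl.get(gene)
        if er is not None and er.is_candidate:
            routes.append("eQTL")
        if not routes:
            continue
        a = assoc.loc[gene] if gene in assoc.index else None
        sig = bool(a is not None and a["significant"])
        slope_sign = (int(np.sign(a["slope"])) if a is not None
                      and a["slope"] != 0 else 0)
        if er is not None:
            flag = congruency_check(qtl_direction, er.direction, slope_sign)
        else:
            flag = NOT_EVALUABLE
        hit = sig and flag != INCONGRUENT
        chrom = str(pos.loc[gene, "chrom"]) if gene in pos.index else ""
        mb = float(pos.loc[gene, "mb"]) if gene in pos.index else np.nan
        rows.append({
            "gene": gene, "route": "+".join(routes), "chrom": chrom,
            "mb": mb, "stratum": stratum,
            "d": float(de.loc[gene, "d"]) if de is not None
            and gene in de.index else np.nan,
            "q": float(de.loc[gene, "q"]) if de is not None
            and gene in de.index else np.nan,
            "eqtl_lod": er.lod if er is not None else np.nan,
            "eqtl_interval": (f"{er.left_cm:g}-{er.right_cm:g}"
                              if er is not None else ""),
            "p_raw": float(a["p_raw"]) if a is not None else np.nan,
            "p_adjusted": float(a["p_adjusted"]) if a is not None else np.nan,
            "congruency": flag, "hit": hit,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["chrom", "mb", "gene"],
                            key=lambda s: s.map(_chrom_key)
                            if s.name == "chrom" else s).reset_index(drop=True)
    return df


def _chrom_key(c):
    try:
        return float(c)
    except (TypeError, ValueError):
        return float("inf")
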