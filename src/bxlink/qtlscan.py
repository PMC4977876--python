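"""Genome scans for a two-class backcross: Haley-Knott regression on hidden
Markov genotype probabilities, permutation significance thresholds with a
length-proportional autosome/X alpha split, Bayes credible intervals,
two-locus (scantwo-style) models, multi-QTL position refinement, and
sex-by-genotype interaction tests.

Model.  At each evaluation position the phenotype is regressed on the
conditional probability of heterozygosity P(HET | observed markers on the
chromosome), computed by a forward-backward pass over a two-state chain
with Haldane transition probabilities and a symmetric genotyping-error
emission.  The LOD at a position is

    LOD = (n/2) * log10(RSS0 / RSS1)

comparing the alternative {covariates + genotype (+ genotype x interactive
covariates)} with the null {covariates}.  On the X the genotype classes are
sex-specific (AA/AB in females, AY/BY in males) and sex always sits in the
null.  An optional extended mode reweights the regression by conditional
genotype variances; with a dense map and low missingness it coincides with
the standard fit, which is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GeneticMap, GenotypeMatrix, HET, HOM, MISSING, X_CHROM
from .simdata import haldane

__all__ = [
    "GenoProbGrid", "ScanResult", "QTLPeak", "PermutationThresholds",
    "calc_genoprob", "scanone_hk", "permutation_thresholds",
    "bayes_interval", "scantwo_chromosome", "scantwo_permutations",
    "refine_positions", "sex_interaction_test", "variance_explained",
    "lod_from_r2",
]


# ---------------------------------------------------------------------------
# Conditional genotype probabilities (forward-backward)
# ---------------------------------------------------------------------------

@dataclass
class ChromProbs:
    chrom: str
    pos_cm: np.ndarray
    pos_mb: np.ndarray
    is_marker: np.ndarray
    names: list
    p_het: np.ndarray          # (n_ind, n_pos): P(HET); on X, P(B allele)


@dataclass
class GenoProbGrid:
    """Per-chromosome conditional genotype probabilities on a cM grid."""
    chroms: dict
    individuals: np.ndarray
    sex: np.ndarray
    step_cm: float
    error_rate: float

    @property
    def chrom_names(self) -> list:
        return list(self.chroms)

    def autosomes(self) -> list:
        return [c for c in self.chroms if c != X_CHROM]

    def genetic_length(self, chroms) -> float:
        return float(sum(np.ptp(self.chroms[c].pos_cm) for c in chroms))

    def subset_individuals(self, mask: np.ndarray) -> "GenoProbGrid":
        new = {c: ChromProbs(cp.chrom, cp.pos_cm, cp.pos_mb, cp.is_marker,
                             cp.names, cp.p_het[mask])
               for c, cp in self.chroms.items()}
        return GenoProbGrid(new, self.individuals[mask], self.sex[mask],
                            self.step_cm, self.error_rate)


def calc_genoprob(gm: GenotypeMatrix, step_cm: float = 2.0,
                  error_rate: float = 1e-4) -> GenoProbGrid:
    """Forward-backward P(HET) at markers and pseudomarkers.

    ``step_cm = 0`` evaluates at markers only.  With ``error_rate = 0`` the
    probability at an observed marker equals the observed call.
    """
    if step_cm < 0:
        raise ValueError("step must be non-negative")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error rate must lie in [0, 0.5)")
    chroms = {}
    for chrom in gm.map.chroms:
        mask = (gm.map.df["chrom"] == chrom).to_numpy()
        sub = gm.map.df.loc[mask]
        mk_cm = sub["cm"].to_numpy(float)
        mk_mb = sub["mb"].to_numpy(float)
        grid_cm, is_marker, names = _build_grid(mk_cm, sub["marker"].to_list(),
                                                chrom, step_cm)
        grid_mb = np.interp(grid_cm, mk_cm, mk_mb)
        obs = np.full((gm.n, len(grid_cm)), MISSING, dtype=np.int8)
        obs[:, is_marker] = gm.geno[:, mask]
        p = _forward_backward(obs, grid_cm, error_rate)
        chroms[chrom] = ChromProbs(chrom, grid_cm, grid_mb, is_marker,
                                   names, p)
    return GenoProbGrid(chroms, gm.individuals, gm.sex, step_cm, error_rate)


def _build_grid(mk_cm: np.ndarray, mk_names: list, chrom: str,
                step_cm: float):
    if step_cm == 0 or len(mk_cm) == 1:
        return (mk_cm.copy(), np.ones(len(mk_cm), bool), list(mk_names))
    pts = list(mk_cm)
    lo, hi = mk_cm[0], mk_cm[-1]
    k = lo + step_cm
    while k < hi - 1e-9:
        pts.append(k)
        k += step_cm
    grid = np.unique(np.round(np.array(pts), 6))
    is_marker = np.isin(grid, np.round(mk_cm, 6))
    names, mi = [], 0
    mk_rounded = np.round(mk_cm, 6)
    for g, m in zip(grid, is_marker):
        if m:
            names.append(mk_names[int(np.flatnonzero(mk_rounded == g)[0])])
        else:
            names.append(f"c{chrom}.loc{g:g}")
    return grid, is_marker, names


def _forward_backward(obs: np.ndarray, pos_cm: np.ndarray,
                      error_rate: float) -> np.ndarray:
    """Two-state forward-backward; returns P(state=HET) per individual/pos."""
    n, m = obs.shape
    e = error_rate
    # emission[obs_code + 1, state]
    emis = np.array([[1.0, 1.0],            # missing
                     [1.0 - e, e],          # observed HOM
                     [e, 1.0 - e]])         # observed HET
    r = haldane(np.diff(pos_cm))
    E = emis[obs + 1]                       # (n, m, 2)
    alpha = np.empty((n, m, 2))
    alpha[:, 0] = 0.5 * E[:, 0]
    alpha[:, 0] /= alpha[:, 0].sum(axis=1, keepdims=True)
    for j in range(1, m):
        stay, sw = 1.0 - r[j - 1], r[j - 1]
        pred = np.empty((n, 2))
        pred[:, 0] = alpha[:, j - 1, 0] * stay + alpha[:, j - 1, 1] * sw
        pred[:, 1] = alpha[:, j - 1, 0] * sw + alpha[:, j - 1, 1] * stay
        a = pred * E[:, j]
        alpha[:, j] = a / a.sum(axis=1, keepdims=True)
    beta = np.ones((n, m, 2))
    for j in range(m - 2, -1, -1):
        stay, sw = 1.0 - r[j], r[j]
        b = beta[:, j + 1] * E[:, j + 1]
        beta[:, j, 0] = b[:, 0] * stay + b[:, 1] * sw
        beta[:, j, 1] = b[:, 0] * sw + b[:, 1] * stay
        beta[:, j] /= beta[:, j].sum(axis=1, keepdims=True)
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post[:, :, 1]


# ---------------------------------------------------------------------------
# Single-QTL scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    df: pd.DataFrame            # chrom, pos_cm, pos_mb, lod
    phenotype: str = "phenotype"
    stratum: str = "all"
    model: dict = field(default_factory=dict)

    def max_lod(self, chroms=None) -> float:
        sub = self.df if chroms is None else \
            self.df[self.df["chrom"].isin(list(chroms))]
        return float(np.nanmax(sub["lod"].to_numpy()))

    def peak(self, chrom: str | None = None):
        """Row of the maximum LOD (leftmost position on ties)."""
        sub = self.df if chrom is None else self.df[self.df["chrom"] == chrom]
        lod = sub["lod"].to_numpy()
        i = int(np.nanargmax(lod))   # argmax returns first (leftmost) max
        return sub.iloc[i]


@dataclass
class QTLPeak:
    """A located QTL, named phenotype_chromosome[_PROX|_DIST]."""
    name: str
    phenotype: str
    chrom: str
    pos_cm: float
    pos_mb: float
    left_mb: float
    right_mb: float
    left_cm: float
    right_cm: float
    lod: float
    r2: float
    direction: int              # +1 heterozygote-higher, -1 lower


def _design_null(n: int, addcovar, intcovar, x_chrom: bool, sex) -> np.ndarray:
    cols = [np.ones(n)]
    if addcovar is not None:
        cols.append(np.atleast_2d(np.asarray(addcovar, float).T).T)
    if intcovar is not None:
        cols.append(np.atleast_2d(np.asarray(intcovar, float).T).T)
    if x_chrom:
        cols.append((np.asarray(sex) == "M").astype(float)[:, None])
    C = np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c
                         for c in cols])
    # drop duplicated columns (e.g. sex passed both as intcovar and X null)
    _, keep = np.unique(np.round(C, 12), axis=1, return_index=True)
    return C[:, np.sort(keep)]


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def _position_regressors(p_het: np.ndarray, intcovar, x_chrom: bool, sex):
    """Genotype regressor block per position: (n, n_pos, m)."""
    n, npos = p_het.shape
    if x_chrom:
        male = (np.asarray(sex) == "M").astype(float)
        blocks = [p_het * (1 - male)[:, None], p_het * male[:, None]]
    else:
        blocks = [p_het]
        if intcovar is not None:
            W = np.atleast_2d(np.asarray(intcovar, float).T).T
            for k in range(W.shape[1]):
                blocks.append(p_het * W[:, k][:, None])
    return np.stack(blocks, axis=2)


def _scan_chrom(y_res: np.ndarray, G_res: np.ndarray, rss0: float,
                n: int) -> np.ndarray:
    """LOD per position from residualized y and genotype blocks (FWL)."""
    # G_res: (n, npos, m)
    gtg = np.einsum("npm,npk->pmk", G_res, G_res)
    gty = np.einsum("npm,n->pm", G_res, y_res)
    m = gtg.shape[1]
    gtg = gtg + np.eye(m)[None] * 1e-10
    try:
        b = np.linalg.solve(gtg, gty[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        b = np.stack([np.linalg.lstsq(A, v, rcond=None)[0]
                      for A, v in zip(gtg, gty)])
    rss1 = np.maximum(rss0 - np.einsum("pm,pm->p", b, gty), 1e-300)
    lod = (n / 2.0) * np.log10(rss0 / rss1)
    return np.maximum(lod, 0.0)


def scanone_hk(probs: GenoProbGrid, phenotype: np.ndarray,
               addcovar=None, intcovar=None, chroms=None,
               extended: bool = False) -> ScanResult:
    """Single-QTL Haley-Knott genome scan.

    ``intcovar`` columns interact with genotype in the alternative model
    and enter the null additively.  Missing phenotype rows are dropped.
    Rank-deficient positions come back with LOD 0 via the ridge-stabilized
    solve (a constant genotype regressor explains nothing).  With
    ``extended=True`` a one-step conditional-variance reweighting is
    applied after the standard fit.
    """
    y = np.asarray(phenotype, float)
    ok = np.isfinite(y)
    if addcovar is not None:
        ok &= np.isfinite(np.atleast_2d(np.asarray(addcovar, float).T).T).all(axis=1)
    if intcovar is not None:
        ok &= np.isfinite(np.atleast_2d(np.asarray(intcovar, float).T).T).all(axis=1)
    sub = probs.subset_individuals(ok) if not ok.all() else probs
    y = y[ok]
    ac = None if addcovar is None else np.asarray(addcovar, float)[ok]
    ic = None if intcovar is None else np.asarray(intcovar, float)[ok]
    n = len(y)
    rows = []
    use = probs.chrom_names if chroms is None else list(chroms)
    for chrom in use:
        cp = sub.chroms[chrom]
        x_chrom = chrom == X_CHROM
        C = _design_null(n, ac, ic, x_chrom, sub.sex)
        y_res = _residualize(y, C)
        rss0 = float(y_res @ y_res)
        G = _position_regressors(cp.p_het, ic, x_chrom, sub.sex)
        G_res = _residualize(G.reshape(n, -1), C).reshape(G.shape)
        lod = _scan_chrom(y_res, G_res, rss0, n)
        if extended:
            lod = _extended_hk(y_res, G_res, rss0, n, cp.p_het, lod)
        for j in range(len(cp.pos_cm)):
            rows.append({"chrom": chrom, "pos_cm": cp.pos_cm[j],
                         "pos_mb": cp.pos_mb[j], "lod": lod[j],
                         "name": cp.names[j]})
    return ScanResult(pd.DataFrame(rows),
                      model={"addcovar": addcovar is not None,
                             "intcovar": intcovar is not None,
                             "extended": extended})


def _extended_hk(y_res, G_res, rss0, n, p_het, lod_std):
    """One-step conditional-variance reweighting of the HK fit.

    The residual variance at position j is inflated by a^2 * p(1-p) for
    individuals with uncertain genotype; weights 1/var_i downweight them.
    At fully-informative positions the weights are constant and the result
    equals the standard fit.
    """
    lod = lod_std.copy()
    for j in range(G_res.shape[1]):
        G = G_res[:, j, :]
        gtg = G.T @ G + np.eye(G.shape[1]) * 1e-10
        b = np.linalg.solve(gtg, G.T @ y_res)
        resid = y_res - G @ b
        sigma2 = float(resid @ resid) / max(n - G.shape[1] - 1, 1)
        a2 = float(b @ b)
        var = sigma2 + a2 * p_het[:, j] * (1 - p_het[:, j])
        w = 1.0 / np.maximum(var, 1e-12)
        sw = np.sqrt(w)
        Gw, yw = G * sw[:, None], y_res * sw
        gtgw = Gw.T @ Gw + np.eye(G.shape[1]) * 1e-10
        bw = np.linalg.solve(gtgw, Gw.T @ yw)
        rss1w = float(yw @ yw - bw @ (Gw.T @ yw))
        rss0w = float(yw @ yw)
        lod[j] = max((n / 2.0) * np.log10(max(rss0w, 1e-300)
                                          / max(rss1w, 1e-300)), 0.0)
    return lod


# ---------------------------------------------------------------------------
# Permutation thresholds
# ---------------------------------------------------------------------------

@dataclass
class PermutationThresholds:
    alpha: float
    auto_threshold: float
    x_threshold: float | None
    alpha_auto: float
    alpha_x: float | None
    n_perm_auto: int
    n_perm_x: int
    perm_max_auto: np.ndarray = field(repr=False, default=None)
    perm_max_x: np.ndarray = field(repr=False, default=None)


def _permute_within_strata(rng, n, strata):
    perm = np.arange(n)
    if strata is None:
        rng.shuffle(perm)
        return perm
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        perm[idx] = rng.permutation(idx)
    return perm


def permutation_thresholds(probs: GenoProbGrid, phenotype: np.ndarray,
                           addcovar=None, intcovar=None, alpha: float = 0.05,
                           n_perm_auto: int = 1000, n_perm_x: int = 27000,
                           seed: int = 0, stratify_by_sex: bool | None = None
                           ) -> PermutationThresholds:
    """Genome-wide LOD thresholds by phenotype permutation.

    Autosome and X maxima are permuted separately (``n_perm_auto`` /
    ``n_perm_x``); the overall alpha is split between the two parts in
    proportion to genetic length, ``alpha_part = 1-(1-alpha)^(L_part/L)``.
    Permutations are within sex strata whenever sex is in the model (any
    interactive covariate present, or by request).
    """
    if n_perm_auto < 1 or (X_CHROM in probs.chroms and n_perm_x < 1):
        raise ValueError("need at least one permutation")
    y = np.asarray(phenotype, float)
    ok = np.isfinite(y)
    sub = probs.subset_individuals(ok) if not ok.all() else probs
    y = y[ok]
    ac = None if addcovar is None else np.asarray(addcovar, float)[ok]
    ic = None if intcovar is None else np.asarray(intcovar, float)[ok]
    n = len(y)
    if stratify_by_sex is None:
        stratify_by_sex = ic is not None or X_CHROM in probs.chroms
    strata = sub.sex if stratify_by_sex else None
    autosomes = sub.autosomes()
    has_x = X_CHROM in sub.chroms
    L_a = sub.genetic_length(autosomes)
    L_x = sub.genetic_length([X_CHROM]) if has_x else 0.0
    L = L_a + L_x
    alpha_a = 1 - (1 - alpha) ** (L_a / L) if L > 0 else alpha
    alpha_x = (1 - (1 - alpha) ** (L_x / L)) if has_x else None

    def perm_maxima(chrom_list, x_mode, n_perm, rng):
        # Pre-residualize genotype blocks once; per permutation only the
        # phenotype changes.
        prep = []
        for chrom in chrom_list:
            cp = sub.chroms[chrom]
            C = _design_null(n, ac, ic, x_mode and chrom == X_CHROM, sub.sex)
            G = _position_regressors(cp.p_het, ic, chrom == X_CHROM, sub.sex)
            G_res = _residualize(G.reshape(n, -1), C).reshape(G.shape)
            prep.append((C, G_res))
        maxima = np.empty(n_perm)
        for b in range(n_perm):
            perm = _permute_within_strata(rng, n, strata)
            yp = y[perm]
            best = 0.0
            for C, G_res in prep:
                y_res = _residualize(yp, C)
                rss0 = float(y_res @ y_res)
                lod = _scan_chrom(y_res, G_res, rss0, n)
                best = max(best, float(np.nanmax(lod)))
            maxima[b] = best
        return maxima

    rng = np.random.default_rng(seed)
    max_a = perm_maxima(autosomes, False, n_perm_auto, rng) \
        if autosomes else np.array([np.inf])
    thr_a = float(np.quantile(max_a, 1 - alpha_a)) if autosomes else np.inf
    if has_x:
        max_x = perm_maxima([X_CHROM], True, n_perm_x, rng)
        thr_x = float(np.quantile(max_x, 1 - alpha_x))
    else:
        max_x, thr_x = None, None
    return PermutationThresholds(alpha, thr_a, thr_x, alpha_a, alpha_x,
                                 n_perm_auto, n_perm_x if has_x else 0,
                                 max_a, max_x)


# ---------------------------------------------------------------------------
# Bayes credible interval
# ---------------------------------------------------------------------------

def bayes_interval(scan: ScanResult, chrom: str, coverage: float = 0.95):
    """95% Bayes credible interval for a peak on one chromosome.

    The posterior is proportional to ``10^LOD`` times the grid-cell width.
    Starting from the peak (leftmost on ties), neighboring grid positions
    are absorbed greedily (larger posterior first, left on ties) until the
    target mass is reached; the interval is then widened by one grid
    position on each side, the conventional conservative reporting.
    Returns ``(left_cm, peak_cm, right_cm, left_mb, peak_mb, right_mb)``.
    """
    sub = scan.df[scan.df["chrom"] == str(chrom)]
    if len(sub) == 0:
        raise KeyError(f"chromosome {chrom} not in scan")
    pos = sub["pos_cm"].to_numpy(float)
    mb = sub["pos_mb"].to_numpy(float)
    lod = sub["lod"].to_numpy(float)
    lod = np.where(np.isfinite(lod), lod, 0.0)
    if len(pos) == 1:
        return (pos[0], pos[0], pos[0], mb[0], mb[0], mb[0])
    width = (np.append(pos[1:], pos[-1]) - np.insert(pos[:-1], 0, pos[0])) / 2
    w = np.power(10.0, lod - lod.max()) * np.maximum(width, 1e-12)
    w = w / w.sum()
    peak = int(np.argmax(lod))
    lo = hi = peak
    mass = w[peak]
    while mass < coverage and (lo > 0 or hi < len(pos) - 1):
        left = w[lo - 1] if lo > 0 else -1.0
        right = w[hi + 1] if hi < len(pos) - 1 else -1.0
        if left >= right:
            lo -= 1
            mass += w[lo]
        else:
            hi += 1
            mass += w[hi]
    lo = max(lo - 1, 0)
    hi = min(hi + 1, len(pos) - 1)
    return (float(pos[lo]), float(pos[peak]), float(pos[hi]),
            float(mb[lo]), float(mb[peak]), float(mb[hi]))


def variance_explained(lod: float, n: int) -> float:
    """Phenotypic variance explained from a scan LOD: 1 - 10^(-2 LOD / n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if lod < 0:
        raise ValueError("LOD must be non-negative")
    return 1.0 - 10.0 ** (-2.0 * lod / n)


def lod_from_r2(r2: float, n: int) -> float:
    """Inverse of :func:`variance_explained`."""
    return -(n / 2.0) * np.log10(1.0 - r2)


def effect_direction(probs: GenoProbGrid, chrom: str, pos_cm: float,
                     phenotype: np.ndarray, sex_stratum: str | None = None
                     ) -> int:
    """Sign of the HET (SPRET-carrier) effect at a position: +1 higher."""
    cp = probs.chroms[str(chrom)]
    j = int(np.argmin(np.abs(cp.pos_cm - pos_cm)))
    g = cp.p_het[:, j]
    y = np.asarray(phenotype, float)
    ok = np.isfinite(y)
    if sex_stratum is not None:
        ok &= probs.sex == sex_stratum
    g, y = g[ok], y[ok]
    cov = float(((g - g.mean()) * (y - y.mean())).mean())
    return 1 if cov >= 0 else -1


def locate_peak(scan: ScanResult, probs: GenoProbGrid, chrom: str,
                phenotype: np.ndarray, name: str, pheno_name: str,
                n_used: int | None = None, suffix: str = "") -> QTLPeak:
    """Assemble a :class:`QTLPeak` (interval, r2, direction) for a chromosome."""
    sub = scan.df[scan.df["chrom"] == str(chrom)]
    row = scan.peak(str(chrom))
    l_cm, p_cm, r_cm, l_mb, p_mb, r_mb = bayes_interval(scan, chrom)
    y = np.asarray(phenotype, float)
    n = n_used if n_used is not None else int(np.isfinite(y).sum())
    qname = f"{name}_{chrom}{suffix}"
    return QTLPeak(qname, pheno_name, str(chrom), float(row["pos_cm"]),
                   float(row["pos_mb"]), l_mb, r_mb, l_cm, r_cm,
                   float(row["lod"]), variance_explained(float(row["lod"]), n),
                   effect_direction(probs, chrom, float(row["pos_cm"]), y))


# ---------------------------------------------------------------------------
# Two-locus models on one chromosome
# ---------------------------------------------------------------------------

@dataclass
class TwoQtlReport:
    chrom: str
    max_single_lod: float
    single_pos: float
    max_add_lod: float
    add_pair: tuple
    max_full_lod: float
    full_pair: tuple
    second_qtl_lod: float        # max_add - max_single
    interaction_lod: float       # max_full - max_add
    second_qtl: bool
    interaction: bool
    directions: tuple            # signs of the two additive coefficients


def scantwo_chromosome(probs: GenoProbGrid, phenotype: np.ndarray,
                       chrom: str, addcovar=None, intcovar=None,
                       threshold_second: float = 2.0,
                       threshold_interaction: float = 2.0,
                       min_sep_cm: float = 10.0) -> TwoQtlReport:
    """Two-locus additive and full models over one chromosome's grid.

    Evidence for a second QTL when (max two-locus additive LOD) minus
    (max single LOD) exceeds ``threshold_second``; for an interaction when
    (max full LOD) minus (max additive LOD) exceeds
    ``threshold_interaction``.  Pairs closer than ``min_sep_cm`` are not
    evaluated (they are indistinguishable from one locus on this grid).
    """
    y = np.asarray(phenotype, float)
    ok = np.isfinite(y)
    sub = probs.subset_individuals(ok) if not ok.all() else probs
    y = y[ok]
    ac = None if addcovar is None else np.asarray(addcovar, float)[ok]
    ic = None if intcovar is None else np.asarray(intcovar, float)[ok]
    cp = sub.chroms[str(chrom)]
    if len(cp.pos_cm) < 3:
        raise ValueError("grid too coarse for a two-locus model")
    n = len(y)
    x_chrom = str(chrom) == X_CHROM
    C = _design_null(n, ac, ic, x_chrom, sub.sex)
    y_res = _residualize(y, C)
    rss0 = float(y_res @ y_res)
    G = _position_regressors(cp.p_het, ic, x_chrom, sub.sex)
    G_res = _residualize(G.reshape(n, -1), C).reshape(G.shape)
    lod1 = _scan_chrom(y_res, G_res, rss0, n)
    j1 = int(np.argmax(lod1))
    best = {"add": (-np.inf, None, None), "full": (-np.inf, None, None)}
    npos = len(cp.pos_cm)
    P = cp.p_het
    for i in range(npos):
        for j in range(i + 1, npos):
            if cp.pos_cm[j] - cp.pos_cm[i] < min_sep_cm:
                continue
            cols = [G_res[:, i, :], G_res[:, j, :]]
            Xadd = np.column_stack(cols)
            lod_add, b = _fit_lod(Xadd, y_res, rss0, n)
            if lod_add > best["add"][0]:
                best["add"] = (lod_add, (i, j), (b[0], b[G_res.shape[2]]))
            inter = _residualize((P[:, i] * P[:, j])[:, None], C)
            Xfull = np.column_stack([Xadd, inter])
            lod_full, _ = _fit_lod(Xfull, y_res, rss0, n)
            if lod_full > best["full"][0]:
                best["full"] = (lod_full, (i, j), None)
    lod_add, pair_add, coefs = best["add"]
    lod_full, pair_full, _ = best["full"]
    second = lod_add - lod1[j1]
    inter_lod = lod_full - lod_add
    dirs = (int(np.sign(coefs[0])) or 1, int(np.sign(coefs[1])) or 1)
    return TwoQtlReport(str(chrom), float(lod1[j1]), float(cp.pos_cm[j1]),
                        float(lod_add),
                        (float(cp.pos_cm[pair_add[0]]),
                         float(cp.pos_cm[pair_add[1]])),
                        float(lod_full),
                        (float(cp.pos_cm[pair_full[0]]),
                         float(cp.pos_cm[pair_full[1]])),
                        float(second), float(inter_lod),
                        bool(second > threshold_second),
                        bool(inter_lod > threshold_interaction), dirs)


def _fit_lod(X: np.ndarray, y_res: np.ndarray, rss0: float, n: int):
    xtx = X.T @ X + np.eye(X.shape[1]) * 1e-10
    xty = X.T @ y_res
    b = np.linalg.solve(xtx, xty)
    rss1 = max(rss0 - float(b @ xty), 1e-300)
    return max((n / 2.0) * np.log10(rss0 / rss1), 0.0), b


def scantwo_permutations(probs: GenoProbGrid, phenotype: np.ndarray,
                         chrom: str, addcovar=None, intcovar=None,
                         n_perm: int = 100, alpha: float = 0.05,
                         seed: int = 0, min_sep_cm: float = 10.0):
    """Permutation thresholds for the second-QTL and interaction contrasts."""
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, float)
    ok = np.isfinite(y)
    y0 = y[ok]
    second, inter = np.empty(n_perm), np.empty(n_perm)
    strata = probs.sex[ok] if intcovar is not None else None
    for b in range(n_perm):
        perm = _permute_within_strata(rng, len(y0), strata)
        yp = np.full(len(y), np.nan)
        yp[ok] = y0[perm]
        rep = scantwo_chromosome(probs, yp, chrom, addcovar, intcovar,
                                 np.inf, np.inf, min_sep_cm)
        second[b] = rep.second_qtl_lod
        inter[b] = rep.interaction_lod
    return (float(np.quantile(second, 1 - alpha)),
            float(np.quantile(inter, 1 - alpha)))


# ---------------------------------------------------------------------------
# Multi-QTL refinement
# ---------------------------------------------------------------------------

def refine_positions(probs: GenoProbGrid, phenotype: np.ndarray,
                     qtl_list: list, addcovar=None, intcovar=None,
                     max_iter: int = 10):
    """Coordinate-ascent repositioning of a multi-QTL additive model.

    Each locus in turn is rescanned over its chromosome's grid with the
    other loci held fixed; iteration stops when no locus moves.  The joint
    LOD is non-decreasing at every step.  Returns
    ``(refined [(chrom, pos_cm)], joint_lod, converged)``.
    """
    if not qtl_list:
        raise ValueError("need at least one QTL")
    y = np.asarray(phenotype, float)
    ok = np.isfinite(y)
    sub = probs.subset_individuals(ok) if not ok.all() else probs
    y = y[ok]
    ac = None if addcovar is None else np.asarray(addcovar, float)[ok]
    ic = None if intcovar is None else np.asarray(intcovar, float)[ok]
    n = len(y)
    loci = [(str(c), float(p)) for c, p in qtl_list]

    def col_for(chrom, pos):
        cp = sub.chroms[chrom]
        j = int(np.argmin(np.abs(cp.pos_cm - pos)))
        x_chrom = chrom == X_CHROM
        return _position_regressors(cp.p_het[:, [j]], ic, x_chrom,
                                    sub.sex)[:, 0, :]

    any_x = any(c == X_CHROM for c, _ in loci)
    C = _design_null(n, ac, ic, any_x, sub.sex)
    y_res = _residualize(y, C)
    rss0 = float(y_res @ y_res)

    def joint_lod(positions):
        X = np.column_stack([col_for(c, p) for c, p in positions])
        X = _residualize(X, C)
        lod, _ = _fit_lod(X, y_res, rss0, n)
        return lod

    current = joint_lod(loci)
    converged = False
    for _ in range(max_iter):
        moved = False
        for k, (chrom, pos) in enumerate(loci):
            cp = sub.chroms[chrom]
            best_pos, best_lod = pos, current
            for cand in cp.pos_cm:
                trial = loci.copy()
                trial[k] = (chrom, float(cand))
                lod = joint_lod(trial)
                if lod > best_lod + 1e-9:
                    best_pos, best_lod = float(cand), lod
            if best_pos != pos:
                loci[k] = (chrom, best_pos)
                current = best_lod
                moved = True
        if not moved:
            converged = True
            break
    return loci, float(current), converged


# ---------------------------------------------------------------------------
# Sex-by-genotype interaction at a marker
# ---------------------------------------------------------------------------

def sex_interaction_test(genotype: np.ndarray, sex: np.ndarray,
                         phenotype: np.ndarray):
    """ANOVA F-test of the sex:genotype interaction at one marker.

    Compares {genotype + sex + genotype x sex} against {genotype + sex}.
    Returns ``(p_interaction, {"M": het_minus_hom, "F": ...})``.
    """
    g = np.asarray(genotype, float)
    y = np.asarray(phenotype, float)
    sx = np.asarray(sex)
    ok = np.isfinite(y) & (g != MISSING)
    g, y, sx = g[ok], y[ok], sx[ok]
    male = (sx == "M").astype(float)
    for s in (0.0, 1.0):
        for gv in (0.0, 1.0):
            if not ((male == s) & (g == gv)).any():
                raise ValueError("empty cell in the sex x genotype layout")
    X_r = np.column_stack([np.ones(len(y)), g, male])
    X_f = np.column_stack([X_r, g * male])
    rss_r = _ols_rss(X_r, y)
    rss_f = _ols_rss(X_f, y)
    df2 = len(y) - X_f.shape[1]
    F = max(rss_r - rss_f, 0.0) / max(rss_f / df2, 1e-300)
    p = float(stats.f.sf(F, 1, df2))
    effects = {}
    for s, lab in ((1.0, "M"), (0.0, "F")):
        m = male == s
        effects[lab] = float(y[m & (g == 1)].mean() - y[m & (g == 0)].mean())
    return p, effects


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)
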