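"""Genotype data structures, cluster-based genotype calling, and pre-analysis QC.

An interspecific backcross ((SPRET x FVB) F1 x FVB) segregates two genotype
classes at every autosomal locus: homozygous FVB/FVB ("AA") and heterozygous
FVB/SPRET ("AB").  On the X chromosome females carry AA/AB as on the
autosomes while males are hemizygous for a single maternal allele ("AY" or
"BY").  This module holds the genetic map and genotype matrix containers,
calls genotypes from two-channel allele-intensity signal, and applies the
standard pre-linkage quality filters (individual missingness, implausible
crossover counts, duplicate samples; marker missingness and segregation
distortion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# Genotype codes (int8 storage).
HOM = 0  # FVB/FVB on autosomes and female X; "A" allele on male X
HET = 1  # FVB/SPRET on autosomes and female X; "B" allele on male X
MISSING = -1

CODE_TO_STR = {HOM: "AA", HET: "AB", MISSING: "-"}
STR_TO_CODE = {"AA": HOM, "AB": HET, "-": MISSING, "": MISSING,
               "AY": HOM, "BY": HET, "NA": MISSING}

X_CHROM = "X"


def code_labels(chrom: str, sex: str) -> dict[int, str]:
    """String labels for stored codes, which differ for hemizygous male X."""
    if chrom == X_CHROM and sex == "M":
        return {HOM: "AY", HET: "BY", MISSING: "-"}
    return {HOM: "AA", HET: "AB", MISSING: "-"}


class GeneticMap:
    """Marker map: name, chromosome, genetic (cM) and physical (Mb) position.

    Markers are kept sorted by chromosome (1..19 then X) and cM.  Names must
    be unique and positions non-decreasing within a chromosome.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"marker", "chrom", "cm", "mb"}
        if not required.issubset(df.columns):
            raise ValueError(f"map requires columns {sorted(required)}")
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        df = df.sort_values(
            ["chrom", "cm"],
            key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s,
            kind="stable",
        ).reset_index(drop=True)
        if df["marker"].duplicated().any():
            raise ValueError("duplicate marker names in map")
        for _, sub in df.groupby("chrom", sort=False):
            if (np.diff(sub["cm"].to_numpy()) < 0).any():
                raise ValueError("cM positions must be non-decreasing")
        self.df = df

    @property
    def markers(self) -> np.ndarray:
        return self.df["marker"].to_numpy()

    @property
    def chroms(self) -> list[str]:
        seen: list[str] = []
        for c in self.df["chrom"]:
            if c not in seen:
                seen.append(c)
        return seen

    def chrom_slice(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == str(chrom)]

    def chrom_length(self, chrom: str) -> float:
        sub = self.chrom_slice(chrom)
        return float(sub["cm"].max() - sub["cm"].min())

    def total_length(self, include_x: bool = True) -> float:
        return sum(self.chrom_length(c) for c in self.chroms
                   if include_x or c != X_CHROM)

    def subset(self, markers: Sequence[str]) -> "GeneticMap":
        keep = self.df[self.df["marker"].isin(set(markers))]
        return GeneticMap(keep)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"<GeneticMap {len(self)} markers on {len(self.chroms)} chromosomes>"


def _chrom_sort_key(c: str) -> float:
    return float("inf") if str(c) == X_CHROM else float(c)


class GenotypeMatrix:
    """Individuals x markers genotype codes, tied to a :class:`GeneticMap`.

    ``geno`` is int8 with values HOM/HET/MISSING; on the male X the same
    codes mean hemizygous AY/BY.
    """

    def __init__(self, individuals: Sequence[str], sex: Sequence[str],
                 geno: np.ndarray, gmap: GeneticMap):
        geno = np.asarray(geno, dtype=np.int8)
        individuals = np.asarray(individuals, dtype=object)
        sex = np.asarray(sex, dtype=object)
        if geno.shape != (len(individuals), len(gmap)):
            raise ValueError("genotype matrix shape does not match map/ids")
        if not set(np.unique(sex)) <= {"M", "F"}:
            raise ValueError("sex must be coded 'M'/'F'")
        self.individuals = individuals
        self.sex = sex
        self.geno = geno
        self.map = gmap

    @property
    def n(self) -> int:
        return len(self.individuals)

    def marker_index(self, marker: str) -> int:
        idx = np.flatnonzero(self.map.markers == marker)
        if len(idx) == 0:
            raise KeyError(f"unknown marker {marker!r}")
        return int(idx[0])

    def genotype_at(self, marker: str) -> np.ndarray:
        return self.geno[:, self.marker_index(marker)]

    def subset(self, individuals_mask: np.ndarray | None = None,
               markers_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        ind = np.ones(self.n, bool) if individuals_mask is None else individuals_mask
        mk = np.ones(len(self.map), bool) if markers_mask is None else markers_mask
        sub_map = GeneticMap(self.map.df.loc[mk])
        return GenotypeMatrix(self.individuals[ind], self.sex[ind],
                              self.geno[np.ix_(ind, mk)], sub_map)

    def __repr__(self) -> str:
        return f"<GenotypeMatrix {self.n} individuals x {len(self.map)} markers>"


# ---------------------------------------------------------------------------
# Cross-format CSV (rotated layout: marker columns carry chromosome and cM
# header rows; phenotype columns come first and have blank header cells).
# ---------------------------------------------------------------------------

def write_cross_csv(path, gm: GenotypeMatrix,
                    phenotypes: pd.DataFrame | None = None) -> None:
    """Write genotypes (+ optional per-individual phenotypes) as cross CSV.

    Layout: row 1 = column names, row 2 = chromosome per marker column
    (blank for phenotype columns), row 3 = cM position, then one row per
    individual with genotype codes ``AA``/``AB``/``-`` (``AY``/``BY`` on the
    male X).  ``id`` and ``sex`` are always emitted as phenotype columns.
    """
    pheno = pd.DataFrame({"id": self_ids(gm), "sex": gm.sex})
    if phenotypes is not None:
        extra = phenotypes.drop(columns=[c for c in ("id", "sex")
                                         if c in phenotypes.columns])
        pheno = pd.concat([pheno, extra.reset_index(drop=True)], axis=1)
    mdf = gm.map.df
    is_x = (mdf["chrom"] == X_CHROM).to_numpy()
    male = gm.sex == "M"
    with open(path, "w") as fh:
        cols = list(pheno.columns) + list(mdf["marker"])
        fh.write(",".join(cols) + "\n")
        fh.write(",".join([""] * len(pheno.columns) + list(mdf["chrom"])) + "\n")
        fh.write(",".join([""] * len(pheno.columns)
                          + [f"{v:g}" for v in mdf["cm"]]) + "\n")
        for i in range(gm.n):
            cells = [_fmt(v) for v in pheno.iloc[i]]
            for j, g in enumerate(gm.geno[i]):
                labels = code_labels(X_CHROM if is_x[j] else "A",
                                     "M" if male[i] else "F")
                cells.append(labels[int(g)])
            fh.write(",".join(cells) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)


def self_ids(gm: GenotypeMatrix) -> np.ndarray:
    return gm.individuals


def read_cross_csv(path, mb_per_cm: float = 2.0):
    """Read cross CSV; returns ``(GenotypeMatrix, phenotype DataFrame)``.

    The rotated layout stores no physical positions; Mb is reconstructed as
    ``cm * mb_per_cm``, matching the simulator's default map scaling.
    """
    raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    names = raw.iloc[0].to_list()
    chrom_row = raw.iloc[1].to_list()
    cm_row = raw.iloc[2].to_list()
    is_marker = [c != "" for c in chrom_row]
    pheno_cols = [n for n, m in zip(names, is_marker) if not m]
    marker_cols = [n for n, m in zip(names, is_marker) if m]
    body = raw.iloc[3:].reset_index(drop=True)
    body.columns = names
    pheno = body[pheno_cols].copy()
    for c in pheno.columns:
        if c not in ("id", "sex"):
            pheno[c] = pd.to_numeric(pheno[c], errors="coerce")
    map_df = pd.DataFrame({
        "marker": marker_cols,
        "chrom": [c for c, m in zip(chrom_row, is_marker) if m],
        "cm": [float(c) for c, m in zip(cm_row, is_marker) if m],
    })
    map_df["mb"] = map_df["cm"] * mb_per_cm
    gmap = GeneticMap(map_df)
    geno = np.full((len(body), len(marker_cols)), MISSING, dtype=np.int8)
    for j, mk in enumerate(marker_cols):
        geno[:, j] = [STR_TO_CODE.get(v, MISSING) for v in body[mk]]
    gm = GenotypeMatrix(pheno["id"].to_numpy(), pheno["sex"].to_numpy(),
                        geno, gmap)
    return gm, pheno


# ---------------------------------------------------------------------------
# Genotype calling from two-channel assay signal
# ---------------------------------------------------------------------------

#: Minimum ratio of second-best to best centroid distance for a confident
#: call; closer ties are set MISSING (conservative, mirrors manual curation).
AMBIGUITY_RATIO = 1.2

_CONTROL_TO_CODE = {"FVB": HOM, "F1": HET}


def _normalize_signal(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Project two channels onto the allele-fraction simplex (a,b)/(a+b)."""
    tot = a + b
    tot = np.where(tot <= 0, np.nan, tot)
    return np.column_stack([a / tot, b / tot])


def call_autosomal_genotypes(signal: pd.DataFrame,
                             control_signals: pd.DataFrame,
                             ambiguity_ratio: float = AMBIGUITY_RATIO
                             ) -> pd.DataFrame:
    """Assign autosomal genotypes by nearest control centroid per marker.

    ``signal``: columns individual, marker, channel_a, channel_b.
    ``control_signals``: columns cls (FVB|SPRET|F1), marker, channel_a,
    channel_b; at least one control per class per marker is required.
    Samples nearest the SPRET centroid (impossible in this backcross) or
    with an ambiguous distance ratio are set MISSING.

    Returns a long DataFrame (individual, marker, code).
    """
    out = []
    for marker, sub in signal.groupby("marker", sort=False):
        ctl = control_signals[control_signals["marker"] == marker]
        centroids = {}
        for cls in ("FVB", "SPRET", "F1"):
            pts = ctl[ctl["cls"] == cls]
            if len(pts) == 0:
                raise ValueError(f"no {cls} control for marker {marker}")
            xy = _normalize_signal(pts["channel_a"].to_numpy(float),
                                   pts["channel_b"].to_numpy(float))
            centroids[cls] = np.nanmean(xy, axis=0)
        xy = _normalize_signal(sub["channel_a"].to_numpy(float),
                               sub["channel_b"].to_numpy(float))
        names = list(centroids)
        cents = np.array([centroids[c] for c in names])
        d = np.linalg.norm(xy[:, None, :] - cents[None, :, :], axis=2)
        order = np.argsort(d, axis=1)
        best = order[:, 0]
        ratio = np.take_along_axis(d, order[:, 1:2], 1)[:, 0] / np.maximum(
            np.take_along_axis(d, order[:, 0:1], 1)[:, 0], 1e-300)
        codes = np.full(len(sub), MISSING, dtype=np.int8)
        for i, (b, r) in enumerate(zip(best, ratio)):
            if not np.isfinite(xy[i]).all():
                continue
            if r < ambiguity_ratio:
                continue
            codes[i] = _CONTROL_TO_CODE.get(names[b], MISSING)
        out.append(pd.DataFrame({"individual": sub["individual"].to_numpy(),
                                 "marker": marker, "code": codes}))
    return pd.concat(out, ignore_index=True)


#: Mahalanobis radius beyond which X-chromosome points are flagged MISSING.
LDA_OUTLIER_RADIUS = 4.0


def call_x_genotypes(signal: pd.DataFrame, sex: pd.Series | dict,
                     outlier_radius: float = LDA_OUTLIER_RADIUS
                     ) -> pd.DataFrame:
    """Call X-chromosome genotypes per sex by two-class linear discriminant.

    Within each sex stratum the two genotype groups are seeded from the
    extremes of the allele fraction, then refined by linear discriminant
    assignment with pooled covariance and equal priors (equivalent to
    Mahalanobis-nearest centroids).  Points beyond ``outlier_radius``
    Mahalanobis units from both centroids, or exactly on the decision
    midplane, are set MISSING.  Codes: females AA/AB -> HOM/HET, males
    AY/BY -> HOM/HET, where the A class is the one with the higher
    channel-A fraction.
    """
    sexmap = sex if isinstance(sex, dict) else dict(zip(sex.index, sex))
    out = []
    for marker, sub in signal.groupby("marker", sort=False):
        sx = np.array([sexmap[i] for i in sub["individual"]], dtype=object)
        xy = _normalize_signal(sub["channel_a"].to_numpy(float),
                               sub["channel_b"].to_numpy(float))
        codes = np.full(len(sub), MISSING, dtype=np.int8)
        for s in ("F", "M"):
            m = (sx == s) & np.isfinite(xy).all(axis=1)
            if m.sum() < 4:
                continue
            codes[m] = _lda_two_class(xy[m], outlier_radius)
        out.append(pd.DataFrame({"individual": sub["individual"].to_numpy(),
                                 "marker": marker, "code": codes}))
    return pd.concat(out, ignore_index=True)


def _lda_two_class(x: np.ndarray, outlier_radius: float) -> np.ndarray:
    """Two-class LDA with pooled covariance on 2-D points.

    Raises if the stratum does not separate into two clusters (all points
    identical along the allele-fraction axis).
    """
    frac = x[:, 0]
    if np.ptp(frac) < 1e-9:
        raise ValueError("sex stratum has fewer than 2 distinguishable clusters")
    # Seed the two classes from the 10th/90th percentile of the allele
    # fraction (robust to stray points), then iterate pooled-covariance
    # linear-discriminant assignment.
    c_lo, c_hi = np.percentile(frac, [10, 90])
    labels = (np.abs(frac - c_hi) < np.abs(frac - c_lo)).astype(int)
    keep = np.ones(len(x), bool)

    def lda_pass(labels, keep):
        mu = np.array([x[keep & (labels == k)].mean(axis=0) for k in (0, 1)])
        centered = (x - mu[labels])[keep]
        cov = centered.T @ centered / max(keep.sum() - 2, 1)
        cov += np.eye(2) * 1e-9
        icov = np.linalg.inv(cov)
        diff = x[:, None, :] - mu[None, :, :]
        d2 = np.einsum("pki,ij,pkj->pk", diff, icov, diff)
        return mu, d2

    d2 = None
    for _ in range(20):
        mu, d2 = lda_pass(labels, keep)
        new = np.argmin(d2, axis=1)
        # refine: exclude Mahalanobis outliers from the class statistics,
        # mimicking manual outlier curation before the discriminant fit
        keep_new = np.sqrt(d2.min(axis=1)) <= outlier_radius
        if (new == labels).all() and (keep_new == keep).all():
            break
        if len(np.unique(new[keep_new])) < 2:
            break
        labels, keep = new, keep_new
    mu, d2 = lda_pass(labels, keep)
    # A class = higher channel-A fraction.
    a_class = int(np.argmax(mu[:, 0]))
    codes = np.where(labels == a_class, HOM, HET).astype(np.int8)
    codes[np.sqrt(d2.min(axis=1)) > outlier_radius] = MISSING
    # Midplane points (equidistant under equal priors) are ambiguous.
    codes[np.isclose(d2[:, 0], d2[:, 1], rtol=0, atol=1e-10)] = MISSING
    return codes


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    """Pre-linkage QC thresholds (defaults are package decisions; the
    source protocol leaves them to the analyst)."""
    t_miss: float = 0.10        # max individual missing fraction
    m_miss: float = 0.10        # max marker missing fraction
    t_dup: float = 0.95         # concordance above which a pair is duplicate
    alpha_seg: float = 1e-6     # segregation-distortion binomial alpha
    t_xo: float | None = None   # max genome-wide crossovers; None = 2x expected

    def __post_init__(self):
        for name in ("t_miss", "m_miss", "t_dup"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0,1]")
        if not 0 < self.alpha_seg < 1:
            raise ValueError("alpha_seg must lie in (0,1)")


def crossover_counts(gm: GenotypeMatrix) -> np.ndarray:
    """Genome-wide count of adjacent-marker genotype switches per individual.

    Switches are counted between consecutive non-missing calls within each
    chromosome; missing calls are skipped, not counted as switches.
    """
    counts = np.zeros(gm.n, dtype=int)
    for chrom in gm.map.chroms:
        mask = (gm.map.df["chrom"] == chrom).to_numpy()
        sub = gm.geno[:, mask]
        for i in range(gm.n):
            row = sub[i]
            obs = row[row != MISSING]
            if len(obs) > 1:
                counts[i] += int((np.diff(obs) != 0).sum())
    return counts


def concordance_matrix(geno: np.ndarray) -> np.ndarray:
    """Pairwise genotype concordance over jointly non-missing markers."""
    n = geno.shape[0]
    conc = np.ones((n, n))
    obs = geno != MISSING
    for i in range(n):
        both = obs[i] & obs[i + 1:]
        eq = (geno[i] == geno[i + 1:]) & both
        denom = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            c = np.where(denom > 0, eq.sum(axis=1) / np.maximum(denom, 1), 0.0)
        conc[i, i + 1:] = conc[i + 1:, i] = c
    return conc


def qc_filter_individuals(gm: GenotypeMatrix,
                          thresholds: QCThresholds | None = None):
    """Drop individuals failing missingness, crossover or duplicate checks.

    Returns ``(filtered GenotypeMatrix, report dict)``; the report lists
    each dropped individual with its reason.
    """
    th = thresholds or QCThresholds()
    miss_frac = (gm.geno == MISSING).mean(axis=1)
    xo = crossover_counts(gm)
    t_xo = th.t_xo
    if t_xo is None:
        t_xo = 2.0 * gm.map.total_length() / 100.0
    drop = np.zeros(gm.n, bool)
    reasons: dict[str, list[str]] = {}

    def mark(i: int, reason: str) -> None:
        drop[i] = True
        reasons.setdefault(str(gm.individuals[i]), []).append(reason)

    for i in np.flatnonzero(miss_frac > th.t_miss):
        mark(i, "missing")
    for i in np.flatnonzero(xo > t_xo):
        mark(i, "crossovers")
    conc = concordance_matrix(gm.geno)
    for i in range(gm.n):
        for j in range(i + 1, gm.n):
            if conc[i, j] > th.t_dup and not (drop[i] or drop[j]):
                # keep the member of the pair with less missing data
                victim = i if miss_frac[i] >= miss_frac[j] else j
                mark(victim, "duplicate")
    report = {
        "n_input": gm.n,
        "n_dropped": int(drop.sum()),
        "dropped": reasons,
        "crossover_threshold": float(t_xo),
    }
    return gm.subset(individuals_mask=~drop), report


def qc_filter_markers(gm: GenotypeMatrix,
                      thresholds: QCThresholds | None = None):
    """Drop markers with high missingness or distorted HOM/HET segregation.

    Segregation is tested per marker by an exact binomial test of the
    SPRET-allele-carrier count against the backcross expectation of 1/2
    (on the X, female AB and male BY both count as carriers).
    """
    th = thresholds or QCThresholds()
    if gm.n < 1:
        raise ValueError("need at least one individual")
    miss_frac = (gm.geno == MISSING).mean(axis=0)
    nmark = len(gm.map)
    drop = miss_frac > th.m_miss
    reasons = np.where(drop, "missing", "").astype(object)
    for j in range(nmark):
        col = gm.geno[:, j]
        obs = col[col != MISSING]
        if len(obs) == 0:
            if not drop[j]:
                drop[j], reasons[j] = True, "missing"
            continue
        k = int((obs == HET).sum())
        p = stats.binomtest(k, len(obs), 0.5).pvalue
        if p < th.alpha_seg and not drop[j]:
            drop[j], reasons[j] = True, "segregation"
    report = {
        "n_input": nmark,
        "n_dropped": int(drop.sum()),
        "n_retained": int((~drop).sum()),
        "dropped": {str(m): str(r) for m, r in
                    zip(gm.map.markers[drop], reasons[drop])},
    }
    return gm.subset(markers_mask=~drop), report
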