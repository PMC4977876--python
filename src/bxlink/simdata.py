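"""Synthetic interspecific-backcross cohorts with planted, known signals.

Every downstream stage of the pipeline (QC, genome scans, candidate-gene
routes, co-expression neighborhoods, tumor statistics) is exercised on
cohorts produced here.  The generator emulates the study design the
pipeline targets: ~374 backcross individuals of both sexes genotyped at 276
markers (~10 cM grid, 19 autosomes + X), additive QTL of 2-10% variance
with optional sex restriction, cis/trans eQTL, a seed-centered co-expressed
gene module, overdispersed papilloma counts positively coupled to BMI in
males, proportional-hazards carcinoma times, and group-structured qPCR Ct
values.  All randomness flows through ``numpy.random.default_rng`` (PCG64):
a fixed seed gives bit-identical output.

Genetic model: each backcross chromosome is a two-state Markov chain
(HOM FVB/FVB vs HET FVB/SPRET) whose transition probability between
adjacent markers is the Haldane recombination fraction
``r = (1 - exp(-2 d/100)) / 2`` (no interference), matching the hidden
Markov model used by the scan module.  Males carry a single maternal X
(recombinant FVB-or-SPRET haplotype, coded AY/BY); females receive a
paternal FVB X, so their X segregates AA/AB like an autosome.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import (GeneticMap, GenotypeMatrix, HET, HOM, MISSING,
                        X_CHROM)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class MapSpec:
    """Marker-grid specification.

    Defaults give 19 autosomes of 130 cM plus a 90 cM X at 10 cM spacing:
    14 markers per autosome and 10 on X, i.e. 276 markers total — the
    marker-panel size of the cohort this generator emulates.
    """
    n_autosomes: int = 19
    chrom_lengths: Sequence[float] | None = None   # cM, autosomes then X
    marker_spacing: float = 10.0                   # cM
    x_length: float = 90.0                         # cM
    autosome_length: float = 130.0                 # cM (used if lengths None)
    mb_per_cm: float = 2.0                         # physical scaling

    def lengths(self) -> list[float]:
        if self.chrom_lengths is not None:
            ls = list(self.chrom_lengths)
            if len(ls) != self.n_autosomes + 1:
                raise ValueError("chrom_lengths must cover autosomes + X")
            return ls
        return [self.autosome_length] * self.n_autosomes + [self.x_length]


@dataclass
class QTLEffect:
    chrom: str
    pos_cm: float
    phenotype: str            # "bmi", "weight", "length" or custom
    effect: float             # additive HET-vs-HOM shift in phenotype SD
    sex: str | None = None    # None, "M" or "F" (sex-restricted effect)


@dataclass
class EQTLEffect:
    gene: str
    marker: str
    effect: float             # HET-vs-HOM shift in expression SD
    kind: str = "cis"         # cis | trans (annotation only; placement differs)


@dataclass
class ModuleSpec:
    """One latent-factor co-expressed module centered on a seed gene.

    With loading ``l`` each member is ``l*F + sqrt(1-l^2)*noise`` so every
    pairwise correlation is ``l**2``.  The default loading 0.7746 plants
    pairwise rho ~ 0.6, the regime of the lipid-metabolism neighborhood the
    pipeline is designed to recover.
    """
    seed_gene: str = "Mod000"
    size: int = 32
    loading: float = 0.7746

    def __post_init__(self):
        if not 0 <= self.loading <= 1:
            raise ValueError("loading must lie in [0,1]")


@dataclass
class TumorModel:
    """Papilloma-count and carcinoma-survival generator parameters.

    Counts are negative-binomial (gamma-Poisson with a per-mouse frailty
    shared across timepoints) with log mean linear in within-sex-
    standardized BMI; dispersion is the NB alpha (var = mu + alpha*mu^2).
    Carcinoma times are exponential with log hazard linear in the same
    standardized BMI, censored administratively.  Defaults plant the
    male-restricted coupling regime: BMI-burden Spearman rho ~ 0.38 in
    males and null in females, and a male hazard log-HR per BMI SD of
    ln(2.36)/2.54 ~ 0.338 (the per-SD rate that makes the top-vs-bottom
    BMI quartile contrast a ~2.36-fold risk).
    """
    dispersion: float = 0.5
    count_intercept: float = np.log(8.0)   # mean burden at 20 weeks, avg BMI
    bmi_coef_male: float = 0.40
    bmi_coef_female: float = 0.0
    baseline_hazard: float = 0.00268       # events/day; ~70% events by day 450
    log_hr_bmi_male: float = 0.338
    log_hr_bmi_female: float = 0.0
    followup_days: float = 450.0

    def __post_init__(self):
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class QPCRSpec:
    """Group-structured Ct generator for a 2x2 inhibitor/promoter design."""
    target_gene: str = "Il6"
    reference_gene: str = "Actb"
    group_target_means: dict = field(default_factory=lambda: {
        "saline/acetone": 30.0, "saline/TPA": 26.0,
        "CBX/acetone": 30.0, "CBX/TPA": 24.0})
    reference_mean: float = 18.0
    sd: float = 0.4
    n_per_group: int = 10

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")


@dataclass
class SimConfig:
    """Full cohort simulation configuration (defaults = study conditions)."""
    n_individuals: int = 374
    sex_ratio: float = 0.5                 # fraction male
    map_spec: MapSpec = field(default_factory=MapSpec)
    qtl_effects: list = field(default_factory=list)
    genotype_error_rate: float = 0.0
    eqtl_effects: list = field(default_factory=list)
    module_spec: ModuleSpec | None = field(default_factory=ModuleSpec)
    tumor_model: TumorModel = field(default_factory=TumorModel)
    qpcr_spec: QPCRSpec = field(default_factory=QPCRSpec)
    n_genes: int = 2000
    pheno_noise_sd: float = 1.0
    expr_noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.genotype_error_rate < 0.5:
            raise ValueError("error rate must lie in [0, 0.5)")
        for e in self.qtl_effects:
            if not np.isfinite(e.effect):
                raise ValueError("QTL effects must be finite")


@dataclass
class GroundTruth:
    """Planted signals serialized alongside the data for recovery tests."""
    qtl: list = field(default_factory=list)
    eqtl: list = field(default_factory=list)
    module_genes: list = field(default_factory=list)
    tumor_model: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Map and genotypes
# ---------------------------------------------------------------------------

def haldane(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: cM distance -> recombination fraction."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, float) / 100.0))


def inverse_haldane(r: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction -> cM distance (Haldane)."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, float))


def simulate_map(map_spec: MapSpec | None = None) -> GeneticMap:
    """Lay markers on an arithmetic cM grid per chromosome.

    Markers sit at 0, s, 2s, ... up to the chromosome length; physical Mb
    positions increase linearly with cM (``mb_per_cm``).
    """
    spec = map_spec or MapSpec()
    if spec.marker_spacing <= 0:
        raise ValueError("marker spacing must be positive")
    rows = []
    lengths = spec.lengths()
    for ci, length in enumerate(lengths):
        if length <= 0:
            raise ValueError("chromosome lengths must be positive")
        chrom = X_CHROM if ci == spec.n_autosomes else str(ci + 1)
        n_mk = int(np.floor(length / spec.marker_spacing + 1e-9)) + 1
        for k in range(n_mk):
            cm = k * spec.marker_spacing
            rows.append({"marker": f"c{chrom}m{k + 1:02d}", "chrom": chrom,
                         "cm": cm, "mb": cm * spec.mb_per_cm})
    return GeneticMap(pd.DataFrame(rows))


def simulate_sexes(n: int, sex_ratio: float, rng: np.random.Generator
                   ) -> np.ndarray:
    n_male = int(round(n * sex_ratio))
    sex = np.array(["M"] * n_male + ["F"] * (n - n_male), dtype=object)
    rng.shuffle(sex)
    return sex


def simulate_genotypes(gmap: GeneticMap, n: int, sex: np.ndarray,
                       error_rate: float = 0.0, seed: int | None = 0,
                       missing_rate: float = 0.0,
                       rng: np.random.Generator | None = None
                       ) -> GenotypeMatrix:
    """Simulate backcross genotypes as per-chromosome Markov chains.

    Autosomes and the female X segregate HOM/HET with P=1/2 at each locus;
    the male X is the maternal recombinant haplotype coded AY/BY with the
    same chain.  Observed codes are corrupted (flipped) at ``error_rate``
    and masked at ``missing_rate``.
    """
    if len(gmap) == 0:
        raise ValueError("empty map")
    rng = rng if rng is not None else np.random.default_rng(seed)
    geno = np.empty((n, len(gmap)), dtype=np.int8)
    col = 0
    for chrom in gmap.chroms:
        sub = gmap.chrom_slice(chrom)
        m = len(sub)
        r = haldane(np.diff(sub["cm"].to_numpy()))
        start = rng.random(n) < 0.5
        if m > 1:
            switches = rng.random((n, m - 1)) < r[None, :]
            states = start[:, None] ^ (np.cumsum(switches, axis=1) % 2).astype(bool)
            chain = np.column_stack([start, states])
        else:
            chain = start[:, None]
        geno[:, col:col + m] = chain.astype(np.int8)
        col += m
    if error_rate > 0:
        flip = rng.random(geno.shape) < error_rate
        geno = np.where(flip, 1 - geno, geno).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random(geno.shape) < missing_rate
        geno[miss] = MISSING
    ids = np.array([f"BX{i + 1:04d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(ids, sex, geno, gmap)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

# Natural-scale anchors for the body phenotypes (per-sex means and SDs in
# the regime of the emulated cohort; length cm, weight g, BMI g/cm^2).
PHENO_SCALE = {
    "length": {"M": 9.83, "F": 9.41, "sd": 0.55},
    "bmi": {"M": 0.27, "F": 0.23, "sd": 0.03},
}


def simulate_phenotypes(gm: GenotypeMatrix, qtl_effects: Sequence[QTLEffect],
                        noise_sd: float = 1.0, seed: int | None = 0,
                        rng: np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Generate body phenotypes with planted additive (sex-optional) QTL.

    Each phenotype's standardized score is ``sum_j a_j * g_j + N(0, sd)``
    with ``g`` the 0/1 HOM/HET indicator at the nearest marker to the
    planted position; a sex-restricted effect is added only in that sex.
    Length and BMI are mapped to natural scale per sex, and weight is
    derived as ``BMI * length^2`` so that BMI = weight/length^2 holds by
    construction.  Custom phenotype names yield standardized columns.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = gm.n
    phenos = {"length", "bmi"} | {e.phenotype for e in qtl_effects}
    weight_effects = [e for e in qtl_effects if e.phenotype == "weight"]
    qtl_effects = [e for e in qtl_effects if e.phenotype != "weight"]
    phenos.discard("weight")   # derived from bmi and length
    z = {}
    for p in sorted(phenos):
        score = rng.normal(0.0, noise_sd, n)
        for e in qtl_effects:
            if e.phenotype != p:
                continue
            g = _genotype_near(gm, e.chrom, e.pos_cm).astype(float)
            g[g == MISSING] = 0.5
            contrib = e.effect * g
            if e.sex is not None:
                contrib = np.where(gm.sex == e.sex, contrib, 0.0)
            score = score + contrib
        z[p] = score
    df = pd.DataFrame({"id": gm.individuals, "sex": gm.sex})
    for p, score in z.items():
        if p in PHENO_SCALE:
            sc = PHENO_SCALE[p]
            mean = np.where(gm.sex == "M", sc["M"], sc["F"])
            df[p] = mean + sc["sd"] * score
        else:
            df[p] = score
    df["weight"] = df["bmi"] * df["length"] ** 2
    if weight_effects:
        # Plant weight QTL on the derived scale: one phenotype SD of the
        # effect equals the within-sex SD of the derived weight, so the
        # a^2/4 variance decomposition holds against total weight variance.
        w = df["weight"].to_numpy(float)
        sd_w = np.empty(n)
        for s in ("M", "F"):
            m = gm.sex == s
            sd_w[m] = w[m].std() if m.any() else 1.0
        for e in weight_effects:
            g = _genotype_near(gm, e.chrom, e.pos_cm).astype(float)
            g[g == MISSING] = 0.5
            contrib = e.effect * sd_w * g
            if e.sex is not None:
                contrib = np.where(gm.sex == e.sex, contrib, 0.0)
            w = w + contrib
        df["weight"] = w
        # keep the defining identity BMI = weight / length^2; weight loci
        # therefore also shift BMI, as they do in a real cohort
        df["bmi"] = df["weight"] / df["length"] ** 2
    return df


def _genotype_near(gm: GenotypeMatrix, chrom: str, pos_cm: float) -> np.ndarray:
    sub = gm.map.df[gm.map.df["chrom"] == str(chrom)]
    if len(sub) == 0:
        raise KeyError(f"no markers on chromosome {chrom}")
    j = (sub["cm"] - pos_cm).abs().idxmin()
    col = gm.map.df.index.get_loc(j)
    return gm.geno[:, col].copy()


def nearest_marker(gmap: GeneticMap, chrom: str, pos_cm: float) -> str:
    """Marker with minimal |cM| distance; ties go to the lower Mb."""
    sub = gmap.df[gmap.df["chrom"] == str(chrom)]
    if len(sub) == 0:
        raise KeyError(f"no markers on chromosome {chrom}")
    d = (sub["cm"] - pos_cm).abs()
    best = sub.loc[d == d.min()].sort_values("mb")
    return str(best["marker"].iloc[0])


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(gm: GenotypeMatrix,
                        eqtl_effects: Sequence[EQTLEffect] = (),
                        module_spec: ModuleSpec | None = None,
                        n_genes: int = 2000, noise_sd: float = 1.0,
                        baseline: float = 8.0, seed: int | None = 0,
                        coupling: Sequence[tuple] = (),
                        rng: np.random.Generator | None = None):
    """Simulate a log2 expression matrix (genes x individuals).

    Background genes are independent ``N(baseline, noise_sd)``.  Module
    genes share one standard-normal latent factor with the configured
    loading.  eQTL genes get an additive genotype shift at their planted
    marker.  ``coupling`` entries ``(gene, vector, coef)`` add
    ``coef * standardized(vector)`` to a gene, which plants direct
    gene-phenotype association beyond what genotype induces.

    Returns ``(expression DataFrame, gene_info DataFrame)``; gene_info has
    gene, chrom, mb (gene start).  cis-eQTL genes are placed at their
    marker's position; all other genes are placed uniformly on the map.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    module_genes: list[str] = []
    if module_spec is not None:
        module_genes = [module_spec.seed_gene] + [
            f"Mod{i:03d}" for i in range(1, module_spec.size)]
    eqtl_genes = [e.gene for e in eqtl_effects]
    named = list(dict.fromkeys(module_genes + eqtl_genes))
    n_bg = n_genes - len(named)
    if n_bg < 0:
        raise ValueError("n_genes smaller than module + eQTL gene count")
    genes = named + [f"G{i:04d}" for i in range(n_bg)]
    n = gm.n
    expr = rng.normal(0.0, noise_sd, (len(genes), n))
    gidx = {g: i for i, g in enumerate(genes)}
    if module_spec is not None and module_spec.size > 0:
        factor = rng.normal(0.0, 1.0, n)
        l = module_spec.loading
        for g in module_genes:
            i = gidx[g]
            expr[i] = (l * factor + np.sqrt(1 - l * l) * expr[i] / noise_sd) * noise_sd
    for e in eqtl_effects:
        gvec = gm.genotype_at(e.marker).astype(float)
        gvec[gvec == MISSING] = 0.5
        expr[gidx[e.gene]] += e.effect * noise_sd * gvec
    for gene, vec, coef in coupling:
        v = np.asarray(vec, float)
        v = (v - v.mean()) / (v.std() or 1.0)
        expr[gidx[gene]] += coef * noise_sd * v
    expr += baseline
    # gene positions
    mdf = gm.map.df
    marker_pos = mdf.set_index("marker")
    chroms = rng.choice(mdf["chrom"].unique(), len(genes))
    mbs = np.empty(len(genes))
    for i, c in enumerate(chroms):
        sub = mdf[mdf["chrom"] == c]
        mbs[i] = rng.uniform(sub["mb"].min(), sub["mb"].max())
    info = pd.DataFrame({"gene": genes, "chrom": chroms, "mb": mbs})
    for e in eqtl_effects:
        if e.kind == "cis":
            row = marker_pos.loc[e.marker]
            info.loc[info["gene"] == e.gene, ["chrom", "mb"]] = \
                [row["chrom"], row["mb"]]
    edf = pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                       columns=gm.individuals)
    return edf, info


# ---------------------------------------------------------------------------
# Tumors, variants, qPCR, GO
# ---------------------------------------------------------------------------

PAPILLOMA_WEEKS = (10, 12, 14, 16, 18, 20)


def standardize_by_sex(values: np.ndarray, sex: np.ndarray) -> np.ndarray:
    z = np.empty(len(values), float)
    for s in ("M", "F"):
        m = sex == s
        if m.any():
            sd = values[m].std()
            z[m] = (values[m] - values[m].mean()) / (sd if sd > 0 else 1.0)
    return z


def simulate_tumors(phenotypes: pd.DataFrame, tumor_model: TumorModel,
                    seed: int | None = 0,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate papilloma counts (weeks 10-20) and carcinoma-free survival.

    Counts share a per-mouse gamma frailty across timepoints and ramp up
    linearly to week 20; the log mean is linear in within-sex-standardized
    BMI with a sex-specific coefficient.  Carcinoma times are exponential
    with log hazard linear in the same score, censored at follow-up end.
    """
    tm = tumor_model
    rng = rng if rng is not None else np.random.default_rng(seed)
    if "bmi" not in phenotypes.columns:
        raise ValueError("phenotype table lacks BMI")
    sex = phenotypes["sex"].to_numpy()
    zbmi = standardize_by_sex(phenotypes["bmi"].to_numpy(float), sex)
    coef = np.where(sex == "M", tm.bmi_coef_male, tm.bmi_coef_female)
    mu20 = np.exp(tm.count_intercept + coef * zbmi)
    n = len(phenotypes)
    if tm.dispersion > 0:
        shape = 1.0 / tm.dispersion
        frailty = rng.gamma(shape, 1.0 / shape, n)
    else:
        frailty = np.ones(n)
    out = {"id": phenotypes["id"].to_numpy(), "sex": sex}
    for w in PAPILLOMA_WEEKS:
        lam = mu20 * (w / PAPILLOMA_WEEKS[-1]) * frailty
        out[f"pap{w}"] = rng.poisson(lam)
    loghr = np.where(sex == "M", tm.log_hr_bmi_male, tm.log_hr_bmi_female)
    rate = tm.baseline_hazard * np.exp(loghr * zbmi)
    t = rng.exponential(1.0 / rate)
    event = t <= tm.followup_days
    out["carcinoma_time"] = np.where(event, t, tm.followup_days)
    out["carcinoma_event"] = event.astype(int)
    return pd.DataFrame(out)


CONSEQUENCE_CLASSES = ("nonsynonymous", "nonsense", "frameshift_del",
                       "frameshift_ins", "splice", "synonymous", "noncoding")


def simulate_variants(gene_info: pd.DataFrame,
                      planted: Sequence[tuple] = (),
                      background_rate: float = 0.3,
                      background_classes: Sequence[str] = ("synonymous",
                                                           "noncoding",
                                                           "nonsynonymous"),
                      seed: int | None = 0,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emit a strain-difference variant table (gene, chrom, mb, consequence).

    ``planted`` entries are ``(gene, consequence, count)`` placed at the
    gene's position.  Background genes independently receive one variant
    with probability ``background_rate``, drawn uniformly from
    ``background_classes``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    pos = gene_info.set_index("gene")
    rows = []
    for gene, cls, count in planted:
        if cls not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {cls!r}")
        row = pos.loc[gene]
        for _ in range(count):
            rows.append({"gene": gene, "chrom": row["chrom"],
                         "mb": float(row["mb"]), "consequence": cls})
    planted_genes = {g for g, _, _ in planted}
    for gene, row in pos.iterrows():
        if gene in planted_genes:
            continue
        if rng.random() < background_rate:
            rows.append({"gene": gene, "chrom": row["chrom"],
                         "mb": float(row["mb"]),
                         "consequence": str(rng.choice(background_classes))})
    return pd.DataFrame(rows, columns=["gene", "chrom", "mb", "consequence"])


def simulate_qpcr(spec: QPCRSpec | None = None, seed: int | None = 0,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Gaussian Ct values per group for target and reference genes.

    The reference gene has the same mean in every group, so the
    delta-delta-Ct analysis should attribute all group structure to the
    target.
    """
    spec = spec or QPCRSpec()
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows = []
    for group, tmean in spec.group_target_means.items():
        for k in range(spec.n_per_group):
            sample = f"{group}#{k + 1}"
            rows.append({"sample": sample, "group": group,
                         "gene": spec.target_gene,
                         "ct": rng.normal(tmean, spec.sd)})
            rows.append({"sample": sample, "group": group,
                         "gene": spec.reference_gene,
                         "ct": rng.normal(spec.reference_mean, spec.sd)})
    return pd.DataFrame(rows)


def simulate_go_annotations(gene_info: pd.DataFrame,
                            enriched_genes: Sequence[str],
                            enriched_term: tuple[str, str] = (
                                "GO:0006629", "lipid metabolic process"),
                            n_background_terms: int = 10,
                            term_size: int = 40,
                            seed: int | None = 0,
                            rng: np.random.Generator | None = None
                            ) -> pd.DataFrame:
    """GO annotation table with one term enriched for the given gene set."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    genes = gene_info["gene"].to_numpy()
    term_size = min(term_size, len(genes))
    rows = [{"term_id": enriched_term[0], "term_name": enriched_term[1],
             "gene": g} for g in enriched_genes]
    extra = rng.choice(genes, min(max(term_size - len(enriched_genes), 0),
                                  len(genes)), replace=False)
    rows += [{"term_id": enriched_term[0], "term_name": enriched_term[1],
              "gene": g} for g in extra]
    for t in range(n_background_terms):
        members = rng.choice(genes, term_size, replace=False)
        rows += [{"term_id": f"GO:{7000000 + t}", "term_name": f"term_{t}",
                  "gene": g} for g in members]
    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)


# ---------------------------------------------------------------------------
# Full-cohort convenience wrapper
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Bundle of all simulated tables plus the planted ground truth."""
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    expression: pd.DataFrame
    gene_info: pd.DataFrame
    variants: pd.DataFrame
    go: pd.DataFrame
    qpcr: pd.DataFrame
    truth: GroundTruth


def simulate_cohort(config: SimConfig | None = None,
                    driver_coupling: float = 0.0) -> Cohort:
    """Simulate a full cohort from one config and one seed.

    ``driver_coupling`` adds a direct BMI association (in expression SD per
    phenotype SD) to each cis-eQTL gene of the 'bmi' phenotype's QTL,
    planting a driver gene detectable beyond its genotype effect.
    Per-stage generators draw from children of one ``SeedSequence`` so each
    stage is independently reproducible.
    """
    cfg = config or SimConfig()
    ss = np.random.SeedSequence(cfg.rng_seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(7)]
    gmap = simulate_map(cfg.map_spec)
    sex = simulate_sexes(cfg.n_individuals, cfg.sex_ratio, rngs[0])
    gm = simulate_genotypes(gmap, cfg.n_individuals, sex,
                            cfg.genotype_error_rate, rng=rngs[1])
    pheno = simulate_phenotypes(gm, cfg.qtl_effects, cfg.pheno_noise_sd,
                                rng=rngs[2])
    coupling = []
    if driver_coupling:
        zb = standardize_by_sex(pheno["bmi"].to_numpy(float), sex)
        for e in cfg.eqtl_effects:
            coupling.append((e.gene, zb, driver_coupling))
    expr, gene_info = simulate_expression(
        gm, cfg.eqtl_effects, cfg.module_spec, cfg.n_genes,
        cfg.expr_noise_sd, rng=rngs[3], coupling=coupling)
    tumors = simulate_tumors(pheno, cfg.tumor_model, rng=rngs[4])
    pheno = pheno.merge(tumors.drop(columns="sex"), on="id")
    planted_vars = [(e.gene, "nonsynonymous", 3) for e in cfg.eqtl_effects]
    variants = simulate_variants(gene_info, planted_vars, rng=rngs[5])
    module_genes = ([] if cfg.module_spec is None else
                    list(expr.index[:cfg.module_spec.size]))
    go = simulate_go_annotations(gene_info, module_genes, rng=rngs[6])
    qpcr = simulate_qpcr(cfg.qpcr_spec, rng=rngs[6])
    truth = GroundTruth(
        qtl=[dataclasses.asdict(e) for e in cfg.qtl_effects],
        eqtl=[dataclasses.asdict(e) for e in cfg.eqtl_effects],
        module_genes=module_genes,
        tumor_model=dataclasses.asdict(cfg.tumor_model),
    )
    return Cohort(gm, pheno, expr, gene_info, variants, go, qpcr, truth)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Serialize a cohort as plain-text tables plus ground-truth JSON."""
    from pathlib import Path
    from .genotypes import write_cross_csv
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_cross_csv(out / "cross.csv", cohort.genotypes, cohort.phenotypes)
    cohort.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    cohort.expression.to_csv(out / "expression.tsv", sep="\t")
    cohort.gene_info.to_csv(out / "genes.tsv", sep="\t", index=False)
    cohort.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    cohort.go.to_csv(out / "go.tsv", sep="\t", index=False)
    cohort.qpcr.to_csv(out / "qpcr.tsv", sep="\t", index=False)
    cohort.truth.to_json(out / "truth.json")
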