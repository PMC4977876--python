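"""Spearman co-expression neighborhoods with permutation GWER thresholds.

A seed gene's neighborhood is the set of genes whose tie-corrected Spearman
correlation with the seed exceeds the 5% genome-wide error rate (GWER)
threshold (first-degree neighbors), plus all above-threshold correlations
of those first-degree members; nodes those extra edges introduce are
second-degree members and are not themselves expanded.  The GWER threshold
is the (1-alpha) quantile of the maximum |rho| obtained when one probe
vector is randomly re-labeled against the whole matrix.  Enrichment of the
neighborhood in a gene-ontology term is the one-sided hypergeometric tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


def spearman_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Spearman rho (average ranks for ties).

    Constant genes have undefined correlation, recorded as NaN off the
    diagonal; the diagonal is 1 by convention.
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = expression.to_numpy(float)
    ranks = stats.rankdata(X, axis=1)
    sd = ranks.std(axis=1)
    Z = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((Z ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Z @ Z.T) / np.outer(denom, denom)
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    return pd.DataFrame(R, index=expression.index, columns=expression.index)


def gwer_threshold(expression: pd.DataFrame, n_perm: int = 1000,
                   alpha: float = 0.05, seed: int = 0) -> float:
    """Permutation genome-wide error-rate threshold on |rho|.

    Each permutation shuffles the sample labels of one randomly chosen
    probe vector and records the maximum |rho| it attains against every
    other gene; the threshold is the (1-alpha) quantile of those maxima.
    Computed per stratum by passing the stratum's expression columns.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    X = expression.to_numpy(float)
    n_genes, n = X.shape
    if n < 3:
        raise ValueError("too few samples")
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(X, axis=1)
    Z = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((Z ** 2).sum(axis=1))
    norm[norm == 0] = np.nan
    Zn = Z / norm[:, None]
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        g = int(rng.integers(n_genes))
        v = Zn[g][rng.permutation(n)]
        rho = Zn @ v
        rho[g] = 0.0 if n_genes > 1 else rho[g]
        if n_genes > 1:
            maxima[b] = np.nanmax(np.abs(rho))
        else:
            maxima[b] = abs(float(Zn[g] @ v))
    return float(np.quantile(maxima, 1.0 - alpha))


@dataclass
class Neighborhood:
    seed: str
    first_degree: set = field(default_factory=set)
    second_degree: set = field(default_factory=set)
    edges: list = field(default_factory=list)   # (a, b, rho), a < b
    threshold: float = np.nan

    @property
    def nodes(self) -> set:
        return {self.seed} | self.first_degree | self.second_degree

    def degree_class(self, gene: str) -> str:
        if gene == self.seed:
            return "seed"
        if gene in self.first_degree:
            return "first"
        return "second"


def build_neighborhood(corr: pd.DataFrame, seed_gene: str,
                       threshold: float) -> Neighborhood:
    """Seed-centered neighborhood at an absolute-rho threshold.

    First-degree members have |rho(seed, g)| >= threshold.  Every pair with
    at least one endpoint in {seed} union first-degree and |rho| >= the
    threshold is a retained edge; new nodes those edges bring in are
    second-degree and are not expanded further.
    """
    if seed_gene not in corr.index:
        raise KeyError(f"seed gene {seed_gene!r} not in matrix")
    genes = corr.index.to_numpy()
    R = corr.to_numpy(float)
    si = int(np.flatnonzero(genes == seed_gene)[0])
    with np.errstate(invalid="ignore"):
        seed_row = np.abs(R[si])
    first_idx = {int(i) for i in np.flatnonzero(seed_row >= threshold)
                 if i != si}
    core = first_idx | {si}
    edges = set()
    for i in sorted(core):
        row = np.abs(R[i])
        for j in np.flatnonzero(row >= threshold):
            j = int(j)
            if j == i or not np.isfinite(R[i, j]):
                continue
            a, b = sorted((i, j))
            edges.add((a, b))
    first = {str(genes[i]) for i in first_idx}
    edge_list = sorted((*sorted((str(genes[a]), str(genes[b]))),
                        float(R[a, b])) for a, b in edges)
    nodes = {g for a, b, _ in edge_list for g in (a, b)}
    second = nodes - first - {seed_gene}
    return Neighborhood(seed_gene, first, second, edge_list, threshold)


def go_enrichment(neighborhood_genes, annotation: pd.DataFrame,
                  universe=None) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each term in the gene set.

    ``annotation``: columns term_id, term_name, gene.  The universe
    defaults to all annotated genes; the neighborhood must be contained in
    it.  p = P(X >= k) with k term genes among the n neighborhood genes
    drawn from N universe genes containing K term genes.  Terms are
    ordered by p.
    """
    nb = set(neighborhood_genes)
    if universe is None:
        universe = set(annotation["gene"])
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    nb &= universe
    N, n = len(universe), len(nb)
    rows = []
    for (tid, tname), sub in annotation.groupby(["term_id", "term_name"],
                                                sort=True):
        term_genes = set(sub["gene"]) & universe
        K = len(term_genes)
        k = len(term_genes & nb)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": tid, "term_name": tname, "k": k, "K": K,
                     "n": n, "N": N, "p": min(p, 1.0)})
    return (pd.DataFrame(rows)
            .sort_values(["p", "term_id"], kind="stable")
            .reset_index(drop=True))


def export_network(nbhd: Neighborhood, outdir, go_flags: dict | None = None):
    """Write node and edge tables importable by standard network viewers.

    ``nodes.tsv``: gene, degree_class, go_flag; ``edges.tsv``: a, b, rho.
    Ordering is deterministic (sorted by name).  Returns the two paths.
    """
    if not nbhd.nodes:
        raise ValueError("empty neighborhood")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    flags = go_flags or {}
    nodes = pd.DataFrame(
        [{"gene": g, "degree_class": nbhd.degree_class(g),
          "go_flag": int(bool(flags.get(g, False)))}
         for g in sorted(nbhd.nodes)])
    edges = pd.DataFrame(nbhd.edges, columns=["a", "b", "rho"])
    npath, epath = out / "nodes.tsv", out / "edges.tsv"
    nodes.to_csv(npath, sep="\t", index=False)
    edges.to_csv(epath, sep="\t", index=False, float_format="%.10g")
    return npath, epath


def read_network(outdir) -> Neighborhood:
    """Round-trip reader for :func:`export_network` output."""
    out = Path(outdir)
    nodes = pd.read_csv(out / "nodes.tsv", sep="\t")
    edges = pd.read_csv(out / "edges.tsv", sep="\t")
    seed = str(nodes.loc[nodes["degree_class"] == "seed", "gene"].iloc[0])
    first = set(nodes.loc[nodes["degree_class"] == "first", "gene"].astype(str))
    second = set(nodes.loc[nodes["degree_class"] == "second", "gene"].astype(str))
    edge_list = sorted((str(a), str(b), float(r))
                       for a, b, r in edges.itertuples(index=False))
    return Neighborhood(seed, first, second, edge_list)
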