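"""Targeted RNA panel expression: normalization, clustering, differential tests.

Two normalization schemes coexist, as they do in the assay's workflow:

* TMM (trimmed mean of M-values) library normalization with TMM-adjusted
  log2 CPM and per-gene Z-scores — feeds hierarchical clustering (Manhattan
  distance, complete linkage);
* RPKM with division by the geometric mean of three stable reference genes
  (VCP, SF3B1, ATP5F1B) — feeds the cluster-comparison expression table.

Differential expression between two sample groups uses a per-gene negative
binomial GLM with a log effective-library-size offset, moderated dispersion,
a Wald test on the group coefficient, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REFERENCE_GENES = ("VCP", "SF3B1", "ATP5F1B")


class ExpressionError(Exception):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x samples raw counts with gene lengths and library sizes.

    ``library_sizes`` defaults to per-sample column sums (total mapped reads
    on the panel).
    """

    counts: pd.DataFrame  # genes x samples, non-negative integers
    gene_lengths: pd.Series  # bp, indexed by gene
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ExpressionError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = list(self.gene_lengths[self.gene_lengths.isna()].index[:5])
            raise ExpressionError(f"gene lengths missing for {missing} ...")
        if (self.gene_lengths <= 0).any():
            raise ExpressionError("gene lengths must be positive")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns).astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene_length", self.gene_lengths)
        out.index.name = "gene"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        if "gene_length" not in df.columns:
            raise ExpressionError(f"{path}: missing gene_length column")
        lengths = df.pop("gene_length")
        return cls(counts=df, gene_lengths=lengths)


# ---------------------------------------------------------------------------
# RPKM and reference-gene normalization
# ---------------------------------------------------------------------------

def rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    value = count * 1e9 / (library_size * length_bp).
    """
    totals = matrix.library_sizes
    zero = totals[totals <= 0]
    if len(zero):
        raise ExpressionError(f"zero total mapped reads for sample(s) {list(zero.index)}")
    return (
        matrix.counts * 1e9
    ).div(matrix.gene_lengths, axis=0).div(totals, axis=1)


def reference_normalize(
    rpkm_matrix: pd.DataFrame, ref_genes: tuple[str, ...] = REFERENCE_GENES
) -> pd.DataFrame:
    """Divide each sample by the geometric mean of its reference-gene RPKMs.

    Samples where any reference gene has zero (or missing) RPKM are flagged
    and excluded from the output.
    """
    missing = [g for g in ref_genes if g not in rpkm_matrix.index]
    if missing:
        raise ExpressionError(f"reference gene(s) absent from matrix: {missing}")
    refs = rpkm_matrix.loc[list(ref_genes)]
    bad = refs.columns[(refs <= 0).any(axis=0)]
    if len(bad):
        logger.warning(
            "excluding %d sample(s) with zero reference-gene RPKM: %s",
            len(bad),
            list(bad[:5]),
        )
    keep = [c for c in rpkm_matrix.columns if c not in set(bad)]
    divisors = np.exp(np.log(refs[keep]).mean(axis=0))
    return rpkm_matrix[keep].div(divisors, axis=1)


# ---------------------------------------------------------------------------
# TMM / log CPM / Z
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the cohort mean upper quartile.  For each sample, genes with a
    zero count in either the sample or the reference are dropped, the log2
    ratios (M) are trimmed by 30% on each side and the log2 abundances (A) by
    5% on each side, and the factor is 2 to the precision-weighted mean of the
    retained M values.  Factors are rescaled to have geometric mean 1.
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        raise ExpressionError("every sample needs a positive library size")
    with np.errstate(invalid="ignore"):
        uq = np.array(
            [np.quantile(X[:, j][X[:, j] > 0] / lib[j], 0.75) if (X[:, j] > 0).any() else 0.0
             for j in range(X.shape[1])]
        )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = X[:, ref_idx]
    ref_lib = lib[ref_idx]

    factors = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref_idx:
            factors[j] = 1.0
            continue
        obs = X[:, j]
        keep = (obs > 0) & (ref > 0)
        if keep.sum() == 0:
            factors[j] = 1.0
            continue
        o = obs[keep] / lib[j]
        r = ref[keep] / ref_lib
        M = np.log2(o / r)
        A = 0.5 * np.log2(o * r)
        # asymptotic inverse variance of M (delta method on binomial counts)
        w = (lib[j] - obs[keep]) / (lib[j] * obs[keep]) + (ref_lib - ref[keep]) / (
            ref_lib * ref[keep]
        )
        n = len(M)
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * sum_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(M).rank().to_numpy()
        rank_a = pd.Series(A).rank().to_numpy()
        keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep2.sum() == 0 or not np.isfinite(M[keep2]).any():
            factors[j] = 1.0
            continue
        mean_m = np.nansum(M[keep2] / w[keep2]) / np.nansum(1.0 / w[keep2])
        factors[j] = 2.0 ** mean_m if np.isfinite(mean_m) else 1.0

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm_log_cpm(counts: pd.DataFrame, prior_count: float = 1.0) -> pd.DataFrame:
    """TMM-adjusted log2 CPM with a prior count."""
    factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=0).astype(float) * factors
    return np.log2((counts + prior_count).div(eff_lib, axis=1) * 1e6)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0, sd 1 (population sd).

    Zero-variance rows become all-zero with a warning.
    """
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0)
    flat = sd[sd == 0].index
    if len(flat):
        logger.warning("%d constant gene row(s) set to Z = 0", len(flat))
    sd = sd.replace(0.0, 1.0)
    z = matrix.sub(mu, axis=0).div(sd, axis=0)
    z.loc[flat] = 0.0
    return z


def tmm_log_cpm_z(matrix: ExpressionMatrix | pd.DataFrame, prior_count: float = 1.0) -> pd.DataFrame:
    """Full clustering-input normalization: TMM -> log2 CPM -> per-gene Z."""
    counts = matrix.counts if isinstance(matrix, ExpressionMatrix) else matrix
    if counts.shape[1] < 2:
        raise ExpressionError("need at least two samples")
    return zscore_rows(tmm_log_cpm(counts, prior_count))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series  # sample -> cluster id (1..k)
    sizes: dict[int, int] = field(default_factory=dict)

    @property
    def minority_size(self) -> int:
        return min(self.sizes.values())

    @property
    def minority_samples(self) -> list[str]:
        minority = min(self.sizes, key=lambda c: (self.sizes[c], c))
        return list(self.labels[self.labels == minority].index)


def cluster_samples(standardized: pd.DataFrame, k: int = 2) -> ClusterResult:
    """Agglomerative clustering of samples (columns).

    Manhattan (L1) distance between sample profiles, complete linkage, labels
    from cutting the tree into ``k`` groups.  Deterministic and invariant to
    sample and gene order.
    """
    n = standardized.shape[1]
    if n < k:
        raise ExpressionError(f"cannot cut {n} samples into {k} clusters")
    if standardized.isna().any().any():
        raise ExpressionError("standardized matrix contains missing values")
    # canonical ordering makes the result order-invariant
    mat = standardized.sort_index(axis=0).sort_index(axis=1)
    dist = ssd.pdist(mat.T.to_numpy(), metric="cityblock")
    Z = sch.linkage(dist, method="complete")
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=mat.columns, name="cluster").reindex(standardized.columns)
    # relabel so cluster 1 is the largest, 2 the next, ...
    order = labels.value_counts().index.tolist()
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = labels.map(remap)
    sizes = labels.value_counts().to_dict()
    return ClusterResult(linkage=Z, labels=labels, sizes={int(c): int(s) for c, s in sizes.items()})


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    table: pd.DataFrame  # per gene: mean1, mean2, fold_change, stat, pvalue, padj
    excluded_genes: list[str] = field(default_factory=list)

    def significant(self, min_fold_change: float = 2.0, alpha: float = 0.05) -> pd.DataFrame:
        """Genes with |fold change| >= threshold (either direction) and padj < alpha."""
        t = self.table
        fc = t["fold_change"]
        return t[
            ((fc >= min_fold_change) | (fc <= 1.0 / min_fold_change)) & (t["padj"] < alpha)
        ]


def _moment_dispersion(counts: np.ndarray, norm: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled within groups on normalized counts."""
    disp_num, disp_den = 0.0, 0.0
    for g in np.unique(groups):
        y = counts[groups == g] / norm[groups == g]
        if len(y) < 2:
            continue
        mu = y.mean()
        if mu <= 0:
            continue
        var = y.var(ddof=1)
        disp_num += (var - mu) / mu**2 * (len(y) - 1)
        disp_den += len(y) - 1
    if disp_den == 0:
        return 0.0
    return max(disp_num / disp_den, 0.0)


def nb_two_group_test(
    matrix: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    prior_dispersion_weight: float = 10.0,
) -> DifferentialResult:
    """Two-group negative binomial GLM differential expression.

    Per gene: NB regression of counts on a group indicator with a log
    effective-library-size offset (TMM-adjusted).  The per-gene moment
    dispersion is moderated toward the cohort mean dispersion with prior
    weight ``prior_dispersion_weight`` observations.  Wald p-values on the
    group coefficient, BH-adjusted.  Fold change is group2 / group1 on the
    model scale.  All-zero genes are excluded with a note.
    """
    counts = matrix.counts if isinstance(matrix, ExpressionMatrix) else matrix
    labels = labels.reindex(counts.columns)
    if labels.isna().any():
        raise ExpressionError("labels missing for some samples")
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ExpressionError(f"need exactly two groups, got {levels}")
    group = (labels == levels[1]).to_numpy().astype(float)
    if group.sum() == 0 or group.sum() == len(group):
        raise ExpressionError("both groups must be non-empty")

    factors = tmm_factors(counts)
    eff_lib = (counts.sum(axis=0) * factors).to_numpy(dtype=float)
    offset = np.log(eff_lib)
    norm = eff_lib / eff_lib.mean()

    X = sm.add_constant(group)
    raw_disp = {}
    excluded = []
    for gene in counts.index:
        y = counts.loc[gene].to_numpy(dtype=float)
        if y.sum() == 0:
            excluded.append(gene)
            continue
        raw_disp[gene] = _moment_dispersion(y, norm, group)
    if not raw_disp:
        return DifferentialResult(pd.DataFrame(), excluded)
    trend = float(np.mean(list(raw_disp.values())))

    rows = []
    for gene, disp in raw_disp.items():
        y = counts.loc[gene].to_numpy(dtype=float)
        n = len(y)
        alpha = (n * disp + prior_dispersion_weight * trend) / (n + prior_dispersion_weight)
        alpha = float(np.clip(alpha, 1e-8, 10.0))
        mean1 = (y[group == 0] / norm[group == 0]).mean()
        mean2 = (y[group == 1] / norm[group == 1]).mean()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
                ).fit()
            beta = fit.params[1]
            stat = fit.tvalues[1]
            p = fit.pvalues[1]
            fc = float(np.exp(beta))
        except Exception:
            stat, p, fc = np.nan, np.nan, np.nan
        rows.append(
            {
                "gene": gene,
                "mean_group1": mean1,
                "mean_group2": mean2,
                "fold_change": fc,
                "log2_fold_change": np.log2(fc) if fc and np.isfinite(fc) and fc > 0 else np.nan,
                "stat": stat,
                "pvalue": p,
                "dispersion": alpha,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    ok = table["pvalue"].notna()
    padj = pd.Series(np.nan, index=table.index)
    if ok.any():
        padj[ok] = multipletests(table.loc[ok, "pvalue"], method="fdr_bh")[1]
    table["padj"] = np.maximum(padj, table["pvalue"])
    return DifferentialResult(table=table, excluded_genes=excluded)


def plot_heatmap(standardized: pd.DataFrame, labels: pd.Series, path) -> None:
    """Basic clustered heat map image for visual inspection only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = labels.sort_values().index
    fig, ax = plt.subplots(figsize=(10, 8))
    im = ax.imshow(standardized[order].to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_xlabel("samples (grouped by cluster)")
    ax.set_ylabel("genes")
    fig.colorbar(im, ax=ax, label="Z score")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
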