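"""CPM normalization and screen-level quality control.

All QC statistics operate on CPM (counts per million): each sample's counts
scaled to a library size of one million.  Correlation, replicate fits,
clustering and PCA default to log2(CPM + 1), the usual variance-stabilizing
choice for count data spanning several decades; pass ``log_transform=False``
for linear-scale analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .demux import CountMatrix
from .panel import ProbePanel


def cpm(counts: pd.DataFrame | CountMatrix) -> pd.DataFrame:
    """Scale each sample (column) to one million total counts.

    Columns with zero total are returned as all-zero with a warning rather
    than dividing by zero.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = df.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"all-zero columns left at zero: {list(df.columns[zero])}",
                      stacklevel=2)
        totals = totals.replace(0, np.nan)
    out = df.div(totals, axis=1) * 1e6
    return out.fillna(0.0)


def _maybe_log(df: pd.DataFrame, log_transform: bool) -> pd.DataFrame:
    return np.log2(df + 1) if log_transform else df


def pearson_matrix(cpm_df: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Pairwise sample-sample Pearson correlation (symmetric, unit diagonal).

    Zero-variance samples get NaN rows/columns, reported with a warning.
    """
    if cpm_df.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = _maybe_log(cpm_df, log_transform)
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"zero-variance samples: {list(x.columns[sd == 0])}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x.to_numpy(), rowvar=False)
    out = pd.DataFrame(corr, index=x.columns, columns=x.columns)
    np.fill_diagonal(out.values, 1.0)
    out.values[np.ix_(sd == 0, sd == 0)] = np.nan
    out.values[sd == 0, :] = np.where(np.eye(len(sd))[sd == 0], 1.0, np.nan)
    out.values[:, sd == 0] = out.values[sd == 0, :].T
    return out


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r_squared: float


def replicate_fit(cpm_df: pd.DataFrame, sample_a: str, sample_b: str,
                  log_transform: bool = True) -> FitResult:
    """Ordinary least squares of replicate b on replicate a over panel genes."""
    if cpm_df.shape[0] < 3:
        raise ValueError("need at least three genes for a replicate fit")
    x = _maybe_log(cpm_df[[sample_a, sample_b]], log_transform)
    res = stats.linregress(x[sample_a], x[sample_b])
    return FitResult(float(res.slope), float(res.intercept), float(res.rvalue ** 2))


def redundant_probe_concordance(probe_cpm: pd.DataFrame, panel: ProbePanel,
                                log_transform: bool = True) -> pd.Series:
    """Per gene with exactly two probes: R^2 between the probes across samples.

    Genes with any other probe count are skipped with a notice.  Note the
    per-gene statistic is informative only for genes that actually vary
    across samples; for a flat (housekeeping) gene both probes see nothing
    but sampling noise and the per-gene R^2 is near zero by construction —
    use :func:`redundant_probe_pooled_r2` for the panel-wide summary.
    """
    out = {}
    skipped = []
    for gene, probes in panel.gene_to_probes.items():
        if len(probes) != 2:
            skipped.append(gene)
            continue
        x = _maybe_log(probe_cpm.loc[list(probes)].T, log_transform)
        res = stats.linregress(x.iloc[:, 0], x.iloc[:, 1])
        out[gene] = float(res.rvalue ** 2)
    if skipped:
        warnings.warn(f"genes without exactly two probes skipped: {len(skipped)}",
                      stacklevel=2)
    return pd.Series(out, name="r_squared")


def redundant_probe_pooled_r2(probe_cpm: pd.DataFrame, panel: ProbePanel,
                              log_transform: bool = True) -> float:
    """One probe-1 vs probe-2 R^2 pooled over all two-probe genes and samples.

    This is the panel-wide concordance summary: points from low- and
    high-abundance genes enter one fit, so the statistic reflects whether a
    second, independent probe pair reports the same abundance over the
    panel's full dynamic range.
    """
    xs, ys = [], []
    for gene, probes in panel.gene_to_probes.items():
        if len(probes) != 2:
            continue
        x = _maybe_log(probe_cpm.loc[list(probes)].T, log_transform)
        xs.append(x.iloc[:, 0].to_numpy())
        ys.append(x.iloc[:, 1].to_numpy())
    if not xs:
        raise ValueError("panel has no two-probe genes")
    res = stats.linregress(np.concatenate(xs), np.concatenate(ys))
    return float(res.rvalue ** 2)


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    labels: pd.Series        # flat cluster labels per sample
    leaf_order: list[str]    # dendrogram left-to-right sample order


def cluster_samples(cpm_df: pd.DataFrame, method: str = "average",
                    metric: str = "pearson", log_transform: bool = True,
                    n_clusters: int = 2) -> ClusterResult:
    """Agglomerative clustering of samples on 1 - Pearson distance (default)."""
    if cpm_df.shape[1] < 2:
        single = pd.Series([1], index=cpm_df.columns, name="cluster")
        return ClusterResult(np.empty((0, 4)), single, list(cpm_df.columns))
    if metric == "pearson":
        dist = 1 - pearson_matrix(cpm_df, log_transform).to_numpy()
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
    else:
        from scipy.spatial.distance import pdist
        condensed = pdist(_maybe_log(cpm_df, log_transform).to_numpy().T, metric=metric)
    Z = linkage(condensed, method=method)
    labels = pd.Series(fcluster(Z, t=n_clusters, criterion="maxclust"),
                       index=cpm_df.columns, name="cluster")
    order = [cpm_df.columns[i] for i in leaves_list(Z)]
    return ClusterResult(Z, labels, order)


@dataclass
class PCAResult:
    scores: pd.DataFrame               # samples x components
    loadings: pd.DataFrame             # genes x components
    explained_variance_ratio: np.ndarray


def pca(cpm_df: pd.DataFrame, log_transform: bool = True, n_components: int = 2,
        scale: bool = False) -> PCAResult:
    """Centered PCA of samples; loadings expose the major contributing genes.

    Sign convention: the largest-|loading| gene on each component is positive,
    so repeated runs are bit-identical.
    """
    n_samples, n_genes = cpm_df.shape[1], cpm_df.shape[0]
    if n_components > min(n_samples, n_genes):
        raise ValueError("n_components exceeds data dimensionality")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    x = _maybe_log(cpm_df, log_transform).to_numpy().T  # samples x genes
    if scale:
        sd = x.std(axis=0, ddof=0)
        x = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T  # genes x comps
    for c in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[i, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=cpm_df.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=cpm_df.index, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )
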