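"""Gene filtering: highly-variable genes and the gene dynamics score (GDS).

HVG ranking uses the classic dispersion statistic (variance of
log-expression over mean) standardized within mean-quantile bins, so genes
are compared against peers of similar abundance.

The GDS measures how much a gene moves along pseudo-time: each gene is
min-max normalized, the pseudo-time-ordered cells are split into
equal-count contiguous bins (5 by default), and the score is the maximum
pairwise absolute difference between bin means.  A constant gene scores 0;
a clean off-to-on step scores 1.

An externally supplied transcription-factor candidate list (e.g. from
regulon analysis) can restrict the genes scored — regulon inference itself
is an external stage consumed as a plain gene list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionDataset

__all__ = ["GdsTable", "select_hvg", "gds", "build_candidate_gene_list"]


@dataclass
class GdsTable:
    """Per-gene pseudo-time bin means and dynamics scores."""

    genes: list[str]
    n_bins: int
    bin_means: pd.DataFrame      # genes x bins (MB)
    scores: pd.Series            # GDS per gene

    def mmd(self, gene: str) -> np.ndarray:
        """Matrix of mean distances for one gene: |MB_i - MB_j|."""
        mb = self.bin_means.loc[gene].to_numpy()
        return np.abs(mb[:, None] - mb[None, :])

    def ranking(self) -> list[str]:
        """Genes by descending GDS, ties broken on gene name."""
        order = sorted(self.genes, key=lambda g: (-self.scores[g], g))
        return order


def select_hvg(data: ExpressionDataset, n: int = 2000) -> list[str]:
    """Top-n genes by mean-binned normalized dispersion.

    Dispersion is variance/mean of the (log) expression; it is z-scored
    within quantile bins of the gene means (up to 20 bins) before ranking.
    Deterministic: ties break on gene name.
    """
    if n > data.n_genes:
        raise ValueError(f"n={n} exceeds n_genes={data.n_genes}")
    X = data.values
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    df = pd.DataFrame({"mean": mean, "disp": disp}, index=data.gene_ids)
    n_bins = min(20, max(1, data.n_genes // 2))
    if n_bins > 1:
        bins = pd.qcut(df["mean"].rank(method="first"), n_bins, labels=False)
    else:
        bins = pd.Series(0, index=df.index)
    grp = df.groupby(bins)["disp"]
    mu, sd = grp.transform("mean"), grp.transform("std").fillna(0.0)
    df["score"] = np.where(sd > 0, (df["disp"] - mu) / sd, df["disp"] - mu)
    order = df.sort_values(["score"], ascending=False, kind="stable")
    order = order.loc[sorted(order.index, key=lambda g: (-order.at[g, "score"], g))]
    return list(order.index[:n])


def gds(data: ExpressionDataset, genes: list[str] | None = None,
        n_bins: int = 5) -> GdsTable:
    """Gene dynamics score over equal-count pseudo-time bins."""
    if n_bins > data.n_cells:
        raise ValueError(f"n_bins={n_bins} exceeds n_cells={data.n_cells}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    genes = list(data.gene_ids) if genes is None else list(genes)
    sub = data.subset_genes(genes)
    X = sub.values
    rng_span = X.max(axis=0) - X.min(axis=0)
    safe = np.where(rng_span > 0, rng_span, 1.0)
    norm = (X - X.min(axis=0)) / safe            # min-max per gene
    norm[:, rng_span == 0] = 0.0                 # constant genes score 0
    chunks = np.array_split(np.arange(sub.n_cells), n_bins)
    mb = np.vstack([norm[idx].mean(axis=0) for idx in chunks]).T  # genes x bins
    scores = np.array([np.abs(row[:, None] - row[None, :]).max() for row in mb])
    return GdsTable(
        genes=genes, n_bins=n_bins,
        bin_means=pd.DataFrame(mb, index=genes,
                               columns=[f"bin{i+1}" for i in range(n_bins)]),
        scores=pd.Series(scores, index=genes, name="GDS"))


def build_candidate_gene_list(table: GdsTable, top_k: int,
                              forced_genes: list[str] = ()) -> list[str]:
    """Union of the top-k GDS genes with a forced list.

    Rank order is preserved and forced genes are appended without
    duplication; a forced gene absent from the scored set is fatal.
    """
    unknown = [g for g in forced_genes if g not in table.scores.index]
    if unknown:
        raise KeyError(f"forced gene(s) not in dataset: {unknown}")
    out = table.ranking()[:top_k]
    out += [g for g in forced_genes if g not in out]
    return out
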