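"""Bootstrapped RPKM quantification of multi-aligned reads.

Short (50-bp) reads from a mixed plant/fungus/bacterium library often align
equally well to several genes, sometimes in different organisms.  Rather
than discarding or fractionally splitting them, each bootstrap iteration
assigns every multi-aligned read uniformly at random to exactly one of its
candidate genes; uniquely aligned reads always count for their single gene.
Across iterations this yields a mean and standard deviation of RPKM (reads
per kilobase of gene per million aligned reads) per gene, where the
"million aligned reads" denominator counts each read once regardless of how
many alignments it has, so the per-iteration library size is constant.

Expression significance is the normal-distribution probability that a
gene's expression is <= 0 given its bootstrap mean and SD, adjusted per
sample by Benjamini-Hochberg; a gene is called expressed when the adjusted
probability is below 0.05 and its mean RPKM exceeds 2.

The per-sample mean RPKM values are then log2-transformed (with a
pseudocount) and quantile-normalized into the genes x samples matrix that
all downstream stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AlignmentTable, GeneCatalog, IntegrityError
from .stats import bh_fdr

DEFAULT_ITERATIONS = 10_000
EXPRESSED_ALPHA = 0.05
EXPRESSED_MIN_RPKM = 2.0


@dataclass(frozen=True)
class BootstrapExpression:
    """Per-gene bootstrap expression estimates for one sample.

    ``frame`` is indexed by gene id with columns ``unique_rpkm`` (RPKM from
    uniquely aligned reads only), ``mean_rpkm``, ``sd_rpkm`` and -- after
    :func:`expression_significance` -- ``p_expressed``, ``q_expressed`` and
    ``expressed_flag``.
    """

    sample_id: str
    frame: pd.DataFrame
    n_reads: int
    iterations: int


def bootstrap_rpkm(
    alignments: AlignmentTable,
    catalog: GeneCatalog,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
) -> BootstrapExpression:
    """Bootstrap-quantify one sample's alignments against a gene catalog.

    Genes that never receive a read report mean and SD of exactly 0; genes
    touched only by uniquely aligned reads report their closed-form RPKM
    with SD exactly 0.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if len(alignments.frame) == 0:
        raise ValueError("alignment table is empty")
    alignments.validate_against(catalog)

    genes = catalog.gene_ids
    n_genes = len(genes)
    gene_pos = pd.Series(np.arange(n_genes), index=genes)

    frame = alignments.frame
    read_codes, _ = pd.factorize(frame["read_id"], sort=False)
    gene_idx = gene_pos[frame["gene_id"]].to_numpy()
    n_reads = int(read_codes.max()) + 1

    # CSR layout of candidate sets, reads sorted by code
    order = np.argsort(read_codes, kind="stable")
    sorted_codes = read_codes[order]
    sorted_genes = gene_idx[order]
    k_per_read = np.bincount(sorted_codes, minlength=n_reads)
    offsets = np.concatenate([[0], np.cumsum(k_per_read)])

    unique_mask = k_per_read == 1
    unique_counts = np.bincount(
        sorted_genes[offsets[:-1][unique_mask]], minlength=n_genes
    ).astype(np.int64)

    multi_reads = np.flatnonzero(~unique_mask)
    n_multi = multi_reads.size
    total = float(n_reads)
    scale = 1e9 / (catalog.lengths.to_numpy(dtype=float) * total)

    if n_multi == 0:
        mean_counts = unique_counts.astype(float)
        sd_counts = np.zeros(n_genes)
    else:
        rng = np.random.default_rng(seed)
        starts = offsets[:-1][multi_reads]
        ks = k_per_read[multi_reads]
        s1 = np.zeros(n_genes)
        s2 = np.zeros(n_genes)
        cmin = np.full(n_genes, np.iinfo(np.int64).max, dtype=np.int64)
        cmax = np.full(n_genes, np.iinfo(np.int64).min, dtype=np.int64)
        for _ in range(iterations):
            pick = starts + (rng.random(n_multi) * ks).astype(np.int64)
            counts = unique_counts + np.bincount(
                sorted_genes[pick], minlength=n_genes
            )
            s1 += counts
            s2 += counts.astype(float) ** 2
            np.minimum(cmin, counts, out=cmin)
            np.maximum(cmax, counts, out=cmax)
        mean_counts = s1 / iterations
        if iterations > 1:
            var = (s2 - iterations * (s1 / iterations) ** 2) / (iterations - 1)
            sd_counts = np.sqrt(np.clip(var, 0.0, None))
        else:
            sd_counts = np.zeros(n_genes)
        constant = cmin == cmax
        mean_counts[constant] = cmin[constant]
        sd_counts[constant] = 0.0

    out = pd.DataFrame(
        {
            "unique_rpkm": unique_counts * scale,
            "mean_rpkm": mean_counts * scale,
            "sd_rpkm": sd_counts * scale,
        },
        index=genes,
    )
    return BootstrapExpression(alignments.sample_id, out, n_reads, iterations)


def expression_significance(
    expr: BootstrapExpression,
    alpha: float = EXPRESSED_ALPHA,
    min_rpkm: float = EXPRESSED_MIN_RPKM,
) -> BootstrapExpression:
    """Call significantly expressed genes from bootstrap mean/SD.

    ``p_expressed`` is the cumulative-normal probability that expression is
    <= 0 given (mean, SD); with SD = 0 it degenerates to 0 for a positive
    mean and 1 otherwise.  ``q_expressed`` adjusts the p-values across the
    sample's genes by Benjamini-Hochberg; a gene is flagged expressed when
    q < ``alpha`` and mean RPKM > ``min_rpkm``.
    """
    frame = expr.frame.copy()
    mean = frame["mean_rpkm"].to_numpy()
    sd = frame["sd_rpkm"].to_numpy()
    p = np.where(mean > 0, 0.0, 1.0)
    pos = sd > 0
    p[pos] = sps.norm.cdf(0.0, loc=mean[pos], scale=sd[pos])
    q = bh_fdr(p)
    frame["p_expressed"] = p
    frame["q_expressed"] = q
    frame["expressed_flag"] = (q < alpha) & (mean > min_rpkm)
    return replace(expr, frame=frame)


def quantify_samples(
    alignments: Mapping[str, AlignmentTable],
    catalog: GeneCatalog,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    significance: bool = True,
) -> Dict[str, BootstrapExpression]:
    """Quantify every sample with per-sample child seeds of ``seed``."""
    seeds = np.random.SeedSequence(seed).spawn(len(alignments))
    out = {}
    for (sample_id, table), ss in zip(alignments.items(), seeds):
        expr = bootstrap_rpkm(
            table, catalog, iterations=iterations, seed=int(ss.generate_state(1)[0])
        )
        out[sample_id] = expression_significance(expr) if significance else expr
    return out


def mean_rpkm_matrix(exprs: Mapping[str, BootstrapExpression]) -> pd.DataFrame:
    """Stack per-sample mean RPKM into a genes x samples frame."""
    frames = {}
    index = None
    for sample_id, expr in exprs.items():
        if index is None:
            index = expr.frame.index
        elif not index.equals(expr.frame.index):
            raise IntegrityError("samples were quantified over different gene sets")
        frames[sample_id] = expr.frame["mean_rpkm"]
    return pd.DataFrame(frames)


def expressed_in_any_sample(exprs: Mapping[str, BootstrapExpression]) -> pd.Series:
    """Boolean per-gene indicator: called expressed in at least one sample."""
    flags = pd.DataFrame(
        {s: e.frame["expressed_flag"] for s, e in exprs.items()}
    )
    return flags.any(axis=1)


def quantile_normalize(matrix: pd.DataFrame, ties: str = "average") -> pd.DataFrame:
    """Force all columns of a matrix to share identical order statistics.

    The reference distribution is the across-column mean of each order
    statistic.  With ``ties="average"`` tied values within a column receive
    the mean of the reference values they span (so exact ties stay tied);
    with ``ties="order"`` ties are broken by position, which makes the
    column distributions exactly identical even in the presence of ties.
    """
    X = matrix.to_numpy(dtype=float)
    n, m = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        assigned = np.empty(n)
        assigned[order[:, j]] = ref
        if ties == "average":
            vals, inv = np.unique(X[:, j], return_inverse=True)
            sums = np.bincount(inv, weights=assigned)
            cnts = np.bincount(inv)
            assigned = (sums / cnts)[inv]
        elif ties != "order":
            raise ValueError("ties must be 'average' or 'order'")
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_matrix(
    expr: Mapping[str, BootstrapExpression] | pd.DataFrame,
    pseudocount: float = 1.0,
    ties: str = "average",
) -> pd.DataFrame:
    """log2(mean RPKM + pseudocount), then quantile normalization.

    Accepts either the per-sample quantification results or a ready genes x
    samples mean-RPKM frame.  Returns the normalized log2 matrix.
    """
    matrix = expr if isinstance(expr, pd.DataFrame) else mean_rpkm_matrix(expr)
    logged = np.log2(matrix + pseudocount)
    return quantile_normalize(logged, ties=ties)


def write_expression_tsv(
    expr: BootstrapExpression,
    path: str | Path,
    log2norm: pd.Series | None = None,
) -> None:
    """Per-sample export mirroring the study's supplementary column roles:
    unique RPKM, bootstrap mean/SD RPKM, normalized log2 value, p-value."""
    out = expr.frame.copy()
    if log2norm is not None:
        out["log2norm_rpkm"] = log2norm
    out.rename_axis("gene_id").to_csv(path, sep="\t")
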