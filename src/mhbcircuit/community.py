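"""Per-organism read-attribution summaries and presence-enrichment tests.

Because 50-bp reads can align to genes of more than one community member, a
read is attributed to *every* organism among its candidate genes; the
per-organism percentages of aligned reads may therefore sum to more than
100%.  Detecting a microbe transcriptionally amounts to asking whether its
read share is enriched in the samples where it was inoculated relative to
those where it was not; the fold is a ratio of group means and the p-value
a one-tailed Welch two-sample t-test on per-sample percentages.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ORGANISMS, AlignmentTable, GeneCatalog, StudyDesign


def organism_read_fractions(
    alignments: Mapping[str, AlignmentTable], catalog: GeneCatalog
) -> pd.DataFrame:
    """Per-sample aligned-read counts and percentages per organism.

    A read counts toward an organism if at least one of its candidate genes
    belongs to it (so multi-organism reads count several times); the
    percentage denominator is the number of reads aligned to any organism.
    """
    org_of_gene = catalog.organisms
    rows = []
    for sample_id, table in alignments.items():
        table.validate_against(catalog)
        frame = table.frame.copy()
        frame["organism"] = org_of_gene.reindex(frame["gene_id"]).to_numpy()
        total = frame["read_id"].nunique()
        row = {"sample_id": sample_id, "total_aligned_reads": total}
        for org in ORGANISMS:
            n = frame.loc[frame["organism"] == org, "read_id"].nunique()
            row[f"reads_{org}"] = n
            row[f"pct_{org}"] = 100.0 * n / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def fold_enrichment_test(
    fractions: pd.DataFrame,
    design: StudyDesign,
    organism: str,
    present_conditions: Iterable[str],
    absent_conditions: Iterable[str],
) -> tuple[float, float]:
    """Fold enrichment of an organism's read share, present vs absent.

    fold = mean(percent | present) / mean(percent | absent); p from a
    one-tailed (greater) Welch t-test on the per-sample percentages.
    """
    col = f"pct_{organism}"
    present = [s for c in present_conditions for s in design.samples_of(c)]
    absent = [s for c in absent_conditions for s in design.samples_of(c)]
    if len(present) < 2 or len(absent) < 2:
        raise ValueError("both condition groups need >= 2 samples")
    x = fractions.loc[present, col].to_numpy(dtype=float)
    y = fractions.loc[absent, col].to_numpy(dtype=float)
    p = float(sps.ttest_ind(x, y, equal_var=False, alternative="greater").pvalue)
    if np.isnan(p):
        # both groups constant: no within-group variance to test against
        p = 0.5 if x.mean() == y.mean() else (0.0 if x.mean() > y.mean() else 1.0)
    if y.mean() == 0:
        warnings.warn(f"zero mean {organism} share in the absent group")
        return float("inf"), p
    return float(x.mean() / y.mean()), p


def phenotype_read_correlation(
    fractions: pd.DataFrame, organism: str, phenotype_values: pd.Series
) -> float:
    """Pearson correlation between per-sample read share and a phenotype."""
    col = f"pct_{organism}"
    paired = pd.concat([fractions[col], phenotype_values], axis=1, join="inner")
    x = paired.iloc[:, 0].to_numpy(dtype=float)
    y = paired.iloc[:, 1].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
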