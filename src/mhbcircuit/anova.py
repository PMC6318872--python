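"""Two-factor permutation ANOVA over the 2x2 community design.

For every gene, expression (normalized log2) is decomposed by classical
fixed-effects two-way ANOVA with factors fungus presence, bacterium
presence and their interaction (Type II sums of squares, so unbalanced
designs are handled; on the balanced 2x2 design Type II equals the textbook
decomposition).  Significance is assessed by permutation: sample labels are
shuffled jointly for all three tests with a single permutation schedule
shared across genes, and p = (1 + #{F* >= F_obs}) / (1 + n_perm), so the
smallest attainable p is 1/(1 + n_perm) and p = 0 is impossible.

Per factor, p-values are adjusted across genes by Benjamini-Hochberg; a
gene is significantly differentially expressed (SDE) when it is significant
for at least one factor.  The per-factor memberships partition the SDE set
into the seven regions of a three-set Venn diagram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

import numpy as np
import pandas as pd

from .io import IntegrityError, StudyDesign
from .stats import bh_fdr

FACTORS = ("fungus", "bacterium", "interaction")


@dataclass(frozen=True)
class AnovaResult:
    """Per-gene F statistics, permutation p-values and BH q-values.

    ``table`` is indexed by gene id with columns ``F_<factor>``,
    ``p_<factor>`` and ``q_<factor>`` for each of fungus, bacterium and
    interaction.
    """

    table: pd.DataFrame
    n_perm: int
    seed: int | None

    def membership(
        self, alpha: float = 0.05, correction: str = "fdr"
    ) -> Dict[str, Set[str]]:
        """Per-factor significant gene sets at level ``alpha``.

        ``correction="fdr"`` thresholds BH q-values (default);
        ``correction="raw"`` thresholds the raw permutation p-values.
        """
        if correction not in ("fdr", "raw"):
            raise ValueError("correction must be 'fdr' or 'raw'")
        col = "q_" if correction == "fdr" else "p_"
        return {
            f: set(self.table.index[self.table[f"{col}{f}"] < alpha])
            for f in FACTORS
        }


def _residual_maker(X: np.ndarray) -> np.ndarray:
    """I - X (X'X)^+ X' : projector onto the orthocomplement of col(X)."""
    n = X.shape[0]
    return np.eye(n) - X @ np.linalg.pinv(X)


def _f_statistics(Y: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Type II two-way ANOVA F statistics for all genes at once.

    Y is genes x samples; A and B are 0/1 factor indicators.  Returns an
    array (genes, 3) with F for A, B and the A:B interaction.
    """
    n = Y.shape[1]
    one = np.ones(n)
    AB = A * B
    M_full = _residual_maker(np.column_stack([one, A, B, AB]))
    M_ab = _residual_maker(np.column_stack([one, A, B]))
    M_a = _residual_maker(np.column_stack([one, A]))
    M_b = _residual_maker(np.column_stack([one, B]))

    def rss(M: np.ndarray) -> np.ndarray:
        return np.einsum("gi,ij,gj->g", Y, M, Y)

    rss_full = rss(M_full)
    rss_ab = rss(M_ab)
    ss_a = rss(M_b) - rss_ab          # SS(A | B)
    ss_b = rss(M_a) - rss_ab          # SS(B | A)
    ss_i = rss_ab - rss_full          # SS(AB | A, B)
    df_resid = n - 4
    if df_resid < 1:
        raise IntegrityError("two-way ANOVA needs more samples than cells")
    mse = rss_full / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.stack([ss_a, ss_b, ss_i], axis=1) / mse[:, None]
    F[~np.isfinite(F)] = 0.0
    # a constant gene has 0/0 everywhere up to projection round-off:
    # define F = 0 (no evidence) rather than a ratio of numerical noise
    F[Y.var(axis=1) == 0.0, :] = 0.0
    return np.clip(F, 0.0, None)


def permutation_anova2(
    matrix: pd.DataFrame,
    design: StudyDesign,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AnovaResult:
    """Permutation two-factor ANOVA of a genes x samples matrix.

    Columns of ``matrix`` must match the design's samples.  Permutations
    shuffle whole sample labels (unrestricted) and the same schedule is
    applied to every gene, so results are reproducible for a fixed seed and
    comparable across genes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    design.validate_for_anova()
    samples = design.sample_ids
    if set(matrix.columns) != set(samples):
        raise IntegrityError("matrix columns do not match design samples")
    Y = matrix[samples].to_numpy(dtype=float)
    A = design.frame["fungus"].to_numpy(dtype=float)
    B = design.frame["bacterium"].to_numpy(dtype=float)

    F_obs = _f_statistics(Y, A, B)
    exceed = np.zeros_like(F_obs, dtype=np.int64)
    rng = np.random.default_rng(seed)
    n = Y.shape[1]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        F_perm = _f_statistics(Y, A[perm], B[perm])
        exceed += F_perm >= F_obs
    p = (1.0 + exceed) / (1.0 + n_perm)

    table = pd.DataFrame(index=matrix.index)
    for j, f in enumerate(FACTORS):
        table[f"F_{f}"] = F_obs[:, j]
        table[f"p_{f}"] = p[:, j]
    for f in FACTORS:
        table[f"q_{f}"] = bh_fdr(table[f"p_{f}"].to_numpy())
    return AnovaResult(table, n_perm, seed)


VENN_REGIONS = (
    "fungus_only",
    "bacterium_only",
    "interaction_only",
    "fungus_bacterium",
    "fungus_interaction",
    "bacterium_interaction",
    "all_three",
)


def sde_partition(
    result: AnovaResult, alpha: float = 0.05, correction: str = "fdr"
) -> Tuple[Dict[str, int], Dict[str, Set[str]]]:
    """Venn partition of significantly differentially expressed genes.

    Returns the counts of the seven Venn regions plus the union size, and
    the per-factor significant gene sets.
    """
    sets = result.membership(alpha=alpha, correction=correction)
    f, b, i = sets["fungus"], sets["bacterium"], sets["interaction"]
    counts = {
        "fungus_only": len(f - b - i),
        "bacterium_only": len(b - f - i),
        "interaction_only": len(i - f - b),
        "fungus_bacterium": len((f & b) - i),
        "fungus_interaction": len((f & i) - b),
        "bacterium_interaction": len((b & i) - f),
        "all_three": len(f & b & i),
        "union": len(f | b | i),
    }
    return counts, sets


def sde_genes(
    result: AnovaResult, alpha: float = 0.05, correction: str = "fdr"
) -> List[str]:
    """Union of the per-factor significant gene sets, in table order."""
    sets = result.membership(alpha=alpha, correction=correction)
    union = sets["fungus"] | sets["bacterium"] | sets["interaction"]
    return [g for g in result.table.index if g in union]
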