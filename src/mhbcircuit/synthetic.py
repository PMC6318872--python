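"""Synthetic tripartite-community experiments with known ground truth.

Emulates the structure of a root metatranscriptome study of a host plant
grown alone or with an ectomycorrhizal fungus and/or a rhizosphere bacterium
(a 2x2 factorial design with replicated samples): three co-resident genomes
with very unequal read shares (>99% of aligned reads from the host), a
configurable fraction of reads that multi-align across genes and organisms
(50-bp reads cannot always be placed uniquely), planted clusters of
condition-responsive host genes -- including a cluster whose response is the
exclusive-or (XOR) of the two microbe-presence factors -- planted annotation
enrichments, and a per-condition phenotype vector (percent mycorrhization)
correlated with a designated cluster.

No nucleotide sequences are simulated: a "read" is an identifier with a true
gene of origin and a candidate alignment set, which is all the downstream
quantification consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (
    CONDITIONS,
    AlignmentTable,
    AnnotationMap,
    GeneCatalog,
    PhenotypeTable,
    StudyDesign,
    annotation_to_tsv,
    condition_name,
)

NULL_CLUSTER = -1  # label for unregulated (pattern-free) genes


class ConfigurationError(ValueError):
    """Raised for inconsistent synthetic-experiment configurations."""


# ---------------------------------------------------------------------------
# pattern presets
# ---------------------------------------------------------------------------

def expression_pattern_matrix(preset_name: str, effect: float = 2.0) -> np.ndarray:
    """Planted log2 fold-change matrices (clusters x conditions).

    Columns follow :data:`mhbcircuit.io.CONDITIONS`:
    (baseline, fungus, bacterium, both); the baseline column is always 0.

    Presets
    -------
    ``"null"``
        A single all-zero row: no regulation anywhere.
    ``"xor-only"``
        One cluster up in exactly the two single-inoculation conditions.
    ``"fig3-like"``
        Six rows mimicking the qualitative shapes observed in the study
        system: one cluster down in every co-culture condition (innate
        immunity), one tracking mycorrhization (down with the bacterium
        alone, up with the fungus, strongly up with both), two responding to
        bacterial presence only (one down, one up), one antifungal-defense
        cluster up only with the fungus alone, and the XOR cluster.
    """
    e = float(effect)
    if e <= 0:
        raise ConfigurationError("effect size must be positive")
    presets = {
        "null": np.zeros((1, 4)),
        "xor-only": np.array([[0.0, e, e, 0.0]]),
        "fig3-like": np.array(
            [
                [0.0, -e, -e / 2, -e / 2],   # down in all co-cultures, most with fungus
                [0.0, e / 4, -e / 2, e],     # mycorrhization-tracking
                [0.0, 0.0, -e, -e],          # down whenever bacterium present
                [0.0, e, 0.0, 0.0],          # antifungal defense: fungus alone
                [0.0, e, e, 0.0],            # XOR of the two presence factors
                [0.0, -e / 2, e / 2, e / 2], # up with bacterium, down with fungus alone
            ]
        ),
    }
    try:
        return presets[preset_name].copy()
    except KeyError:
        raise KeyError(
            f"unknown pattern preset {preset_name!r}; "
            f"available: {sorted(presets)}"
        ) from None


def xor_rows(pattern_matrix: np.ndarray) -> List[int]:
    """Indices of rows that are up iff exactly one presence factor is true."""
    out = []
    for i, row in enumerate(np.asarray(pattern_matrix, dtype=float)):
        if row[1] > 0 and row[2] > 0 and row[3] <= 0 and row[0] == 0:
            out.append(i)
    return out


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

def _default_gene_counts() -> Dict[str, int]:
    return {"host": 1200, "fungus": 120, "bacterium": 60}


def _default_phenotype_plan() -> Dict[str, Tuple[float, float, float]]:
    # (pct mycorrhization, shoot g, root g); mycorrhization is 0 wherever the
    # fungus is absent and ~1.7x higher with the helper bacterium present.
    return {
        "baseline": (0.0, 0.80, 0.50),
        "fungus": (30.0, 0.82, 0.52),
        "bacterium": (0.0, 0.81, 0.50),
        "both": (51.0, 0.80, 0.53),
    }


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic tripartite experiment.

    Attributes
    ----------
    n_genes_per_organism
        Catalog sizes per organism label.
    gene_length_range
        Closed interval (bp) for uniform gene lengths.
    n_replicates
        Biological replicates per condition (the study design uses 3).
    pattern_matrix
        Planted log2 fold change vs the host-alone baseline, one row per
        planted cluster, columns in :data:`CONDITIONS` order (baseline
        column must be 0).
    genes_per_cluster
        Host genes assigned to each planted cluster; remaining host genes
        are nulls.
    multimap_fraction
        Fraction of reads receiving 1-3 extra decoy alignments to random
        catalog genes (cross-organism decoys allowed).
    noise_sd
        SD of lognormal replicate noise on expected counts (natural-log
        scale).
    library_size
        Aligned reads per sample.
    organism_absent_share, organism_present_fold
        Fraction of reads attributed to each microbe when it is absent
        (spurious cross-alignment background) and the fold increase when it
        is inoculated; the host takes the remaining share.
    enrichment_plan
        Triples (cluster index, term, fraction of cluster genes annotated).
    annotation_background_rate
        Probability that any host gene carries a planted term by chance.
    n_background_terms, terms_per_gene
        Size of the random background GO vocabulary and mean number of
        background terms per host gene.
    phenotype_plan
        condition -> (percent mycorrhization, shoot biomass g, root biomass
        g); mycorrhization must be 0 where the fungus is absent.
    poisson
        Draw read counts Poisson around expectations (True) or round
        expectations deterministically (False; useful for exactness tests).
    seed
        RNG seed; all outputs are deterministic given the seed.
    """

    n_genes_per_organism: Dict[str, int] = field(default_factory=_default_gene_counts)
    gene_length_range: Tuple[int, int] = (300, 3000)
    n_replicates: int = 3
    pattern_matrix: np.ndarray = field(
        default_factory=lambda: expression_pattern_matrix("fig3-like")
    )
    genes_per_cluster: int = 60
    multimap_fraction: float = 0.10
    noise_sd: float = 0.25
    library_size: int = 200_000
    organism_absent_share: Dict[str, float] = field(
        default_factory=lambda: {"fungus": 0.0010, "bacterium": 0.00005}
    )
    organism_present_fold: Dict[str, float] = field(
        default_factory=lambda: {"fungus": 12.0, "bacterium": 3.0}
    )
    enrichment_plan: List[Tuple[int, str, float]] | None = None
    annotation_background_rate: float = 0.01
    n_background_terms: int = 30
    terms_per_gene: float = 2.0
    phenotype_plan: Dict[str, Tuple[float, float, float]] = field(
        default_factory=_default_phenotype_plan
    )
    poisson: bool = True
    seed: int = 0

    @property
    def n_clusters_planted(self) -> int:
        return int(np.asarray(self.pattern_matrix).shape[0])

    def validate(self) -> None:
        pat = np.asarray(self.pattern_matrix, dtype=float)
        if pat.ndim != 2 or pat.shape[1] != len(CONDITIONS):
            raise ConfigurationError(
                f"pattern_matrix must be (clusters x {len(CONDITIONS)}); "
                f"got shape {pat.shape}"
            )
        if not np.all(pat[:, 0] == 0):
            raise ConfigurationError("pattern_matrix baseline column must be 0")
        if not 0.0 <= self.multimap_fraction <= 1.0:
            raise ConfigurationError("multimap_fraction must lie in [0, 1]")
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least one replicate")
        if len(xor_rows(pat)) > 1:
            raise ConfigurationError(
                "at most one planted cluster may carry the XOR pattern"
            )
        host = self.n_genes_per_organism.get("host", 0)
        if self.n_clusters_planted * self.genes_per_cluster > host:
            raise ConfigurationError("planted clusters exceed host catalog size")
        for cond, (pct, _, _) in self.phenotype_plan.items():
            if pct != 0.0 and cond in ("baseline", "bacterium"):
                raise ConfigurationError(
                    "percent mycorrhization must be 0 where the fungus is absent"
                )


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_experiment`."""

    cluster_of_gene: pd.Series          # gene_id -> planted cluster (NULL_CLUSTER = none)
    pattern_matrix: np.ndarray          # clusters x conditions, log2 vs baseline
    xor_cluster: int | None             # index of the planted XOR cluster, if any
    enrichment_plan: List[Tuple[int, str, float]]
    phenotype: PhenotypeTable
    read_origin: Dict[str, pd.Series]   # sample_id -> read_id -> true gene
    true_counts: pd.DataFrame           # genes x samples true read counts

    def planted_genes(self, cluster: int) -> List[str]:
        s = self.cluster_of_gene
        return list(s.index[s == cluster])


@dataclass
class SyntheticExperiment:
    """A full generated experiment: inputs for every analysis stage + truth."""

    alignments: Dict[str, AlignmentTable]
    catalog: GeneCatalog
    design: StudyDesign
    annotations: AnnotationMap
    phenotype: PhenotypeTable
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _largest_remainder_round(expected: np.ndarray) -> np.ndarray:
    """Round non-negative expectations to integers conserving the total."""
    floor = np.floor(expected).astype(np.int64)
    deficit = int(np.round(expected.sum())) - int(floor.sum())
    if deficit > 0:
        frac = expected - floor
        top = np.argsort(-frac, kind="stable")[:deficit]
        floor[top] += 1
    return floor


def _build_catalog(cfg: SyntheticConfig, rng: np.random.Generator) -> GeneCatalog:
    rows = []
    lo, hi = cfg.gene_length_range
    for org in ("host", "fungus", "bacterium"):
        n = cfg.n_genes_per_organism.get(org, 0)
        lengths = rng.integers(lo, hi + 1, size=n)
        for i in range(n):
            rows.append((f"{org}_g{i:05d}", org, int(lengths[i])))
    return GeneCatalog.from_frame(
        pd.DataFrame(rows, columns=["gene_id", "organism", "length_bp"])
    )


def _condition_shares(cfg: SyntheticConfig, fungus: bool, bacterium: bool) -> Dict[str, float]:
    shares = {}
    for org, present in (("fungus", fungus), ("bacterium", bacterium)):
        base = cfg.organism_absent_share.get(org, 0.0)
        shares[org] = base * (cfg.organism_present_fold.get(org, 1.0) if present else 1.0)
    shares["host"] = 1.0 - shares["fungus"] - shares["bacterium"]
    if shares["host"] <= 0:
        raise ConfigurationError("microbial shares exceed the whole library")
    return shares


def _build_annotations(
    cfg: SyntheticConfig,
    catalog: GeneCatalog,
    cluster_of_gene: pd.Series,
    plan: List[Tuple[int, str, float]],
    rng: np.random.Generator,
) -> AnnotationMap:
    host_genes = list(catalog.gene_ids[catalog.organisms == "host"])
    annotations: AnnotationMap = {}
    # random background vocabulary over host genes
    vocab = [f"GO:{1000001 + i:07d}" for i in range(cfg.n_background_terms)]
    n_terms = rng.poisson(cfg.terms_per_gene, size=len(host_genes))
    for gene, k in zip(host_genes, n_terms):
        if k > 0:
            picks = rng.choice(len(vocab), size=min(k, len(vocab)), replace=False)
            annotations.setdefault(gene, set()).update(vocab[i] for i in picks)
    # planted enrichments: a fraction of the cluster plus a thin background
    for cluster, term, fraction in plan:
        members = list(cluster_of_gene.index[cluster_of_gene == cluster])
        n_in = max(1, int(round(fraction * len(members))))
        chosen = rng.choice(len(members), size=n_in, replace=False)
        for i in chosen:
            annotations.setdefault(members[i], set()).add(term)
        others = [g for g in host_genes if cluster_of_gene.get(g, NULL_CLUSTER) != cluster]
        bg = rng.random(len(others)) < cfg.annotation_background_rate
        for g, hit in zip(others, bg):
            if hit:
                annotations.setdefault(g, set()).add(term)
    return annotations


def generate_experiment(config: SyntheticConfig) -> SyntheticExperiment:
    """Generate a complete synthetic experiment from a validated config.

    Expected reads for gene g in a sample are proportional to
    ``length_bp * baseline_abundance * 2**pattern[cluster(g), condition]``
    times per-gene lognormal replicate noise, scaled so each organism
    receives its condition-dependent share of the library; counts are drawn
    Poisson around expectations (or rounded deterministically when
    ``config.poisson`` is off).  A ``multimap_fraction`` of reads receives
    1-3 decoy alignments drawn uniformly from the whole catalog, so decoys
    may cross organism boundaries.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    catalog = _build_catalog(config, rng)
    genes = catalog.gene_ids
    n_genes = len(genes)
    organisms = catalog.organisms.to_numpy()
    lengths = catalog.lengths.to_numpy(dtype=float)

    # baseline abundances: log-uniform over three orders of magnitude
    abundance = 10.0 ** rng.uniform(0.0, 3.0, size=n_genes)

    # planted cluster assignment over the first host genes (host genes were
    # generated in catalog order, so a contiguous block is an arbitrary subset)
    pat = np.asarray(config.pattern_matrix, dtype=float)
    host_idx = np.flatnonzero(organisms == "host")
    shuffled = rng.permutation(host_idx)
    cluster_label = np.full(n_genes, NULL_CLUSTER, dtype=int)
    for c in range(config.n_clusters_planted):
        block = shuffled[c * config.genes_per_cluster : (c + 1) * config.genes_per_cluster]
        cluster_label[block] = c
    cluster_of_gene = pd.Series(cluster_label, index=genes, name="cluster")

    # per-gene log2 fold change per condition
    log2fc = np.zeros((n_genes, len(CONDITIONS)))
    for c in range(config.n_clusters_planted):
        log2fc[cluster_label == c, :] = pat[c, :]

    # design table
    rows = []
    for ci, cond in enumerate(CONDITIONS):
        fungus = cond in ("fungus", "both")
        bacterium = cond in ("bacterium", "both")
        for r in range(config.n_replicates):
            rows.append((f"{cond}_r{r + 1}", int(fungus), int(bacterium), r + 1))
    design = StudyDesign(
        pd.DataFrame(rows, columns=["sample_id", "fungus", "bacterium", "replicate"])
    )

    org_order = ("host", "fungus", "bacterium")
    org_masks = {o: organisms == o for o in org_order}

    alignments: Dict[str, AlignmentTable] = {}
    read_origin: Dict[str, pd.Series] = {}
    true_counts = pd.DataFrame(0, index=genes, columns=design.sample_ids, dtype=np.int64)

    cond_of_sample = design.condition
    for sample_id in design.sample_ids:
        cond = cond_of_sample[sample_id]
        ci = CONDITIONS.index(cond)
        fungus = cond in ("fungus", "both")
        bacterium = cond in ("bacterium", "both")
        shares = _condition_shares(config, fungus, bacterium)

        weight = abundance * lengths * (2.0 ** log2fc[:, ci])
        if config.noise_sd > 0:
            weight = weight * np.exp(rng.normal(0.0, config.noise_sd, size=n_genes))
        expected = np.zeros(n_genes)
        for org in org_order:
            mask = org_masks[org]
            total = weight[mask].sum()
            if total > 0:
                expected[mask] = config.library_size * shares[org] * weight[mask] / total

        if config.poisson:
            counts = rng.poisson(expected)
        else:
            counts = _largest_remainder_round(expected)
        true_counts[sample_id] = counts

        # reads: one row per (read, candidate gene)
        n_reads = int(counts.sum())
        true_gene_idx = np.repeat(np.arange(n_genes), counts)
        read_ids = np.array([f"{sample_id}_r{i:07d}" for i in range(n_reads)])

        n_multi = int(round(config.multimap_fraction * n_reads))
        if n_multi > 0:
            multi_pick = rng.choice(n_reads, size=n_multi, replace=False)
            n_decoys = rng.integers(1, 4, size=n_multi)  # 1..3 extra alignments
            decoy_read_rows = np.repeat(multi_pick, n_decoys)
            decoy_gene = rng.integers(0, n_genes, size=decoy_read_rows.size)
            # a decoy equal to the true gene would not add an alignment; bump it
            clash = decoy_gene == true_gene_idx[decoy_read_rows]
            decoy_gene[clash] = (decoy_gene[clash] + 1) % n_genes
            all_rows = np.concatenate([np.arange(n_reads), decoy_read_rows])
            all_genes = np.concatenate([true_gene_idx, decoy_gene])
        else:
            all_rows = np.arange(n_reads)
            all_genes = true_gene_idx

        frame = pd.DataFrame(
            {
                "read_id": read_ids[all_rows],
                "gene_id": genes.to_numpy()[all_genes],
            }
        ).drop_duplicates()
        alignments[sample_id] = AlignmentTable(sample_id, frame.reset_index(drop=True))
        read_origin[sample_id] = pd.Series(
            genes.to_numpy()[true_gene_idx], index=read_ids, name="true_gene"
        )

    plan = config.enrichment_plan
    if plan is None:
        xr = xor_rows(pat)
        plan = [(xr[0], "GO:0048544", 0.15)] if xr else []
    annotations = _build_annotations(config, catalog, cluster_of_gene, plan, rng)

    phen_frame = pd.DataFrame(
        [
            (cond, *config.phenotype_plan[cond])
            for cond in CONDITIONS
            if cond in config.phenotype_plan
        ],
        columns=["condition", "pct_mycorrhization", "shoot_biomass_g", "root_biomass_g"],
    ).set_index("condition")
    phenotype = PhenotypeTable(phen_frame)

    xr = xor_rows(pat)
    truth = SyntheticTruth(
        cluster_of_gene=cluster_of_gene,
        pattern_matrix=pat,
        xor_cluster=xr[0] if xr else None,
        enrichment_plan=list(plan),
        phenotype=phenotype,
        read_origin=read_origin,
        true_counts=true_counts,
    )
    return SyntheticExperiment(alignments, catalog, design, annotations, phenotype, truth)


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

def write_fixtures(exp: SyntheticExperiment, outdir: str | Path, sam: bool = False) -> None:
    """Write an experiment to plain-text fixture files.

    Layout: ``catalog.tsv``, ``design.csv``, ``annotations.tsv``,
    ``phenotype.csv``, ``alignments/<sample>.tsv`` (and ``.sam`` when
    requested) and ``truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    exp.catalog.to_tsv(outdir / "catalog.tsv")
    exp.design.to_csv(outdir / "design.csv")
    annotation_to_tsv(exp.annotations, outdir / "annotations.tsv")
    exp.phenotype.to_csv(outdir / "phenotype.csv")
    for sample_id, table in exp.alignments.items():
        table.to_tsv(outdir / "alignments" / f"{sample_id}.tsv")
        if sam:
            _write_sam(table, exp.catalog, outdir / "alignments" / f"{sample_id}.sam")
    truth = {
        "cluster_of_gene": {
            g: int(c)
            for g, c in exp.truth.cluster_of_gene.items()
            if c != NULL_CLUSTER
        },
        "pattern_matrix": exp.truth.pattern_matrix.tolist(),
        "xor_cluster": exp.truth.xor_cluster,
        "enrichment_plan": [list(t) for t in exp.truth.enrichment_plan],
        "conditions": list(CONDITIONS),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _write_sam(table: AlignmentTable, catalog: GeneCatalog, path: Path) -> None:
    """Minimal unsorted SAM: gene models as references, flag 256 for secondary."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": g, "LN": int(l)}
            for g, l in zip(catalog.gene_ids, catalog.lengths)
        ],
    }
    ref_index = {g: i for i, g in enumerate(catalog.gene_ids)}
    lengths = catalog.lengths
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        seen: set[str] = set()
        for read_id, gene_id in zip(table.frame["read_id"], table.frame["gene_id"]):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = str(read_id)
            rec.reference_id = ref_index[gene_id]
            rec.reference_start = 0
            rec.mapping_quality = 255
            rec.cigartuples = [(0, min(50, int(lengths[gene_id])))]
            rec.flag = 256 if read_id in seen else 0
            seen.add(read_id)
            out.write(rec)
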