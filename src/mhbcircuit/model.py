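"""Model/Results front end over the full analysis.

`TripartiteCircuitModel` bundles the inputs of a tripartite-community root
transcriptome experiment (per-sample alignments, gene catalog, 2x2 design,
annotation map, per-condition phenotypes); its :meth:`fit` runs the staged
analysis -- bootstrap RPKM quantification, quantile normalization,
permutation two-factor ANOVA, K-means/silhouette clustering, hypergeometric
annotation enrichment, constrained Bayesian-network search, Boolean gate
fitting and the sensor-candidate screen -- and returns a
:class:`CircuitResults` holding every stage's estimates, a text
``summary()`` and exporters.  All randomness derives from a single seed, so
refitting with the same inputs and seed reproduces identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Set

import json

import numpy as np
import pandas as pd

from . import anova as _anova
from . import circuit as _circuit
from . import cluster as _cluster
from . import community as _community
from . import enrich as _enrich
from . import quantify as _quantify
from .io import (
    CONDITIONS,
    AlignmentTable,
    AnnotationMap,
    GeneCatalog,
    PhenotypeTable,
    StudyDesign,
)


def _child_seeds(seed: int | None, n: int) -> List[int]:
    """Independent child seeds (< 2**31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n)]


@dataclass
class TripartiteCircuitModel:
    """The unfitted model: experiment inputs plus stage parameters."""

    alignments: Mapping[str, AlignmentTable]
    catalog: GeneCatalog
    design: StudyDesign
    annotations: AnnotationMap
    phenotype: PhenotypeTable

    @classmethod
    def from_synthetic(cls, config=None, **kwargs) -> "TripartiteCircuitModel":
        """Build a model from a generated synthetic experiment.

        Accepts a :class:`~mhbcircuit.synthetic.SyntheticConfig` (or keyword
        overrides of its defaults).  The planted truth is attached as
        ``model.truth`` for recovery checks.
        """
        from .synthetic import SyntheticConfig, generate_experiment

        if config is None:
            config = SyntheticConfig(**kwargs)
        exp = generate_experiment(config)
        model = cls(
            exp.alignments, exp.catalog, exp.design, exp.annotations, exp.phenotype
        )
        model.truth = exp.truth  # type: ignore[attr-defined]
        return model

    @classmethod
    def from_files(
        cls,
        alignment_paths: Mapping[str, str],
        catalog_path: str,
        design_path: str,
        annotation_path: str,
        phenotype_path: str,
    ) -> "TripartiteCircuitModel":
        from .io import read_annotation_tsv

        alignments = {
            s: AlignmentTable.from_tsv(p, sample_id=s)
            for s, p in alignment_paths.items()
        }
        return cls(
            alignments,
            GeneCatalog.from_tsv(catalog_path),
            StudyDesign.from_csv(design_path),
            read_annotation_tsv(annotation_path),
            PhenotypeTable.from_csv(phenotype_path),
        )

    def fit(
        self,
        iterations: int = 10_000,
        n_perm: int = 10_000,
        k_min: int = 2,
        k_max: int = 12,
        alpha: float = 0.05,
        sde_correction: str = "fdr",
        enrichment_alpha: float = 0.05,
        n_bins: int = 2,
        max_parents: int = 5,
        bn_restarts: int = 20,
        kmeans_restarts: int = 25,
        up_threshold: float = 0.5,
        sensor_terms: Set[str] = frozenset({"GO:0048544"}),
        host_organism: str = "host",
        seed: int | None = 0,
    ) -> "CircuitResults":
        """Run the full staged analysis and return the fitted results."""
        s_quant, s_perm, s_kmeans, s_bn = _child_seeds(seed, 4)

        exprs = _quantify.quantify_samples(
            self.alignments, self.catalog, iterations=iterations, seed=s_quant
        )
        fractions = _community.organism_read_fractions(self.alignments, self.catalog)
        matrix = _quantify.normalize_matrix(exprs)

        host_genes = set(self.catalog.gene_ids[self.catalog.organisms == host_organism])
        expressed = _quantify.expressed_in_any_sample(exprs)
        tested = [g for g in matrix.index if g in host_genes and expressed[g]]
        anova_res = _anova.permutation_anova2(
            matrix.loc[tested], self.design, n_perm=n_perm, seed=s_perm
        )
        venn, _ = _anova.sde_partition(anova_res, alpha=alpha, correction=sde_correction)
        sde = _anova.sde_genes(anova_res, alpha=alpha, correction=sde_correction)

        if len(sde) <= k_min:
            raise RuntimeError(
                f"only {len(sde)} SDE genes at alpha={alpha}; cannot cluster"
            )
        cmodel = _cluster.select_k_silhouette(
            matrix.loc[sde],
            k_min=k_min,
            k_max=k_max,
            seed=s_kmeans,
            n_restarts=kmeans_restarts,
        )
        cmodel = _cluster.with_profiles(cmodel, matrix, self.design)
        profiles = cmodel.profiles

        myc = self.phenotype.mycorrhization
        r_all = {}
        for c in profiles.index:
            x = profiles.loc[c].to_numpy()
            r_all[c] = (
                float(np.corrcoef(x, myc.reindex(profiles.columns))[0, 1])
                if np.std(x) > 0
                else np.nan
            )
        target_cluster = int(pd.Series(r_all).idxmax())
        pheno_r, pheno_z, pheno_p = _cluster.profile_phenotype_correlation(
            profiles, myc, target_cluster
        )

        background = [g for g in host_genes if self.annotations.get(g)]
        enrichment = _enrich.enrich_clusters(
            cmodel.assignment, self.annotations, background, alpha=enrichment_alpha
        )

        ntable = _circuit.build_node_table(cmodel, matrix, self.design)
        ntable = _circuit.discretize_nodes(ntable, n_bins=n_bins)
        net = _circuit.learn_structure(
            ntable, max_parents=max_parents, n_restarts=bn_restarts, seed=s_bn
        )
        pruned = _circuit.transitive_prune(net)
        boolean = _circuit.fit_gates(pruned, ntable, self.design, up_threshold)
        screen = _circuit.screen_sensor_candidates(
            boolean, enrichment, cmodel, self.annotations, sensor_terms
        )

        # the circuit's output: the binary state of the mycorrhization-
        # correlated cluster stands in for MHB activity
        output_node = _circuit.cluster_node_name(target_cluster)
        mhb_activity = boolean.condition_states[output_node]

        return CircuitResults(
            model=self,
            expression=exprs,
            read_fractions=fractions,
            matrix=matrix,
            anova=anova_res,
            venn_counts=venn,
            sde_genes=sde,
            clusters=cmodel,
            phenotype_correlations=pheno_r,
            target_cluster=target_cluster,
            target_cluster_z=pheno_z,
            target_cluster_p=pheno_p,
            enrichment=enrichment,
            node_table=ntable,
            network=net,
            pruned_network=pruned,
            circuit=boolean,
            sensor_screen=screen,
            mhb_activity=mhb_activity,
            params=dict(
                iterations=iterations,
                n_perm=n_perm,
                k_min=k_min,
                k_max=k_max,
                alpha=alpha,
                sde_correction=sde_correction,
                enrichment_alpha=enrichment_alpha,
                n_bins=n_bins,
                max_parents=max_parents,
                bn_restarts=bn_restarts,
                kmeans_restarts=kmeans_restarts,
                up_threshold=up_threshold,
                sensor_terms=sorted(sensor_terms),
                seed=seed,
            ),
        )


@dataclass
class CircuitResults:
    """Everything the fitted analysis produced."""

    model: TripartiteCircuitModel
    expression: Dict[str, _quantify.BootstrapExpression]
    read_fractions: pd.DataFrame
    matrix: pd.DataFrame
    anova: _anova.AnovaResult
    venn_counts: Dict[str, int]
    sde_genes: List[str]
    clusters: _cluster.ClusterModel
    phenotype_correlations: pd.Series
    target_cluster: int
    target_cluster_z: float
    target_cluster_p: float
    enrichment: pd.DataFrame
    node_table: _circuit.NodeTable
    network: _circuit.BayesNetStructure
    pruned_network: _circuit.BayesNetStructure
    circuit: _circuit.BooleanCircuit
    sensor_screen: pd.DataFrame
    mhb_activity: pd.Series
    params: Dict[str, object]

    @property
    def candidate_genes(self) -> List[str]:
        return _circuit.candidate_genes(self.sensor_screen)

    def xor_gate_on(self, genes) -> bool:
        """Is the cluster where most of ``genes`` landed controlled by an
        XOR of the two presence inputs?  (Recovery check against a known
        set of co-regulated genes, e.g. a planted synthetic cluster.)"""
        landed = self.clusters.assignment.reindex(
            [g for g in genes if g in self.clusters.assignment.index]
        ).dropna()
        if landed.empty:
            return False
        home = int(landed.value_counts().idxmax())
        gate = self.circuit.gates.get(_circuit.cluster_node_name(home))
        return bool(
            gate
            and gate.gate == "XOR"
            and set(_circuit.PRESENCE_NODES) <= set(gate.relevant)
        )

    def xor_clusters(self) -> List[int]:
        """Clusters controlled by an XOR of the two presence inputs."""
        out = []
        for node in self.circuit.xor_nodes():
            gate = self.circuit.gates[node]
            if set(_circuit.PRESENCE_NODES) <= set(gate.relevant):
                out.append(int(node.split("_")[-1]))
        return sorted(out)

    def cluster_worksheet(self) -> pd.DataFrame:
        """Per-cluster gene listing: normalized expression, ANOVA q-values,
        mean log2 fold change vs baseline, and annotations, grouped by
        cluster (one row per SDE gene)."""
        design = self.model.design
        baseline = design.samples_of("baseline")
        rows = []
        for gene, cluster in self.clusters.assignment.sort_values().items():
            expr = self.matrix.loc[gene]
            base = expr[baseline].mean()
            q = self.anova.table.loc[gene]
            rows.append(
                {
                    "cluster": int(cluster),
                    "gene_id": gene,
                    "mean_log2norm": float(expr.mean()),
                    "q_fungus": float(q["q_fungus"]),
                    "q_bacterium": float(q["q_bacterium"]),
                    "q_interaction": float(q["q_interaction"]),
                    **{
                        f"log2fc_{cond}": float(
                            expr[design.samples_of(cond)].mean() - base
                        )
                        for cond in CONDITIONS
                    },
                    "annotations": ";".join(
                        sorted(self.model.annotations.get(gene, ()))
                    ),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Tripartite community regulatory-circuit analysis")
        add("=" * 52)
        fr = self.read_fractions
        add(
            "Read attribution (mean % of aligned reads): "
            + ", ".join(
                f"{o} {fr[f'pct_{o}'].mean():.3f}%" for o in ("host", "fungus", "bacterium")
            )
        )
        add(
            f"SDE genes (alpha={self.params['alpha']}, "
            f"{self.params['sde_correction']}): {len(self.sde_genes)}"
        )
        add("  Venn: " + ", ".join(f"{k}={v}" for k, v in self.venn_counts.items()))
        sil = self.clusters.silhouette_by_k
        add(
            f"Clusters: K={self.clusters.K} "
            f"(silhouette {sil[self.clusters.K]:.3f}; "
            f"range tested {min(sil)}-{max(sil)})"
        )
        add("Cluster sizes: " + ", ".join(
            f"{c}:{n}" for c, n in self.clusters.sizes().items()
        ))
        add(
            f"Mycorrhization-correlated cluster: {self.target_cluster} "
            f"(PCC {self.phenotype_correlations[self.target_cluster]:.2f}, "
            f"z={self.target_cluster_z:.2f}, one-tailed p={self.target_cluster_p:.4f})"
        )
        add(
            f"Bayesian network: {len(self.pruned_network.edges)} edges after "
            f"pruning (score {self.network.score:.2f})"
        )
        for node, gate in sorted(self.circuit.gates.items()):
            add(
                f"  {node} <- {','.join(gate.parents) or '-'} : {gate.gate} "
                f"({gate.mismatches} mismatches)"
            )
        xor = self.xor_clusters()
        add(f"XOR-controlled clusters: {xor if xor else 'none'}")
        add(
            f"Sensor candidates (terms {self.params['sensor_terms']}): "
            f"{len(self.candidate_genes)} genes"
        )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write every stage's outputs as plain-text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import expression_matrix_to_tsv
        from .quantify import write_expression_tsv

        for sample_id, expr in self.expression.items():
            write_expression_tsv(
                expr,
                outdir / f"expression_{sample_id}.tsv",
                log2norm=self.matrix[sample_id],
            )
        expression_matrix_to_tsv(self.matrix, outdir / "log2norm_matrix.tsv")
        self.read_fractions.to_csv(outdir / "read_fractions.tsv", sep="\t")
        self.anova.table.rename_axis("gene_id").to_csv(
            outdir / "anova.tsv", sep="\t"
        )
        (outdir / "venn_counts.json").write_text(json.dumps(self.venn_counts, indent=1))
        self.clusters.assignment.rename_axis("gene_id").to_frame().to_csv(
            outdir / "cluster_assignment.tsv", sep="\t"
        )
        self.clusters.profiles.to_csv(outdir / "cluster_profiles.tsv", sep="\t")
        pd.Series(self.clusters.silhouette_by_k, name="silhouette").rename_axis(
            "K"
        ).to_frame().to_csv(outdir / "silhouette_trace.tsv", sep="\t")
        self.cluster_worksheet().to_csv(
            outdir / "cluster_worksheet.tsv", sep="\t", index=False
        )
        _enrich.write_enrichment_tsv(self.enrichment, outdir / "enrichment.tsv")
        (outdir / "network.json").write_text(
            json.dumps(_circuit.structure_to_json(self.pruned_network), indent=1)
        )
        (outdir / "circuit.dot").write_text(
            _circuit.circuit_to_dot(
                self.circuit, _circuit.cluster_node_name(self.target_cluster)
            )
        )
        _circuit.gates_to_frame(self.circuit).to_csv(
            outdir / "gates.tsv", sep="\t", index=False
        )
        self.sensor_screen.to_csv(outdir / "sensor_screen.tsv", sep="\t", index=False)
        (outdir / "params.json").write_text(json.dumps(self.params, indent=1))
        (outdir / "summary.txt").write_text(self.summary() + "\n")
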