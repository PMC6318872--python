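"""Readers, writers and lightweight containers for tripartite-community data.

The package analyses root metatranscriptomes from a laboratory community of a
host plant, an ectomycorrhizal fungus and a rhizosphere bacterium, sampled
under a 2x2 factorial design (each microbe present or absent).  This module
defines the tabular containers every analysis stage consumes:

* :class:`GeneCatalog` -- gene id, organism of origin, gene length (bp),
  read from a TSV or from GFF3 gene features.
* :class:`AlignmentTable` -- one sample's read-to-candidate-gene alignments
  (a read may align to several genes, possibly in different organisms),
  read from SAM or a simple long-format TSV.
* :class:`StudyDesign` -- sample metadata for the 2x2 factorial design.
* :class:`PhenotypeTable` -- per-condition percent mycorrhization and biomass.
* annotation maps -- gene -> set of GO biological-process terms, from a
  two-column TSV or GAF 2.x.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Set

import numpy as np
import pandas as pd

#: Canonical condition order used throughout: host alone, host + fungus,
#: host + bacterium, host + both microbes.
CONDITIONS = ("baseline", "fungus", "bacterium", "both")

ORGANISMS = ("host", "fungus", "bacterium")

_GO_RE = re.compile(r"^GO:\d{7}$")


def condition_name(fungus_present: bool, bacterium_present: bool) -> str:
    """Canonical condition label for one cell of the 2x2 design."""
    if fungus_present and bacterium_present:
        return "both"
    if fungus_present:
        return "fungus"
    if bacterium_present:
        return "bacterium"
    return "baseline"


class IntegrityError(ValueError):
    """Raised when cross-referenced tables disagree (unknown gene ids etc.)."""


@dataclass(frozen=True)
class GeneCatalog:
    """Gene models of the three community members.

    Parameters
    ----------
    frame : DataFrame indexed by gene_id with columns ``organism`` and
        ``length_bp``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if not f.index.is_unique:
            raise IntegrityError("gene ids in catalog are not unique")
        missing = {"organism", "length_bp"} - set(f.columns)
        if missing:
            raise IntegrityError(f"catalog missing columns: {sorted(missing)}")
        if (f["length_bp"] < 1).any():
            raise IntegrityError("gene lengths must be >= 1 bp")

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def lengths(self) -> pd.Series:
        return self.frame["length_bp"]

    @property
    def organisms(self) -> pd.Series:
        return self.frame["organism"]

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneCatalog":
        f = frame.copy()
        if "gene_id" in f.columns:
            f = f.set_index("gene_id")
        f["length_bp"] = f["length_bp"].astype(np.int64)
        return cls(f[["organism", "length_bp"]])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_gff3(cls, path: str | Path, feature_type: str = "gene") -> "GeneCatalog":
        """Build a catalog from GFF3 gene features.

        Gene length is ``end - start + 1`` (1-based inclusive coordinates).
        The organism label is taken from an ``organism`` attribute when
        present, otherwise from the seqid column.
        """
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        rows = []
        for feat in db.features_of_type(feature_type):
            organism = feat.attributes.get("organism", [feat.seqid])[0]
            rows.append((feat.id, organism, feat.end - feat.start + 1))
        frame = pd.DataFrame(rows, columns=["gene_id", "organism", "length_bp"])
        return cls.from_frame(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.rename_axis("gene_id").reset_index().to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class AlignmentTable:
    """One sample's read alignments in long format.

    ``frame`` has columns ``read_id`` and ``gene_id``; one row per candidate
    alignment, so a multi-mapped read contributes several rows.  The aligner
    is expected to have been run in report-all-alignments mode, so candidate
    sets are complete and mapping quality carries no information.
    """

    sample_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"read_id", "gene_id"} - set(self.frame.columns)
        if missing:
            raise IntegrityError(f"alignment table missing columns: {sorted(missing)}")

    @property
    def n_reads(self) -> int:
        return self.frame["read_id"].nunique()

    def validate_against(self, catalog: GeneCatalog) -> None:
        unknown = ~self.frame["gene_id"].isin(catalog.gene_ids)
        if unknown.any():
            bad = self.frame.loc[unknown, "gene_id"].iloc[0]
            raise IntegrityError(f"aligned gene {bad!r} absent from catalog")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "AlignmentTable":
        frame = pd.read_csv(path, sep="\t")
        if sample_id is None:
            if "sample_id" not in frame.columns:
                raise IntegrityError("no sample_id column and none supplied")
            ids = frame["sample_id"].unique()
            if len(ids) != 1:
                raise IntegrityError("alignment TSV holds multiple samples")
            sample_id = str(ids[0])
        return cls(sample_id, frame[["read_id", "gene_id"]].reset_index(drop=True))

    @classmethod
    def from_sam(cls, path: str | Path, sample_id: str) -> "AlignmentTable":
        """Read alignments from SAM/BAM; unmapped records are dropped and all
        mapped records for a read are collapsed into its candidate set."""
        import pysam

        rows = []
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                rows.append((rec.query_name, rec.reference_name))
        frame = pd.DataFrame(rows, columns=["read_id", "gene_id"]).drop_duplicates()
        return cls(sample_id, frame.reset_index(drop=True))

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["sample_id"] = self.sample_id
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class StudyDesign:
    """The 2x2 factorial sample sheet: microbe presence flags per sample."""

    frame: pd.DataFrame  # columns: sample_id, fungus, bacterium, replicate

    def __post_init__(self) -> None:
        missing = {"sample_id", "fungus", "bacterium", "replicate"} - set(
            self.frame.columns
        )
        if missing:
            raise IntegrityError(f"design missing columns: {sorted(missing)}")
        if not self.frame["sample_id"].is_unique:
            raise IntegrityError("duplicate sample ids in design")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def condition(self) -> pd.Series:
        """Per-sample condition label, indexed by sample id."""
        labels = [
            condition_name(bool(f), bool(b))
            for f, b in zip(self.frame["fungus"], self.frame["bacterium"])
        ]
        return pd.Series(labels, index=self.frame["sample_id"], name="condition")

    def samples_of(self, condition: str) -> list[str]:
        cond = self.condition
        return list(cond.index[cond == condition])

    def validate_for_anova(self) -> None:
        counts = self.condition.value_counts()
        for cond in CONDITIONS:
            if counts.get(cond, 0) < 2:
                raise IntegrityError(
                    f"condition {cond!r} has <2 replicates; two-factor ANOVA "
                    "needs every cell of the 2x2 design at least twice"
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "StudyDesign":
        frame = pd.read_csv(path)
        frame["fungus"] = frame["fungus"].astype(int)
        frame["bacterium"] = frame["bacterium"].astype(int)
        return cls(frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-condition phenotypes: percent mycorrhization and dry biomass."""

    frame: pd.DataFrame  # index: condition; columns below

    COLUMNS = ("pct_mycorrhization", "shoot_biomass_g", "root_biomass_g")

    def __post_init__(self) -> None:
        f = self.frame
        missing = set(self.COLUMNS) - set(f.columns)
        if missing:
            raise IntegrityError(f"phenotype table missing columns: {sorted(missing)}")
        pct = f["pct_mycorrhization"]
        if ((pct < 0) | (pct > 100)).any():
            raise IntegrityError("percent mycorrhization outside [0, 100]")

    @property
    def mycorrhization(self) -> pd.Series:
        return self.frame["pct_mycorrhization"]

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhenotypeTable":
        frame = pd.read_csv(path).set_index("condition")
        return cls(frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.rename_axis("condition").reset_index().to_csv(path, index=False)


AnnotationMap = Dict[str, Set[str]]


def read_annotation_tsv(path: str | Path) -> AnnotationMap:
    """Read a two-column (gene_id, term) TSV into a gene -> terms map."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="!", dtype=str)
    frame = frame.iloc[:, :2]
    frame.columns = ["gene_id", "term"]
    out: AnnotationMap = {}
    for gene, term in zip(frame["gene_id"], frame["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def read_annotation_gaf(path: str | Path, aspect: str = "P") -> AnnotationMap:
    """Read a GAF 2.x file, keeping (DB object id, GO id) pairs of one aspect.

    Columns 2 and 5 (1-based) carry the gene id and GO term; column 9 the
    ontology aspect (P = biological process).
    """
    out: AnnotationMap = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[8] != aspect:
                continue
            gene, term = cols[1], cols[4]
            out.setdefault(gene, set()).add(term)
    return out


def annotation_to_tsv(annotations: AnnotationMap, path: str | Path) -> None:
    rows = [(g, t) for g, terms in sorted(annotations.items()) for t in sorted(terms)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def validate_go_terms(annotations: AnnotationMap) -> None:
    """Check that GO-style identifiers are syntactically valid (GO:NNNNNNN)."""
    for gene, terms in annotations.items():
        for term in terms:
            if term.startswith("GO:") and not _GO_RE.match(term):
                raise IntegrityError(f"malformed GO term {term!r} on gene {gene!r}")


def expression_matrix_from_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix TSV (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def expression_matrix_to_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("gene_id").to_csv(path, sep="\t")
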