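"""Binary Gene Ontology feature vectors.

Each gene is described by three equal-length 0/1 vectors, one per GO
namespace (Molecular Function, Cellular Component, Biological Process).
Column *j* of the MF matrix is 1 for gene *i* iff the *j*-th term of the
MF term catalog is directly annotated to that gene; likewise for CC and
BP.  The three matrices share one column count ``m`` — the size of the
largest namespace catalog — with shorter catalogs zero-padded on the
right, so the three vectors of a gene are interchangeable inputs to the
same network architecture.

Only direct annotations are used: no DAG ancestor propagation, no
evidence-code filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

Namespace = Literal["MF", "CC", "BP"]
NAMESPACES: tuple[Namespace, ...] = ("MF", "CC", "BP")

#: GAF aspect code -> namespace
_ASPECT_TO_NS = {"F": "MF", "C": "CC", "P": "BP"}


class AnnotationParseError(ValueError):
    """Raised for malformed annotation rows; message names the line."""


@dataclass
class GeneAnnotation:
    """Direct GO term sets of one gene, split by namespace."""

    gene_id: str
    mf_terms: set[str] = field(default_factory=set)
    cc_terms: set[str] = field(default_factory=set)
    bp_terms: set[str] = field(default_factory=set)

    def terms(self, namespace: Namespace) -> set[str]:
        return {"MF": self.mf_terms, "CC": self.cc_terms, "BP": self.bp_terms}[namespace]


@dataclass
class TermCatalog:
    """Ordered term vocabulary of one namespace.

    ``terms`` is sorted lexicographically so the column layout of the
    feature matrices is reproducible; ``padded_length`` may exceed
    ``len(terms)`` when another namespace has a larger catalog.
    """

    namespace: Namespace
    terms: list[str]
    padded_length: int = -1

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("term catalog contains duplicates")
        if self.padded_length < 0:
            self.padded_length = len(self.terms)
        if self.padded_length < len(self.terms):
            raise ValueError("padded_length smaller than the catalog")

    def index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.terms)}


@dataclass
class FeatureMatrix:
    """Genes × m binary matrix for one namespace (CSR, dtype int8)."""

    namespace: Namespace
    gene_order: list[str]
    values: sp.csr_matrix
    catalog: TermCatalog

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        i = self.gene_order.index(gene_id)
        return np.asarray(self.values[i].todense()).ravel()


def read_annotations(path: str | Path, format: str = "tsv") -> list[GeneAnnotation]:
    """Read gene→GO annotations from a 3-column TSV or a GAF 2.x file.

    TSV rows are ``gene<TAB>namespace<TAB>term`` with namespace in
    {MF, CC, BP}.  GAF rows follow the GAF 2.x column layout: column 2
    holds the gene symbol, column 5 the GO ID, column 9 the aspect
    (F/C/P); ``!`` comment lines are skipped.  Duplicate (gene, term)
    pairs collapse; genes are returned sorted by ID.
    """
    path = Path(path)
    if format not in ("tsv", "gaf"):
        raise ValueError(f"unknown annotation format: {format!r}")
    records: dict[str, GeneAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if format == "gaf":
                if line.startswith("!"):
                    continue
                cols = line.split("\t")
                if len(cols) < 9:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: GAF row has {len(cols)} columns, need >= 9"
                    )
                gene, term, aspect = cols[1], cols[4], cols[8]
                if aspect not in _ASPECT_TO_NS:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: unknown GAF aspect {aspect!r}"
                    )
                ns = _ASPECT_TO_NS[aspect]
            else:
                cols = line.split("\t")
                if len(cols) != 3:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: expected 3 tab-separated fields, got {len(cols)}"
                    )
                gene, ns, term = (c.strip() for c in cols)
                if ns not in NAMESPACES:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: unknown namespace {ns!r} (expected MF/CC/BP)"
                    )
            if not gene or not term:
                raise AnnotationParseError(f"{path}:{lineno}: blank gene or term ID")
            rec = records.setdefault(gene, GeneAnnotation(gene))
            rec.terms(ns).add(term)  # type: ignore[arg-type]
    return [records[g] for g in sorted(records)]


def build_term_catalog(
    annotations: Sequence[GeneAnnotation], namespace: Namespace
) -> TermCatalog:
    """Union of a namespace's term sets over all genes, sorted."""
    if not annotations:
        raise ValueError("no annotations given")
    union: set[str] = set()
    for ann in annotations:
        union |= ann.terms(namespace)
    if not union:
        logger.warning("namespace %s has an empty term catalog", namespace)
    return TermCatalog(namespace=namespace, terms=sorted(union))


def build_feature_matrices(
    annotations: Sequence[GeneAnnotation], gene_order: Sequence[str]
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix]:
    """Build the MF, CC and BP matrices over ``gene_order``.

    All three share column count m = the largest catalog size; shorter
    catalogs are zero-padded on the right.  Genes without an annotation
    record get all-zero rows (the PPI graph may contain unannotated
    genes); this is logged, not fatal.
    """
    by_gene = {a.gene_id: a for a in annotations}
    missing = [g for g in gene_order if g not in by_gene]
    if missing:
        logger.info(
            "%d of %d genes have no annotation record; all-zero feature rows",
            len(missing), len(gene_order),
        )
    catalogs = {ns: build_term_catalog(annotations, ns) for ns in NAMESPACES}
    m = max(len(c.terms) for c in catalogs.values())
    out = []
    for ns in NAMESPACES:
        cat = catalogs[ns]
        cat.padded_length = m
        idx = cat.index()
        rows, cols = [], []
        for i, gene in enumerate(gene_order):
            ann = by_gene.get(gene)
            if ann is None:
                continue
            for term in ann.terms(ns):
                rows.append(i)
                cols.append(idx[term])
        values = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(len(gene_order), m),
        )
        out.append(FeatureMatrix(ns, list(gene_order), values, cat))
    return tuple(out)  # type: ignore[return-value]


def write_feature_matrix(fm: FeatureMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus gene-order and term-order sidecar TSVs."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), fm.values.tocoo(), field="integer")
    prefix.with_name(prefix.name + ".genes.tsv").write_text(
        "".join(f"{g}\n" for g in fm.gene_order)
    )
    prefix.with_name(prefix.name + ".terms.tsv").write_text(
        "".join(f"{t}\n" for t in fm.catalog.terms)
    )


def read_feature_matrix(namespace: Namespace, prefix: str | Path) -> FeatureMatrix:
    prefix = Path(prefix)
    values = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))), dtype=np.int8)
    genes = prefix.with_name(prefix.name + ".genes.tsv").read_text().splitlines()
    terms = prefix.with_name(prefix.name + ".terms.tsv").read_text().splitlines()
    cat = TermCatalog(namespace, terms, padded_length=values.shape[1])
    return FeatureMatrix(namespace, genes, values, cat)
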