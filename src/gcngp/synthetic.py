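"""Seeded synthetic datasets for the full pipeline.

The generator plants both information channels the method exploits:

* **Network channel** — an Erdős–Rényi background graph at edge
  probability ``p_out`` with a densely connected disease module at
  ``p_in`` (guilt by association: disease genes cluster in the PPI
  network).
* **Annotation channel** — per namespace, a set of enriched GO terms
  that disease genes carry with probability ``p_term_disease`` while
  background genes carry any term with probability
  ``p_term_background``.

Setting ``p_in = p_out`` ablates the network signal; equalising the
term probabilities ablates the annotation signal — each channel can be
switched off independently.  Genes are laid out at regular offsets on
``chrom_count`` chromosomes so linkage intervals are well defined.  All
outputs are plain-text files, byte-reproducible from the seed; a JSON
manifest records the planted ground truth.

A single global seed fans out to per-component substreams
(``numpy.random.SeedSequence.spawn``) so adding a generator does not
perturb existing fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .eval_stats import ScoreTable
from .go_features import NAMESPACES


@dataclass
class FixtureConfig:
    """Defaults: 300 genes, a 20-gene disease module (p_in=0.3 inside,
    p_out=0.01 background), 60 terms per namespace of which 8 are
    enriched in disease genes (carried with probability 0.6 vs 0.05
    background), 5 chromosomes."""

    n_genes: int = 300
    n_disease: int = 20
    p_in: float = 0.3
    p_out: float = 0.01
    n_terms_per_namespace: int = 60
    n_enriched_terms: int = 8
    p_term_disease: float = 0.6
    p_term_background: float = 0.05
    chrom_count: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not (0 <= self.p_term_background <= self.p_term_disease <= 1):
            raise ValueError("need 0 <= p_term_background <= p_term_disease <= 1")
        if self.n_disease >= self.n_genes:
            raise ValueError("n_disease must be < n_genes")
        if self.n_enriched_terms > self.n_terms_per_namespace:
            raise ValueError("n_enriched_terms exceeds n_terms_per_namespace")
        if self.chrom_count < 1:
            raise ValueError("chrom_count must be >= 1")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_fixture(config: FixtureConfig, out_dir: str | Path) -> dict:
    """Write annotations.tsv, ppi_edges.tsv, coordinates.tsv,
    diseases.gmt and manifest.json under ``out_dir``; return the
    manifest (planted ground truth) as a dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    rng_graph, rng_annot, rng_misc = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    genes = _gene_ids(config.n_genes)
    disease = genes[: config.n_disease]  # module membership is in the manifest
    disease_set = set(disease)

    # --- PPI: planted partition -------------------------------------------
    edges: list[tuple[str, str]] = []
    n = config.n_genes
    for i in range(n):
        for j in range(i + 1, n):
            p = (
                config.p_in
                if genes[i] in disease_set and genes[j] in disease_set
                else config.p_out
            )
            if rng_graph.random() < p:
                edges.append((genes[i], genes[j]))
    if not edges:
        raise ValueError("degenerate config produced an edge-free graph")
    covered = {g for e in edges for g in e}
    if len(covered) < n:
        # isolated genes are dropped on load; fine unless everything is isolated
        if not covered:
            raise ValueError("all genes isolated")

    # --- GO annotations ----------------------------------------------------
    enriched: dict[str, list[str]] = {}
    ann_rows: list[tuple[str, str, str]] = []
    for ns in NAMESPACES:
        terms = [
            f"GO:{ns}{t:04d}" for t in range(config.n_terms_per_namespace)
        ]
        enr = terms[: config.n_enriched_terms]
        enriched[ns] = enr
        for g in genes:
            is_dis = g in disease_set
            for t in terms:
                p = (
                    config.p_term_disease
                    if (is_dis and t in enr)
                    else config.p_term_background
                )
                if rng_annot.random() < p:
                    ann_rows.append((g, ns, t))

    # --- coordinates: regular offsets over chromosomes, shuffled order ----
    placement = rng_misc.permutation(n)
    coords: dict[str, tuple[str, int, int]] = {}
    per_chrom = int(np.ceil(n / config.chrom_count))
    gene_len, gap = 1_000, 9_000
    for slot, gi in enumerate(placement):
        chrom = f"chr{slot // per_chrom + 1}"
        pos = (slot % per_chrom) * (gene_len + gap)
        coords[genes[gi]] = (chrom, pos, pos + gene_len)

    # --- write files -------------------------------------------------------
    (out_dir / "annotations.tsv").write_text(
        "".join(f"{g}\t{ns}\t{t}\n" for g, ns, t in ann_rows)
    )
    (out_dir / "ppi_edges.tsv").write_text(
        "".join(f"{a}\t{b}\n" for a, b in edges)
    )
    (out_dir / "coordinates.tsv").write_text(
        "".join(
            f"{c}\t{s}\t{e}\t{g}\n"
            for g, (c, s, e) in sorted(coords.items())
        )
    )
    (out_dir / "diseases.gmt").write_text(
        "planted_module\tsynthetic planted disease module\t"
        + "\t".join(disease) + "\n"
    )
    manifest = {
        "config": asdict(config),
        "disease_genes": disease,
        "enriched_terms": enriched,
        "n_edges": len(edges),
        "files": {
            "annotations": "annotations.tsv",
            "ppi": "ppi_edges.tsv",
            "coordinates": "coordinates.tsv",
            "diseases": "diseases.gmt",
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one gene set per line — name, description, then genes."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ValueError(f"{path}:{lineno}: GMT row needs name, description, genes")
        sets[cols[0]] = cols[2:]
    return sets


def read_coordinates(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """BED-like TSV: chrom, start, end, gene (0-based half-open)."""
    coords: dict[str, tuple[str, int, int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ValueError(f"{path}:{lineno}: expected chrom, start, end, gene")
        coords[cols[3]] = (cols[0], int(cols[1]), int(cols[2]))
    return coords


def generate_score_table(
    n_diseases: int,
    methods: list[str],
    effect_sizes: dict[str, float],
    noise_sd: float,
    seed: int,
) -> ScoreTable:
    """Gaussian AUC-like table clipped to [0, 100] for testing the
    rank statistics; ``effect_sizes`` are per-method mean shifts around
    a baseline of 70."""
    if n_diseases < 2 or len(methods) < 2:
        raise ValueError("need >= 2 diseases and >= 2 methods")
    rng = np.random.default_rng(seed)
    base = 70.0
    mat = np.empty((n_diseases, len(methods)))
    for j, m in enumerate(methods):
        mat[:, j] = base + effect_sizes.get(m, 0.0) + rng.normal(
            0.0, noise_sd, size=n_diseases
        )
    mat = np.clip(mat, 0.0, 100.0)
    rows = [f"disease_{i + 1}" for i in range(n_diseases)]
    return ScoreTable(rows, list(methods), mat)
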