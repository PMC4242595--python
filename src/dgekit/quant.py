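"""Tag mapping, counting, TPM normalization, and saturation curves.

Observed 21-bp tags are matched against the virtual catalog allowing at
most one substitution, with exact matches taking priority (best-hit
semantics).  The 1-mismatch search enumerates the 63 single-base
variants of each observed tag against the exact-match index, which is
exact at desk scale; tags whose best hits span two or more genes are
ambiguous and discarded, mirroring unique-mapping quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dgekit.reference import TAG_LEN, TagCatalog

_BASES = "ACGT"


@dataclass
class LibraryCounts:
    """Mapping outcome of one tag library.

    ``unique_mapped_total + unmapped + ambiguous == clean_tag_total``
    exactly; malformed (wrong-length) tags are excluded from the clean
    total and tracked separately.
    """

    library_id: str
    clean_tag_total: int
    unique_mapped_total: int
    gene_counts: dict[str, int] = field(default_factory=dict)
    unmapped: int = 0
    ambiguous: int = 0
    malformed: int = 0

    def __post_init__(self):
        if self.unique_mapped_total != sum(self.gene_counts.values()):
            raise ValueError("unique_mapped_total != sum of gene counts")
        if self.unique_mapped_total + self.unmapped + self.ambiguous != self.clean_tag_total:
            raise ValueError("mapped + unmapped + ambiguous != clean_tag_total")

    def counts_series(self, gene_universe: list[str] | None = None) -> pd.Series:
        s = pd.Series(self.gene_counts, dtype=np.int64)
        if gene_universe is not None:
            s = s.reindex(gene_universe, fill_value=0)
        return s.sort_index()


def _as_tag_items(tag_list) -> list[tuple[str, int]]:
    """Normalize a tag library to (sequence, count) pairs.

    Accepts a dict/Series of counts, a list of (tag, count) pairs, or a
    plain iterable of tag strings (each counted once).
    """
    if isinstance(tag_list, pd.Series):
        return [(str(t), int(c)) for t, c in tag_list.items()]
    if isinstance(tag_list, dict):
        return [(str(t), int(c)) for t, c in tag_list.items()]
    items = list(tag_list)
    if items and isinstance(items[0], (tuple, list)):
        return [(str(t), int(c)) for t, c in items]
    out: dict[str, int] = {}
    for t in items:
        out[t] = out.get(t, 0) + 1
    return list(out.items())


def _variants(tag: str):
    for i in range(TAG_LEN):
        orig = tag[i]
        for b in _BASES:
            if b != orig:
                yield tag[:i] + b + tag[i + 1 :]


def _genes_at_best_level(tag: str, catalog: TagCatalog) -> set[str | None]:
    """Distinct gene assignments among catalog hits at the best mismatch level."""
    exact = catalog.lookup(tag)
    if exact:
        return {t.gene_id for t in exact}
    hits: set[str | None] = set()
    for v in _variants(tag):
        for t in catalog.lookup(v):
            hits.add(t.gene_id)
    return hits


def map_tags(tag_list, catalog: TagCatalog, max_mismatch: int = 1,
             library_id: str = "library") -> LibraryCounts:
    """Map a tag library to the catalog and count per gene.

    A tag is counted to a gene when all best-level hits agree on that
    single gene; hits spanning two or more distinct genes are ambiguous
    and discarded; no hit within ``max_mismatch`` substitutions (or hits
    only on gene-less catalog entries) leaves the tag unmapped.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    items = _as_tag_items(tag_list)
    gene_counts: dict[str, int] = {}
    clean = mapped = unmapped = ambiguous = malformed = 0
    for tag, count in items:
        if count < 0:
            raise ValueError("negative tag count")
        if len(tag) != TAG_LEN:
            malformed += count
            continue
        clean += count
        if max_mismatch == 0:
            genes = {t.gene_id for t in catalog.lookup(tag)}
        else:
            genes = _genes_at_best_level(tag, catalog)
        genes.discard(None)
        if len(genes) == 1:
            g = next(iter(genes))
            gene_counts[g] = gene_counts.get(g, 0) + count
            mapped += count
        elif len(genes) >= 2:
            ambiguous += count
        else:
            unmapped += count
    return LibraryCounts(
        library_id=library_id,
        clean_tag_total=clean,
        unique_mapped_total=mapped,
        gene_counts=gene_counts,
        unmapped=unmapped,
        ambiguous=ambiguous,
        malformed=malformed,
    )


def tpm_normalize(library_counts: LibraryCounts | pd.Series,
                  denominator: str | int = "unique") -> pd.Series:
    """Tags-per-million normalization of one library.

    ``denominator`` selects the library-size denominator: "unique"
    (uniquely mapped tag total, the default, matching unique-mapping
    quantification), "clean" (all clean tags), or an explicit integer.
    """
    if isinstance(library_counts, LibraryCounts):
        counts = library_counts.counts_series()
        if denominator == "unique":
            denom = library_counts.unique_mapped_total
        elif denominator == "clean":
            denom = library_counts.clean_tag_total
        else:
            denom = int(denominator)
    else:
        counts = pd.Series(library_counts, dtype=float).sort_index()
        denom = int(counts.sum()) if denominator in ("unique", "clean") else int(denominator)
    if denom <= 0:
        raise ValueError("TPM denominator must be positive")
    return counts.astype(float) * 1e6 / denom


def expression_matrix(libraries: list[LibraryCounts],
                      gene_universe: list[str] | None = None,
                      denominator: str = "unique") -> pd.DataFrame:
    """genes x libraries TPM matrix from mapped libraries."""
    if gene_universe is None:
        universe: set[str] = set()
        for lib in libraries:
            universe.update(lib.gene_counts)
        gene_universe = sorted(universe)
    cols = {}
    for lib in libraries:
        tpm = tpm_normalize(lib, denominator=denominator)
        cols[lib.library_id] = tpm.reindex(gene_universe, fill_value=0.0)
    return pd.DataFrame(cols, index=gene_universe)


def saturation_curve(tag_list, catalog: TagCatalog, n_steps: int, seed: int,
                     n_genes_total: int | None = None) -> pd.DataFrame:
    """Gene-detection saturation under subsampled sequencing depth.

    Subsamples the library without replacement at ``n_steps`` evenly
    spaced depths from 0 to the full clean-tag total and reports, per
    depth, the fraction of annotated genes with at least one uniquely
    mapped tag.  ``n_genes_total`` defaults to the number of catalog
    genes with a canonical tag.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    items = [(t, c) for t, c in _as_tag_items(tag_list) if len(t) == TAG_LEN]
    total = sum(c for _, c in items)
    if n_genes_total is None:
        n_genes_total = len(catalog.genes_with_canonical)
    if n_genes_total <= 0:
        raise ValueError("no annotated genes to detect")

    # map each distinct tag once
    tag_gene: list[str | None] = []
    for tag, _ in items:
        genes = _genes_at_best_level(tag, catalog)
        genes.discard(None)
        tag_gene.append(next(iter(genes)) if len(genes) == 1 else None)

    # expand to a per-copy gene-index array and shuffle once: the first
    # d entries are a without-replacement subsample of depth d
    gene_ids = sorted({g for g in tag_gene if g is not None})
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    expanded = np.empty(total, dtype=np.int64)
    pos = 0
    for (tag, count), g in zip(items, tag_gene):
        expanded[pos : pos + count] = gene_idx[g] if g is not None else -1
        pos += count
    rng = np.random.default_rng(seed)
    rng.shuffle(expanded)

    depths = np.unique(np.linspace(0, total, n_steps).round().astype(np.int64))
    rows = []
    seen = np.zeros(len(gene_ids), dtype=bool)
    prev = 0
    for d in depths:
        chunk = expanded[prev:d]
        seen[chunk[chunk >= 0]] = True
        prev = int(d)
        rows.append((int(d), float(seen.sum()) / n_genes_total))
    return pd.DataFrame(rows, columns=["depth", "fraction_detected"])
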