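"""Virtual NlaIII tag catalog construction.

A DGE library tags each transcript at the 3'-most NlaIII site (CATG) and
sequences the 17 bp downstream, so the mappable "virtual tag" is a 21-bp
sequence beginning with CATG.  Because CATG is palindromic, every genomic
occurrence yields a potential tag on each strand: the plus-strand tag
reads the 17 bp to the right of the site, the minus-strand tag the
reverse complement of the 17 bp to the left.
"""

from __future__ import annotations

import hashlib
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

TAG_LEN = 21
SITE = "CATG"
DOWNSTREAM = TAG_LEN - len(SITE)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VirtualTag:
    """One catalog entry: a 21-bp tag anchored at a genomic CATG site.

    ``site_position`` is the 0-based leftmost reference coordinate of the
    CATG; on the minus strand the tag spans ``[site_position - 17,
    site_position + 4)`` and its sequence is read on the reverse strand.
    """

    sequence: str
    chrom: str
    site_position: int
    strand: str
    gene_id: str | None = None
    transcript_id: str | None = None
    is_canonical: bool = False
    is_unique: bool = True

    def __post_init__(self):
        if len(self.sequence) != TAG_LEN:
            raise ValueError(f"tag length must be {TAG_LEN}")
        if not self.sequence.startswith(SITE):
            raise ValueError("tag must begin with CATG")
        if self.is_canonical and self.gene_id is None:
            raise ValueError("canonical tag requires a gene assignment")


class TagCatalog:
    """Collection of virtual tags with exact-match and gene lookups."""

    def __init__(self, tags: list[VirtualTag], genome_digest: str):
        self.tags = tags
        self.genome_digest = genome_digest
        self.index: dict[str, list[int]] = defaultdict(list)
        for i, t in enumerate(tags):
            self.index[t.sequence].append(i)
        self._canonical_by_tx = {
            t.transcript_id: t for t in tags if t.is_canonical
        }

    def __len__(self) -> int:
        return len(self.tags)

    def lookup(self, sequence: str) -> list[VirtualTag]:
        return [self.tags[i] for i in self.index.get(sequence, ())]

    def canonical_for(self, transcript_id: str) -> VirtualTag | None:
        return self._canonical_by_tx.get(transcript_id)

    @property
    def gene_ids(self) -> list[str]:
        return sorted({t.gene_id for t in self.tags if t.gene_id is not None})

    @property
    def genes_with_canonical(self) -> list[str]:
        return sorted({t.gene_id for t in self.tags if t.is_canonical})

    def no_canonical_report(self, annotation: pd.DataFrame) -> list[str]:
        """Transcripts of the annotation lacking a usable sense-strand site."""
        return sorted(
            set(annotation["transcript_id"]) - set(self._canonical_by_tx)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [t.sequence for t in self.tags],
                "chrom": [t.chrom for t in self.tags],
                "site_position": [t.site_position for t in self.tags],
                "strand": [t.strand for t in self.tags],
                "gene_id": [t.gene_id for t in self.tags],
                "transcript_id": [t.transcript_id for t in self.tags],
                "is_canonical": [t.is_canonical for t in self.tags],
                "is_unique": [t.is_unique for t in self.tags],
            }
        )

    def digest(self) -> str:
        """Checksum of the catalog contents (idempotence checks)."""
        h = hashlib.sha256()
        for t in self.tags:
            h.update(
                f"{t.sequence}\t{t.chrom}\t{t.site_position}\t{t.strand}\t"
                f"{t.gene_id}\t{t.transcript_id}\t{t.is_canonical}\n".encode()
            )
        return h.hexdigest()


def _genome_digest(genome: dict[str, str]) -> str:
    h = hashlib.sha256()
    for chrom in sorted(genome):
        h.update(chrom.encode())
        h.update(b"\x00")
        h.update(genome[chrom].encode())
    return h.hexdigest()


def _find_sites(seq: str) -> list[int]:
    """All start positions of CATG in ``seq`` (overlaps impossible)."""
    sites, start = [], 0
    while True:
        p = seq.find(SITE, start)
        if p < 0:
            return sites
        sites.append(p)
        start = p + 1


def _validate_annotation(annotation: pd.DataFrame, genome: dict[str, str]) -> pd.DataFrame:
    required = {"chrom", "start", "end", "transcript_id", "strand", "gene_id"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    for _, row in annotation.iterrows():
        if row["chrom"] not in genome:
            raise ValueError(f"annotation references unknown chromosome {row['chrom']!r}")
        L = len(genome[row["chrom"]])
        if not (0 <= row["start"] < row["end"] <= L):
            raise ValueError(
                f"transcript {row['transcript_id']} coordinates "
                f"[{row['start']}, {row['end']}) outside {row['chrom']} (len {L})"
            )
        if row["strand"] not in "+-":
            raise ValueError(f"bad strand {row['strand']!r}")
    return annotation


def build_tag_catalog(genome: dict[str, str], annotation: pd.DataFrame) -> TagCatalog:
    """Scan a genome for virtual tags and annotate them to transcripts.

    Parameters
    ----------
    genome : dict
        chromosome name -> uppercase sequence (A/C/G/T/N).
    annotation : DataFrame
        columns chrom, start, end, transcript_id, strand, gene_id
        (0-based half-open).

    For every CATG with 17 usable downstream bases on either strand one
    :class:`VirtualTag` is emitted; tags containing N are excluded.  A
    tag is assigned to a transcript (and its gene) when the full 21-mer
    lies inside the transcript on the matching strand.  The sense-strand
    tag whose site is 3'-most within each transcript is flagged
    canonical.  Uniqueness is computed over the full catalog.
    """
    annotation = _validate_annotation(annotation, genome)
    for chrom, seq in genome.items():
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{chrom}: non-ACGTN characters {sorted(bad)}")

    # raw tag sites per chromosome
    raw: list[tuple[str, str, int, str]] = []  # (sequence, chrom, pos, strand)
    for chrom in sorted(genome):
        seq = genome[chrom]
        for p in _find_sites(seq):
            if p + TAG_LEN <= len(seq):
                s = seq[p : p + TAG_LEN]
                if "N" not in s:
                    raw.append((s, chrom, p, "+"))
            if p + len(SITE) - TAG_LEN >= 0:
                s = reverse_complement(seq[p + len(SITE) - TAG_LEN : p + len(SITE)])
                if "N" not in s:
                    raw.append((s, chrom, p, "-"))

    # transcript assignment: full 21-mer within the transcript, strand match
    by_chrom_strand: dict[tuple[str, str], list[tuple[int, int, str, str]]] = defaultdict(list)
    for _, row in annotation.iterrows():
        by_chrom_strand[(row["chrom"], row["strand"])].append(
            (int(row["start"]), int(row["end"]), row["transcript_id"], row["gene_id"])
        )

    def tag_span(pos: int, strand: str) -> tuple[int, int]:
        if strand == "+":
            return pos, pos + TAG_LEN
        return pos + len(SITE) - TAG_LEN, pos + len(SITE)

    assigned: list[tuple[str, str, int, str, str | None, str | None]] = []
    for s, chrom, pos, strand in raw:
        lo, hi = tag_span(pos, strand)
        tx_id = gene_id = None
        for start, end, tid, gid in sorted(by_chrom_strand.get((chrom, strand), ())):
            if start <= lo and hi <= end:
                tx_id, gene_id = tid, gid
                break
        assigned.append((s, chrom, pos, strand, gene_id, tx_id))

    # canonical site per transcript: 3'-most sense-strand site.  On the
    # plus strand that is the largest site coordinate; on the minus
    # strand the smallest (transcription runs right to left).
    canonical_pos: dict[str, int] = {}
    for s, chrom, pos, strand, gene_id, tx_id in assigned:
        if tx_id is None:
            continue
        tx_strand = strand  # matched on strand already
        if tx_id not in canonical_pos:
            canonical_pos[tx_id] = pos
        elif tx_strand == "+" and pos > canonical_pos[tx_id]:
            canonical_pos[tx_id] = pos
        elif tx_strand == "-" and pos < canonical_pos[tx_id]:
            canonical_pos[tx_id] = pos

    seq_counts = Counter(s for s, *_ in assigned)
    tags = [
        VirtualTag(
            sequence=s,
            chrom=chrom,
            site_position=pos,
            strand=strand,
            gene_id=gene_id,
            transcript_id=tx_id,
            is_canonical=(tx_id is not None and canonical_pos.get(tx_id) == pos),
            is_unique=(seq_counts[s] == 1),
        )
        for s, chrom, pos, strand, gene_id, tx_id in assigned
    ]
    return TagCatalog(tags, _genome_digest(genome))


def canonical_tag(transcript_id: str, catalog: TagCatalog,
                  annotation: pd.DataFrame | None = None) -> VirtualTag | None:
    """The canonical (3'-most sense-strand) tag of a transcript.

    Returns None when the transcript has no usable site; raises KeyError
    for a transcript id absent from the provided annotation (or, without
    an annotation, absent from the catalog entirely).
    """
    if annotation is not None:
        if transcript_id not in set(annotation["transcript_id"]):
            raise KeyError(f"unknown transcript id {transcript_id!r}")
    tag = catalog.canonical_for(transcript_id)
    if tag is None and annotation is None:
        known = {t.transcript_id for t in catalog.tags if t.transcript_id}
        if transcript_id not in known:
            raise KeyError(f"unknown transcript id {transcript_id!r}")
    return tag
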