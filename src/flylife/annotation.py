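"""Transcript models and GTF round-tripping.

Internal coordinates are 0-based half-open intervals on the genome; GTF I/O
converts to/from the format's 1-based inclusive convention.  The 3' terminus
of a transcript sits at the highest genomic coordinate on the plus strand and
at the lowest on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["Transcript", "TranscriptCatalog", "write_gtf", "read_gtf"]


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, 0-based half-open

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty/inverted exon [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def length(self) -> int:
        """Spliced length in bp (sum of exon lengths)."""
        return sum(end - start for start, end in self.exons)

    def three_prime_walk(self) -> list[tuple[int, int]]:
        """Exons ordered from the 3' end toward the 5' end.

        On '+' the walk starts at the rightmost exon, on '-' at the leftmost.
        """
        return list(reversed(self.exons)) if self.strand == "+" else list(self.exons)


@dataclass
class TranscriptCatalog:
    """Gene model: every gene owns at least one transcript."""

    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def add(self, tx: Transcript) -> None:
        self.transcripts[tx.transcript_id] = tx

    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self.transcripts[transcript_id]

    def genes(self) -> dict[str, list[Transcript]]:
        by_gene: dict[str, list[Transcript]] = {}
        for tx in self.transcripts.values():
            by_gene.setdefault(tx.gene_id, []).append(tx)
        return by_gene

    def gene_ids(self) -> list[str]:
        return sorted({tx.gene_id for tx in self.transcripts.values()})


def write_gtf(catalog: TranscriptCatalog | Iterable[Transcript], path, header_lines=()) -> None:
    """Write exon features as GTF (1-based, inclusive, gene_id/transcript_id attributes)."""
    txs = (
        catalog.transcripts.values()
        if isinstance(catalog, TranscriptCatalog)
        else list(catalog)
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        for tx in sorted(txs, key=lambda t: (t.chrom, t.exons[0][0], t.transcript_id)):
            for start, end in tx.exons:
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            tx.chrom,
                            "flylife",
                            "exon",
                            str(start + 1),  # 0-based half-open -> 1-based inclusive
                            str(end),
                            ".",
                            tx.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_gtf(path) -> TranscriptCatalog:
    """Read exon features from a GTF file into a catalog (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        rec = grouped.setdefault(
            tid, {"gene": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        rec["exons"].append((feat.start - 1, feat.end))  # back to 0-based half-open
    catalog = TranscriptCatalog()
    for tid, rec in grouped.items():
        catalog.add(
            Transcript(
                transcript_id=tid,
                gene_id=rec["gene"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
            )
        )
    return catalog
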