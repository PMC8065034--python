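"""Genome + transcript annotation handling and splice-site extraction.

Internal coordinates are 0-based half-open throughout; anything read from or
written to GFF3/GTF is converted at the boundary (those formats are 1-based
inclusive).  "Sense" always means the transcript strand: minus-strand genes
are handled by reverse-complementing genome slices before any motif logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import gffutils
from Bio import SeqIO

from .errors import (
    AnnotationParseError,
    BoundsError,
    ConsistencyError,
    DomainError,
    UsageError,
)

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse-complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """A named chromosome/scaffold sequence (upper-case A/C/G/T/N)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AnnotationParseError(f"contig {self.name!r} has empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise AnnotationParseError(
                f"contig {self.name!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int, strand: str = "+") -> str:
        """Genome slice [start, end) on the given strand (5'->3')."""
        if start < 0 or end > len(self.sequence):
            raise BoundsError(
                f"[{start}, {end}) outside contig {self.name!r} of length {len(self)}"
            )
        s = self.sequence[start:end]
        return s if strand == "+" else revcomp(s)


@dataclass
class TranscriptModel:
    """A (protein-coding) transcript: ordered exon intervals on one contig.

    ``exons`` are 0-based half-open genomic intervals sorted in transcript
    5'->3' order, i.e. descending genomic coordinate for minus-strand
    transcripts.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationParseError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationParseError(f"{self.transcript_id}: no exons")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 >= s2:
                raise AnnotationParseError(
                    f"{self.transcript_id}: exons overlap or abut "
                    f"({s1},{e1}) vs ({s2},{e2})"
                )
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise AnnotationParseError(
                f"{self.transcript_id}: exons not in transcript 5'->3' order"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals of introns, in transcript 5'->3' order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return out


@dataclass(frozen=True)
class SpliceSite:
    """One splice donor (exon|GT-intron) or acceptor (intron-AG|exon).

    ``dinucleotide_coords`` are the 0-based genomic coordinates of the two
    intronic bases in the order they are read on the transcript sense strand
    (GT for a canonical donor, AG for a canonical acceptor).
    """

    transcript_id: str
    kind: str  # "donor" | "acceptor"
    intron_index: int  # 1-based intron ordinal
    dinucleotide_coords: tuple[int, int]
    motif: str
    canonical: bool
    flanking_exon_index: int  # 1-based exon ordinal whose boundary this is

    def __post_init__(self) -> None:
        if self.kind not in ("donor", "acceptor"):
            raise DomainError(f"unknown splice-site kind {self.kind!r}")
        expect = "GT" if self.kind == "donor" else "AG"
        if self.canonical != (self.motif == expect):
            raise ConsistencyError(
                f"canonical flag inconsistent with motif {self.motif!r} for {self.kind}"
            )


def _attr(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            vals = feature.attributes[name]
            if vals:
                return vals[0]
    return None


def parse_annotation(
    fasta_path,
    annotation_path,
    dialect: str = "gff3",
) -> tuple[dict[str, Contig], list[TranscriptModel]]:
    """Load a genome FASTA and a GFF3/GTF annotation.

    Returns contigs keyed by name and transcripts with exons in transcript
    5'->3' order.  Transcripts on contigs absent from the FASTA are dropped
    with a warning; a record with end < start raises
    :class:`AnnotationParseError` naming the offending feature.
    """
    if dialect not in ("gff3", "gtf"):
        raise UsageError(f"unknown annotation dialect {dialect!r} (gff3 or gtf)")

    contigs: dict[str, Contig] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        contigs[rec.id] = Contig(rec.id, str(rec.seq).upper())

    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # transcript-level features let GFF3 Parent chains resolve gene ids
    tx_gene: dict[str, str] = {}
    tx_biotype: dict[str, str] = {}
    for ftype in ("transcript", "mRNA"):
        for f in db.features_of_type(ftype):
            tid = _attr(f, "transcript_id", "ID") or f.id
            gid = _attr(f, "gene_id", "Parent")
            if gid:
                tx_gene[tid] = gid
            bt = _attr(f, "transcript_biotype", "biotype", "gene_biotype")
            if bt:
                tx_biotype[tid] = bt

    grouped: dict[str, dict] = {}
    for f in db.features_of_type("exon"):
        if f.end < f.start:
            raise AnnotationParseError(
                f"exon with end < start ({f.start}..{f.end}) at {f.seqid}: {f}"
            )
        tid = _attr(f, "transcript_id", "Parent")
        if tid is None:
            raise AnnotationParseError(f"exon without transcript attribute: {f}")
        gid = _attr(f, "gene_id") or tx_gene.get(tid, tid)
        info = grouped.setdefault(
            tid, {"gene": gid, "contig": f.seqid, "strand": f.strand, "exons": []}
        )
        info["exons"].append((f.start - 1, f.end))  # 1-based inclusive -> half-open

    transcripts: list[TranscriptModel] = []
    for tid, info in grouped.items():
        if info["contig"] not in contigs:
            logger.warning(
                "dropping transcript %s: contig %r not in FASTA", tid, info["contig"]
            )
            continue
        exons = sorted(info["exons"])
        if info["strand"] == "-":
            exons = exons[::-1]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene"],
                contig=info["contig"],
                strand=info["strand"],
                exons=exons,
                biotype=tx_biotype.get(tid, "protein_coding"),
            )
        )
    return contigs, transcripts


MIN_INTRON_LENGTH = 4  # below this the donor and acceptor dinucleotides overlap


def extract_splice_sites(
    transcript: TranscriptModel, contigs: Mapping[str, Contig]
) -> list[SpliceSite]:
    """One donor + one acceptor per intron, motifs read on the sense strand.

    Introns shorter than 4 nt are skipped with a warning.  Non-canonical
    motifs are returned with ``canonical=False``.
    """
    contig = contigs[transcript.contig]
    for s, e in transcript.exons:
        if s < 0 or e > len(contig):
            raise BoundsError(
                f"{transcript.transcript_id}: exon ({s},{e}) outside {contig.name}"
            )
    sites: list[SpliceSite] = []
    for i, (istart, iend) in enumerate(transcript.introns(), start=1):
        if iend - istart < MIN_INTRON_LENGTH:
            logger.warning(
                "%s: intron %d is %d nt (<%d), skipping its splice sites",
                transcript.transcript_id, i, iend - istart, MIN_INTRON_LENGTH,
            )
            continue
        if transcript.strand == "+":
            donor_coords = (istart, istart + 1)
            acceptor_coords = (iend - 2, iend - 1)
            donor_motif = contig.sequence[istart : istart + 2]
            acceptor_motif = contig.sequence[iend - 2 : iend]
        else:
            donor_coords = (iend - 1, iend - 2)
            acceptor_coords = (istart + 1, istart)
            donor_motif = revcomp(contig.sequence[iend - 2 : iend])
            acceptor_motif = revcomp(contig.sequence[istart : istart + 2])
        sites.append(
            SpliceSite(
                transcript_id=transcript.transcript_id,
                kind="donor",
                intron_index=i,
                dinucleotide_coords=donor_coords,
                motif=donor_motif,
                canonical=donor_motif == "GT",
                flanking_exon_index=i,
            )
        )
        sites.append(
            SpliceSite(
                transcript_id=transcript.transcript_id,
                kind="acceptor",
                intron_index=i,
                dinucleotide_coords=acceptor_coords,
                motif=acceptor_motif,
                canonical=acceptor_motif == "AG",
                flanking_exon_index=i + 1,
            )
        )
    return sites


def spliced_position(
    site: SpliceSite, transcript: TranscriptModel
) -> tuple[int, float]:
    """Map a splice site to spliced-mRNA coordinates.

    A donor maps to the last exonic base of its flanking exon, an acceptor to
    the first exonic base of its flanking exon.  Returns the 1-based mRNA
    offset and the percentage of the spliced transcript length.
    """
    if site.transcript_id != transcript.transcript_id:
        raise ConsistencyError(
            f"site belongs to {site.transcript_id}, not {transcript.transcript_id}"
        )
    if site.flanking_exon_index > transcript.n_exons:
        raise ConsistencyError("flanking exon index outside transcript")
    lengths = [e - s for s, e in transcript.exons]
    if site.kind == "donor":
        offset = sum(lengths[: site.flanking_exon_index])
    else:
        offset = sum(lengths[: site.flanking_exon_index - 1]) + 1
    percent = offset / transcript.spliced_length * 100.0
    return offset, percent


EXON_GROUPS = ("first", "second", "middle", "second_to_last", "last")


def exon_group(site: SpliceSite, transcript: TranscriptModel) -> str:
    """Bin the exon flanking a site: first/second/middle/second-to-last/last.

    Terminal labels take precedence (last > second_to_last > first > second >
    middle), so a 2-exon gene's exon 2 is "last", not "second".
    """
    n = transcript.n_exons
    if n < 2:
        raise DomainError("single-exon transcript has no splice sites to bin")
    idx = site.flanking_exon_index
    if idx == n:
        return "last"
    if idx == 1:
        return "first"
    if idx == n - 1:
        return "second_to_last"
    if idx == 2:
        return "second"
    return "middle"


def read_site_motif(site: SpliceSite, contigs: Mapping[str, Contig], contig_name: str) -> str:
    """Re-read a site's dinucleotide from the genome (sense strand)."""
    c1, c2 = site.dinucleotide_coords
    seq = contigs[contig_name].sequence
    if c1 < c2:  # plus-strand transcript
        return seq[c1 : c2 + 1]
    return revcomp(seq[c2 : c1 + 1])


def iter_spliced(transcript: TranscriptModel, contigs: Mapping[str, Contig]) -> str:
    """The spliced mRNA sequence (sense strand)."""
    contig = contigs[transcript.contig]
    return "".join(
        contig.slice(s, e, transcript.strand) for s, e in transcript.exons
    )
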