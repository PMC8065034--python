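"""Guide-table serialization (TSV and BED6) and FASTA/GFF3 writers.

All user-facing genomic coordinates are 1-based inclusive except BED, which
is 0-based half-open per its own convention.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import Contig, TranscriptModel
from .guide_design import GuideCandidate
from .scoring import ScoredGuide

GUIDE_TABLE_COLUMNS = [
    "gene_id",
    "transcript_ids",
    "editor",
    "site_kind",
    "intron_index",
    "exon_group",
    "protospacer",
    "pam_seq",
    "contig",
    "strand",
    "span_start",
    "span_end",
    "target_genomic_coord",
    "target_position",
    "preceding_base",
    "following_base",
    "predicted_edit",
    "bystanders",
    "in_window",
    "score",
    "passes_threshold",
    "rank",
]


def _row(guide: GuideCandidate, score=None, passes=None, rank=None) -> dict:
    s1, e1 = guide.span_1based
    return {
        "gene_id": guide.gene_id,
        "transcript_ids": ",".join(guide.transcripts),
        "editor": guide.editor,
        "site_kind": guide.site_kind,
        "intron_index": guide.site.intron_index if guide.site else None,
        "exon_group": guide.exon_group_label,
        "protospacer": guide.protospacer,
        "pam_seq": guide.pam_seq,
        "contig": guide.contig,
        "strand": guide.strand,
        "span_start": s1,
        "span_end": e1,
        "target_genomic_coord": guide.target_coord_1based,
        "target_position": guide.target_position,
        "preceding_base": guide.preceding_base,
        "following_base": guide.following_base,
        "predicted_edit": guide.predicted_edit,
        "bystanders": ";".join(f"{p}:{c + 1}" for p, c in guide.bystanders),
        "in_window": guide.in_window,
        "score": score,
        "passes_threshold": passes,
        "rank": rank,
    }


def guides_to_dataframe(
    guides: Sequence[GuideCandidate] | Sequence[ScoredGuide],
) -> pd.DataFrame:
    rows = []
    for g in guides:
        if isinstance(g, ScoredGuide):
            rows.append(_row(g.guide, g.score, g.passes_threshold, g.rank))
        else:
            rows.append(_row(g))
    return pd.DataFrame(rows, columns=GUIDE_TABLE_COLUMNS)


def write_guide_table(
    guides: Sequence[GuideCandidate] | Sequence[ScoredGuide],
    path,
    format: str = "tsv",
) -> None:
    """Write guides as a fixed-column TSV or a BED6 of protospacer spans."""
    if format == "tsv":
        guides_to_dataframe(guides).to_csv(path, sep="\t", index=False)
        return
    if format != "bed":
        raise ValueError(f"unknown guide-table format {format!r}")
    lines = []
    for g in guides:
        score = round(g.score) if isinstance(g, ScoredGuide) else 0
        guide = g.guide if isinstance(g, ScoredGuide) else g
        name = "|".join(
            str(x)
            for x in (
                guide.gene_id or ".",
                guide.editor,
                guide.site_kind or ".",
                guide.target_position,
            )
        )
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    guide.contig,
                    guide.span[0],
                    guide.span[1],
                    name,
                    score,
                    guide.strand,
                )
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_guide_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(contigs: Mapping[str, Contig] | Iterable[Contig], path) -> None:
    if isinstance(contigs, Mapping):
        contigs = contigs.values()
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.name}\n")
            for i in range(0, len(c.sequence), 60):
                fh.write(c.sequence[i : i + 60] + "\n")


def write_gff3(transcripts: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        seen_genes = set()
        for tx in transcripts:
            gstart = min(s for s, _ in tx.exons) + 1
            gend = max(e for _, e in tx.exons)
            if tx.gene_id not in seen_genes:
                seen_genes.add(tx.gene_id)
                fh.write(
                    f"{tx.contig}\tbesplice\tgene\t{gstart}\t{gend}\t.\t"
                    f"{tx.strand}\t.\tID={tx.gene_id}\n"
                )
            fh.write(
                f"{tx.contig}\tbesplice\tmRNA\t{gstart}\t{gend}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id};Parent={tx.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(tx.exons), start=1):
                fh.write(
                    f"{tx.contig}\tbesplice\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id};"
                    f"gene_id={tx.gene_id};transcript_id={tx.transcript_id}\n"
                )
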