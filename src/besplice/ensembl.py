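"""Optional network adapter: fetch transcript structure from Ensembl REST.

Convenience for interactive use only — requires network access and is never
exercised by the test suite. Everything else in the package works from local
FASTA + GFF3/GTF files.
"""

from __future__ import annotations

import json
import urllib.request

from .annotation import TranscriptModel

REST_BASE = "https://rest.ensembl.org"


def fetch_transcript(transcript_id: str, timeout: float = 30.0) -> TranscriptModel:
    """Look up one Ensembl transcript ID and build a TranscriptModel.

    Exon coordinates are converted from Ensembl's 1-based inclusive
    convention to the package's 0-based half-open intervals, ordered
    transcript 5'->3'.
    """
    url = f"{REST_BASE}/lookup/id/{transcript_id}?expand=1;content-type=application/json"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = json.load(resp)
    strand = "+" if data.get("strand", 1) >= 0 else "-"
    exons = sorted((e["start"] - 1, e["end"]) for e in data["Exon"])
    if strand == "-":
        exons = exons[::-1]
    return TranscriptModel(
        transcript_id=data["id"],
        gene_id=data.get("Parent", data["id"]),
        contig=str(data["seq_region_name"]),
        strand=strand,
        exons=exons,
        biotype=data.get("biotype", "protein_coding"),
    )
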