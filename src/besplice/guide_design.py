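"""Enumeration of base-editor sgRNAs that disrupt splice sites.

The editable base for each editor x site-kind combination is fixed by the
GT/AG motif chemistry: a cytidine editor (C->T) reaches the donor or acceptor
G only through its complementary C on the opposite strand, an adenosine
editor (A->G) reaches the donor T through its complementary A (antisense) and
the acceptor A directly on the sense strand.  Protospacer positions are
1-based from the 5' (PAM-distal) end; only 3'-PAM (Cas9-family) geometry is
supported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .annotation import (
    Contig,
    SpliceSite,
    TranscriptModel,
    exon_group,
    revcomp,
    spliced_position,
)
from .errors import ConfigError, ConsistencyError, DomainError, EmptyInputError

_COMP = str.maketrans("ACGTN", "TGCAN")

IUPAC = {k: set(v) for k, v in ambiguous_dna_values.items() if k != "X"}
IUPAC["N"] = set("ACGT")  # an N in the genome never satisfies a PAM


@dataclass(frozen=True)
class EditorSpec:
    """A base editor + PAM configuration.

    ``window`` is the inclusive protospacer-position interval of high
    deaminase activity; it annotates and scores guides but never filters the
    enumeration.
    """

    name: str
    edited_base: str  # "C" (CBE) or "A" (ABE)
    protospacer_length: int = 20
    pam: str = "NGG"
    window: tuple[int, int] = (4, 8)

    def __post_init__(self) -> None:
        if self.edited_base not in ("C", "A"):
            raise ConfigError(
                f"unsupported edited base {self.edited_base!r} (need C or A)"
            )
        bad = set(self.pam.upper()) - set(IUPAC)
        if bad:
            raise ConfigError(f"PAM {self.pam!r} has non-IUPAC characters {sorted(bad)}")
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.protospacer_length):
            raise ConfigError(
                f"window {self.window} outside 1..{self.protospacer_length}"
            )

    @property
    def conversion(self) -> tuple[str, str]:
        return ("C", "T") if self.edited_base == "C" else ("A", "G")


BE4 = EditorSpec("BE4", "C")
ABE710 = EditorSpec("ABE7.10", "A")
ABE8E = EditorSpec("ABE8e", "A")


@dataclass
class GuideCandidate:
    """One protospacer/PAM placement whose edit hits a splice-site base.

    ``span`` is the 0-based half-open genomic interval of the protospacer on
    the plus strand of the contig; ``strand`` is the genomic strand the
    protospacer (and hence the edited base) lies on.  ``preceding_base`` /
    ``following_base`` are read on the protospacer strand and fall back to
    the flanking genomic base when the target sits at a protospacer end.
    """

    editor: str
    edited_base: str
    contig: str
    strand: str
    span: tuple[int, int]
    protospacer: str
    pam_seq: str
    target_position: int
    target_coord: int  # 0-based genomic
    preceding_base: str | None
    following_base: str | None
    bystanders: list[tuple[int, int]]  # (protospacer position, 0-based coord)
    in_window: bool
    site: SpliceSite | None = None
    site_kind: str | None = None
    predicted_edit: str | None = None
    gene_id: str | None = None
    transcripts: list[str] = field(default_factory=list)
    mrna_offset: int | None = None
    mrna_percent: float | None = None
    exon_group_label: str | None = None

    @property
    def span_1based(self) -> tuple[int, int]:
        return (self.span[0] + 1, self.span[1])

    @property
    def target_coord_1based(self) -> int:
        return self.target_coord + 1

    def placement_key(self) -> tuple:
        """Identity of the physical placement, independent of annotation."""
        return (
            self.editor,
            self.strand,
            self.span,
            self.target_position,
            self.protospacer,
            self.pam_seq,
        )


def pam_matches(pam_seq: str, pam_pattern: str) -> bool:
    if len(pam_seq) != len(pam_pattern):
        return False
    return all(
        b != "N" and b in IUPAC[p] for b, p in zip(pam_seq, pam_pattern.upper())
    )


def splice_target(site: SpliceSite, transcript_strand: str) -> dict[str, tuple[int, str]]:
    """The editable base (0-based coord, genomic strand) per edited base.

    Donor GT: the C complementary to G and the A complementary to T both sit
    on the transcript-antisense strand.  Acceptor AG: the C complementary to
    G is antisense; the A itself is sense.
    """
    flip = {"+": "-", "-": "+"}
    c_first, c_second = site.dinucleotide_coords
    if site.kind == "donor":
        return {
            "C": (c_first, flip[transcript_strand]),
            "A": (c_second, flip[transcript_strand]),
        }
    return {
        "C": (c_second, flip[transcript_strand]),
        "A": (c_first, transcript_strand),
    }


def _protospacer_coord(strand: str, span: tuple[int, int], position: int) -> int:
    """Genomic 0-based coord of protospacer ``position`` (1-based from 5')."""
    lo, hi = span
    return lo + position - 1 if strand == "+" else hi - position


def _build_candidate(
    contig: Contig,
    editor: EditorSpec,
    strand: str,
    lo: int,
    target_position: int,
    target_coord: int,
) -> GuideCandidate | None:
    """Assemble one placement; None if out of bounds or overlapping N."""
    L, P = editor.protospacer_length, len(editor.pam)
    hi = lo + L
    if strand == "+":
        pam_lo, pam_hi = hi, hi + P
    else:
        pam_lo, pam_hi = lo - P, lo
    if min(lo, pam_lo) < 0 or max(hi, pam_hi) > len(contig):
        return None
    protospacer = contig.slice(lo, hi, strand)
    pam_seq = contig.slice(pam_lo, pam_hi, strand)
    if "N" in protospacer or not pam_matches(pam_seq, editor.pam):
        return None
    if protospacer[target_position - 1] != editor.edited_base:
        return None

    def context(pos: int) -> str | None:
        if 1 <= pos <= L:
            return protospacer[pos - 1]
        coord = _protospacer_coord(strand, (lo, hi), pos)
        if not (0 <= coord < len(contig)):
            return None
        base = contig.sequence[coord]
        return base if strand == "+" else base.translate(_COMP)

    wlo, whi = editor.window
    bystanders = [
        (p, _protospacer_coord(strand, (lo, hi), p))
        for p in range(wlo, whi + 1)
        if p != target_position and protospacer[p - 1] == editor.edited_base
    ]
    return GuideCandidate(
        editor=editor.name,
        edited_base=editor.edited_base,
        contig=contig.name,
        strand=strand,
        span=(lo, hi),
        protospacer=protospacer,
        pam_seq=pam_seq,
        target_position=target_position,
        target_coord=target_coord,
        preceding_base=context(target_position - 1),
        following_base=context(target_position + 1),
        bystanders=bystanders,
        in_window=wlo <= target_position <= whi,
    )


def _predicted_edit(
    editor: EditorSpec, target_coord: int, guide_strand: str, transcript_strand: str
) -> str:
    ref, alt = editor.conversion
    if guide_strand != transcript_strand:
        ref, alt = ref.translate(_COMP), alt.translate(_COMP)
    return f"{ref}{target_coord + 1}>{alt}"


def design_guides(
    sites: Iterable[SpliceSite],
    editor: EditorSpec,
    contigs: Mapping[str, Contig],
    transcripts: Sequence[TranscriptModel],
    include_noncanonical: bool = False,
) -> list[GuideCandidate]:
    """Enumerate every protospacer placement editing a splice-site base.

    All target positions 1..L are enumerated; window membership is recorded,
    not filtered.  Identical placements shared between transcripts are merged
    with their transcript ids accumulated (the earliest spliced-mRNA offset
    is kept for ranking).
    """
    tx_by_id = {t.transcript_id: t for t in transcripts}
    L = editor.protospacer_length
    merged: dict[tuple, GuideCandidate] = {}
    for site in sites:
        if not site.canonical and not include_noncanonical:
            continue
        tx = tx_by_id.get(site.transcript_id)
        if tx is None:
            raise ConsistencyError(f"no transcript {site.transcript_id!r} supplied")
        contig = contigs[tx.contig]
        target_coord, target_strand = splice_target(site, tx.strand)[editor.edited_base]
        for k in range(1, L + 1):
            lo = target_coord - k + 1 if target_strand == "+" else target_coord + k - L
            cand = _build_candidate(contig, editor, target_strand, lo, k, target_coord)
            if cand is None:
                continue
            offset, percent = spliced_position(site, tx)
            cand.site = site
            cand.site_kind = site.kind
            cand.predicted_edit = _predicted_edit(
                editor, target_coord, target_strand, tx.strand
            )
            cand.gene_id = tx.gene_id
            cand.transcripts = [tx.transcript_id]
            cand.mrna_offset = offset
            cand.mrna_percent = percent
            cand.exon_group_label = (
                exon_group(site, tx) if tx.n_exons >= 2 else None
            )
            key = (cand.contig, cand.strand, cand.span, cand.target_coord)
            if key in merged:
                prev = merged[key]
                if tx.transcript_id not in prev.transcripts:
                    prev.transcripts.append(tx.transcript_id)
                if offset < (prev.mrna_offset if prev.mrna_offset is not None else offset + 1):
                    prev.mrna_offset, prev.mrna_percent = offset, percent
            else:
                merged[key] = cand
    out = list(merged.values())
    out.sort(key=lambda g: (g.contig, g.span, g.strand, g.target_position))
    for g in out:
        g.transcripts.sort()
    return out


def enumerate_bystanders(
    guide: GuideCandidate, editor: EditorSpec
) -> list[tuple[int, int]]:
    """Editable bases inside the activity window other than the target."""
    wlo, whi = editor.window
    return [
        (p, _protospacer_coord(guide.strand, guide.span, p))
        for p in range(wlo, whi + 1)
        if p != guide.target_position
        and guide.protospacer[p - 1] == editor.edited_base
    ]


def simulate_edit(
    guide: GuideCandidate,
    contigs: Mapping[str, Contig],
    edit_positions: str = "target_only",
) -> tuple[str, bool]:
    """Apply the editor's transition in silico and test splice-site loss.

    Returns the edited protospacer-region sequence read on the transcript
    sense strand and whether the canonical GT/AG dinucleotide was destroyed.
    """
    if edit_positions not in ("target_only", "full_window"):
        raise DomainError(f"edit_positions {edit_positions!r}")
    if guide.site is None:
        raise ConsistencyError("guide carries no splice site")
    contig = contigs[guide.contig]
    seq = list(contig.sequence)
    alt = "T" if guide.edited_base == "C" else "G"
    coords = [guide.target_coord]
    if edit_positions == "full_window":
        coords += [c for _, c in guide.bystanders]
    for c in coords:
        if guide.strand == "+":
            seq[c] = alt
        else:
            seq[c] = alt.translate(_COMP)
    edited = "".join(seq)

    c1, c2 = guide.site.dinucleotide_coords
    if c1 < c2:  # plus-strand transcript
        motif = edited[c1 : c2 + 1]
        local = edited[guide.span[0] : guide.span[1]]
    else:
        motif = revcomp(edited[c2 : c1 + 1])
        local = revcomp(edited[guide.span[0] : guide.span[1]])
    expected = "GT" if guide.site.kind == "donor" else "AG"
    return local, motif != expected


def brute_force_scan(
    contig: Contig,
    editor: EditorSpec,
    target_coord: int,
    target_strand: str,
) -> list[GuideCandidate]:
    """Independent oracle: naive full-contig sweep of both strands.

    Slides an (L+|PAM|)-mer over every offset of both strands, tests the PAM
    against the explicitly expanded IUPAC string set, and keeps placements
    whose protospacer covers the target base.  Output placements must match
    :func:`design_guides` on the same site.
    """
    base = contig.sequence[target_coord]
    if target_strand == "-":
        base = base.translate(_COMP)
    if base != editor.edited_base:
        raise DomainError(
            f"target base {base!r} at {target_coord} ({target_strand}) is not "
            f"{editor.edited_base!r}"
        )
    L, P = editor.protospacer_length, len(editor.pam)
    pam_set = {
        "".join(p)
        for p in itertools.product(*(sorted(IUPAC[c]) for c in editor.pam.upper()))
    }
    n = len(contig)
    out: list[GuideCandidate] = []

    # plus strand
    for lo in range(0, n - L - P + 1):
        proto = contig.sequence[lo : lo + L]
        pam = contig.sequence[lo + L : lo + L + P]
        if "N" in proto or pam not in pam_set:
            continue
        if target_strand == "+" and lo <= target_coord < lo + L:
            k = target_coord - lo + 1
            if proto[k - 1] == editor.edited_base:
                cand = _build_candidate(contig, editor, "+", lo, k, target_coord)
                if cand is not None:
                    out.append(cand)

    # minus strand: index j on the reverse complement maps to genomic n-1-j
    rc = revcomp(contig.sequence)
    for j in range(0, n - L - P + 1):
        proto = rc[j : j + L]
        pam = rc[j + L : j + L + P]
        if "N" in proto or pam not in pam_set:
            continue
        if target_strand == "-":
            jt = n - 1 - target_coord
            if j <= jt < j + L:
                k = jt - j + 1
                if proto[k - 1] == editor.edited_base:
                    lo = n - (j + L)
                    cand = _build_candidate(contig, editor, "-", lo, k, target_coord)
                    if cand is not None:
                        out.append(cand)

    out.sort(key=lambda g: (g.contig, g.span, g.strand, g.target_position))
    return out


PENTA_OFFSETS = (-2, -1, 0, 1, 2)


def pentanucleotide_motif(guides: Sequence[GuideCandidate]) -> pd.DataFrame:
    """Base frequencies at protospacer offsets -2..+2 around the target.

    Offsets that fall outside the protospacer are excluded from that
    column's denominator, so every column sums to 1.
    """
    if not guides:
        raise EmptyInputError("pentanucleotide motif needs at least one guide")
    counts = pd.DataFrame(0.0, index=list("ACGT"), columns=list(PENTA_OFFSETS))
    for g in guides:
        L = len(g.protospacer)
        for off in PENTA_OFFSETS:
            p = g.target_position + off
            if 1 <= p <= L:
                counts.loc[g.protospacer[p - 1], off] += 1
    return counts / counts.sum(axis=0)
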