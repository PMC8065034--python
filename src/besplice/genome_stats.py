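"""Genome-scale targetability summaries.

Answers, for a transcript set and a list of editor/PAM configurations: how
many genes undergo splicing, what fraction of those can be hit by at least
one splice-disrupting guide, how many distinct guides each gene has, and how
early in the spliced mRNA the first guide falls.  Works identically on a
whole annotated genome or on synthetic fixture genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation import Contig, TranscriptModel, extract_splice_sites
from .errors import EmptyInputError
from .guide_design import EditorSpec, GuideCandidate, design_guides


@dataclass
class TargetabilitySummary:
    n_genes: int
    n_spliced_genes: int
    n_targetable_spliced_genes: int
    fraction_spliced_targetable: float | None  # None when no spliced genes
    guides_per_gene: dict[str, int]
    first_guide_percent: dict[str, float]  # per targetable gene
    editor_specs: list[str] = field(default_factory=list)
    guides_by_gene: dict[str, list[GuideCandidate]] = field(default_factory=dict)


def _dedup_key(g: GuideCandidate) -> tuple:
    # PAM identity deliberately excluded so overlapping PAM sets (NGG within
    # NG) do not double-count the same physical placement.
    return (g.edited_base, g.contig, g.strand, g.span, g.target_coord)


def targetability_summary(
    transcripts: Sequence[TranscriptModel],
    editor_specs: Sequence[EditorSpec],
    contigs: Mapping[str, Contig],
    include_noncanonical: bool = False,
) -> TargetabilitySummary:
    """Per-gene guide counts and the spliced-gene targetable fraction.

    A gene is *spliced* iff any of its transcripts has >= 2 exons, and
    *targetable* iff at least one guide exists across all supplied editor
    specs; guides are deduplicated per gene across transcripts and specs.
    """
    if not transcripts:
        raise EmptyInputError("no transcripts supplied")
    genes: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        genes.setdefault(tx.gene_id, []).append(tx)

    guides_per_gene: dict[str, int] = {}
    first_pct: dict[str, float] = {}
    guides_by_gene: dict[str, list[GuideCandidate]] = {}
    n_spliced = 0
    n_targetable = 0
    for gene_id, txs in genes.items():
        spliced = any(t.n_exons >= 2 for t in txs)
        if not spliced:
            continue
        n_spliced += 1
        seen: dict[tuple, GuideCandidate] = {}
        for spec in editor_specs:
            sites = [s for t in txs for s in extract_splice_sites(t, contigs)]
            for g in design_guides(sites, spec, contigs, txs, include_noncanonical):
                key = _dedup_key(g)
                if key not in seen:
                    seen[key] = g
                elif g.mrna_percent is not None and (
                    seen[key].mrna_percent is None
                    or g.mrna_percent < seen[key].mrna_percent
                ):
                    seen[key] = g
        gene_guides = list(seen.values())
        guides_per_gene[gene_id] = len(gene_guides)
        guides_by_gene[gene_id] = gene_guides
        if gene_guides:
            n_targetable += 1
            first_pct[gene_id] = min(
                g.mrna_percent for g in gene_guides if g.mrna_percent is not None
            )
    return TargetabilitySummary(
        n_genes=len(genes),
        n_spliced_genes=n_spliced,
        n_targetable_spliced_genes=n_targetable,
        fraction_spliced_targetable=(
            n_targetable / n_spliced if n_spliced else None
        ),
        guides_per_gene=guides_per_gene,
        first_guide_percent=first_pct,
        editor_specs=[f"{s.name}/{s.pam}" for s in editor_specs],
        guides_by_gene=guides_by_gene,
    )


def first_guide_positions(summary: TargetabilitySummary) -> dict[str, float]:
    """Quartiles of the per-gene earliest guide position (% of mRNA).

    Linear-interpolation (type-7) quantiles of each targetable gene's
    minimum spliced-position percentage.
    """
    if not summary.first_guide_percent:
        raise EmptyInputError("no targetable genes")
    vals = np.array(sorted(summary.first_guide_percent.values()))
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"q1": float(q1), "median": float(med), "q3": float(q3)}


def guides_per_gene_quantiles(summary: TargetabilitySummary) -> dict[str, float]:
    if not summary.guides_per_gene:
        raise EmptyInputError("no spliced genes")
    vals = np.array(sorted(summary.guides_per_gene.values()))
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"q1": float(q1), "median": float(med), "q3": float(q3)}


def format_report(summary: TargetabilitySummary) -> str:
    """Human-readable targetability report."""
    lines = [
        f"editor specs: {', '.join(summary.editor_specs)}",
        f"genes: {summary.n_genes}",
        f"spliced genes: {summary.n_spliced_genes}",
        f"targetable spliced genes: {summary.n_targetable_spliced_genes}",
    ]
    if summary.fraction_spliced_targetable is not None:
        lines.append(
            "fraction of spliced genes targetable: "
            f"{summary.fraction_spliced_targetable:.4f}"
        )
    else:
        lines.append("fraction of spliced genes targetable: n/a (no spliced genes)")
    if summary.first_guide_percent:
        fq = first_guide_positions(summary)
        gq = guides_per_gene_quantiles(summary)
        lines.append(f"guides per gene (q1/median/q3): {gq['q1']}/{gq['median']}/{gq['q3']}")
        lines.append(
            "first-guide mRNA position % (q1/median/q3): "
            f"{fq['q1']:.2f}/{fq['median']:.2f}/{fq['q3']:.2f}"
        )
    return "\n".join(lines)
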