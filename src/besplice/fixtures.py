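"""Deterministic synthetic data: genes with canonical splice sites and
meta-analysis tables with planted context/position effects.

Gene fixtures plant the canonical GT..AG intron motifs (GTAAGT consensus
when the intron has room) and, per splice site and editor, a Poisson number
of PAM-enabling dinucleotides, so the expected guide yield is controllable.
With ``pam_density=0`` the whole contig is sampled without any GG or CC
dinucleotide, which provably leaves no NGG placement on either strand.
Ground truth guide lists always come from the brute-force oracle, never from
the production enumeration path.

Meta-table fixtures draw raw editing values as
``study_amplitude x context_multiplier x window_shape(position) + noise``
clamped to [0, 100], mirroring the structure of a cross-study literature
meta-analysis (per-study scale differences, a bell-shaped activity window,
preceding-base effects, and a fraction of guides entered by two studies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Contig, SpliceSite, TranscriptModel, extract_splice_sites
from .errors import ConfigError
from .guide_design import (
    ABE710,
    BE4,
    EditorSpec,
    GuideCandidate,
    IUPAC,
    brute_force_scan,
    splice_target,
)

_COMP = str.maketrans("ACGTN", "TGCAN")

# ---------------------------------------------------------------------------
# FIX1: the 60-nt hand-built worked example (static, not generated)

FIX1_SEQUENCE = "ATGGCTAGCTAGACCATTCAGGAGCTGAAGGTAAGTCTTTCTCTCTCTAGGATCCAAATG"
FIX1_CONTIG_NAME = "chrT"
FIX1_TRANSCRIPT_ID = "TX1"
FIX1_GENE_ID = "GENE1"


def fix1_contig() -> Contig:
    return Contig(FIX1_CONTIG_NAME, FIX1_SEQUENCE)


def fix1_transcript() -> TranscriptModel:
    # exons 1-30 and 51-60 in 1-based inclusive coordinates
    return TranscriptModel(
        transcript_id=FIX1_TRANSCRIPT_ID,
        gene_id=FIX1_GENE_ID,
        contig=FIX1_CONTIG_NAME,
        strand="+",
        exons=[(0, 30), (50, 60)],
    )


def fix1_sites() -> list[SpliceSite]:
    return extract_splice_sites(fix1_transcript(), {FIX1_CONTIG_NAME: fix1_contig()})


# ---------------------------------------------------------------------------
# gene fixtures


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for one synthetic gene."""

    n_exons: int = 4
    exon_length: tuple[int, int] = (30, 80)
    intron_length: tuple[int, int] = (24, 60)
    flank_length: tuple[int, int] = (25, 40)
    pam_density: float = 1.0  # expected planted PAM placements / site / editor
    plant_noncanonical: bool = False
    strand: str = "+"
    editor_specs: tuple[EditorSpec, ...] = (BE4, ABE710)

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise ConfigError("n_exons must be >= 1")
        for name, (lo, hi) in (
            ("exon_length", self.exon_length),
            ("intron_length", self.intron_length),
            ("flank_length", self.flank_length),
        ):
            if lo > hi or lo < 1:
                raise ConfigError(f"bad {name} range ({lo}, {hi})")
        if self.intron_length[0] < 6:
            raise ConfigError("introns must be >= 6 nt to hold both motifs")
        if self.pam_density < 0:
            raise ConfigError("pam_density must be >= 0")
        if self.strand not in "+-":
            raise ConfigError("strand must be '+' or '-'")


@dataclass
class FixtureTruth:
    """A generated gene plus oracle-computed ground truth."""

    config: FixtureConfig
    seed: int
    contig: Contig
    transcript: TranscriptModel
    sites: list[SpliceSite]
    truth: dict[str, list[GuideCandidate]]  # editor name -> oracle guides

    def to_fasta(self) -> str:
        seq = self.contig.sequence
        lines = [f">{self.contig.name}"]
        lines += [seq[i : i + 60] for i in range(0, len(seq), 60)]
        return "\n".join(lines) + "\n"

    def to_gff3(self) -> str:
        tx = self.transcript
        lines = ["##gff-version 3"]
        gstart = min(s for s, _ in tx.exons) + 1
        gend = max(e for _, e in tx.exons)
        lines.append(
            f"{tx.contig}\tfixture\tgene\t{gstart}\t{gend}\t.\t{tx.strand}\t.\t"
            f"ID={tx.gene_id}"
        )
        lines.append(
            f"{tx.contig}\tfixture\tmRNA\t{gstart}\t{gend}\t.\t{tx.strand}\t.\t"
            f"ID={tx.transcript_id};Parent={tx.gene_id}"
        )
        for i, (s, e) in enumerate(sorted(tx.exons), start=1):
            lines.append(
                f"{tx.contig}\tfixture\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id};"
                f"gene_id={tx.gene_id};transcript_id={tx.transcript_id}"
            )
        return "\n".join(lines) + "\n"


def _sample_bases(rng: np.random.Generator, n: int, prev: str, no_gg_cc: bool,
                  avoid_last: str = "") -> str:
    """Random bases; optionally never forming GG or CC with the previous base."""
    out = []
    for i in range(n):
        choices = "ACGT"
        if no_gg_cc and prev in "GC":
            choices = choices.replace(prev, "")
        if i == n - 1 and avoid_last:
            choices = "".join(c for c in choices if c not in avoid_last) or choices
        b = choices[int(rng.integers(len(choices)))]
        out.append(b)
        prev = b
    return "".join(out)


def make_fixture_gene(
    config: FixtureConfig, seed: int, contig_name: str = "ctg1",
    gene_id: str = "GENE_F", transcript_id: str = "TX_F",
    compute_truth: bool = True,
) -> FixtureTruth:
    """One synthetic gene with oracle-verified guide truth.

    Reproducible: the same (config, seed) always yields a byte-identical
    contig and truth.
    """
    rng = np.random.default_rng(seed)
    no_gg_cc = config.pam_density == 0
    donor_motif = "GC" if config.plant_noncanonical else "GT"

    parts: list[str] = []
    exon_coords: list[tuple[int, int]] = []
    pos = 0
    prev = ""

    flank5 = _sample_bases(rng, int(rng.integers(*config.flank_length, endpoint=True)),
                           prev, no_gg_cc)
    parts.append(flank5)
    pos += len(flank5)
    prev = flank5[-1] if flank5 else ""

    for i in range(config.n_exons):
        elen = int(rng.integers(*config.exon_length, endpoint=True))
        # the next fixed base is the donor G: avoid creating GG in no-PAM mode
        avoid = "G" if (no_gg_cc and i < config.n_exons - 1) else ""
        exon = _sample_bases(rng, elen, prev, no_gg_cc, avoid_last=avoid)
        parts.append(exon)
        exon_coords.append((pos, pos + elen))
        pos += elen
        prev = exon[-1]
        if i < config.n_exons - 1:
            ilen = int(rng.integers(*config.intron_length, endpoint=True))
            if ilen >= 8:
                head = donor_motif + "AAGT"
            else:
                head = donor_motif
            mid = _sample_bases(rng, ilen - len(head) - 2, head[-1], no_gg_cc,
                                avoid_last="")
            intron = head + mid + "AG"
            parts.append(intron)
            pos += ilen
            prev = "G"

    flank3 = _sample_bases(rng, int(rng.integers(*config.flank_length, endpoint=True)),
                           prev, no_gg_cc)
    parts.append(flank3)
    seq = list("".join(parts))

    transcript = TranscriptModel(
        transcript_id=transcript_id, gene_id=gene_id, contig=contig_name,
        strand="+", exons=exon_coords,
    )
    contig = Contig(contig_name, "".join(seq))
    sites = extract_splice_sites(transcript, {contig_name: contig})

    # protect the splice-site dinucleotides from PAM planting
    protected = {c for s in sites for c in s.dinucleotide_coords}

    if config.pam_density > 0:
        for site in sites:
            for spec in config.editor_specs:
                n_plant = int(rng.poisson(config.pam_density))
                if n_plant == 0:
                    continue
                t, strand = splice_target(site, "+")[spec.edited_base]
                ks = rng.permutation(np.arange(1, spec.protospacer_length + 1))
                planted = 0
                for k in ks:
                    if planted >= n_plant:
                        break
                    k = int(k)
                    L, P = spec.protospacer_length, len(spec.pam)
                    if strand == "+":
                        lo = t - k + 1
                        pam_coords = [lo + L + i for i in range(P)]
                    else:
                        lo = t + k - L
                        pam_coords = [lo - 1 - i for i in range(P)]
                    span_ok = 0 <= min(pam_coords + [lo]) and max(
                        pam_coords + [lo + L - 1]
                    ) < len(seq)
                    if not span_ok or any(c in protected for c in pam_coords):
                        continue
                    for c, pam_char in zip(pam_coords, spec.pam.upper()):
                        allowed = IUPAC[pam_char]
                        current = seq[c] if strand == "+" else seq[c].translate(_COMP)
                        if current not in allowed:
                            want = sorted(allowed)[0]
                            seq[c] = want if strand == "+" else want.translate(_COMP)
                        protected.add(c)
                    planted += 1

    final = "".join(seq)
    exons = exon_coords
    tstrand = "+"
    if config.strand == "-":
        n = len(final)
        final = final.translate(_COMP)[::-1]
        # flipping ascending plus-strand exons yields descending genomic
        # intervals, which is already transcript 5'->3' for the minus strand
        exons = [(n - e, n - s) for s, e in exon_coords]
        tstrand = "-"

    contig = Contig(contig_name, final)
    transcript = TranscriptModel(
        transcript_id=transcript_id, gene_id=gene_id, contig=contig_name,
        strand=tstrand, exons=exons,
    )
    sites = extract_splice_sites(transcript, {contig_name: contig})

    truth: dict[str, list[GuideCandidate]] = {}
    for spec in config.editor_specs if compute_truth else ():
        guides: list[GuideCandidate] = []
        for site in sites:
            if not site.canonical and not config.plant_noncanonical:
                continue
            t, strand = splice_target(site, tstrand)[spec.edited_base]
            base = contig.sequence[t]
            if strand == "-":
                base = base.translate(_COMP)
            if base != spec.edited_base:
                continue
            guides.extend(brute_force_scan(contig, spec, t, strand))
        seen = set()
        unique = []
        for g in sorted(guides, key=lambda g: (g.span, g.strand, g.target_position)):
            key = (g.strand, g.span, g.target_coord)
            if key not in seen:
                seen.add(key)
                unique.append(g)
        truth[spec.name] = unique

    return FixtureTruth(
        config=config, seed=seed, contig=contig, transcript=transcript,
        sites=sites, truth=truth,
    )


def make_fixture_genes(
    n_genes: int,
    seed: int,
    n_pam_free: int = 0,
    config: FixtureConfig | None = None,
    compute_truth: bool = True,
) -> tuple[dict[str, Contig], list[TranscriptModel], list[FixtureTruth]]:
    """A small synthetic genome: one gene per contig.

    The first ``n_pam_free`` genes are built with ``pam_density=0`` (no GG/CC
    anywhere, hence untargetable with NGG), the rest with the given config.
    """
    config = config or FixtureConfig()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_genes)]
    contigs: dict[str, Contig] = {}
    transcripts: list[TranscriptModel] = []
    truths: list[FixtureTruth] = []
    for i in range(n_genes):
        cfg = config
        if i < n_pam_free:
            cfg = FixtureConfig(
                n_exons=config.n_exons, exon_length=config.exon_length,
                intron_length=config.intron_length, flank_length=config.flank_length,
                pam_density=0.0, plant_noncanonical=config.plant_noncanonical,
                strand=config.strand, editor_specs=config.editor_specs,
            )
        ft = make_fixture_gene(
            cfg, child_seeds[i], contig_name=f"ctg{i + 1:04d}",
            gene_id=f"GENE{i + 1:04d}", transcript_id=f"TX{i + 1:04d}",
            compute_truth=compute_truth,
        )
        contigs[ft.contig.name] = ft.contig
        transcripts.append(ft.transcript)
        truths.append(ft)
    return contigs, transcripts, truths


# ---------------------------------------------------------------------------
# meta-analysis table fixtures

# Preceding-base multipliers anchored to the cross-study means the two
# deaminases show (T-preceded targets edit best, G-preceded worst; the T/G
# ratios are 28.7/6.9 for the cytidine editor and 24.5/6.3 for the adenosine
# editor, with A/C contexts intermediate).
DEFAULT_MULTIPLIERS = {
    "BE4": {"T": 1.0, "A": 0.46, "C": 0.42, "G": round(6.9 / 28.7, 4)},
    "ABE7.10": {"T": 1.0, "C": 0.62, "A": 0.45, "G": round(6.3 / 24.5, 4)},
}
DEFAULT_WINDOW_SD = {"BE4": 2.4, "ABE7.10": 1.6}


@dataclass(frozen=True)
class MetaFixtureConfig:
    """Knobs for one synthetic meta-analysis table.

    Defaults mirror the scale of the published cross-study dataset: 6
    studies, 102 unique guides, ~4.4 recorded edits per guide (~447 total),
    two editors, additive percent-scale noise.
    """

    n_studies: int = 6
    n_guides: int = 102
    mean_edits_per_guide: float = 4.38
    noise_sd: float = 2.0
    duplicate_rate: float = 0.15  # chance a guide is entered by a 2nd study
    editors: tuple[str, ...] = ("BE4", "ABE7.10")
    window_center: float = 6.0
    amplitude_range: tuple[float, float] = (40.0, 95.0)
    multipliers: dict | None = None  # editor -> preceding base -> multiplier
    window_sd: dict | None = None  # editor -> gaussian sd of the window


def _window_shape(pos: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-((pos - center) ** 2) / (2.0 * sd**2))


def _clamp_mean(mu: float, sigma: float) -> float:
    """E[max(0, N(mu, sigma^2))] — expectation of the zero-clamped draw."""
    if sigma == 0:
        return max(mu, 0.0)
    z = mu / sigma
    phi = math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
    Phi = 0.5 * (1 + math.erf(z / math.sqrt(2)))
    return mu * Phi + sigma * phi


def make_fixture_meta(
    config: MetaFixtureConfig, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Synthetic meta-analysis table plus its planted parameters.

    Returns the record table and a dict holding the planted multipliers,
    window parameters, per-study amplitudes, and the analytic expected
    context means/fold-changes under the zero-clamped noise model (the
    recoverable values a perfect pipeline should converge to).
    """
    rng = np.random.default_rng(seed)
    multipliers = config.multipliers or DEFAULT_MULTIPLIERS
    window_sd = config.window_sd or DEFAULT_WINDOW_SD

    studies = [f"study{i + 1}" for i in range(config.n_studies)]
    amplitudes = {
        (s, "cellA"): float(rng.uniform(*config.amplitude_range)) for s in studies
    }

    rows = []
    for gi in range(config.n_guides):
        editor = config.editors[gi % len(config.editors)]
        guide_id = f"g{gi + 1:04d}"
        study = studies[int(rng.integers(len(studies)))]
        entered_by = [study]
        if rng.random() < config.duplicate_rate and config.n_studies > 1:
            other = studies[int(rng.integers(len(studies)))]
            if other != study:
                entered_by.append(other)
        n_edits = min(1 + int(rng.poisson(max(config.mean_edits_per_guide - 1, 0))), 20)
        # a real protospacer has one editable-base context per position
        positions = rng.choice(np.arange(1, 21), size=n_edits, replace=False)
        preceding = rng.choice(list("ACGT"), size=n_edits)
        following = rng.choice(list("ACGT"), size=n_edits)
        for st in entered_by:
            amp = amplitudes[(st, "cellA")]
            for p, pre, fol in zip(positions, preceding, following):
                shape = float(
                    _window_shape(np.array([p]), config.window_center,
                                  window_sd[editor])[0]
                )
                mu = amp * multipliers[editor][pre] * shape
                raw = mu + rng.normal(0.0, config.noise_sd)
                rows.append(
                    {
                        "study_id": st,
                        "cell_type": "cellA",
                        "editor": editor,
                        "guide_id": guide_id,
                        "position": int(p),
                        "preceding_base": str(pre),
                        "following_base": str(fol),
                        "raw_efficiency": float(np.clip(raw, 0.0, 100.0)),
                    }
                )
    df = pd.DataFrame(rows, columns=[
        "study_id", "cell_type", "editor", "guide_id", "position",
        "preceding_base", "following_base", "raw_efficiency",
    ])

    # analytic expected context means under the clamped-noise model:
    # average over uniform positions and the drawn study amplitudes
    pos_grid = np.arange(1, 21, dtype=float)
    expected_means: dict[str, dict[str, float]] = {}
    expected_folds: dict[str, dict[str, float]] = {}
    for editor in config.editors:
        shapes = _window_shape(pos_grid, config.window_center, window_sd[editor])
        means = {}
        for base, m in multipliers[editor].items():
            vals = [
                _clamp_mean(a * m * s, config.noise_sd)
                for a in amplitudes.values()
                for s in shapes
            ]
            means[base] = float(np.mean(vals))
        expected_means[editor] = means
        expected_folds[editor] = {
            f"{b1}/{b2}": means[b1] / means[b2]
            for b1 in means
            for b2 in means
            if b1 != b2
        }

    planted = {
        "multipliers": multipliers,
        "window_sd": window_sd,
        "window_center": config.window_center,
        "amplitudes": amplitudes,
        "noise_sd": config.noise_sd,
        "expected_context_means": expected_means,
        "expected_fold_changes": expected_folds,
        "n_guides": config.n_guides,
        "n_records": len(df),
    }
    return df, planted
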