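"""Guide scoring from position x preceding-base activity profiles.

The score of a guide is the LOESS-smoothed normalized editing efficiency
expected for its dinucleotide context (preceding base + target) at its
protospacer position — a direct lookup into the meta-analysis curves.  The
base following the target is recorded on guides but not scored; it has a
much smaller effect on deaminase activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DomainError, EmptyInputError
from .guide_design import GuideCandidate
from .meta_analysis import POSITIONS, ProfileCurve, loess_fit


@dataclass
class ActivityProfile:
    """Per-preceding-base activity curves for one editor, plus a pooled one."""

    editor: str
    curves: dict[str, ProfileCurve]  # keys "A","C","G","T" (as available) + "all"
    provenance: str

    def __post_init__(self) -> None:
        if "all" not in self.curves:
            raise DomainError("profile requires a pooled 'all' curve")

    def curve_for(self, preceding_base: str | None) -> ProfileCurve:
        if preceding_base is not None and preceding_base in self.curves:
            return self.curves[preceding_base]
        return self.curves["all"]


@dataclass
class ScoredGuide:
    guide: GuideCandidate
    score: float
    passes_threshold: bool
    rank: int


DEFAULT_MIN_POINTS = 10


def build_activity_profile(
    collapsed: pd.DataFrame,
    editor: str,
    span: float,
    min_points: int = DEFAULT_MIN_POINTS,
    source: str = "meta-analysis",
) -> ActivityProfile:
    """LOESS-smooth collapsed meta records into per-context curves.

    Contexts with fewer than ``min_points`` records fall back to the pooled
    curve rescaled by (context mean / overall mean); the fallback is noted
    in the profile provenance.
    """
    sub = collapsed[collapsed["editor"] == editor]
    if sub.empty:
        raise EmptyInputError(f"no meta records for editor {editor!r}")
    overall_mean = sub["normalized_efficiency"].mean()
    all_values = loess_fit(
        sub["position"].to_numpy(), sub["normalized_efficiency"].to_numpy(), span
    )
    curves = {"all": ProfileCurve(editor, "all", all_values, span)}
    fallbacks = []
    for base in "ACGT":
        ctx = sub[sub["preceding_base"] == base]
        if len(ctx) == 0:
            continue
        if len(ctx) >= min_points:
            vals = loess_fit(
                ctx["position"].to_numpy(),
                ctx["normalized_efficiency"].to_numpy(),
                span,
            )
        else:
            scale = ctx["normalized_efficiency"].mean() / overall_mean
            vals = {
                int(p): float(min(max(all_values[int(p)] * scale, 0.0), 100.0))
                for p in POSITIONS
            }
            fallbacks.append(base)
        curves[base] = ProfileCurve(editor, base, vals, span)
    provenance = f"{source}; span={span}"
    if fallbacks:
        provenance += f"; rescaled-all fallback for sparse context(s) {fallbacks}"
    return ActivityProfile(editor=editor, curves=curves, provenance=provenance)


def score_guide(guide: GuideCandidate, profile: ActivityProfile) -> float:
    """Expected normalized editing (%) for the guide's context and position."""
    if not (1 <= guide.target_position <= 20):
        raise DomainError(
            f"target position {guide.target_position} outside the 1..20 profile domain"
        )
    value = profile.curve_for(guide.preceding_base)[guide.target_position]
    return float(min(max(value, 0.0), 100.0))


DEFAULT_MIN_SCORE = 20.0  # percent of the per-dataset maximum


def rank_and_filter(
    guides: list[GuideCandidate],
    profile: ActivityProfile,
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[ScoredGuide]:
    """Score, rank, and flag guides against the selection threshold.

    Ordering: score descending, then earlier spliced-mRNA position, donors
    before acceptors, then protospacer lexicographically.  Nothing is
    removed; ``passes_threshold`` records the >= min_score rule.
    """
    kind_order = {"donor": 0, "acceptor": 1, None: 2}
    scored = [(score_guide(g, profile), g) for g in guides]
    scored.sort(
        key=lambda sg: (
            -sg[0],
            sg[1].mrna_offset if sg[1].mrna_offset is not None else float("inf"),
            kind_order.get(sg[1].site_kind, 2),
            sg[1].protospacer,
        )
    )
    return [
        ScoredGuide(guide=g, score=s, passes_threshold=s >= min_score, rank=i)
        for i, (s, g) in enumerate(scored, start=1)
    ]


PROFILE_COLUMNS = ["editor", "context", "position", "value", "span", "provenance"]


def write_profile(profile: ActivityProfile, path) -> None:
    rows = [
        {
            "editor": profile.editor,
            "context": ctx,
            "position": p,
            "value": curve[int(p)],
            "span": curve.span,
            "provenance": profile.provenance,
        }
        for ctx, curve in sorted(profile.curves.items())
        for p in POSITIONS
    ]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_profile(path) -> ActivityProfile:
    df = pd.read_csv(path, sep="\t")
    editors = df["editor"].unique()
    if len(editors) != 1:
        raise DomainError("profile file must describe exactly one editor")
    curves = {}
    for ctx, grp in df.groupby("context"):
        values = {int(p): float(v) for p, v in zip(grp["position"], grp["value"])}
        curves[str(ctx)] = ProfileCurve(
            str(editors[0]), str(ctx), values, float(grp["span"].iloc[0])
        )
    provenance = str(df["provenance"].iloc[0])
    return ActivityProfile(editor=str(editors[0]), curves=curves, provenance=provenance)
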