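"""Literature meta-analysis of base-editing efficiency.

Pipeline: per-(study, cell type) normalization to the group maximum, then
averaging repeated observations of the same guide/position across studies,
then aggregation by dinucleotide context and LOESS smoothing of the
position-activity relationship.  Editing values are percentages throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError, FitError

logger = logging.getLogger(__name__)

META_COLUMNS = [
    "study_id",
    "cell_type",
    "editor",
    "guide_id",
    "position",
    "preceding_base",
    "following_base",
    "raw_efficiency",
]

POSITIONS = np.arange(1, 21)


def validate_meta_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"meta table missing columns {missing}")
    if ((df["raw_efficiency"] < 0) | (df["raw_efficiency"] > 100)).any():
        raise DomainError("raw_efficiency outside [0, 100]")
    if ((df["position"] < 1) | (df["position"] > 20)).any():
        raise DomainError("position outside [1, 20]")
    return df


def normalize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Scale each (study, cell type) group to its own maximum (=100).

    Controls for delivery and baseline-efficiency differences between works.
    Groups whose efficiencies are all zero carry no scale information and are
    dropped with a warning.
    """
    df = validate_meta_table(records).copy()
    gmax = df.groupby(["study_id", "cell_type"])["raw_efficiency"].transform("max")
    dead = gmax == 0
    if dead.any():
        for study, cell in (
            df.loc[dead, ["study_id", "cell_type"]].drop_duplicates().itertuples(index=False)
        ):
            logger.warning("dropping all-zero group (%s, %s)", study, cell)
        df = df.loc[~dead].copy()
        gmax = gmax.loc[~dead]
    df["normalized_efficiency"] = df["raw_efficiency"] / gmax * 100.0
    return df


def collapse_duplicates(normalized: pd.DataFrame) -> pd.DataFrame:
    """Average a guide's normalized editing per position across studies."""
    if "normalized_efficiency" not in normalized.columns:
        raise DomainError("records must be normalized first")
    agg = (
        normalized.groupby(["editor", "guide_id", "position"], sort=True)
        .agg(
            normalized_efficiency=("normalized_efficiency", "mean"),
            preceding_base=("preceding_base", "first"),
            following_base=("following_base", "first"),
        )
        .reset_index()
    )
    return agg


@dataclass
class ContextSummary:
    """Per-context efficiency summaries for one editor."""

    editor: str
    group_by: str  # "preceding" | "following"
    position_means: pd.DataFrame  # index context, columns position
    context_means: pd.Series  # index context
    fold_changes: pd.DataFrame  # pairwise mean(c1)/mean(c2)
    missing_contexts: list[str] = field(default_factory=list)

    def fold_change(self, c1: str, c2: str) -> float:
        return float(self.context_means[c1] / self.context_means[c2])


def context_summary(
    collapsed: pd.DataFrame, editor: str, group_by: str = "preceding"
) -> ContextSummary:
    """Aggregate collapsed records by the base flanking the target.

    The overall context mean pools all positions; the pairwise fold-change
    between contexts is the ratio of those means.
    """
    if group_by not in ("preceding", "following"):
        raise DomainError(f"group_by {group_by!r}")
    col = f"{group_by}_base"
    sub = collapsed[collapsed["editor"] == editor]
    if sub.empty:
        raise EmptyInputError(f"no records for editor {editor!r}")
    present = sorted(sub[col].dropna().unique())
    missing = [b for b in "ACGT" if b not in present]
    if missing:
        logger.warning("editor %s: no records for context(s) %s", editor, missing)
    position_means = (
        sub.groupby([col, "position"])["normalized_efficiency"].mean().unstack("position")
    )
    context_means = sub.groupby(col)["normalized_efficiency"].mean()
    fold = pd.DataFrame(
        np.asarray(context_means)[:, None] / np.asarray(context_means)[None, :],
        index=context_means.index,
        columns=context_means.index,
    )
    return ContextSummary(
        editor=editor,
        group_by=group_by,
        position_means=position_means,
        context_means=context_means,
        fold_changes=fold,
        missing_contexts=missing,
    )


@dataclass(frozen=True)
class ProfileCurve:
    """A smoothed position-activity curve for one editor/context."""

    editor: str
    context: str  # preceding base or "all"
    values: dict[int, float]  # position 1..20 -> percent, clamped to [0, 100]
    span: float

    def __post_init__(self) -> None:
        for p in POSITIONS:
            v = self.values.get(int(p))
            if v is None or not (0.0 <= v <= 100.0):
                raise DomainError(f"curve value at position {p} missing or out of range")

    def __getitem__(self, position: int) -> float:
        return self.values[position]


def _tricube(d: np.ndarray, dmax: float) -> np.ndarray:
    if dmax == 0:
        return np.ones_like(d)
    u = np.clip(d / dmax, 0.0, 1.0)
    return (1.0 - u**3) ** 3


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float,
    degree: int = 2,
    query: np.ndarray = POSITIONS,
) -> dict[int, float]:
    """Classical LOESS evaluated at integer protospacer positions.

    For each query point, a weighted least-squares polynomial of the given
    degree is fit over the ceil(span * n) nearest points with tricube
    weights (nearest-neighbour ties broken toward lower x), then evaluated
    at the query.  Results are clamped to [0, 100].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not (0.0 < span <= 1.0):
        raise FitError(f"span must be in (0, 1], got {span}")
    q = max(int(math.ceil(span * n)), degree + 1)
    if n < degree + 1 or n < q:
        raise FitError(
            f"need at least {max(degree + 1, q)} points for degree {degree}, "
            f"span {span}; got {n}"
        )
    order_x = np.lexsort((x,))  # stable pre-sort so distance ties pick lower x
    xs, ys = x[order_x], y[order_x]
    out: dict[int, float] = {}
    for x0 in query:
        d = np.abs(xs - x0)
        sel = np.argsort(d, kind="stable")[:q]
        dmax = d[sel].max()
        w = _tricube(d[sel], dmax)
        if w.sum() == 0:  # all neighbours exactly at the bandwidth edge
            w = np.ones_like(w)
        # the tricube zeroes the farthest neighbours; with clustered x the
        # weighted system can be rank-deficient, so drop the local degree to
        # what the distinct supported abscissae can identify
        supported = np.unique(xs[sel][w > 0])
        deg = min(degree, max(len(supported) - 1, 0))
        X = np.vander(xs[sel], N=deg + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], ys[sel] * sw, rcond=None)
        val = float(np.polynomial.polynomial.polyval(x0, beta))
        out[int(x0)] = float(np.clip(val, 0.0, 100.0))
    return out


def read_meta_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_meta_table(df)


def write_meta_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
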