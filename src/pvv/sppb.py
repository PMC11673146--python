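"""SPPB component scoring, totals, and label-distribution summaries.

The short physical performance battery (SPPB) sums three 0-4 point
sub-scores — standing balance, a 4 m walk, and a 5-repetition
sit-to-stand — to a 0-12 total.  Thresholds follow the standard clinical
scoring sheet.  Interval endpoints are handled left-closed: "4.82-6.2 s"
means [4.82, 6.2); a 4 m walk of exactly 8.70 s still earns 2 points
because "more than 8.70 s" is read strictly.

``summarize_label`` quantifies whether a candidate regression label is
usable: a strong ceiling effect (a large fraction of subjects at the
maximum score, as SPPB totals show in mobile cohorts) makes a score a poor
regression target, whereas TUG times are continuous and near-normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SppbInput:
    """Component times (s); ``sts5_time`` may be None = could not complete."""

    side_by_side_hold: float
    semi_tandem_hold: float
    tandem_hold: float
    walk4m_time: float
    sts5_time: float | None


@dataclass(frozen=True)
class SppbScore:
    balance_points: int
    walk_points: int
    sts_points: int

    @property
    def total(self) -> int:
        return self.balance_points + self.walk_points + self.sts_points


@dataclass(frozen=True)
class LabelSummary:
    n: int
    mean: float
    sd: float
    skewness: float
    ceiling_fraction: float
    histogram: tuple[int, ...]
    bin_edges: tuple[float, ...]
    imbalanced: bool


def score_balance(
    side_by_side_hold: float, semi_tandem_hold: float, tandem_hold: float
) -> int:
    """Balance sub-score, 0-4 points.

    +1 for a full 10 s side-by-side hold, +1 for a full 10 s semi-tandem
    hold; the tandem stance earns +2 for 10 s, +1 for 3 to under 10 s.
    """
    for name, hold in (
        ("side_by_side", side_by_side_hold),
        ("semi_tandem", semi_tandem_hold),
        ("tandem", tandem_hold),
    ):
        if hold < 0:
            raise ValueError(f"{name} hold time must be non-negative, got {hold}")
    points = int(side_by_side_hold >= 10.0) + int(semi_tandem_hold >= 10.0)
    if tandem_hold >= 10.0:
        points += 2
    elif tandem_hold >= 3.0:
        points += 1
    return min(points, 4)


def score_walk4m(time: float) -> int:
    """4 m walk sub-score, 1-4 points: <4.82 s -> 4; [4.82, 6.2) -> 3;
    [6.2, 8.7] -> 2; >8.7 s -> 1."""
    if time <= 0:
        raise ValueError(f"walk time must be positive, got {time}")
    if time < 4.82:
        return 4
    if time < 6.2:
        return 3
    if time <= 8.7:
        return 2
    return 1


def score_sts5(time: float | None) -> int:
    """5-repetition sit-to-stand sub-score, 0-4 points.

    <11.2 s -> 4; [11.2, 13.7) -> 3; [13.7, 17) -> 2; [17, 60) -> 1;
    >= 60 s or unable (None) -> 0.
    """
    if time is None:
        return 0
    if time <= 0:
        raise ValueError(f"sit-to-stand time must be positive, got {time}")
    if time < 11.2:
        return 4
    if time < 13.7:
        return 3
    if time < 17.0:
        return 2
    if time < 60.0:
        return 1
    return 0


def score_sppb(inp: SppbInput) -> SppbScore:
    """Composite SPPB score; total is bounded in [0, 12] by construction."""
    return SppbScore(
        balance_points=score_balance(
            inp.side_by_side_hold, inp.semi_tandem_hold, inp.tandem_hold
        ),
        walk_points=score_walk4m(inp.walk4m_time),
        sts_points=score_sts5(inp.sts5_time),
    )


def summarize_label(
    values,
    max_possible: float | None = None,
    ceiling_threshold: float = 0.4,
    bins: int = 10,
) -> LabelSummary:
    """Distribution summary used to judge regression-label suitability.

    ``ceiling_fraction`` is the proportion of values at ``max_possible``
    (0 when no maximum applies); the label is flagged imbalanced when that
    fraction reaches ``ceiling_threshold``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values to summarize")
    counts, edges = np.histogram(x, bins=bins)
    ceiling = 0.0
    if max_possible is not None:
        ceiling = float(np.mean(x == max_possible))
    return LabelSummary(
        n=len(x),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        skewness=0.0 if x.std() == 0 else float(stats.skew(x)),
        ceiling_fraction=ceiling,
        histogram=tuple(int(c) for c in counts),
        bin_edges=tuple(float(e) for e in edges),
        imbalanced=ceiling >= ceiling_threshold,
    )
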