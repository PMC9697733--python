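"""Per-subject grading summaries and group statistics.

Summaries mirror one grading row per subject: INL dot counts and their
granule/elongated split, mean conservative extents, location tallies with
integer percentages (rounded half away from zero), and ONL counts and
extents.  Group results are reported as medians (midpoint of the two
central order statistics for even counts) and compared with a two-sided
unpaired Wilcoxon rank-sum test: exact enumeration of the rank-sum
distribution when the combined sample is small and tie-free, a
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import load_subject_table

__all__ = [
    "SubjectSummary",
    "summarize_subject",
    "group_median",
    "wilcoxon_rank_sum",
    "reproduce_summary_table",
    "round_half_away",
    "ABSENT",
]

ABSENT = float("nan")   # explicit marker for "no ONL dots" (printed as a dash)


def round_half_away(x: float) -> int:
    """Round to integer with halves going away from zero (0.5 -> 1, -0.5 -> -1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def is_absent(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class SubjectSummary:
    """One subject's grading row."""

    subject_id: str
    group: str                      # 'patient' | 'control'
    inl_dot_count: int
    granule_count: int
    elongated_count: int
    mean_elongated_extent: float    # µm; NaN when no elongated elements
    location_counts: dict           # near_IPL / inside_INL / near_OPL -> count
    location_percentages: dict      # same keys -> integer percent of inl_dot_count
    onl_dot_count: int
    mean_onl_extent: float          # µm; NaN (absent) when onl_dot_count = 0
    class_counts: dict              # final_class -> count

    def __post_init__(self) -> None:
        if self.granule_count + self.elongated_count != self.inl_dot_count:
            raise ValueError("granule_count + elongated_count must equal inl_dot_count")


def summarize_subject(classified, onl_elements, subject_id="", group="") -> SubjectSummary:
    """Tally one subject's classified INL elements and filtered ONL elements.

    ``classified`` is a list of :class:`~hrdot.perfusion.ClassifiedElement`
    for the INL (branch children already merged into parents);
    ``onl_elements`` a list of :class:`~hrdot.tracing.Element` from the ONL
    pipeline.  Mean extents average the conservative extents of the
    relevant elements; a subject with no ONL elements carries the explicit
    absent marker.
    """
    inl_elements = [c.element for c in classified]
    n = len(inl_elements)
    granules = [e for e in inl_elements if e.shape_class == "granule"]
    elongated = [e for e in inl_elements if e.shape_class == "elongated"]
    loc_counts = {k: 0 for k in ("near_IPL", "inside_INL", "near_OPL")}
    for e in inl_elements:
        if e.location in loc_counts:
            loc_counts[e.location] += 1
    loc_pct = {
        k: (round_half_away(100.0 * v / n) if n else 0) for k, v in loc_counts.items()
    }
    class_counts = {
        k: 0 for k in ("granule", "perfused_filiform", "nonperfused_filiform", "unclassifiable")
    }
    for c in classified:
        class_counts[c.final_class] += 1
    return SubjectSummary(
        subject_id=str(subject_id),
        group=group,
        inl_dot_count=n,
        granule_count=len(granules),
        elongated_count=len(elongated),
        mean_elongated_extent=(
            float(np.mean([e.conservative_extent for e in elongated])) if elongated else ABSENT
        ),
        location_counts=loc_counts,
        location_percentages=loc_pct,
        onl_dot_count=len(onl_elements),
        mean_onl_extent=(
            float(np.mean([e.conservative_extent for e in onl_elements]))
            if onl_elements else ABSENT
        ),
        class_counts=class_counts,
    )


def group_median(values, absent_as_zero: bool = False) -> float:
    """Median with the even-count midpoint convention; the explicit absent
    marker is replaced by 0 when ``absent_as_zero`` is set, rejected
    otherwise."""
    vals = []
    for v in values:
        if is_absent(v):
            if not absent_as_zero:
                raise ValueError("absent value in input (pass absent_as_zero=True)")
            vals.append(0.0)
        else:
            vals.append(float(v))
    if not vals:
        raise ValueError("group_median needs at least one value")
    vals.sort()
    m = len(vals)
    if m % 2:
        return vals[m // 2]
    return (vals[m // 2 - 1] + vals[m // 2]) / 2.0


def _rank_sum_exact_sf(n_a: int, n_b: int) -> np.ndarray:
    """Distribution of the rank-sum of group A over all C(N, n_a) assignments
    of the ranks 1..N, by dynamic programming; returns counts indexed by sum."""
    N = n_a + n_b
    max_sum = n_a * N
    # counts[k, s] = number of k-subsets of processed ranks with sum s
    counts = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, N + 1):
        for k in range(min(rank, n_a), 0, -1):
            counts[k, rank:] += counts[k - 1, :-rank or None]
    return counts[n_a]


def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Two-sided unpaired Wilcoxon rank-sum test.

    Mid-ranks for ties; exact enumeration of the rank-sum distribution when
    the combined sample size is at most 20 and tie-free, otherwise the
    normal approximation with tie correction.  Returns (rank-sum statistic
    of the first group, two-sided p).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    ranks[order] = np.arange(1, pooled.size + 1, dtype=float)
    # mid-ranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < sorted_vals.size:
        j = i
        while j + 1 < sorted_vals.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w = float(ranks[: a.size].sum())
    n_a, n_b = a.size, b.size
    N = n_a + n_b
    has_ties = np.unique(pooled).size < N
    if np.unique(pooled).size == 1:
        return w, 1.0
    if N <= 20 and not has_ties:
        dist = _rank_sum_exact_sf(n_a, n_b)
        total = dist.sum()
        wi = int(round(w))
        p_low = dist[: wi + 1].sum() / total
        p_high = dist[wi:].sum() / total
        return w, float(min(1.0, 2.0 * min(p_low, p_high)))
    mean = n_a * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (N * (N - 1))
    var = n_a * n_b / 12.0 * (N + 1 - tie_term)
    if var <= 0:
        return w, 1.0
    zstat = (w - mean) / math.sqrt(var)
    p = float(2.0 * 0.5 * math.erfc(abs(zstat) / math.sqrt(2.0)))
    return w, min(p, 1.0)


# printed group-summary cells of the reference study's grading table
_PRINTED = {
    "inl_dot_count": (13.0, 9.5),
    "granule_count": (3.0, 2.0),
    "elongated_count": (10.0, 8.5),
    "mean_elongated_extent_um": (73.0, 81.5),
    "near_ipl_count": (5.0, 3.0),
    "inside_inl_count": (3.0, 0.0),
    "near_opl_count": (5.5, 8.0),
    "near_ipl_pct": (31.0, 23.0),
    "inside_inl_pct": (23.0, 5.0),
    "near_opl_pct": (46.0, 73.0),
    "onl_dot_count": (2.0, 0.5),
    "mean_onl_extent_um": (23.0, 5.5),
}


def reproduce_summary_table(subjects: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute every group-summary cell of the packaged grading table from
    its per-subject cells and compare with the printed values.

    Count and extent summaries are medians (ONL extents with absent taken
    as zero); the location-percentage summaries reproduce the printed
    values as the mean of the per-subject percentages, rounded half away
    from zero.  Returns a frame with computed and printed values per cell
    and a ``match`` flag; every cell must match exactly.
    """
    if subjects is None:
        subjects = load_subject_table()
    pat = subjects[subjects["group"] == "patient"]
    con = subjects[subjects["group"] == "control"]
    rows = []
    for key, (printed_p, printed_c) in _PRINTED.items():
        for grp, frame, printed in (("patient", pat, printed_p), ("control", con, printed_c)):
            if key == "mean_onl_extent_um":
                computed = group_median(frame[key], absent_as_zero=True)
            elif key.endswith("_pct"):
                computed = float(round_half_away(float(frame[key].mean())))
            else:
                computed = group_median(frame[key])
            rows.append({
                "cell": key, "group": grp,
                "computed": float(computed), "printed": float(printed),
                "match": float(computed) == float(printed),
            })
    return pd.DataFrame(rows)
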