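"""Integration of genetic (cM), physical-chromosome (FL) and pseudochromosome
(Mbp) marker maps, with orientation detection and order-discordance metrics.

Marker order on the physical chromosome follows cytogenetic convention: the
short arm is drawn at the top, so markers are sorted by ascending fractional
length — descending RPHC on the short arm, then ascending RPHC on the long
arm. A linkage group, however, is published in an arbitrary orientation and
may be upended relative to the chromosome; orientation is detected by Kendall
rank correlation against the physical order and the genetic order reversed
when the flipped orientation correlates better.

Two discordance metrics are reported for every map pair, because published
"markers in the wrong position" counts are not produced by a single rule:

* rank-mismatch — the number of shared markers whose ordinal rank differs
  between the two orders;
* minimal-removal — the minimum number of markers whose removal makes the
  remaining orders identical, computed as n minus the length of the longest
  increasing subsequence (LIS) of one order's ranks taken in the other's
  sequence.

Minimal-removal never exceeds rank-mismatch (removing every rank-mismatched
marker leaves the concordant markers in identical order).
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from scipy.stats import kendalltau

from .cytogenetics import KaryotypeArm, ProbePosition, rphc_to_fl

__all__ = [
    "MarkerMapEntry",
    "ConcordanceReport",
    "physical_order",
    "detect_orientation",
    "rank_mismatch_count",
    "rank_mismatched_markers",
    "min_removal_count",
    "min_removal_markers",
    "build_report",
    "entries_from_tables",
]


@dataclass(frozen=True)
class MarkerMapEntry:
    """One marker's coordinates on up to three maps (absent = None)."""

    marker_id: str
    genetic_cM: float | None = None
    physical_fl: float | None = None
    physical_arm: str | None = None
    pseudo_mbp: float | None = None


@dataclass
class ConcordanceReport:
    """Order-concordance result for one pair of maps."""

    map_pair: str
    n_shared: int
    orientation_flipped: bool
    rank_mismatch_count: int
    rank_mismatch_pct: float
    min_removal_count: int
    min_removal_pct: float
    discordant_markers: dict[str, list[str]] = field(default_factory=dict)
    comparable: bool = True

    def to_dict(self) -> dict:
        return {
            "map_pair": self.map_pair,
            "n_shared": self.n_shared,
            "orientation_flipped": self.orientation_flipped,
            "rank_mismatch_count": self.rank_mismatch_count,
            "rank_mismatch_pct": self.rank_mismatch_pct,
            "min_removal_count": self.min_removal_count,
            "min_removal_pct": self.min_removal_pct,
            "discordant_markers": self.discordant_markers,
            "comparable": self.comparable,
        }


def physical_order(positions: Sequence[ProbePosition]) -> list[str]:
    """Marker order along the physical chromosome (short-arm telomere first).

    Sorts by ascending FL: short-arm markers by descending RPHC, then long-arm
    markers by ascending RPHC. Ties are broken by marker id with a warning.
    """
    ids = [p.probe_id for p in positions]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate marker id(s): {dup}")

    def key(p: ProbePosition) -> tuple:
        if p.arm == "short":
            return (0, -p.rphc_mean, p.probe_id)
        if p.arm == "long":
            return (1, p.rphc_mean, p.probe_id)
        raise ValueError(f"probe {p.probe_id}: unknown arm {p.arm!r}")

    seen: dict[tuple, str] = {}
    for p in positions:
        k = key(p)[:2]
        if k in seen:
            warnings.warn(
                f"tied positions for {seen[k]} and {p.probe_id}; "
                "breaking tie by marker id",
                stacklevel=2,
            )
        seen[k] = p.probe_id
    return [p.probe_id for p in sorted(positions, key=key)]


def detect_orientation(
    genetic: Sequence[tuple[str, float]],
    physical_fl: Sequence[tuple[str, float]],
) -> str:
    """Decide whether a linkage group is drawn ``as_is`` or ``flipped``
    relative to the physical chromosome.

    Compares Kendall rank correlation of cM vs. FL over shared markers in both
    orientations; needs >= 3 shared markers, else returns ``undetermined``.
    """
    cm = dict(genetic)
    fl = dict(physical_fl)
    shared = [m for m, _ in genetic if m in fl]
    if len(shared) < 3:
        return "undetermined"
    x = [cm[m] for m in shared]
    y = [fl[m] for m in shared]
    tau_as_is = kendalltau(x, y).statistic
    tau_flipped = kendalltau([-v for v in x], y).statistic
    return "flipped" if tau_flipped > tau_as_is else "as_is"


def _check_same_set(order_a: Sequence[str], order_b: Sequence[str]) -> None:
    sa, sb = set(order_a), set(order_b)
    if len(sa) != len(order_a) or len(sb) != len(order_b):
        raise ValueError("orders contain duplicate markers")
    if sa != sb:
        raise ValueError(
            f"marker sets differ: only in a {sorted(sa - sb)}, "
            f"only in b {sorted(sb - sa)}"
        )


def rank_mismatch_count(order_a: Sequence[str], order_b: Sequence[str]) -> int:
    """Number of markers whose ordinal rank differs between the two orders."""
    return len(rank_mismatched_markers(order_a, order_b))


def rank_mismatched_markers(
    order_a: Sequence[str], order_b: Sequence[str]
) -> list[str]:
    """Markers whose rank differs between the orders, in ``order_a`` order."""
    _check_same_set(order_a, order_b)
    rank_b = {m: i for i, m in enumerate(order_b)}
    return [m for i, m in enumerate(order_a) if rank_b[m] != i]


def _lis_length(seq: Sequence[int]) -> int:
    """Length of the longest strictly increasing subsequence (patience sort)."""
    tails: list[int] = []
    for x in seq:
        i = bisect.bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def min_removal_count(order_a: Sequence[str], order_b: Sequence[str]) -> int:
    """Minimum number of markers to remove so the remaining orders agree.

    Equals n minus the length of the longest increasing subsequence of
    ``order_a`` ranks read along ``order_b``.
    """
    _check_same_set(order_a, order_b)
    rank_a = {m: i for i, m in enumerate(order_a)}
    seq = [rank_a[m] for m in order_b]
    return len(seq) - _lis_length(seq)


def min_removal_markers(
    order_a: Sequence[str], order_b: Sequence[str]
) -> list[str]:
    """One minimum set of markers whose removal reconciles the two orders.

    The kept markers are a longest increasing subsequence of ``order_a`` ranks
    along ``order_b``; when several LIS exist one is returned deterministically.
    """
    _check_same_set(order_a, order_b)
    rank_a = {m: i for i, m in enumerate(order_a)}
    seq = [rank_a[m] for m in order_b]
    n = len(seq)
    # O(n^2) DP with predecessor recovery; n is tens of markers at most.
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if seq[j] < seq[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -i)) if n else -1
    keep: set[int] = set()
    while end != -1:
        keep.add(end)
        end = prev[end]
    return [order_b[i] for i in range(n) if i not in keep]


def entries_from_tables(
    positions: Sequence[ProbePosition],
    genetic: pd.DataFrame | None,
    pseudo: pd.DataFrame | None,
    karyotype: KaryotypeArm,
) -> list[MarkerMapEntry]:
    """Join aggregated positions with genetic/pseudochromosome map tables.

    ``genetic`` needs columns marker_id and cM; ``pseudo`` needs marker_id and
    mbp_bin. Markers absent from a map get None for that coordinate.
    """
    cm = dict(zip(genetic["marker_id"], genetic["cM"])) if genetic is not None else {}
    mbp = (
        dict(zip(pseudo["marker_id"], pseudo["mbp_bin"]))
        if pseudo is not None
        else {}
    )
    entries = []
    for p in positions:
        entries.append(
            MarkerMapEntry(
                marker_id=p.probe_id,
                genetic_cM=float(cm[p.probe_id]) if p.probe_id in cm else None,
                physical_fl=rphc_to_fl(p.rphc_mean, p.arm, karyotype),
                physical_arm=p.arm,
                pseudo_mbp=float(mbp[p.probe_id]) if p.probe_id in mbp else None,
            )
        )
    return entries


def _pair_report(
    name: str,
    physical: list[tuple[str, float]],
    other: list[tuple[str, float]],
    *,
    detect_flip: bool,
) -> ConcordanceReport:
    phys_ids = [m for m, _ in physical]
    other_shared = [(m, v) for m, v in other if m in set(phys_ids)]
    phys_shared = [(m, v) for m, v in physical if m in {x for x, _ in other_shared}]
    n = len(other_shared)
    if n < 2:
        return ConcordanceReport(
            map_pair=name, n_shared=n, orientation_flipped=False,
            rank_mismatch_count=0, rank_mismatch_pct=0.0,
            min_removal_count=0, min_removal_pct=0.0, comparable=False,
        )
    flipped = False
    if detect_flip:
        flipped = detect_orientation(other_shared, phys_shared) == "flipped"
    other_order = [m for m, _ in sorted(other_shared, key=lambda t: t[1])]
    if flipped:
        other_order = other_order[::-1]
    phys_order = [m for m, _ in phys_shared]
    mism = rank_mismatched_markers(phys_order, other_order)
    removed = min_removal_markers(phys_order, other_order)
    return ConcordanceReport(
        map_pair=name,
        n_shared=n,
        orientation_flipped=flipped,
        rank_mismatch_count=len(mism),
        rank_mismatch_pct=round(100.0 * len(mism) / n, 1),
        min_removal_count=len(removed),
        min_removal_pct=round(100.0 * len(removed) / n, 1),
        discordant_markers={"rank_mismatch": mism, "min_removal": removed},
    )


def build_report(
    entries: Sequence[MarkerMapEntry],
    positions: Sequence[ProbePosition],
    karyotype: KaryotypeArm,
) -> tuple[dict[str, ConcordanceReport], pd.DataFrame]:
    """Compare all three map pairs and emit the integrated per-marker table.

    Returns reports keyed ``genetic_vs_physical``, ``pseudo_vs_physical`` and
    ``genetic_vs_pseudo``; a marker missing from one map is excluded from that
    map's pairs only. Orientation flips are detected against the physical
    order for the genetic and pseudochromosome maps independently.
    """
    phys_ids = physical_order(list(positions))
    fl_by_id = {e.marker_id: e.physical_fl for e in entries}
    physical = [(m, fl_by_id[m]) for m in phys_ids if fl_by_id.get(m) is not None]
    genetic = [
        (e.marker_id, e.genetic_cM) for e in entries if e.genetic_cM is not None
    ]
    pseudo = [
        (e.marker_id, e.pseudo_mbp) for e in entries if e.pseudo_mbp is not None
    ]

    reports = {
        "genetic_vs_physical": _pair_report(
            "genetic_vs_physical", physical, genetic, detect_flip=True
        ),
        "pseudo_vs_physical": _pair_report(
            "pseudo_vs_physical", physical, pseudo, detect_flip=True
        ),
    }
    # genetic vs pseudo: both linear maps; orient genetic the same way as
    # against the physical chromosome, then compare against Mbp order.
    gen_flip = reports["genetic_vs_physical"].orientation_flipped
    shared_gp = {m for m, _ in genetic} & {m for m, _ in pseudo}
    gen_order = [m for m, _ in sorted(genetic, key=lambda t: t[1]) if m in shared_gp]
    if gen_flip:
        gen_order = gen_order[::-1]
    pse_order = [m for m, _ in sorted(pseudo, key=lambda t: t[1]) if m in shared_gp]
    n_gp = len(shared_gp)
    if n_gp >= 2:
        mism = rank_mismatched_markers(pse_order, gen_order)
        removed = min_removal_markers(pse_order, gen_order)
        reports["genetic_vs_pseudo"] = ConcordanceReport(
            map_pair="genetic_vs_pseudo",
            n_shared=n_gp,
            orientation_flipped=gen_flip,
            rank_mismatch_count=len(mism),
            rank_mismatch_pct=round(100.0 * len(mism) / n_gp, 1),
            min_removal_count=len(removed),
            min_removal_pct=round(100.0 * len(removed) / n_gp, 1),
            discordant_markers={"rank_mismatch": mism, "min_removal": removed},
        )
    else:
        reports["genetic_vs_pseudo"] = ConcordanceReport(
            map_pair="genetic_vs_pseudo", n_shared=n_gp,
            orientation_flipped=gen_flip, rank_mismatch_count=0,
            rank_mismatch_pct=0.0, min_removal_count=0, min_removal_pct=0.0,
            comparable=False,
        )

    pos_by_id = {p.probe_id: p for p in positions}
    flagged = {
        m
        for r in reports.values()
        for ms in r.discordant_markers.values()
        for m in ms
    }
    table = pd.DataFrame(
        [
            {
                "marker_id": e.marker_id,
                "cM": e.genetic_cM,
                "FL": round(e.physical_fl, 1) if e.physical_fl is not None else None,
                "arm": e.physical_arm,
                "RPHC": round(pos_by_id[e.marker_id].rphc_mean, 1)
                if e.marker_id in pos_by_id
                else None,
                "mbp_bin": e.pseudo_mbp,
                "discordant": e.marker_id in flagged,
            }
            for e in sorted(
                entries,
                key=lambda e: phys_ids.index(e.marker_id)
                if e.marker_id in phys_ids
                else len(phys_ids),
            )
        ]
    )
    return reports, table
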