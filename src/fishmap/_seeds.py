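"""Exact k-mer seeding shared by transcript placement and the off-target screen.

Seeds are maximal exact-match runs between a query and a subject sequence,
found from a k-mer index of the query and merged along diagonals. Matching is
case-insensitive (soft masking does not hide a repeat from alignment); k-mers
containing N never match.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

__all__ = ["SeedRun", "find_seed_runs", "cluster_runs"]


@dataclass(frozen=True)
class SeedRun:
    """A maximal exact match: query [q_start, q_end) == subject [s_start, s_end)."""

    q_start: int
    s_start: int
    length: int

    @property
    def q_end(self) -> int:
        return self.q_start + self.length

    @property
    def s_end(self) -> int:
        return self.s_start + self.length

    @property
    def diagonal(self) -> int:
        return self.s_start - self.q_start


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    return index


def find_seed_runs(query: str, subject: str, k: int) -> list[SeedRun]:
    """All maximal exact matches of length >= k between query and subject."""
    q = query.upper()
    s = subject.upper()
    if len(q) < k or len(s) < k:
        return []
    index = _kmer_index(q, k)
    # k-mer hit positions grouped by diagonal, then merged into runs
    by_diag: dict[int, list[int]] = defaultdict(list)
    for j in range(len(s) - k + 1):
        kmer = s[j : j + k]
        for i in index.get(kmer, ()):
            by_diag[j - i].append(j)
    runs: list[SeedRun] = []
    for diag, positions in by_diag.items():
        positions.sort()
        start = prev = positions[0]
        for j in positions[1:]:
            if j == prev + 1:
                prev = j
                continue
            runs.append(SeedRun(start - diag, start, prev - start + k))
            start = prev = j
        runs.append(SeedRun(start - diag, start, prev - start + k))
    return sorted(runs, key=lambda r: (r.s_start, r.q_start))


def cluster_runs(runs: list[SeedRun], max_gap: int) -> list[list[SeedRun]]:
    """Group runs whose subject spans lie within ``max_gap`` of each other.

    Used to delimit candidate loci: each cluster becomes one window for local
    alignment or one chaining problem.
    """
    if not runs:
        return []
    ordered = sorted(runs, key=lambda r: r.s_start)
    clusters: list[list[SeedRun]] = [[ordered[0]]]
    end = ordered[0].s_end
    for r in ordered[1:]:
        if r.s_start - end <= max_gap:
            clusters[-1].append(r)
            end = max(end, r.s_end)
        else:
            clusters.append([r])
            end = r.s_end
    return clusters
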