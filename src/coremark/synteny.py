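"""Collinear-block construction and core-genome definition.

A *core genome* for a structurally diverse genus is the set of reference
regions that align collinearly (syntenically, on one strand, in
consistent order) with every assembly in a panel.  The pipeline here:

1. ``read_paf`` — parse pairwise alignments (PAF, 0-based half-open).
2. ``chain_anchors`` — sparse dynamic programming groups anchors into
   maximal-score collinear chains per (target, query, strand), with a
   gap ceiling on both genomes; chains need at least ``min_anchors``
   anchors (default 3).
3. ``select_one_to_one`` — greedy quota filtering by descending chain
   score so each reference/query locus is used once per assembly;
   accepted chains are collapsed to their bounding intervals, which
   smooths out small local tandem duplications; bounding reference
   spans must exceed ``min_block_len`` (default 10 kb).
4. ``coverage_and_core`` — an interval sweep counts, at every reference
   base, how many assemblies have a retained block there; the core is
   the set of maximal runs at the full assembly count.
5. ``fit_core_decay`` — the core shrinks as assemblies are added; a
   three-parameter exponential decay y(k) = A + B·exp(−c·k) fitted to
   mean core size against panel size k extrapolates the plateau A.

All coordinates are 0-based half-open; BED output matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from ._util import Interval, intersect_many, merge_intervals, stream_rng, total_length


@dataclass(frozen=True)
class AlignmentRecord:
    """One PAF alignment line (anchor)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    n_matches: int
    aln_len: int
    mapq: int

    def validate(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"bad query interval {self.qstart}-{self.qend} (len {self.qlen})")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"bad target interval {self.tstart}-{self.tend} (len {self.tlen})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.n_matches > self.aln_len:
            raise ValueError("n_matches exceeds alignment length")


@dataclass
class Chain:
    anchors: list[AlignmentRecord]
    score: int
    strand: str

    @property
    def tname(self) -> str:
        return self.anchors[0].tname

    @property
    def qname(self) -> str:
        return self.anchors[0].qname

    @property
    def t_span(self) -> Interval:
        return (min(a.tstart for a in self.anchors), max(a.tend for a in self.anchors))

    @property
    def q_span(self) -> Interval:
        return (min(a.qstart for a in self.anchors), max(a.qend for a in self.anchors))


@dataclass(frozen=True)
class SyntenyBlock:
    assembly: str
    tname: str
    tstart: int
    tend: int
    qname: str
    qstart: int
    qend: int
    score: int


def read_paf(path, min_mapq: int = 0) -> list[AlignmentRecord]:
    """Parse a PAF file into alignment records; malformed lines raise with line number."""
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected >= 12 tab-separated columns")
            try:
                rec = AlignmentRecord(
                    qname=cols[0],
                    qlen=int(cols[1]),
                    qstart=int(cols[2]),
                    qend=int(cols[3]),
                    strand=cols[4],
                    tname=cols[5],
                    tlen=int(cols[6]),
                    tstart=int(cols[7]),
                    tend=int(cols[8]),
                    n_matches=int(cols[9]),
                    aln_len=int(cols[10]),
                    mapq=int(cols[11]),
                )
                rec.validate()
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if rec.mapq >= min_mapq:
                records.append(rec)
    return records


def write_paf(path, records: Iterable[AlignmentRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.qname, r.qlen, r.qstart, r.qend, r.strand,
                        r.tname, r.tlen, r.tstart, r.tend,
                        r.n_matches, r.aln_len, r.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# chaining


def _chainable(
    a: AlignmentRecord, b: AlignmentRecord, strand: str, max_gap: int, max_gap_diff: int
) -> bool:
    """Can anchor ``b`` follow anchor ``a`` in a collinear chain?

    Both genomic gaps must be non-negative and at most ``max_gap``, and
    their difference at most ``max_gap_diff``: a strongly unbalanced gap
    is an insertion/deletion (presence/absence variant), which ends the
    collinear block rather than being absorbed into it.
    """
    tgap = b.tstart - a.tend
    if not (0 <= tgap <= max_gap):
        return False
    qgap = (b.qstart - a.qend) if strand == "+" else (a.qstart - b.qend)
    if not (0 <= qgap <= max_gap):
        return False
    return abs(tgap - qgap) <= max_gap_diff


def _best_chain(
    anchors: list[AlignmentRecord], strand: str, max_gap: int, max_gap_diff: int
) -> list[int]:
    """Indices of the maximum-score collinear subsequence (anchors sorted by tstart)."""
    n = len(anchors)
    dp = [a.n_matches for a in anchors]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if _chainable(anchors[j], anchors[i], strand, max_gap, max_gap_diff):
                cand = dp[j] + anchors[i].n_matches
                if cand > dp[i]:
                    dp[i] = cand
                    prev[i] = j
    best = max(range(n), key=lambda i: dp[i])
    path = []
    while best != -1:
        path.append(best)
        best = prev[best]
    return path[::-1]


def chain_anchors(
    records: Sequence[AlignmentRecord],
    max_gap: int = 1_000_000,
    min_anchors: int = 3,
    max_gap_diff: int = 1_000,
) -> list[Chain]:
    """Group anchors into maximal-score collinear chains.

    Per (tname, qname, strand) group, the best chain is found by sparse
    DP (strictly increasing target starts; query increasing on '+',
    decreasing on '−'; inter-anchor gaps <= ``max_gap`` on both genomes
    and gap imbalance <= ``max_gap_diff``), its anchors are removed, and
    the search repeats, so each anchor joins at most one chain.  Chains
    shorter than ``min_anchors`` are discarded.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if min_anchors < 1:
        raise ValueError("min_anchors must be >= 1")
    groups: dict[tuple[str, str, str], list[AlignmentRecord]] = {}
    for rec in records:
        groups.setdefault((rec.tname, rec.qname, rec.strand), []).append(rec)
    chains: list[Chain] = []
    for (tname, qname, strand), group in sorted(groups.items()):
        pool = sorted(group, key=lambda a: (a.tstart, a.qstart))
        while pool:
            idx = _best_chain(pool, strand, max_gap, max_gap_diff)
            members = [pool[i] for i in idx]
            chosen = set(idx)
            pool = [a for i, a in enumerate(pool) if i not in chosen]
            if len(members) >= min_anchors:
                chains.append(Chain(members, sum(a.n_matches for a in members), strand))
    chains.sort(key=lambda c: (-c.score, c.tname, c.t_span[0], c.qname))
    return chains


def _overlap_len(iv: Interval, accepted: list[Interval]) -> int:
    return sum(max(0, min(iv[1], e) - max(iv[0], s)) for s, e in accepted)


def select_one_to_one(
    chains: Sequence[Chain],
    assembly: str,
    overlap_tol: float = 0.1,
    min_block_len: int = 10_000,
) -> list[SyntenyBlock]:
    """Greedy one-to-one quota filtering of chains for one assembly.

    Chains are visited in descending score (ties by target locus); a
    chain is accepted only if its reference span and its query span each
    overlap previously accepted spans by at most ``overlap_tol`` of the
    chain's own span length.  Accepted chains are collapsed to bounding
    intervals; blocks whose reference span is <= ``min_block_len`` are
    dropped.
    """
    if not (0 <= overlap_tol < 1):
        raise ValueError("overlap_tol must be in [0, 1)")
    ordered = sorted(chains, key=lambda c: (-c.score, c.tname, c.t_span[0], c.qname))
    accepted_t: dict[str, list[Interval]] = {}
    accepted_q: dict[str, list[Interval]] = {}
    blocks: list[SyntenyBlock] = []
    for chain in ordered:
        t_span, q_span = chain.t_span, chain.q_span
        t_ov = _overlap_len(t_span, accepted_t.get(chain.tname, []))
        q_ov = _overlap_len(q_span, accepted_q.get(chain.qname, []))
        if t_ov > overlap_tol * (t_span[1] - t_span[0]):
            continue
        if q_ov > overlap_tol * (q_span[1] - q_span[0]):
            continue
        accepted_t.setdefault(chain.tname, []).append(t_span)
        accepted_q.setdefault(chain.qname, []).append(q_span)
        blocks.append(
            SyntenyBlock(
                assembly=assembly,
                tname=chain.tname, tstart=t_span[0], tend=t_span[1],
                qname=chain.qname, qstart=q_span[0], qend=q_span[1],
                score=chain.score,
            )
        )
    blocks = [b for b in blocks if b.tend - b.tstart > min_block_len]
    blocks.sort(key=lambda b: (b.tname, b.tstart))
    return blocks


# ---------------------------------------------------------------------------
# coverage profile and core


@dataclass
class CoverageProfile:
    """Run-length encoded per-base count of assemblies covering the reference.

    ``runs[chrom]`` is a list of ``(start, end, count)`` covering the
    chromosome exactly (counts partition the reference).
    """

    n_assemblies: int
    ref_lengths: dict[str, int]
    runs: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    def mean_coverage(self, chrom: str, start: int, end: int) -> float:
        acc = 0
        for s, e, c in self.runs.get(chrom, []):
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                acc += (hi - lo) * c
        return acc / (end - start) if end > start else 0.0

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.runs):
                for s, e, c in self.runs[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{c}\n")


def coverage_and_core(
    blocks_by_assembly: dict[str, Sequence[SyntenyBlock]],
    ref_lengths: dict[str, int],
) -> tuple[CoverageProfile, dict[str, list[Interval]]]:
    """Sweep retained blocks into a coverage profile and extract the core.

    Core = maximal reference intervals covered by a block of *every*
    assembly.  Raises if a block exceeds its reference chromosome.
    """
    if not blocks_by_assembly:
        raise ValueError("need at least one assembly")
    n = len(blocks_by_assembly)
    events: dict[str, list[tuple[int, int]]] = {c: [] for c in ref_lengths}
    for asm, blocks in blocks_by_assembly.items():
        per_chrom: dict[str, list[Interval]] = {}
        for b in blocks:
            if b.tname not in ref_lengths:
                raise ValueError(f"block on unknown chromosome {b.tname!r}")
            if b.tend > ref_lengths[b.tname]:
                raise ValueError(f"block {b.tname}:{b.tstart}-{b.tend} exceeds reference length")
            per_chrom.setdefault(b.tname, []).append((b.tstart, b.tend))
        # merge per assembly so overlapping blocks of one assembly count once
        for chrom, ivs in per_chrom.items():
            for s, e in merge_intervals(ivs):
                events[chrom].append((s, 1))
                events[chrom].append((e, -1))
    profile = CoverageProfile(n_assemblies=n, ref_lengths=dict(ref_lengths))
    core: dict[str, list[Interval]] = {}
    for chrom, length in ref_lengths.items():
        evs = sorted(events[chrom])
        runs: list[tuple[int, int, int]] = []
        core_ivs: list[Interval] = []
        pos, count = 0, 0
        for x, delta in evs + [(length, 0)]:
            if x > pos:
                runs.append((pos, x, count))
                if count == n:
                    core_ivs.append((pos, x))
                pos = x
            count += delta
        if pos < length:
            runs.append((pos, length, count))
        profile.runs[chrom] = runs
        core[chrom] = merge_intervals(core_ivs)
    return profile, core


def core_size_series(
    present_by_assembly: dict[str, dict[str, list[Interval]]],
    n_orderings: int = 100,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Mean core size at each panel size k, averaged over random orderings.

    ``present_by_assembly[asm][chrom]`` lists the reference intervals an
    assembly covers.  For each random ordering of the assemblies the
    cumulative intersection length is recorded at every prefix size k;
    means over orderings form the decay series.
    """
    names = sorted(present_by_assembly)
    n = len(names)
    n_orderings = min(n_orderings, math.factorial(n))
    rng = stream_rng(seed, "core-size-series")
    chroms = sorted({c for d in present_by_assembly.values() for c in d})
    sums = np.zeros(n)
    for _ in range(n_orderings):
        order = rng.permutation(n)
        acc = {c: merge_intervals(present_by_assembly[names[order[0]]].get(c, [])) for c in chroms}
        sums[0] += sum(total_length(v) for v in acc.values())
        for ki in range(1, n):
            nxt = present_by_assembly[names[order[ki]]]
            acc = {c: intersect_many([acc[c], nxt.get(c, [])]) for c in chroms}
            sums[ki] += sum(total_length(v) for v in acc.values())
    return [(k + 1, sums[k] / n_orderings) for k in range(n)]


@dataclass
class DecayFit:
    A: float           # plateau (bases)
    B: float           # amplitude (bases)
    c: float           # decay rate per assembly (nan when degenerate)
    n_converge: int    # smallest k with predicted excess <= eps*A
    rmse: float
    converged: bool
    degenerate: bool = False

    def predict(self, k):
        if self.degenerate:
            return np.full_like(np.asarray(k, dtype=float), self.A)
        return self.A + self.B * np.exp(-self.c * np.asarray(k, dtype=float))


def fit_core_decay(core_sizes_by_k: Sequence[tuple[float, float]], eps: float = 0.01) -> DecayFit:
    """Fit y(k) = A + B·exp(−c·k) to the core-size decay series.

    ``n_converge`` is the smallest integer k with B·exp(−c·k) <= eps·A.
    A constant series returns the degenerate fit A = mean, B = 0.
    """
    pts = sorted(core_sizes_by_k)
    ks = np.array([k for k, _ in pts], dtype=float)
    ys = np.array([y for _, y in pts], dtype=float)
    if np.unique(ks).size < 4:
        raise ValueError("need at least 4 distinct k values")
    if np.any(ys <= 0):
        raise ValueError("core sizes must be positive")
    scale = ys.mean()
    if np.allclose(ys, ys[0], rtol=1e-12, atol=1e-9 * scale):
        return DecayFit(A=float(ys.mean()), B=0.0, c=float("nan"),
                        n_converge=int(ks[0]), rmse=0.0, converged=True, degenerate=True)

    def model(k, A, B, c):
        return A + B * np.exp(-c * k)

    A0 = max(ys.min(), 1e-9)
    B0 = max(ys[0] - A0, 1e-9) * np.exp(0.5 * ks[0])
    p0 = (A0, B0, 0.5)
    converged = True
    try:
        popt, _ = optimize.curve_fit(
            model, ks, ys, p0=p0, maxfev=20_000,
            bounds=([0, 0, 1e-9], [np.inf, np.inf, np.inf]),
        )
    except RuntimeError:
        popt = p0
        converged = False
    A, B, c = (float(x) for x in popt)
    resid = ys - model(ks, A, B, c)
    rmse = float(np.sqrt(np.mean(resid**2)))
    if B <= 0 or A <= 0:
        n_conv = int(ks[0])
    else:
        n_conv = max(1, math.ceil(math.log(B / (eps * A)) / c))
    return DecayFit(A=A, B=B, c=c, n_converge=n_conv, rmse=rmse, converged=converged)


# ---------------------------------------------------------------------------
# window features


def window_feature_correlation(
    profile: CoverageProfile,
    feature_intervals: dict[str, Sequence[Interval]],
    window: int = 1_000_000,
):
    """Per-window mean coverage vs feature density with Spearman correlation.

    Windows tile each chromosome at ``window`` bases (final partial
    window kept).  Feature density is the fraction of window bases
    covered by the feature track.  Returns ``(DataFrame, rho, p)`` with
    a two-sided Spearman rank test (midranks for ties).
    """
    import pandas as pd

    if window < 10_000:
        raise ValueError("window must be >= 10 kb")
    rows = []
    for chrom, length in sorted(profile.ref_lengths.items()):
        merged = merge_intervals(feature_intervals.get(chrom, []))
        for start in range(0, length, window):
            end = min(start + window, length)
            cov = profile.mean_coverage(chrom, start, end)
            feat = sum(
                max(0, min(e, end) - max(s, start)) for s, e in merged
            ) / (end - start)
            rows.append((chrom, start, end, cov, feat))
    if not rows:
        raise ValueError("reference produced zero windows")
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_coverage", "feature_density"])
    if len(table) < 2 or table["mean_coverage"].nunique() == 1 or table["feature_density"].nunique() == 1:
        return table, float("nan"), float("nan")
    rho, p = stats.spearmanr(table["mean_coverage"], table["feature_density"])
    return table, float(rho), float(p)


def write_core_bed(path, core: dict[str, list[Interval]]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(core):
            for s, e in core[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_blocks_bed(path, blocks: Iterable[SyntenyBlock]) -> None:
    with open(path, "w") as fh:
        for b in sorted(blocks, key=lambda b: (b.tname, b.tstart)):
            fh.write(
                f"{b.tname}\t{b.tstart}\t{b.tend}\t{b.assembly}\t"
                f"{b.qname}:{b.qstart}-{b.qend}\t{b.score}\n"
            )
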