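"""Chaining, one-to-one selection, coverage/core and decay fitting.

Chaining and selection are checked against exhaustive/naive re-implementations
on small random instances; the decay fit against its own generating function.
"""

import itertools
import math

import numpy as np
import pytest

from coremark import synteny
from coremark._util import jaccard
from coremark.synteny import AlignmentRecord, Chain


def rec(tstart, tend, qstart, qend, strand="+", score=None, tname="chr1", qname="q1"):
    return AlignmentRecord(
        qname=qname, qlen=1_000_000, qstart=qstart, qend=qend, strand=strand,
        tname=tname, tlen=1_000_000, tstart=tstart, tend=tend,
        n_matches=score if score is not None else (tend - tstart),
        aln_len=tend - tstart, mapq=60,
    )


# ---------------------------------------------------------------------------
# PAF parsing


def test_read_paf_empty_file(tmp_path):
    p = tmp_path / "empty.paf"
    p.write_text("")
    assert synteny.read_paf(p) == []


def test_read_paf_roundtrip(tmp_path):
    p = tmp_path / "one.paf"
    r = rec(500, 900, 100, 200)
    synteny.write_paf(p, [r])
    (parsed,) = synteny.read_paf(p)
    assert (parsed.qstart, parsed.qend, parsed.tstart, parsed.tend) == (100, 200, 500, 900)


def test_read_paf_rejects_inverted_interval(tmp_path):
    p = tmp_path / "bad.paf"
    p.write_text("q1\t1000\t200\t100\t+\tchr1\t1000\t0\t100\t50\t100\t60\n")
    with pytest.raises(ValueError, match="bad.paf:1"):
        synteny.read_paf(p)


def test_read_paf_rejects_short_line(tmp_path):
    p = tmp_path / "short.paf"
    p.write_text("q1\t1000\t100\t200\n")
    with pytest.raises(ValueError, match="12"):
        synteny.read_paf(p)


# ---------------------------------------------------------------------------
# chaining oracle


def chainable_oracle(a, b, strand, max_gap, max_gap_diff):
    tg = b.tstart - a.tend
    if strand == "+":
        qg = b.qstart - a.qend
    else:
        qg = a.qstart - b.qend
    return 0 <= tg <= max_gap and 0 <= qg <= max_gap and abs(tg - qg) <= max_gap_diff


def exhaustive_chains(records, max_gap, min_anchors, max_gap_diff):
    """Repeatedly extract the max-score valid chain by full subset search."""
    groups = {}
    for r in records:
        groups.setdefault((r.tname, r.qname, r.strand), []).append(r)
    chains = []
    for (t, q, strand), group in sorted(groups.items()):
        pool = sorted(group, key=lambda a: (a.tstart, a.qstart))
        while pool:
            best, best_score = None, -1
            for size in range(1, len(pool) + 1):
                for combo in itertools.combinations(range(len(pool)), size):
                    members = [pool[i] for i in combo]
                    if all(
                        chainable_oracle(members[i], members[i + 1], strand, max_gap, max_gap_diff)
                        for i in range(len(members) - 1)
                    ):
                        score = sum(m.n_matches for m in members)
                        if score > best_score:
                            best, best_score = combo, score
            members = [pool[i] for i in best]
            pool = [a for i, a in enumerate(pool) if i not in set(best)]
            if len(members) >= min_anchors:
                chains.append(Chain(members, best_score, strand))
    return chains


def test_two_anchors_below_min_anchors():
    records = [rec(0, 100, 0, 100), rec(150, 250, 150, 250)]
    assert synteny.chain_anchors(records, min_anchors=3) == []


def test_collinear_run_with_outlier():
    run = [rec(i * 200, i * 200 + 100, i * 200, i * 200 + 100) for i in range(5)]
    outlier = rec(420, 520, 5000, 5100)  # off the diagonal
    chains = synteny.chain_anchors(run + [outlier], max_gap=200)
    assert len(chains) == 1
    assert len(chains[0].anchors) == 5
    assert outlier not in chains[0].anchors


def test_minus_strand_rule():
    # query coordinates decrease as target increases: valid only on '-'
    minus = [rec(i * 200, i * 200 + 100, 1000 - i * 200, 1100 - i * 200, "-") for i in range(3)]
    assert len(synteny.chain_anchors(minus, max_gap=200)) == 1
    plus = [
        AlignmentRecord(r.qname, r.qlen, r.qstart, r.qend, "+", r.tname, r.tlen,
                        r.tstart, r.tend, r.n_matches, r.aln_len, r.mapq)
        for r in minus
    ]
    assert synteny.chain_anchors(plus, max_gap=200) == []


def random_instance(rng, n_max=12):
    """Random anchors: a couple of noisy diagonals plus scattered outliers."""
    records = []
    n = 0
    for _d in range(int(rng.integers(1, 3))):
        strand = rng.choice(["+", "-"])
        t = int(rng.integers(0, 300))
        q = int(rng.integers(0, 300))
        run_len = int(rng.integers(2, 6))
        for _ in range(run_len):
            if n >= n_max:
                break
            length = int(rng.integers(20, 80))
            if strand == "+":
                records.append(rec(t, t + length, q, q + length, "+",
                                   score=int(rng.integers(10, 100))))
                q += length + int(rng.integers(0, 60))
            else:
                records.append(rec(t, t + length, q - length, q, "-",
                                   score=int(rng.integers(10, 100))))
                q -= length + int(rng.integers(0, 60))
            t += length + int(rng.integers(0, 60))
            n += 1
    while n < int(rng.integers(3, n_max + 1)):
        length = int(rng.integers(20, 80))
        t = int(rng.integers(0, 600))
        q = int(rng.integers(0, 600))
        records.append(rec(t, t + length, q, q + length, rng.choice(["+", "-"]),
                           score=int(rng.integers(10, 100))))
        n += 1
    return records


@pytest.mark.parametrize("batch", range(4))
def test_chaining_matches_exhaustive_search(batch):
    rng = np.random.default_rng(1000 + batch)
    for _ in range(50):
        records = random_instance(rng)
        for min_anchors in (1, 2, 3):
            got = synteny.chain_anchors(records, max_gap=120, min_anchors=min_anchors,
                                        max_gap_diff=80)
            want = exhaustive_chains(records, 120, min_anchors, 80)
            assert sorted(c.score for c in got) == sorted(c.score for c in want)
            assert sum(len(c.anchors) for c in got) == sum(len(c.anchors) for c in want)


# ---------------------------------------------------------------------------
# one-to-one selection


def naive_select(chains, overlap_tol, min_block_len):
    """Independent greedy re-implementation using per-base position sets."""
    ordered = sorted(chains, key=lambda c: (-c.score, c.tname, c.t_span[0], c.qname))
    used_t, used_q, accepted = {}, {}, []
    for ch in ordered:
        t = set(range(*ch.t_span))
        q = set(range(*ch.q_span))
        ut = used_t.setdefault(ch.tname, set())
        uq = used_q.setdefault(ch.qname, set())
        if len(t & ut) <= overlap_tol * len(t) and len(q & uq) <= overlap_tol * len(q):
            ut |= t
            uq |= q
            accepted.append(ch)
    return sorted(
        (ch.t_span for ch in accepted if ch.t_span[1] - ch.t_span[0] > min_block_len)
    )


def mkchain(tstart, tend, qstart, qend, score):
    return Chain([rec(tstart, tend, qstart, qend, score=score)], score, "+")


def test_disjoint_chains_both_accepted():
    blocks = synteny.select_one_to_one(
        [mkchain(0, 200, 0, 200, 90), mkchain(300, 500, 300, 500, 80)], "a", min_block_len=50
    )
    assert [(b.tstart, b.tend) for b in blocks] == [(0, 200), (300, 500)]


def test_identical_span_keeps_higher_score():
    blocks = synteny.select_one_to_one(
        [mkchain(0, 200, 0, 200, 900), mkchain(0, 200, 500, 700, 700)], "a", min_block_len=50
    )
    assert len(blocks) == 1
    assert blocks[0].score == 900


def test_eight_chain_instance_matches_exhaustive_max_score_set():
    """Fixed instance where greedy acceptance equals the optimal 1:1 subset."""
    chains = [
        mkchain(0, 100, 0, 100, 95),
        mkchain(0, 100, 300, 400, 60),     # conflicts on reference with #1
        mkchain(150, 260, 150, 260, 80),
        mkchain(150, 260, 600, 700, 40),   # conflicts with #3
        mkchain(300, 420, 300, 420, 70),
        mkchain(500, 640, 150, 260, 50),   # conflicts on query with #3
        mkchain(500, 640, 800, 940, 65),
        mkchain(700, 820, 1000, 1120, 30),
    ]
    got = sorted(
        ((b.tstart, b.tend) for b in synteny.select_one_to_one(chains, "a", 0.1, 50))
    )
    # exhaustive max-score 1:1-feasible subset
    best_set, best_score = None, -1
    for size in range(len(chains) + 1):
        for combo in itertools.combinations(chains, size):
            ok = True
            for a, b in itertools.combinations(combo, 2):
                t_ov = max(0, min(a.t_span[1], b.t_span[1]) - max(a.t_span[0], b.t_span[0]))
                q_ov = max(0, min(a.q_span[1], b.q_span[1]) - max(a.q_span[0], b.q_span[0]))
                if t_ov > 0.1 * min(a.t_span[1] - a.t_span[0], b.t_span[1] - b.t_span[0]):
                    ok = False
                if q_ov > 0.1 * min(a.q_span[1] - a.q_span[0], b.q_span[1] - b.q_span[0]):
                    ok = False
            score = sum(c.score for c in combo)
            if ok and score > best_score:
                best_set, best_score = combo, score
    want = sorted(c.t_span for c in best_set if c.t_span[1] - c.t_span[0] > 50)
    assert got == want


@pytest.mark.parametrize("seed", range(8))
def test_selection_matches_naive_greedy(seed):
    rng = np.random.default_rng(2000 + seed)
    chains = []
    for _ in range(int(rng.integers(3, 12))):
        t = int(rng.integers(0, 800))
        q = int(rng.integers(0, 800))
        ln = int(rng.integers(50, 300))
        chains.append(mkchain(t, t + ln, q, q + ln, int(rng.integers(10, 1000))))
    got = sorted((b.tstart, b.tend) for b in synteny.select_one_to_one(chains, "a", 0.1, 60))
    assert got == naive_select(chains, 0.1, 60)


# ---------------------------------------------------------------------------
# coverage and core


def block(tstart, tend, asm="a"):
    return synteny.SyntenyBlock(asm, "chr1", tstart, tend, "q1", tstart, tend, tend - tstart)


def test_single_assembly_core_is_its_coverage():
    profile, core = synteny.coverage_and_core({"a": [block(0, 1000)]}, {"chr1": 1000})
    assert core["chr1"] == [(0, 1000)]
    assert profile.runs["chr1"] == [(0, 1000, 1)]


def test_two_assembly_intersection():
    profile, core = synteny.coverage_and_core(
        {"a": [block(0, 600)], "b": [block(400, 1000, "b")]}, {"chr1": 1000}
    )
    assert core["chr1"] == [(400, 600)]


def test_coverage_partitions_reference():
    rng = np.random.default_rng(7)
    blocks = {}
    for asm in "abc":
        ivs = []
        for _ in range(5):
            s = int(rng.integers(0, 900))
            ivs.append(block(s, s + int(rng.integers(10, 100)), asm))
        blocks[asm] = ivs
    profile, _core = synteny.coverage_and_core(blocks, {"chr1": 1000})
    assert sum(e - s for s, e, _c in profile.runs["chr1"]) == 1000


def test_block_beyond_reference_rejected():
    with pytest.raises(ValueError, match="exceeds"):
        synteny.coverage_and_core({"a": [block(0, 2000)]}, {"chr1": 1000})


def test_core_recovery_on_simulated_pangenome(pangenome):
    t = pangenome
    blocks = {}
    for name, _seq in t.assemblies:
        chains = synteny.chain_anchors(t.truth_alignments[name])
        blocks[name] = synteny.select_one_to_one(chains, name)
    _profile, core = synteny.coverage_and_core(blocks, {t.reference_name: t.ref_len})
    assert jaccard(core[t.reference_name], t.truth_core) >= 0.95


# ---------------------------------------------------------------------------
# decay fit


def test_constant_series_degenerate_fit():
    fit = synteny.fit_core_decay([(k, 40.0) for k in range(1, 10)])
    assert fit.degenerate
    assert fit.A == 40.0 and fit.B == 0.0
    assert math.isnan(fit.c)


def test_noiseless_parameter_recovery():
    ks = np.arange(1, 10)
    ys = 40 + 200 * np.exp(-0.5 * ks)
    fit = synteny.fit_core_decay(list(zip(ks, ys)))
    assert abs(fit.A - 40) < 0.01
    assert abs(fit.c - 0.5) < 0.001
    # analytic convergence point: 200 exp(-0.5 k) <= 0.4  =>  k >= 12.43
    assert fit.n_converge == 13


def test_too_few_points_rejected():
    with pytest.raises(ValueError):
        synteny.fit_core_decay([(1, 100.0), (2, 80.0), (3, 70.0)])


def test_decay_recovery_under_noise():
    ks = np.arange(1, 13)
    recovered = []
    for rep in range(20):
        rng = np.random.default_rng(300 + rep)
        ys = (100 + 400 * np.exp(-0.6 * ks)) * (1 + rng.normal(0, 0.02, ks.size))
        fit = synteny.fit_core_decay(list(zip(ks, ys)))
        recovered.append(fit.A)
    assert np.all(np.abs(np.array(recovered) - 100) / 100 < 0.05)


def test_core_size_series_monotone(pangenome):
    t = pangenome
    present = {a: {t.reference_name: t.present_intervals(a)} for a, _ in t.assemblies}
    series = synteny.core_size_series(present, n_orderings=10, seed=2)
    sizes = [y for _k, y in series]
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))
    # k = n is the full intersection regardless of ordering
    truth_len = sum(e - s for s, e in t.truth_core)
    assert sizes[-1] == pytest.approx(truth_len)


# ---------------------------------------------------------------------------
# window features


def test_window_correlation_perfect_positive_and_negative():
    profile = synteny.CoverageProfile(
        n_assemblies=3, ref_lengths={"chr1": 100_000},
        runs={"chr1": [(0, 20_000, 0), (20_000, 40_000, 1), (40_000, 60_000, 2),
                        (60_000, 80_000, 3), (80_000, 100_000, 1)]},
    )
    pos = {"chr1": [(20_000, 24_000), (40_000, 48_000), (60_000, 72_000), (80_000, 84_000)]}
    table, rho, _p = synteny.window_feature_correlation(profile, pos, window=20_000)
    assert len(table) == 5
    assert rho == pytest.approx(1.0)
    # anti-monotone with the coverage ranks (tied windows get tied densities)
    neg = {"chr1": [(0, 18_000), (20_000, 30_000), (40_000, 46_000),
                    (60_000, 62_000), (80_000, 90_000)]}
    _t, rho_neg, _p = synteny.window_feature_correlation(profile, neg, window=20_000)
    assert rho_neg == pytest.approx(-1.0)


def test_window_correlation_matches_midrank_formula():
    rng = np.random.default_rng(21)
    counts = rng.integers(0, 4, size=20)
    runs = [(i * 10_000, (i + 1) * 10_000, int(c)) for i, c in enumerate(counts)]
    profile = synteny.CoverageProfile(3, {"chr1": 200_000}, {"chr1": runs})
    feats = {"chr1": [(i * 10_000, i * 10_000 + int(w)) for i, w in
                      enumerate(rng.integers(0, 10_000, size=20))]}
    table, rho, _p = synteny.window_feature_correlation(profile, feats, window=10_000)

    def midranks(x):
        order = np.argsort(x, kind="stable")
        ranks = np.empty(len(x))
        sx = np.array(x)[order]
        i = 0
        while i < len(x):
            j = i
            while j < len(x) and sx[j] == sx[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return ranks

    rx = midranks(table["mean_coverage"].to_numpy())
    ry = midranks(table["feature_density"].to_numpy())
    expect = np.corrcoef(rx, ry)[0, 1]
    assert rho == pytest.approx(expect, abs=1e-12)
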