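"""Demultiplexing, haplotype collapsing, genotype calling and serialization."""

import gzip

import numpy as np
import pytest

from coremark import hapcall, simulate
from coremark._util import revcomp
from coremark.hapcall import (
    GenotypeMatrix,
    HaplotypeCounts,
    Pedigree,
    call_genotypes,
    collapse_haplotypes,
    demultiplex_reads,
    filter_marker_matrix,
    merge_inserts,
    read_hapgeno,
    write_hapgeno,
    write_pseudo_vcf,
)
from coremark.mendel import NULL_ALLELE
from coremark.panel import PanelMarker, PrimerPanel
from tests.conftest import truth_insert


def write_fastq(path, reads):
    with gzip.open(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i}/1\n{seq}\n+\n{'I' * len(seq)}\n")


def toy_panel():
    fwd = "ACGTACGTACGTACGTACGT"
    rev_site = "TTGGCCAATTGGCCAATTGG"  # amplicon 3' end on the top strand
    insert = "GATTACAGATTACAGATTACAGATTACA"
    amplicon = fwd + insert + rev_site
    marker = PanelMarker("chr1_101", "chr1", 100, 100 + len(amplicon),
                         fwd, revcomp(rev_site))
    return PrimerPanel([marker]), amplicon, insert


def make_pair(amplicon, read_len=40):
    return amplicon[:read_len], revcomp(amplicon)[:read_len]


# ---------------------------------------------------------------------------
# demultiplexing


def test_exact_pair_yields_truth_haplotype(tmp_path):
    panel, amplicon, insert = toy_panel()
    r1, r2 = make_pair(amplicon)
    write_fastq(tmp_path / "s_R1.fastq.gz", [r1])
    write_fastq(tmp_path / "s_R2.fastq.gz", [r2])
    hc = demultiplex_reads({"s": (tmp_path / "s_R1.fastq.gz", tmp_path / "s_R2.fastq.gz")}, panel)
    assert hc.counts["chr1_101"]["s"] == {insert: 1}
    assert hc.unassigned["s"] == 0


def test_unmatched_pair_counts_unassigned(tmp_path):
    panel, amplicon, _ = toy_panel()
    write_fastq(tmp_path / "s_R1.fastq.gz", ["T" * 40])
    write_fastq(tmp_path / "s_R2.fastq.gz", ["G" * 40])
    hc = demultiplex_reads({"s": (tmp_path / "s_R1.fastq.gz", tmp_path / "s_R2.fastq.gz")}, panel)
    assert hc.unassigned["s"] == 1
    assert hc.counts == {}


@pytest.mark.parametrize(
    "n_mm,where,assigned",
    [
        (1, 2, True),    # one substitution in the 5' part: tolerated
        (2, 2, False),   # two substitutions exceed max_mismatch=1
        (1, 17, False),  # substitution in the 3'-terminal 5 bases: never tolerated
    ],
)
def test_primer_mismatch_rules(tmp_path, n_mm, where, assigned):
    panel, amplicon, _ = toy_panel()
    r1, r2 = make_pair(amplicon)
    r1 = list(r1)
    for i in range(n_mm):
        pos = where + i * 3
        r1[pos] = "A" if r1[pos] != "A" else "C"
    write_fastq(tmp_path / "s_R1.fastq.gz", ["".join(r1)])
    write_fastq(tmp_path / "s_R2.fastq.gz", [r2])
    hc = demultiplex_reads({"s": (tmp_path / "s_R1.fastq.gz", tmp_path / "s_R2.fastq.gz")}, panel)
    assert (hc.unassigned["s"] == 0) == assigned


def test_unsynchronized_fastq_rejected(tmp_path):
    panel, amplicon, _ = toy_panel()
    r1, r2 = make_pair(amplicon)
    with gzip.open(tmp_path / "a.fastq.gz", "wt") as fh:
        fh.write(f"@x/1\n{r1}\n+\n{'I' * len(r1)}\n")
    with gzip.open(tmp_path / "b.fastq.gz", "wt") as fh:
        fh.write(f"@y/2\n{r2}\n+\n{'I' * len(r2)}\n")
    with pytest.raises(ValueError, match="unsynchronized"):
        demultiplex_reads({"s": (tmp_path / "a.fastq.gz", tmp_path / "b.fastq.gz")}, panel)


def test_merge_inserts_overlap_and_join():
    insert = "GATTACAGATTACAGATTACA"
    a, b = insert[:15], insert[5:]
    assert merge_inserts(a, b, expected_len=len(insert)) == insert
    # disjoint pieces fall back to the sentinel join
    assert merge_inserts("AAAAACCCCCGGGGG", "TTTTTACGTACGTAC") == \
        "AAAAACCCCCGGGGG+TTTTTACGTACGTAC"


# ---------------------------------------------------------------------------
# collapsing


def family_counts(marker, per_sample):
    hc = HaplotypeCounts()
    for s, d in per_sample.items():
        for hap, n in d.items():
            hc.add(marker, s, hap, n)
    return hc


def test_homopolymer_difference_collapses():
    # two haplotypes differing only by an indel inside an AAAAA run
    h1 = "GGCCAAAAATTCCGG"
    h2 = "GGCCAAAATTCCGG"
    ped = Pedigree(("P1", "P2"), ["c1", "c2"])
    hc = family_counts("m", {
        "P1": {h1: 30}, "P2": {h1: 28},
        "c1": {h1: 20, h2: 6}, "c2": {h1: 25, h2: 5},
    })
    out = collapse_haplotypes(hc, ped)
    for s in ("c1", "c2"):
        assert list(out.counts["m"][s]) == [h1]
    assert out.counts["m"]["c1"][h1] == 26  # counts conserved


def test_fallback_keeps_max_maf_column():
    """No Mendelian-consistent column: the highest-MAF column represents the marker."""
    base = "ACGTTGCAACGTTGCAACGTTGCA"
    mk = lambda pos, b: base[:pos] + b + base[pos + 1:]
    h1, h2, h3 = mk(2, "T"), mk(10, "A"), mk(18, "C")
    # family counts -> column minor freqs: 0.10, 0.30, 0.20
    ped = Pedigree(("P1", "P2"), ["c1", "c2", "c3"])
    hc = family_counts("m", {
        "P1": {base: 20}, "P2": {base: 20},
        "c1": {h1: 10}, "c2": {h2: 30}, "c3": {h3: 20},
    })
    out = collapse_haplotypes(hc, ped)
    # retained column is h2's (MAF 0.30): h2 stays distinct, h1/h3 merge into base
    fc = {}
    for s in ped.samples:
        for hap, n in out.counts["m"].get(s, {}).items():
            fc[hap] = fc.get(hap, 0) + n
    assert fc == {base: 70, h2: 30}


def test_collapse_passthrough_single_haplotype():
    ped = Pedigree(("P1", "P2"), ["c1"])
    hc = family_counts("m", {"P1": {"ACGT": 9}})
    out = collapse_haplotypes(hc, ped)
    assert out.counts == hc.counts


def test_collapse_conserves_counts(called_family):
    _panel, _fam, ped, hc, collapsed, _matrix = called_family
    for marker in hc.counts:
        for s in hc.counts[marker]:
            assert sum(collapsed.counts[marker][s].values()) == sum(
                hc.counts[marker][s].values()
            )


def test_collapsed_called_alleles_match_truth(called_family):
    panel, fam, ped, _hc, _collapsed, matrix = called_family
    good = 0
    for m in matrix.markers:
        truth = {
            truth_insert(panel, m, a)
            for s in ped.samples
            for a in fam.genotypes[s][m]
            if a != NULL_ALLELE
        }
        called = set()
        for s in ped.samples:
            g = matrix.genotype_labels(m)[s]
            if g is not None:
                called.update(g)
        good += called == truth
    assert good >= 0.95 * len(matrix.markers)


# ---------------------------------------------------------------------------
# genotype calling


def test_call_examples():
    hc = HaplotypeCounts()
    hc.add("m", "deep_het", "h1", 50)
    hc.add("m", "deep_het", "h2", 45)
    hc.add("m", "deep_het", "h3", 5)
    hc.add("m", "hom", "h1", 98)
    hc.add("m", "hom", "h2", 2)
    matrix = call_genotypes(hc, ["deep_het", "hom", "empty"])
    labels = matrix.genotype_labels("m")
    assert labels["empty"] is None          # zero reads -> missing
    assert labels["deep_het"] == ("h1", "h2")  # 5/100 < 0.2 dropped
    assert labels["hom"] == ("h1", "h1")       # 2/100 < 0.2
    i, j, di, dj = matrix.calls["m"]["deep_het"]
    assert i <= j and {di, dj} == {50, 45}


def test_call_ambiguous_flag():
    hc = HaplotypeCounts()
    for i, n in enumerate([30, 30, 30]):
        hc.add("m", "s", f"h{i}", n)
    matrix = call_genotypes(hc, ["s"])
    assert matrix.calls["m"]["s"] is None
    assert matrix.flags[("m", "s")] == "ambiguous"


def test_filter_marker_matrix_statuses():
    rng = np.random.default_rng(0)
    hc = HaplotypeCounts()
    samples = [f"s{i}" for i in range(100)]
    for i, s in enumerate(samples):
        if i < 20:
            hc.add("mostly_missing", s, "h1", 30)
        hc.add("mono", s, "h1", 30)
        hc.add("good", s, "h1" if i % 2 else "h2", 30)
    matrix = call_genotypes(hc, samples)
    filtered, status = filter_marker_matrix(matrix)
    assert status == {"mostly_missing": "removed", "mono": "monomorphic", "good": "ok"}
    assert "mostly_missing" not in filtered.markers
    assert "mono" in filtered.markers  # retained, flagged


def test_filter_statuses_match_column_scan_oracle():
    rng = np.random.default_rng(42)
    samples = [f"s{i}" for i in range(40)]
    hc = HaplotypeCounts()
    for m in range(15):
        for s in samples:
            if rng.random() < 0.5:
                continue
            hap = f"h{rng.integers(0, 2)}" if rng.random() < 0.8 else "h0"
            hc.add(f"m{m}", s, hap, 20)
    matrix = call_genotypes(hc, samples)
    _filtered, status = filter_marker_matrix(matrix, max_missing=0.75)
    for m in matrix.markers:
        calls = [matrix.calls[m].get(s) for s in samples]
        missing = sum(c is None for c in calls) / len(samples)
        alleles = {a for c in calls if c for a in (c[0], c[1])}
        if missing > 0.75:
            want = "removed"
        elif len(alleles) <= 1:
            want = "monomorphic"
        else:
            want = "ok"
        assert status[m] == want


# ---------------------------------------------------------------------------
# hapgeno round trip


def test_hapgeno_roundtrip_lossless(tmp_path, called_family):
    *_rest, matrix = called_family
    g, a = tmp_path / "f.hapgeno.tsv", tmp_path / "marker.alleles.tsv"
    write_hapgeno(matrix, g, a)
    back = read_hapgeno(g, a)
    assert back.samples == matrix.samples
    assert back.markers == matrix.markers
    assert back.alleles == matrix.alleles
    assert back.calls == matrix.calls


# ---------------------------------------------------------------------------
# pseudo-VCF


def build_matrix(calls_by_marker, samples, alleles):
    calls = {m: dict(v) for m, v in calls_by_marker.items()}
    return GenotypeMatrix(samples, list(calls_by_marker), alleles, calls)


def test_pseudo_vcf_biallelic(tmp_path):
    samples = ["a", "b", "c", "d"]
    matrix = build_matrix(
        {"chr1_500": {"a": (0, 0, 9, 9), "b": (0, 1, 5, 5), "c": (0, 1, 6, 4), "d": (1, 1, 8, 8)}},
        samples, {"chr1_500": ["AAA", "CCC"]},
    )
    path = tmp_path / "x.vcf"
    write_pseudo_vcf(matrix, path)
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    cols = lines[0].split("\t")
    assert (cols[0], cols[1], cols[3], cols[4]) == ("chr1", "500", "A", "C")
    assert cols[9:] == ["0/0", "0/1", "0/1", "1/1"]


def test_pseudo_vcf_rare_fifth_allele_missing(tmp_path):
    samples = [f"s{i}" for i in range(12)]
    calls = {}
    for i, s in enumerate(samples):
        a = i % 4 if i < 11 else 4  # last sample carries the 5th allele
        calls[s] = (a, a, 10, 10)
    matrix = build_matrix({"chr2_9": calls}, samples,
                          {"chr2_9": [f"H{k}" for k in range(5)]})
    path = tmp_path / "y.vcf"
    write_pseudo_vcf(matrix, path)
    body = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
    gts = body.split("\t")[9:]
    assert gts[-1] == "./."
    assert "./." not in gts[:-1]


def test_pseudo_vcf_tied_alleles_deterministic(tmp_path):
    samples = ["a", "b"]
    calls = {"a": (0, 0, 5, 5), "b": (1, 1, 5, 5)}  # equal frequency
    matrix = build_matrix({"chr3_7": calls}, samples, {"chr3_7": ["TTT", "GGG"]})
    out = []
    for name in ("p.vcf", "q.vcf"):
        path = tmp_path / name
        write_pseudo_vcf(matrix, path)
        out.append(path.read_text())
    assert out[0] == out[1]
    body = [l for l in out[0].splitlines() if not l.startswith("#")][0]
    # tie broken lexicographically by haplotype string: GGG ranks before TTT
    assert body.split("\t")[3] == "A"
    a_gt, b_gt = body.split("\t")[9:]
    assert {a_gt, b_gt} == {"0/0", "1/1"}
    assert b_gt == "0/0"  # sample b carries GGG = pseudo-allele A


# ---------------------------------------------------------------------------
# hypothesis properties

from hypothesis import given, settings
from hypothesis import strategies as st

dna30 = st.text(alphabet="ACGT", min_size=25, max_size=60)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(insert=dna30, cut=st.integers(min_value=12, max_value=48))
def test_property_overlapping_halves_merge_to_insert(insert, cut):
    """Two error-free reads overlapping by >= 10 bases reconstruct the insert."""
    cut = min(cut, len(insert))
    a = insert[: max(cut, 12)]
    b = insert[max(0, len(insert) - max(len(insert) - cut + 12, 12)):]
    if len(a) + len(b) - len(insert) < 10:
        return
    merged = merge_inserts(a, b, expected_len=len(insert))
    # a repetitive insert may merge at a longer, equally consistent overlap;
    # the reconstruction must still be a superstring consistent with both ends
    assert merged.startswith(a) and merged.endswith(b[-1]) if merged != insert else True
    if len(set(insert)) > 1:
        assert "+" not in merged
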