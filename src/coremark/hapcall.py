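"""Amplicon read pairs -> per-marker haplotype genotypes.

The genotyping model treats the whole amplicon insert as one
multiallelic *microhaplotype* allele rather than calling its SNPs
separately:

1. ``demultiplex_reads`` assigns each read pair to a marker by its PCR
   primers (R1 must start with the forward primer, R2 with the reverse
   primer, each within ``max_mismatch`` substitutions but with the five
   3'-terminal primer bases exact — mirroring RNase H2 activation,
   which requires a perfect 3' match).  Primers are trimmed and the two
   inserts merged into a haplotype string (joined with '+' when they do
   not overlap).
2. ``collapse_haplotypes`` removes sequencing-error haplotypes: each
   haplotype is aligned to the marker's dominant haplotype, variant
   columns inside homopolymer runs or segregating non-Mendelian-ly in
   the family are dropped, and haplotypes are re-keyed on the surviving
   columns (read counts are conserved).
3. ``call_genotypes`` makes diploid calls from per-allele depths, and
   ``write_pseudo_vcf`` recodes the four most frequent alleles per
   marker as pseudo-bases A/C/G/T for downstream tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from ._util import revcomp
from .mendel import CrossModel, expected_offspring_ratios, segregation_chi2
from .panel import PrimerPanel


@dataclass
class Pedigree:
    parents: tuple[str, ...]
    progeny: list[str]
    cross_type: str = "F1"
    family: str = "FAM1"

    @property
    def samples(self) -> list[str]:
        return list(self.parents) + list(self.progeny)

    @classmethod
    def from_family(cls, family) -> "Pedigree":
        """Build from a simulated family truth object (duck-typed)."""
        return cls(tuple(family.parent_names), list(family.progeny),
                   family.cross_type, family.family)

    @classmethod
    def read_tsv(cls, path, cross_type: str | None = None) -> "Pedigree":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {h: header.index(h) for h in ("child", "mother", "father", "family")}
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                if cols and cols != [""]:
                    rows.append(tuple(cols[idx[h]] for h in ("child", "mother", "father", "family")))
        if not rows:
            raise ValueError(f"empty pedigree {path}")
        mothers = {r[1] for r in rows}
        fathers = {r[2] for r in rows}
        if len(mothers) != 1 or len(fathers) != 1:
            raise ValueError("pedigree must describe a single biparental family")
        mother, father = rows[0][1], rows[0][2]
        selfed = mother == father
        if cross_type is None:
            cross_type = "F2" if selfed else "F1"
        parents = (mother,) if selfed else (mother, father)
        return cls(parents, [r[0] for r in rows], cross_type, rows[0][3])


@dataclass
class HaplotypeCounts:
    """marker -> sample -> haplotype string -> read-pair count."""

    counts: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)

    def add(self, marker: str, sample: str, hap: str, n: int = 1) -> None:
        self.counts.setdefault(marker, {}).setdefault(sample, {})
        self.counts[marker][sample][hap] = self.counts[marker][sample].get(hap, 0) + n

    def total(self, marker: str, sample: str) -> int:
        return sum(self.counts.get(marker, {}).get(sample, {}).values())

    def marker_mean_depth(self, samples: Sequence[str]) -> dict[str, float]:
        out = {}
        for marker in self.counts:
            out[marker] = sum(self.total(marker, s) for s in samples) / len(samples)
        return out


# ---------------------------------------------------------------------------
# demultiplexing


def _primer_match(prefix: str, primer: str, max_mismatch: int) -> bool:
    """Hamming match with the 3'-terminal 5 bases exact (RNase H2 rule)."""
    if len(prefix) < len(primer):
        return False
    if prefix[len(primer) - 5 : len(primer)] != primer[-5:]:
        return False
    mm = 0
    for a, b in zip(prefix, primer):
        if a != b:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def _iter_pairs(r1_path, r2_path):
    from pysam import FastxFile

    with FastxFile(str(r1_path)) as f1, FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            n1 = e1.name.rsplit("/", 1)[0]
            n2 = e2.name.rsplit("/", 1)[0]
            if n1 != n2:
                raise ValueError(f"unsynchronized FASTQ pair: {e1.name!r} vs {e2.name!r}")
            yield e1.sequence, e2.sequence


def merge_inserts(a: str, b: str, expected_len: int | None = None,
                  min_overlap: int = 10, max_mismatch: int = 1) -> str:
    """Merge R1 insert with the reverse-complemented R2 insert.

    Tries the overlap implied by the expected insert length first
    (± a few bases to absorb indels), then scans all overlaps from
    longest to shortest.  Unmergeable pairs are joined with '+'.
    """
    cap = min(len(a), len(b))

    def try_overlap(o: int) -> bool:
        if o < min_overlap or o > cap:
            return False
        x, y = a[-o:], b[:o]
        if x == y:
            return True
        mm = 0
        for c1, c2 in zip(x, y):
            if c1 != c2:
                mm += 1
                if mm > max_mismatch:
                    return False
        return True

    order: list[int] = []
    if expected_len is not None:
        o0 = len(a) + len(b) - expected_len
        for d in (0, -1, 1, -2, 2, -3, 3):
            order.append(o0 + d)
    order.extend(range(cap, min_overlap - 1, -1))
    seen = set()
    for o in order:
        if o in seen:
            continue
        seen.add(o)
        if try_overlap(o):
            return a + b[o:]
    return a + "+" + b


def demultiplex_reads(
    fastq_pairs: Mapping[str, tuple],
    panel: PrimerPanel,
    max_mismatch: int = 1,
) -> HaplotypeCounts:
    """Assign read pairs to markers by primer prefixes and build haplotypes.

    ``fastq_pairs`` maps sample name to its (R1, R2) FASTQ paths.  A
    pair is assigned to a marker iff R1 begins with its forward primer
    and R2 with its reverse primer (Hamming distance <= ``max_mismatch``
    each, no indels, 3'-terminal 5 bases exact); both primers are then
    trimmed, R2 reverse-complemented, and the two inserts merged.
    """
    markers = list(panel)
    exact_fwd: dict[str, list] = {}
    for m in markers:
        exact_fwd.setdefault(m.fwd_primer, []).append(m)
    fwd_lens = sorted({len(m.fwd_primer) for m in markers})
    hc = HaplotypeCounts()
    for sample, (r1_path, r2_path) in fastq_pairs.items():
        hc.unassigned.setdefault(sample, 0)
        for r1, r2 in _iter_pairs(r1_path, r2_path):
            hit = None
            for pl in fwd_lens:
                for m in exact_fwd.get(r1[:pl], []):
                    if r2.startswith(m.rev_primer):
                        hit = m
                        break
                if hit:
                    break
            if hit is None:
                for m in markers:
                    if _primer_match(r1, m.fwd_primer, max_mismatch) and _primer_match(
                        r2, m.rev_primer, max_mismatch
                    ):
                        hit = m
                        break
            if hit is None:
                hc.unassigned[sample] += 1
                continue
            a = r1[len(hit.fwd_primer):]
            b = revcomp(r2[len(hit.rev_primer):])
            expected = hit.amplicon_len - len(hit.fwd_primer) - len(hit.rev_primer)
            hap = merge_inserts(a, b, expected_len=expected)
            hc.add(hit.marker_id, sample, hap)
    return hc


# ---------------------------------------------------------------------------
# error-haplotype collapsing


def _align_columns(hap: str, dominant: str) -> dict:
    """Symbols of ``hap`` per dominant-haplotype column.

    Columns are dominant positions (substituted base or '-' for a
    deletion) plus ``(j, 'I')`` insertion slots holding the bases
    inserted after dominant position j ('' when none).
    """
    res = edlib.align(hap, dominant, task="path", mode="NW")
    cols: dict = {}
    qi = ti = 0
    for length, op in _parse_cigar(res["cigar"]):
        if op in "=XM":
            for _ in range(length):
                if hap[qi] != dominant[ti]:
                    cols[ti] = hap[qi]
                qi += 1
                ti += 1
        elif op == "D":  # gap in hap vs dominant
            for _ in range(length):
                cols[ti] = "-"
                ti += 1
        elif op == "I":  # insertion in hap
            key = (ti - 1, "I")
            cols[key] = cols.get(key, "") + hap[qi : qi + length]
            qi += length
    return cols


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _homopolymer_positions(seq: str, min_run: int) -> set[int]:
    pos: set[int] = set()
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            pos.update(range(i, j))
        i = j
    return pos


def _call_from_counts(counts: dict, min_depth: int, min_frac: float):
    """Top-two allele call from per-allele depths; None when missing/ambiguous."""
    total = sum(counts.values())
    if total < min_depth:
        return None
    kept = [(c, a) for a, c in counts.items() if c / total >= min_frac]
    kept.sort(key=lambda x: (-x[0], str(x[1])))
    if not kept or len(kept) > 2:
        return None
    if len(kept) == 1:
        return (kept[0][1], kept[0][1])
    pair = sorted([kept[0][1], kept[1][1]], key=str)
    return (pair[0], pair[1])


def collapse_haplotypes(
    hc: HaplotypeCounts,
    pedigree: Pedigree,
    homopolymer_min: int = 4,
    seg_alpha: float = 1e-3,
    min_depth: int = 5,
    min_frac: float = 0.2,
) -> HaplotypeCounts:
    """Collapse sequencing-error haplotypes onto true allele classes.

    Per marker every haplotype is aligned (unit gap costs) to the most
    frequent one; variant columns falling inside homopolymer runs of
    the dominant haplotype, or whose family segregation fails the
    Mendelian χ² at ``seg_alpha``, are discarded.  If no column
    survives, the single column with the highest minor-allele frequency
    represents the marker.  Haplotypes are re-keyed on the retained
    columns (each class is named by its most frequent member) and
    per-sample counts are summed, so total counts are conserved.
    """
    out = HaplotypeCounts(unassigned=dict(hc.unassigned))
    samples = pedigree.samples
    for marker, per_sample in hc.counts.items():
        family_counts: dict[str, int] = {}
        for s in samples:
            for hap, n in per_sample.get(s, {}).items():
                family_counts[hap] = family_counts.get(hap, 0) + n
        haps = sorted(family_counts, key=lambda h: (-family_counts[h], h))
        if len(haps) <= 1:
            for s, d in per_sample.items():
                for hap, n in d.items():
                    out.add(marker, s, hap, n)
            continue
        dominant = haps[0]
        columns: dict[str, dict] = {h: _align_columns(h, dominant) for h in haps}
        variant_cols = sorted({c for cols in columns.values() for c in cols}, key=str)

        def col_allele(hap: str, col) -> str:
            cols = columns[hap]
            if col in cols:
                return cols[col]
            if isinstance(col, tuple):
                return ""  # no insertion
            return dominant[col]

        hp = _homopolymer_positions(dominant, homopolymer_min)
        kept_cols = []
        for col in variant_cols:
            j = col[0] if isinstance(col, tuple) else col
            if j in hp:
                continue
            kept_cols.append(col)

        # informativeness + Mendelian screen per column: a column whose
        # called genotypes are monomorphic across the family is sequencing
        # noise (its minor symbol never reaches a callable fraction) and
        # carries no haplotype information, so it is dropped outright.
        sample_items = {s: list(per_sample.get(s, {}).items()) for s in samples}

        def column_ok(col) -> bool:
            per_col_calls = {}
            for s in samples:
                acc: dict[str, int] = {}
                for hap, n in sample_items[s]:
                    a = col_allele(hap, col)
                    acc[a] = acc.get(a, 0) + n
                per_col_calls[s] = _call_from_counts(acc, min_depth, min_frac)
            distinct = {g for g in per_col_calls.values() if g is not None}
            if len(distinct) <= 1:
                return False  # uninformative noise column
            parent_calls = [per_col_calls.get(p) for p in pedigree.parents]
            if any(c is None for c in parent_calls):
                return True  # polymorphic but untestable: keep
            if pedigree.cross_type == "F2":
                model = CrossModel("F2", parent_calls[0])
            else:
                model = CrossModel(pedigree.cross_type, parent_calls[0], parent_calls[-1])
            observed: dict = {}
            for s in pedigree.progeny:
                g = per_col_calls.get(s)
                if g is not None:
                    observed[g] = observed.get(g, 0) + 1
            if not observed:
                return True
            res = segregation_chi2(observed, expected_offspring_ratios(model), seg_alpha)
            return res.verdict == "mendelian"

        mendelian_cols = [c for c in kept_cols if column_ok(c)]
        if not mendelian_cols and kept_cols:
            # every non-homopolymer column failed the segregation screen:
            # keep the single column with the biggest minor allele frequency
            # (homopolymer columns stay hard-filtered)
            total_reads = sum(family_counts.values())

            def maf(col) -> float:
                acc: dict[str, int] = {}
                for hap, n in family_counts.items():
                    a = col_allele(hap, col)
                    acc[a] = acc.get(a, 0) + n
                return 1.0 - max(acc.values()) / total_reads

            mendelian_cols = [max(kept_cols, key=lambda c: (maf(c), str(c)))]

        key_of = {h: tuple(col_allele(h, c) for c in mendelian_cols) for h in haps}
        rep: dict[tuple, str] = {}
        for h in haps:  # haps already sorted by descending family count
            rep.setdefault(key_of[h], h)
        for s, d in per_sample.items():
            for hap, n in d.items():
                out.add(marker, s, rep[key_of[hap]], n)
    return out


# ---------------------------------------------------------------------------
# genotype matrix


@dataclass
class GenotypeMatrix:
    samples: list[str]
    markers: list[str]
    alleles: dict[str, list[str]]  # marker -> haplotype strings by descending family count
    calls: dict[str, dict[str, tuple[int, int, int, int] | None]]  # (i, j, depth_i, depth_j)
    flags: dict[tuple[str, str], str] = field(default_factory=dict)

    def genotype_labels(self, marker: str) -> dict[str, tuple[str, str] | None]:
        """Calls as unordered haplotype-string pairs (mendel-facing view)."""
        cat = self.alleles[marker]
        out = {}
        for s in self.samples:
            c = self.calls[marker].get(s)
            out[s] = None if c is None else tuple(sorted((cat[c[0]], cat[c[1]])))
        return out

    def labelled_calls(self) -> dict[str, dict[str, tuple[str, str] | None]]:
        return {m: self.genotype_labels(m) for m in self.markers}

    def missing_fraction(self, marker: str) -> float:
        vals = [self.calls[marker].get(s) for s in self.samples]
        return sum(v is None for v in vals) / len(vals)

    def n_alleles_called(self, marker: str) -> int:
        seen = set()
        for c in self.calls[marker].values():
            if c is not None:
                seen.update((c[0], c[1]))
        return len(seen)


def call_genotypes(hc: HaplotypeCounts, samples: Sequence[str],
                   min_depth: int = 5, min_frac: float = 0.2) -> GenotypeMatrix:
    """Diploid calls from per-haplotype read depths.

    Total depth below ``min_depth`` -> missing; alleles at count
    fraction >= ``min_frac`` are kept (top two by count); one survivor
    -> homozygote, two -> heterozygote, more -> missing with an
    ``ambiguous`` flag.
    """
    samples = list(samples)
    markers = sorted(hc.counts)
    alleles: dict[str, list[str]] = {}
    calls: dict[str, dict[str, tuple[int, int, int, int] | None]] = {}
    flags: dict[tuple[str, str], str] = {}
    for marker in markers:
        per_sample = hc.counts[marker]
        family_counts: dict[str, int] = {}
        for s in samples:
            for hap, n in per_sample.get(s, {}).items():
                family_counts[hap] = family_counts.get(hap, 0) + n
        catalog = sorted(family_counts, key=lambda h: (-family_counts[h], h))
        rank = {h: i for i, h in enumerate(catalog)}
        alleles[marker] = catalog
        calls[marker] = {}
        for s in samples:
            counts = per_sample.get(s, {})
            total = sum(counts.values())
            if total < min_depth:
                calls[marker][s] = None
                continue
            kept = [(n, rank[h], h) for h, n in counts.items() if n / total >= min_frac]
            kept.sort(key=lambda x: (-x[0], x[1]))
            if not kept:
                calls[marker][s] = None
            elif len(kept) > 2:
                calls[marker][s] = None
                flags[(marker, s)] = "ambiguous"
            elif len(kept) == 1:
                n, i, _h = kept[0]
                calls[marker][s] = (i, i, n, n)
            else:
                (n1, i1, _), (n2, i2, _) = kept[0], kept[1]
                if i1 > i2:
                    i1, i2, n1, n2 = i2, i1, n2, n1
                calls[marker][s] = (i1, i2, n1, n2)
    return GenotypeMatrix(samples, markers, alleles, calls, flags)


def filter_marker_matrix(matrix: GenotypeMatrix, max_missing: float = 0.75):
    """Flag markers by missingness and polymorphism.

    Markers missing in more than ``max_missing`` of samples are
    ``removed``; single-allele markers are ``monomorphic`` (retained in
    the matrix, excluded from mapping exports); others ``ok``.
    Returns (filtered matrix, per-marker status dict).
    """
    status: dict[str, str] = {}
    for m in matrix.markers:
        if matrix.missing_fraction(m) > max_missing:
            status[m] = "removed"
        elif matrix.n_alleles_called(m) <= 1:
            status[m] = "monomorphic"
        else:
            status[m] = "ok"
    kept = [m for m in matrix.markers if status[m] != "removed"]
    filtered = GenotypeMatrix(
        samples=list(matrix.samples),
        markers=kept,
        alleles={m: matrix.alleles[m] for m in kept},
        calls={m: matrix.calls[m] for m in kept},
        flags={k: v for k, v in matrix.flags.items() if k[0] in kept},
    )
    return filtered, status


# ---------------------------------------------------------------------------
# hapgeno dialect


def write_hapgeno(matrix: GenotypeMatrix, geno_path, alleles_path) -> None:
    """Write the hapgeno TSV and its allele sidecar (bit-exact dialect).

    Cells are ``i/j:di,dj`` with i <= j indexing the sidecar's ranked
    haplotype strings, or ``./.`` for missing.
    """
    with open(geno_path, "w") as fh:
        fh.write("marker\t" + "\t".join(matrix.samples) + "\n")
        for m in matrix.markers:
            cells = []
            for s in matrix.samples:
                c = matrix.calls[m].get(s)
                cells.append("./." if c is None else f"{c[0]}/{c[1]}:{c[2]},{c[3]}")
            fh.write(m + "\t" + "\t".join(cells) + "\n")
    with open(alleles_path, "w") as fh:
        fh.write("marker\trank\thaplotype\n")
        for m in matrix.markers:
            for i, hap in enumerate(matrix.alleles[m]):
                fh.write(f"{m}\t{i}\t{hap}\n")


def read_hapgeno(geno_path, alleles_path) -> GenotypeMatrix:
    alleles: dict[str, list[str]] = {}
    with open(alleles_path) as fh:
        fh.readline()
        for line in fh:
            m, rank, hap = line.rstrip("\n").split("\t")
            alleles.setdefault(m, [])
            assert int(rank) == len(alleles[m]), "sidecar ranks must be dense and ordered"
            alleles[m].append(hap)
    calls: dict[str, dict[str, tuple[int, int, int, int] | None]] = {}
    markers: list[str] = []
    with open(geno_path) as fh:
        samples = fh.readline().rstrip("\n").split("\t")[1:]
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            m = cols[0]
            markers.append(m)
            calls[m] = {}
            for s, cell in zip(samples, cols[1:]):
                if cell == "./.":
                    calls[m][s] = None
                else:
                    gt, depths = cell.split(":")
                    i, j = (int(x) for x in gt.split("/"))
                    di, dj = (int(x) for x in depths.split(","))
                    calls[m][s] = (i, j, di, dj)
    return GenotypeMatrix(list(samples), markers, alleles, calls)


# ---------------------------------------------------------------------------
# pseudo-allele VCF


def write_pseudo_vcf(matrix: GenotypeMatrix, path, max_alleles: int = 4) -> None:
    """Recode the top-``max_alleles`` family alleles per marker as A/C/G/T.

    Alleles map to pseudo-bases in descending family-wide call
    frequency (ties by haplotype string); REF is always the most
    frequent (A).  A sample carrying any rarer allele is emitted as
    missing at that marker.  CHROM/POS come from the marker id.
    """
    bases = "ACGT"[:max_alleles]
    rows = []
    for m in matrix.markers:
        freq: dict[int, int] = {}
        for c in matrix.calls[m].values():
            if c is not None:
                for idx in (c[0], c[1]):
                    freq[idx] = freq.get(idx, 0) + 1
        if not freq:
            warnings.warn(f"marker {m} has zero called samples; skipped")
            continue
        ranked = sorted(freq, key=lambda i: (-freq[i], matrix.alleles[m][i]))
        top = ranked[:max_alleles]
        code = {idx: bases[r] for r, idx in enumerate(top)}
        chrom, pos = m.rsplit("_", 1)
        gts = []
        for s in matrix.samples:
            c = matrix.calls[m].get(s)
            if c is None or c[0] not in code or c[1] not in code:
                gts.append("./.")
            else:
                a, b = sorted((bases.index(code[c[0]]), bases.index(code[c[1]])))
                gts.append(f"{a}/{b}")
        alts = [bases[r] for r in range(1, len(top))]
        rows.append((chrom, int(pos), code[top[0]], ",".join(alts) or ".", gts))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({r[0] for r in rows}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples) + "\n")
        for chrom, pos, ref, alt, gts in rows:
            fh.write(f"{chrom}\t{pos}\t{chrom}_{pos}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
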