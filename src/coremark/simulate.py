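"""Synthetic pan-genomes, panel variation, biparental families and amplicon reads.

Every downstream stage of the pipeline is testable against known truth
generated here:

* ``simulate_pangenome`` — a reference chromosome with tandem-repeat
  tracts, plus diverged assemblies that each lose a set of *dispensable*
  (presence/absence) segments; truth alignments (PAF anchors split at
  every dispensable boundary) and the truth core (reference bases kept
  by every assembly) are emitted alongside.
* ``simulate_panel_variants`` — a multi-sample biallelic SNP panel on
  the reference at a controlled per-base density and genotype
  missingness (the diversity panel used for marker design).
* ``simulate_family`` — F1/F2/BC families with Poisson crossover
  recombination and optional null (non-amplifying) alleles that
  transmit Mendelian-ly but never produce reads.
* ``simulate_amplicon_reads`` — paired-end reads per sample with
  lognormal per-marker depth, substitution errors and single-base
  indels inside homopolymer runs.

Determinism: every output draws from its own RNG stream derived from
``seed`` plus a stable hash of the stream's role, so identical seeds
give byte-identical files and adding an output never perturbs others.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._util import (
    Interval,
    complement_intervals,
    merge_intervals,
    revcomp,
    stream_rng,
    total_length,
    write_fasta,
)
from .mendel import NULL_ALLELE
from .panel import PanelMarker, PrimerPanel
from .synteny import AlignmentRecord, write_paf

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _place_intervals(
    rng: np.random.Generator,
    ref_len: int,
    target_total: int,
    min_len: int,
    max_len: int,
    min_gap: int,
) -> list[Interval]:
    """Sample non-overlapping intervals totalling about ``target_total`` bases.

    Intervals keep at least ``min_gap`` bases apart so the collinear
    segments between them stay individually alignable.
    """
    placed: list[Interval] = []
    total = 0
    attempts = 0
    while total < target_total and attempts < 20_000:
        attempts += 1
        remaining = target_total - total
        hi = min(max_len, max(min_len, remaining))
        length = int(rng.integers(min_len, hi + 1))
        start = int(rng.integers(0, ref_len - length))
        ok = all(start >= e + min_gap or start + length + min_gap <= s for s, e in placed)
        if ok:
            placed.append((start, start + length))
            total += length
    return sorted(placed)


@dataclass
class PanGenomeTruth:
    reference_name: str
    reference: str
    assemblies: list[tuple[str, str]]
    dispensable_intervals: dict[str, list[Interval]]
    repeat_intervals: list[Interval]
    truth_alignments: dict[str, list[AlignmentRecord]]
    truth_core: list[Interval]

    @property
    def ref_len(self) -> int:
        return len(self.reference)

    def present_intervals(self, assembly: str) -> list[Interval]:
        return complement_intervals(self.dispensable_intervals[assembly], self.ref_len)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "reference.fa", [(self.reference_name, self.reference)])
        write_fasta(outdir / "assemblies.fa", self.assemblies)
        for name, _seq in self.assemblies:
            write_paf(outdir / f"{name}.paf", self.truth_alignments[name])
        truth = {
            "reference_name": self.reference_name,
            "ref_len": self.ref_len,
            "dispensable_intervals": {k: [list(iv) for iv in v] for k, v in self.dispensable_intervals.items()},
            "repeat_intervals": [list(iv) for iv in self.repeat_intervals],
            "truth_core": [list(iv) for iv in self.truth_core],
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


def simulate_pangenome(
    seed: int,
    ref_len: int = 2_000_000,
    n_assemblies: int = 5,
    snp_rate: float = 0.02,
    dispensable_frac: float = 0.3,
    repeat_frac: float = 0.05,
    reference_name: str = "chr1",
    min_dispensable: int = 5_000,
    max_dispensable: int = 50_000,
    min_gap: int = 20_000,
    anchor_len: int = 5_000,
) -> PanGenomeTruth:
    """Reference + diverged assemblies with presence/absence truth.

    Each assembly is the reference with substitutions at ``snp_rate``
    minus its own dispensable intervals (uniformly placed, minimum 5 kb,
    drawn independently per assembly to a total of about
    ``dispensable_frac * ref_len``).  Repeat tracts are tandem arrays of
    a unit of at most 100 bp.  Truth PAF anchors tile exactly the kept
    (collinear) segments, split at every dispensable boundary.
    """
    if ref_len < 10_000:
        raise ValueError("ref_len must be at least 10 kb")
    if not (0 <= dispensable_frac < 1 and 0 <= repeat_frac < 1):
        raise ValueError("fractions must lie in [0, 1)")
    if snp_rate >= 0.2:
        raise ValueError("snp_rate must be below 0.2")
    disp_target = int(round(dispensable_frac * ref_len))
    if 0 < disp_target < min_dispensable:
        raise ValueError(
            f"reference too small: dispensable target {disp_target} bp is below the "
            f"minimum interval length {min_dispensable} bp"
        )
    rep_target = int(round(repeat_frac * ref_len))
    if 0 < rep_target < 200:
        raise ValueError("reference too small to place the requested repeat fraction")

    rng_ref = stream_rng(seed, "reference")
    ref = _random_seq(rng_ref, ref_len)

    repeat_intervals: list[Interval] = []
    if rep_target:
        repeat_intervals = _place_intervals(
            rng_ref, ref_len, rep_target, min_len=200, max_len=max(2_000, 200), min_gap=1_000
        )
        for s, e in repeat_intervals:
            unit_len = int(rng_ref.integers(10, 101))
            unit = _random_seq(rng_ref, unit_len)
            tract = np.tile(unit, (e - s) // unit_len + 1)[: e - s]
            ref[s:e] = tract
    reference = _to_str(ref)

    assemblies: list[tuple[str, str]] = []
    dispensable: dict[str, list[Interval]] = {}
    alignments: dict[str, list[AlignmentRecord]] = {}
    for i in range(n_assemblies):
        name = f"asm{i + 1}"
        rng = stream_rng(seed, f"assembly:{name}")
        seq = ref.copy()
        snp_pos = np.nonzero(rng.random(ref_len) < snp_rate)[0]
        if snp_pos.size:
            shift = rng.integers(1, 4, size=snp_pos.size)
            codes = np.searchsorted(_BASES, seq[snp_pos])  # ACGT sorted => code
            seq[snp_pos] = _BASES[(codes + shift) % 4]
        disp = (
            _place_intervals(rng, ref_len, disp_target, min_dispensable, max_dispensable, min_gap)
            if disp_target
            else []
        )
        kept = complement_intervals(disp, ref_len)
        qlen = ref_len - total_length(disp)
        # assembly sequence = reference-with-SNPs minus dispensable intervals
        asm_seq = _to_str(np.concatenate([seq[s:e] for s, e in kept]) if kept else np.empty(0, np.uint8))
        # anchors tile each kept segment
        records: list[AlignmentRecord] = []
        offset = 0
        is_snp = np.zeros(ref_len, dtype=bool)
        is_snp[snp_pos] = True
        snp_cum = np.concatenate([[0], np.cumsum(is_snp)])
        for s, e in kept:
            seg = e - s
            n_chunks = max(1, round(seg / anchor_len))
            bounds = np.linspace(s, e, n_chunks + 1).astype(int)
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b <= a:
                    continue
                mism = int(snp_cum[b] - snp_cum[a])
                records.append(
                    AlignmentRecord(
                        qname=name, qlen=qlen,
                        qstart=offset + (a - s), qend=offset + (b - s),
                        strand="+",
                        tname=reference_name, tlen=ref_len,
                        tstart=int(a), tend=int(b),
                        n_matches=(b - a) - mism, aln_len=b - a, mapq=60,
                    )
                )
            offset += seg
        assemblies.append((name, asm_seq))
        dispensable[name] = disp
        alignments[name] = records

    truth_core = complement_intervals(
        merge_intervals([iv for ivs in dispensable.values() for iv in ivs]), ref_len
    )
    return PanGenomeTruth(
        reference_name=reference_name,
        reference=reference,
        assemblies=assemblies,
        dispensable_intervals=dispensable,
        repeat_intervals=repeat_intervals,
        truth_alignments=alignments,
        truth_core=truth_core,
    )


# ---------------------------------------------------------------------------
# diversity-panel variants


@dataclass
class PanelVariants:
    """In-memory multi-sample biallelic SNP panel (also a VCF writer)."""

    chrom: str
    positions: np.ndarray        # 0-based
    ref: list[str]
    alt: list[str]
    genotypes: np.ndarray        # (n_sites, n_samples, 2) allele indices
    missing: np.ndarray          # (n_sites, n_samples) bool
    samples: list[str]
    ref_len: int

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def write_vcf(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={self.chrom},length={self.ref_len}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.samples) + "\n")
            for i in range(self.n_sites):
                gts = []
                for j in range(len(self.samples)):
                    if self.missing[i, j]:
                        gts.append("./.")
                    else:
                        a, b = self.genotypes[i, j]
                        gts.append(f"{a}/{b}")
                fh.write(
                    f"{self.chrom}\t{int(self.positions[i]) + 1}\t.\t{self.ref[i]}\t{self.alt[i]}"
                    f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
                )


def simulate_panel_variants(
    truth: PanGenomeTruth,
    n_samples: int = 40,
    target_density: float = 0.032,
    missing_rate: float = 0.1,
    seed: int = 0,
) -> PanelVariants:
    """Biallelic SNPs on the reference at ``target_density`` variants/base.

    Site allele frequencies are uniform on [0.05, 0.95]; genotypes are
    Hardy–Weinberg draws; per-genotype missingness is independent at
    ``missing_rate``.
    """
    if not (0 < target_density <= 0.1):
        raise ValueError("target_density must lie in (0, 0.1]")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = stream_rng(seed, "panel-variants")
    n_sites = int(round(target_density * truth.ref_len))
    pos = np.sort(rng.choice(truth.ref_len, size=n_sites, replace=False))
    ref_arr = np.frombuffer(truth.reference.encode(), dtype=np.uint8)
    refs = [chr(ref_arr[p]) for p in pos]
    alts = []
    for r in refs:
        choices = [b for b in "ACGT" if b != r]
        alts.append(choices[int(rng.integers(0, 3))])
    af = rng.uniform(0.05, 0.95, size=n_sites)
    gts = (rng.random((n_sites, n_samples, 2)) < af[:, None, None]).astype(np.int8)
    missing = rng.random((n_sites, n_samples)) < missing_rate
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    return PanelVariants(
        chrom=truth.reference_name, positions=pos, ref=refs, alt=alts,
        genotypes=gts, missing=missing, samples=samples, ref_len=truth.ref_len,
    )


# ---------------------------------------------------------------------------
# families


@dataclass(frozen=True)
class MarkerLocus:
    marker_id: str
    chrom: str
    pos: int


@dataclass
class ParentHaplotypes:
    """Phased parental alleles at each marker.

    ``haplotypes[marker_id]`` is ``(p1_hap1, p1_hap2, p2_hap1, p2_hap2)``;
    allele values are arbitrary labels (full amplicon sequences for read
    simulation, or abstract symbols like 'H'/'f').
    """

    loci: list[MarkerLocus]
    chrom_lengths: dict[str, int]
    haplotypes: dict[str, tuple[str, str, str, str]]
    parent_names: tuple[str, str] = ("P1", "P2")


@dataclass
class FamilyTruth:
    cross_type: str
    loci: list[MarkerLocus]
    parent_names: tuple[str, ...]
    progeny: list[str]
    genotypes: dict[str, dict[str, tuple[str, str]]]  # sample -> marker -> allele pair
    null_markers: set[tuple[str, str]] = field(default_factory=set)  # (parent, marker)
    recomb_rate: float = 0.0
    family: str = "FAM1"

    @property
    def samples(self) -> list[str]:
        return list(self.parent_names) + list(self.progeny)

    def pedigree(self) -> list[tuple[str, str, str, str]]:
        """(child, mother, father, family) rows."""
        if self.cross_type == "F2":
            mother = father = self.parent_names[0]
        else:
            mother, father = self.parent_names[0], self.parent_names[-1]
        return [(c, mother, father, self.family) for c in self.progeny]

    def write_pedigree(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("child\tmother\tfather\tfamily\n")
            for row in self.pedigree():
                fh.write("\t".join(row) + "\n")


def _gametes(
    loci_by_chrom: dict[str, list[MarkerLocus]],
    chrom_lengths: dict[str, int],
    genotype: Mapping[str, tuple[str, str]],
    recomb_rate: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """One gamete: Poisson-count crossovers at ``recomb_rate`` cM/Mb per chromosome."""
    gamete: dict[str, str] = {}
    for chrom, loci in loci_by_chrom.items():
        length = chrom_lengths[chrom]
        expected = recomb_rate * (length / 1e6) / 100.0
        n_co = int(rng.poisson(expected)) if expected > 0 else 0
        breaks = np.sort(rng.uniform(0, length, size=n_co))
        phase = int(rng.integers(0, 2))
        for locus in loci:
            flips = int(np.searchsorted(breaks, locus.pos))
            gamete[locus.marker_id] = genotype[locus.marker_id][(phase + flips) % 2]
    return gamete


def simulate_family(
    parents: ParentHaplotypes,
    cross_type: str = "F1",
    n_progeny: int = 100,
    recomb_rate: float = 3.0,
    null_spec: Sequence[tuple] = (),
    seed: int = 0,
    family: str = "FAM1",
) -> FamilyTruth:
    """Simulate a biparental family with recombination and optional nulls.

    ``F1``/``BC`` progeny unite a gamete from each parent; ``F2``
    progeny self parent 1 (the F1 individual — pass its genotype as
    parent 1).  ``null_spec`` entries are ``(parent_index, marker_id)``
    or ``(parent_index, marker_id, hap_index)`` (default hap 1): the
    named haplotype becomes a null allele that transmits normally but
    produces no amplicon reads and is unobservable in genotype calls.
    """
    if cross_type not in ("F1", "F2", "BC"):
        raise ValueError(f"unknown cross type {cross_type!r}")
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    haps = {m: list(v) for m, v in parents.haplotypes.items()}
    null_markers: set[tuple[str, str]] = set()
    for entry in null_spec:
        pidx, marker = entry[0], entry[1]
        hidx = entry[2] if len(entry) > 2 else 1
        haps[marker][2 * pidx + hidx] = NULL_ALLELE
        null_markers.add((parents.parent_names[pidx], marker))

    p1 = {m: (v[0], v[1]) for m, v in haps.items()}
    p2 = {m: (v[2], v[3]) for m, v in haps.items()}
    loci_by_chrom: dict[str, list[MarkerLocus]] = {}
    for locus in sorted(parents.loci, key=lambda l: (l.chrom, l.pos)):
        loci_by_chrom.setdefault(locus.chrom, []).append(locus)

    rng = stream_rng(seed, f"family:{family}")
    genotypes: dict[str, dict[str, tuple[str, str]]] = {}
    if cross_type == "F2":
        parent_names: tuple[str, ...] = (parents.parent_names[0],)
        genotypes[parents.parent_names[0]] = {m: p1[m] for m in haps}
        mk_progeny = lambda: {
            m: (g1[m], g2[m])
            for g1, g2 in [(
                _gametes(loci_by_chrom, parents.chrom_lengths, p1, recomb_rate, rng),
                _gametes(loci_by_chrom, parents.chrom_lengths, p1, recomb_rate, rng),
            )]
            for m in haps
        }
    else:
        parent_names = parents.parent_names
        genotypes[parents.parent_names[0]] = {m: p1[m] for m in haps}
        genotypes[parents.parent_names[1]] = {m: p2[m] for m in haps}
        mk_progeny = lambda: {
            m: (g1[m], g2[m])
            for g1, g2 in [(
                _gametes(loci_by_chrom, parents.chrom_lengths, p1, recomb_rate, rng),
                _gametes(loci_by_chrom, parents.chrom_lengths, p2, recomb_rate, rng),
            )]
            for m in haps
        }

    progeny = [f"{family}_{i + 1:04d}" for i in range(n_progeny)]
    for child in progeny:
        genotypes[child] = mk_progeny()
    return FamilyTruth(
        cross_type=cross_type,
        loci=list(parents.loci),
        parent_names=parent_names,
        progeny=progeny,
        genotypes=genotypes,
        null_markers=null_markers,
        recomb_rate=recomb_rate,
        family=family,
    )


def observable_genotype(g: tuple[str, str]) -> tuple[str, str] | None:
    """What a genotype looks like after amplification: Ø-het appears homozygous."""
    a, b = g
    if a == NULL_ALLELE and b == NULL_ALLELE:
        return None
    if a == NULL_ALLELE:
        return (b, b)
    if b == NULL_ALLELE:
        return (a, a)
    return tuple(sorted((a, b)))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# marker panels with sequence alleles


def simulate_cross_inputs(
    n_markers: int = 50,
    n_chroms: int = 5,
    chrom_len: int = 20_000_000,
    amplicon_len_range: tuple[int, int] = (270, 300),
    primer_len: int = 20,
    n_variant_sites: int = 4,
    n_founder_alleles: int = 4,
    seed: int = 0,
) -> tuple[PrimerPanel, ParentHaplotypes]:
    """A synthetic primer panel plus phased parental amplicon alleles.

    Markers are evenly spaced along ``n_chroms`` chromosomes.  Per
    marker, ``n_founder_alleles`` distinct allele sequences differ at
    ``n_variant_sites`` positions of the insert (kept >= 10 bp away from
    the primers); the four parental haplotype slots draw from that pool,
    so parents are heterozygous at most markers.
    """
    rng = stream_rng(seed, "cross-inputs")
    loci: list[MarkerLocus] = []
    markers: list[PanelMarker] = []
    haplotypes: dict[str, tuple[str, str, str, str]] = {}
    chrom_lengths = {f"chr{c + 1}": chrom_len for c in range(n_chroms)}
    seen_primers: set[str] = set()
    for i in range(n_markers):
        chrom = f"chr{(i % n_chroms) + 1}"
        slot = i // n_chroms
        pos = int((slot + 1) * chrom_len / (n_markers // n_chroms + 2))
        amp_len = int(rng.integers(amplicon_len_range[0], amplicon_len_range[1] + 1))
        while True:
            fwd = _to_str(_random_seq(rng, primer_len))
            if fwd not in seen_primers:
                seen_primers.add(fwd)
                break
        rev_site = _to_str(_random_seq(rng, primer_len))  # amplicon 3' end, top strand
        insert_len = amp_len - 2 * primer_len
        base_insert = _random_seq(rng, insert_len)
        sites = rng.choice(np.arange(10, insert_len - 10), size=n_variant_sites, replace=False)
        alleles: list[str] = []
        while len(alleles) < n_founder_alleles:
            ins = base_insert.copy()
            ins[sites] = _random_seq(rng, n_variant_sites)
            seq = fwd + _to_str(ins) + rev_site
            if seq not in alleles:
                alleles.append(seq)
        slots = tuple(alleles[int(j)] for j in rng.integers(0, n_founder_alleles, size=4))
        marker_id = f"{chrom}_{pos + 1}"
        loci.append(MarkerLocus(marker_id, chrom, pos))
        markers.append(
            PanelMarker(
                marker_id=marker_id, chrom=chrom, start=pos, end=pos + amp_len,
                fwd_primer=fwd, rev_primer=revcomp(rev_site),
            )
        )
        haplotypes[marker_id] = slots
    panel = PrimerPanel(markers)
    return panel, ParentHaplotypes(loci, chrom_lengths, haplotypes)


# ---------------------------------------------------------------------------
# amplicon reads


def _apply_homopolymer_indels(read: list[str], rate: float, rng: np.random.Generator, min_run: int = 4) -> list[str]:
    if rate <= 0:
        return read
    out: list[str] = []
    i = 0
    n = len(read)
    while i < n:
        j = i
        while j < n and read[j] == read[i]:
            j += 1
        run = read[i:j]
        if j - i >= min_run and rng.random() < rate:
            if rng.random() < 0.5:
                run = run + [read[i]]  # single-base insertion
            else:
                run = run[:-1]         # single-base deletion
        out.extend(run)
        i = j
    return out


def _mutate_read(seq: str, sub_error: float, hp_rate: float, rng: np.random.Generator) -> str:
    read = list(seq)
    read = _apply_homopolymer_indels(read, hp_rate, rng)
    if sub_error > 0:
        arr = np.array(read)
        hits = np.nonzero(rng.random(arr.size) < sub_error)[0]
        for h in hits:
            choices = [b for b in "ACGT" if b != arr[h]]
            arr[h] = choices[int(rng.integers(0, 3))]
        read = list(arr)
    return "".join(read)


def simulate_amplicon_reads(
    panel: PrimerPanel,
    family: FamilyTruth,
    outdir,
    depth_log10_mean: float = 1.7,
    depth_log10_sd: float = 0.5,
    sub_error: float = 0.005,
    homopolymer_indel: float = 0.002,
    read_len: int = 160,
    seed: int = 0,
) -> dict[str, tuple[Path, Path]]:
    """Paired FASTQ per sample from truth genotypes.

    Per-marker mean depth is 10**Normal(depth_log10_mean,
    depth_log10_sd), shared across samples; each allele copy of a
    sample contributes Poisson(depth/2) read pairs.  R1 starts with the
    forward primer, R2 with the reverse primer; substitution errors are
    applied per base, and homopolymer runs >= 4 gain or lose a single
    base at ``homopolymer_indel`` per run.  Null alleles emit nothing.
    Qualities are constant Q40 ('I').
    """
    max_primer = max(max(len(m.fwd_primer), len(m.rev_primer)) for m in panel)
    if read_len < max_primer + 20:
        raise ValueError("read_len must be at least primer length + 20")
    for m in panel:
        if m.amplicon_len < len(m.fwd_primer) + len(m.rev_primer):
            raise ValueError(f"marker {m.marker_id}: amplicon shorter than its primers")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    depth_rng = stream_rng(seed, "marker-depth")
    marker_depth = {m.marker_id: float(10 ** depth_rng.normal(depth_log10_mean, depth_log10_sd)) for m in panel}
    paths: dict[str, tuple[Path, Path]] = {}
    for sample in family.samples:
        rng = stream_rng(seed, f"reads:{sample}")
        p1 = outdir / f"{sample}_R1.fastq.gz"
        p2 = outdir / f"{sample}_R2.fastq.gz"
        with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
            idx = 0
            for m in panel:
                geno = family.genotypes[sample].get(m.marker_id)
                if geno is None:
                    continue
                for allele in geno:
                    if allele == NULL_ALLELE:
                        continue
                    n_reads = int(rng.poisson(marker_depth[m.marker_id] / 2.0))
                    for _ in range(n_reads):
                        r1 = _mutate_read(allele[:read_len], sub_error, homopolymer_indel, rng)
                        r2 = _mutate_read(revcomp(allele)[:read_len], sub_error, homopolymer_indel, rng)
                        idx += 1
                        name = f"sim:{sample}:{idx}"
                        f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
                        f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")
        paths[sample] = (p1, p2)
    return paths


def simulate_parent_variant_vcf(
    panel: PrimerPanel,
    family: FamilyTruth,
    outdir,
    ref_lengths: Mapping[str, int],
    background_rate: float = 0.02,
    seed: int = 0,
) -> dict[str, Path]:
    """Per-parent VCFs in which null alleles manifest as primer-site variants.

    Every (parent, marker) in ``family.null_markers`` receives a SNP
    inside the marker's forward-primer window; background SNPs land
    elsewhere at ``background_rate`` per marker.  Used to audit the
    primer-mismatch explanation of hemizygous markers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for parent in family.parent_names:
        rng = stream_rng(seed, f"parent-vcf:{parent}")
        records: list[tuple[str, int]] = []
        for m in panel:
            fw = m.fwd_window()
            if (parent, m.marker_id) in family.null_markers:
                records.append((m.chrom, int(rng.integers(fw[0], fw[1]))))
            elif rng.random() < background_rate:
                lo, hi = fw[1] + 5, m.rev_window()[0] - 5
                if hi > lo:
                    records.append((m.chrom, int(rng.integers(lo, hi))))
        records.sort()
        path = outdir / f"{parent}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in sorted(ref_lengths):
                fh.write(f"##contig=<ID={chrom},length={ref_lengths[chrom]}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{parent}\n")
            for chrom, pos in records:
                fh.write(f"{chrom}\t{pos + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
        out[parent] = path
    return out
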