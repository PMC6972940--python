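"""Amplicon marker selection inside the core genome.

Markers must transfer across a structurally diverse genus, so targets
are restricted to core-genome regions and screened on three axes:

* **moderate polymorphism** — enough panel variation inside the
  amplicon to make a multiallelic haplotype tag, but not so much that
  primer sites drift (default band 2–7% variant sites per base, or the
  empirical 25th–75th percentile band);
* **data quality** — regions whose panel genotypes are mostly missing
  are unreliable (default cut: mean missing rate above 50%);
* **spacing** — roughly one marker per 200 kb, with gene-rich regions
  upweighted; a 1-Mb window with no qualified candidate falls back to
  its best-covered core region so the map keeps physical coverage.

``design_amplicons`` then finds, per selected region, primer windows
that are variant-free, unmasked and unique in the repeat-masked
reference, enclosing a 270–330 bp amplicon, maximizing the number of
panel variants captured inside the insert.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._util import Interval, merge_intervals, revcomp, stream_rng
from .panel import PanelMarker, PrimerPanel
from .repeatmask import count_kmers
from .synteny import CoverageProfile


@dataclass
class RegionStats:
    chrom: str
    start: int
    end: int
    diversity: float      # variant sites per base across the panel
    missing_rate: float   # mean missing-genotype fraction over the region's sites
    core_coverage: float  # mean assembly count
    gene_density: float   # fraction of bases overlapping the gene track
    source: str = "candidate"

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# variant access


def load_variants(vcf) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends, missing_frac) arrays from a VCF.

    Accepts a path or an in-memory ``simulate.PanelVariants``.  ``ends``
    is the reference-allele span end, so indels cover their full span.
    """
    if hasattr(vcf, "positions"):  # PanelVariants
        pos = np.asarray(vcf.positions)
        ends = pos + np.array([len(r) for r in vcf.ref])
        miss = vcf.missing.mean(axis=1) if vcf.missing.size else np.zeros(pos.size)
        return {vcf.chrom: (pos, ends, miss)}
    from cyvcf2 import VCF

    acc: dict[str, list[tuple[int, int, float]]] = {}
    handle = VCF(str(vcf))
    n_samples = len(handle.samples)
    for rec in handle:
        gts = rec.genotypes
        if n_samples:
            missing = sum(1 for g in gts if g[0] == -1 or g[1] == -1) / n_samples
        else:
            missing = 0.0
        acc.setdefault(rec.CHROM, []).append((rec.start, rec.start + len(rec.REF), missing))
    out = {}
    for chrom, rows in acc.items():
        rows.sort()
        arr = np.array(rows, dtype=float)
        out[chrom] = (arr[:, 0].astype(int), arr[:, 1].astype(int), arr[:, 2])
    return out


def _vcf_chroms(vcf) -> set[str]:
    if hasattr(vcf, "positions"):
        return {vcf.chrom}
    from cyvcf2 import VCF

    return set(VCF(str(vcf)).seqnames)


def region_stats(
    core: Mapping[str, Sequence[Interval]],
    vcf,
    gene_intervals: Mapping[str, Sequence[Interval]] | None = None,
    profile: CoverageProfile | None = None,
) -> list[RegionStats]:
    """Length/diversity/missingness statistics for every core region.

    diversity = variant records starting inside the region / length;
    missing_rate = mean missing-genotype fraction over those records
    (0 when the region has no variants).
    """
    chroms = [c for c, ivs in core.items() if ivs]
    known = _vcf_chroms(vcf)
    offenders = sorted(set(chroms) - known)
    if offenders:
        raise ValueError(f"chromosomes absent from the VCF: {', '.join(offenders)}")
    variants = load_variants(vcf)
    genes = {c: merge_intervals(v) for c, v in (gene_intervals or {}).items()}
    out: list[RegionStats] = []
    for chrom in sorted(core):
        starts, _ends, miss = variants.get(chrom, (np.empty(0, int), np.empty(0, int), np.empty(0)))
        for s, e in core[chrom]:
            lo, hi = np.searchsorted(starts, [s, e])
            n_var = int(hi - lo)
            density = n_var / (e - s)
            missing = float(miss[lo:hi].mean()) if n_var else 0.0
            cov = profile.mean_coverage(chrom, s, e) if profile is not None else float("nan")
            gd = 0.0
            for gs, ge in genes.get(chrom, []):
                gd += max(0, min(ge, e) - max(gs, s))
            out.append(RegionStats(chrom, int(s), int(e), density, missing, cov, gd / (e - s)))
    return out


def filter_candidates(
    stats: Sequence[RegionStats],
    min_len: int = 200,
    div_lo: float = 0.02,
    div_hi: float = 0.07,
    max_missing: float = 0.5,
    mode: str = "absolute",
) -> list[RegionStats]:
    """Drop regions that are short, too (in)variable, or mostly missing.

    Removal is by strict inequality: length < ``min_len``, diversity
    strictly above ``div_hi`` or strictly below ``div_lo``, or missing
    rate strictly above ``max_missing``.  ``mode='percentile'`` replaces
    the diversity band with the empirical 25th–75th percentiles.
    """
    if mode not in ("absolute", "percentile"):
        raise ValueError(f"unknown mode {mode!r}")
    if div_lo >= div_hi:
        raise ValueError("div_lo must be below div_hi")
    if mode == "percentile" and stats:
        divs = np.array([r.diversity for r in stats])
        div_lo, div_hi = (float(x) for x in np.percentile(divs, [25, 75]))
    return [
        r
        for r in stats
        if r.length >= min_len
        and not (r.diversity > div_hi or r.diversity < div_lo)
        and not (r.missing_rate > max_missing)
    ]


def select_spaced_markers(
    candidates: Sequence[RegionStats],
    spacing: int = 200_000,
    fallback_window: int = 1_000_000,
    gene_weight: float = 1.0,
    seed: int = 0,
    all_regions: Sequence[RegionStats] | None = None,
    ref_lengths: Mapping[str, int] | None = None,
) -> list[RegionStats]:
    """One candidate per ``spacing`` bin, gene-density-weighted.

    Within each bin a candidate is drawn with probability proportional
    to ``1 + gene_weight * gene_density`` (seeded RNG).  A
    ``fallback_window`` stretch with no qualified candidate at all
    admits the core region with the highest ``core_coverage`` in that
    window (from ``all_regions``, i.e. regardless of the polymorphism
    filters).  Output is position-sorted.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    chrom_ext: dict[str, int] = dict(ref_lengths or {})
    pool = list(candidates) + list(all_regions or [])
    for r in pool:
        chrom_ext[r.chrom] = max(chrom_ext.get(r.chrom, 0), r.end)
    rng = stream_rng(seed, "marker-spacing")
    by_bin: dict[tuple[str, int], list[RegionStats]] = {}
    for r in candidates:
        by_bin.setdefault((r.chrom, r.start // spacing), []).append(r)
    selected: list[RegionStats] = []
    for chrom in sorted(chrom_ext):
        n_bins = -(-chrom_ext[chrom] // spacing)
        for b in range(n_bins):
            cands = sorted(by_bin.get((chrom, b), []), key=lambda r: r.start)
            if not cands:
                continue
            w = np.array([1.0 + gene_weight * r.gene_density for r in cands])
            selected.append(cands[int(rng.choice(len(cands), p=w / w.sum()))])
        # fallback for empty 1-Mb windows
        n_win = -(-chrom_ext[chrom] // fallback_window)
        for wdx in range(n_win):
            ws, we = wdx * fallback_window, (wdx + 1) * fallback_window
            if any(ws <= r.start < we for r in candidates if r.chrom == chrom):
                continue
            pool_w = [r for r in (all_regions or []) if r.chrom == chrom and ws <= r.start < we]
            if pool_w:
                best = max(pool_w, key=lambda r: (r.core_coverage, -r.start))
                selected.append(dataclasses.replace(best, source="fallback"))
    if not selected:
        warnings.warn("no markers selected")
    selected.sort(key=lambda r: (r.chrom, r.start))
    return selected


# ---------------------------------------------------------------------------
# amplicon design


@dataclass
class MarkerDesign:
    region: RegionStats
    status: str                      # ok | failed
    marker: PanelMarker | None = None


def _bad_base_mask(seq: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """True where a base is 'N' or covered by a variant's reference span."""
    n = len(seq)
    bad = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
    diff = np.zeros(n + 1, dtype=np.int64)
    np.add.at(diff, np.clip(starts, 0, n), 1)
    np.add.at(diff, np.clip(ends, 0, n), -1)
    return bad | (np.cumsum(diff[:-1]) > 0)


def design_amplicons(
    selected: Sequence[RegionStats],
    masked_reference: Mapping[str, str],
    vcf,
    primer_len_range: tuple[int, int] = (18, 27),
    amplicon_range: tuple[int, int] = (270, 330),
    k: int = 31,
) -> list[MarkerDesign]:
    """Place conserved, unique primer pairs inside each selected region.

    Both primer windows must be free of panel variants and of masked
    ('N') bases, and the ``k``-mer anchored at the forward primer start
    (and the one ending at the amplicon end) must occur exactly once in
    the masked reference — the uniqueness screen that keeps
    amplification on target.  Among feasible (start, length) pairs the
    design maximizes the number of panel variants enclosed between the
    primers; ties go to the leftmost, shortest amplicon.  Regions with
    no feasible pair are reported with status ``failed``.
    """
    primer_len = min(max(20, primer_len_range[0]), primer_len_range[1])
    table = count_kmers(masked_reference, k)
    variants = load_variants(vcf)
    masks: dict[str, np.ndarray] = {}
    uniq_cache: dict[str, np.ndarray] = {}
    results: list[MarkerDesign] = []
    for region in selected:
        chrom = region.chrom
        seq = masked_reference[chrom]
        starts, ends, _miss = variants.get(chrom, (np.empty(0, int), np.empty(0, int), np.empty(0)))
        if chrom not in masks:
            bad = _bad_base_mask(seq, starts, ends)
            masks[chrom] = np.concatenate([[0], np.cumsum(bad)])
            # canonical k-mer uniqueness per window start
            from .repeatmask import _encode, _window_codes

            codes, valid = _window_codes(_encode(seq), k)
            counts = table._lookup(codes)
            uniq_cache[chrom] = valid & (counts == 1)
        bad_cum = masks[chrom]
        uniq = uniq_cache[chrom]
        lo_amp, hi_amp = amplicon_range
        best: tuple[int, int, int] | None = None  # (-n_var, start, length)
        s_lo, s_hi = region.start, region.end
        for L in range(lo_amp, hi_amp + 1):
            smax = s_hi - L
            if smax < s_lo:
                break
            s = np.arange(s_lo, smax + 1)
            e = s + L
            f_ok = (bad_cum[s + primer_len] - bad_cum[s]) == 0
            r_ok = (bad_cum[e] - bad_cum[e - primer_len]) == 0
            u_ok = np.zeros(s.size, dtype=bool)
            in_f = s < uniq.size
            u_ok[in_f] = uniq[s[in_f]]
            u2 = (e - k >= 0) & (e - k < uniq.size)
            u_ok &= np.where(u2, uniq[np.clip(e - k, 0, max(uniq.size - 1, 0))], False)
            ok = f_ok & r_ok & u_ok
            if not ok.any():
                continue
            n_var = np.searchsorted(starts, e[ok] - primer_len) - np.searchsorted(starts, s[ok] + primer_len)
            i_best = int(np.lexsort((s[ok], -n_var))[0])
            cand = (-int(n_var[i_best]), int(s[ok][i_best]), L)
            if best is None or cand < best:
                best = cand
        if best is None:
            results.append(MarkerDesign(region, "failed"))
            continue
        n_var, s0, L = -best[0], best[1], best[2]
        fwd = seq[s0 : s0 + primer_len]
        rev = revcomp(seq[s0 + L - primer_len : s0 + L])
        marker = PanelMarker(
            marker_id=f"{chrom}_{s0 + 1}",
            chrom=chrom, start=s0, end=s0 + L,
            fwd_primer=fwd, rev_primer=rev,
            n_target_variants=int(n_var), status="ok",
        )
        results.append(MarkerDesign(region, "ok", marker))
    return results


def designs_to_panel(designs: Sequence[MarkerDesign]) -> PrimerPanel:
    return PrimerPanel([d.marker for d in designs if d.marker is not None])
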