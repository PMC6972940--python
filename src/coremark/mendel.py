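"""Mendelian segregation QC for biparental amplicon families.

Haplotype markers genotyped in a mapping family should segregate at the
ratios implied by the parental genotypes; a Pearson χ² goodness-of-fit
test flags distorted markers.  A recurrent cause of apparent distortion
in amplicon data is *hemizygosity*: one parental allele is missing from
a homolog or fails to amplify (a null allele, written Ø).  A Ø-carrying
heterozygote is observed as homozygous for its visible allele, which
shifts the observable class ratios.  ``hemizygosity_scan`` re-tests a
distorted or monoallelic marker under every one- and two-null parental
model and reports the best-fitting one; a marker is "rescued" when some
null model restores Mendelian expectations.

Cross types:

* ``F1``/``BC`` — progeny unite one gamete from each of the two given
  parents (for a backcross, pass the recurrent parent and the F1).
* ``F2`` — progeny derive from selfing parent 1 (the F1 individual).

Genotypes are unordered allele pairs; alleles are arbitrary hashable
labels (haplotype strings, pseudo-alleles, sex-locus symbols...).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: sentinel for a hemizygous / non-amplifying (null) allele
NULL_ALLELE = "Ø"

Allele = Hashable
Genotype = tuple[Allele, Allele]

CROSS_TYPES = ("F1", "F2", "BC")
#: default χ² distortion tolerances per cross type
DEFAULT_TOLERANCE = {"F1": 1e-3, "BC": 1e-3, "F2": 1e-10}


def _norm(g: Sequence[Allele]) -> Genotype:
    a, b = g
    return tuple(sorted((a, b), key=str))  # type: ignore[return-value]


@dataclass(frozen=True)
class CrossModel:
    cross_type: str
    parent1: Genotype
    parent2: Genotype | None = None  # None for a selfed F2

    def __post_init__(self):
        if self.cross_type not in CROSS_TYPES:
            raise ValueError(f"unknown cross type {self.cross_type!r}")
        if self.cross_type != "F2" and self.parent2 is None:
            raise ValueError(f"{self.cross_type} cross needs two parents")
        for p in (self.parent1, self.parent2):
            if p is not None and all(a == NULL_ALLELE for a in p):
                raise ValueError("a parent cannot carry two null alleles")

    @property
    def null_count(self) -> int:
        alleles = list(self.parent1) + list(self.parent2 or ())
        return sum(1 for a in alleles if a == NULL_ALLELE)

    def describe(self) -> str:
        fmt = lambda g: "/".join(str(a) for a in g)
        p2 = self.parent1 if self.parent2 is None else self.parent2
        op = "self" if self.cross_type == "F2" else "x"
        return f"{fmt(self.parent1)} {op} {fmt(p2)}"


def expected_offspring_ratios(model: CrossModel) -> dict[Genotype, float]:
    """Observable offspring genotype-class probabilities by gamete enumeration.

    Each parent transmits either allele at probability 1/2, giving four
    equiprobable unions.  A genotype with one Ø is *observed* as
    homozygous for its visible allele; Ø/Ø is unobservable (missing) and
    the remaining probabilities are renormalized.
    """
    p1 = model.parent1
    p2 = model.parent1 if model.cross_type == "F2" else model.parent2
    assert p2 is not None
    probs: dict[Genotype, Fraction] = {}
    for a, b in itertools.product(p1, p2):
        if a == NULL_ALLELE and b == NULL_ALLELE:
            continue  # unobservable; renormalized below
        if a == NULL_ALLELE:
            g = (b, b)
        elif b == NULL_ALLELE:
            g = (a, a)
        else:
            g = (a, b)
        g = _norm(g)
        probs[g] = probs.get(g, Fraction(0)) + Fraction(1, 4)
    total = sum(probs.values())
    if total == 0:
        raise ValueError("no observable offspring class")
    return {g: float(p / total) for g, p in sorted(probs.items(), key=lambda kv: str(kv[0]))}


@dataclass
class SegregationResult:
    observed: dict[Genotype, int]
    expected: dict[Genotype, float]
    chi2: float
    df: int
    p: float
    verdict: str  # mendelian | distorted | monomorphic | failed
    model: CrossModel | None = None


def segregation_chi2(
    observed: Mapping[Genotype, int],
    expected: Mapping[Genotype, float],
    tolerance: float = 1e-3,
) -> SegregationResult:
    """Pearson χ² goodness of fit of observed class counts to expected ratios.

    df = number of expected classes − 1; upper-tail p.  An observed
    class with zero expected probability yields verdict ``failed``
    (the model cannot produce the data), not an exception.
    """
    observed = {_norm(g): int(c) for g, c in observed.items() if c > 0}
    n = sum(observed.values())
    if n <= 0:
        raise ValueError("no observed offspring")
    exp_classes = {_norm(g): p for g, p in expected.items() if p > 0}
    stray = set(observed) - set(exp_classes)
    if stray:
        return SegregationResult(dict(observed), dict(exp_classes), float("inf"),
                                 max(len(exp_classes) - 1, 0), 0.0, "failed")
    classes = sorted(exp_classes, key=str)
    obs = np.array([observed.get(g, 0) for g in classes], dtype=float)
    exp = np.array([exp_classes[g] * n for g in classes], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = len(classes) - 1
    if df == 0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(chi2, df))
    verdict = "distorted" if p < tolerance else "mendelian"
    return SegregationResult(dict(observed), dict(exp_classes), chi2, df, p, verdict)


# ---------------------------------------------------------------------------
# hemizygosity scan


def _null_models(base: CrossModel) -> list[CrossModel]:
    """All cross models obtained by masking parental alleles with Ø.

    One-null models replace a single allele of either parent; two-null
    models replace one allele in each parent (never both alleles of one
    parent, which would be unobservable).  Duplicates collapse.
    """
    def variants(parent: Genotype | None) -> list[Genotype | None]:
        if parent is None:
            return [None]
        a, b = parent
        out = []
        for masked in ({(NULL_ALLELE, b), (a, NULL_ALLELE)}):
            if not all(x == NULL_ALLELE for x in masked):
                out.append(_norm(masked))
        return sorted(set(out), key=str)

    models: dict[tuple, CrossModel] = {}
    p1s = variants(base.parent1)
    p2s = variants(base.parent2)
    singles = [(p1, base.parent2) for p1 in p1s] + [(base.parent1, p2) for p2 in p2s if base.parent2 is not None]
    doubles = [(p1, p2) for p1 in p1s for p2 in p2s if base.parent2 is not None]
    for p1, p2 in singles + doubles:
        try:
            m = CrossModel(base.cross_type, _norm(p1), None if p2 is None else _norm(p2))
        except ValueError:
            continue
        models[(m.parent1, m.parent2)] = m
    base_key = (_norm(base.parent1), None if base.parent2 is None else _norm(base.parent2))
    models.pop(base_key, None)
    return list(models.values())


def hemizygosity_scan(
    observed: Mapping[Genotype, int],
    base_model: CrossModel,
    tolerance: float = 1e-3,
) -> tuple[SegregationResult, list[SegregationResult]]:
    """Re-test a marker under every one/two-null parental model.

    Returns the best result (maximum p; the base no-null model competes
    too) and all per-model results.  The marker is *rescued* when the
    best model has a null allele and p >= tolerance.
    """
    results: list[SegregationResult] = []
    for model in [base_model] + _null_models(base_model):
        try:
            exp = expected_offspring_ratios(model)
        except ValueError:
            continue
        res = segregation_chi2(observed, exp, tolerance)
        res.model = model
        results.append(res)
    best = max(results, key=lambda r: (r.p, -(r.model.null_count if r.model else 0)))
    return best, results


# ---------------------------------------------------------------------------
# marker classification


@dataclass
class MarkerQC:
    marker: str
    klass: str  # failed | monomorphic | distorted | mappable
    chi2: float
    p: float
    mean_depth: float
    rescued: bool = False
    best_model: str = ""
    best_p: float = float("nan")


def classify_markers(
    calls: Mapping[str, Mapping[str, Genotype | None]],
    mean_depth: Mapping[str, float],
    parents: tuple[str, str] | tuple[str],
    progeny: Sequence[str],
    cross_type: str = "F1",
    tolerance: float | None = None,
) -> pd.DataFrame:
    """Classify each marker as failed / monomorphic / distorted / mappable.

    * failed — mean family read depth below 1.
    * monomorphic — at most one distinct allele among progeny calls.
    * distorted — χ² of progeny classes vs parental expectation below
      the cross-specific tolerance.
    * mappable — everything else (including markers whose parents are
      uncalled, which cannot be segregation-tested; χ² is NaN there).

    Distorted and monomorphic markers are additionally scanned under
    hemizygous (null-allele) models and flagged ``rescued`` when a null
    model restores Mendelian fit.
    """
    tol = DEFAULT_TOLERANCE[cross_type] if tolerance is None else tolerance
    rows: list[MarkerQC] = []
    for marker in calls:
        sample_calls = calls[marker]
        depth = float(mean_depth.get(marker, 0.0))
        prog = [sample_calls.get(s) for s in progeny]
        obs_counts: dict[Genotype, int] = {}
        alleles: set[Allele] = set()
        for g in prog:
            if g is None:
                continue
            g = _norm(g)
            obs_counts[g] = obs_counts.get(g, 0) + 1
            alleles.update(g)
        if depth < 1.0:
            rows.append(MarkerQC(marker, "failed", float("nan"), float("nan"), depth))
            continue
        parent_calls = [sample_calls.get(p) for p in parents]
        have_parents = all(g is not None for g in parent_calls)
        base = None
        if have_parents:
            if cross_type == "F2":
                base = CrossModel("F2", _norm(parent_calls[0]))
            else:
                base = CrossModel(cross_type, _norm(parent_calls[0]), _norm(parent_calls[-1]))
        if len(alleles) <= 1 or not obs_counts:
            qc = MarkerQC(marker, "monomorphic", float("nan"), float("nan"), depth)
            if base is not None and obs_counts:
                best, _ = hemizygosity_scan(obs_counts, base, tol)
                qc.best_model = best.model.describe() if best.model else ""
                qc.best_p = best.p
                qc.rescued = bool(best.model and best.model.null_count > 0 and best.p >= tol)
            rows.append(qc)
            continue
        if base is None:
            rows.append(MarkerQC(marker, "mappable", float("nan"), float("nan"), depth))
            continue
        res = segregation_chi2(obs_counts, expected_offspring_ratios(base), tol)
        if res.verdict in ("distorted", "failed"):
            best, _ = hemizygosity_scan(obs_counts, base, tol)
            rescued = bool(best.model and best.model.null_count > 0 and best.p >= tol)
            rows.append(MarkerQC(marker, "distorted", res.chi2, res.p, depth, rescued,
                                 best.model.describe() if best.model else "", best.p))
        else:
            rows.append(MarkerQC(marker, "mappable", res.chi2, res.p, depth))
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# primer-mismatch audit


def primer_variant_check(parent_vcfs: Mapping[str, str], panel) -> pd.DataFrame:
    """Flag markers whose primer windows carry a variant in a parent.

    A variant record intersects a primer window when the span of its
    reference allele overlaps the window (indel-aware).  Returns a tidy
    frame (marker, parent, flag).
    """
    from cyvcf2 import VCF

    windows = {}
    for m in panel:
        windows.setdefault(m.chrom, []).append((m.marker_id, m.fwd_window(), m.rev_window()))
    rows = []
    for parent, path in parent_vcfs.items():
        hit: set[str] = set()
        for rec in VCF(str(path)):
            start = rec.POS - 1
            end = start + len(rec.REF)
            for marker_id, fw, rw in windows.get(rec.CHROM, []):
                if (start < fw[1] and end > fw[0]) or (start < rw[1] and end > rw[0]):
                    hit.add(marker_id)
        for m in panel:
            rows.append((m.marker_id, parent, m.marker_id in hit))
    return pd.DataFrame(rows, columns=["marker", "parent", "primer_mismatch"])


def primer_mismatch_summary(flags: pd.DataFrame, rescued_markers: set[str]) -> dict[str, float]:
    """Fraction of markers with any primer mismatch, split by hemizygosity rescue."""
    any_hit = flags.groupby("marker")["primer_mismatch"].any()
    res = any_hit.index.isin(rescued_markers)
    out = {}
    out["rescued"] = float(any_hit[res].mean()) if res.any() else float("nan")
    out["other"] = float(any_hit[~res].mean()) if (~res).any() else float("nan")
    return out


# ---------------------------------------------------------------------------
# IBS distance and MDS


def ibs_matrix(
    calls: Mapping[str, Mapping[str, Genotype | None]],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Pairwise identity-by-state over shared non-missing markers.

    Per marker a pair scores (number of shared alleles)/2, i.e. 1 for an
    identical genotype, 1/2 for one shared allele, 0 for none; IBS is
    the mean over markers called in both samples (NaN when none).
    """
    samples = list(samples)
    n = len(samples)
    shared = np.zeros((n, n))
    count = np.zeros((n, n))
    for marker in calls:
        row = [calls[marker].get(s) for s in samples]
        for i in range(n):
            gi = row[i]
            if gi is None:
                continue
            for j in range(i, n):
                gj = row[j]
                if gj is None:
                    continue
                a = list(gi)
                score = 0
                for allele in gj:
                    if allele in a:
                        a.remove(allele)
                        score += 1
                shared[i, j] += score / 2.0
                count[i, j] += 1
    with np.errstate(invalid="ignore"):
        ibs = np.where(count > 0, shared / np.maximum(count, 1), np.nan)
    ibs = np.where(count > 0, ibs, np.nan)
    full = np.triu(ibs) + np.triu(ibs, 1).T
    return pd.DataFrame(full, index=samples, columns=samples)


def ibs_mds(
    calls: Mapping[str, Mapping[str, Genotype | None]],
    samples: Sequence[str],
    n_coords: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """1−IBS distance matrix and classical (metric) MDS coordinates.

    Classical MDS double-centers the squared distance matrix and takes
    the top eigenvectors scaled by the square roots of their
    eigenvalues.  Samples with no shared markers against some other
    sample are excluded with a warning.
    """
    if len(samples) < 3:
        raise ValueError("MDS needs at least 3 samples")
    ibs = ibs_matrix(calls, samples)
    dist = 1.0 - ibs
    keep = list(dist.index)
    while np.isnan(dist.loc[keep, keep].to_numpy()).any():
        nan_counts = dist.loc[keep, keep].isna().sum(axis=1)
        worst = nan_counts.idxmax()
        warnings.warn(f"sample {worst} shares no markers with some samples; excluded from MDS")
        keep.remove(worst)
    D = dist.loc[keep, keep].to_numpy()
    n = len(keep)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_coords, n)
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0, None))
    cols = [f"MDS{i + 1}" for i in range(k)]
    return dist.loc[keep, keep], pd.DataFrame(coords, index=keep, columns=cols)
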