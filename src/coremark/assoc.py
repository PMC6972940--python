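"""Marker–trait association with kinship correction.

The model is the standard single-random-effect mixed linear model

    y = Xα + Pβ + u + ε,    u ~ N(0, σg²·K),   ε ~ N(0, σe²·I)

with y the phenotype, X the marker design (genotype-class indicators
for multiallelic haplotype markers, or allele dosage for biallelic
input), P fixed covariates (typically the first two MDS coordinates)
and K the centered identity-by-state kinship matrix.

Estimation follows the spectral (EMMA-style) scheme: with
K = U·diag(s)·Uᵀ the model whitens to weighted least squares with
weights 1/(s_i + δ), δ = σe²/σg².  δ is estimated once by REML on the
null (covariates-only) model via a log-grid plus golden-section
refinement, then held fixed for every marker test (the
"population parameters previously determined" approximation), so each
marker costs one weighted F-test.  Per-marker R² is the reduction in
generalized residual sum of squares.  When the REML optimum sits at
the no-genetic-variance boundary the weights collapse to identity and
every test reduces exactly to ordinary least squares.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mendel import ibs_matrix


def centered_ibs_kinship(
    calls: Mapping[str, Mapping[str, tuple | None]],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Double-centered pairwise IBS matrix (row/col means removed, grand mean added)."""
    if len(samples) < 2:
        raise ValueError("kinship needs at least 2 samples")
    ibs = ibs_matrix(calls, samples)
    arr = ibs.to_numpy()
    if np.isnan(arr).any():
        bad = [s for s, row in zip(samples, np.isnan(arr)) if row.all()]
        raise ValueError(f"samples with no genotype data: {bad or 'pairwise gaps'}")
    row = arr.mean(axis=1, keepdims=True)
    col = arr.mean(axis=0, keepdims=True)
    K = arr - row - col + arr.mean()
    K = (K + K.T) / 2
    return pd.DataFrame(K, index=list(samples), columns=list(samples))


# ---------------------------------------------------------------------------
# REML for the variance ratio


def _reml_loglik(delta: float, ys: np.ndarray, Ws: np.ndarray, s: np.ndarray) -> float:
    """Restricted log-likelihood of the null model at variance ratio δ.

    Inputs are already rotated by the eigenvectors of K; weights are
    1/(s+δ).
    """
    n, q = Ws.shape
    d = s + delta
    w = 1.0 / d
    WtW = (Ws * w[:, None]).T @ Ws
    try:
        beta = np.linalg.solve(WtW, (Ws * w[:, None]).T @ ys)
    except np.linalg.LinAlgError:
        return -np.inf
    r = ys - Ws @ beta
    rss = float(np.sum(w * r * r))
    sign, logdet_WtW = np.linalg.slogdet(WtW)
    if sign <= 0 or rss <= 0:
        return -np.inf
    return -0.5 * (
        (n - q) * math.log(rss / (n - q))
        + np.sum(np.log(d))
        + logdet_WtW
        + (n - q)
    )


def _estimate_delta(ys, Ws, s, grid=(-6.0, 8.0), n_grid: int = 120) -> tuple[float, bool]:
    """Grid + golden-section REML estimate of δ; flags the σg²≈0 boundary."""
    logd = np.linspace(grid[0], grid[1], n_grid)
    ll = np.array([_reml_loglik(10.0**x, ys, Ws, s) for x in logd])
    i = int(np.nanargmax(ll))
    if i >= n_grid - 2:
        return math.inf, True  # genetic variance indistinguishable from zero
    lo, hi = logd[max(i - 1, 0)], logd[min(i + 1, n_grid - 1)]
    phi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = _reml_loglik(10.0**c, ys, Ws, s), _reml_loglik(10.0**d, ys, Ws, s)
    for _ in range(60):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = _reml_loglik(10.0**c, ys, Ws, s)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = _reml_loglik(10.0**d, ys, Ws, s)
    return 10.0 ** ((a + b) / 2), False


@dataclass
class AssocResult:
    table: pd.DataFrame          # marker, p, neg_log10_p, effect, r2, df
    delta: float                 # σe²/σg² used for every test
    identity_limit: bool         # True when σg² ≈ 0 (tests are exactly OLS)
    threshold: float             # −log10 Bonferroni bound
    skipped: list[str] = field(default_factory=list)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["neg_log10_p"] >= self.threshold]


def _design_from_genotypes(genos: Sequence, coding: str) -> tuple[np.ndarray, bool]:
    """Marker design matrix: genotype-class indicators or allele dosage."""
    if coding == "dosage":
        alleles = sorted({a for g in genos for a in g})
        if len(alleles) > 2:
            raise ValueError("dosage coding needs a biallelic marker")
        ref = alleles[0]
        x = np.array([[sum(1 for a in g if a != ref)] for g in genos], dtype=float)
        return x, x.std() > 0
    classes = sorted({tuple(sorted(g, key=str)) for g in genos}, key=str)
    if len(classes) < 2:
        return np.zeros((len(genos), 0)), False
    cols = classes[1:]  # first class absorbed by the intercept
    x = np.array([[1.0 if tuple(sorted(g, key=str)) == c else 0.0 for c in cols] for g in genos])
    return x, True


def mlm_associate(
    y: Mapping[str, float] | pd.Series,
    marker_genotypes: Mapping[str, Mapping[str, tuple | None]],
    covariates: pd.DataFrame | None,
    K: pd.DataFrame,
    coding: str = "indicator",
    alpha: float = 0.05,
) -> AssocResult:
    """Per-marker mixed-model tests with a shared REML variance ratio.

    Samples with missing phenotype are dropped listwise; per marker,
    samples with missing genotype are dropped for that test.  Markers
    with a singular fixed-effect design are skipped with a diagnostic.
    """
    y = pd.Series(y, dtype=float).dropna()
    samples = [s for s in K.index if s in y.index]
    if covariates is not None:
        samples = [s for s in samples if s in covariates.index]
    if len(samples) < 5:
        raise ValueError("too few phenotyped samples")
    yv = y.loc[samples].to_numpy()
    Karr = K.loc[samples, samples].to_numpy()
    s_eig, U = np.linalg.eigh(Karr)
    s_eig = np.clip(s_eig, 0.0, None)
    P = covariates.loc[samples].to_numpy() if covariates is not None else np.empty((len(samples), 0))
    W = np.column_stack([np.ones(len(samples)), P])
    ys, Ws = U.T @ yv, U.T @ W
    delta, identity = _estimate_delta(ys, Ws, s_eig)
    weights = np.ones_like(s_eig) if identity else 1.0 / (s_eig + delta)
    sw = np.sqrt(weights)

    yw = sw * ys
    Ww = sw[:, None] * Ws
    sample_pos = {smp: i for i, smp in enumerate(samples)}
    rows = []
    skipped: list[str] = []
    for marker, genos in marker_genotypes.items():
        idx = [sample_pos[smp] for smp in samples if genos.get(smp) is not None]
        if len(idx) < 5:
            skipped.append(marker)
            continue
        gl = [genos[samples[i]] for i in idx]
        try:
            Xm, poly = _design_from_genotypes(gl, coding)
        except ValueError:
            skipped.append(marker)
            continue
        if not poly:
            skipped.append(marker)
            continue
        # rotate/weight only the retained rows: recompute on the subset
        sub = np.array(idx)
        if len(idx) == len(samples):
            yws, Wws = yw, Ww
            Xw = sw[:, None] * (U.T @ _expand(Xm, sub, len(samples)))
        else:
            # missing genotypes: refit the rotation on the subset kinship
            Ksub = Karr[np.ix_(sub, sub)]
            s2, U2 = np.linalg.eigh(Ksub)
            s2 = np.clip(s2, 0.0, None)
            w2 = np.ones_like(s2) if identity else 1.0 / (s2 + delta)
            sw2 = np.sqrt(w2)
            yws = sw2 * (U2.T @ yv[sub])
            Wws = sw2[:, None] * (U2.T @ W[sub])
            Xw = sw2[:, None] * (U2.T @ Xm)
        res = _gls_f_test(yws, Wws, Xw)
        if res is None:
            skipped.append(marker)
            continue
        p, eff, r2, df = res
        rows.append((marker, p, -math.log10(max(p, 1e-300)), eff, r2, df))
    table = pd.DataFrame(rows, columns=["marker", "p", "neg_log10_p", "effect", "r2", "df"])
    thr = bonferroni_threshold(max(len(table), 1), alpha)
    return AssocResult(table, delta, identity, thr, skipped)


def _expand(Xm: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, Xm.shape[1]))
    out[idx] = Xm
    return out


def _gls_f_test(yw, Ww, Xw):
    """F-test of the marker columns given covariates, on whitened data."""
    n = yw.size
    full = np.column_stack([Ww, Xw])
    q0, q1 = Ww.shape[1], full.shape[1]
    if np.linalg.matrix_rank(full) < q1 or n <= q1:
        # collinear marker design (e.g. confounded with covariates)
        if np.linalg.matrix_rank(full) <= q0:
            return None
        full = full[:, : np.linalg.matrix_rank(full)]
        q1 = full.shape[1]
        if q1 <= q0:
            return None
    beta0, rss0 = _ols_rss(yw, Ww)
    beta1, rss1 = _ols_rss(yw, full)
    df1 = q1 - q0
    df2 = n - q1
    if df2 <= 0 or rss1 <= 0:
        return None
    F = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = float(stats.f.sf(F, df1, df2))
    effect = float(np.max(np.abs(beta1[q0:]))) if q1 > q0 else 0.0
    r2 = float((rss0 - rss1) / rss0) if rss0 > 0 else 0.0
    return p, effect, r2, (df1, df2)


def _ols_rss(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r)


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Family-wise −log10 significance bound: −log10(α / N)."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return float(-math.log10(alpha / n_markers))


# ---------------------------------------------------------------------------
# genotype–phenotype concordance


def sex_concordance(
    genotypes: Mapping[str, tuple],
    phenotypes: Mapping[str, Hashable],
    dominance: Sequence[Hashable] = ("M", "H", "f"),
) -> tuple[float, dict]:
    """Best dominance-consistent mapping of genotype classes to phenotypes.

    Marker alleles are assigned labels from the dominance order (most
    to least dominant); a genotype's phenotype is its most dominant
    assigned label, except that the most recessive label requires
    homozygosity.  All assignments are enumerated and the one
    maximizing agreement with the observed phenotypes is returned with
    its agreement fraction.
    """
    shared = [s for s in genotypes if s in phenotypes and genotypes[s] is not None]
    if not shared:
        raise ValueError("no samples with both genotype and phenotype")
    alleles = sorted({a for s in shared for a in genotypes[s]}, key=str)
    rank = {lab: i for i, lab in enumerate(dominance)}
    best_frac, best_map = -1.0, {}
    for assign in itertools.product(dominance, repeat=len(alleles)):
        amap = dict(zip(alleles, assign))
        gmap: dict[tuple, Hashable] = {}
        hits = 0
        for s in shared:
            g = tuple(sorted(genotypes[s], key=str))
            if g not in gmap:
                labs = sorted((amap[g[0]], amap[g[1]]), key=lambda l: rank[l])
                gmap[g] = labs[0]
            if gmap[g] == phenotypes[s]:
                hits += 1
        frac = hits / len(shared)
        if frac > best_frac:
            best_frac, best_map = frac, {g: p for g, p in gmap.items()}
    return best_frac, best_map
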