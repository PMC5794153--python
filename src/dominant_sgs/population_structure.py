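"""Among-population structure for dominant markers: AMOVA, F_ST with a
permutation G-test, and the Mantel test for isolation by distance.

AMOVA follows Excoffier's distance-matrix formulation on squared Euclidean
distances between band-phenotype vectors; variance components come from the
expected mean squares with unequal group sizes, and significance from free
permutation of individuals among populations (or exhaustive enumeration on
tiny instances).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dominant_freqs import LocusFreqs
from .io_geo import MISSING, MarkerMatrix


def phenotype_sq_distances(markers: MarkerMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distances between phenotype vectors.

    Missing loci are dropped pairwise; to keep pairs with different
    completeness comparable, the per-pair mean squared difference over shared
    loci is rescaled to the full locus count.
    """
    x = markers.values.astype(float)
    x[markers.values == MISSING] = np.nan
    n, l = x.shape
    valid = ~np.isnan(x)
    x0 = np.where(valid, x, 0.0)
    # shared-locus counts and raw sums of squared differences, via products
    shared = valid.astype(float) @ valid.T.astype(float)
    g = x0 @ x0.T
    # sum over shared loci of (xi - xj)^2 = sum xi^2 + sum xj^2 - 2 xi.xj,
    # with the squared sums restricted to the loci valid in both individuals
    xi2 = (x0 * x0) @ valid.T.astype(float)
    d2 = xi2 + xi2.T - 2.0 * g
    if np.any(shared == 0):
        bad = np.argwhere((shared == 0) & ~np.eye(n, dtype=bool))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"individuals {markers.individual_ids[i]} and "
                f"{markers.individual_ids[j]} share no typed locus"
            )
    with np.errstate(invalid="ignore"):
        d2 = d2 * (l / shared)
    np.fill_diagonal(d2, 0.0)
    return d2


def _amova_ss(d2: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float]:
    """(SS_between, SS_within) from a squared-distance matrix and group index lists."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for idx in groups:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total - ss_within, ss_within


@dataclass
class AmovaResults:
    """One-level AMOVA partition with its permutation test."""

    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ms_between: float
    ms_within: float
    sigma2_between: float
    sigma2_within: float
    pct_between: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str
    note: str = ""

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["Between pop.", "Within pop."],
                "df": [self.df_between, self.df_within],
                "SSD": [self.ss_between, self.ss_within],
                "MSD": [self.ms_between, self.ms_within],
                "variance_pct": [self.pct_between, self.pct_within],
                "Phi": [self.phi_st, np.nan],
                "p": [self.p_value, np.nan],
            }
        )

    def summary(self) -> str:
        head = "Analysis of molecular variance (band-phenotype distances)"
        body = self.table().to_string(
            index=False, float_format=lambda v: f"{v:.4g}", na_rep=""
        )
        tail = (
            f"Phi_ST = {self.phi_st:.4f}   p = {self.p_value:.4g} "
            f"({self.method}, {self.n_permutations} permutations)"
        )
        out = "\n".join([head, "=" * len(head), body, "-" * len(head), tail])
        if self.note:
            out += f"\nnote: {self.note}"
        return out


class Amova:
    """AMOVA model over a marker matrix and population labels.

    Parameters
    ----------
    markers : MarkerMatrix
    pop_labels : array-like of str, one per individual.
    """

    def __init__(self, markers: MarkerMatrix, pop_labels) -> None:
        labels = np.asarray(pop_labels).astype(str)
        if labels.size != markers.n_individuals:
            raise ValueError("one population label per individual required")
        keep = np.ones(labels.size, dtype=bool)
        for pop, cnt in zip(*np.unique(labels, return_counts=True)):
            if cnt < 2:
                warnings.warn(
                    f"population {pop} has a single individual; excluded from AMOVA",
                    stacklevel=2,
                )
                keep &= labels != pop
        ids = [i for i, k in zip(markers.individual_ids, keep) if k]
        self.markers = markers.subset(ids)
        self.labels = labels[keep]
        if len(np.unique(self.labels)) < 2:
            raise ValueError("AMOVA needs at least two populations of size >= 2")
        self._d2 = phenotype_sq_distances(self.markers)

    def _components(self, labels: np.ndarray):
        pops, inv = np.unique(labels, return_inverse=True)
        groups = [np.flatnonzero(inv == k) for k in range(len(pops))]
        n = labels.size
        k = len(pops)
        ss_b, ss_w = _amova_ss(self._d2, groups)
        df_b, df_w = k - 1, n - k
        ms_b, ms_w = ss_b / df_b, ss_w / df_w
        sizes = np.array([len(g) for g in groups], dtype=float)
        n0 = (n - (sizes**2).sum() / n) / (k - 1)
        s2_w = ms_w
        s2_b = (ms_b - ms_w) / n0
        return df_b, df_w, ss_b, ss_w, ms_b, ms_w, s2_b, s2_w

    def _phi(self, labels: np.ndarray) -> float:
        *_, s2_b, s2_w = self._components(labels)
        tot = s2_b + s2_w
        return 0.0 if tot <= 0 else s2_b / tot

    def fit(self, n_perm: int = 999, seed: int | None = None, method: str = "permutation") -> AmovaResults:
        """Partition variance and test Phi_ST.

        ``method='exact'`` enumerates every ordering of the observed label
        vector (feasible for <= 8 individuals) and reports the exact fraction
        of orderings with Phi >= observed; ``'permutation'`` uses ``n_perm``
        random permutations with the add-one rule.
        """
        df_b, df_w, ss_b, ss_w, ms_b, ms_w, s2_b, s2_w = self._components(self.labels)
        note = ""
        tot = s2_b + s2_w
        if tot <= 0:
            phi = 0.0
            note = "all phenotypes identical: Phi undefined, reported as 0"
        else:
            phi = s2_b / tot
        pct_b = 100.0 * max(s2_b, 0.0) / max(tot, np.finfo(float).tiny)
        pct_b = min(max(pct_b, 0.0), 100.0)
        if method == "exact":
            n = self.labels.size
            if n > 9:
                raise ValueError("exact enumeration is limited to <= 9 individuals")
            count = 0
            total = 0
            for perm in itertools.permutations(range(n)):
                total += 1
                if self._phi(self.labels[list(perm)]) >= phi - 1e-12:
                    count += 1
            p = count / total
            n_used = total
        elif method == "permutation":
            rng = np.random.default_rng(seed)
            hits = 0
            lab = self.labels.copy()
            for _ in range(n_perm):
                rng.shuffle(lab)
                if self._phi(lab) >= phi - 1e-12:
                    hits += 1
            p = (hits + 1) / (n_perm + 1)
            n_used = n_perm
        else:
            raise ValueError("method must be 'permutation' or 'exact'")
        return AmovaResults(
            df_between=df_b,
            df_within=df_w,
            ss_between=ss_b,
            ss_within=ss_w,
            ms_between=ms_b,
            ms_within=ms_w,
            sigma2_between=s2_b,
            sigma2_within=s2_w,
            pct_between=pct_b,
            pct_within=100.0 - pct_b,
            phi_st=phi,
            p_value=p,
            n_permutations=n_used,
            seed=seed,
            method=method,
            note=note,
        )


def amova(markers: MarkerMatrix, pop_labels, n_perm: int = 999,
          seed: int | None = None, method: str = "permutation") -> AmovaResults:
    """Functional wrapper around :class:`Amova`."""
    return Amova(markers, pop_labels).fit(n_perm=n_perm, seed=seed, method=method)


@dataclass
class FstResult:
    fst: float
    g_statistic: float
    p_value: float
    n_permutations: int
    seed: int | None

    def summary(self) -> str:
        return (
            f"Wright's F_ST (dominant-band allele frequencies): {self.fst:.4f}\n"
            f"G = {self.g_statistic:.2f}, permutation p = {self.p_value:.4g} "
            f"({self.n_permutations} permutations of individuals among populations)"
        )


def _fst_from_freqs(p_by_pop: np.ndarray) -> float:
    """Variance-standardised F_ST over loci (ratio of sums).

    ``p_by_pop`` is (k populations, L loci) of band-allele frequencies; the
    across-population variance (ddof=1) is standardised by p_bar*(1-p_bar),
    weighting loci by p_bar*(1-p_bar) — i.e. sum of variances over sum of
    limiting variances.
    """
    p_bar = p_by_pop.mean(axis=0)
    var_k = p_by_pop.var(axis=0, ddof=1)
    w = p_bar * (1.0 - p_bar)
    keep = w > 1e-12
    if not keep.any():
        raise ValueError("all loci monomorphic: F_ST undefined")
    return float(var_k[keep].sum() / w[keep].sum())


def _g_statistic(counts_band: np.ndarray, counts_total: np.ndarray) -> float:
    """Summed per-locus G over population x {band, no-band} contingency tables."""
    obs = np.stack([counts_band, counts_total - counts_band], axis=-1).astype(float)
    # expected from margins, per locus
    col = obs.sum(axis=0, keepdims=True)          # (1, L, 2)
    row = obs.sum(axis=-1, keepdims=True)         # (k, L, 1)
    tot = obs.sum(axis=(0, -1), keepdims=True)    # (1, L, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = row * col / tot
        term = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(2.0 * np.nansum(term))


def fst_g_test(
    markers: MarkerMatrix,
    pop_labels,
    freqs_by_pop: dict[str, LocusFreqs] | None = None,
    n_perm: int = 5000,
    seed: int | None = None,
) -> FstResult:
    """Non-hierarchical Wright F_ST with a permutation G-test.

    F_ST comes from the per-population Bayesian band-allele frequencies
    (``freqs_by_pop``; if omitted, frequencies are estimated here under a
    uniform prior to keep the call self-contained).  Significance permutes
    individuals among populations and recomputes the G statistic of the
    loci-summed population x phenotype contingency counts.
    """
    labels = np.asarray(pop_labels).astype(str)
    pops = list(dict.fromkeys(labels))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    obs = markers.values
    typed_n = (obs != MISSING).sum(axis=0)
    nband_obs = (obs == 1).sum(axis=0)
    if not np.any((nband_obs > 0) & (nband_obs < typed_n)):
        raise ValueError("monomorphic marker matrix: F_ST undefined")
    if freqs_by_pop is None:
        from .dominant_freqs import band_absence_counts, estimate_locus_freqs, fit_null_prior

        freqs_by_pop = {}
        for pop in pops:
            ids = [i for i, lab in zip(markers.individual_ids, labels) if lab == pop]
            m, n = band_absence_counts(markers.subset(ids))
            keep = n > 0
            if not keep.all():
                raise ValueError(f"population {pop} has entirely-missing loci")
            prior = fit_null_prior(m / n, n)
            freqs_by_pop[pop] = estimate_locus_freqs(
                m, n, prior=prior, locus_ids=markers.locus_ids
            )
    p_by_pop = np.vstack([freqs_by_pop[pop].p_hat for pop in pops])
    fst = _fst_from_freqs(p_by_pop)

    x = markers.values
    band = (x == 1).astype(float)
    typed = (x != MISSING).astype(float)
    onehot = np.vstack([(labels == pop).astype(float) for pop in pops])
    g_obs = _g_statistic(onehot @ band, onehot @ typed)

    rng = np.random.default_rng(seed)
    hits = 0
    idx = np.arange(labels.size)
    for _ in range(n_perm):
        rng.shuffle(idx)
        oh = onehot[:, idx]
        if _g_statistic(oh @ band, oh @ typed) >= g_obs - 1e-9:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return FstResult(fst=fst, g_statistic=g_obs, p_value=p, n_permutations=n_perm, seed=seed)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None
    alternative: str

    def summary(self) -> str:
        return (
            f"Mantel r = {self.r:.4f}, p = {self.p_value:.4g} "
            f"({self.alternative}, {self.n_permutations} permutations)"
        )


def mantel_test(
    genetic_d,
    geographic_d,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel correlation between two distance matrices with a permutation test.

    r is the Pearson correlation of the lower-triangle entries; the null
    distribution permutes rows/columns of one matrix jointly (one-sided by
    default, add-one rule).
    """
    d1 = np.asarray(genetic_d, dtype=float)
    d2 = np.asarray(geographic_d, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 2 or d1.shape[0] != d1.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    if not (np.allclose(d1, d1.T) and np.allclose(d2, d2.T)):
        raise ValueError("matrices must be symmetric")
    k = d1.shape[0]
    if k < 4:
        warnings.warn(
            f"only {k} populations: the permutation null has very low resolution",
            stacklevel=2,
        )
    il = np.tril_indices(k, -1)
    v1 = d1[il]

    def _corr(mat: np.ndarray) -> float:
        v2 = mat[il]
        v1c = v1 - v1.mean()
        v2c = v2 - v2.mean()
        denom = np.sqrt((v1c**2).sum() * (v2c**2).sum())
        return float((v1c * v2c).sum() / denom) if denom > 0 else 0.0

    r_obs = _corr(d2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        r_p = _corr(d2[np.ix_(perm, perm)])
        if alternative == "greater":
            hits += r_p >= r_obs - 1e-12
        elif alternative == "two-sided":
            hits += abs(r_p) >= abs(r_obs) - 1e-12
        else:
            raise ValueError("alternative must be 'greater' or 'two-sided'")
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_perm, seed=seed,
                        alternative=alternative)
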