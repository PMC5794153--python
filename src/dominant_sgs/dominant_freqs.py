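"""Allele frequencies, diversity and Nei distances from dominant band phenotypes.

A dominant biallelic locus shows a band whenever at least one amplifiable
allele is present, so only the null-homozygote proportion z is observable.
Under within-population Hardy-Weinberg equilibrium z = q^2 for null-allele
frequency q.  Frequencies are estimated by the Bayesian scheme of
Zhivotovsky (1999): an empirical Beta(a, b) prior on z is fitted across loci
by the method of moments (correcting the between-locus variance for binomial
sampling noise), the posterior of z given m band-absent individuals out of n
typed is Beta(a+m, b+n-m), and the point estimate is the posterior mean of
q = sqrt(z), available in closed form through log-Beta functions.

Diversity follows Nei: per-locus gene diversity h = 2*p*q (with an n/(n-1)
small-sample factor for the per-population table), averaged over loci, with
the among-population component Hb = Ht - Hw taken on the uncorrected scale so
that it is non-negative by construction.  Between-population divergence uses
Nei's standard (1972) distance, with the 1978 unbiased variant behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, betaincinv

from .io_geo import MISSING, MarkerMatrix, SampleTable


@dataclass(frozen=True)
class NullPrior:
    """Beta(a, b) prior on the null-homozygote proportion z = q^2."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("prior hyperparameters must be positive")


UNIFORM_PRIOR = NullPrior(1.0, 1.0)


@dataclass
class LocusFreqs:
    """Per-locus frequency estimates within one population."""

    locus_ids: list[str]
    n: np.ndarray        # typed individuals per locus
    m: np.ndarray        # band-absent count per locus
    q_hat: np.ndarray    # posterior-mean null-allele frequency
    p_hat: np.ndarray    # band-allele frequency, 1 - q_hat
    var_q: np.ndarray    # posterior variance of q
    prior: NullPrior
    f_is: float = 0.0

    @property
    def low_information(self) -> np.ndarray:
        """Lynch-Milligan guard: loci with fewer than 3 band-absent individuals.

        Estimates are kept (the Bayesian posterior already regularises) but
        flagged for the user.
        """
        return self.m < 3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.locus_ids,
                "n": self.n,
                "m_absent": self.m,
                "q_null": self.q_hat,
                "p_band": self.p_hat,
                "var_q": self.var_q,
                "low_information": self.low_information,
            }
        )


def fit_null_prior(band_absence_fractions, sample_sizes) -> NullPrior:
    """Method-of-moments fit of the Beta prior on z across loci.

    ``band_absence_fractions`` are the observed per-locus m/n; the raw
    between-locus variance is corrected by the mean binomial sampling
    variance z(1-z)/n.  A non-positive corrected variance (e.g. all loci at
    the same fraction) falls back to the uniform prior with a warning.
    """
    z = np.asarray(band_absence_fractions, dtype=float)
    n = np.broadcast_to(np.asarray(sample_sizes, dtype=float), z.shape)
    if z.size < 2:
        warnings.warn("too few loci to fit a prior; using uniform", stacklevel=2)
        return UNIFORM_PRIOR
    if np.any((z < 0) | (z > 1)):
        raise ValueError("band-absence fractions must lie in [0, 1]")
    if z.size < 10:
        warnings.warn("fewer than 10 loci: prior fit is weakly informed", stacklevel=2)
    mu = z.mean()
    v = z.var(ddof=1) - np.mean(z * (1.0 - z) / n)
    if not (0 < mu < 1) or v <= 1e-12:
        warnings.warn(
            "corrected between-locus variance non-positive; falling back to uniform prior",
            stacklevel=2,
        )
        return UNIFORM_PRIOR
    v = min(v, mu * (1.0 - mu) * 0.999)  # keep the Beta proper
    c = mu * (1.0 - mu) / v - 1.0
    if c <= 0:
        warnings.warn("overdispersed fractions; falling back to uniform prior", stacklevel=2)
        return UNIFORM_PRIOR
    return NullPrior(mu * c, (1.0 - mu) * c)


def _posterior_mean_sqrt(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """E[sqrt(z)] for z ~ Beta(alpha, beta), in log-Gamma space."""
    return np.exp(betaln(alpha + 0.5, beta) - betaln(alpha, beta))


def _q_from_z(z: np.ndarray, f_is: float) -> np.ndarray:
    # solve z = q^2 + f*q*(1-q) for q in [0,1]
    if f_is == 0.0:
        return np.sqrt(z)
    a = 1.0 - f_is
    return (-f_is + np.sqrt(f_is * f_is + 4.0 * a * z)) / (2.0 * a)


def estimate_locus_freqs(
    m,
    n,
    prior: NullPrior = UNIFORM_PRIOR,
    locus_ids: list[str] | None = None,
    f_is: float = 0.0,
    quad_points: int = 512,
) -> LocusFreqs:
    """Posterior-mean null-allele frequencies for one population.

    With ``f_is`` = 0 the null-homozygote proportion is z = q^2 and
    q_hat = B(a+m+1/2, b+n-m) / B(a+m, b+n-m) exactly.  With inbreeding,
    z = q^2 + F_IS*q*(1-q); the posterior of z is unchanged and q_hat is the
    posterior expectation of the root q(z), evaluated by quantile-midpoint
    quadrature on the Beta posterior.
    """
    m = np.atleast_1d(np.asarray(m, dtype=float))
    n = np.broadcast_to(np.atleast_1d(np.asarray(n, dtype=float)), m.shape).astype(float)
    if np.any(n < 1):
        raise ValueError("each locus needs at least one typed individual")
    if np.any((m < 0) | (m > n)):
        raise ValueError("band-absent count m must satisfy 0 <= m <= n")
    if not (0.0 <= f_is < 1.0):
        raise ValueError("F_IS must lie in [0, 1)")
    alpha = prior.a + m
    beta = prior.b + n - m
    e_z = alpha / (alpha + beta)
    if f_is == 0.0:
        q_hat = _posterior_mean_sqrt(alpha, beta)
        e_q2 = e_z
    else:
        u = (np.arange(quad_points) + 0.5) / quad_points
        # z-quantiles per locus: (loci, quad_points)
        zq = betaincinv(alpha[:, None], beta[:, None], u[None, :])
        qq = _q_from_z(zq, f_is)
        q_hat = qq.mean(axis=1)
        e_q2 = (qq * qq).mean(axis=1)
    var_q = np.maximum(e_q2 - q_hat**2, 0.0)
    ids = locus_ids if locus_ids is not None else [f"L{i+1}" for i in range(m.size)]
    return LocusFreqs(
        locus_ids=list(ids),
        n=n.astype(int),
        m=m.astype(int),
        q_hat=q_hat,
        p_hat=1.0 - q_hat,
        var_q=var_q,
        prior=prior,
        f_is=f_is,
    )


def band_absence_counts(markers: MarkerMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(m, n) per locus: band-absent count and typed count, missing excluded."""
    x = markers.values
    typed = x != MISSING
    n = typed.sum(axis=0)
    m = ((x == 0) & typed).sum(axis=0)
    return m, n


def estimate_population_frequencies(
    markers: MarkerMatrix,
    samples: SampleTable,
    f_is: float = 0.0,
    prior: NullPrior | str = "fitted",
) -> dict[str, LocusFreqs]:
    """Zhivotovsky-prior frequency estimates for every population.

    The prior is fitted per population from its own across-locus distribution
    of band-absence fractions (``prior='fitted'``), or a shared
    :class:`NullPrior` may be supplied.
    """
    if samples.ids != markers.individual_ids:
        markers = markers.subset(samples.ids)
    out: dict[str, LocusFreqs] = {}
    labels = samples.labels()
    for pop in samples.populations:
        sub = markers.values[labels == pop]
        mm = MarkerMatrix(
            [i for i, lab in zip(markers.individual_ids, labels) if lab == pop],
            markers.locus_ids,
            sub,
        )
        m, n = band_absence_counts(mm)
        keep = n > 0
        if not keep.all():
            raise ValueError(
                f"population {pop}: {int((~keep).sum())} loci entirely missing"
            )
        pop_prior = (
            fit_null_prior(m / n, n) if isinstance(prior, str) and prior == "fitted" else prior
        )
        out[pop] = estimate_locus_freqs(
            m, n, prior=pop_prior, locus_ids=markers.locus_ids, f_is=f_is
        )
    return out


@dataclass
class DiversitySummary:
    """Within/between-population gene-diversity partition (Table-1-style)."""

    per_population: pd.DataFrame  # columns: pop, n, PPL, HE, SE_HE
    hw: float                     # mean within-population diversity (uncorrected 2pq)
    hb: float                     # between-population component, Ht - Hw
    ht: float                     # total diversity at pooled mean frequencies
    mean_he: float                # mean of the per-population HE column
    mean_ppl: float               # mean percentage of polymorphic loci
    polymorphism_threshold: float

    def summary(self) -> str:
        lines = [
            "Gene diversity (dominant markers, Bayesian allele frequencies)",
            "=" * 62,
            self.per_population.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "-" * 62,
            f"mean HE  = {self.mean_he:.4f}    mean PPL = {self.mean_ppl:.1f}%",
            f"Hw = {self.hw:.4f}   Hb = {self.hb:.4f}   Ht = {self.ht:.4f}",
        ]
        return "\n".join(lines)


def population_diversity(
    freqs_by_pop: dict[str, LocusFreqs],
    polymorphism_threshold: float = 0.05,
) -> DiversitySummary:
    """Nei gene diversity per population plus the Hw/Hb/Ht partition.

    Per-population H_E uses h_l = 2*p*q*n/(n-1) averaged over loci, its
    standard error the across-locus sd / sqrt(L), and PPL the percentage of
    loci with min(p, q) above the threshold (5% rule by default).
    """
    rows = []
    p_stack = []
    hw_terms = []
    for pop, lf in freqs_by_pop.items():
        p, q, n = lf.p_hat, lf.q_hat, lf.n.astype(float)
        corr = np.where(n > 1, n / (n - 1.0), np.nan)
        h = 2.0 * p * q * corr
        he = float(np.nanmean(h))
        nloci = lf.p_hat.size
        se = float(np.nanstd(h, ddof=1) / np.sqrt(nloci)) if nloci > 1 else float("nan")
        ppl = 100.0 * float(np.mean(np.minimum(p, q) > polymorphism_threshold))
        rows.append({"pop": pop, "n": int(round(float(np.median(lf.n)))),
                     "PPL": ppl, "HE": he, "SE_HE": se})
        p_stack.append(p)
        hw_terms.append(np.mean(2.0 * p * q))
    per_pop = pd.DataFrame(rows)
    p_arr = np.vstack(p_stack)
    p_bar = p_arr.mean(axis=0)
    ht = float(np.mean(2.0 * p_bar * (1.0 - p_bar)))
    hw = float(np.mean(hw_terms))
    return DiversitySummary(
        per_population=per_pop,
        hw=hw,
        hb=ht - hw,
        ht=ht,
        mean_he=float(per_pop["HE"].mean()),
        mean_ppl=float(per_pop["PPL"].mean()),
        polymorphism_threshold=polymorphism_threshold,
    )


def nei_distance(
    freqs_by_pop: dict[str, LocusFreqs],
    variant: str = "nei1972",
) -> pd.DataFrame:
    """Pairwise Nei genetic distance between populations, D = -ln(Jxy/sqrt(Jx*Jy)).

    Gene identities J are accumulated over loci from the biallelic (p, q)
    frequency pairs.  ``variant='nei1978'`` applies the unbiased
    small-sample correction (2n*J - 1)/(2n - 1) to the within-population
    identities.
    """
    pops = list(freqs_by_pop)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    lens = {freqs_by_pop[p].p_hat.size for p in pops}
    if len(lens) != 1:
        raise ValueError("populations must share one locus set")
    if variant not in ("nei1972", "nei1978"):
        raise ValueError("variant must be 'nei1972' or 'nei1978'")
    k = len(pops)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            fx, fy = freqs_by_pop[pops[i]], freqs_by_pop[pops[j]]
            jx_l = fx.p_hat**2 + fx.q_hat**2
            jy_l = fy.p_hat**2 + fy.q_hat**2
            if variant == "nei1978":
                nx2, ny2 = 2.0 * fx.n, 2.0 * fy.n
                jx_l = (nx2 * jx_l - 1.0) / (nx2 - 1.0)
                jy_l = (ny2 * jy_l - 1.0) / (ny2 - 1.0)
            jx = float(np.sum(jx_l))
            jy = float(np.sum(jy_l))
            jxy = float(np.sum(fx.p_hat * fy.p_hat + fx.q_hat * fy.q_hat))
            d[i, j] = d[j, i] = max(0.0, -np.log(jxy / np.sqrt(jx * jy)))
    return pd.DataFrame(d, index=pops, columns=pops)
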