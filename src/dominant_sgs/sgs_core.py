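"""Fine-scale spatial genetic structure from dominant markers.

The chain implemented here is the standard isolation-by-distance toolkit for
within-population analyses: pairwise kinship coefficients F_ij estimated from
band phenotypes under an assumed inbreeding coefficient F_IS, a distance-class
correlogram with permutation envelopes, the regression slope b_F of kinship on
ln(distance), the Sp statistic

    Sp = -b_F / (1 - F_1),

Wright's neighbourhood size N_b = (F_1 - 1)/b_F, and the axial gene-dispersal
distance sigma_g = sqrt(N_b / (4*pi*D_E)) under census and reduced effective
densities D_E.

Kinship estimator
-----------------
For a dominant locus with band-allele frequency p (null frequency q = 1 - p)
and inbreeding F, the null-homozygote probability is q*h with
h = F + (1 - F)*q, so the band indicator x has mean B = 1 - q*h.  The
pairwise moment estimator is the multilocus ratio of sums

    F_ij = sum_l (x_il - B_l)(x_jl - B_l) / sum_l 4 p_l q_l h_l^2,

whose expectation equals the kinship coefficient to first order in
relatedness (exactly for pairs sharing at most one allele identical by
descent; pairs that can share both, e.g. full sibs, are inflated by a
four-gene identity term — see the pedigree calibration tests).  At F = 0 the
denominator reduces to 4*p*q^3.  Loci missing in either individual are
dropped from both sums; loci with a constant phenotype in the analysed
population carry no information and are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dominant_freqs import LocusFreqs
from .io_geo import MISSING, MarkerMatrix


@dataclass
class KinshipMatrix:
    """Pairwise dominant-marker kinship within one population."""

    individual_ids: list[str]
    values: np.ndarray        # symmetric, nan diagonal, nan for uninformative pairs
    loci_used: np.ndarray     # per-pair count of shared informative loci
    f_is: float

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) kinship values in lexicographic pair order."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]


def kinship_dominant(
    markers: MarkerMatrix,
    locus_freqs: LocusFreqs,
    f_is: float = 0.0,
) -> KinshipMatrix:
    """Pairwise kinship from band phenotypes given per-locus frequencies.

    ``locus_freqs`` must hold the band-allele frequencies estimated for the
    same population the individuals belong to.
    """
    if not (0.0 <= f_is < 1.0):
        raise ValueError("F_IS must lie in [0, 1); F_IS = 1 degenerates the estimator")
    if len(locus_freqs.p_hat) != markers.n_loci:
        raise ValueError("frequency table does not match the marker loci")
    x = markers.values.astype(float)
    valid = markers.values != MISSING
    x[~valid] = 0.0

    p = locus_freqs.p_hat
    q = locus_freqs.q_hat
    # exclude loci with a constant observed phenotype: no pairwise information
    typed = valid.sum(axis=0)
    nband = (markers.values == 1).sum(axis=0)
    informative = (typed > 0) & (nband > 0) & (nband < typed)
    if not informative.any():
        raise ValueError("no informative (polymorphic) loci in this population")
    h = f_is + (1.0 - f_is) * q
    b = 1.0 - q * h
    w = 4.0 * p * q * h * h
    p = p[informative]
    b = b[informative]
    w = w[informative]
    x = x[:, informative]
    valid = valid[:, informative]

    dev = np.where(valid, x - b, 0.0)
    num = dev @ dev.T
    den = valid.astype(float) @ (valid * w[None, :]).T
    shared = valid.astype(float) @ valid.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(den > 0, num / den, np.nan)
    np.fill_diagonal(k, np.nan)
    k = (k + k.T) / 2.0  # enforce exact symmetry against fp noise
    return KinshipMatrix(
        individual_ids=list(markers.individual_ids),
        values=k,
        loci_used=shared.astype(int),
        f_is=f_is,
    )


@dataclass
class DistanceClassing:
    """Contiguous distance classes with near-equal pair counts."""

    bounds: np.ndarray          # length n_classes + 1, half-open [lo, hi)
    pair_counts: np.ndarray
    mean_distance: np.ndarray   # mean within-class pairwise distance
    n_classes: int
    conforming: bool = True     # False when the >=5-class floor could not be met

    def assign(self, distances: np.ndarray) -> np.ndarray:
        """Class index for each distance (last class closed above)."""
        idx = np.searchsorted(self.bounds[1:-1], distances, side="right")
        return np.clip(idx, 0, self.n_classes - 1)


def build_distance_classes(
    geo_distances: np.ndarray,
    min_pairs: int = 40,
    class_range: tuple[int, int] = (5, 30),
) -> DistanceClassing:
    """Quantile-based distance classes holding at least ``min_pairs`` pairs each.

    The number of classes is the largest value inside ``class_range`` that
    keeps every class at or above ``min_pairs``.  When even the lower bound is
    unattainable the whole range collapses to a single class, flagged
    non-conforming.
    """
    d = np.asarray(geo_distances, dtype=float)
    if d.ndim == 2:
        d = d[np.triu_indices(d.shape[0], 1)]
    n_pairs = d.size
    if n_pairs < min_pairs:
        raise ValueError(
            f"only {n_pairs} pairs available but {min_pairs} required per class; "
            "lower min_pairs for very small samples"
        )
    lo, hi = class_range
    n_classes = min(hi, n_pairs // min_pairs)
    conforming = True
    if n_classes < lo:
        warnings.warn(
            f"{n_pairs} pairs support only {n_classes} class(es) of >= {min_pairs} "
            f"pairs, below the {lo}-class floor; falling back to a single class "
            "(flagged non-conforming)",
            stacklevel=2,
        )
        n_classes = 1
        conforming = False
    while n_classes >= 1:
        qs = np.quantile(d, np.linspace(0, 1, n_classes + 1))
        qs[0] = d.min()
        qs[-1] = np.nextafter(d.max(), np.inf)  # closed top class
        # duplicate quantiles (heavily tied distances) would create empty classes
        if np.all(np.diff(qs) > 0):
            idx = np.clip(np.searchsorted(qs[1:-1], d, side="right"), 0, n_classes - 1)
            counts = np.bincount(idx, minlength=n_classes)
            if counts.min() >= min(min_pairs, n_pairs):
                means = np.array(
                    [d[idx == c].mean() for c in range(n_classes)]
                )
                return DistanceClassing(
                    bounds=qs,
                    pair_counts=counts,
                    mean_distance=means,
                    n_classes=n_classes,
                    conforming=conforming and n_classes >= lo,
                )
        n_classes -= 1
        conforming = False
    raise ValueError("could not build distance classes (degenerate distances)")


@dataclass
class SgsResult:
    """Correlogram, regression slope and derived SGS statistics."""

    classes: pd.DataFrame          # lo, hi, n_pairs, mean_dist, mean_kinship, env_lo, env_hi, significant
    f1: float                      # mean kinship, first distance class
    b_f: float                     # OLS slope of kinship on ln(distance)
    b_f_env: tuple[float, float]   # permutation envelope for the slope
    slope_significant: bool
    sp: float
    n_permutations: int
    envelope: float
    seed: int | None
    classing: DistanceClassing = field(repr=False)
    n_pairs_regression: int = 0
    no_positive_sgs: bool = False  # b_F >= 0: Sp reported but not interpretable

    def neighborhood_size(self) -> float:
        """Wright's N_b = (F_1 - 1)/b_F; requires a negative slope."""
        if self.b_f >= 0:
            raise ValueError("b_F >= 0: no positive SGS, neighbourhood size undefined")
        return (self.f1 - 1.0) / self.b_f

    def dispersal(self, census_density_per_ha: float,
                  fractions=(1.0, 0.5, 0.25, 0.1),
                  force: bool = False) -> "DispersalEstimates":
        return dispersal_estimates(
            self.f1, self.b_f, census_density_per_ha, fractions=fractions,
            significant=self.slope_significant or force,
        )

    def summary(self) -> str:
        head = "Fine-scale spatial genetic structure"
        sig = "significant" if self.slope_significant else "not significant"
        lines = [
            head,
            "=" * len(head),
            self.classes.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "-" * len(head),
            f"F_1 = {self.f1:.4f}   b_F = {self.b_f:.4f} "
            f"[{int(self.envelope*100)}% envelope {self.b_f_env[0]:.4f}, "
            f"{self.b_f_env[1]:.4f}; {sig}]",
            f"Sp = {self.sp:.4f}   ({self.n_permutations} permutations, "
            f"{self.n_pairs_regression} pairs in regression)",
        ]
        if self.no_positive_sgs:
            lines.append("warning: b_F >= 0 — no positive SGS; Sp not interpretable")
        return "\n".join(lines)

    def plot_correlogram(self, ax=None, **kwargs):
        """Kinship correlogram with the permutation envelope (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.classes
        ax.plot(c["mean_dist"], c["mean_kinship"], "o-", **kwargs)
        sig = c[c["significant"]]
        ax.plot(sig["mean_dist"], sig["mean_kinship"], "o", mfc="black", mec="black")
        ax.plot(c["mean_dist"], c["env_lo"], ":", color="grey")
        ax.plot(c["mean_dist"], c["env_hi"], ":", color="grey")
        ax.axhline(0.0, lw=0.5, color="black")
        ax.set_xscale("log")
        ax.set_xlabel("distance (m)")
        ax.set_ylabel("mean kinship $F_{ij}$")
        return ax


def sp_statistic(b_f: float, f_1: float) -> float:
    """Sp = -b_F / (1 - F_1)."""
    if f_1 >= 1.0:
        raise ValueError("F_1 must be below 1")
    return -b_f / (1.0 - f_1)


def neighborhood_size(f_1: float, b_f: float) -> float:
    """N_b = (F_1 - 1)/b_F, defined for negative slopes."""
    if b_f >= 0:
        raise ValueError("b_F must be negative")
    return (f_1 - 1.0) / b_f


def fit_sgs(
    kinship: KinshipMatrix,
    geo_distances: np.ndarray,
    classes: DistanceClassing | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    envelope: float = 0.95,
    min_pairs: int = 40,
    max_dist: float | None = None,
) -> SgsResult:
    """Correlogram, b_F, permutation envelopes and Sp for one population.

    The regression of F_ij on ln(d_ij) runs over all pairs with d > 0 (and
    d <= ``max_dist`` when given); pairs at identical coordinates stay in the
    first-class mean but cannot enter the log regression.  The permutation
    scheme shuffles the assignment of spatial locations to individuals, which
    leaves the distance multiset (hence class sizes, ln-distance mean and
    variance) fixed and re-pairs kinship values with distances.
    """
    d = np.asarray(geo_distances, dtype=float)
    n = kinship.n
    if d.shape != (n, n):
        raise ValueError("distance matrix does not match the kinship matrix")
    if classes is None:
        classes = build_distance_classes(d, min_pairs=min_pairs)
    iu = np.triu_indices(n, 1)
    dvec = d[iu]
    kvec = kinship.values[iu]
    cls = classes.assign(dvec)
    nc = classes.n_classes

    finite = np.isfinite(kvec)
    reg_mask_static = dvec > 0
    if max_dist is not None:
        reg_mask_static &= dvec <= max_dist
    reg = finite & reg_mask_static
    if reg.sum() < 3:
        raise ValueError("fewer than 3 positive-distance pairs: slope undefined")
    lnd = np.zeros_like(dvec)
    lnd[dvec > 0] = np.log(dvec[dvec > 0])

    def class_means(kv: np.ndarray, ok: np.ndarray) -> np.ndarray:
        sums = np.bincount(cls, weights=np.where(ok, kv, 0.0), minlength=nc)
        cnts = np.bincount(cls, weights=ok.astype(float), minlength=nc)
        with np.errstate(invalid="ignore"):
            return sums / cnts

    def slope(kv: np.ndarray, ok: np.ndarray) -> float:
        m = ok & reg_mask_static
        x = lnd[m]
        y = kv[m]
        xc = x - x.mean()
        return float((xc * y).sum() / (xc * xc).sum())

    obs_means = class_means(kvec, finite)
    b_obs = slope(kvec, finite)
    f1 = float(obs_means[0])

    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1.0 - envelope) / 2.0, 1.0 - (1.0 - envelope) / 2.0
    perm_means = np.empty((n_perm, nc))
    perm_slopes = np.empty(n_perm)
    ii, jj = iu
    for t in range(n_perm):
        pm = rng.permutation(n)
        kv = kinship.values[pm[ii], pm[jj]]
        ok = np.isfinite(kv)
        perm_means[t] = class_means(kv, ok)
        perm_slopes[t] = slope(kv, ok)
    env_lo = np.nanquantile(perm_means, lo_q, axis=0)
    env_hi = np.nanquantile(perm_means, hi_q, axis=0)
    slope_lo, slope_hi = np.nanquantile(perm_slopes, [lo_q, hi_q])
    cls_sig = (obs_means < env_lo) | (obs_means > env_hi)
    slope_sig = bool(b_obs < slope_lo or b_obs > slope_hi)

    table = pd.DataFrame(
        {
            "lo": classes.bounds[:-1],
            "hi": classes.bounds[1:],
            "n_pairs": classes.pair_counts,
            "mean_dist": classes.mean_distance,
            "mean_kinship": obs_means,
            "env_lo": env_lo,
            "env_hi": env_hi,
            "significant": cls_sig,
        }
    )
    sp = sp_statistic(b_obs, f1)
    return SgsResult(
        classes=table,
        f1=f1,
        b_f=b_obs,
        b_f_env=(float(slope_lo), float(slope_hi)),
        slope_significant=slope_sig,
        sp=sp,
        n_permutations=n_perm,
        envelope=envelope,
        seed=seed,
        classing=classes,
        n_pairs_regression=int(reg.sum()),
        no_positive_sgs=bool(b_obs >= 0),
    )


@dataclass
class DispersalEstimates:
    """Neighbourhood size and gene-dispersal distances under density scenarios."""

    nb: float
    census_density_per_ha: float
    table: pd.DataFrame  # columns: fraction, density_per_ha, density_per_m2, sigma_g_m

    def summary(self) -> str:
        head = (
            f"N_b = {self.nb:.1f} individuals "
            f"(census density {self.census_density_per_ha:.3g} trees/ha)"
        )
        return head + "\n" + self.table.to_string(
            index=False, float_format=lambda v: f"{v:.4g}"
        )


def gene_dispersal_sigma(nb: float, density_per_ha: float, fraction: float = 1.0) -> float:
    """sigma_g (m) from N_b = 4*pi*D_E*sigma_g^2 with D_E = fraction * census.

    Densities enter as trees/ha and are converted to trees/m^2 (1 ha = 10^4 m^2).
    """
    if nb <= 0:
        raise ValueError("N_b must be positive")
    if density_per_ha <= 0 or fraction <= 0:
        raise ValueError("density and fraction must be positive")
    d_m2 = fraction * density_per_ha / 1e4
    return float(np.sqrt(nb / (4.0 * np.pi * d_m2)))


def dispersal_estimates(
    f_1: float | None = None,
    b_f: float | None = None,
    census_density_per_ha: float = None,
    fractions=(1.0, 0.5, 0.25, 0.1),
    significant: bool = True,
    nb: float | None = None,
) -> DispersalEstimates:
    """N_b and sigma_g under census and reduced effective densities.

    Either supply (``f_1``, ``b_f``) — requiring a significantly negative
    slope — or a pre-computed ``nb``.  Each fraction f gives an effective
    density D_E = f * census and sigma_g = sqrt(N_b / (4*pi*D_E)), so halving
    the density multiplies sigma_g by sqrt(2) exactly.
    """
    if census_density_per_ha is None or census_density_per_ha <= 0:
        raise ValueError("census density (trees/ha) must be positive")
    if nb is None:
        if f_1 is None or b_f is None:
            raise ValueError("supply (f_1, b_f) or nb")
        if b_f >= 0:
            raise ValueError("b_F >= 0: no positive SGS, dispersal estimates refused")
        if not significant:
            raise ValueError(
                "b_F not significantly negative: dispersal estimates suppressed "
                "(pass significant=True only for a significant slope)"
            )
        nb = neighborhood_size(f_1, b_f)
    rows = [
        {
            "fraction": f,
            "density_per_ha": f * census_density_per_ha,
            "density_per_m2": f * census_density_per_ha / 1e4,
            "sigma_g_m": gene_dispersal_sigma(nb, census_density_per_ha, f),
        }
        for f in fractions
    ]
    return DispersalEstimates(
        nb=float(nb),
        census_density_per_ha=float(census_density_per_ha),
        table=pd.DataFrame(rows),
    )


class DominantSGS:
    """Fine-scale SGS model for one population of dominant-marker genotypes.

    Composes the full chain: band-allele frequency estimation (Bayesian,
    Zhivotovsky prior, unless frequencies are supplied), pairwise kinship
    under the assumed ``f_is``, distance classing, and the permutation-tested
    correlogram/regression.  ``fit`` returns an :class:`SGSResults`-style
    object (:class:`SgsResult`) extended with dispersal helpers.

    Parameters
    ----------
    markers : MarkerMatrix for the individuals of one population.
    coords_m : (n, 2) planar coordinates in metres, same order as markers.
    f_is : assumed inbreeding coefficient used by the kinship estimator.
    locus_freqs : optional pre-computed frequencies; estimated here otherwise.
    """

    def __init__(
        self,
        markers: MarkerMatrix,
        coords_m: np.ndarray,
        f_is: float = 0.19,
        locus_freqs: LocusFreqs | None = None,
        min_pairs: int = 40,
        class_range: tuple[int, int] = (5, 30),
        max_dist: float | None = None,
    ) -> None:
        from .dominant_freqs import band_absence_counts, estimate_locus_freqs, fit_null_prior

        coords = np.asarray(coords_m, dtype=float)
        if coords.shape != (markers.n_individuals, 2):
            raise ValueError("coords_m must be (n_individuals, 2) metres")
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        self.markers = markers
        self.coords = coords
        self.f_is = float(f_is)
        if locus_freqs is None:
            m, n = band_absence_counts(markers)
            keep = n > 0
            if not keep.all():
                raise ValueError("some loci are entirely missing in this population")
            prior = fit_null_prior(m / n, n)
            locus_freqs = estimate_locus_freqs(
                m, n, prior=prior, locus_ids=markers.locus_ids
            )
        self.locus_freqs = locus_freqs
        self.min_pairs = min_pairs
        self.class_range = class_range
        self.max_dist = max_dist
        from scipy.spatial.distance import pdist, squareform

        self.distances = squareform(pdist(coords))
        self.kinship = kinship_dominant(markers, locus_freqs, f_is=self.f_is)

    def fit(self, n_perm: int = 10000, seed: int | None = None,
            envelope: float = 0.95) -> SgsResult:
        classes = build_distance_classes(
            self.distances, min_pairs=self.min_pairs, class_range=self.class_range
        )
        return fit_sgs(
            self.kinship,
            self.distances,
            classes=classes,
            n_perm=n_perm,
            seed=seed,
            envelope=envelope,
            max_dist=self.max_dist,
        )
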