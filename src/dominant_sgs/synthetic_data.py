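"""Dominant-marker data generators with known truth.

Two designs, both emulating a multi-population AFLP survey (six populations
of roughly 11-50 adults typed at ~400 dominant loci):

``simulate_clustered``
    Balding-Nichols divergence: each population's band-allele frequency at
    each locus is a Beta draw around the ancestral frequency with variance
    theta_div * p * (1 - p), so theta_div is the target F_ST.  Genotypes are
    drawn with inbreeding F_IS = s/(2 - s) induced by partial selfing, and
    populations sit in small, widely separated patches (no within-patch
    structure).

``simulate_spatial``
    A forward-time isolation-by-distance process on a toroidal lattice:
    density D is held exactly at one plant per site (spacing 1/sqrt(D)),
    generations do not overlap, each site's new occupant draws its mother
    from a Gaussian(sigma_s) seed kernel around the site and its father from
    a Gaussian(sigma_p) pollen kernel around the mother (selfing with
    probability s).  The lattice regulation avoids the spatial clumping that
    unregulated continuous-space models develop, which would make the local
    density — and hence neighbourhood size — ill-defined.  At drift-dispersal
    equilibrium the axial gene-dispersal variance is
    sigma_g^2 = sigma_s^2 + sigma_p^2/2 (pollen moves one gamete) and
    Wright's neighbourhood size N_b = 4*pi*D*sigma_g^2, giving an expected
    Sp of about 1/N_b.  Sampling mimics an exhaustive field census of a
    transect-shaped window rather than global random thinning.

The generators are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_geo import MarkerMatrix, SampleTable
import pandas as pd

#: Table-1-like default sample sizes for six populations
DEFAULT_POP_SIZES = (50, 20, 50, 22, 17, 11)


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the emulated study design."""

    n_populations: int = 6
    n_individuals: tuple = DEFAULT_POP_SIZES
    n_loci: int = 401
    ancestral_freq: tuple = ("uniform", 0.1, 0.9)  # band-allele frequency law
    theta_div: float = 0.39        # Balding-Nichols target F_ST
    selfing: float = 0.3193        # induces F_IS = s/(2-s) ~ 0.19
    spatial_mode: str = "random"   # "random" (clustered patches) or "idist"
    # clustered mode geometry
    patch_size_m: float = 200.0
    patch_spacing_m: float = 10000.0
    # isolation-by-distance mode; extent may be a scalar (square) or (x, y)
    extent_m: float | tuple = (250.0, 65.0)
    density_per_m2: float = 0.054
    sigma_s: float = 2.0
    sigma_p: float = 7.0
    generations: int = 300
    n_sample: int | None = 200     # target size of the sampled window census
    sample_window: tuple | None = None  # (w_x, w_y) metres; derived when None
    seed: int = 0

    def __post_init__(self) -> None:
        if np.isscalar(self.n_individuals):
            self.n_individuals = (int(self.n_individuals),) * self.n_populations
        self.n_individuals = tuple(int(v) for v in self.n_individuals)
        if len(self.n_individuals) != self.n_populations:
            raise ValueError("need one sample size per population")
        if not (0.0 <= self.selfing <= 1.0):
            raise ValueError("selfing rate must lie in [0, 1]")
        if not (0.0 <= self.theta_div <= 1.0):
            raise ValueError("theta_div must lie in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        if self.spatial_mode not in ("random", "idist"):
            raise ValueError("spatial_mode must be 'random' or 'idist'")
        if np.isscalar(self.extent_m):
            self.extent_m = (float(self.extent_m), float(self.extent_m))
        self.extent_m = (float(self.extent_m[0]), float(self.extent_m[1]))
        if min(*self.extent_m, self.density_per_m2, self.sigma_s, self.sigma_p) <= 0:
            raise ValueError("extent, density and dispersal sigmas must be positive")

    @property
    def f_is_expected(self) -> float:
        """Equilibrium inbreeding under partial selfing, s/(2 - s)."""
        s = self.selfing
        return s / (2.0 - s)

    @property
    def sigma_g2(self) -> float:
        """Axial gene-dispersal variance sigma_s^2 + sigma_p^2/2 (idist mode)."""
        return self.sigma_s**2 + self.sigma_p**2 / 2.0

    @property
    def nb_expected(self) -> float:
        return 4.0 * np.pi * self.density_per_m2 * self.sigma_g2


@dataclass
class SimTruth:
    """Ground truth stored alongside a simulated dataset."""

    mode: str
    allele_freqs: np.ndarray          # (k, L) band-allele frequencies (clustered)
    f_is_expected: float
    f_is_realized: float
    target_fst: float | None = None
    sigma_g2: float | None = None
    nb: float | None = None
    sp_expected: float | None = None
    seed: int | None = None
    genotypes: np.ndarray = field(default=None, repr=False)  # sampled band-allele counts
    labels: np.ndarray = field(default=None, repr=False)


def dominant_mask(genotypes) -> np.ndarray:
    """Band phenotype (0/1) from diploid band-allele counts {0, 1, 2}."""
    g = np.asarray(genotypes)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotype counts must be 0, 1 or 2 band alleles")
    return (g >= 1).astype(np.int8)


def _draw_ancestral(rng: np.random.Generator, law: tuple, n_loci: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], n_loci)
    if kind == "beta":
        return rng.beta(law[1], law[2], n_loci)
    raise ValueError(f"unknown ancestral frequency law '{kind}'")


def _genotypes_with_inbreeding(rng, p: np.ndarray, n: int, f: float) -> np.ndarray:
    """(n, L) band-allele counts at frequencies p with inbreeding f."""
    q = 1.0 - p
    pr2 = p * p + f * p * q
    pr1 = 2.0 * p * q * (1.0 - f)
    u = rng.random((n, p.size))
    return np.where(u < pr2, 2, np.where(u < pr2 + pr1, 1, 0)).astype(np.int8)


def _realized_f_is(genotypes: np.ndarray, labels: np.ndarray) -> float:
    """1 - H_obs/H_exp pooled over populations and loci."""
    h_obs_sum = 0.0
    h_exp_sum = 0.0
    for pop in np.unique(labels):
        g = genotypes[labels == pop]
        p = g.mean(axis=0) / 2.0
        h_obs_sum += float((g == 1).mean(axis=0).sum())
        h_exp_sum += float((2.0 * p * (1.0 - p)).sum())
    return 1.0 - h_obs_sum / h_exp_sum if h_exp_sum > 0 else float("nan")


def simulate_clustered(config: SimConfig) -> tuple[MarkerMatrix, SampleTable, SimTruth]:
    """Balding-Nichols clustered populations of dominant phenotypes."""
    if config.spatial_mode != "random":
        raise ValueError("simulate_clustered requires spatial_mode='random'")
    if config.theta_div >= 1.0:
        raise ValueError("theta_div = 1 degenerates to fixed loci; rejected")
    rng = np.random.default_rng(config.seed)
    k, l = config.n_populations, config.n_loci
    p_anc = _draw_ancestral(rng, config.ancestral_freq, l)
    theta = config.theta_div
    if theta > 0:
        c = (1.0 - theta) / theta
        p_pop = rng.beta(p_anc * c, (1.0 - p_anc) * c, size=(k, l))
        p_pop = np.clip(p_pop, 1e-9, 1.0 - 1e-9)
    else:
        p_pop = np.tile(p_anc, (k, 1))
    f = config.f_is_expected

    genos, labels, ids, xs, ys = [], [], [], [], []
    for kk, n_k in enumerate(config.n_individuals):
        genos.append(_genotypes_with_inbreeding(rng, p_pop[kk], n_k, f))
        pop = f"P{kk + 1}"
        labels += [pop] * n_k
        ids += [f"{pop}_{i + 1}" for i in range(n_k)]
        cx = kk * config.patch_spacing_m
        xs.append(cx + rng.uniform(0, config.patch_size_m, n_k))
        ys.append(rng.uniform(0, config.patch_size_m, n_k))
    genotypes = np.vstack(genos)
    labels = np.asarray(labels)
    markers = MarkerMatrix(ids, [f"L{j + 1}" for j in range(l)], dominant_mask(genotypes))
    samples = SampleTable(pd.DataFrame({
        "id": ids,
        "pop": labels,
        "x_m": np.concatenate(xs),
        "y_m": np.concatenate(ys),
    }))
    truth = SimTruth(
        mode="random",
        allele_freqs=p_pop,
        f_is_expected=f,
        f_is_realized=_realized_f_is(genotypes, labels),
        target_fst=theta,
        seed=config.seed,
        genotypes=genotypes,
        labels=labels,
    )
    return markers, samples, truth


def _torus_sq_dist_rect(pos_a: np.ndarray, pos_b: np.ndarray, extents: tuple) -> np.ndarray:
    """(len(a), len(b)) minimum-image squared distances on a rectangular torus."""
    out = None
    for ax in (0, 1):
        d = np.abs(np.subtract.outer(pos_a[:, ax].astype(np.float32),
                                     pos_b[:, ax].astype(np.float32)))
        np.minimum(d, np.float32(extents[ax]) - d, out=d)
        d *= d
        out = d if out is None else out + d
    return out


def _lattice_kernel_cumsum(pos: np.ndarray, extents: tuple, sigma: float,
                           exclude_self: bool) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise cumulative Gaussian kernel over torus distances (static lattice)."""
    sq = _torus_sq_dist_rect(pos, pos, extents)
    w = np.exp(-sq / np.float32(2.0 * sigma * sigma)).astype(np.float64)
    if exclude_self:
        np.fill_diagonal(w, 0.0)
    cum = np.cumsum(w, axis=1)
    return cum, cum[:, -1].copy()


def simulate_spatial(config: SimConfig) -> tuple[MarkerMatrix, SampleTable, SimTruth]:
    """Forward isolation-by-distance simulation on a toroidal lattice."""
    if config.spatial_mode != "idist":
        raise ValueError("simulate_spatial requires spatial_mode='idist'")
    nb = config.nb_expected
    if nb < 1.0:
        raise ValueError(
            f"expected neighbourhood size {nb:.2f} < 1: drift-dominated "
            "configuration rejected"
        )
    rng = np.random.default_rng(config.seed)
    ext_x, ext_y = config.extent_m
    spacing = 1.0 / np.sqrt(config.density_per_m2)
    nx, ny = max(2, int(round(ext_x / spacing))), max(2, int(round(ext_y / spacing)))
    lx, ly = nx * spacing, ny * spacing
    gx, gy = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    n = pos.shape[0]
    if n < 2:
        raise ValueError("density*area yields fewer than 2 individuals")
    l = config.n_loci
    p0 = _draw_ancestral(rng, config.ancestral_freq, l)
    geno = rng.binomial(2, p0, size=(n, l)).astype(np.int8)
    s = config.selfing
    # kernels are static on the lattice: precompute cumulative rows once
    cum_s, tot_s = _lattice_kernel_cumsum(pos, (lx, ly), config.sigma_s, False)
    cum_p, tot_p = _lattice_kernel_cumsum(pos, (lx, ly), config.sigma_p, True)

    for _ in range(config.generations):
        mothers = (cum_s < (rng.random(n) * tot_s)[:, None]).sum(axis=1)
        fathers = (cum_p[mothers] < (rng.random(n) * tot_p[mothers])[:, None]).sum(axis=1)
        if s > 0:
            self_mask = rng.random(n) < s
            fathers[self_mask] = mothers[self_mask]
        mat = (rng.random((n, l)) < geno[mothers] / 2.0).astype(np.int8)
        pat = (rng.random((n, l)) < geno[fathers] / 2.0).astype(np.int8)
        geno = mat + pat

    # exhaustive census of a central transect-shaped window
    if config.n_sample is None or config.n_sample >= n:
        take = np.arange(n)
    else:
        if config.sample_window is not None:
            w_x, w_y = config.sample_window
        else:
            area = config.n_sample / config.density_per_m2
            w_x = min(2.0 * np.sqrt(area), lx / 2.0)
            w_y = area / w_x
        w_x, w_y = min(w_x, lx / 2.0), min(w_y, ly / 2.0)
        lo_x, lo_y = (lx - w_x) / 2.0, (ly - w_y) / 2.0
        inside = (
            (pos[:, 0] >= lo_x) & (pos[:, 0] < lo_x + w_x)
            & (pos[:, 1] >= lo_y) & (pos[:, 1] < lo_y + w_y)
        )
        take = np.flatnonzero(inside)
        if take.size < 10:
            raise ValueError("sampling window caught fewer than 10 individuals")
    geno_s = geno[take]
    pos_s = pos[take]
    labels = np.asarray(["P1"] * take.size)
    ids = [f"P1_{i + 1}" for i in range(take.size)]
    markers = MarkerMatrix(ids, [f"L{j + 1}" for j in range(l)], dominant_mask(geno_s))
    samples = SampleTable(pd.DataFrame({
        "id": ids, "pop": labels, "x_m": pos_s[:, 0], "y_m": pos_s[:, 1],
    }))
    truth = SimTruth(
        mode="idist",
        allele_freqs=geno.mean(axis=0, keepdims=True) / 2.0,
        f_is_expected=config.f_is_expected,
        f_is_realized=_realized_f_is(geno_s, labels),
        sigma_g2=config.sigma_g2,
        nb=nb,
        sp_expected=1.0 / nb,
        seed=config.seed,
        genotypes=geno_s,
        labels=labels,
    )
    return markers, samples, truth


def idist_config_for_nb(
    nb_target: float,
    sigma_s: float = 2.0,
    sigma_p: float = 7.0,
    n_loci: int = 300,
    n_sample: int = 200,
    generations: int = 300,
    transect_m: float = 120.0,
    seed: int = 0,
) -> SimConfig:
    """Recovery-test configuration with a target neighbourhood size.

    The census density follows from D = N_b / (4*pi*sigma_g^2) with
    sigma_g^2 = sigma_s^2 + sigma_p^2/2.  The sampled window is a transect
    whose long axis (default 120 m, about 20 sigma_g) spans the log-linear
    range of the kinship correlogram; its width is set by the target census
    n_sample / (D * transect).  The torus extent keeps every within-window
    separation under half the period on both axes.
    """
    sigma_g2 = sigma_s**2 + sigma_p**2 / 2.0
    dens = nb_target / (4.0 * np.pi * sigma_g2)
    w_y = n_sample / (dens * transect_m)
    ext = (max(2.1 * transect_m, 50.0), max(2.1 * w_y, 50.0))
    return SimConfig(
        n_populations=1,
        n_individuals=(n_sample,),
        n_loci=n_loci,
        ancestral_freq=("uniform", 0.2, 0.8),
        theta_div=0.0,
        selfing=0.0,
        spatial_mode="idist",
        extent_m=ext,
        density_per_m2=dens,
        sigma_s=sigma_s,
        sigma_p=sigma_p,
        generations=generations,
        n_sample=n_sample,
        sample_window=(transect_m, w_y),
        seed=seed,
    )


def genotype_fst(genotypes: np.ndarray, labels: np.ndarray) -> float:
    """Weir-Cockerham-style theta from true diploid genotypes (test oracle aid).

    Standard two-allele variance-components estimator, ratio of sums over
    loci; no inbreeding correction beyond the observed-heterozygosity term.
    """
    pops = np.unique(labels)
    k = len(pops)
    if k < 2:
        raise ValueError("need at least two populations")
    ns = np.array([(labels == pop).sum() for pop in pops], dtype=float)
    p_i = np.vstack([genotypes[labels == pop].mean(axis=0) / 2.0 for pop in pops])
    h_i = np.vstack([(genotypes[labels == pop] == 1).mean(axis=0) for pop in pops])
    n_bar = ns.mean()
    n_c = (k * n_bar - (ns**2).sum() / (k * n_bar)) / (k - 1)
    p_bar = (ns[:, None] * p_i).sum(axis=0) / (k * n_bar)
    s2 = (ns[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((k - 1) * n_bar)
    h_bar = (ns[:, None] * h_i).sum(axis=0) / (k * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (k - 1) / k * s2 - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (k - 1) / k * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    denom = (a + b + c).sum()
    if denom <= 0:
        raise ValueError("monomorphic data: F_ST undefined")
    return float(a.sum() / denom)


def replace_config(config: SimConfig, **kwargs) -> SimConfig:
    """dataclasses.replace passthrough (kept for a stable public surface)."""
    return replace(config, **kwargs)
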