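"""End-to-end orchestration: frequencies -> diversity -> structure -> SGS.

One :class:`RunConfig` drives the whole analysis; every stochastic stage
draws from an independent, reproducibly derived substream of the master
seed, so changing e.g. the Mantel permutations can never alter the SGS
results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dominant_freqs import (
    DiversitySummary,
    estimate_population_frequencies,
    nei_distance,
    population_diversity,
)
from .io_geo import (
    MarkerMatrix,
    SampleTable,
    ensure_planar,
    read_marker_table,
    read_sample_table,
)
from .population_structure import Amova, fst_g_test, mantel_test
from .sgs_core import DominantSGS, SgsResult, dispersal_estimates

log = logging.getLogger("dominant_sgs")


@dataclass
class RunConfig:
    """Settings for a full run; defaults follow the emulated study protocol."""

    marker_path: str | None = None
    sample_path: str | None = None
    f_is: float = 0.19
    polymorphism_threshold: float = 0.05
    n_perm_sgs: int = 10000
    n_perm_fst: int = 5000
    n_perm_amova: int = 999
    n_perm_mantel: int = 9999
    density_per_ha: dict = field(default_factory=dict)   # population -> trees/ha
    scenario_fractions: tuple = (1.0, 0.5, 0.25, 0.1)
    subgroups: dict = field(default_factory=dict)        # name -> list of individual ids
    min_pairs: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (
            ("n_perm_sgs", self.n_perm_sgs),
            ("n_perm_fst", self.n_perm_fst),
            ("n_perm_amova", self.n_perm_amova),
            ("n_perm_mantel", self.n_perm_mantel),
        ):
            if val < 1:
                raise ValueError(f"{name} must be positive")
        for pop, dens in self.density_per_ha.items():
            if dens <= 0:
                raise ValueError(f"census density for {pop} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must state a seed explicitly")
        return cls(**raw)


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Reproducible per-stage seed, independent across stage names."""
    return np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])


def _seed_int(master_seed: int, stage: str) -> int:
    return int(stage_seed(master_seed, stage).generate_state(1)[0] % (2**31))


@dataclass
class RunReport:
    """All result tables of one run, plus provenance."""

    diversity: DiversitySummary
    nei_d: pd.DataFrame
    amova: "object"
    fst: "object"
    mantel: "object | None"
    sgs: dict[str, SgsResult]
    dispersal: dict[str, "object"]
    provenance: dict

    def sgs_table(self) -> pd.DataFrame:
        rows = []
        for pop, res in self.sgs.items():
            row = {
                "pop": pop,
                "Sp": res.sp,
                "F1": res.f1,
                "bF": res.b_f,
                "significant": res.slope_significant,
                "Nb": res.neighborhood_size() if res.b_f < 0 else np.nan,
            }
            disp = self.dispersal.get(pop)
            if disp is not None:
                row["DE_per_ha"] = disp.census_density_per_ha
                for frac, sig in zip(disp.table["fraction"], disp.table["sigma_g_m"]):
                    row[f"sigma_g_{frac:g}"] = sig
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_means(self) -> dict:
        return summarize_across_populations(self)

    def content_hash(self) -> str:
        """Stable digest of every numeric result (determinism checks)."""
        parts = [
            self.diversity.per_population.round(10).to_csv(),
            self.nei_d.round(10).to_csv() if len(self.nei_d) else "",
            "" if self.amova is None else self.amova.table().round(10).to_csv(),
            "" if self.fst is None else f"{self.fst.fst:.10f}|{self.fst.p_value:.10f}",
            "" if self.mantel is None else f"{self.mantel.r:.10f}|{self.mantel.p_value:.10f}",
            self.sgs_table().round(10).to_csv(),
        ]
        return hashlib.sha256("\n".join(parts).encode()).hexdigest()

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = (
            f"dominant-sgs {self.provenance['version']} "
            f"seed={self.provenance['seed']}"
        )

        def _tsv(df: pd.DataFrame, name: str) -> None:
            with open(out / name, "w") as fh:
                fh.write(f"# {stamp}\n")
                df.to_csv(fh, sep="\t", index=False)

        _tsv(self.diversity.per_population, "diversity.tsv")
        if len(self.nei_d):
            _tsv(self.nei_d.reset_index(names="pop"), "nei_distance.tsv")
        if self.amova is not None:
            _tsv(self.amova.table(), "amova.tsv")
        _tsv(self.sgs_table(), "sgs.tsv")
        for pop, res in self.sgs.items():
            _tsv(res.classes, f"correlogram_{pop}.tsv")
        with open(out / "report.json", "w") as fh:
            json.dump(
                {
                    "provenance": self.provenance,
                    "fst": None
                    if self.fst is None
                    else {"estimate": self.fst.fst, "p": self.fst.p_value},
                    "mantel": None
                    if self.mantel is None
                    else {"r": self.mantel.r, "p": self.mantel.p_value},
                    "amova": None
                    if self.amova is None
                    else {
                        "phi_st": self.amova.phi_st,
                        "p": self.amova.p_value,
                        "pct_between": self.amova.pct_between,
                        "pct_within": self.amova.pct_within,
                    },
                    "means": self.summary_means(),
                    "hash": self.content_hash(),
                },
                fh,
                indent=2,
            )


def run_all(
    config: RunConfig,
    markers: MarkerMatrix | None = None,
    samples: SampleTable | None = None,
) -> RunReport:
    """Execute the full analysis; inputs may be passed in memory or via paths."""
    t0 = time.time()
    if markers is None:
        if config.marker_path is None:
            raise ValueError("no marker data: set marker_path or pass markers")
        markers = read_marker_table(config.marker_path)
    if samples is None:
        if config.sample_path is None:
            raise ValueError("no sample data: set sample_path or pass samples")
        samples = read_sample_table(config.sample_path)
    if samples.ids != markers.individual_ids:
        markers = markers.subset(samples.ids)
    samples = ensure_planar(samples)
    labels = samples.labels()
    seed = config.seed

    log.info("stage frequencies: %d populations, %d loci", len(samples.populations), markers.n_loci)
    freqs = estimate_population_frequencies(markers, samples)
    diversity = population_diversity(freqs, config.polymorphism_threshold)
    multi_pop = len(samples.populations) >= 2
    nei_d = nei_distance(freqs) if multi_pop else pd.DataFrame()

    amova_res = fst_res = None
    if multi_pop:
        log.info("stage AMOVA (%d permutations)", config.n_perm_amova)
        amova_res = Amova(markers, labels).fit(
            n_perm=config.n_perm_amova, seed=_seed_int(seed, "amova")
        )
        log.info("stage F_ST G-test (%d permutations)", config.n_perm_fst)
        fst_res = fst_g_test(
            markers, labels, freqs_by_pop=freqs,
            n_perm=config.n_perm_fst, seed=_seed_int(seed, "fst"),
        )
    else:
        log.info("single population: among-population stages skipped")

    mantel_res = None
    pops = samples.populations
    if len(pops) >= 3:
        log.info("stage Mantel (%d permutations)", config.n_perm_mantel)
        cents = np.vstack(
            [samples.coords_m()[labels == pop].mean(axis=0) for pop in pops]
        )
        geo_pop = np.sqrt(((cents[:, None, :] - cents[None, :, :]) ** 2).sum(-1))
        mantel_res = mantel_test(
            nei_d.loc[pops, pops].to_numpy(), geo_pop,
            n_perm=config.n_perm_mantel, seed=_seed_int(seed, "mantel"),
        )

    sgs_units: dict[str, list[str]] = {
        pop: [i for i, lab in zip(samples.ids, labels) if lab == pop] for pop in pops
    }
    for name, ids in config.subgroups.items():
        missing = set(ids) - set(samples.ids)
        if missing:
            raise ValueError(f"subgroup {name}: unknown individuals {sorted(missing)}")
        sgs_units[name] = list(ids)

    sgs_results: dict[str, SgsResult] = {}
    dispersal: dict[str, object] = {}
    for name, ids in sgs_units.items():
        sub_samples = samples.select(samples.data["id"].isin(ids))
        sub_markers = markers.subset(sub_samples.ids)
        n_pairs = len(ids) * (len(ids) - 1) // 2
        if n_pairs < config.min_pairs:
            log.warning("SGS unit %s skipped: only %d pairs", name, n_pairs)
            continue
        log.info("stage SGS %s: %d individuals (%d permutations)", name, len(ids), config.n_perm_sgs)
        model = DominantSGS(
            sub_markers, sub_samples.coords_m(), f_is=config.f_is, min_pairs=config.min_pairs
        )
        res = model.fit(n_perm=config.n_perm_sgs, seed=_seed_int(seed, f"sgs:{name}"))
        sgs_results[name] = res
        if res.b_f < 0 and res.slope_significant:
            dens = config.density_per_ha.get(name)
            if dens is None:
                raise ValueError(
                    f"population {name} shows significant SGS but no census density "
                    "was configured (density_per_ha)"
                )
            dispersal[name] = dispersal_estimates(
                res.f1, res.b_f, dens, fractions=config.scenario_fractions
            )

    report = RunReport(
        diversity=diversity,
        nei_d=nei_d,
        amova=amova_res,
        fst=fst_res,
        mantel=mantel_res,
        sgs=sgs_results,
        dispersal=dispersal,
        provenance={
            "version": __version__,
            "seed": seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config).items()
            },
            "n_individuals": markers.n_individuals,
            "n_loci": markers.n_loci,
            "elapsed_s": round(time.time() - t0, 3),
        },
    )
    log.info("run complete in %.1fs", time.time() - t0)
    return report


def summarize_across_populations(report: RunReport) -> dict:
    """Unweighted means of H_E, PPL across populations and Sp across SGS rows."""
    per_pop = report.diversity.per_population
    sp_vals = [r.sp for r in report.sgs.values() if np.isfinite(r.sp)]
    return {
        "mean_HE": float(per_pop["HE"].mean()),
        "mean_PPL": float(per_pop["PPL"].mean()),
        "mean_Sp": float(np.mean(sp_vals)) if sp_vals else float("nan"),
        "sp_composition": list(report.sgs),
    }
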