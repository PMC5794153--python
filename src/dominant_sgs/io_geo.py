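"""Marker-table and sample-table I/O, coordinate projection and pairwise distances.

Dominant markers (AFLP bands and the like) are stored as band phenotypes:
1 = band present (at least one amplifiable allele), 0 = band absent
(null homozygote), plus a missing code.  Sample metadata carry a population
label and either geographic (lat/lon, decimal degrees) or planar (x_m/y_m,
metres) coordinates; fine-scale spatial analyses always run on metres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.spatial.distance import pdist, squareform

MISSING = -1  # internal code for a missing band phenotype

#: mean Earth radius (m), also used by the haversine formula
EARTH_RADIUS_M = 6371008.8


class MarkerTableError(ValueError):
    """Raised when a marker table violates the 0/1/missing contract."""


@dataclass
class MarkerMatrix:
    """Individuals x dominant loci band phenotypes.

    ``values`` is an int8 array with entries in {0, 1, MISSING}.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n, l = self.values.shape
        if n < 1 or l < 1:
            raise MarkerTableError("need at least one individual and one locus")
        if len(self.individual_ids) != n or len(self.locus_ids) != l:
            raise MarkerTableError("id lists inconsistent with value matrix shape")
        if len(set(self.individual_ids)) != n:
            raise MarkerTableError("duplicate individual ids")
        if len(set(self.locus_ids)) != l:
            raise MarkerTableError("duplicate locus ids")
        bad = ~np.isin(self.values, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MarkerTableError(
                f"non-binary phenotype {self.values[i, j]} at individual "
                f"'{self.individual_ids[i]}', locus '{self.locus_ids[j]}'"
            )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def subset(self, individual_ids: list[str]) -> "MarkerMatrix":
        """Row-subset preserving the given order."""
        pos = {iid: k for k, iid in enumerate(self.individual_ids)}
        idx = [pos[i] for i in individual_ids]
        return MarkerMatrix(list(individual_ids), list(self.locus_ids), self.values[idx])

    def to_dataframe(self, missing_code: str = "NA") -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.individual_ids, columns=self.locus_ids, dtype=object)
        return df.where(df != MISSING, missing_code)


@dataclass
class SampleTable:
    """Per-individual metadata: population label and coordinates.

    Wraps a DataFrame with columns ``id``, ``pop`` and optionally
    ``lat``/``lon`` (decimal degrees) and/or ``x_m``/``y_m`` (planar metres).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True).copy()
        for col in ("id", "pop"):
            if col not in df.columns:
                raise ValueError(f"sample table misses required column '{col}'")
        df["id"] = df["id"].astype(str)
        df["pop"] = df["pop"].astype(str)
        if (df["pop"].str.len() == 0).any():
            raise ValueError("empty population label")
        if df["id"].duplicated().any():
            raise ValueError("duplicate individual ids in sample table")
        for col in ("lat", "lon", "x_m", "y_m"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="coerce")
                if np.isinf(df[col].to_numpy(dtype=float, na_value=np.nan)).any():
                    raise ValueError(f"non-finite values in column '{col}'")
        self.data = df

    @property
    def ids(self) -> list[str]:
        return self.data["id"].tolist()

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.data["pop"]))

    def labels(self) -> np.ndarray:
        return self.data["pop"].to_numpy()

    @property
    def has_planar(self) -> bool:
        return {"x_m", "y_m"} <= set(self.data.columns) and (
            self.data[["x_m", "y_m"]].notna().all().all()
        )

    @property
    def has_geographic(self) -> bool:
        return {"lat", "lon"} <= set(self.data.columns) and (
            self.data[["lat", "lon"]].notna().all().all()
        )

    def coords_m(self) -> np.ndarray:
        if not self.has_planar:
            raise ValueError("planar coordinates absent; call project_coordinates() first")
        return self.data[["x_m", "y_m"]].to_numpy(dtype=float)

    def select(self, mask) -> "SampleTable":
        return SampleTable(self.data.loc[mask].reset_index(drop=True))


def _sep_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_marker_table(path, missing_code: str = "NA", sep: str | None = None) -> MarkerMatrix:
    """Read a delimited marker table: first row = locus ids, first column = individual ids."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0, dtype=str, comment="#")
    values = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == missing_code:
                values[i, j] = MISSING
            elif cell in ("0", "1"):
                values[i, j] = int(cell)
            else:
                raise MarkerTableError(
                    f"invalid phenotype '{cell}' at individual '{df.index[i]}', "
                    f"locus '{df.columns[j]}' (expected 0, 1 or '{missing_code}')"
                )
    return MarkerMatrix([str(x) for x in df.index], [str(x) for x in df.columns], values)


def write_marker_table(markers: MarkerMatrix, path, missing_code: str = "NA",
                       sep: str | None = None, header_comment: str | None = None) -> None:
    out_sep = _sep_for(path, sep)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        markers.to_dataframe(missing_code).to_csv(fh, sep=out_sep, index_label="id")


def read_sample_table(path, sep: str | None = None) -> SampleTable:
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype={"id": str, "pop": str}, comment="#")
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path, sep: str | None = None,
                       header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        samples.data.to_csv(fh, sep=_sep_for(path, sep), index=False)


def write_structure(markers: MarkerMatrix, path, missing_code: str = "-9") -> None:
    """Export in STRUCTURE one-row-per-individual format.

    Dominant data: one pseudo-haploid column per locus (band phenotype),
    missing coded -9 by default.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(markers.locus_ids) + "\n")
        for iid, row in zip(markers.individual_ids, markers.values):
            cells = [missing_code if v == MISSING else str(int(v)) for v in row]
            fh.write(iid + "\t" + "\t".join(cells) + "\n")


def haversine_m(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in metres on the mean-radius sphere."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def project_coordinates(samples: SampleTable) -> SampleTable:
    """Project lat/lon to planar metres via a centroid-centred transverse Mercator.

    A spherical Gauss-Krueger projection with the central meridian through the
    sample centroid; within ~150 km of the central meridian the scale error is
    below 0.03%, comfortably inside the 0.1% contract for UTM-scale extents.
    Tables that already carry complete ``x_m``/``y_m`` columns pass through
    unchanged.
    """
    if samples.has_planar:
        return samples
    if not samples.has_geographic:
        raise ValueError("coordinates missing: need lat/lon (or pre-projected x_m/y_m)")
    df = samples.data.copy()
    lat = np.radians(df["lat"].to_numpy(dtype=float))
    lon = np.radians(df["lon"].to_numpy(dtype=float))
    lon_span = np.degrees(lon.max() - lon.min())
    if lon_span > 6.0:
        warnings.warn(
            f"longitude span {lon_span:.1f} deg exceeds one UTM-like zone; "
            "projected distances may degrade beyond the 0.1% contract",
            stacklevel=2,
        )
    lam0 = lon.mean()
    phi0 = lat.mean()
    b = np.cos(lat) * np.sin(lon - lam0)
    df["x_m"] = EARTH_RADIUS_M * np.arctanh(b)
    df["y_m"] = EARTH_RADIUS_M * (np.arctan2(np.tan(lat), np.cos(lon - lam0)) - phi0)
    return SampleTable(df)


def pairwise_geo_distances(samples: SampleTable) -> np.ndarray:
    """Square symmetric Euclidean distance matrix (metres) over planar coordinates."""
    d = squareform(pdist(samples.coords_m()))
    return d


def ensure_planar(samples: SampleTable) -> SampleTable:
    """Project if needed, so ``coords_m`` is guaranteed to succeed."""
    return samples if samples.has_planar else project_coordinates(samples)
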