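"""Core in-memory containers shared across the pipeline.

Phenotype tables are plain :class:`pandas.DataFrame` objects with documented
columns; the classes here cover the structures that need invariants enforced
(pedigrees, genotype matrices, heating curves).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"

PEDIGREE_COLUMNS = ["id", "sire", "dam", "generation"]
SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


@dataclass
class Pedigree:
    """Ordered pedigree: ``id, sire, dam, generation`` with ``"0"`` = unknown.

    Invariants (checked on construction): parents appear before their
    offspring, no animal is its own ancestor, and within the table the sire
    and dam columns are disjoint id sets.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEDIGREE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"pedigree missing columns: {missing}")
        self.df = self.df[PEDIGREE_COLUMNS].reset_index(drop=True)
        for col in ("id", "sire", "dam"):
            self.df[col] = self.df[col].astype(str)
        ids = self.df["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate animal id {dup!r}")
        seen: set[str] = set()
        for row in self.df.itertuples(index=False):
            for parent in (row.sire, row.dam):
                if parent != UNKNOWN_PARENT and parent not in seen:
                    if parent == row.id:
                        raise ValueError(f"{row.id} is its own parent")
                    raise ValueError(
                        f"parent {parent!r} of {row.id!r} does not precede it"
                    )
            seen.add(row.id)
        sires = set(self.df["sire"]) - {UNKNOWN_PARENT}
        dams = set(self.df["dam"]) - {UNKNOWN_PARENT}
        overlap = sires & dams
        if overlap:
            raise ValueError(f"ids used both as sire and dam: {sorted(overlap)[:5]}")

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    @property
    def n(self) -> int:
        return len(self.df)

    def founders(self) -> list[str]:
        mask = (self.df["sire"] == UNKNOWN_PARENT) & (self.df["dam"] == UNKNOWN_PARENT)
        return self.df.loc[mask, "id"].tolist()

    def offspring(self) -> list[str]:
        mask = (self.df["sire"] != UNKNOWN_PARENT) | (self.df["dam"] != UNKNOWN_PARENT)
        return self.df.loc[mask, "id"].tolist()

    def parent_indices(self) -> np.ndarray:
        """(n, 2) integer array of sire/dam row indices, -1 for unknown."""
        pos = {a: i for i, a in enumerate(self.df["id"])}
        out = np.full((self.n, 2), -1, dtype=np.int64)
        for i, row in enumerate(self.df.itertuples(index=False)):
            if row.sire != UNKNOWN_PARENT:
                out[i, 0] = pos[row.sire]
            if row.dam != UNKNOWN_PARENT:
                out[i, 1] = pos[row.dam]
        return out


def validate_snp_map(snp_map: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SNP_MAP_COLUMNS if c not in snp_map.columns]
    if missing:
        raise ValueError(f"SNP map missing columns: {missing}")
    snp_map = snp_map[SNP_MAP_COLUMNS].reset_index(drop=True)
    if snp_map["snp_id"].duplicated().any():
        raise ValueError("duplicate SNP identifiers in map")
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
    return snp_map


MISSING_CODE = -1


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs reference-allele dosages in {0,1,2}, -1 = missing."""

    ids: list[str]
    snp_map: pd.DataFrame
    codes: np.ndarray  # (n_ind, n_snp) int8

    def __post_init__(self) -> None:
        self.snp_map = validate_snp_map(self.snp_map)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.ids), len(self.snp_map)):
            raise ValueError(
                f"genotype shape {self.codes.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.snp_map)} SNPs"
            )
        bad = ~np.isin(self.codes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def call_rate_individuals(self) -> np.ndarray:
        return (self.codes != MISSING_CODE).mean(axis=1)

    def call_rate_snps(self) -> np.ndarray:
        return (self.codes != MISSING_CODE).mean(axis=0)

    def ref_allele_freq(self) -> np.ndarray:
        """Reference-allele frequency per SNP over non-missing calls."""
        called = self.codes != MISSING_CODE
        n_called = called.sum(axis=0)
        dose = np.where(called, self.codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_called > 0, dose / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        p = self.ref_allele_freq()
        return np.minimum(p, 1.0 - p)

    def mean_imputed(self) -> np.ndarray:
        """Float dosage matrix with missing cells set to the SNP mean."""
        out = self.codes.astype(np.float64)
        miss = self.codes == MISSING_CODE
        if miss.any():
            col_mean = 2.0 * np.nan_to_num(self.ref_allele_freq(), nan=0.0)
            out[miss] = np.broadcast_to(col_mean, out.shape)[miss]
        return out

    def subset_individuals(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:  # id tokens
            pos = {a: i for i, a in enumerate(self.ids)}
            idx = np.array([pos[str(a)] for a in keep], dtype=np.int64)
        return GenotypeMatrix(
            ids=[self.ids[i] for i in idx],
            snp_map=self.snp_map.copy(),
            codes=self.codes[idx],
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            ids=list(self.ids),
            snp_map=self.snp_map.iloc[keep].reset_index(drop=True),
            codes=self.codes[:, keep],
        )

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero((self.snp_map["snp_id"] == snp_id).to_numpy())
        if len(hits) != 1:
            raise KeyError(f"SNP {snp_id!r} not uniquely present in map")
        return int(hits[0])


@dataclass
class HeatingCurve:
    """Piecewise-linear heating profile of one challenge group.

    ``ramps`` are (duration in hours, rate in degC/h) segments; after the
    last listed segment the final ``rate`` continues indefinitely, so the
    temperature function is defined (and non-decreasing) for any loss time.
    """

    group: str
    initial_temp: float
    ramps: tuple[tuple[float, float], ...] = ((1.5, 3.1),)
    final_rate: float = 0.9

    _grid_t: np.ndarray = field(init=False, repr=False)
    _grid_h: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for dur, rate in self.ramps:
            if dur <= 0 or rate < 0:
                raise ValueError("ramps need positive duration and rate >= 0")
        if self.final_rate < 0:
            raise ValueError("final heating rate must be >= 0")
        # dense grid for the cumulative-heat inverse (quarter-minute steps)
        t = np.arange(0.0, 48.0 * 60.0 + 0.25, 0.25)
        excess = self.temperature(t) - self.initial_temp
        h = np.concatenate(([0.0], np.cumsum(0.5 * (excess[1:] + excess[:-1]) * 0.25)))
        self._grid_t = t
        self._grid_h = h

    def temperature(self, minutes: np.ndarray | float) -> np.ndarray | float:
        """Water temperature (degC) at ``minutes`` after challenge start."""
        t = np.asarray(minutes, dtype=np.float64)
        temp = np.full(t.shape, self.initial_temp)
        elapsed = 0.0
        for dur_h, rate in self.ramps:
            dur = dur_h * 60.0
            within = np.clip(t - elapsed, 0.0, dur)
            temp = temp + rate / 60.0 * within
            elapsed += dur
        temp = temp + self.final_rate / 60.0 * np.clip(t - elapsed, 0.0, None)
        return temp if temp.shape else float(temp)

    def cumulative_heat(self, minutes: np.ndarray | float) -> np.ndarray | float:
        """Continuous integral of (T(s) - T(0)) ds, in degC*min."""
        out = np.interp(np.asarray(minutes, dtype=np.float64), self._grid_t, self._grid_h)
        return out if out.shape else float(out)

    def inverse_cumulative_heat(self, heat: np.ndarray | float) -> np.ndarray | float:
        """Time (min) at which the cumulative heat reaches ``heat``."""
        h = np.asarray(heat, dtype=np.float64)
        if np.any(h < 0) or np.any(h > self._grid_h[-1]):
            raise ValueError("cumulative heat outside the tabulated challenge window")
        out = np.interp(h, self._grid_h, self._grid_t)
        return out if out.shape else float(out)


def default_heating_curves(initial_temps: dict[str, float] | None = None) -> dict[str, "HeatingCurve"]:
    """The seven-group challenge design: 3.1 degC/h for 1.5 h then 0.9 degC/h.

    Group initial temperatures span the reported 16.1-18.4 degC range
    (G7 coldest, G4 warmest, 17.3 on average).
    """
    if initial_temps is None:
        initial_temps = {
            "G1": 17.6, "G2": 17.5, "G3": 17.3, "G4": 18.4,
            "G5": 17.0, "G6": 17.2, "G7": 16.1,
        }
    return {
        g: HeatingCurve(group=g, initial_temp=t0, ramps=((1.5, 3.1),), final_rate=0.9)
        for g, t0 in initial_temps.items()
    }
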