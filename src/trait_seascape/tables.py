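"""Core tabular containers: environment (R), abundance (L) and fuzzy trait (Q) tables.

All three are thin, validated wrappers around pandas DataFrames with the
delimited-text conventions used throughout the package: comma-separated,
UTF-8, header row, first column holds the row identifier. Fuzzy-trait
columns are flattened as ``trait__modality`` on disk and kept as a
two-level column MultiIndex in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codebook import TraitCodebook

logger = logging.getLogger(__name__)

SUBSTRATUM_LEVELS = ("muddy-to-sandy-mud", "sandy-to-muddy-sand", "coarse-and-mixed")

QUANTITATIVE_DESCRIPTORS = (
    "TEMP", "TEMPCV", "SAL", "SHEAR", "PAR", "POC",
    "fCSED", "sCSED", "DOX", "DOXCV", "botfluxPOC", "Depth",
)


class ValidationError(ValueError):
    """A table failed validation; the message names the offending cell."""


# ---------------------------------------------------------------------------
# Fuzzy trait table (Q)
# ---------------------------------------------------------------------------

@dataclass
class FuzzyTraitTable:
    """Taxa x (trait, modality) affinity matrix, blocked by trait.

    ``data`` has a two-level column MultiIndex ``(trait_id, modality)``.
    Raw affinities are 0/1 votes for the modalities a taxon has affinity
    for; ``to_profile`` rescales each non-empty taxon-trait block to sum
    to one so blocks read as fuzzy frequency profiles. Blocks whose row
    is all zero are "missing": the taxon is undocumented for that trait.
    """

    data: pd.DataFrame
    is_profile: bool = False
    provenance: pd.DataFrame | None = None  # taxa x traits: "species"|"genus"

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValidationError("fuzzy trait table needs (trait, modality) columns")
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("negative trait affinity")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        seen: dict[str, None] = {}
        for t, _ in self.data.columns:
            seen.setdefault(t)
        return list(seen)

    def block(self, trait_id: str) -> pd.DataFrame:
        """The taxa x modalities sub-table of one trait."""
        return self.data[trait_id]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean taxa x trait frame; True where a block row is empty."""
        out = {}
        for t in self.traits:
            out[t] = (self.block(t).sum(axis=1) == 0) | self.block(t).isna().all(axis=1)
        return pd.DataFrame(out)

    def to_profile(self) -> "FuzzyTraitTable":
        """Rescale each non-empty taxon-trait block row to sum to 1."""
        if self.is_profile:
            return self
        parts = []
        for t in self.traits:
            b = self.block(t).astype(float)
            s = b.sum(axis=1)
            scaled = b.div(s.where(s > 0, 1.0), axis=0)  # empty rows stay zero
            scaled.columns = pd.MultiIndex.from_product([[t], scaled.columns])
            parts.append(scaled)
        return FuzzyTraitTable(pd.concat(parts, axis=1), is_profile=True,
                               provenance=self.provenance)

    def complete_taxa(self, trait_ids=None) -> list[str]:
        """Taxa with non-empty blocks for every requested trait."""
        mask = self.missing_mask()
        cols = list(trait_ids) if trait_ids is not None else list(mask.columns)
        keep = ~mask[cols].any(axis=1)
        dropped = [t for t, k in keep.items() if not k]
        if dropped:
            logger.info("excluding %d taxa with missing trait blocks: %s",
                        len(dropped), dropped)
        return [t for t, k in keep.items() if k]

    def subset_taxa(self, taxa) -> "FuzzyTraitTable":
        prov = self.provenance.loc[taxa] if self.provenance is not None else None
        return FuzzyTraitTable(self.data.loc[list(taxa)], self.is_profile, prov)

    def subset_traits(self, trait_ids) -> "FuzzyTraitTable":
        cols = [c for c in self.data.columns if c[0] in set(trait_ids)]
        return FuzzyTraitTable(self.data[cols], self.is_profile, self.provenance)

    def validate(self, codebook: TraitCodebook) -> None:
        for trait_id, modality in self.data.columns:
            codebook.validate_modality(trait_id, modality)
        if self.is_profile:
            for t in self.traits:
                s = self.block(t).sum(axis=1).to_numpy()
                ok = np.isclose(s, 1.0, atol=1e-12) | (s == 0)
                if not ok.all():
                    bad = self.data.index[~ok][0]
                    raise ValidationError(f"profile row {bad!r} of trait {t} sums to {s[~ok][0]}")

    # -- delimited text -----------------------------------------------------

    def write_csv(self, path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{t}__{m}" for t, m in flat.columns]
        flat.index.name = "taxon"
        flat.to_csv(path)

    @classmethod
    def read_csv(cls, path, codebook: TraitCodebook | None = None,
                 is_profile: bool = False) -> "FuzzyTraitTable":
        flat = pd.read_csv(path, index_col=0)
        cols = []
        for c in flat.columns:
            if "__" not in c:
                raise ValidationError(f"column {c!r} is not of the form trait__modality")
            cols.append(tuple(c.split("__", 1)))
        flat.columns = pd.MultiIndex.from_tuples(cols)
        table = cls(flat, is_profile=is_profile)
        if codebook is not None:
            table.validate(codebook)
        return table


# ---------------------------------------------------------------------------
# Abundance table (L)
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Sites x taxa densities (individuals per m^2)."""

    data: pd.DataFrame
    transform: str = "raw"  # "raw" | "log10p1"

    def __post_init__(self) -> None:
        arr = self.data.to_numpy()
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing density at site {self.data.index[i]!r}, taxon {self.data.columns[j]!r}")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative density at site {self.data.index[i]!r}, taxon {self.data.columns[j]!r}")
        if self.transform not in ("raw", "log10p1"):
            raise ValidationError(f"unknown transform state {self.transform!r}")

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def log10p1(self) -> "AbundanceTable":
        """Down-scale large densities: d -> log10(d + 1). Applies once only."""
        if self.transform != "raw":
            raise ValidationError("abundance table is already log10(x+1)-transformed")
        return AbundanceTable(np.log10(self.data + 1.0), transform="log10p1")

    def write_csv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "site"
        out.to_csv(path)

    @classmethod
    def read_csv(cls, path, transform: str = "raw") -> "AbundanceTable":
        return cls(pd.read_csv(path, index_col=0), transform=transform)


# ---------------------------------------------------------------------------
# Environment table (R)
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentTable:
    """Sites x abiotic descriptors; quantitative plus a 3-level substratum factor."""

    data: pd.DataFrame
    substratum_col: str = "Substratum"

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            col = self.data.columns[self.data.isna().any().to_numpy()][0]
            site = self.data.index[self.data[col].isna()][0]
            raise ValidationError(f"missing value for {col!r} at site {site!r}")
        if self.substratum_col in self.data.columns:
            bad = set(self.data[self.substratum_col]) - set(SUBSTRATUM_LEVELS)
            if bad:
                raise ValidationError(f"unknown substratum level(s) {sorted(bad)}")

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def quantitative(self) -> pd.DataFrame:
        return self.data.select_dtypes(include=[np.number])

    @property
    def categorical(self) -> pd.DataFrame:
        return self.data.select_dtypes(exclude=[np.number])

    def write_csv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "site"
        out.to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "EnvironmentTable":
        return cls(pd.read_csv(path, index_col=0))


# ---------------------------------------------------------------------------
# Cross-table I/O and validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    unmatched_taxa_in_L: list[str] = field(default_factory=list)
    unmatched_taxa_in_Q: list[str] = field(default_factory=list)
    unmatched_sites: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.unmatched_taxa_in_L or self.unmatched_taxa_in_Q
                    or self.unmatched_sites)


def read_tables(r_path, l_path, q_path, codebook: TraitCodebook,
                ) -> tuple[EnvironmentTable, AbundanceTable, FuzzyTraitTable, ValidationReport]:
    """Read and cross-validate the R, L, Q triple.

    Sites and taxa are aligned to the intersection across tables, in L's
    order; identifiers present in one table only are reported, and the
    report is logged.
    """
    R = EnvironmentTable.read_csv(r_path)
    L = AbundanceTable.read_csv(l_path)
    Q = FuzzyTraitTable.read_csv(q_path, codebook=codebook)

    report = ValidationReport(
        unmatched_taxa_in_L=[t for t in L.taxa if t not in set(Q.taxa)],
        unmatched_taxa_in_Q=[t for t in Q.taxa if t not in set(L.taxa)],
        unmatched_sites=sorted(set(L.sites) ^ set(R.sites)),
    )
    if not report.clean:
        logger.warning("identifier mismatches across tables: %s", report)

    sites = [s for s in L.sites if s in set(R.sites)]
    taxa = [t for t in L.taxa if t in set(Q.taxa)]
    R = EnvironmentTable(R.data.loc[sites])
    L = AbundanceTable(L.data.loc[sites, taxa], transform=L.transform)
    Q = Q.subset_taxa(taxa)
    return R, L, Q, report


def write_tables(R: EnvironmentTable, L: AbundanceTable, Q: FuzzyTraitTable,
                 r_path, l_path, q_path) -> None:
    R.write_csv(Path(r_path))
    L.write_csv(Path(l_path))
    Q.write_csv(Path(q_path))


# ---------------------------------------------------------------------------
# Climatology summaries
# ---------------------------------------------------------------------------

def climatology_stats(series: pd.DataFrame | np.ndarray, ddof: int = 0) -> pd.DataFrame:
    """Per-site summary of an abiotic time series: mean, min, max, sd, cv.

    ``series`` is sites x time. The coefficient of variation is sd/mean;
    where the mean is 0 it is undefined and reported as NaN. The standard
    deviation uses the population denominator (``ddof=0``) by default.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] < 2:
        raise ValidationError("climatology needs a series of length >= 2")
    index = series.index if isinstance(series, pd.DataFrame) else range(arr.shape[0])
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.where(mean != 0, mean, 1.0), np.nan)
    return pd.DataFrame(
        {"mean": mean, "min": arr.min(axis=1), "max": arr.max(axis=1), "sd": sd, "cv": cv},
        index=index,
    )
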