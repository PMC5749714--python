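"""Incidence matrices, cave metadata, ranked taxonomies, and trait tables.

The central container is :class:`IncidenceMatrix`, a binary species x site
table.  Rows are species, columns are sites (caves); row totals are species
occupancies, column totals are site richnesses, and the grand total is the
matrix fill F.  Readers accept delimited text (comma or tab); counts are
binarized on input because every downstream metric is defined on
presence-absence data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Internal taxonomic ranks from most to least inclusive.  The species
#: itself is the tip of the implied tree and is not a column.
RANKS = (
    "order",
    "suborder",
    "superfamily",
    "family",
    "subfamily",
    "tribe",
    "genus",
    "subgenus",
)

METADATA_COLUMNS = (
    "site_id",
    "longitude",
    "latitude",
    "length_m",
    "depth_m",
    "altitude_m",
    "visits",
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary species x site occupancy table.

    Parameters
    ----------
    values :
        2-D int array of 0/1, shape ``(n_species, n_sites)``.
    species_ids, site_ids :
        Unique row / column labels.
    """

    values: np.ndarray
    species_ids: tuple[str, ...]
    site_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.int8)
        if values.ndim != 2:
            raise ValidationError("incidence values must be 2-D")
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValidationError("incidence entries must be 0 or 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "species_ids", tuple(map(str, self.species_ids)))
        object.__setattr__(self, "site_ids", tuple(map(str, self.site_ids)))
        if len(self.species_ids) != values.shape[0]:
            raise ValidationError("species_ids length does not match row count")
        if len(self.site_ids) != values.shape[1]:
            raise ValidationError("site_ids length does not match column count")
        for what, ids in (("species", self.species_ids), ("site", self.site_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicate {what} labels: {dupes}")

    # -- derived marginals -------------------------------------------------
    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        """Occupancy r_i: number of sites occupied by each species."""
        return self.values.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """Richness c_j: number of species present at each site."""
        return self.values.sum(axis=0)

    @property
    def fill(self) -> int:
        """Total number of occurrences F."""
        return int(self.values.sum())

    # -- construction / conversion ----------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IncidenceMatrix":
        """Build from a DataFrame (index = species, columns = sites)."""
        numeric = frame.apply(pd.to_numeric, errors="coerce")
        values = numeric.to_numpy(dtype=float)
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing/non-numeric cell {frame.iat[i, j]!r} at species "
                f"{frame.index[i]!r}, site {frame.columns[j]!r}"
            )
        if (values < 0).any():
            raise ValidationError("negative cell in incidence table")
        return cls((values > 0).astype(np.int8), tuple(frame.index.astype(str)),
                   tuple(frame.columns.astype(str)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.species_ids),
                            columns=list(self.site_ids))

    def with_values(self, values: np.ndarray) -> "IncidenceMatrix":
        """Same labels, new entries (used by the randomizers)."""
        return IncidenceMatrix(values, self.species_ids, self.site_ids)

    def subset_sites(self, site_ids, drop_empty_species: bool = True) -> "IncidenceMatrix":
        """Restrict to the given sites; optionally drop emptied species rows."""
        site_ids = [str(s) for s in site_ids]
        missing = [s for s in site_ids if s not in set(self.site_ids)]
        if missing:
            raise KeyError(f"unknown site ids: {missing}")
        col_idx = [self.site_ids.index(s) for s in site_ids]
        values = self.values[:, col_idx]
        species = self.species_ids
        if drop_empty_species:
            keep = values.sum(axis=1) > 0
            values = values[keep]
            species = tuple(s for s, k in zip(species, keep) if k)
        return IncidenceMatrix(values, species, tuple(site_ids))

    def species_index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(str(species_id))
        except ValueError:
            raise KeyError(f"unknown species label: {species_id!r}") from None


class TaxonomyTable:
    """Ranked classification of species over up to nine levels.

    Wraps a DataFrame indexed by species id with the columns of
    :data:`RANKS`; empty / NaN cells mean the rank is absent for that
    species (common in practice: not every lineage has, e.g., a named
    suborder or tribe).  The table implies a tree; construction verifies
    that no taxon value appears under two different parents.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        frame.index = frame.index.astype(str)
        if frame.index.duplicated().any():
            raise ValidationError("duplicate species in taxonomy")
        for rank in RANKS:
            if rank not in frame.columns:
                frame[rank] = pd.NA
        frame = frame[list(RANKS)]
        # normalize empties to NA
        frame = frame.where(frame.notna() & (frame.astype(str).apply(lambda c: c.str.strip()) != ""))
        self.frame = frame
        self._paths: dict[str, tuple[tuple[str, str], ...]] = {}
        for sp, row in frame.iterrows():
            self._paths[sp] = tuple(
                (rank, str(row[rank])) for rank in RANKS if pd.notna(row[rank])
            )
        self._check_tree_consistency()

    def _check_tree_consistency(self):
        parent_of: dict[tuple[str, str], tuple] = {}
        for sp, path in self._paths.items():
            for k, node in enumerate(path):
                parent = path[k - 1] if k else ("root", "root")
                prior = parent_of.setdefault(node, parent)
                if prior != parent:
                    raise ValidationError(
                        f"taxon {node[1]!r} ({node[0]}) appears under two parents: "
                        f"{prior[1]!r} and {parent[1]!r}"
                    )

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def path(self, species_id: str) -> tuple[tuple[str, str], ...]:
        """The (rank, taxon) nodes from order down to subgenus, skipping
        absent ranks.  The species itself is the tip and not included."""
        try:
            return self._paths[str(species_id)]
        except KeyError:
            raise KeyError(f"species {species_id!r} not in taxonomy") from None

    def __contains__(self, species_id) -> bool:
        return str(species_id) in self._paths

    def __len__(self) -> int:
        return len(self._paths)


@dataclass
class FilterResult:
    """Outcome of a site filter: the reduced matrix plus what was dropped."""

    matrix: IncidenceMatrix
    dropped_sites: tuple[str, ...]
    dropped_species: tuple[str, ...]


@dataclass
class ValidationReport:
    """Cross-table consistency report (report-only, never raises)."""

    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.ok:
            return "dataset consistent: no issues"
        return "\n".join(self.issues)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path, **kwargs) -> pd.DataFrame:
    # sep=None sniffs comma vs tab
    return pd.read_csv(path, sep=None, engine="python", **kwargs)


def read_incidence_matrix(path, species_as_rows: bool = True) -> IncidenceMatrix:
    """Read a delimited incidence table.

    First row holds site ids, first column species ids (transposed when
    ``species_as_rows`` is False).  Cells must parse to nonnegative
    numbers; counts > 0 binarize to 1.
    """
    frame = _read_table(path, index_col=0)
    if not species_as_rows:
        frame = frame.T
    matrix = IncidenceMatrix.from_frame(frame)
    logger.info(
        "read incidence matrix: %d species x %d sites, fill %d",
        matrix.n_species, matrix.n_sites, matrix.fill,
    )
    return matrix


def write_incidence_matrix(matrix: IncidenceMatrix, path, sep: str = ",") -> None:
    matrix.to_frame().to_csv(path, sep=sep)


def read_cave_metadata(path) -> pd.DataFrame:
    """Read cave metadata; requires the standard columns, returns a frame
    indexed by site_id with a derived ``sampling_class`` column."""
    frame = _read_table(path)
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    frame["site_id"] = frame["site_id"].astype(str)
    if frame["site_id"].duplicated().any():
        raise ValidationError("duplicate site_id in metadata")
    frame = frame.set_index("site_id")
    _check_metadata(frame)
    frame["sampling_class"] = [assign_sampling_class(v) for v in frame["visits"]]
    return frame


def _check_metadata(frame: pd.DataFrame) -> None:
    lon, lat = frame["longitude"], frame["latitude"]
    if ((lon < -180) | (lon > 180)).any() or ((lat < -90) | (lat > 90)).any():
        raise ValidationError("coordinates outside plausible bounds")
    if (frame["length_m"].dropna() <= 0).any():
        raise ValidationError("cave length must be > 0")
    if (frame["depth_m"].dropna() < 0).any():
        raise ValidationError("cave depth must be >= 0")


def read_taxonomy(path) -> TaxonomyTable:
    frame = _read_table(path)
    if "species_id" not in frame.columns:
        raise ValidationError("taxonomy table needs a species_id column")
    return TaxonomyTable(frame.set_index("species_id"))


def read_traits(path) -> pd.DataFrame:
    """Read a categorical trait table indexed by species_id."""
    frame = _read_table(path)
    if "species_id" not in frame.columns:
        raise ValidationError("trait table needs a species_id column")
    frame["species_id"] = frame["species_id"].astype(str)
    if frame["species_id"].duplicated().any():
        raise ValidationError("duplicate species_id in traits")
    return frame.set_index("species_id")


# ---------------------------------------------------------------------------
# sampling-intensity rules


def assign_sampling_class(visits: int) -> int:
    """Map a cave's visit count to its sampling-intensity class.

    Classes: 1-3 visits -> 1 (less sampled), 4-6 -> 2, 7-9 -> 3,
    10-12 -> 4 (very highly sampled).  Visit counts outside 1-12 are
    rejected: the classification is defined only on that range.
    """
    visits = int(visits)
    if not 1 <= visits <= 12:
        raise ValueError(f"visits must be in 1..12, got {visits}")
    return (visits - 1) // 3 + 1


def filter_by_visits(matrix: IncidenceMatrix, metadata: pd.DataFrame,
                     min_visits: int = 3) -> FilterResult:
    """Drop under-surveyed sites (visits < ``min_visits``).

    Species left with zero occurrences after the site filter are dropped
    and reported, so the returned matrix is again a valid analysis
    matrix (its species pool is recomputed).
    """
    missing = [s for s in matrix.site_ids if s not in metadata.index]
    if missing:
        raise ValidationError(f"sites missing from metadata: {missing}")
    visits = metadata.loc[list(matrix.site_ids), "visits"]
    keep_sites = [s for s, v in zip(matrix.site_ids, visits) if v >= min_visits]
    dropped_sites = tuple(s for s in matrix.site_ids if s not in set(keep_sites))
    filtered = matrix.subset_sites(keep_sites, drop_empty_species=True)
    dropped_species = tuple(s for s in matrix.species_ids
                            if s not in set(filtered.species_ids))
    if dropped_species:
        logger.info("site filter emptied %d species rows: %s",
                    len(dropped_species), ", ".join(dropped_species))
    return FilterResult(filtered, dropped_sites, dropped_species)


def validate_dataset(matrix: IncidenceMatrix,
                     metadata: pd.DataFrame | None = None,
                     taxonomy: TaxonomyTable | None = None,
                     traits: pd.DataFrame | None = None) -> ValidationReport:
    """Cross-check key agreement between the tables; never raises."""
    report = ValidationReport()
    mat_sites = set(matrix.site_ids)
    mat_species = set(matrix.species_ids)
    if metadata is not None:
        meta_sites = set(metadata.index.astype(str))
        for s in sorted(mat_sites - meta_sites):
            report.issues.append(f"site {s!r} in matrix but not in metadata")
        for s in sorted(meta_sites - mat_sites):
            report.issues.append(f"site {s!r} in metadata but not in matrix")
    for name, table_species in (
        ("taxonomy", set(taxonomy.species_ids) if taxonomy is not None else None),
        ("traits", set(traits.index.astype(str)) if traits is not None else None),
    ):
        if table_species is None:
            continue
        for s in sorted(mat_species - table_species):
            report.issues.append(f"species {s!r} in matrix but not in {name}")
        for s in sorted(table_species - mat_species):
            report.issues.append(f"species {s!r} in {name} but not in matrix")
    return report
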