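"""Host-record ingestion and genus-level trait derivation.

The raw input is a species-level host-record table (moth species, genus-level
taxon, host plant family, host plant order), the layout of a typical
host-plant compilation for a moth clade. From it we derive, per genus-level
taxon:

* host diversity ``hd`` — the number of distinct plant orders recorded across
  all species of the taxon, a proxy for cumulative (past and present) host
  breadth;
* ``max_polyphagy`` — the largest number of distinct orders recorded for any
  single species, i.e. the polyphagy of the taxon's most polyphagous species;
* binary polyphagy codings ``poly3``/``poly7`` — whether any single species
  feeds on at least 3 (resp. 7) plant orders.

Species richness is supplied externally (a taxon -> count map): counting
described species is editorial work, not computation.

Plant-order names are matched case-insensitively after whitespace trimming;
no taxonomic synonym resolution is attempted. Records are de-duplicated on
the (species, order) pair. Non-angiosperm orders count toward ``hd`` exactly
like angiosperm ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "GenusTraits",
    "HOST_RECORD_COLUMNS",
    "read_host_records",
    "host_records_from_frame",
    "derive_genus_traits",
    "code_binary_trait",
    "order_usage_matrix",
]

HOST_RECORD_COLUMNS = (
    "moth_species",
    "genus_taxon",
    "plant_family",
    "plant_order",
)


@dataclass(frozen=True)
class GenusTraits:
    """Per-taxon summary of host use and species richness."""

    taxon: str
    n_species: int
    host_orders: frozenset[str]
    max_polyphagy: int

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise InputError(f"{self.taxon}: n_species must be >= 1")
        if not 0 <= self.max_polyphagy <= self.hd:
            raise InputError(
                f"{self.taxon}: max_polyphagy {self.max_polyphagy} outside "
                f"[0, hd={self.hd}]"
            )

    @property
    def hd(self) -> int:
        """Host diversity: number of distinct plant orders used by the taxon."""
        return len(self.host_orders)

    @property
    def poly3(self) -> int:
        return int(self.max_polyphagy >= 3)

    @property
    def poly7(self) -> int:
        return int(self.max_polyphagy >= 7)

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "n_species": self.n_species,
            "host_orders": sorted(self.host_orders),
            "hd": self.hd,
            "max_polyphagy": self.max_polyphagy,
            "poly3": self.poly3,
            "poly7": self.poly7,
        }


def _norm(name: str) -> str:
    return str(name).strip().casefold()


def host_records_from_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate and de-duplicate an in-memory host-record table.

    Enforces the four canonical columns, rejects empty cells (with the
    offending row number), normalises plant-order case/whitespace for
    matching, and drops duplicated (species, order) pairs.
    """
    missing = [c for c in HOST_RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"missing column(s): {missing}")
    df = frame.loc[:, list(HOST_RECORD_COLUMNS)].copy()
    for col in HOST_RECORD_COLUMNS:
        df[col] = df[col].astype("string").str.strip()
    bad = df.isna().any(axis=1) | (df == "").any(axis=1)
    if bad.any():
        row = int(df.index[bad][0])
        raise InputError(f"empty cell in host-record table at row {row}")
    df["plant_order"] = df["plant_order"].map(_norm)
    n_before = len(df)
    df = df.drop_duplicates(subset=["moth_species", "plant_order"], keep="first")
    logger.info(
        "host records: %d rows loaded, %d after (species, order) de-duplication",
        n_before,
        len(df),
    )
    if len(df) == 0:
        logger.warning("host-record table is empty")
    return df.reset_index(drop=True)


def read_host_records(path, sep: str = "\t") -> pd.DataFrame:
    """Load a delimited host-record file (TSV by default)."""
    try:
        frame = pd.read_csv(path, sep=sep, dtype="string")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: no header row") from exc
    return host_records_from_frame(frame)


def derive_genus_traits(
    records: pd.DataFrame, richness: Mapping[str, int]
) -> list[GenusTraits]:
    """Collate species-level records into per-taxon :class:`GenusTraits`.

    ``hd`` is the count of distinct plant orders across all of the taxon's
    species; ``max_polyphagy`` the maximum over species of distinct orders
    per species. Every taxon present in ``records`` must appear in the
    ``richness`` map. Output order is sorted by taxon name, so row order of
    the input is irrelevant.
    """
    records = host_records_from_frame(records)
    taxa = sorted(records["genus_taxon"].unique())
    missing = [t for t in taxa if t not in richness]
    if missing:
        raise InputError(f"taxa missing from richness map: {missing}")
    out = []
    for taxon, grp in records.groupby("genus_taxon", sort=True):
        per_species = grp.groupby("moth_species")["plant_order"].nunique()
        out.append(
            GenusTraits(
                taxon=str(taxon),
                n_species=int(richness[str(taxon)]),
                host_orders=frozenset(grp["plant_order"]),
                max_polyphagy=int(per_species.max()),
            )
        )
    return out


def code_binary_trait(
    traits: Iterable[GenusTraits], threshold: int
) -> dict[str, int]:
    """0/1 coding: does any single species of the taxon use >= ``threshold`` orders?

    ``threshold=3`` and ``threshold=7`` give the "3+ orders" / "7+ orders"
    polyphagy characters.
    """
    if threshold < 1:
        raise InputError("threshold must be >= 1")
    return {t.taxon: int(t.max_polyphagy >= threshold) for t in traits}


def order_usage_matrix(
    traits: Iterable[GenusTraits], orders: list[str]
) -> pd.DataFrame:
    """Binary taxon x order usage matrix.

    Cell (t, o) is 1 iff order ``o`` is among taxon ``t``'s host orders.
    Column sums are the per-order taxon counts used to rank orders by how
    many genus-level taxa use them (e.g. to select the ten most widely used
    orders for signal testing). Orders unknown to every taxon are allowed
    (all-zero column) but warned about.
    """
    if not orders:
        raise InputError("orders list must be non-empty")
    traits = list(traits)
    norm_orders = [_norm(o) for o in orders]
    mat = pd.DataFrame(
        [[int(o in t.host_orders) for o in norm_orders] for t in traits],
        index=[t.taxon for t in traits],
        columns=list(orders),
        dtype=int,
    )
    unused = [o for o in orders if mat[o].sum() == 0]
    if unused:
        logger.warning("order(s) used by no taxon: %s", unused)
    return mat
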