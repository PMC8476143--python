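"""Intron presence/absence site table.

A site is a column of an intron-aware protein alignment at which at least
one species has an intron.  Each site carries one state per species:
present (1), absent (0) or ambiguous ('?', treated as missing data and
marginalized over both states during inference).

States are held in an int8 matrix (sites x species) with codes 0, 1 and 2
for '?', alongside per-site metadata (gene, 1-based ordinal from the 5'
end, 0-based CDS nucleotide offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SiteRecord",
    "IntronSiteTable",
    "TableFormatError",
    "read_intron_table",
    "filter_sites",
]

MISSING = 2  # internal code for '?'

_META_COLS = ["site_id", "gene_id", "ordinal", "cds_offset"]
_CODE_TO_CHAR = {0: "0", 1: "1", MISSING: "?"}
_CHAR_TO_CODE = {"0": 0, "1": 1, "?": MISSING}


class TableFormatError(ValueError):
    """Raised on malformed site-table input."""


@dataclass
class SiteRecord:
    """One intron site: metadata plus one state per species."""

    site_id: str
    gene_id: str
    ordinal: int
    cds_offset: int
    states: np.ndarray  # int8, one code per species

    @property
    def ambiguous_count(self) -> int:
        return int(np.sum(self.states == MISSING))

    @property
    def present_count(self) -> int:
        return int(np.sum(self.states == 1))


class IntronSiteTable:
    """Site x species matrix of {0, 1, ?} with site metadata.

    Parameters
    ----------
    species
        Ordered species labels (must match the tree leaves when used with
        one).
    states
        int8 array of shape (n_sites, n_species) with codes {0, 1, 2}.
    meta
        DataFrame with columns site_id, gene_id, ordinal, cds_offset.
    """

    def __init__(self, species: list[str], states: np.ndarray, meta: pd.DataFrame):
        states = np.asarray(states, dtype=np.int8)
        if states.ndim != 2 or states.shape[1] != len(species):
            raise TableFormatError("state matrix shape does not match species list")
        if not np.isin(states, [0, 1, MISSING]).all():
            raise TableFormatError("state codes must be 0, 1 or 2 ('?')")
        if len(meta) != states.shape[0]:
            raise TableFormatError("metadata rows do not match state rows")
        missing_cols = [c for c in _META_COLS if c not in meta.columns]
        if missing_cols:
            raise TableFormatError(f"metadata missing columns {missing_cols}")
        self.species = list(species)
        self.states = states
        self.meta = meta.reset_index(drop=True)[_META_COLS].copy()

    # -- basic views -------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.states.shape[0]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def ambiguous_counts(self) -> np.ndarray:
        return np.sum(self.states == MISSING, axis=1)

    def site(self, i: int) -> SiteRecord:
        row = self.meta.iloc[i]
        return SiteRecord(
            site_id=str(row.site_id),
            gene_id=str(row.gene_id),
            ordinal=int(row.ordinal),
            cds_offset=int(row.cds_offset),
            states=self.states[i],
        )

    def __iter__(self):
        return (self.site(i) for i in range(self.n_sites))

    def __len__(self) -> int:
        return self.n_sites

    def subset(self, indices) -> "IntronSiteTable":
        indices = np.asarray(indices)
        return IntronSiteTable(
            self.species, self.states[indices], self.meta.iloc[indices]
        )

    def reorder_species(self, order: list[str]) -> "IntronSiteTable":
        """Return a table with species columns in ``order``."""
        missing = [s for s in order if s not in self.species]
        if missing:
            raise TableFormatError(f"species not in table: {missing}")
        cols = [self.species.index(s) for s in order]
        return IntronSiteTable(list(order), self.states[:, cols], self.meta)

    # -- io ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        chars = np.vectorize(_CODE_TO_CHAR.get)(self.states)
        df = self.meta.copy()
        for j, sp in enumerate(self.species):
            df[sp] = chars[:, j]
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntronSiteTable":
        species = [c for c in df.columns if c not in _META_COLS]
        states = np.empty((len(df), len(species)), dtype=np.int8)
        for j, sp in enumerate(species):
            col = df[sp].astype(str).str.strip()
            codes = col.map(_CHAR_TO_CODE)
            if codes.isna().any():
                row = int(np.nonzero(codes.isna().to_numpy())[0][0])
                raise TableFormatError(
                    f"unknown state {col.iloc[row]!r} at row {row}, column {sp!r}"
                )
            states[:, j] = codes.to_numpy(dtype=np.int8)
        return cls(species, states, df[_META_COLS])


def read_intron_table(path, tree=None) -> IntronSiteTable:
    """Read a TSV site table (metadata columns then species columns).

    When ``tree`` is given, the table's species are cross-checked against
    the tree's leaf names and reordered to match them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing metadata columns {missing}")
    df["ordinal"] = df["ordinal"].astype(int)
    df["cds_offset"] = df["cds_offset"].astype(int)
    table = IntronSiteTable.from_frame(df)
    if tree is not None:
        extra = [s for s in table.species if s not in tree.leaf_names]
        absent = [s for s in tree.leaf_names if s not in table.species]
        if extra or absent:
            raise TableFormatError(
                f"species mismatch with tree (extra in table: {extra}, "
                f"missing from table: {absent})"
            )
        table = table.reorder_species(tree.leaf_names)
    return table


def filter_sites(table: IntronSiteTable, max_ambiguous: int) -> IntronSiteTable:
    """Apply the ambiguity cutoff and the observability rule.

    Retains exactly the sites with at most ``max_ambiguous`` '?' states AND
    at least one unambiguous present state.  A site that is absent in every
    unambiguously aligned species can never have entered the table from
    real alignments, so such rows are dropped; the likelihood is
    conditioned on the same event (see :mod:`intronevo.likelihood`).
    """
    if max_ambiguous < 0:
        raise ValueError("max_ambiguous must be >= 0")
    keep = (table.ambiguous_counts <= max_ambiguous) & (
        np.any(table.states == 1, axis=1)
    )
    return table.subset(np.nonzero(keep)[0])
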