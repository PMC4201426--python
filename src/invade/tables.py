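"""Parsing and validation of species status and life-history trait tables.

The status table lists each alien species with its family, order, and a
regulatory appendix category:

* appendix 1 — prohibited aliens ("strong invaders"), the positive class;
* appendix 2 — permitted aliens (noninvasive);
* appendix 3 — invasive aliens ("weak invaders");
* appendices 4/5 — species invasive (or potentially so) only elsewhere;
  these carry no in-country invasion intensity and are excluded from
  analysis with a warning.

The binary response is ``y = 1`` for prohibited and ``y = 0`` for
nonprohibited (permitted + invasive).

The trait table is a PanTHERIA-style species-by-trait numeric matrix with
a missing-value sentinel (default −999).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import normalize_name

__all__ = [
    "StatusTable",
    "TraitTable",
    "parse_status",
    "parse_traits",
    "CATEGORY_BY_APPENDIX",
]

log = logging.getLogger(__name__)

CATEGORY_BY_APPENDIX = {1: "prohibited", 2: "permitted", 3: "invasive"}
STATUS_COLUMNS = ("species", "family", "order", "appendix")


@dataclass
class StatusTable:
    """Validated species status table.

    ``data`` holds one row per analyzed species with columns
    ``species, family, order, appendix, category, y``; ``excluded`` holds
    any appendix-4/5 rows that were set aside.
    """

    data: pd.DataFrame
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def species(self) -> list[str]:
        return self.data["species"].tolist()

    @property
    def y(self) -> pd.Series:
        return self.data.set_index("species")["y"]

    @property
    def prohibited(self) -> list[str]:
        return self.data.loc[self.data["y"] == 1, "species"].tolist()

    def members(self, category: str) -> list[str]:
        """Species in one analysis category; 'nonprohibited' = permitted + invasive."""
        if category == "nonprohibited":
            mask = self.data["category"].isin(["permitted", "invasive"])
        else:
            mask = self.data["category"] == category
        return self.data.loc[mask, "species"].tolist()

    def counts(self) -> dict[str, int]:
        return self.data["category"].value_counts().to_dict()

    def restrict_to(self, species) -> "StatusTable":
        """Keep only the given species (names normalized); logs the drop count."""
        keep = {normalize_name(s) for s in species}
        mask = self.data["species"].isin(keep)
        dropped = int((~mask).sum())
        if dropped:
            log.warning("dropping %d status rows absent from the species set", dropped)
        return StatusTable(self.data.loc[mask].reset_index(drop=True), self.excluded)


def parse_status(source: str | os.PathLike | pd.DataFrame) -> StatusTable:
    """Parse and validate a status CSV (or DataFrame).

    Required columns: species, family, order, appendix.  Appendix values
    must lie in 1–5; 1→prohibited (y=1), 2→permitted, 3→invasive (y=0);
    4/5 are excluded with a warning.  Duplicate species are an error.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in STATUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"status table missing required columns: {missing}")
    df = df.loc[:, list(STATUS_COLUMNS)]
    df["species"] = df["species"].map(normalize_name)
    dupes = df["species"][df["species"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate species in status table: {sorted(dupes)}")
    try:
        df["appendix"] = df["appendix"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-integer appendix value: {exc}") from exc
    bad = sorted(set(df["appendix"]) - {1, 2, 3, 4, 5})
    if bad:
        raise ValueError(f"unknown appendix values: {bad} (expected 1-5)")

    excluded = df[df["appendix"].isin([4, 5])].reset_index(drop=True)
    if len(excluded):
        log.warning(
            "excluding %d species in appendices 4/5 (not invasive in-country): %s",
            len(excluded), ", ".join(excluded["species"]),
        )
    kept = df[df["appendix"].isin([1, 2, 3])].reset_index(drop=True)
    kept["category"] = kept["appendix"].map(CATEGORY_BY_APPENDIX)
    kept["y"] = (kept["appendix"] == 1).astype(int)
    table = StatusTable(kept, excluded)
    log.info("status table: %s", table.counts())
    return table


@dataclass
class TraitTable:
    """Species-by-trait numeric matrix; missing values stored as NaN.

    ``usable_n`` records the complete-case count per trait; columns with
    zero usable values are listed in ``unusable``.
    """

    data: pd.DataFrame  # index: species; columns: traits
    sentinel: float = -999.0

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    @property
    def usable_n(self) -> pd.Series:
        return self.data.notna().sum()

    @property
    def unusable(self) -> list[str]:
        n = self.usable_n
        return list(n.index[n == 0])

    def write_csv(self, path: str | os.PathLike) -> None:
        out = self.data.fillna(self.sentinel)
        out.to_csv(path, index_label="species", float_format="%.10g")


def parse_traits(source: str | os.PathLike | pd.DataFrame,
                 missing_sentinel: float = -999.0) -> TraitTable:
    """Parse a trait CSV: first column species, remaining columns numeric.

    Cells equal to ``missing_sentinel`` become NaN.  A non-numeric cell
    that is not the sentinel is an error.  Duplicate species are an error.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        if df.index.name is None or str(df.index.dtype) != "object":
            df = df.set_index(df.columns[0])
    else:
        df = pd.read_csv(source, index_col=0)
    df.index = [normalize_name(str(s)) for s in df.index]
    df.index.name = "species"
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate species in trait table: {dupes}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric value in trait column {col!r}: {exc}") from exc
    df = df.where(~np.isclose(df.astype(float), float(missing_sentinel)), np.nan)
    table = TraitTable(df.astype(float), float(missing_sentinel))
    if table.unusable:
        log.warning("trait columns with no usable values: %s", table.unusable)
    return table
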