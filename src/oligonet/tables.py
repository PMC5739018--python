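"""Samples-by-oligotypes count tables and their on-disk layout.

The central object of the pipeline is a samples x oligotypes count matrix with
per-sample dates (year, day-of-year) and per-oligotype taxonomy strings.  On
disk the table is a TSV with one row per oligotype (id, taxonomy, then one
column per sample), the layout commonly used for amplicon abundance matrices.
Sample ids follow the ``Y<year>_D<day>`` convention so dates round-trip
through plain TSV without a sidecar file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_SAMPLE_ID_RE = re.compile(r"^Y(?P<year>\d+)_D(?P<day>\d+)$")


def sample_id(year: int, day: int) -> str:
    return f"Y{year}_D{day:03d}"


def parse_sample_id(sid: str) -> tuple[int, int]:
    """Return (year, day-of-year) encoded in a sample id."""
    m = _SAMPLE_ID_RE.match(sid)
    if m is None:
        raise ValueError(f"sample id {sid!r} does not follow Y<year>_D<day>")
    return int(m.group("year")), int(m.group("day"))


@dataclass
class OligotypeTable:
    """Count matrix (samples x oligotypes) with dates and taxonomy.

    Parameters
    ----------
    counts
        Non-negative integer counts, index = sample ids, columns = oligotype
        ids.
    dates
        DataFrame indexed like ``counts`` with integer columns ``year`` and
        ``day`` (day-of-year).  If omitted, dates are parsed from sample ids.
    taxonomy
        Semicolon-ranked taxonomy strings indexed by oligotype id.  Missing
        entries default to ``"Unclassified"``.
    """

    counts: pd.DataFrame
    dates: pd.DataFrame = None
    taxonomy: pd.Series = None
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self):
        if self.dates is None:
            parsed = [parse_sample_id(s) for s in self.counts.index]
            self.dates = pd.DataFrame(
                parsed, index=self.counts.index, columns=["year", "day"]
            )
        if self.taxonomy is None:
            self.taxonomy = pd.Series(
                "Unclassified", index=self.counts.columns, dtype=object
            )
        self.taxonomy = self.taxonomy.reindex(self.counts.columns).fillna(
            "Unclassified"
        )
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate oligotype ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if not self.dates.index.equals(self.counts.index):
            raise ValueError("dates index does not match counts index")
        for _, sub in self.dates.groupby("year"):
            d = sub["day"].to_numpy()
            if not (np.diff(d) > 0).all():
                raise ValueError("sample days must be strictly increasing within a year")
        self._validated = True

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_oligotypes(self) -> int:
        return self.counts.shape[1]

    @property
    def oligotype_ids(self) -> pd.Index:
        return self.counts.columns

    def proportions(self) -> pd.DataFrame:
        """Per-sample relative abundances (read proportions)."""
        tot = self.counts.sum(axis=1)
        if (tot == 0).any():
            raise ValueError("sample with zero total count")
        return self.counts.div(tot, axis=0)

    def subset_oligotypes(self, ids) -> "OligotypeTable":
        ids = pd.Index(ids)
        return OligotypeTable(
            counts=self.counts.loc[:, ids].copy(),
            dates=self.dates.copy(),
            taxonomy=self.taxonomy.loc[ids].copy(),
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write oligotypes-as-rows TSV: id, taxonomy, one column per sample."""
        out = self.counts.T.copy()
        out.insert(0, "taxonomy", self.taxonomy.loc[out.index].to_numpy())
        out.index.name = "oligotype"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "OligotypeTable":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        taxonomy = raw["taxonomy"].astype(str)
        counts = raw.drop(columns=["taxonomy"]).T.astype(np.int64)
        counts.index.name = None
        return cls(counts=counts, taxonomy=taxonomy)
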