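"""Filtering and prevalence classification of oligotype count tables.

Mirrors the bookkeeping done before network construction on real amplicon
data sets: taxonomy-based removal (chloroplast / mitochondria / unclassified
reads), a low-prevalence filter, and an intersection step so both yearly
tables carry exactly the same oligotype set.  A separate prevalence
classifier splits oligotypes into broadly prevalent (above a high count
threshold in most samples) versus narrowly prevalent bloom responders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import OligotypeTable


def remove_taxa(
    table: OligotypeTable, patterns: list[str]
) -> tuple[OligotypeTable, int, float]:
    """Drop oligotypes whose taxonomy contains any pattern (case-insensitive).

    Returns the filtered table, the number of oligotypes removed and the
    fraction of total reads they carried.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    tax = table.taxonomy.astype(str).str.lower()
    hit = pd.Series(False, index=table.oligotype_ids)
    for p in patterns:
        hit |= tax.str.contains(p.lower(), regex=False)
    removed = hit.sum()
    total = table.counts.to_numpy().sum()
    removed_abundance = table.counts.loc[:, hit].to_numpy().sum() / total if total else 0.0
    return table.subset_oligotypes(table.oligotype_ids[~hit]), int(removed), float(removed_abundance)


def prevalence_filter(
    table: OligotypeTable,
    min_prevalence: float = 0.10,
    presence_threshold: int = 1,
) -> OligotypeTable:
    """Keep oligotypes present (count >= threshold) in >= ``min_prevalence`` of samples."""
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    present = (table.counts >= presence_threshold).mean(axis=0)
    keep = present >= min_prevalence
    return table.subset_oligotypes(table.oligotype_ids[keep])


def intersect_years(
    table_a: OligotypeTable, table_b: OligotypeTable
) -> tuple[OligotypeTable, OligotypeTable]:
    """Restrict both tables to oligotypes observed (count > 0) in both years."""
    if len(set(table_a.counts.index) & set(table_b.counts.index)):
        raise ValueError("year tables must have disjoint sample sets")
    seen_a = table_a.counts.columns[(table_a.counts > 0).any(axis=0)]
    seen_b = table_b.counts.columns[(table_b.counts > 0).any(axis=0)]
    shared = [c for c in table_a.counts.columns if c in set(seen_a) & set(seen_b)]
    if not shared:
        raise ValueError("no oligotype present in both years")
    return table_a.subset_oligotypes(shared), table_b.subset_oligotypes(shared)


@dataclass
class PrevalenceReport:
    """Per-oligotype prevalence under a high count threshold.

    ``table`` has one row per oligotype with columns ``max_rel_abundance``,
    ``prevalence`` (fraction of samples with count strictly above the
    threshold), ``cls`` in {broad, narrow, intermediate} and ``zero_flag``
    for oligotypes that never exceed the threshold (reported as
    intermediate: the narrow class is reserved for taxa that do bloom
    somewhere).
    """

    table: pd.DataFrame
    count_threshold: int
    broad_cut: float
    narrow_cut: float


def classify_prevalence(
    table: OligotypeTable,
    count_threshold: int = 500,
    broad_cut: float = 0.75,
    narrow_cut: float = 0.10,
) -> PrevalenceReport:
    """Broad (> broad_cut of samples) vs narrow (< narrow_cut) prevalence classes."""
    if not (0 < narrow_cut < broad_cut < 1):
        raise ValueError("need 0 < narrow_cut < broad_cut < 1")
    prev = (table.counts > count_threshold).mean(axis=0)
    max_rel = table.proportions().max(axis=0)
    cls = np.where(
        prev > broad_cut, "broad", np.where((prev > 0) & (prev < narrow_cut), "narrow", "intermediate")
    )
    rep = pd.DataFrame(
        {
            "max_rel_abundance": max_rel,
            "prevalence": prev,
            "cls": cls,
            "zero_flag": prev == 0,
        }
    )
    return PrevalenceReport(
        table=rep, count_threshold=count_threshold, broad_cut=broad_cut, narrow_cut=narrow_cut
    )


def network_preprocess(
    table_a: OligotypeTable,
    table_b: OligotypeTable,
    taxa_patterns: tuple = ("chloroplast", "mitochondria", "no_relative"),
    min_prevalence: float = 0.10,
) -> tuple[OligotypeTable, OligotypeTable, dict]:
    """Three-step pre-network filtration with per-step accounting.

    Steps: (1) taxonomy removal, (2) low-prevalence removal within each
    year, (3) intersection of the two years.  Returns the filtered tables
    and a bookkeeping dict with oligotypes and abundance fractions removed
    at every step.
    """
    acc: dict = {}
    a1, n_a, f_a = remove_taxa(table_a, list(taxa_patterns))
    b1, n_b, f_b = remove_taxa(table_b, list(taxa_patterns))
    acc["taxa_removed"] = {"a": n_a, "b": n_b}
    acc["taxa_removed_abundance"] = {"a": f_a, "b": f_b}

    a2 = prevalence_filter(a1, min_prevalence=min_prevalence)
    b2 = prevalence_filter(b1, min_prevalence=min_prevalence)
    acc["low_prevalence_removed"] = {
        "a": a1.n_oligotypes - a2.n_oligotypes,
        "b": b1.n_oligotypes - b2.n_oligotypes,
    }

    a3, b3 = intersect_years(a2, b2)
    acc["single_year_removed"] = {
        "a": a2.n_oligotypes - a3.n_oligotypes,
        "b": b2.n_oligotypes - b3.n_oligotypes,
    }
    acc["retained"] = a3.n_oligotypes
    return a3, b3, acc
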