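"""Empirical Hill-number diversity and Pielou evenness.

Hill numbers express diversity as an effective number of equally abundant
species: q=0 is richness, q=1 the exponential of Shannon entropy, q=2 the
inverse Simpson concentration.  Pielou's J normalises Shannon entropy by
its maximum ln(S), so J = 1 means a perfectly even community.  Only the
plug-in (empirical) estimators are provided; no interpolation,
extrapolation or bootstrap intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import OligotypeTable


def _proportions(counts) -> np.ndarray:
    p = np.asarray(counts, dtype=float)
    if (p < 0).any():
        raise ValueError("counts must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("counts must have a positive sum")
    return p[p > 0] / total


def hill_number(counts, q: int) -> float:
    """Effective number of species of order q in {0, 1, 2}."""
    p = _proportions(counts)
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    if q == 2:
        return float(1.0 / (p**2).sum())
    raise ValueError("q must be 0, 1 or 2")


def pielou_J(counts, mode: str = "shannon_entropy") -> float:
    """Pielou's evenness J.

    ``shannon_entropy`` (default): J = H / ln(S) with H the Shannon entropy
    of the proportions — bounded in [0, 1].  ``paper_literal``: J = D1 /
    ln(S) with D1 the exponential Shannon diversity, the literal reading of
    some published formulations; it can exceed 1 and is provided for
    comparability only.  Natural logarithms throughout.
    """
    p = _proportions(counts)
    S = p.size
    if S < 2:
        raise ValueError("Pielou's J needs at least 2 species with positive counts")
    H = -(p * np.log(p)).sum()
    if mode == "shannon_entropy":
        return float(H / np.log(S))
    if mode == "paper_literal":
        return float(np.exp(H) / np.log(S))
    raise ValueError(f"unknown mode {mode!r}")


def diversity_profile(table: OligotypeTable, j_mode: str = "shannon_entropy") -> pd.DataFrame:
    """Per-sample richness, expShannon, invSimpson and Pielou J."""
    rows = {}
    for sid, row in table.counts.iterrows():
        c = row.to_numpy()
        rows[sid] = {
            "richness": hill_number(c, 0),
            "expShannon": hill_number(c, 1),
            "invSimpson": hill_number(c, 2),
            "pielou_J": pielou_J(c, mode=j_mode) if (c > 0).sum() >= 2 else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.counts.index]
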