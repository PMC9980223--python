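"""Polygenic index construction: greedy LD clumping and weighted scores.

A polygenic index (PGI) is the weighted sum of effect-allele dosages over a
panel of approximately independent trait-associated variants.  Variants are
selected from GWAS summary statistics by p-value thresholding plus greedy
LD clumping: walk the panel in ascending p-value order and keep a variant
only if no already-kept variant on the same chromosome lies within the
distance window and is in LD (r^2) above the threshold with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VariantPanel", "LdReference", "clump_variants", "build_pgi",
           "PANEL_COLUMNS"]

PANEL_COLUMNS = ["variant_id", "chromosome", "position", "effect_allele",
                 "other_allele", "weight", "p_value", "effect_allele_freq"]


class MissingLdError(KeyError):
    """r^2 unavailable for an in-window variant pair (never assumed zero)."""


def validate_panel(panel: pd.DataFrame, require: tuple[str, ...] = ()) -> pd.DataFrame:
    """Check a variant panel: required columns, unique ids, sane p-values."""
    missing = [c for c in ("variant_id",) + require if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns: {missing}")
    if panel["variant_id"].duplicated().any():
        dups = panel.loc[panel["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant ids: {dups[:5]}")
    if "p_value" in panel.columns:
        p = panel["p_value"].to_numpy(dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p_value must lie in (0, 1]")
    if {"effect_allele", "other_allele"} <= set(panel.columns):
        same = panel["effect_allele"].astype(str) == panel["other_allele"].astype(str)
        if same.any():
            raise ValueError("effect and other allele must differ")
    return panel


# Back-compat alias used by callers treating a panel as a type.
VariantPanel = pd.DataFrame


class LdReference:
    """Empirical pairwise-r^2 lookup computed from a reference dosage matrix.

    Parameters
    ----------
    dosages
        DataFrame, rows = reference samples, columns = variant ids.
    """

    def __init__(self, dosages: pd.DataFrame):
        self._ids = list(dosages.columns)
        x = dosages.to_numpy(dtype=float)
        sd = x.std(axis=0)
        if np.any(sd == 0):
            mono = [v for v, s in zip(self._ids, sd) if s == 0]
            raise ValueError(f"monomorphic reference variants: {mono[:5]}")
        with np.errstate(invalid="ignore"):
            self._r2 = np.corrcoef(x, rowvar=False) ** 2
        self._index = {v: i for i, v in enumerate(self._ids)}

    def r2(self, a: str, b: str) -> float:
        try:
            return float(self._r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise MissingLdError(
                f"no LD information for pair ({a}, {b})") from exc


def clump_variants(panel: pd.DataFrame, ld, p_threshold: float = 5e-8,
                   window_kb: float = 10_000, r2_threshold: float = 0.01
                   ) -> pd.DataFrame:
    """Greedy p-value-ordered LD clumping.

    Variants with p above ``p_threshold`` are discarded, the rest are
    visited in ascending p-value order (ties broken by chromosome,
    position, variant id), and a variant is kept iff every already-kept
    variant on its chromosome within ``window_kb`` kilobases has
    r^2 < ``r2_threshold`` with it.

    ``ld`` must expose ``r2(id_a, id_b)`` and raise for unknown pairs; a
    missing r^2 for an in-window pair is an error, never treated as
    independence.  Output preserves the input columns, in the greedy
    acceptance order.
    """
    validate_panel(panel, require=("chromosome", "position", "p_value"))
    candidates = panel[panel["p_value"] <= p_threshold].copy()
    candidates = candidates.sort_values(
        ["p_value", "chromosome", "position", "variant_id"],
        kind="stable")
    kept: list[int] = []
    kept_by_chrom: dict[object, list[tuple[float, str]]] = {}
    window_bp = window_kb * 1000.0
    for row in candidates.itertuples():
        accept = True
        for pos, vid in kept_by_chrom.get(row.chromosome, ()):
            if abs(row.position - pos) <= window_bp:
                if ld.r2(row.variant_id, vid) >= r2_threshold:
                    accept = False
                    break
        if accept:
            kept.append(row.Index)
            kept_by_chrom.setdefault(row.chromosome, []).append(
                (row.position, row.variant_id))
    return candidates.loc[kept]


def build_pgi(dosages: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Weighted-dosage polygenic index for every sample.

    ``dosages`` has rows = samples, columns = variant ids, counted on the
    panel's effect allele (harmonize upstream).  Returns a DataFrame
    indexed by sample id with columns ``raw_score`` (sum_j w_j * dosage_ij)
    and ``standardized_score`` (z-scored within the supplied sample; this
    is how "per standard deviation of the index" effect sizes arise, so
    standardize mothers, fathers and children separately).
    """
    validate_panel(panel, require=("weight",))
    ids = panel["variant_id"].tolist()
    absent = [v for v in ids if v not in dosages.columns]
    if absent:
        raise KeyError(f"panel variants absent from dosages: {absent}")
    x = dosages[ids].to_numpy(dtype=float)
    w = panel["weight"].to_numpy(dtype=float)
    raw = x @ w
    sd = raw.std()
    std = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    if sd == 0 and len(raw) > 0:
        warnings.warn("polygenic index has zero variance; standardized "
                      "scores set to 0", stacklevel=2)
    return pd.DataFrame({"raw_score": raw, "standardized_score": std},
                        index=pd.Index(dosages.index, name="sample_id"))
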