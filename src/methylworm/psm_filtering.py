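"""Methyl-restricted target-decoy FDR, localization filtering, and
fraction-duplicate collapse.

The FDR estimate considers only PSMs bearing at least one methyl
modification: decoy and target methyl PSMs are ranked together by search
score and target PSMs are removed from the low-scoring end until the
decoy/target ratio among retained methyl PSMs reaches the 1% target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Mod


@dataclass
class FilterConfig:
    methyl_fdr_target: float = 0.01
    min_localization: float = 0.75

    def __post_init__(self):
        if not (0 < self.methyl_fdr_target < 1 and 0 < self.min_localization < 1):
            raise ValueError("FilterConfig fractions must lie in (0,1)")


def _has_methyl(mods) -> bool:
    return any(Mod(*m).is_methyl() if not isinstance(m, Mod) else m.is_methyl()
               for m in mods)


def compute_methyl_fdr_threshold(
    psms: pd.DataFrame, target_fdr: float = 0.01
) -> tuple:
    """Score cutoff at which the methyl-PSM decoy/target ratio <= target_fdr.

    Returns ``(cutoff, retained, achieved_fdr)`` where ``retained`` holds the
    target methyl PSMs scoring at or above the cutoff. The cutoff is the most
    permissive (lowest) score achieving the target; score ties are kept or
    dropped together. If no cutoff achieves the target the retained set is
    empty and a warning is issued.
    """
    methyl = psms[[_has_methyl(m) for m in psms["mods"]]]
    targets = methyl[~methyl["is_decoy"]]
    if targets.empty:
        raise ValueError("no target methyl PSMs in input")
    t_scores = np.sort(targets["score"].to_numpy())
    d_scores = np.sort(methyl.loc[methyl["is_decoy"], "score"].to_numpy())

    best_cutoff = None
    achieved = None
    # candidate cutoffs are the distinct target scores, scanned from the most
    # permissive upward; counts via sorted-array arithmetic
    for c in np.unique(t_scores):
        n_t = len(t_scores) - np.searchsorted(t_scores, c, side="left")
        n_d = len(d_scores) - np.searchsorted(d_scores, c, side="left")
        fdr = n_d / n_t
        if fdr <= target_fdr:
            best_cutoff = float(c)
            achieved = float(fdr)
            break
    if best_cutoff is None:
        warnings.warn("no score cutoff achieves the methyl FDR target; "
                      "retaining no methyl PSMs")
        return np.inf, targets.iloc[0:0], np.nan
    retained = targets[targets["score"] >= best_cutoff]
    return best_cutoff, retained, achieved


def filter_localization(psms: pd.DataFrame, min_localization: float = 0.75) -> pd.DataFrame:
    """Drop methyl modifications below the localization threshold.

    The comparison is inclusive (a probability of exactly 0.75 survives with
    the default). Non-methyl modifications are untouched. A PSM is retained
    only if at least one methyl modification survives.
    """
    new_mods, keep = [], []
    for mods in psms["mods"]:
        kept = tuple(
            m for m in mods
            if not m.is_methyl() or m.localization_prob >= min_localization
        )
        new_mods.append(kept)
        keep.append(_has_methyl(kept))
    out = psms.copy()
    out["mods"] = new_mods
    return out[np.asarray(keep)]


def mods_key(mods) -> str:
    """Canonical key for a full modification set (proteoform identity)."""
    return ";".join(f"{m.position}:{m.residue}:{m.form}"
                    for m in sorted(mods, key=lambda m: (m.position, m.form)))


def collapse_fractions(
    peptides: pd.DataFrame, abundance_columns: list | None = None
) -> pd.DataFrame:
    """One row per (sequence, modification set): keep the fraction whose
    summed abundance across samples is highest.

    ``peptides`` needs columns ``peptide``, ``mods`` (or ``mods_key``) and
    ``fraction`` plus abundance columns. Provenance is recorded in
    ``source_fraction``.
    """
    df = peptides.copy()
    if "mods_key" not in df.columns:
        df["mods_key"] = [mods_key(m) for m in df["mods"]]
    if abundance_columns is None:
        abundance_columns = [c for c in df.columns
                             if c == "abundance" or c.startswith("abundance_")]
    totals = df[abundance_columns].sum(axis=1, skipna=True)
    df = df.assign(_total=totals)
    idx = df.groupby(["peptide", "mods_key"], sort=False)["_total"].idxmax()
    out = df.loc[idx].drop(columns="_total")
    out = out.rename(columns={"fraction": "source_fraction"})
    return out.reset_index(drop=True)


def filter_psms(
    psms: pd.DataFrame, config: FilterConfig | None = None, per_fraction: bool = False
) -> dict:
    """Full filtering stage: methyl FDR then localization.

    With ``per_fraction=True`` the FDR threshold is computed within each SCX
    fraction separately; the default applies one global threshold.
    Returns a dict with the retained table and stage bookkeeping.
    """
    config = config or FilterConfig()
    if per_fraction:
        parts, cutoffs = [], {}
        for frac, grp in psms.groupby("fraction"):
            c, kept, _ = compute_methyl_fdr_threshold(grp, config.methyl_fdr_target)
            cutoffs[frac] = c
            parts.append(kept)
        retained = pd.concat(parts) if parts else psms.iloc[0:0]
        cutoff = cutoffs
        achieved = np.nan
    else:
        cutoff, retained, achieved = compute_methyl_fdr_threshold(
            psms, config.methyl_fdr_target
        )
    localized = filter_localization(retained, config.min_localization)
    return {
        "psms": localized,
        "score_cutoff": cutoff,
        "achieved_fdr": achieved,
        "n_input": len(psms),
        "n_after_fdr": len(retained),
        "n_after_localization": len(localized),
    }
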