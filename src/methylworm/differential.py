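"""Differential methyl-peptide statistics.

Methyl peptides with whole-cell-lysate protein data are tested with a
protein-adjusted contrast (the PTM fold change minus the protein fold
change, with variances added and a Satterthwaite df combining the two
comparisons); peptides without protein data fall back to a plain Welch
test. After an initial Benjamini-Hochberg pass, features with q >= 0.05 form
an empirical null of t-statistics against which all p-values are recomputed
(two-sided tail with add-one smoothing), followed by a final BH correction
and regulation calls at |log2FC| > 0.585 (1.5-fold) and q < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .summarization import bh_qvalues
from .types import AbundanceMatrix


@dataclass
class GroupStats:
    mean: float
    variance: float
    n: int

    @classmethod
    def from_values(cls, values) -> "GroupStats":
        x = np.asarray(values, dtype=float)
        return cls(float(x.mean()), float(x.var(ddof=1)), len(x))


@dataclass
class DifferentialThresholds:
    q_cut: float = 0.05
    lfc_cut: float = 0.585  # log2(1.5)
    lfc_cut_strong: float = 1.0

    def __post_init__(self):
        if min(self.q_cut, self.lfc_cut, self.lfc_cut_strong) <= 0:
            raise ValueError("thresholds must be positive")


def welch_test(g1: GroupStats, g2: GroupStats) -> tuple:
    """(t, df, two-sided p) for unequal-variance two-sample comparison."""
    if g1.n < 2 or g2.n < 2:
        raise ValueError("need n >= 2 per group")
    se2 = g1.variance / g1.n + g2.variance / g2.n
    diff = g1.mean - g2.mean
    if se2 == 0:
        if diff == 0:
            return 0.0, np.inf, 1.0
        return float(np.sign(diff) * np.inf), np.inf, 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / (
        (g1.variance / g1.n) ** 2 / (g1.n - 1)
        + (g2.variance / g2.n) ** 2 / (g2.n - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def adjusted_ptm_test(
    ptm: tuple, prot: tuple
) -> tuple:
    """Protein-adjusted PTM contrast.

    ``ptm`` and ``prot`` are (GroupStats, GroupStats) pairs for the same two
    conditions. The adjusted effect is the PTM group difference minus the
    protein group difference; its squared standard error is the sum of the
    two comparisons' squared standard errors, and the df combines them by
    Satterthwaite. Returns (adjusted log2fc, t, df, two-sided p).
    """
    (p1, p2), (w1, w2) = ptm, prot
    d_ptm = p1.mean - p2.mean
    d_prot = w1.mean - w2.mean
    se2_ptm = p1.variance / p1.n + p2.variance / p2.n
    se2_prot = w1.variance / w1.n + w2.variance / w2.n
    _, df_ptm, _ = welch_test(p1, p2) if se2_ptm > 0 else (0, np.inf, 1)
    _, df_prot, _ = welch_test(w1, w2) if se2_prot > 0 else (0, np.inf, 1)
    delta = d_ptm - d_prot
    se2 = se2_ptm + se2_prot
    if se2 == 0:
        t = 0.0 if delta == 0 else float(np.sign(delta) * np.inf)
        return float(delta), t, np.inf, (1.0 if delta == 0 else 0.0)
    denom = 0.0
    if se2_ptm > 0 and np.isfinite(df_ptm):
        denom += se2_ptm**2 / df_ptm
    if se2_prot > 0 and np.isfinite(df_prot):
        denom += se2_prot**2 / df_prot
    df = se2**2 / denom if denom > 0 else np.inf
    t = delta / np.sqrt(se2)
    p = 2 * stats.t.sf(abs(t), df) if np.isfinite(df) else 2 * stats.norm.sf(abs(t))
    return float(delta), float(t), float(df), float(p)


def empirical_null_recalibrate(
    t_stats, initial_p, q_threshold: float = 0.05, min_null: int = 20
) -> np.ndarray:
    """Recompute p-values against an empirical null of non-significant t's.

    Features with BH(initial_p) >= q_threshold form the null set N; each
    feature's new p is (1 + #{t in N : |t| >= |t_i|}) / (1 + |N|). If fewer
    than ``min_null`` features enter the null, recalibration is skipped with
    a warning and the initial p-values are returned.
    """
    t = np.asarray(t_stats, dtype=float)
    p0 = np.asarray(initial_p, dtype=float)
    q0 = bh_qvalues(p0)
    null_t = np.abs(t[q0 >= q_threshold])
    if null_t.size == 0:
        raise ValueError("empty empirical null set")
    if null_t.size < min_null:
        warnings.warn(f"only {null_t.size} features in the empirical null; "
                      "skipping recalibration")
        return p0
    null_sorted = np.sort(null_t)
    n_ge = null_sorted.size - np.searchsorted(null_sorted, np.abs(t), side="left")
    return (1 + n_ge) / (1 + null_sorted.size)


def differential_call(
    log2fc: float, q: float, thresholds: DifferentialThresholds | None = None
) -> str:
    """'up' / 'down' / 'ns' with strict inequalities at both thresholds."""
    th = thresholds or DifferentialThresholds()
    if q < th.q_cut and log2fc > th.lfc_cut:
        return "up"
    if q < th.q_cut and log2fc < -th.lfc_cut:
        return "down"
    return "ns"


def run_differential(
    ptm_matrix: AbundanceMatrix,
    contrast: tuple,
    protein_matrix: AbundanceMatrix | None = None,
    protein_of: pd.Series | None = None,
    thresholds: DifferentialThresholds | None = None,
    recalibrate: bool = True,
) -> pd.DataFrame:
    """Per-feature differential table for one contrast (g1 vs g2).

    Features whose master protein is present in ``protein_matrix`` get the
    protein-adjusted test; the rest get the Welch test. Then empirical-null
    recalibration, BH, and regulation calls.
    """
    th = thresholds or DifferentialThresholds()
    g1, g2 = contrast
    s1 = ptm_matrix.samples_for(g1)
    s2 = ptm_matrix.samples_for(g2)
    rows = []
    for f in ptm_matrix.values.index:
        x1 = GroupStats.from_values(ptm_matrix.values.loc[f, s1])
        x2 = GroupStats.from_values(ptm_matrix.values.loc[f, s2])
        prot = protein_of.get(f) if protein_of is not None else None
        if (
            protein_matrix is not None
            and prot is not None
            and prot in protein_matrix.values.index
        ):
            ps1 = protein_matrix.samples_for(g1)
            ps2 = protein_matrix.samples_for(g2)
            w1 = GroupStats.from_values(protein_matrix.values.loc[prot, ps1])
            w2 = GroupStats.from_values(protein_matrix.values.loc[prot, ps2])
            lfc, t, df, p = adjusted_ptm_test((x1, x2), (w1, w2))
            adjusted = True
        else:
            t, df, p = welch_test(x1, x2)
            lfc = x1.mean - x2.mean
            adjusted = False
        rows.append({"feature": f, "log2fc": lfc, "t": t, "df": df, "p": p,
                     "adjusted_for_protein": adjusted})
    out = pd.DataFrame(rows).set_index("feature")
    p_final = out["p"].to_numpy()
    if recalibrate:
        p_final = empirical_null_recalibrate(out["t"].to_numpy(), p_final,
                                             th.q_cut)
    out["p_recalibrated"] = p_final
    out["q"] = bh_qvalues(p_final)
    out["call"] = [differential_call(l, q, th)
                   for l, q in zip(out["log2fc"], out["q"])]
    return out
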