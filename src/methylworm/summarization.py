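"""Covariation-weighted peptide-to-protein summarization and protein-level
two-group significance.

Peptides of one protein are combined by an iterative consensus: each peptide
row is centered, the consensus starts at the per-sample median, and peptides
are re-weighted by the square of their positive Pearson correlation with the
consensus until convergence. Uninformative peptides (weight below a
signal-to-noise floor) are excluded and the consensus refit, so co-varying
peptides dominate and noise peptides are ignored. Protein-level two-group
p-values follow the order-statistic (PECA) construction: the probability
under uniformity that the median of n peptide p-values is as small as
observed, Beta(k, n-k+1) with k the median rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AbundanceMatrix


@dataclass
class ProteinSummary:
    protein: str
    abundance: pd.Series  # per-sample log2
    weights: pd.Series  # per contributing peptide, in [0,1]
    n_peptides_used: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def summarize_protein(
    peptides: pd.DataFrame,
    protein: str = "",
    weight_floor: float = 0.01,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> ProteinSummary:
    """Consensus profile of one protein from its peptide rows (complete data).

    weight_i = max(0, r(peptide_i, consensus))^2; anti-correlated peptides
    get weight zero and cannot flip the consensus. Per-sample protein
    abundance = consensus + mean offset of the peptides used.
    """
    if peptides.empty:
        raise ValueError("no peptide rows")
    rows = peptides.to_numpy(dtype=float)
    offsets = rows.mean(axis=1)
    centered = rows - offsets[:, None]

    if len(rows) == 1:
        return ProteinSummary(
            protein,
            pd.Series(rows[0], index=peptides.columns),
            pd.Series([1.0], index=peptides.index),
            1,
        )

    active = np.arange(len(rows))
    while True:
        consensus = np.median(centered[active], axis=0)
        w = np.zeros(len(active))
        for it in range(maxiter):
            w = np.array([max(0.0, _pearson(centered[i], consensus)) ** 2
                          for i in active])
            if w.sum() == 0:
                break
            new = (w[:, None] * centered[active]).sum(axis=0) / w.sum()
            if np.max(np.abs(new - consensus)) < tol:
                consensus = new
                break
            consensus = new
        if w.sum() == 0:
            # all peptides anti-correlated with any consensus: keep the single
            # peptide with the largest variance as the best representative
            warnings.warn(f"protein {protein}: mutually anti-correlated "
                          "peptides; using single best peptide")
            best = int(np.argmax(np.var(centered, axis=1)))
            weights = pd.Series(0.0, index=peptides.index)
            weights.iloc[best] = 1.0
            return ProteinSummary(
                protein, pd.Series(rows[best], index=peptides.columns), weights, 1
            )
        good = w >= weight_floor
        if good.all() or not good.any():
            break
        active = active[good]
    weights = pd.Series(0.0, index=peptides.index)
    weights.iloc[active] = w
    abundance = consensus + offsets[active].mean()
    return ProteinSummary(
        protein, pd.Series(abundance, index=peptides.columns), weights, len(active)
    )


def summarize_proteins(
    matrix: AbundanceMatrix, protein_of: pd.Series
) -> tuple:
    """Roll a complete peptide matrix up to proteins.

    ``protein_of`` maps peptide feature id -> protein id. Returns
    ``(protein AbundanceMatrix, weight report DataFrame)``.
    """
    rows, weight_rows = [], []
    for prot, feats in protein_of.groupby(protein_of):
        summ = summarize_protein(matrix.values.loc[feats.index], prot)
        rows.append(summ.abundance.rename(prot))
        for pep, w in summ.weights.items():
            weight_rows.append({"protein": prot, "peptide": pep, "weight": w,
                                "n_peptides_used": summ.n_peptides_used})
    values = pd.DataFrame(rows)
    return (
        AbundanceMatrix(values, matrix.design, "log2"),
        pd.DataFrame(weight_rows),
    )


def peca_pvalue(peptide_pvalues) -> float:
    """Order-statistic protein p from its peptides' two-group p-values.

    With n peptide p-values and the (lower) median at rank k = floor((n+1)/2),
    the protein p is BetaCDF(p_median; k, n-k+1) — the probability that the
    k-th of n uniform order statistics is at most the observed median.
    """
    p = np.sort(np.asarray(list(peptide_pvalues), dtype=float))
    if p.size == 0:
        raise ValueError("no peptide p-values")
    n = p.size
    k = (n + 1) // 2 if n % 2 else n // 2
    return float(stats.beta.cdf(p[k - 1], k, n - k + 1))


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def protein_differential(
    matrix: AbundanceMatrix,
    protein_of: pd.Series,
    contrast: tuple,
) -> pd.DataFrame:
    """Two-group protein significance: per-peptide Welch t-tests combined by
    the PECA order statistic, then BH q-values; the log2 fold change comes
    from the summarized per-sample protein profiles."""
    g1, g2 = contrast
    s1 = matrix.samples_for(g1)
    s2 = matrix.samples_for(g2)
    prot_mat, _ = summarize_proteins(matrix, protein_of)
    rows = []
    for prot, feats in protein_of.groupby(protein_of):
        sub = matrix.values.loc[feats.index]
        pvals = [
            stats.ttest_ind(sub.loc[f, s1], sub.loc[f, s2], equal_var=False).pvalue
            for f in sub.index
        ]
        pvals = [1.0 if not np.isfinite(p) else p for p in pvals]
        lfc = float(prot_mat.values.loc[prot, s1].mean()
                    - prot_mat.values.loc[prot, s2].mean())
        rows.append({"protein": prot, "log2fc": lfc, "n_peptides": len(pvals),
                     "p": peca_pvalue(pvals)})
    out = pd.DataFrame(rows).set_index("protein")
    out["q"] = bh_qvalues(out["p"])
    return out
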