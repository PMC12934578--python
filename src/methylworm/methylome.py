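"""Descriptive methylome statistics and motif analysis.

Counting follows proteoform semantics: a residue carrying two methyl forms
(say MMA and ADMA) contributes two unique sites, while per-protein residue
counts and methylation density count each residue once. Density is the
percentage of a protein's arginines (or lysines) that are methylated, with
the denominator taken over the full sequence regardless of MS coverage.
Motif analysis extracts ±7-residue windows around each methylated residue
and scores per-position residue enrichment against background frequencies
with binomial tail probabilities (the pLogo statistic).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

GAP = "-"  # terminal padding symbol, excluded from motif counts


def _unique_sites(sites: pd.DataFrame) -> pd.DataFrame:
    return sites.drop_duplicates(subset=["protein", "position", "form"])


def count_unique_sites(sites: pd.DataFrame) -> dict:
    """Counts per form, per residue class, and total (proteoform semantics)."""
    if sites.empty:
        return {"total": 0, "by_form": {}, "by_residue": {}}
    u = _unique_sites(sites)
    return {
        "total": len(u),
        "by_form": u["form"].value_counts().to_dict(),
        "by_residue": u["residue"].value_counts().to_dict(),
    }


def sites_per_protein(sites: pd.DataFrame) -> dict:
    """Per-protein methylated-residue counts (each residue counted once).

    Also partitions methylated proteins into lysine-only / arginine-only /
    both classes; the three partition sizes sum to the number of methylated
    proteins.
    """
    if sites.empty:
        return {"per_protein": pd.Series(dtype=int), "histogram": {},
                "partition": {"K-only": 0, "R-only": 0, "both": 0}}
    residues = sites.drop_duplicates(subset=["protein", "position"])
    per_protein = residues.groupby("protein").size()
    classes = sites.groupby("protein")["residue"].agg(lambda r: frozenset(r))
    partition = {
        "K-only": int(sum(c == {"K"} for c in classes)),
        "R-only": int(sum(c == {"R"} for c in classes)),
        "both": int(sum(c == {"K", "R"} for c in classes)),
    }
    return {
        "per_protein": per_protein,
        "histogram": per_protein.value_counts().sort_index().to_dict(),
        "partition": partition,
    }


def methylation_density(
    sequence: str, sites: pd.DataFrame, residue_class: str
) -> float | None:
    """Percent of a protein's residues of one class that are methylated.

    The denominator is every residue of the class in the full sequence. A
    protein with zero residues of the class is excluded (returns None with a
    warning). Duplicate site rows do not inflate the numerator.
    """
    total = sequence.count(residue_class)
    if total == 0:
        warnings.warn(f"no {residue_class} residues in sequence; density undefined")
        return None
    sub = sites[sites["residue"] == residue_class]
    n_methylated = sub.drop_duplicates(subset=["protein", "position"]).shape[0]
    return 100.0 * n_methylated / total


def density_table(proteome: dict, sites: pd.DataFrame, residue_class: str) -> pd.Series:
    """Density per methylated protein (proteins lacking the residue class or
    any site of that class are excluded)."""
    out = {}
    for prot, grp in sites[sites["residue"] == residue_class].groupby("protein"):
        if prot not in proteome:
            continue
        d = methylation_density(proteome[prot], grp, residue_class)
        if d is not None:
            out[prot] = d
    return pd.Series(out, dtype=float)


def extract_windows(
    sites: pd.DataFrame, proteome: dict, flank: int = 7
) -> list:
    """±flank windows centered on each methylated residue, gap-padded at the
    protein termini so every window has length 2*flank + 1."""
    windows = []
    for _, s in _unique_sites(sites).iterrows():
        seq = proteome[s["protein"]]
        pos = int(s["position"])  # 1-based
        left = seq[max(0, pos - 1 - flank) : pos - 1]
        right = seq[pos : pos + flank]
        win = GAP * (flank - len(left)) + left + seq[pos - 1] + right + GAP * (flank - len(right))
        windows.append(win)
    return windows


def background_frequencies(proteome: dict) -> dict:
    """Position-independent residue frequencies over the whole proteome."""
    counts: dict = {}
    total = 0
    for seq in proteome.values():
        for a in seq:
            counts[a] = counts.get(a, 0) + 1
            total += 1
    return {a: c / total for a, c in counts.items()}


def plogo_scores(
    windows: list, background: dict, flank: int = 7
) -> pd.DataFrame:
    """Signed binomial log-probability scores per position and residue.

    For residue r at flank position j, with k occurrences among the n
    non-gap characters at that position and background probability p:
    score = -log10 P(X >= k) when k/n > p (overrepresentation, positive),
    score = log10 P(X <= k) when k/n < p (depletion, negative), and 0 when
    k/n = p, with X ~ Binomial(n, p). Gap characters from terminal padding
    are excluded from n. Degenerate backgrounds: p = 0 scores +inf when the
    residue occurs (0 otherwise); p = 1 scores -inf when it is ever absent.
    """
    if not windows:
        raise ValueError("no foreground windows")
    width = 2 * flank + 1
    if any(len(w) != width for w in windows):
        raise ValueError(f"all windows must have length {width}")
    positions = list(range(-flank, flank + 1))
    residues = sorted(set(background))
    scores = pd.DataFrame(0.0, index=positions, columns=residues)
    cols = np.array([list(w) for w in windows])
    for j, pos in enumerate(positions):
        col = cols[:, j]
        col = col[col != GAP]
        n = len(col)
        if n == 0:
            continue
        for r in residues:
            k = int(np.sum(col == r))
            p = background[r]
            frac = k / n
            if p <= 0:
                scores.loc[pos, r] = np.inf if k > 0 else 0.0
                continue
            if p >= 1:
                scores.loc[pos, r] = -np.inf if k < n else 0.0
                continue
            if frac > p:
                tail = stats.binom.sf(k - 1, n, p)  # P(X >= k)
                scores.loc[pos, r] = -np.log10(max(tail, 1e-300))
            elif frac < p:
                tail = stats.binom.cdf(k, n, p)  # P(X <= k)
                scores.loc[pos, r] = np.log10(max(tail, 1e-300))
    return scores


def summarize_methylome(sites: pd.DataFrame, proteome: dict, flank: int = 7) -> dict:
    """Site counts, per-protein statistics, densities, and motif scores.

    Dimethyl-arginine without neutral-loss confirmation is tabulated as
    'DMA (unresolved)' so confirmed ADMA/SDMA remain separate evidence-based
    classes.
    """
    tab = sites.copy()
    if "evidence" in tab.columns:
        unresolved = (tab["form"] == "DMA") & (tab["evidence"] != "neutral-loss-confirmed")
        tab.loc[unresolved, "form"] = "DMA (unresolved)"
    counts = count_unique_sites(tab)
    per_prot = sites_per_protein(tab)
    bg = background_frequencies(proteome)
    out = {"counts": counts, "per_protein": per_prot}
    for cls in ("R", "K"):
        sub = tab[tab["residue"] == cls]
        out[f"density_{cls}"] = density_table(proteome, sub, cls)
        if len(sub):
            wins = extract_windows(sub, proteome, flank)
            out[f"motif_{cls}"] = plogo_scores(wins, bg, flank)
    return out
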