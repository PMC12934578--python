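"""Synthetic study generator.

Emulates every input the pipeline consumes — a proteome, tryptic digests, a
methylome with RG/RGG-biased arginine sites, PSM tables with overlapping
target/decoy score distributions, annotated MS/MS spectra carrying
form-specific neutral-loss peaks, and genotype-structured abundance matrices
with intensity-dependent (MNAR) and random (MAR) missingness — together with
the ground truth needed to score every downstream stage.

The defaults mirror the study conditions: a 3-genotype x 3-replicate design
(wild type plus Type I and Type II methyltransferase knockouts), lysine
methylation more prevalent than arginine (74% of sites), trimethyl-lysine the
dominant lysine form, dimethyl > monomethyl among arginine, ADMA >> SDMA, a
0.02 Da per-measurement mass error, and knockout-1 ablation effects drawn
from the -9..-5 log2 range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import (
    AMINO_ACIDS,
    FORM_DELTAS,
    FORM_LOSSES,
    GENOTYPES,
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
)
from .types import AbundanceMatrix, FragmentAnnotation, Mod, SpectrumRecord, make_design


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Knobs of the synthetic study. All randomness flows from `seed`."""

    n_proteins: int = 60
    protein_length_range: tuple = (120, 400)
    rgg_protein_fraction: float = 0.4  # proteins carrying RGG repeat blocks
    rg_motif_bias: float = 0.7  # P(an R-methyl site sits in an RG context)
    n_sites: int = 180  # methylome of the scale the study quantified
    k_fraction: float = 0.74  # lysine share of methyl sites
    k_form_props: tuple = (0.107, 0.107, 0.786)  # mono/di/tri-K
    r_form_props: tuple = (0.256, 0.744)  # MMA / DMA among arginine sites
    adma_fraction_of_dma: float = 0.9  # true ADMA share among DMA sites
    n_substrate_sites: int = 36  # R sites ablated in knockout 1
    ablation_log2fc_range: tuple = (-9.0, -5.0)
    mass_sigma: float = 0.02  # Da, per measurement
    n_replicates: int = 3
    # PSM simulation
    psms_per_site: int = 3
    decoy_fraction: float = 0.3
    false_target_rate: float = 1.0  # false targets emitted per decoy
    target_score_mean: float = 3.0
    decoy_score_mean: float = 0.5
    score_sd: float = 1.0
    high_localization_fraction: float = 0.85
    # spectrum simulation
    nl_rel_intensity: float = 0.05  # NL companion intensity vs parent peak
    nl_weak_fraction: float = 0.0  # NL peaks deliberately below the 0.1% gate
    # abundance simulation
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    peptide_offset_sd: float = 1.0
    noise_sd: float = 0.3
    protein_effect_fraction: float = 0.3
    protein_effect_sd: float = 1.5
    mnar_quantile: float = 0.04  # censor values below this global quantile
    mar_rate: float = 0.04
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.protein_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid protein_length_range")
        if self.mass_sigma <= 0:
            raise ConfigurationError("mass_sigma must be > 0")
        if self.n_proteins < 0 or self.n_sites < 0 or self.n_substrate_sites < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for a named stage; reproducible per seed."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass
class GroundTruth:
    """Everything a test needs to score the pipeline without re-simulation."""

    sites: pd.DataFrame  # protein, residue, position, form, ko1_dependent, ablation_log2fc
    true_protein_effects: pd.DataFrame  # protein x genotype log2FC vs WT
    true_peptide_effects: pd.DataFrame = None  # feature x genotype log2FC vs WT
    missingness_labels: pd.DataFrame = None  # observed / MAR-censored / MNAR-censored
    true_values: pd.DataFrame = None  # pre-censoring log2 matrix


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

# Approximate background residue frequencies of a metazoan proteome; used for
# random sequence draws and as the default motif background.
_BG_FREQS = {
    "A": 0.065, "C": 0.020, "D": 0.053, "E": 0.065, "F": 0.046,
    "G": 0.054, "H": 0.023, "I": 0.061, "K": 0.064, "L": 0.086,
    "M": 0.026, "N": 0.049, "P": 0.049, "Q": 0.041, "R": 0.051,
    "S": 0.081, "T": 0.059, "V": 0.062, "W": 0.011, "Y": 0.032,
}


def generate_proteome(config: SimConfig) -> dict:
    """Random proteome; a configurable fraction of proteins carry RGG blocks.

    Returns an ordered mapping protein id -> amino-acid sequence.
    Deterministic for a fixed seed.
    """
    rng = config.rng(1)
    aas = np.array(list(_BG_FREQS))
    probs = np.array(list(_BG_FREQS.values()))
    probs = probs / probs.sum()
    lo, hi = config.protein_length_range
    proteome = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(aas, size=length, p=probs))
        if rng.random() < config.rgg_protein_fraction:
            # insert 2-4 RGG repeats at random (non-terminal) anchors
            for _ in range(int(rng.integers(2, 5))):
                pos = int(rng.integers(1, max(2, length - 4)))
                seq[pos : pos + 3] = list("RGG")
        proteome[f"P{i + 1:04d}"] = "".join(seq)[:length]
    return proteome


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def digest(
    sequence: str,
    max_missed: int = 4,
    length_range: tuple = (7, 50),
    trypsin_p: bool = False,
) -> list:
    """In-silico tryptic digest.

    Cleaves C-terminal to K or R; with the classic rule (default) cleavage is
    suppressed when the next residue is proline, with ``trypsin_p=True`` it is
    not. Emits all products with 0..max_missed missed cleavages that pass the
    length filter, each as a dict with 1-based ``start``/``end`` coordinates.
    """
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = length_range
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and (trypsin_p or sequence[i + 1] != "P"):
            cuts.append(i + 1)
    cuts.append(len(sequence))
    peptides = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(cuts))):
            start, end = cuts[a], cuts[b]
            if lo <= end - start <= hi:
                peptides.append(
                    {
                        "peptide": sequence[start:end],
                        "start": start + 1,
                        "end": end,
                        "missed_cleavages": b - a - 1,
                    }
                )
    return peptides


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def simulate_methylome(proteome: dict, config: SimConfig) -> GroundTruth:
    """Place methyl sites on the proteome with the configured form mixture.

    Arginine sites prefer RG contexts with probability ``rg_motif_bias``;
    ``n_substrate_sites`` of the arginine sites are flagged knockout-1
    dependent and given an ablation log2 fold change drawn from
    ``ablation_log2fc_range``.
    """
    if not proteome:
        raise ConfigurationError("empty proteome")
    rng = config.rng(2)

    k_pool, r_rg_pool, r_other_pool = [], [], []
    for pid, seq in proteome.items():
        for i, aa in enumerate(seq):
            if aa == "K":
                k_pool.append((pid, i + 1))
            elif aa == "R":
                if seq[i + 1 : i + 2] == "G":
                    r_rg_pool.append((pid, i + 1))
                else:
                    r_other_pool.append((pid, i + 1))

    n_k = int(round(config.n_sites * config.k_fraction))
    n_r = config.n_sites - n_k
    if n_k > len(k_pool) or n_r > len(r_rg_pool) + len(r_other_pool):
        raise ConfigurationError("requested more sites than available residues")

    def sample(pool, n):
        idx = rng.choice(len(pool), size=n, replace=False) if n else []
        return [pool[int(i)] for i in idx]

    k_sites = sample(k_pool, n_k)
    n_rg = min(int(rng.binomial(n_r, config.rg_motif_bias)), len(r_rg_pool))
    if n_r - n_rg > len(r_other_pool):
        n_rg = n_r - len(r_other_pool)
    r_sites = sample(r_rg_pool, n_rg) + sample(r_other_pool, n_r - n_rg)

    rows = []
    k_props = np.asarray(config.k_form_props) / np.sum(config.k_form_props)
    for pid, pos in k_sites:
        form = rng.choice(["mono-K", "di-K", "tri-K"], p=k_props)
        rows.append((pid, "K", pos, str(form)))
    r_props = np.asarray(config.r_form_props) / np.sum(config.r_form_props)
    for pid, pos in r_sites:
        if rng.choice(["MMA", "DMA"], p=r_props) == "MMA":
            form = "MMA"
        else:
            form = "ADMA" if rng.random() < config.adma_fraction_of_dma else "SDMA"
        rows.append((pid, "R", pos, form))

    sites = pd.DataFrame(rows, columns=["protein", "residue", "position", "form"])
    sites["site_id"] = [
        f"{p}_{r}{pos}_{f}" for p, r, pos, f in zip(
            sites.protein, sites.residue, sites.position, sites.form
        )
    ]
    sites["ko1_dependent"] = False
    sites["ablation_log2fc"] = 0.0

    r_idx = sites.index[sites.residue == "R"]
    n_dep = min(config.n_substrate_sites, len(r_idx))
    if n_dep:
        dep = rng.choice(r_idx, size=n_dep, replace=False)
        sites.loc[dep, "ko1_dependent"] = True
        lo, hi = config.ablation_log2fc_range
        sites.loc[dep, "ablation_log2fc"] = rng.uniform(lo, hi, size=n_dep)

    effects = pd.DataFrame(0.0, index=list(proteome), columns=list(GENOTYPES[1:]))
    return GroundTruth(sites=sites, true_protein_effects=effects)


# ---------------------------------------------------------------------------
# PSM table
# ---------------------------------------------------------------------------

def _peptide_for_site(proteome, pid, pos, max_missed=4, length_range=(7, 50)):
    """Shortest tryptic peptide of `pid` covering residue `pos`, or None."""
    best = None
    for pep in digest(proteome[pid], max_missed, length_range):
        if pep["start"] <= pos <= pep["end"]:
            if best is None or pep["end"] - pep["start"] < best["end"] - best["start"]:
                best = pep
    return best


def simulate_psm_table(
    sites: pd.DataFrame, proteome: dict, config: SimConfig
) -> pd.DataFrame:
    """Target + decoy PSM table over the simulated methylome.

    True-target scores ~ N(target_score_mean, score_sd), decoys ~
    N(decoy_score_mean, score_sd) with a tunable overlap; localization
    probabilities are a mixture straddling the 0.75 filter; SCX fractions
    E1-E3 are assigned with deliberate duplicates of some peptides across two
    fractions. Alongside each decoy a false-target PSM (an incorrect match
    carrying the target flag but scoring like a decoy — the population the
    decoys are meant to model) is emitted; the ground-truth column
    ``true_match`` distinguishes them so the realized false-discovery
    proportion can be recounted exactly.
    """
    rng = config.rng(3)
    fractions = ["E1", "E2", "E3"]
    rows = []
    psm_counter = 0

    def charge_for(pep):
        return int(np.clip(2 + pep.count("K") + pep.count("R") // 2, 2, 4))

    for _, site in sites.iterrows():
        pep = _peptide_for_site(proteome, site.protein, site.position)
        if pep is None:
            continue
        pep_pos = site.position - pep["start"] + 1
        mods = (Mod(pep_pos, site.residue, site.form, 1.0),)
        n_psm = max(1, int(rng.poisson(config.psms_per_site)))
        frac_main = fractions[int(rng.integers(0, 3))]
        duplicate_frac = (
            fractions[int(rng.integers(0, 3))] if rng.random() < 0.25 else None
        )
        for j in range(n_psm):
            psm_counter += 1
            if rng.random() < config.high_localization_fraction:
                loc = float(np.clip(rng.uniform(0.80, 1.0), 0, 1))
            else:
                loc = float(np.clip(rng.uniform(0.30, 0.749), 0, 1))
            mods_j = (mods[0]._replace(localization_prob=loc),)
            frac = frac_main
            if duplicate_frac is not None and duplicate_frac != frac_main and j == n_psm - 1:
                frac = duplicate_frac
            mass = peptide_mass(pep["peptide"], mods_j)
            z = charge_for(pep["peptide"])
            rows.append(
                {
                    "psm_id": f"PSM{psm_counter:06d}",
                    "peptide": pep["peptide"],
                    "master_protein": site.protein,
                    "mods": mods_j,
                    "score": float(rng.normal(config.target_score_mean, config.score_sd)),
                    "is_decoy": False,
                    "fraction": frac,
                    "sample": "pooled",
                    "precursor_mz": (mass + z * PROTON_MASS) / z,
                    "charge": z,
                    "abundance": float(rng.lognormal(14, 1)),
                    "site_id": site.site_id,
                    "pep_start": pep["start"],
                }
            )

    for r in rows:
        r["true_match"] = True
    n_targets = len(rows)
    n_decoys = int(round(n_targets * config.decoy_fraction / (1 - config.decoy_fraction)))
    pids = list(proteome)
    # decoys and, pairwise, false targets drawn from the same low-score
    # population (the incorrect matches the decoys model)
    n_false = int(round(n_decoys * config.false_target_rate))
    for kind, n_kind in (("decoy", n_decoys), ("false_target", n_false)):
        for _ in range(n_kind):
            psm_counter += 1
            pid = pids[int(rng.integers(0, len(pids)))]
            peps = digest(proteome[pid][::-1], 2, (7, 50))
            if not peps:
                continue
            pep = peps[int(rng.integers(0, len(peps)))]
            seq = pep["peptide"]
            kr = [i + 1 for i, a in enumerate(seq) if a in "KR"]
            if not kr:
                continue
            pos = kr[int(rng.integers(0, len(kr)))]
            res = seq[pos - 1]
            form = "MMA" if res == "R" else "mono-K"
            mods_j = (Mod(pos, res, form, float(rng.uniform(0.5, 1.0))),)
            mass = peptide_mass(seq, mods_j)
            z = charge_for(seq)
            rows.append(
                {
                    "psm_id": f"PSM{psm_counter:06d}",
                    "peptide": seq,
                    "master_protein": (f"DECOY_{pid}" if kind == "decoy" else pid),
                    "mods": mods_j,
                    "score": float(rng.normal(config.decoy_score_mean, config.score_sd)),
                    "is_decoy": kind == "decoy",
                    "fraction": fractions[int(rng.integers(0, 3))],
                    "sample": "pooled",
                    "precursor_mz": (mass + z * PROTON_MASS) / z,
                    "charge": z,
                    "abundance": float(rng.lognormal(13, 1)),
                    "site_id": "",
                    "pep_start": pep["start"],
                    "true_match": False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def peptide_mass(peptide: str, mods: tuple = ()) -> float:
    """Monoisotopic neutral mass of a (modified) peptide."""
    try:
        mass = sum(RESIDUE_MASSES[a] for a in peptide) + WATER_MASS
    except KeyError as e:  # pragma: no cover
        raise ValueError(f"unknown residue {e}") from None
    return mass + sum(FORM_DELTAS[m.form] for m in mods)


def simulate_spectrum(
    peptide: str,
    mods: tuple,
    charge: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    spectrum_id: str = "scan1",
    mass_sigma: float | None = None,
) -> SpectrumRecord:
    """Annotated b/y ladder with neutral-loss companion peaks.

    Every fragment containing a dimethyl-arginine site, and the precursor,
    gets a companion peak displaced by that site's form-specific loss mass
    (sites combined for the precursor when several are present), perturbed by
    Gaussian error with SD ``mass_sigma``. A configurable fraction of
    companions is emitted below the 0.1% relative-intensity gate as negative
    fixtures.
    """
    for m in mods:
        if m.form in ("MMA", "DMA", "ADMA", "SDMA") and peptide[m.position - 1] != "R":
            raise ValueError(f"arginine methyl form on {peptide[m.position - 1]}")
        if m.form in ("mono-K", "di-K", "tri-K") and peptide[m.position - 1] != "K":
            raise ValueError(f"lysine methyl form on {peptide[m.position - 1]}")
    if rng is None:
        rng = config.rng(4)
    sigma = config.mass_sigma if mass_sigma is None else mass_sigma
    L = len(peptide)
    dma_sites = [m for m in mods if m.form in FORM_LOSSES]

    # raw entries: [true_mz, peak_charge, intensity, annotation-or-None];
    # each peak receives its own independent mass error at the end, so the
    # parent-minus-loss difference carries the propagated sigma*sqrt(2).
    raw = []

    # fragment ladder, singly charged b/y ions
    prefix = np.cumsum([RESIDUE_MASSES[a] for a in peptide])
    mod_mass_at = np.zeros(L)
    for m in mods:
        mod_mass_at[m.position - 1] += FORM_DELTAS[m.form]
    mod_prefix = np.cumsum(mod_mass_at)
    for k in range(1, L):
        b_mass = prefix[k - 1] + mod_prefix[k - 1]
        y_mass = (prefix[-1] - prefix[k - 1]) + (mod_prefix[-1] - mod_prefix[k - 1]) + WATER_MASS
        raw.append([b_mass + PROTON_MASS, 1, float(rng.lognormal(10, 0.5)), ("b", k, (1, k))])
        raw.append([y_mass + PROTON_MASS, 1, float(rng.lognormal(10.5, 0.5)),
                    ("y", k, (L - k + 1, L))])

    M = peptide_mass(peptide, mods)
    precursor_mz = (M + charge * PROTON_MASS) / charge
    base_guess = max((r[2] for r in raw), default=1.0)

    def nl_intensity(parent_intensity):
        if config.nl_weak_fraction > 0 and rng.random() < config.nl_weak_fraction:
            return 0.0005 * base_guess
        return config.nl_rel_intensity * parent_intensity

    # companions: one per contained dimethyl site on each fragment, and the
    # combined loss (plus single-site losses when several) on the precursor
    for true_mz, z, inten0, ann in list(raw):
        _, _, span = ann
        for m in dma_sites:
            if span[0] <= m.position <= span[1]:
                raw.append([true_mz - FORM_LOSSES[m.form], 1, nl_intensity(inten0), None])
    if dma_sites:
        total_loss = sum(FORM_LOSSES[m.form] for m in dma_sites)
        prec_intensity = float(rng.lognormal(11, 0.5))
        raw.append([precursor_mz - total_loss / charge, charge,
                    nl_intensity(prec_intensity), None])
        if len(dma_sites) > 1:
            for m in dma_sites:
                raw.append([precursor_mz - FORM_LOSSES[m.form] / charge, charge,
                            nl_intensity(prec_intensity), None])

    # independent per-peak mass error; sigma is on the neutral-mass scale, so
    # an ion at charge z is perturbed by sigma/z in m/z
    if sigma > 0:
        mz_arr = np.array([r[0] + rng.normal(0, sigma / r[1]) for r in raw])
    else:
        mz_arr = np.array([r[0] for r in raw])
    int_arr = np.array([r[2] for r in raw])
    annotations = [
        FragmentAnnotation(i, r[3][0], r[3][1], 1, r[3][2])
        for i, r in enumerate(raw)
        if r[3] is not None
    ]
    # the recorded precursor m/z is itself a measurement with error
    precursor_obs = precursor_mz + (rng.normal(0, sigma / charge) if sigma > 0 else 0.0)
    return SpectrumRecord(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_obs,
        charge=charge,
        mz=mz_arr,
        intensity=int_arr,
        annotations=annotations,
        peptide=peptide,
        mods=tuple(mods),
    )


# ---------------------------------------------------------------------------
# Abundance matrices
# ---------------------------------------------------------------------------

def simulate_abundance(
    truth: GroundTruth, proteome: dict, config: SimConfig
) -> tuple:
    """Peptide and protein log2 abundance matrices under the genotype design.

    log2 abundance = protein baseline + genotype effect + peptide offset +
    N(0, noise_sd); knockout-1-dependent methyl peptides additionally receive
    their ablation shift in genotype KO1. Censoring: values below the global
    ``mnar_quantile`` quantile are removed (MNAR), then uniform random dropout
    at ``mar_rate`` (MAR). Every censored cell is labeled in the returned
    GroundTruth.

    Returns (peptide AbundanceMatrix, protein AbundanceMatrix, GroundTruth).
    """
    rng = config.rng(5)
    design = make_design(config.n_replicates)
    samples = list(design.index)
    genotype = design["genotype"]

    pids = list(proteome)
    baseline = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, len(pids)), index=pids
    )
    effects = pd.DataFrame(0.0, index=pids, columns=["KO1", "KO2"])
    affected = rng.random(len(pids)) < config.protein_effect_fraction
    for g in ("KO1", "KO2"):
        effects.loc[affected, g] = rng.normal(0, config.protein_effect_sd, affected.sum())

    # protein matrix
    prot_true = pd.DataFrame(index=pids, columns=samples, dtype=float)
    for s in samples:
        g = genotype[s]
        eff = effects[g] if g in effects.columns else 0.0
        prot_true[s] = baseline + eff + rng.normal(0, config.noise_sd, len(pids))

    # peptide matrix: one feature per methyl site
    sites = truth.sites
    feat_ids = list(sites.site_id)
    pep_offset = pd.Series(
        rng.normal(0, config.peptide_offset_sd, len(feat_ids)), index=feat_ids
    )
    pep_true = pd.DataFrame(index=feat_ids, columns=samples, dtype=float)
    site_protein = pd.Series(sites.protein.values, index=feat_ids)
    ablation = pd.Series(
        np.where(sites.ko1_dependent, sites.ablation_log2fc, 0.0), index=feat_ids
    )
    for s in samples:
        g = genotype[s]
        eff = effects[g].reindex(site_protein.values).to_numpy() if g in effects.columns else 0.0
        vals = baseline.reindex(site_protein.values).to_numpy() + eff + pep_offset.to_numpy()
        if g == "KO1":
            vals = vals + ablation.to_numpy()
        pep_true[s] = vals + rng.normal(0, config.noise_sd, len(feat_ids))

    def censor(true_df, rng):
        vals = true_df.to_numpy().copy()
        labels = np.full(vals.shape, "observed", dtype=object)
        thresh = np.nanquantile(vals, config.mnar_quantile)
        mnar = vals < thresh
        labels[mnar] = "MNAR-censored"
        mar = (rng.random(vals.shape) < config.mar_rate) & ~mnar
        labels[mar] = "MAR-censored"
        vals[mnar | mar] = np.nan
        return (
            pd.DataFrame(vals, index=true_df.index, columns=true_df.columns),
            pd.DataFrame(labels, index=true_df.index, columns=true_df.columns),
        )

    pep_obs, pep_labels = censor(pep_true, rng)
    prot_obs, _ = censor(prot_true, rng)

    pep_fx = pd.DataFrame(0.0, index=feat_ids, columns=["KO1", "KO2"])
    for g in ("KO1", "KO2"):
        pep_fx[g] = effects[g].reindex(site_protein.values).to_numpy()
    pep_fx["KO1"] += ablation

    out_truth = GroundTruth(
        sites=sites,
        true_protein_effects=effects,
        true_peptide_effects=pep_fx,
        missingness_labels=pep_labels,
        true_values=pep_true,
    )
    return (
        AbundanceMatrix(pep_obs, design),
        AbundanceMatrix(prot_obs, design),
        out_truth,
    )


def simulate_study(config: SimConfig | None = None) -> dict:
    """Run the full generator; returns all artifacts keyed by name."""
    config = config or SimConfig()
    proteome = generate_proteome(config)
    truth = simulate_methylome(proteome, config)
    psms = simulate_psm_table(truth.sites, proteome, config)
    peptide_matrix, protein_matrix, truth = simulate_abundance(truth, proteome, config)
    return {
        "config": config,
        "proteome": proteome,
        "truth": truth,
        "psms": psms,
        "peptide_matrix": peptide_matrix,
        "protein_matrix": protein_matrix,
    }
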