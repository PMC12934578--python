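"""Physical constants and modification chemistry shared across the pipeline.

All masses are monoisotopic and in daltons. The diagnostic neutral losses of
dimethylarginine are computed from atomic masses: asymmetric dimethylarginine
(ADMA) loses dimethylamine (C2H7N) and symmetric dimethylarginine (SDMA) loses
methylamine (CH5N) during collision-induced dissociation.
"""

from __future__ import annotations

# Atomic monoisotopic masses
MASS_H = 1.0078250319
MASS_C = 12.0
MASS_N = 14.0030740052
MASS_O = 15.9949146221
MASS_S = 31.97207069

PROTON_MASS = 1.007276
WATER_MASS = 2 * MASS_H + MASS_O  # 18.010565

# Neutral losses diagnostic for dimethylarginine forms
LOSS_DIMETHYLAMINE = 2 * MASS_C + 7 * MASS_H + MASS_N  # ADMA, 45.0578
LOSS_METHYLAMINE = MASS_C + 5 * MASS_H + MASS_N  # SDMA, 31.0422

# Modification mass deltas (added to the residue)
METHYL_DELTA = MASS_C + 2 * MASS_H  # 14.01565 per methyl group
DIMETHYL_DELTA = 2 * METHYL_DELTA
TRIMETHYL_DELTA = 3 * METHYL_DELTA
OXIDATION_DELTA = MASS_O
ACETYL_DELTA = 2 * MASS_C + 2 * MASS_H + MASS_O  # 42.010565
CARBAMIDOMETHYL_DELTA = 2 * MASS_C + 3 * MASS_H + MASS_N + MASS_O  # 57.021464

# Monoisotopic residue masses (peptide-bond residues, i.e. minus water)
RESIDUE_MASSES = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Methylation forms by residue class
R_METHYL_FORMS = ("MMA", "DMA", "ADMA", "SDMA")
K_METHYL_FORMS = ("mono-K", "di-K", "tri-K")
METHYL_FORMS = R_METHYL_FORMS + K_METHYL_FORMS

FORM_DELTAS = {
    "MMA": METHYL_DELTA,
    "DMA": DIMETHYL_DELTA,
    "ADMA": DIMETHYL_DELTA,
    "SDMA": DIMETHYL_DELTA,
    "mono-K": METHYL_DELTA,
    "di-K": DIMETHYL_DELTA,
    "tri-K": TRIMETHYL_DELTA,
    "oxidation": OXIDATION_DELTA,
    "acetyl": ACETYL_DELTA,
    "carbamidomethyl": CARBAMIDOMETHYL_DELTA,
}

# Neutral loss per dimethylarginine form
FORM_LOSSES = {"ADMA": LOSS_DIMETHYLAMINE, "SDMA": LOSS_METHYLAMINE}

# Study design labels: wild type and the two methyltransferase knockouts.
# KO1 models loss of the dominant Type I enzyme (MMA/ADMA writer), KO2 the
# Type II enzyme (MMA/SDMA writer).
GENOTYPES = ("WT", "KO1", "KO2")
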