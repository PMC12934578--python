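"""Core data containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .constants import GENOTYPES, METHYL_FORMS


class Mod(NamedTuple):
    """One modification on a peptide.

    position is a 1-based residue index into the peptide sequence.
    """

    position: int
    residue: str
    form: str
    localization_prob: float = 1.0

    def is_methyl(self) -> bool:
        return self.form in METHYL_FORMS


class FragmentAnnotation(NamedTuple):
    """Annotation tying a spectrum peak to a b/y fragment ion.

    span is a 1-based closed interval of peptide residues covered by the ion.
    """

    peak_index: int
    ion_type: str  # 'b' or 'y'
    ordinal: int
    charge: int
    span: tuple  # (start, end), 1-based closed


@dataclass
class SpectrumRecord:
    """One MS/MS scan: precursor, peak list, optional fragment annotations."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    annotations: list = field(default_factory=list)
    peptide: str | None = None
    mods: tuple = ()

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        if not np.all(order == np.arange(len(order))):
            remap = {int(old): int(new) for new, old in enumerate(order)}
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            self.annotations = [
                a._replace(peak_index=remap[a.peak_index]) for a in self.annotations
            ]

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self.intensity) else 0.0


@dataclass
class AbundanceMatrix:
    """Feature x sample abundance matrix with its experimental design.

    values: DataFrame indexed by feature id, columns are sample ids, NaN marks
    a missing measurement. design: DataFrame indexed by sample id with columns
    'genotype' and 'replicate'.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    scale: str = "log2"  # 'log2' or 'linear'

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        obs = self.values.to_numpy()
        if np.any(~np.isfinite(obs) & ~np.isnan(obs)):
            raise ValueError("observed values must be finite")

    @property
    def mask(self) -> pd.DataFrame:
        """True where the value is missing."""
        return self.values.isna()

    def samples_for(self, genotype: str) -> list:
        return list(self.design.index[self.design["genotype"] == genotype])

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.design.copy(), self.scale)


def make_design(n_replicates: int = 3, genotypes: Sequence[str] = GENOTYPES) -> pd.DataFrame:
    """Standard design: len(genotypes) groups x n_replicates samples."""
    rows = []
    for g in genotypes:
        for r in range(1, n_replicates + 1):
            rows.append({"sample": f"{g}_{r}", "genotype": g, "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


# Column schema for methyl site tables used throughout (one row per
# (protein, position, form) observation, possibly with duplicates).
SITE_COLUMNS = ["protein", "residue", "position", "form", "evidence"]
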