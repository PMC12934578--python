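"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython, MGF through pyteomics; tables are plain TSV.
Modification sets are serialized as ``pos:residue:form:prob`` triples joined
by ';' so PSM tables round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .types import AbundanceMatrix, FragmentAnnotation, Mod, SpectrumRecord


# --- FASTA -----------------------------------------------------------------

def write_fasta(proteome: dict, path):
    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


# --- MGF + annotations -----------------------------------------------------

def write_mgf(spectra: list, path, annotation_path=None):
    """Write spectra to MGF; TITLE carries the spectrum id. Fragment
    annotations, which MGF cannot hold, go to a sidecar TSV keyed by id."""
    entries = []
    for s in spectra:
        entries.append({
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.spectrum_id,
                "pepmass": s.precursor_mz,
                "charge": s.charge,
            },
        })
    _mgf.write(entries, str(path), file_mode="w")
    if annotation_path is not None:
        rows = []
        for s in spectra:
            for a in s.annotations:
                rows.append({
                    "spectrum_id": s.spectrum_id,
                    "peak_index": a.peak_index,
                    "ion_type": a.ion_type,
                    "ordinal": a.ordinal,
                    "charge": a.charge,
                    "span_start": a.span[0],
                    "span_end": a.span[1],
                })
        pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


def read_mgf(path, annotation_path=None) -> list:
    ann_by_id: dict = {}
    if annotation_path is not None and Path(annotation_path).exists():
        df = pd.read_csv(annotation_path, sep="\t")
        for sid, grp in df.groupby("spectrum_id"):
            ann_by_id[sid] = [
                FragmentAnnotation(int(r.peak_index), r.ion_type, int(r.ordinal),
                                   int(r.charge), (int(r.span_start), int(r.span_end)))
                for r in grp.itertuples()
            ]
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            sid = entry["params"]["title"]
            charge = int(entry["params"]["charge"][0])
            pepmass = entry["params"]["pepmass"]
            spectra.append(SpectrumRecord(
                spectrum_id=sid,
                precursor_mz=float(pepmass[0] if isinstance(pepmass, tuple) else pepmass),
                charge=charge,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                annotations=ann_by_id.get(sid, []),
            ))
    return spectra


# --- PSM / site tables -----------------------------------------------------

def encode_mods(mods) -> str:
    return ";".join(f"{m.position}:{m.residue}:{m.form}:{m.localization_prob:.6g}"
                    for m in mods)


def decode_mods(s) -> tuple:
    if not isinstance(s, str) or not s:
        return ()
    out = []
    for part in s.split(";"):
        pos, res, form, prob = part.split(":")
        out.append(Mod(int(pos), res, form, float(prob)))
    return tuple(out)


def write_psm_table(psms: pd.DataFrame, path):
    df = psms.copy()
    df["mods"] = [encode_mods(m) for m in df["mods"]]
    df.to_csv(path, sep="\t", index=False)


def read_psm_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     na_values=[""], dtype={"mods": str})
    df["mods"] = [decode_mods(m) for m in df["mods"].fillna("")]
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return df


# --- Abundance matrices ----------------------------------------------------

def write_matrix(matrix: AbundanceMatrix, values_path, design_path=None):
    matrix.values.to_csv(values_path, sep="\t", index_label="feature")
    if design_path is not None:
        matrix.design.to_csv(design_path, sep="\t", index_label="sample")


def read_matrix(values_path, design_path, scale="log2") -> AbundanceMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="feature")
    design = pd.read_csv(design_path, sep="\t", index_col="sample")
    return AbundanceMatrix(values, design, scale)


# --- Reports ---------------------------------------------------------------

def write_json(obj, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
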