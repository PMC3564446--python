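"""Readers and writers for the pipeline's plain-text formats.

Spectra come in as MGF (via pyteomics) or two-column TSV peak lists;
protein sets as FASTA (via Biopython); oxidation matrices, peptide specs,
metabolite series, and annotations as TSV; ground truth as JSON.  A small
curated reference dataset of 29 cysteine-peptide oxidation trajectories
from chronologically aging yeast (standard and caloric-restriction
conditions, with peroxide-sensitivity annotations) ships with the package.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .metabolites import MetaboliteSeries
from .quant import OxidationMatrix, PeptideSpec, Spectrum
from .synthetic import PeptideLibrary, SyntheticTruth

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_spectrum_tsv",
    "read_spectrum_tsv",
    "write_spectra_mgf",
    "read_spectra_mgf",
    "write_peptide_specs",
    "read_peptide_specs",
    "write_library_fasta",
    "read_fasta",
    "write_metabolites_tsv",
    "read_metabolites_tsv",
    "read_annotations_tsv",
    "write_truth_json",
    "read_truth_json",
    "load_reference_trajectories",
    "reference_annotations",
]


def _day_label(day: float) -> str:
    d = float(day)
    return f"D{int(d)}" if d.is_integer() else f"D{d}"


def _parse_day(label: str) -> float:
    return float(label.lstrip("sdn_").lstrip("D"))


def write_matrix_tsv(matrix: OxidationMatrix, path: str | Path) -> None:
    """Matrix TSV with columns peptide, D0.., sd_D0.., n_D0.. (percent units)."""
    days = matrix.days
    out = pd.DataFrame(index=matrix.mean.index)
    out.index.name = "peptide"
    for d in days:
        out[_day_label(d)] = matrix.mean[d]
    if matrix.sd is not None:
        for d in days:
            out[f"sd_{_day_label(d)}"] = matrix.sd[d]
    if matrix.n is not None:
        for d in days:
            out[f"n_{_day_label(d)}"] = matrix.n[d]
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_matrix_tsv(path: str | Path, condition: str) -> OxidationMatrix:
    raw = pd.read_csv(path, sep="\t", index_col="peptide")
    day_cols = [c for c in raw.columns if c.startswith("D")]
    days = [_parse_day(c) for c in day_cols]
    mean = raw[day_cols].astype(float)
    mean.columns = days
    sd = n = None
    sd_cols = [c for c in raw.columns if c.startswith("sd_")]
    if sd_cols:
        sd = raw[sd_cols].astype(float)
        sd.columns = [_parse_day(c) for c in sd_cols]
    n_cols = [c for c in raw.columns if c.startswith("n_")]
    if n_cols:
        n = raw[n_cols].fillna(0).astype(int)
        n.columns = [_parse_day(c) for c in n_cols]
    return OxidationMatrix(condition, mean, sd, n)


def write_spectrum_tsv(spectrum: Spectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# m/z\tintensity\n")
        for mz, inten in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{mz:.6f}\t{inten:.6g}\n")


def read_spectrum_tsv(path: str | Path) -> Spectrum:
    mzs, intens = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")
            mzs.append(float(a))
            intens.append(float(b))
    return Spectrum(mzs, intens)


def write_spectra_mgf(
    spectra: Mapping[str, Spectrum], path: str | Path, pepmass: Mapping[str, float] | None = None
) -> None:
    """Write spectra as MGF (BEGIN IONS blocks with TITLE/PEPMASS)."""
    entries = []
    for title, s in spectra.items():
        params = {"title": title}
        if pepmass and title in pepmass:
            params["pepmass"] = pepmass[title]
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_spectra_mgf(path: str | Path) -> dict[str, Spectrum]:
    out: dict[str, Spectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            title = entry["params"].get("title", f"spectrum{i}")
            out[title] = Spectrum(entry["m/z array"], entry["intensity array"])
    return out


_SPEC_COLS = ["peptide_id", "protein_id", "cys_positions", "n_cys", "reduced_mz", "charge"]


def write_peptide_specs(specs: Iterable[PeptideSpec], path: str | Path) -> None:
    rows = [
        {
            "peptide_id": s.peptide_id,
            "protein_id": s.protein_id,
            "cys_positions": ";".join(str(p) for p in s.cys_positions),
            "n_cys": s.n_cys,
            "reduced_mz": s.reduced_mz,
            "charge": s.charge,
        }
        for s in specs
    ]
    pd.DataFrame(rows, columns=_SPEC_COLS).to_csv(path, sep="\t", index=False)


def read_peptide_specs(path: str | Path) -> list[PeptideSpec]:
    raw = pd.read_csv(path, sep="\t")
    return [
        PeptideSpec(
            peptide_id=str(r.peptide_id),
            protein_id=str(r.protein_id),
            cys_positions=tuple(int(p) for p in str(r.cys_positions).split(";")),
            reduced_mz=float(r.reduced_mz),
            charge=int(r.charge),
        )
        for r in raw.itertuples()
    ]


def write_library_fasta(library: PeptideLibrary, path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(seq),
            id=pid,
            description=f"cys_pos={library.sites[pid]} label={library.labels[pid]}",
        )
        for pid, seq in library.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


_MET_COLS = ["day", "gsh_M", "gssg_M", "nadph", "nadp", "atp", "viability"]


def write_metabolites_tsv(series: MetaboliteSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "day": series.days,
            "gsh_M": series.gsh,
            "gssg_M": series.gssg,
            "nadph": series.nadph,
            "nadp": series.nadp,
            "atp": series.atp,
            "viability": series.viability,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_metabolites_tsv(path: str | Path, condition: str) -> MetaboliteSeries:
    raw = pd.read_csv(path, sep="\t")
    missing = set(_MET_COLS) - set(raw.columns)
    if missing:
        raise ValueError(f"metabolite TSV missing column(s): {sorted(missing)}")
    return MetaboliteSeries(
        condition=condition,
        days=raw["day"].to_numpy(float),
        gsh=raw["gsh_M"].to_numpy(float),
        gssg=raw["gssg_M"].to_numpy(float),
        nadph=raw["nadph"].to_numpy(float),
        nadp=raw["nadp"].to_numpy(float),
        atp=raw["atp"].to_numpy(float),
        viability=raw["viability"].to_numpy(float),
    )


def read_annotations_tsv(path: str | Path) -> dict[str, bool]:
    """peptide_id<TAB>peroxide_sensitive(0/1)."""
    raw = pd.read_csv(path, sep="\t")
    return {
        str(r.peptide_id): bool(int(r.peroxide_sensitive)) for r in raw.itertuples()
    }


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "labels": truth.label_of,
        "true_values": {p: list(v) for p, v in truth.true_values.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth_json(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        dict(payload["labels"]),
        {p: np.asarray(v, dtype=float) for p, v in payload["true_values"].items()},
    )


# --- bundled reference dataset ---------------------------------------------

_REFERENCE_FILE = "early_oxidation_trajectories.tsv"


def _reference_frame() -> pd.DataFrame:
    with resources.files("thiolox.data").joinpath(_REFERENCE_FILE).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="gene")


def load_reference_trajectories() -> tuple[OxidationMatrix, OxidationMatrix]:
    """The bundled 29-peptide oxidation dataset as (standard, CR) matrices.

    Rows without caloric-restriction measurements carry NaN trajectories in
    the CR matrix.  Values are mean % oxidation; no SD/replicate layers.
    """
    raw = _reference_frame()
    std_days = [0.0, 1.0, 2.0, 3.0, 4.0]
    cr_days = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0]
    std = raw[[f"std_D{int(d)}" for d in std_days]].astype(float)
    std.columns = std_days
    cr = raw[[f"cr_D{int(d)}" for d in cr_days]].astype(float)
    cr.columns = cr_days
    return (
        OxidationMatrix("standard", std),
        OxidationMatrix("caloric_restriction", cr),
    )


def reference_annotations() -> tuple[dict[str, bool], set[str]]:
    """(peroxide-sensitivity map, genes flagged as following the general pattern)."""
    raw = _reference_frame()
    peroxide = {g: bool(v) for g, v in raw["peroxide_sensitive"].items()}
    general = {g for g, v in raw["general_pattern"].items() if v}
    return peroxide, general
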