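"""Readers and writers for the pipeline's plain-text formats.

All tabular formats are UTF-8 with a header row; TSV for sequencing-derived
tables, CSV for wet-lab tables.  Readers validate the header against the
expected schema and raise :class:`SchemaError` naming the offending file,
column, or row.  Writers produce canonical column order and LF line endings
so that write-then-read is the identity and repeated runs are byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .biomarkers import EnzymePlate, GeoChipMatrix, PlfaProfile
from .community import OtuTable, ScgHits

__all__ = [
    "SchemaError",
    "read_otu_table",
    "read_copy_numbers",
    "read_scg_hits",
    "read_gc_reads",
    "read_fasta",
    "read_ribosomal_ids",
    "read_plfa_profiles",
    "read_fumigation",
    "read_enzyme_plate",
    "read_geochip",
    "write_table",
]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _read_delimited(path: str | Path, sep: str, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    bad = df[df[required].isna().any(axis=1)]
    if len(bad):
        # +2: header line and 1-based numbering
        raise SchemaError(
            f"{path}: row {bad.index[0] + 2} has missing values in required columns"
        )
    return df


def read_otu_table(table_path: str | Path, taxonomy_path: str | Path | None = None) -> OtuTable:
    """OTU count TSV (first column otu_id, one column per sample) + taxonomy TSV."""
    df = _read_delimited(table_path, "\t", ["otu_id"]).set_index("otu_id")
    if df.shape[1] == 0:
        raise SchemaError(f"{table_path}: no sample columns")
    taxonomy: dict[str, str] = {}
    if taxonomy_path is not None:
        tax = _read_delimited(taxonomy_path, "\t", ["otu_id", "taxonomy"])
        taxonomy = dict(zip(tax["otu_id"], tax["taxonomy"]))
    return OtuTable(counts=df, taxonomy=taxonomy)


def read_copy_numbers(path: str | Path) -> dict[str, float]:
    df = _read_delimited(path, "\t", ["taxon", "copies"])
    return dict(zip(df["taxon"], df["copies"].astype(float)))


def read_scg_hits(hits_path: str | Path, totals_path: str | Path) -> dict[str, ScgHits]:
    hits = _read_delimited(hits_path, "\t", ["sample", "gene", "length_bp", "aligned_bp"])
    totals = _read_delimited(totals_path, "\t", ["sample", "total_bp"])
    total_by_sample = dict(zip(totals["sample"], totals["total_bp"]))
    out: dict[str, ScgHits] = {}
    for sample, grp in hits.groupby("sample", sort=False):
        if sample not in total_by_sample:
            raise SchemaError(f"{totals_path}: no total_bp for sample {sample!r}")
        out[sample] = ScgHits(
            hits=grp[["gene", "length_bp", "aligned_bp"]].reset_index(drop=True),
            total_bp=float(total_by_sample[sample]),
        )
    return out


def read_gc_reads(path: str | Path) -> dict[str, np.ndarray]:
    df = _read_delimited(path, "\t", ["sample", "gc_fraction"])
    return {
        s: grp["gc_fraction"].to_numpy(dtype=float)
        for s, grp in df.groupby("sample", sort=False)
    }


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_ribosomal_ids(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_plfa_profiles(
    peaks_path: str | Path, meta_path: str | Path, internal_standard: str = "19:0"
) -> list[PlfaProfile]:
    peaks = _read_delimited(peaks_path, ",", ["sample", "marker", "peak_area"])
    meta = _read_delimited(
        meta_path, ",", ["sample", "internal_standard_amount_nmol", "dry_mass_g"]
    ).set_index("sample")
    profiles = []
    for sample, grp in peaks.groupby("sample", sort=False):
        areas = dict(zip(grp["marker"], grp["peak_area"].astype(float)))
        if internal_standard not in areas:
            raise SchemaError(
                f"{peaks_path}: sample {sample!r} lacks the {internal_standard} internal standard"
            )
        if sample not in meta.index:
            raise SchemaError(f"{meta_path}: no metadata row for sample {sample!r}")
        profiles.append(
            PlfaProfile(
                sample_id=str(sample),
                areas={m: a for m, a in areas.items() if m != internal_standard},
                internal_standard_area=areas[internal_standard],
                internal_standard_amount_nmol=float(
                    meta.loc[sample, "internal_standard_amount_nmol"]
                ),
                dry_mass_g=float(meta.loc[sample, "dry_mass_g"]),
            )
        )
    return profiles


def read_fumigation(path: str | Path) -> pd.DataFrame:
    return _read_delimited(path, ",", ["sample", "analyte", "fumigated", "nonfumigated"])


def read_enzyme_plate(
    standards_path: str | Path,
    wells_path: str | Path,
    **plate_kwargs,
) -> EnzymePlate:
    std = _read_delimited(standards_path, ",", ["concentration_uM", "fluorescence"])
    wells = _read_delimited(wells_path, ",", ["sample", "enzyme", "test", "control"])
    return EnzymePlate(
        standards=dict(zip(std["concentration_uM"].astype(float), std["fluorescence"].astype(float))),
        wells=wells,
        **plate_kwargs,
    )


def read_geochip(
    signal_path: str | Path,
    background_path: str | Path,
    snr_path: str | Path,
    groups_path: str | Path,
) -> GeoChipMatrix:
    def matrix(p: str | Path) -> pd.DataFrame:
        return _read_delimited(p, "\t", ["probe"]).set_index("probe")

    groups_df = _read_delimited(groups_path, "\t", ["sample", "group"])
    return GeoChipMatrix(
        signal=matrix(signal_path),
        background=matrix(background_path),
        snr=matrix(snr_path),
        groups=dict(zip(groups_df["sample"], groups_df["group"])),
    )


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t",
                index_label: str | None = None) -> Path:
    """Canonical table writer: LF endings, stable float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=index_label is not None,
              index_label=index_label, float_format="%.17g", lineterminator="\n")
    return path


def write_sidecar(path: str | Path, metadata: dict) -> Path:
    """JSON metadata sidecar (parameters, seed, package version) for an artifact."""
    from . import __version__

    sidecar = Path(str(path) + ".meta.json")
    payload = {"artifact": Path(path).name, "version": __version__, **metadata}
    with open(sidecar, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return sidecar
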