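"""File formats: FASTA, primer tables, band lists.

Conventions: FASTA wrapped at 60 columns with key=value metadata in the
header; tabular files are UTF-8, tab-delimited, header row, Unix newlines.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequences import DnaSequence, PrimerRecord

__all__ = [
    "FastaEntry",
    "read_fasta",
    "write_fasta",
    "read_primer_tsv",
    "default_primers",
    "read_bands_tsv",
    "write_bands_tsv",
]


@dataclass
class FastaEntry:
    name: str
    sequence: DnaSequence
    metadata: dict[str, str]

    @property
    def header(self) -> str:
        meta = " ".join(f"{k}={v}" for k, v in self.metadata.items())
        return f"{self.name} {meta}".strip()


def _parse_metadata(description: str, name: str) -> dict[str, str]:
    meta = {}
    for token in description.split()[1:] if description.startswith(name) else description.split():
        if "=" in token:
            k, _, v = token.partition("=")
            meta[k] = v
    return meta


def read_fasta(path) -> list[FastaEntry]:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = DnaSequence(str(rec.seq))
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec.id!r}: {exc}") from exc
        entries.append(FastaEntry(rec.id, seq, _parse_metadata(rec.description, rec.id)))
    if not entries:
        raise ValueError(f"{path}: no records")
    return entries


def write_fasta(entries: list[FastaEntry], path) -> None:
    records = [
        SeqRecord(Seq(str(e.sequence)), id=e.name, description=e.header[len(e.name):].strip())
        for e in entries
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # 60-column wrap


def read_primer_tsv(path=None) -> dict[str, PrimerRecord]:
    """Primer table: columns name, sequence (extra columns are carried along).

    Returns a dict keyed by primer name.  With no path, the packaged table
    of the six assay primers is loaded.
    """
    if path is None:
        with resources.files("rflpkit.data").joinpath("primers.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"name", "sequence"} - set(df.columns)
    if missing:
        raise ValueError(f"primer table missing columns: {sorted(missing)}")
    primers = {}
    for i, row in df.iterrows():
        try:
            primers[row["name"]] = PrimerRecord.from_sequence(row["name"], row["sequence"])
        except ValueError as exc:
            raise ValueError(f"primer table row {i + 2}: {exc}") from exc
    return primers


def default_primers() -> dict[str, PrimerRecord]:
    return read_primer_tsv()


def read_bands_tsv(path) -> dict[str, dict[str, list[float]]]:
    """Observed gel bands: columns sample, tube, band_bp -> sample -> tube -> sizes."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "tube", "band_bp"} - set(df.columns)
    if missing:
        raise ValueError(f"bands table missing columns: {sorted(missing)}")
    out: dict[str, dict[str, list[float]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample"]), {}).setdefault(str(row["tube"]), []).append(
            float(row["band_bp"])
        )
    return out


def write_bands_tsv(bands: dict[str, dict[str, list[float]]], path) -> None:
    rows = [
        {"sample": sample, "tube": tube, "band_bp": bp}
        for sample, tubes in bands.items()
        for tube, sizes in tubes.items()
        for bp in sizes
    ]
    pd.DataFrame(rows, columns=["sample", "tube", "band_bp"]).to_csv(
        path, sep="\t", index=False
    )


def atomic_write_text(path, text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)
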