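"""Readers and writers for labelled alignments, sample metadata, and assay tables.

The on-disk formats are deliberately plain: aligned FASTA (gap character
``-``) for sequence matrices, and tab-separated text with a header row for
metadata and assay results.  Two reference tables of previously genotyped
samples ship with the package under ``mtsnip/data`` and are loaded with
:func:`load_fixture_table`.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALIGNMENT_ALPHABET = frozenset("ACGT-N")
FRAGMENT_ALPHABET = frozenset("ACGTN")

#: strings that denote a missing value in metadata tables (en-dash matches
#: the typography of museum tables; a bare hyphen is accepted as well)
MISSING_MARKERS = frozenset({"", "-", "–", "—", "NA", "na", "n/a"})

#: symbol codes used by array-based routines throughout the package
SYMBOL_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
CODE_SYMBOLS = "ACGT-N"
GAP_CODE = SYMBOL_CODES["-"]
N_CODE = SYMBOL_CODES["N"]


class DataError(ValueError):
    """Raised for malformed input files or inconsistent datasets."""


@dataclass
class SampleRecord:
    """One row of a sample table (museum/field specimen metadata)."""

    sample_id: str
    species: str = ""
    tissue: str = ""
    source: str = ""
    locality_name: str = ""
    lat: Optional[float] = None
    lon: Optional[float] = None
    age_yrBP: Optional[float] = None
    haplotype_label: Optional[str] = None
    sex: Optional[str] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise DataError("sample_id must be non-empty")
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise DataError(f"latitude out of range for {self.sample_id!r}: {self.lat}")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise DataError(f"longitude out of range for {self.sample_id!r}: {self.lon}")
        if self.age_yrBP is not None and self.age_yrBP < 0:
            raise DataError(f"age_yrBP must be >= 0 for {self.sample_id!r}")


@dataclass
class SexAssayRecord:
    """Outcome of the three-step W / autosomal PCR sexing protocol."""

    sample_id: str
    w_assay: str = "not_done"
    autosomal_assay: str = "not_done"
    w_retest: str = "not_done"

    _DOMAIN = frozenset({"positive", "negative", "not_done"})

    def __post_init__(self) -> None:
        for name in ("w_assay", "autosomal_assay", "w_retest"):
            value = getattr(self, name)
            if value not in self._DOMAIN:
                raise DataError(
                    f"{name} for {self.sample_id!r} must be one of "
                    f"positive/negative/not_done, got {value!r}"
                )


@dataclass
class LabelledAlignment:
    """An equal-length sequence matrix tied to per-sample metadata.

    Columns are addressed 1-based inclusive throughout the package.  When a
    ``reference_id`` is set, alignment columns can additionally be reported
    in the ungapped coordinates of that row.
    """

    sequences: dict[str, str]
    metadata: list[SampleRecord]
    reference_id: Optional[str] = None
    _records_by_id: dict[str, SampleRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise DataError("alignment contains no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            by_len: dict[int, str] = {}
            for sid, seq in self.sequences.items():
                by_len.setdefault(len(seq), sid)
            detail = ", ".join(f"{sid!r} (len {n})" for n, sid in sorted(by_len.items()))
            raise DataError(f"ragged alignment: {detail}")
        for sid, seq in self.sequences.items():
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise DataError(
                    f"sequence {sid!r} contains symbols outside ACGT-N: {sorted(bad)}"
                )
        self._records_by_id = {r.sample_id: r for r in self.metadata}
        if len(self._records_by_id) != len(self.metadata):
            seen: set[str] = set()
            dupes = sorted(
                {r.sample_id for r in self.metadata if r.sample_id in seen or seen.add(r.sample_id)}
            )
            raise DataError(f"duplicate sample ids in metadata: {dupes}")
        orphans = sorted(set(self.sequences) - set(self._records_by_id))
        if orphans:
            raise DataError(f"sequence ids without metadata record: {orphans}")
        if self.reference_id is not None and self.reference_id not in self.sequences:
            raise DataError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def record(self, sample_id: str) -> SampleRecord:
        return self._records_by_id[sample_id]

    def to_codes(self, ids: Optional[Iterable[str]] = None) -> tuple[list[str], np.ndarray]:
        """Encode rows as a (n, L) uint8 matrix using :data:`SYMBOL_CODES`."""
        ids = list(ids) if ids is not None else self.ids
        table = np.full(128, 255, dtype=np.uint8)
        for sym, code in SYMBOL_CODES.items():
            table[ord(sym)] = code
        mat = np.empty((len(ids), self.length), dtype=np.uint8)
        for i, sid in enumerate(ids):
            mat[i] = table[np.frombuffer(self.sequences[sid].encode(), dtype=np.uint8)]
        return ids, mat

    def reference_positions(self) -> np.ndarray:
        """Map alignment columns to 1-based ungapped reference positions.

        Returns an int array of length L; gap columns of the reference row
        carry the position of the preceding reference base (0 before the
        first base).
        """
        if self.reference_id is None:
            raise DataError("alignment has no reference row")
        ref = self.sequences[self.reference_id]
        is_base = np.frombuffer(ref.encode(), dtype=np.uint8) != ord("-")
        return np.cumsum(is_base).astype(int)


def _parse_float(value: str, what: str, sample_id: str) -> Optional[float]:
    if value.strip() in MISSING_MARKERS:
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise DataError(f"bad {what} for {sample_id!r}: {value!r}") from exc


_CANONICAL_COLUMNS = {
    "sample_id": "sample_id",
    "sample id": "sample_id",
    "species": "species",
    "tissue": "tissue",
    "tissue type": "tissue",
    "source": "source",
    "locality_name": "locality_name",
    "location": "locality_name",
    "locality": "locality_name",
    "lat": "lat",
    "latitude": "lat",
    "lon": "lon",
    "longitude": "lon",
    "age_yrbp": "age_yrBP",
    "haplotype": "haplotype_label",
    "haplotype_label": "haplotype_label",
    "sex": "sex",
    "notes": "notes",
}


def read_metadata(path) -> list[SampleRecord]:
    """Read a sample-metadata TSV.  Unknown columns are folded into notes."""
    with open(path, encoding="utf-8", newline="") as handle:
        return _read_metadata_handle(handle, str(path))


def _read_metadata_handle(handle, label: str) -> list[SampleRecord]:
    reader = csv.reader(handle, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise DataError(f"{label}: empty metadata table") from None
    mapped = [_CANONICAL_COLUMNS.get(h.strip().lower()) for h in header]
    if "sample_id" not in mapped:
        raise DataError(f"{label}: metadata header lacks a sample_id column")
    records = []
    for row in reader:
        if not row or all(not c.strip() for c in row):
            continue
        values: dict[str, str] = {}
        extras: list[str] = []
        for col, raw, raw_name in zip(mapped, row, header):
            if col is None:
                if raw.strip() and raw.strip() not in MISSING_MARKERS:
                    extras.append(f"{raw_name.strip()}={raw.strip()}")
            else:
                values[col] = raw.strip()
        sid = values.get("sample_id", "")
        notes = values.get("notes", "")
        if notes in MISSING_MARKERS:
            notes = ""
        if extras:
            notes = "; ".join(filter(None, [notes, *extras]))

        def _text(col: str) -> str:
            v = values.get(col, "")
            return "" if v in MISSING_MARKERS else v

        hap = _text("haplotype_label") or None
        sex = _text("sex") or None
        records.append(
            SampleRecord(
                sample_id=sid,
                species=_text("species"),
                tissue=_text("tissue"),
                source=_text("source"),
                locality_name=_text("locality_name"),
                lat=_parse_float(values.get("lat", ""), "lat", sid),
                lon=_parse_float(values.get("lon", ""), "lon", sid),
                age_yrBP=_parse_float(values.get("age_yrBP", ""), "age_yrBP", sid),
                haplotype_label=hap,
                sex=sex,
                notes=notes,
            )
        )
    return records


def write_metadata(records: list[SampleRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["sample_id", "species", "tissue", "source", "locality_name",
             "lat", "lon", "age_yrBP", "haplotype", "sex", "notes"]
        )
        for r in records:
            writer.writerow(
                [
                    r.sample_id, r.species, r.tissue, r.source, r.locality_name,
                    "" if r.lat is None else repr(r.lat),
                    "" if r.lon is None else repr(r.lon),
                    "" if r.age_yrBP is None else repr(r.age_yrBP),
                    r.haplotype_label or "", r.sex or "", r.notes,
                ]
            )


def read_alignment(fasta_path, metadata_path, reference_id: Optional[str] = None) -> LabelledAlignment:
    """Read an aligned FASTA plus its metadata TSV into a LabelledAlignment.

    Ids are matched case-sensitively; a FASTA record missing from the
    metadata, a ragged alignment, or an out-of-alphabet symbol is a hard
    error.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in sequences:
            raise DataError(f"duplicate FASTA id {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise DataError(f"{fasta_path}: no FASTA records found")
    metadata = read_metadata(metadata_path)
    return LabelledAlignment(sequences=sequences, metadata=metadata, reference_id=reference_id)


def write_alignment(aln: LabelledAlignment, fasta_path, metadata_path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.sequences.items()]
    with open(fasta_path, "w", encoding="utf-8") as handle:
        SeqIO.write(records, handle, "fasta")
    write_metadata(aln.metadata, metadata_path)


def read_fragments(fasta_path) -> dict[str, str]:
    """Read short fragment sequences (alphabet ACGTN) keyed by record id."""
    frags: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - FRAGMENT_ALPHABET
        if bad:
            raise DataError(f"fragment {rec.id!r} contains symbols outside ACGTN: {sorted(bad)}")
        frags[rec.id] = seq
    return frags


def read_assay_table(path) -> list[SexAssayRecord]:
    """Read a TSV of sexing-assay outcomes (columns sample_id, w_assay,
    autosomal_assay, w_retest; missing cells mean not_done)."""
    records = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise DataError(f"{path}: assay table lacks a sample_id column")
        for row in reader:
            def _res(col: str) -> str:
                v = (row.get(col) or "").strip()
                return "not_done" if v in MISSING_MARKERS else v

            records.append(
                SexAssayRecord(
                    sample_id=row["sample_id"].strip(),
                    w_assay=_res("w_assay"),
                    autosomal_assay=_res("autosomal_assay"),
                    w_retest=_res("w_retest"),
                )
            )
    return records


def write_assay_table(records: list[SexAssayRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "w_assay", "autosomal_assay", "w_retest"])
        for r in records:
            writer.writerow([r.sample_id, r.w_assay, r.autosomal_assay, r.w_retest])


_FIXTURES = {"table1": "table1.tsv", "table2": "table2.tsv"}


def load_fixture_table(name: str) -> list[SampleRecord]:
    """Load one of the packaged sample tables (``"table1"`` or ``"table2"``)."""
    try:
        filename = _FIXTURES[name]
    except KeyError:
        raise DataError(f"unknown fixture table {name!r}; expected one of {sorted(_FIXTURES)}") from None
    text = resources.files("mtsnip.data").joinpath(filename).read_text(encoding="utf-8")
    records = _read_metadata_handle(_io.StringIO(text), f"fixture:{name}")
    if name == "table2":
        # all rows of this table are swamp bone fragments from one site
        records = [
            replace(r, tissue="bone", source="swamp", locality_name="Tiniroto")
            for r in records
        ]
    return records
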