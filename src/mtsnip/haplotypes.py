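"""Haplotype catalogues, fragment typing, locality grouping, diversity ratios.

Catalogues are kept per species: labels look like ``D3`` (species prefix +
integer) and the same window string under two species keeps both labels.
Sampling localities closer than a threshold (default 25 km, strict) are
merged by single linkage into one locality group before diversity ratios
are computed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

from .io import DataError, SampleRecord

__all__ = [
    "HaplotypeCatalog",
    "LocalityGrouping",
    "Occurrence",
    "AmbiguousHaplotypeError",
    "assign_haplotype",
    "group_localities",
    "diversity_ratio",
    "tiniroto_summary",
    "haversine_km",
    "catalog_from_records",
]

EARTH_RADIUS_KM = 6371.0088


class AmbiguousHaplotypeError(ValueError):
    """An N-bearing fragment matches more than one catalogued haplotype."""

    def __init__(self, fragment: str, candidates: list[str]):
        self.candidates = sorted(candidates)
        super().__init__(
            f"fragment {fragment!r} matches multiple haplotypes: {', '.join(self.candidates)}"
        )


class Occurrence(NamedTuple):
    sample_id: str
    haplotype_label: str
    locality: str  # locality name (or group id once grouped)


@dataclass
class HaplotypeCatalog:
    """Label -> window sequence mapping for one species, plus occurrences."""

    species: str
    prefix: str
    entries: dict[str, Optional[str]] = field(default_factory=dict)
    occurrences: list[Occurrence] = field(default_factory=list)

    def __post_init__(self) -> None:
        seqs = [s for s in self.entries.values() if s is not None]
        if len(seqs) != len(set(seqs)):
            raise DataError(f"duplicate window sequences in catalog for {self.species!r}")

    def next_label(self) -> str:
        used = set()
        for label in self.entries:
            if label.startswith(self.prefix) and label[len(self.prefix):].isdigit():
                used.add(int(label[len(self.prefix):]))
        n = 1
        while n in used:
            n += 1
        return f"{self.prefix}{n}"

    def add_occurrence(self, sample_id: str, label: str, locality: str = "") -> None:
        if label not in self.entries:
            raise DataError(f"unknown haplotype label {label!r} for species {self.species!r}")
        self.occurrences.append(Occurrence(sample_id, label, locality))

    def frequencies(self) -> dict[str, int]:
        freq: dict[str, int] = {}
        for occ in self.occurrences:
            freq[occ.haplotype_label] = freq.get(occ.haplotype_label, 0) + 1
        return freq


def species_prefix(species: str) -> str:
    """Default label prefix: initials of the binomial (``D. robustus`` -> ``Dr``)."""
    parts = [p for p in species.replace(".", " ").split() if p]
    if not parts:
        return "H"
    if len(parts) == 1:
        return parts[0][0].upper()
    return parts[0][0].upper() + parts[1][0].lower()


def _matches(fragment: str, entry: str) -> bool:
    return all(f == e or f == "N" or e == "N" for f, e in zip(fragment, entry))


def assign_haplotype(
    fragment_seq: str,
    catalog: HaplotypeCatalog,
    species: Optional[str] = None,
) -> str:
    """Type a fragment's window sequence against the catalogue.

    Exact match (N matches anything) returns the existing label; no match
    mints a new label from the species prefix; an N-induced multi-match
    raises :class:`AmbiguousHaplotypeError`.  The fragment must cover the
    full window.
    """
    if species is not None and species != catalog.species:
        raise DataError(
            f"catalog is for species {catalog.species!r}, fragment claims {species!r}"
        )
    fragment_seq = fragment_seq.upper()
    window_lens = {len(s) for s in catalog.entries.values() if s is not None}
    if len(window_lens) > 1:
        raise DataError("catalog window sequences have inconsistent lengths")
    if window_lens:
        (wlen,) = window_lens
        if len(fragment_seq) < wlen:
            raise DataError(
                f"fragment (length {len(fragment_seq)}) shorter than window (length {wlen})"
            )
        if len(fragment_seq) > wlen:
            raise DataError(
                f"fragment (length {len(fragment_seq)}) longer than window (length {wlen}); "
                "pass the extracted window sequence"
            )
    hits = [
        label
        for label, seq in catalog.entries.items()
        if seq is not None and _matches(fragment_seq, seq)
    ]
    if len(hits) > 1:
        raise AmbiguousHaplotypeError(fragment_seq, hits)
    if hits:
        return hits[0]
    label = catalog.next_label()
    catalog.entries[label] = fragment_seq
    return label


# ---------------------------------------------------------------------------
# locality grouping


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


@dataclass
class LocalityGrouping:
    """Partition of locality names into groups of nearby sites."""

    groups: dict[str, set[str]]  # group id -> locality names
    threshold_km: float

    def __post_init__(self) -> None:
        self._assignment = {
            name: gid for gid, names in self.groups.items() for name in names
        }

    def group_of(self, locality_name: str) -> str:
        # an unseen locality is its own singleton group
        return self._assignment.get(locality_name, locality_name)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


class _DSU:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def group_localities(
    records: list[SampleRecord], threshold_km: float = 25.0
) -> LocalityGrouping:
    """Single-linkage grouping of localities under great-circle distance.

    Localities strictly closer than ``threshold_km`` are chained into one
    group; records without coordinates form singleton groups by exact name.
    """
    coords: dict[str, tuple[float, float]] = {}
    names: list[str] = []
    for rec in records:
        name = rec.locality_name or rec.sample_id
        if name not in coords:
            names.append(name)
            if rec.lat is not None and rec.lon is not None:
                coords[name] = (rec.lat, rec.lon)
            else:
                coords[name] = None  # type: ignore[assignment]
    dsu = _DSU(names)
    with_xy = [n for n in names if coords[n] is not None]
    for i, a in enumerate(with_xy):
        for b in with_xy[i + 1 :]:
            if haversine_km(*coords[a], *coords[b]) < threshold_km:
                dsu.union(a, b)
    clusters: dict[str, set[str]] = {}
    for name in names:
        clusters.setdefault(dsu.find(name), set()).add(name)
    groups = {}
    for members in clusters.values():
        gid = min(members)  # deterministic representative
        groups[gid] = members
    return LocalityGrouping(groups=groups, threshold_km=threshold_km)


def diversity_ratio(
    catalog: HaplotypeCatalog,
    grouping: Optional[LocalityGrouping] = None,
    species: Optional[str] = None,
) -> float:
    """Distinct haplotype labels divided by distinct occupied locality groups."""
    if species is not None and species != catalog.species:
        raise DataError(
            f"catalog is for species {catalog.species!r}, asked for {species!r}"
        )
    if not catalog.occurrences:
        raise DataError(f"no occurrences recorded for species {catalog.species!r}")
    labels = {occ.haplotype_label for occ in catalog.occurrences}
    if grouping is None:
        localities = {occ.locality for occ in catalog.occurrences}
    else:
        localities = {grouping.group_of(occ.locality) for occ in catalog.occurrences}
    if not localities:
        raise DataError("zero occupied localities")
    return len(labels) / len(localities)


def catalog_from_records(
    records: list[SampleRecord],
    species: str,
    window_seqs: Optional[dict[str, str]] = None,
) -> HaplotypeCatalog:
    """Build a catalogue from labelled sample records of one species.

    ``window_seqs`` optionally maps haplotype label -> window sequence; when
    absent the entries carry None and the catalogue supports counting but
    not fragment assignment.
    """
    catalog = HaplotypeCatalog(species=species, prefix=species_prefix(species))
    for rec in records:
        if rec.species != species or rec.haplotype_label is None:
            continue
        label = rec.haplotype_label
        if label not in catalog.entries:
            catalog.entries[label] = (window_seqs or {}).get(label)
        catalog.occurrences.append(
            Occurrence(rec.sample_id, label, rec.locality_name)
        )
    return catalog


def tiniroto_summary(records: list[SampleRecord]) -> dict:
    """Counts of samples, haplotypes, and species over a fragment table."""
    haplotypes = sorted({r.haplotype_label for r in records if r.haplotype_label})
    species = sorted({r.species for r in records if r.species})
    return {
        "n_samples": len(records),
        "n_haplotypes": len(haplotypes),
        "n_species": len(species),
        "haplotype_list": haplotypes,
    }


def write_catalog_tsv(catalogs: list[HaplotypeCatalog], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["label", "window_sequence", "species"])
        for cat in catalogs:
            for label, seq in sorted(cat.entries.items()):
                writer.writerow([label, seq or "", cat.species])


def read_catalog_tsv(path) -> list[HaplotypeCatalog]:
    by_species: dict[str, HaplotypeCatalog] = {}
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            sp = row["species"]
            cat = by_species.setdefault(
                sp, HaplotypeCatalog(species=sp, prefix=species_prefix(sp))
            )
            cat.entries[row["label"]] = row["window_sequence"] or None
    return list(by_species.values())
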