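"""Scan an alignment for short hyper-variable windows with conserved flanks.

A candidate window is scored by how many labelled group pairs it separates
(no window string shared between the two groups), how many distinct window
strings it resolves, and how conserved its primer-length flanks are.  The
composite score is ``discrimination * min(left, right flank conservation)``;
distinct-string count breaks ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from .io import GAP_CODE, N_CODE, LabelledAlignment

__all__ = [
    "SnippetCandidate",
    "window_discrimination",
    "flank_conservation",
    "scan_snippets",
    "write_candidates_tsv",
]


@dataclass
class SnippetCandidate:
    start_col: int  # 1-based inclusive alignment columns
    end_col: int
    window_len: int
    species_discrimination: float
    haplotype_count: int
    left_flank_conservation: float
    right_flank_conservation: float
    amplicon_len: int
    composite_score: float
    ref_start: Optional[int] = None
    ref_end: Optional[int] = None


def _group_labels(aln: LabelledAlignment, group_by: str) -> dict[str, str]:
    labels = {}
    for sid in aln.ids:
        rec = aln.record(sid)
        if not hasattr(rec, group_by):
            raise ValueError(f"metadata has no field {group_by!r}")
        labels[sid] = str(getattr(rec, group_by))
    return labels


def window_discrimination(
    aln: LabelledAlignment, start: int, end: int, group_by: str = "species"
) -> tuple[float, int]:
    """Fraction of group pairs separated by the window, plus distinct-string count.

    Two groups are separated iff no exact window string (gaps included)
    occurs in both.  Samples whose window is entirely gaps are excluded with
    a warning.
    """
    if not 1 <= start <= end <= aln.length:
        raise ValueError(f"window [{start}, {end}] outside alignment of length {aln.length}")
    labels = _group_labels(aln, group_by)
    if len(set(labels.values())) < 2:
        raise ValueError(f"group_by={group_by!r} yields fewer than 2 groups")
    strings_by_group: dict[str, set[str]] = {}
    distinct: set[str] = set()
    for sid in aln.ids:
        window = aln.sequences[sid][start - 1 : end]
        if set(window) == {"-"}:
            warnings.warn(f"sample {sid!r} has an all-gap window [{start}, {end}]; excluded")
            continue
        strings_by_group.setdefault(labels[sid], set()).add(window)
        distinct.add(window)
    groups = sorted(strings_by_group)
    pairs = list(combinations(groups, 2))
    if not pairs:
        return 0.0, len(distinct)
    separated = sum(
        1 for a, b in pairs if not (strings_by_group[a] & strings_by_group[b])
    )
    return separated / len(pairs), len(distinct)


def _column_conservation(mat: np.ndarray) -> np.ndarray:
    """Per-column frequency of the modal non-N symbol (gap is a symbol)."""
    n, L = mat.shape
    cons = np.empty(L, dtype=float)
    counts = np.zeros((6, L), dtype=np.int64)
    for code in range(6):
        counts[code] = (mat == code).sum(axis=0)
    non_n = counts[:5]
    denom = non_n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cons = np.where(denom > 0, non_n.max(axis=0) / np.maximum(denom, 1), 0.0)
    return cons


def flank_conservation(
    aln: LabelledAlignment, start: int, end: int, primer_len: int = 20
) -> tuple[float, float]:
    """Mean modal-symbol frequency over the two primer-length flanks.

    A flank truncated by the alignment edge is scored over the available
    columns and flagged with a warning.
    """
    if not 1 <= start <= end <= aln.length:
        raise ValueError(f"window [{start}, {end}] outside alignment of length {aln.length}")
    _, mat = aln.to_codes()
    cons = _column_conservation(mat)
    left_lo = start - 1 - primer_len
    if left_lo < 0:
        warnings.warn(f"left flank truncated by alignment edge (window start {start})")
        left_lo = 0
    right_hi = end + primer_len
    if right_hi > aln.length:
        warnings.warn(f"right flank truncated by alignment edge (window end {end})")
        right_hi = aln.length
    left_cols = cons[left_lo : start - 1]
    right_cols = cons[end:right_hi]
    left = float(left_cols.mean()) if left_cols.size else 0.0
    right = float(right_cols.mean()) if right_cols.size else 0.0
    return left, right


def scan_snippets(
    aln: LabelledAlignment,
    window_len: int = 30,
    primer_len: int = 20,
    max_amplicon: int = 70,
    group_by: str = "species",
    relax_amplicon: bool = False,
) -> list[SnippetCandidate]:
    """Score every admissible window and return candidates ranked best-first.

    Ranking: composite score descending, then distinct window strings
    descending, then leftmost start column.  Only windows whose full
    amplicon (window plus both primers) fits inside the alignment are
    scanned.
    """
    amplicon_len = window_len + 2 * primer_len
    if amplicon_len > max_amplicon and not relax_amplicon:
        raise ValueError(
            f"amplicon length {amplicon_len} exceeds max_amplicon={max_amplicon}; "
            "pass relax_amplicon=True to override"
        )
    if amplicon_len > aln.length:
        raise ValueError(
            f"alignment (length {aln.length}) is shorter than the amplicon ({amplicon_len})"
        )
    labels = _group_labels(aln, group_by)
    if len(set(labels.values())) < 2:
        raise ValueError(f"group_by={group_by!r} yields fewer than 2 groups")
    ids, mat = aln.to_codes()
    cons = _column_conservation(mat)
    cums = np.concatenate([[0.0], np.cumsum(cons)])
    group_of = np.array([labels[sid] for sid in ids])
    group_names = sorted(set(group_of))
    n_pairs = len(group_names) * (len(group_names) - 1) // 2
    ref_pos = aln.reference_positions() if aln.reference_id is not None else None

    candidates = []
    first_start = primer_len + 1
    last_start = aln.length - window_len - primer_len + 1
    for start in range(first_start, last_start + 1):
        end = start + window_len - 1
        window = mat[:, start - 1 : end]
        all_gap = (window == GAP_CODE).all(axis=1)
        if all_gap.any():
            for sid in np.array(ids)[all_gap]:
                warnings.warn(f"sample {sid!r} has an all-gap window [{start}, {end}]; excluded")
        keep = ~all_gap
        rows = window[keep]
        row_keys = [r.tobytes() for r in rows]
        distinct = len(set(row_keys))
        strings_by_group: dict[str, set[bytes]] = {}
        for g, key in zip(group_of[keep], row_keys):
            strings_by_group.setdefault(g, set()).add(key)
        separated = sum(
            1
            for a, b in combinations(group_names, 2)
            if a in strings_by_group
            and b in strings_by_group
            and not (strings_by_group[a] & strings_by_group[b])
        )
        discrimination = separated / n_pairs if n_pairs else 0.0
        left = float((cums[start - 1] - cums[start - 1 - primer_len]) / primer_len)
        right = float((cums[end + primer_len] - cums[end]) / primer_len)
        cand = SnippetCandidate(
            start_col=start,
            end_col=end,
            window_len=window_len,
            species_discrimination=discrimination,
            haplotype_count=distinct,
            left_flank_conservation=left,
            right_flank_conservation=right,
            amplicon_len=amplicon_len,
            composite_score=discrimination * min(left, right),
        )
        if ref_pos is not None:
            cand.ref_start = int(ref_pos[start - 1])
            cand.ref_end = int(ref_pos[end - 1])
        candidates.append(cand)
    candidates.sort(key=lambda c: (-c.composite_score, -c.haplotype_count, c.start_col))
    return candidates


def write_candidates_tsv(candidates: list[SnippetCandidate], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            "start_col\tend_col\twindow_len\tdiscrimination\thaplotype_count\t"
            "left_flank\tright_flank\tamplicon_len\tcomposite_score\tref_start\tref_end\n"
        )
        for c in candidates:
            handle.write(
                f"{c.start_col}\t{c.end_col}\t{c.window_len}\t"
                f"{c.species_discrimination:.6g}\t{c.haplotype_count}\t"
                f"{c.left_flank_conservation:.6g}\t{c.right_flank_conservation:.6g}\t"
                f"{c.amplicon_len}\t{c.composite_score:.6g}\t"
                f"{'' if c.ref_start is None else c.ref_start}\t"
                f"{'' if c.ref_end is None else c.ref_end}\n"
            )
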