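"""Three-step W-chromosome / autosomal molecular-sexing decision logic.

Birds are ZW: only females carry W, so a W-specific product indicates a
female.  Protocol: (1) W assay on every sample; (2) W-negative samples are
checked for amplifiable nuclear DNA with an autosomal assay; (3) autosomal
positives are retested with the W assay.  Two W negatives plus an autosomal
positive call a male; no autosomal product leaves the sample unsexed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import DataError, SampleRecord, SexAssayRecord

__all__ = ["SexCall", "call_sex", "sex_ratio", "calls_from_table"]

# printed assay primer sequences, kept for documentation only
W_PRIMERS = {
    "moaWF": "CACTGTTTTCTTACTAATAGCGAAGT",
    "moaWR": "ATGTTAAGCAATGCTCTATGACA",
}
AUTOSOMAL_PRIMERS = {
    "msox9F": "CTGCTCCTTGAATCTGATGA",
    "msox9R": "CTTAGGCCAACGATACGAAA",
}
W_PRODUCT_BP = 58
AUTOSOMAL_PRODUCT_BP = 72


@dataclass
class SexCall:
    sample_id: str
    call: str  # female | male | unknown
    evidence: str
    flagged: bool = False


def call_sex(record: SexAssayRecord) -> SexCall:
    """Apply the three-step decision procedure to one assay record."""
    if record.w_assay == "not_done":
        raise DataError(f"{record.sample_id!r}: W assay was not performed")
    flagged = False
    evidence_parts = [f"W={record.w_assay}"]
    if record.w_retest != "not_done" and record.autosomal_assay != "positive":
        # retest should only be run after an autosomal positive
        flagged = True
        evidence_parts.append("protocol: retest without autosomal positive")
    if record.autosomal_assay != "not_done":
        evidence_parts.append(f"autosomal={record.autosomal_assay}")
    if record.w_retest != "not_done":
        evidence_parts.append(f"W retest={record.w_retest}")
    evidence = "; ".join(evidence_parts)

    if record.w_assay == "positive" or record.w_retest == "positive":
        return SexCall(record.sample_id, "female", evidence, flagged)
    # W negative on the first pass from here on
    if record.autosomal_assay == "positive":
        if record.w_retest == "negative":
            return SexCall(record.sample_id, "male", evidence, flagged)
        # retest pending: nuclear DNA amplifies but step 3 is missing
        return SexCall(record.sample_id, "unknown", evidence + "; retest pending", True)
    # no amplifiable nuclear DNA (or step 2 not done)
    return SexCall(record.sample_id, "unknown", evidence, flagged)


def sex_ratio(calls: list[SexCall]) -> dict:
    """Counts by call plus a reduced male:female ratio string."""
    n_male = sum(1 for c in calls if c.call == "male")
    n_female = sum(1 for c in calls if c.call == "female")
    n_unknown = sum(1 for c in calls if c.call == "unknown")
    if n_male >= 1:
        ratio = f"1:{n_female / n_male:g}"
    else:
        ratio = f"0:{n_female}"
    return {
        "n_male": n_male,
        "n_female": n_female,
        "n_unknown": n_unknown,
        "ratio_text": ratio,
    }


_TABLE_SEX = {"M": "male", "F": "female"}


def calls_from_table(records: list[SampleRecord]) -> list[SexCall]:
    """Turn the sex column of a packaged sample table into SexCall objects."""
    calls = []
    for rec in records:
        call = _TABLE_SEX.get((rec.sex or "").upper(), "unknown")
        calls.append(SexCall(rec.sample_id, call, evidence="table sex column"))
    return calls
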