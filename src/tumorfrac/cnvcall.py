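"""Tumor-purity correction of copy-number calls with confidence gating.

The observed copy number ``C`` in a mixed sample is a blend of tumor and
diploid non-tumor genomes: ``f*x + (1-f)*2 = C``, where ``f`` is the tumor
cellularity and ``x`` the tumor-intrinsic copy number. Inverting gives the
purity-corrected value ``x = (C - 2*(1-f)) / f``. Because a revised
(usually lower) cellularity raises ``x`` for any ``C > 2``, re-estimating
cellularity can change which amplifications are called and reported.

A call is *reported* when it is a primary software call (corrected copies
at or above a caller threshold, default ``x >= 4``) and it passes the
confidence gate: at least 5 of 6 QC criteria met, the criteria being
cellularity >= 50%, read count >= 10,000, MAPD <= 0.5, lower 5% copy bound
>= 4, corrected CNV level >= 5 copies, and call p-value <= 1e-5 (all
thresholds inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "CRITERIA_NAMES",
    "CNVRecord",
    "CallSetComparison",
    "correct_copy_number",
    "evaluate_confidence",
    "records_from_frame",
    "records_to_frame",
    "read_cnv_csv",
    "write_cnv_csv",
    "recall_with_tcf",
    "compare_call_sets",
]

CRITERIA_NAMES = (
    "cellularity_ge_50",
    "reads_ge_10000",
    "mapd_le_0_5",
    "conf5_ge_4",
    "level_ge_5",
    "p_le_1e5",
)

#: Default primary-call predicate: corrected copy number at/above this.
CALL_THRESHOLD = 4.0
MIN_CRITERIA = 5

CSV_COLUMNS = [
    "case_id",
    "gene",
    "C",
    "f",
    "read_count",
    "mapd",
    "cn_conf_5",
    "p_value",
]


def correct_copy_number(C: float, f: float) -> float:
    """Purity-corrected copy number ``x = (C - 2*(1-f)) / f``.

    ``C = 2`` is a fixed point for every cellularity (a diploid locus stays
    diploid), and ``f = 1`` returns ``C`` unchanged. Negative results
    (possible when ``C < 2*(1-f)``) are returned as-is; callers flag them
    as implausible rather than clamping.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError(f"cellularity f must lie in (0, 1], got {f}")
    if C < 0:
        raise ValueError(f"observed copy number must be >= 0, got {C}")
    return (C - 2.0 * (1.0 - f)) / f


@dataclass(frozen=True)
class CNVRecord:
    """One gene-level copy-number call with QC metrics and its verdict.

    Input fields are the observed copy number ``C``, cellularity ``f``, and
    the QC quartet (read count, MAPD, lower 5% copy bound, p-value); a
    missing QC field (None) counts as an unmet criterion. Output fields
    (``x``, ``criteria``, ``n_met``, ``confident``, ``is_call``,
    ``implausible``) are filled by :func:`evaluate_confidence`.
    """

    case_id: str
    gene: str
    C: float
    f: float
    read_count: int | None = None
    mapd: float | None = None
    cn_conf_5: float | None = None
    p_value: float | None = None
    x: float | None = None
    criteria: tuple[bool, ...] | None = None
    n_met: int | None = None
    confident: bool | None = None
    is_call: bool | None = None
    implausible: bool = False

    @property
    def reported(self) -> bool:
        """Final reported status: primary call passing the confidence gate."""
        return bool(self.is_call and self.confident)


def evaluate_confidence(
    record: CNVRecord,
    min_criteria: int = MIN_CRITERIA,
    call_threshold: float = CALL_THRESHOLD,
) -> CNVRecord:
    """Correct the copy number and evaluate the 6-criterion gate.

    All thresholds are inclusive; ``confident`` means at least
    ``min_criteria`` of the six are met. ``is_call`` applies the separate
    primary-call predicate ``x >= call_threshold``. Negative corrected
    copy numbers are flagged ``implausible`` and kept.
    """
    x = correct_copy_number(record.C, record.f)
    criteria = (
        record.f >= 0.50,
        record.read_count is not None and record.read_count >= 10_000,
        record.mapd is not None and record.mapd <= 0.5,
        record.cn_conf_5 is not None and record.cn_conf_5 >= 4.0,
        x >= 5.0,
        record.p_value is not None and record.p_value <= 1e-5,
    )
    n_met = sum(criteria)
    return replace(
        record,
        x=x,
        criteria=criteria,
        n_met=n_met,
        confident=n_met >= min_criteria,
        is_call=x >= call_threshold,
        implausible=x < 0,
    )


def records_from_frame(frame: pd.DataFrame, evaluate: bool = True, **gate) -> list[CNVRecord]:
    """Build records from a DataFrame with the documented CSV columns."""
    records = []
    for row in frame.itertuples(index=False):
        rec = CNVRecord(
            case_id=str(row.case_id),
            gene=str(row.gene),
            C=float(row.C),
            f=float(row.f),
            read_count=None if pd.isna(row.read_count) else int(row.read_count),
            mapd=None if pd.isna(row.mapd) else float(row.mapd),
            cn_conf_5=None if pd.isna(row.cn_conf_5) else float(row.cn_conf_5),
            p_value=None if pd.isna(row.p_value) else float(row.p_value),
        )
        records.append(evaluate_confidence(rec, **gate) if evaluate else rec)
    return records


def records_to_frame(records: list[CNVRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in CSV_COLUMNS}
        row.update(
            x=r.x, n_met=r.n_met, confident=r.confident,
            is_call=r.is_call, implausible=r.implausible,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def read_cnv_csv(path, **gate) -> list[CNVRecord]:
    """Read a CNV call table (documented header) and evaluate the gate."""
    frame = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"CNV table {path} lacks columns: {sorted(missing)}")
    return records_from_frame(frame, **gate)


def write_cnv_csv(records: list[CNVRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def recall_with_tcf(
    records: list[CNVRecord],
    new_f_by_case: dict[str, float],
    **gate,
) -> list[CNVRecord]:
    """Re-call the set with revised per-case cellularity (pure transform).

    Every case present in ``records`` must have a revised ``f``; the input
    records are untouched. Records with an unchanged ``f`` are unchanged
    in the output (idempotence).
    """
    missing = sorted({r.case_id for r in records} - set(new_f_by_case))
    if missing:
        raise KeyError(f"no revised cellularity for cases: {missing[:5]}")
    return [
        evaluate_confidence(replace(r, f=float(new_f_by_case[r.case_id])), **gate)
        for r in records
    ]


def _round1(value: float) -> float:
    return float(f"{value:.1f}")


@dataclass(frozen=True)
class CallSetComparison:
    """Before/after call-set arithmetic.

    Headline counts are per case (a case is a software call if any of its
    gene records passes the primary-call predicate, and a confident call
    if any record is reported); gained/lost gene lists are gene-level.
    Percent changes are reported to one decimal, the discrepancy percent
    to zero decimals. When the before count is zero the corresponding
    percent is None rather than a division error.
    """

    software_calls_before: int
    software_calls_after: int
    software_change_pct: float | None
    confident_before: int
    confident_after: int
    confident_change_pct: float | None
    discrepant_cases: int
    discrepancy_pct: float | None
    genes_gained: tuple[str, ...]
    genes_lost: tuple[str, ...]

    def summary(self) -> str:
        sc = "n/a" if self.software_change_pct is None else f"{self.software_change_pct:+.1f}%"
        cc = "n/a" if self.confident_change_pct is None else f"{self.confident_change_pct:+.1f}%"
        dp = "n/a" if self.discrepancy_pct is None else f"{self.discrepancy_pct:.0f}%"
        return (
            f"software calls {self.software_calls_after} vs "
            f"{self.software_calls_before} ({sc}); confident calls "
            f"{self.confident_after} vs {self.confident_before} ({cc}); "
            f"discrepancy {dp} ({self.discrepant_cases}/"
            f"{self.software_calls_before})"
        )


def compare_call_sets(
    before: list[CNVRecord],
    after: list[CNVRecord],
) -> CallSetComparison:
    """Compare evaluated call sets before and after cellularity revision.

    The two sets must cover identical (case, gene) keys. Discrepancy is
    the fraction of before software-call cases whose final reported status
    changed after revision.
    """
    key = lambda r: (r.case_id, r.gene)
    b_map = {key(r): r for r in before}
    a_map = {key(r): r for r in after}
    if set(b_map) != set(a_map):
        diff = set(b_map) ^ set(a_map)
        raise KeyError(f"call sets do not share (case, gene) keys: {sorted(diff)[:5]}")
    for r in list(b_map.values()) + list(a_map.values()):
        if r.is_call is None:
            raise ValueError("records must be evaluated before comparison")

    def case_flags(recs):
        calls, reported = set(), set()
        for r in recs:
            if r.is_call:
                calls.add(r.case_id)
            if r.reported:
                reported.add(r.case_id)
        return calls, reported

    b_calls, b_rep = case_flags(before)
    a_calls, a_rep = case_flags(after)

    def pct_change(a: int, b: int) -> float | None:
        return None if b == 0 else _round1(100.0 * (a - b) / b)

    discrepant = {
        c for c in b_calls if (c in b_rep) != (c in a_rep)
    }
    gained = tuple(sorted(k[1] for k in a_map if a_map[k].reported and not b_map[k].reported))
    lost = tuple(sorted(k[1] for k in b_map if b_map[k].reported and not a_map[k].reported))
    n_b_calls = len(b_calls)
    return CallSetComparison(
        software_calls_before=n_b_calls,
        software_calls_after=len(a_calls),
        software_change_pct=pct_change(len(a_calls), n_b_calls),
        confident_before=len(b_rep),
        confident_after=len(a_rep),
        confident_change_pct=pct_change(len(a_rep), len(b_rep)),
        discrepant_cases=len(discrepant),
        discrepancy_pct=(
            None if n_b_calls == 0
            else float(round(100.0 * len(discrepant) / n_b_calls))
        ),
        genes_gained=gained,
        genes_lost=lost,
    )
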