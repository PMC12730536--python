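"""miRNA quality filtering.

Three selection criteria are applied to mature miRNA records:

1. abundance — strictly more than ``min_reads`` deep-sequencing reads
   ("more than" is an exclusive bound: a count equal to the threshold fails);
2. length — between ``min_len`` and ``max_len`` nucleotides, inclusive;
3. orientation — the record's alignment orientation flag must be 5'->3'
   (records default to compliant; the flag exists for callers whose upstream
   alignment reports antisense mappings).

Filtering never fails: every input record lands in either ``kept`` or
``rejected`` with machine-readable reason codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import MatureMiRNA

LOW_READS = "LOW_READS"
BAD_LENGTH = "BAD_LENGTH"
BAD_ORIENTATION = "BAD_ORIENTATION"


@dataclass
class QcReport:
    kept: list[MatureMiRNA] = field(default_factory=list)
    rejected: list[tuple[MatureMiRNA, frozenset[str]]] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)


def filter_mirnas(
    mirnas: list[MatureMiRNA],
    min_reads: int = 1400,
    min_len: int = 19,
    max_len: int = 25,
    require_read_counts: bool = True,
) -> QcReport:
    """Partition ``mirnas`` into kept/rejected under the three criteria.

    A record is kept iff ``read_count > min_reads`` (strict), ``min_len <=
    len <= max_len`` (inclusive) and its orientation flag is compliant.
    Records lacking a read count are rejected with ``LOW_READS`` unless
    ``require_read_counts`` is False, in which case the abundance criterion
    is waived for them.
    """
    if min_reads < 0 or min_len <= 0 or max_len <= 0:
        raise ValueError("thresholds must be positive")
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    report = QcReport()
    for m in mirnas:
        reasons = set()
        if m.read_count is None:
            if require_read_counts:
                reasons.add(LOW_READS)
        elif m.read_count <= min_reads:
            reasons.add(LOW_READS)
        if not (min_len <= len(m) <= max_len):
            reasons.add(BAD_LENGTH)
        if m.orientation != "5p3p":
            reasons.add(BAD_ORIENTATION)
        if reasons:
            report.rejected.append((m, frozenset(reasons)))
        else:
            report.kept.append(m)
    return report
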