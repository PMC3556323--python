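"""Sequencing-library bookkeeping.

Run-level read counts from a sequencing summary table are combined into
library totals and the derived QC/mapping percentages: QC pass rate is
relative to total reads, mapping rate relative to QC-passed reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class LibrarySummary:
    total_reads: int
    qc_passed: int
    mapped: int

    @property
    def pct_qc_passed(self) -> float:
        return 100.0 * self.qc_passed / self.total_reads

    @property
    def pct_mapped(self) -> float:
        """Mapped reads as a percentage of QC-passed reads."""
        return 100.0 * self.mapped / self.qc_passed


def summarize_library(
    run_reads: Sequence[int], qc_passed: int, mapped: int
) -> LibrarySummary:
    """Combine per-run read counts for one library and derive percentages."""
    if not run_reads or any(r <= 0 for r in run_reads):
        raise ValueError("run read counts must be positive")
    total = int(sum(run_reads))
    if not 0 < qc_passed <= total:
        raise ValueError("qc_passed must be in (0, total]")
    if not 0 < mapped <= qc_passed:
        raise ValueError("mapped must be in (0, qc_passed]")
    return LibrarySummary(total, int(qc_passed), int(mapped))
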