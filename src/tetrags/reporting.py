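"""Run-level bookkeeping summaries (sequencing throughput, alignment)."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class AlignmentSummary:
    n_markers: int
    n_aligned: int

    @property
    def n_unaligned(self) -> int:
        return self.n_markers - self.n_aligned

    @property
    def percent_aligned(self) -> float:
        return 100.0 * self.n_aligned / self.n_markers


def alignment_summary(n_markers: int, n_aligned: int) -> AlignmentSummary:
    """Aligned/unaligned marker bookkeeping for the Manhattan pseudo-chromosome."""
    if n_markers <= 0 or not 0 <= n_aligned <= n_markers:
        raise ValueError("need 0 <= n_aligned <= n_markers, n_markers > 0")
    return AlignmentSummary(n_markers, n_aligned)


def mean_reads_per_sample(total_reads: int, n_samples: int) -> int:
    """Average sequencing reads per sample, rounded to the nearest read."""
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    return round(total_reads / n_samples)
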