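"""Read-depth genotype calling for autotetraploid GBS data.

GBS tag pairs yield, per sample and biallelic locus, counts of reads
carrying each of the two alleles.  In an autotetraploid the three
heterozygous dosage classes (simplex AAAa, duplex AAaa, triplex Aaaa)
cannot be distinguished reliably at typical GBS depths, so heterozygotes
are collapsed onto a single diploid-style code and homozygous calls are
protected by a depth threshold chosen so that the probability of a
simplex heterozygote showing reads of only one allele is small
(about 4.2% at 11 reads).

Codes: 0 = homozygous minor, 1 = heterozygous, 2 = homozygous major,
MISSING (-1) = insufficient depth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled genotype; kept distinct from the {0, 1, 2} codes.
MISSING: int = -1


@dataclass
class CallingThresholds:
    """Depth and call-rate thresholds for genotype calling.

    Parameters
    ----------
    het_min_depth :
        Minimum total reads to call a locus heterozygous when both
        alleles are observed (default 4).
    hom_min_depth :
        Minimum reads to call a monoallelic locus homozygous (default
        11); below this the locus is set to MISSING because a simplex
        heterozygote could plausibly have produced only one allele.
    max_missing_rate :
        Markers with a missing fraction strictly above this are dropped
        (default 0.30, i.e. call rate of at least 70%).
    """

    het_min_depth: int = 4
    hom_min_depth: int = 11
    max_missing_rate: float = 0.30

    def __post_init__(self) -> None:
        if self.het_min_depth < 1 or self.hom_min_depth < 1:
            raise ValueError("depth thresholds must be >= 1")
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must be in [0, 1]")


@dataclass
class ReadCountMatrix:
    """Per sample x marker counts of reads for the two tag alleles."""

    major: np.ndarray  # (n_samples, n_markers) int
    minor: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.major = np.asarray(self.major)
        self.minor = np.asarray(self.minor)
        if self.major.shape != self.minor.shape:
            raise ValueError("major and minor count matrices must have equal shape")
        if (self.major < 0).any() or (self.minor < 0).any():
            raise ValueError("read counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")

    @property
    def n_samples(self) -> int:
        return self.major.shape[0]

    @property
    def n_markers(self) -> int:
        return self.major.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.major + self.minor


@dataclass
class DiploidCodedMatrix:
    """{0,1,2} coded genotypes with MISSING sentinel.

    ``codes`` is (n_samples, n_markers) int8; call rate is per marker.
    """

    codes: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        allowed = {MISSING, 0, 1, 2}
        present = set(np.unique(self.codes).tolist()) if self.codes.size else set()
        if not present <= allowed:
            raise ValueError(f"invalid genotype codes: {present - allowed}")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of MISSING cells."""
        if self.codes.shape[0] == 0:
            return np.zeros(self.codes.shape[1])
        return (self.codes == MISSING).mean(axis=0)

    @property
    def call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_rate


def call_genotype(
    major_reads: int, minor_reads: int, thresholds: CallingThresholds | None = None
) -> int:
    """Call a single cell from its two allele read counts.

    Both alleles observed -> heterozygote (1) if total depth reaches
    ``het_min_depth``; a single allele observed -> homozygote (2 for the
    major allele, 0 for the minor) if depth reaches ``hom_min_depth``;
    otherwise MISSING.
    """
    if major_reads < 0 or minor_reads < 0:
        raise ValueError("read counts must be non-negative")
    thr = thresholds or CallingThresholds()
    total = major_reads + minor_reads
    if total == 0:
        return MISSING
    if major_reads > 0 and minor_reads > 0:
        return 1 if total >= thr.het_min_depth else MISSING
    if total < thr.hom_min_depth:
        return MISSING
    return 2 if major_reads > 0 else 0


def call_matrix(
    rc: ReadCountMatrix, thresholds: CallingThresholds | None = None
) -> DiploidCodedMatrix:
    """Vectorised per-cell calling over a whole read-count matrix."""
    thr = thresholds or CallingThresholds()
    total = rc.major + rc.minor
    het = (rc.major > 0) & (rc.minor > 0)
    codes = np.full(total.shape, MISSING, dtype=np.int8)
    codes[het & (total >= thr.het_min_depth)] = 1
    hom_ok = ~het & (total >= thr.hom_min_depth)
    codes[hom_ok & (rc.major > 0)] = 2
    codes[hom_ok & (rc.minor > 0)] = 0
    return DiploidCodedMatrix(codes, list(rc.sample_ids), list(rc.marker_ids))


def collapse_tetraploid(dosage):
    """Collapse tetraploid major-allele dosage {0..4} to diploid codes.

    Nulliplex (0) -> 0, quadruplex (4) -> 2, the three heterozygous
    classes (simplex, duplex, triplex) -> 1.  Accepts scalars or arrays.
    """
    arr = np.asarray(dosage)
    if arr.size and ((arr < 0) | (arr > 4)).any():
        raise ValueError("dosage must be in {0,1,2,3,4}")
    mapping = np.array([0, 1, 1, 1, 2], dtype=np.int8)
    out = mapping[arr]
    return out if arr.ndim else int(out)


def miscall_probability(majority_fraction: float, depth: int) -> float:
    """Probability that all reads at a heterozygous locus carry one allele.

    For a simplex heterozygote the per-read major-allele probability is
    3/4, so at the default homozygous-call depth of 11 reads the
    probability of a monoallelic (hence falsely homozygous) observation
    is 0.75^11 + 0.25^11 = 4.22%.  Strictly decreasing in depth.
    """
    if not 0.0 < majority_fraction < 1.0:
        raise ValueError("majority_fraction must be in the open interval (0, 1)")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    p = majority_fraction
    return p**depth + (1.0 - p) ** depth


def filter_markers_by_callrate(
    m: DiploidCodedMatrix, max_missing_rate: float = 0.30
) -> DiploidCodedMatrix:
    """Drop markers whose missing fraction exceeds ``max_missing_rate``.

    The comparison is strict: a marker missing in exactly 30% of samples
    is retained at the default threshold.  Retained genotype values are
    never altered.
    """
    if m.n_markers == 0 or m.n_samples == 0:
        warnings.warn("filtering an empty genotype matrix", stacklevel=2)
        return DiploidCodedMatrix(m.codes.copy(), list(m.sample_ids), list(m.marker_ids))
    keep = m.missing_rate <= max_missing_rate
    removed = int((~keep).sum())
    logger.info(
        "call-rate filter removed %d of %d markers (max missing %.2f)",
        removed,
        m.n_markers,
        max_missing_rate,
    )
    kept_ids = [mid for mid, k in zip(m.marker_ids, keep) if k]
    return DiploidCodedMatrix(m.codes[:, keep].copy(), list(m.sample_ids), kept_ids)
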