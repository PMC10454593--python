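"""Core domain types shared across the pipeline.

Coordinate convention: all genomic coordinates are 1-based inclusive
(VCF positions and segment start/end alike).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ClonevoError(Exception):
    """Base class for user-facing pipeline errors."""


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant with per-sample allelic depths.

    ``counts`` maps sample_id -> (ref_count, alt_count). ``gene`` and
    ``consequence`` are optional annotations carried through from the
    VCF INFO field; they are never computed here.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    counts: dict[str, tuple[int, int]]
    gene: str | None = None
    consequence: str | None = None
    is_indel: bool = False

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def vaf(self, sample_id: str) -> float:
        ref, alt = self.counts[sample_id]
        depth = ref + alt
        return alt / depth if depth > 0 else 0.0


@dataclass(frozen=True)
class Segment:
    """Allele-specific copy-number segment (ASCAT-style integer states)."""

    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ClonevoError(
                f"segment {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.n_minor > self.n_major or self.n_minor < 0:
            raise ClonevoError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"require n_major >= n_minor >= 0, got {self.n_major}+{self.n_minor}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def total(self) -> int:
        return self.n_major + self.n_minor


@dataclass
class SamplePanel:
    """Per-sample tumor purity and ordered collection dates for one patient.

    ``dates`` are floats (e.g. decimal years) or ordinal labels cast to
    float; they only need a total order. ``sex`` controls the normal copy
    number of the sex chromosomes (AR sits on chrX, so this matters).
    """

    samples: list[str]
    purity: dict[str, float]
    dates: dict[str, float]
    sex: str = "male"
    normal_sample: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ClonevoError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for s in self.samples:
            if s not in self.purity or s not in self.dates:
                raise ClonevoError(f"sample {s!r} missing purity or date")
            p = self.purity[s]
            if not (0.0 < p <= 1.0):
                raise ClonevoError(f"purity for {s!r} must be in (0,1], got {p}")

    def ordered_samples(self) -> list[str]:
        """Samples sorted by collection date, ties broken by panel order."""
        order = {s: i for i, s in enumerate(self.samples)}
        return sorted(self.samples, key=lambda s: (self.dates[s], order[s]))


def normal_copy_number(chrom: str, sex: str) -> int:
    """Total copy number of a locus in normal cells.

    Autosomes are 2; chrX is 1 in males, 2 in females; chrY is 1 in
    males and absent (0) in females.
    """
    name = chrom.removeprefix("chr")
    if name == "X":
        return 1 if sex == "male" else 2
    if name == "Y":
        return 1 if sex == "male" else 0
    return 2


@dataclass(frozen=True)
class PloidyCall:
    """Length-weighted mean total copy number and the WGD flag.

    Whole-genome doubling is defined as ploidy strictly greater than 3.
    """

    ploidy: float
    wgd: bool


@dataclass
class GenomicEvent:
    """A gene- or arm-level copy-number event, with per-sample presence."""

    kind: str  # LOH | loss | gain | focal_amplification
    scope: str  # gene | arm
    target: str
    sample_presence: dict[str, bool] = field(default_factory=dict)

    KINDS = ("LOH", "loss", "gain", "focal_amplification")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.scope, self.target, self.kind)

    def present_in(self) -> frozenset[str]:
        return frozenset(s for s, p in self.sample_presence.items() if p)
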