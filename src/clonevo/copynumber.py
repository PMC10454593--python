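"""Interpretation of allele-specific copy-number profiles.

Ploidy is the segment-length-weighted mean total copy number; whole-genome
doubling (WGD) is called when ploidy exceeds 3 (strict inequality). Gene-
and arm-level events (LOH, loss, gain, focal amplification) are called
relative to each sample's own ploidy so that, e.g., a single-copy region in
a tetraploid genome is still recognized as a loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .types import (
    ClonevoError,
    GenomicEvent,
    PloidyCall,
    Segment,
    normal_copy_number,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    """A named genomic interval (gene body or chromosome arm)."""

    chrom: str
    start: int
    end: int
    name: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def compute_ploidy(segments: list[Segment]) -> PloidyCall:
    """Length-weighted mean total copy number over all segments.

    ploidy = sum(len_i * total_i) / sum(len_i), len = end - start + 1.
    WGD iff ploidy > 3.
    """
    if not segments:
        raise ClonevoError("compute_ploidy: empty segment list")
    total_len = sum(s.length for s in segments)
    weighted = sum(s.length * s.total for s in segments)
    ploidy = weighted / total_len
    if ploidy <= 0:
        raise ClonevoError("compute_ploidy: non-positive ploidy")
    return PloidyCall(ploidy=ploidy, wgd=ploidy > 3.0)


def _overlapping(segments: list[Segment], region: Region) -> list[Segment]:
    return [
        s
        for s in segments
        if s.chrom == region.chrom and s.start <= region.end and s.end >= region.start
    ]


def _covered_length(segments: list[Segment], region: Region) -> int:
    cov = 0
    for s in segments:
        lo = max(s.start, region.start)
        hi = min(s.end, region.end)
        if lo <= hi:
            cov += hi - lo + 1
    return cov


def call_gene_events(
    segments: list[Segment],
    gene_table: list[Region],
    ploidy_call: PloidyCall,
    sex: str = "male",
    amp_factor: float = 2.0,
    focal_max_len: int = 10_000_000,
) -> list[GenomicEvent]:
    """Gene-level copy-number events for one sample.

    Per gene (fully covered by segments; uncovered genes are no-calls with
    a warning):

    - ``LOH`` if the minor allele count is exactly 0 across the whole span;
    - ``loss`` if the minimum total copy number over the span is below
      round(ploidy);
    - ``focal_amplification`` if any overlapping segment no longer than
      ``focal_max_len`` reaches total >= amp_factor * ploidy.

    On sex chromosomes the ploidy baseline is scaled by the normal copy
    number (a hemizygous male chrX locus is expected at ploidy/2 copies),
    and LOH is only defined where the normal genome is heterozygous
    (normal copy number 2).

    When a gene straddles segments of different states, the most extreme
    state per event kind wins (minimum for loss/LOH, maximum for
    amplification) and a warning is logged.
    """
    events: list[GenomicEvent] = []
    ploidy = ploidy_call.ploidy
    for gene in gene_table:
        over = _overlapping(segments, gene)
        if not over or _covered_length(over, gene) < gene.length:
            log.warning("gene %s not fully covered by segments: no-call", gene.name)
            continue
        if len({(s.n_major, s.n_minor) for s in over}) > 1:
            log.warning(
                "gene %s straddles segments of different states; "
                "using most extreme state per event kind",
                gene.name,
            )
        ncn = normal_copy_number(gene.chrom, sex)
        if ncn == 0:
            continue
        expected = ploidy * ncn / 2.0
        min_minor = min(s.n_minor for s in over)
        min_total = min(s.total for s in over)
        if min_minor == 0 and ncn == 2:
            events.append(GenomicEvent(kind="LOH", scope="gene", target=gene.name))
        if min_total < round(expected):
            events.append(GenomicEvent(kind="loss", scope="gene", target=gene.name))
        for s in over:
            if s.length <= focal_max_len and s.total >= amp_factor * expected:
                events.append(
                    GenomicEvent(
                        kind="focal_amplification", scope="gene", target=gene.name
                    )
                )
                break
    return events


def call_arm_events(
    segments: list[Segment],
    arm_table: list[Region],
    ploidy_call: PloidyCall,
    sex: str = "male",
    arm_gain_margin: float = 0.6,
    arm_frac: float = 0.9,
    min_coverage: float = 0.5,
) -> list[GenomicEvent]:
    """Arm-level gain/loss/LOH calls for one sample.

    An arm is a gain when its length-weighted mean total copy number is at
    least expected + ``arm_gain_margin`` (expected = ploidy scaled by the
    arm's normal copy number / 2), a loss when it is at most
    expected - ``arm_gain_margin``, and LOH when at least ``arm_frac`` of
    the covered arm length has minor allele count 0 (only where the normal
    genome is heterozygous). Arms with less than ``min_coverage`` of their
    length covered by segments are no-calls.
    """
    events: list[GenomicEvent] = []
    ploidy = ploidy_call.ploidy
    for arm in arm_table:
        over = _overlapping(segments, arm)
        cov = _covered_length(over, arm)
        if cov < min_coverage * arm.length:
            log.warning("arm %s has <%.0f%% segment coverage: no-call",
                        arm.name, 100 * min_coverage)
            continue
        ncn = normal_copy_number(arm.chrom, sex)
        if ncn == 0:
            continue
        expected = ploidy * ncn / 2.0
        wsum = 0.0
        loh_len = 0
        for s in over:
            olen = min(s.end, arm.end) - max(s.start, arm.start) + 1
            wsum += olen * s.total
            if s.n_minor == 0:
                loh_len += olen
        mean_total = wsum / cov
        if mean_total >= expected + arm_gain_margin:
            events.append(GenomicEvent(kind="gain", scope="arm", target=arm.name))
        elif mean_total <= expected - arm_gain_margin:
            events.append(GenomicEvent(kind="loss", scope="arm", target=arm.name))
        if loh_len >= arm_frac * cov and ncn == 2:
            events.append(GenomicEvent(kind="LOH", scope="arm", target=arm.name))
    return events


def compare_events_across_samples(
    per_sample_events: dict[str, list[GenomicEvent]],
) -> dict[str, list[GenomicEvent]]:
    """Partition events by how widely they are shared across samples.

    Returns ``{"shared_all": [...], "shared_subset": [...], "private": [...]}``
    where each event carries a full per-sample presence map. Events are
    ordered deterministically by (scope, target, kind).
    """
    if len(per_sample_events) < 2:
        raise ClonevoError("compare_events_across_samples requires >= 2 samples")
    samples = sorted(per_sample_events)
    keys: dict[tuple[str, str, str], dict[str, bool]] = {}
    for sample, events in per_sample_events.items():
        for ev in events:
            presence = keys.setdefault(ev.key, {s: False for s in samples})
            presence[sample] = True
    out: dict[str, list[GenomicEvent]] = {
        "shared_all": [],
        "shared_subset": [],
        "private": [],
    }
    for key in sorted(keys):
        scope, target, kind = key
        presence = keys[key]
        ev = GenomicEvent(kind=kind, scope=scope, target=target,
                          sample_presence=dict(presence))
        n = sum(presence.values())
        if n == len(samples):
            out["shared_all"].append(ev)
        elif n == 1:
            out["private"].append(ev)
        else:
            out["shared_subset"].append(ev)
    return out
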