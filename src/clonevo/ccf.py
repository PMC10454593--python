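"""Cancer-cell-fraction estimation from allele counts.

Model: a variant present in a fraction ``ccf`` of tumor cells, on ``m``
of the locus's tumor copies, in a sample of purity ``rho`` whose tumor
cells carry ``cn`` total copies at the locus (normal cells carry
``normal_cn``), has expected VAF

    E[vaf] = ccf * rho * m / (rho * cn + (1 - rho) * normal_cn)

Multiplicity is estimated per variant and per sample by choosing the
m in {1..n_major} whose clonal (ccf = 1) expected VAF is closest to the
observed VAF; CCF then inverts the formula. Raw CCFs slightly above 1
arise from binomial noise and are reported raw but clipped to 1 for
clustering; values above ``ccf_cap`` (default 1.2) are flagged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ClonevoError, SamplePanel, Segment, VariantRecord, normal_copy_number

log = logging.getLogger(__name__)

CCF_CAP = 1.2
MIN_DEPTH = 10


def expected_vaf(ccf: float, purity: float, cn: int, normal_cn: int, m: int) -> float:
    """Expected VAF under the purity/copy-number model above."""
    denom = purity * cn + (1.0 - purity) * normal_cn
    if denom <= 0:
        raise ClonevoError("expected_vaf: non-positive effective copy number")
    return ccf * purity * m / denom


def estimate_multiplicity(
    vaf: float, purity: float, n_major: int, n_minor: int, normal_cn: int
) -> int:
    """Most likely number of mutated copies, m in {1..n_major}.

    Chooses the m minimizing |vaf - E[vaf | ccf=1, m]|; ties go to the
    smaller m. The search is capped at n_major because a point mutation
    arises on one parental haplotype and can only be multiplied up to
    that haplotype's copy number.
    """
    if not (0.0 < purity <= 1.0):
        raise ClonevoError(f"purity must be in (0,1], got {purity}")
    if n_major < 1:
        raise ClonevoError("estimate_multiplicity requires n_major >= 1")
    cn = n_major + n_minor
    best_m, best_err = 1, float("inf")
    for m in range(1, n_major + 1):
        err = abs(vaf - expected_vaf(1.0, purity, cn, normal_cn, m))
        if err < best_err:  # strict: ties keep the smaller m
            best_m, best_err = m, err
    return best_m


def compute_ccf(
    vaf: float,
    purity: float,
    n_major: int,
    n_minor: int,
    normal_cn: int,
    multiplicity: int,
) -> float:
    """Invert the expected-VAF model to a cancer cell fraction."""
    if purity * multiplicity <= 0:
        raise ClonevoError("compute_ccf: purity * multiplicity must be > 0")
    cn = n_major + n_minor
    return vaf * (purity * cn + (1.0 - purity) * normal_cn) / (purity * multiplicity)


def _locate(segments: list[Segment], chrom: str, pos: int) -> Segment | None:
    for s in segments:
        if s.chrom == chrom and s.start <= pos <= s.end:
            return s
    return None


def build_ccf_matrix(
    variants: list[VariantRecord],
    segments: dict[str, list[Segment]],
    panel: SamplePanel,
    min_depth: int = MIN_DEPTH,
    ccf_cap: float = CCF_CAP,
) -> pd.DataFrame:
    """Per-variant, per-sample CCF table (long format).

    Columns: variant_id, sample, vaf, multiplicity, total_cn, normal_cn,
    ccf_raw, ccf (clipped to [0,1]), flag. Variants that fall in a region
    uncovered by segments, in a zero-copy region, or with depth below
    ``min_depth`` in ANY tumor sample are excluded entirely (the logged
    ``flag`` says why); multiplicity is estimated independently per sample
    because copy number can differ between samples.
    """
    rows = []
    n_excluded = 0
    for v in variants:
        if v.is_indel:
            n_excluded += 1
            log.info("excluding %s: indel", v.variant_id)
            continue
        entry_rows = []
        reason = None
        for s in panel.samples:
            seg = _locate(segments.get(s, []), v.chrom, v.pos)
            if seg is None:
                reason = f"uncovered in {s}"
                break
            if seg.total == 0 or seg.n_major == 0:
                reason = f"zero tumor copies in {s}"
                break
            ref, alt = v.counts[s]
            depth = ref + alt
            if depth < min_depth:
                reason = f"depth {depth} < {min_depth} in {s}"
                break
            ncn = normal_copy_number(v.chrom, panel.sex)
            vaf = alt / depth
            m = estimate_multiplicity(vaf, panel.purity[s], seg.n_major,
                                      seg.n_minor, ncn)
            raw = compute_ccf(vaf, panel.purity[s], seg.n_major, seg.n_minor,
                              ncn, m)
            flag = "ccf_above_cap" if raw > ccf_cap else ""
            entry_rows.append(
                dict(
                    variant_id=v.variant_id,
                    sample=s,
                    vaf=vaf,
                    multiplicity=m,
                    total_cn=seg.total,
                    normal_cn=ncn,
                    ccf_raw=raw,
                    ccf=min(max(raw, 0.0), 1.0),
                    flag=flag,
                )
            )
        if reason is not None:
            n_excluded += 1
            log.info("excluding %s: %s", v.variant_id, reason)
            continue
        rows.extend(entry_rows)
    if n_excluded:
        log.info("build_ccf_matrix: excluded %d of %d variants",
                 n_excluded, len(variants))
    df = pd.DataFrame(
        rows,
        columns=["variant_id", "sample", "vaf", "multiplicity", "total_cn",
                 "normal_cn", "ccf_raw", "ccf", "flag"],
    )
    return df


def ccf_wide(ccf_matrix: pd.DataFrame, panel: SamplePanel) -> pd.DataFrame:
    """Pivot the long CCF table to variants x samples (clipped CCF)."""
    wide = ccf_matrix.pivot(index="variant_id", columns="sample", values="ccf")
    return wide[panel.samples]


def mean_absolute_ccf_error(
    ccf_matrix: pd.DataFrame, truth: dict[str, dict[str, float]]
) -> float:
    """Mean |estimated - true| CCF over all (variant, sample) entries."""
    errs = [
        abs(row.ccf - truth[row.variant_id][row.sample])
        for row in ccf_matrix.itertuples()
        if row.variant_id in truth
    ]
    if not errs:
        raise ClonevoError("no overlap between CCF matrix and truth")
    return float(np.mean(errs))
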