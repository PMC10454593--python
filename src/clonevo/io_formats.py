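"""File formats: VCF input, segment/panel/region TSVs, result writers.

Conventions
-----------
- All coordinates are 1-based inclusive, in VCF and in every TSV.
- TSVs are tab-separated with a mandatory header row; lines starting with
  ``#`` are comments.
- Floats in result tables are written with 6 decimal places; reading a
  result back reproduces every numeric field at that precision.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .clustering import ClusterResult, cluster_members
from .phylogeny import CloneTree, TimedEvent
from .types import (
    ClonevoError,
    GenomicEvent,
    SamplePanel,
    Segment,
    VariantRecord,
)
from .copynumber import Region

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"

_DATA_DIR = Path(__file__).parent / "data"


def read_vcf(
    path: str | Path,
    tumor_sample_ids: list[str],
    normal_sample_id: str | None = None,
    skip_nonpass: bool = True,
    multiallelic: str = "skip",
) -> list[VariantRecord]:
    """Read somatic variants with AD-style allelic depths.

    Returns one record per biallelic variant row (multi-allelic rows are
    split into one record per alt, or skipped, per ``multiallelic``).
    Indels are parsed and flagged but kept; downstream stages exclude
    them from CCF/clustering.
    """
    if multiallelic not in ("skip", "split"):
        raise ClonevoError("multiallelic must be 'skip' or 'split'")
    vcf = VCF(str(path))
    wanted = list(tumor_sample_ids) + (
        [normal_sample_id] if normal_sample_id else []
    )
    missing = [s for s in wanted if s not in vcf.samples]
    if missing:
        raise ClonevoError(
            f"samples {missing} not found in {path}; VCF has {vcf.samples}"
        )
    col = {s: vcf.samples.index(s) for s in wanted}
    records: list[VariantRecord] = []
    for row in vcf:
        if skip_nonpass and row.FILTER is not None:
            continue
        alts = row.ALT
        if len(alts) > 1 and multiallelic == "skip":
            log.info("skipping multi-allelic row %s:%d", row.CHROM, row.POS)
            continue
        ad = row.format("AD")
        if ad is None:
            raise ClonevoError(
                f"row {row.CHROM}:{row.POS}: no AD (allelic depth) FORMAT field"
            )
        gene = row.INFO.get("GENE")
        csq = row.INFO.get("CSQ")
        for ai, alt in enumerate(alts):
            counts = {}
            for s in wanted:
                ref_n = max(int(ad[col[s], 0]), 0)
                alt_n = max(int(ad[col[s], 1 + ai]), 0)
                counts[s] = (ref_n, alt_n)
            if not any(sum(counts[s]) > 0 for s in tumor_sample_ids):
                continue
            records.append(
                VariantRecord(
                    chrom=row.CHROM,
                    pos=row.POS,
                    ref=row.REF,
                    alt=str(alt),
                    counts=counts,
                    gene=gene,
                    consequence=csq,
                    is_indel=len(row.REF) != 1 or len(str(alt)) != 1,
                )
            )
    return records


def read_segments(path: str | Path) -> dict[str, list[Segment]]:
    """Allele-specific segments per sample from a TSV.

    Columns: sample, chrom, start, end, nMajor, nMinor. Segments of one
    sample must not overlap; the returned lists are sorted by
    (chrom, start).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "chrom", "start", "end", "nMajor", "nMinor"}
    if not required <= set(df.columns):
        raise ClonevoError(
            f"segment file {path} missing columns {sorted(required - set(df.columns))}"
        )
    out: dict[str, list[Segment]] = {}
    for sample, grp in df.groupby("sample"):
        segs = [
            Segment(
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                n_major=int(r.nMajor),
                n_minor=int(r.nMinor),
            )
            for r in grp.itertuples()
        ]
        segs.sort(key=lambda s: (s.chrom, s.start))
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ClonevoError(
                    f"overlapping segments in sample {sample}: "
                    f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
                )
        out[str(sample)] = segs
    return out


def read_panel(path: str | Path) -> SamplePanel:
    """Sample panel TSV: sample, purity, date, sex (one sex per patient)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "purity", "date", "sex"}
    if not required <= set(df.columns):
        raise ClonevoError(
            f"panel file {path} missing columns {sorted(required - set(df.columns))}"
        )
    sexes = set(df["sex"])
    if len(sexes) != 1:
        raise ClonevoError(f"panel must have a single sex, got {sorted(sexes)}")
    return SamplePanel(
        samples=[str(s) for s in df["sample"]],
        purity={str(r.sample): float(r.purity) for r in df.itertuples()},
        dates={str(r.sample): float(r.date) for r in df.itertuples()},
        sex=str(df["sex"].iloc[0]),
    )


def read_region_table(path: str | Path) -> list[Region]:
    """BED-like TSV (chrom, start, end, name), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "name"}
    if not required <= set(df.columns):
        raise ClonevoError(
            f"region table {path} missing columns {sorted(required - set(df.columns))}"
        )
    return [
        Region(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
               name=str(r.name))
        for r in df.itertuples()
    ]


def default_gene_table() -> list[Region]:
    """Bundled hg38 coordinates for the cancer genes tracked by default
    (PTEN, RB1, TP53, AR)."""
    return read_region_table(_DATA_DIR / "genes_hg38.tsv")


def default_arm_table() -> list[Region]:
    """Bundled approximate hg38 chromosome-arm spans."""
    return read_region_table(_DATA_DIR / "arms_hg38.tsv")


def write_results(
    ccf_matrix: pd.DataFrame | None,
    cluster_result: ClusterResult | None,
    clone_tree: CloneTree | None,
    per_sample_events: dict[str, list[GenomicEvent]] | None,
    out_dir: str | Path,
    timed_events: list[TimedEvent] | None = None,
    panel: SamplePanel | None = None,
) -> dict[str, Path]:
    """Write the full result bundle; returns the paths written.

    Files: ccf.tsv, clusters.tsv, assignments.tsv, events.tsv,
    timed_events.tsv, tree.json, tree.nwk. All re-readable with the
    readers in this module / plain pandas.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ClonevoError(f"output directory {out} not writable: {exc}") from exc

    paths: dict[str, Path] = {}

    if ccf_matrix is not None:
        ccf_path = out / "ccf.tsv"
        ccf_matrix.to_csv(ccf_path, sep="\t", index=False,
                          float_format=FLOAT_FMT)
        paths["ccf"] = ccf_path

    if cluster_result is not None:
        rows = []
        samples = (
            panel.samples
            if panel is not None
            else sorted(next(iter(cluster_result.centers.values())))
        )
        for cid in sorted(cluster_result.centers):
            row = {"cluster": cid, "size": cluster_result.sizes[cid]}
            for s in samples:
                row[f"center_{s}"] = cluster_result.centers[cid][s]
            rows.append(row)
        cl_path = out / "clusters.tsv"
        pd.DataFrame(rows).to_csv(cl_path, sep="\t", index=False,
                                  float_format=FLOAT_FMT)
        paths["clusters"] = cl_path

        asn_path = out / "assignments.tsv"
        pd.DataFrame(
            sorted(cluster_result.assignments.items()),
            columns=["variant_id", "cluster"],
        ).to_csv(asn_path, sep="\t", index=False)
        paths["assignments"] = asn_path

    if per_sample_events is not None:
        rows = []
        for sample in sorted(per_sample_events):
            for ev in per_sample_events[sample]:
                rows.append(
                    {"sample": sample, "scope": ev.scope, "target": ev.target,
                     "kind": ev.kind}
                )
        ev_path = out / "events.tsv"
        pd.DataFrame(rows, columns=["sample", "scope", "target", "kind"]).to_csv(
            ev_path, sep="\t", index=False
        )
        paths["events"] = ev_path

    if timed_events is not None:
        rows = [
            {
                "target": te.label,
                "scope": te.scope,
                "kind": te.kind,
                "last_absent": "" if te.last_absent is None else f"{te.last_absent:g}",
                "first_present": ""
                if te.first_present is None
                else f"{te.first_present:g}",
                "interval": te.interval_str(),
            }
            for te in timed_events
        ]
        te_path = out / "timed_events.tsv"
        pd.DataFrame(
            rows,
            columns=["target", "scope", "kind", "last_absent", "first_present",
                     "interval"],
        ).to_csv(te_path, sep="\t", index=False)
        paths["timed_events"] = te_path

    if clone_tree is not None:
        tree_path = out / "tree.json"
        tree_path.write_text(json.dumps(clone_tree.to_dict(), indent=2) + "\n")
        paths["tree_json"] = tree_path
        nwk_path = out / "tree.nwk"
        nwk_path.write_text(clone_tree.to_newick() + "\n")
        paths["tree_newick"] = nwk_path

    return paths


def read_tree_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
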