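"""End-to-end orchestration: VCF + segments + panel -> clone tree + timing."""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import ccf as ccf_mod
from . import clustering, copynumber, io_formats, phylogeny
from .config import RunConfig
from .types import ClonevoError, GenomicEvent, PloidyCall, SamplePanel, Segment

log = logging.getLogger(__name__)


@dataclass
class ResultBundle:
    panel: SamplePanel
    ccf_matrix: pd.DataFrame
    cluster_result: clustering.ClusterResult
    ploidy: dict[str, PloidyCall]
    per_sample_events: dict[str, list[GenomicEvent]]
    event_partition: dict[str, list[GenomicEvent]]
    tree: phylogeny.CloneTree
    timed_events: list[phylogeny.TimedEvent]
    paths: dict[str, Path]

    def summary(self) -> str:
        lines = [
            f"variants clustered: {len(self.cluster_result.assignments)}",
            f"clusters: {len(self.cluster_result.centers)}",
        ]
        for s in self.panel.samples:
            pc = self.ploidy[s]
            lines.append(
                f"sample {s}: ploidy {pc.ploidy:.2f}, WGD {'yes' if pc.wgd else 'no'}"
            )
        lines.append(f"MRCA cluster: {self.tree.root}")
        lines.append(f"tree: {self.tree.to_newick()}")
        for te in self.timed_events:
            lines.append(f"event {te.label} ({te.kind}): {te.interval_str()}")
        return "\n".join(lines)


def setup_logging(out_dir: str | Path, config: RunConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = logging.getLogger("clonevo")
    root.setLevel(logging.INFO)
    root.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(out / "run.log", mode="w"),
    ):
        handler.setFormatter(fmt)
        root.addHandler(handler)
    root.info("run hash %s seed %d", config.run_hash(), config.seed)
    root.info("config %s", config.echo())


def call_copy_number(
    segments: dict[str, list[Segment]],
    panel: SamplePanel,
    config: RunConfig,
    gene_table=None,
    arm_table=None,
) -> tuple[dict[str, PloidyCall], dict[str, list[GenomicEvent]]]:
    gene_table = gene_table or io_formats.default_gene_table()
    arm_table = arm_table or io_formats.default_arm_table()
    ploidy: dict[str, PloidyCall] = {}
    events: dict[str, list[GenomicEvent]] = {}
    for s in panel.samples:
        call = copynumber.compute_ploidy(segments[s])
        ploidy[s] = call
        events[s] = copynumber.call_gene_events(
            segments[s], gene_table, call, sex=panel.sex,
            amp_factor=config.amp_factor, focal_max_len=config.focal_max_len,
        ) + copynumber.call_arm_events(
            segments[s], arm_table, call, sex=panel.sex,
            arm_gain_margin=config.arm_gain_margin, arm_frac=config.arm_frac,
        )
    return ploidy, events


def run_all(
    vcf_path: str | Path,
    segments_path: str | Path,
    panel_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> ResultBundle:
    """Execute read -> CCF -> cluster -> CN events -> tree -> timing -> write."""
    config = config or RunConfig()
    setup_logging(out_dir, config)

    panel = io_formats.read_panel(panel_path)
    segments = io_formats.read_segments(segments_path)
    missing = [s for s in panel.samples if s not in segments]
    if missing:
        raise ClonevoError(f"samples {missing} have no segments")
    variants = io_formats.read_vcf(
        vcf_path, panel.samples,
        skip_nonpass=config.skip_nonpass, multiallelic=config.multiallelic,
    )
    log.info("read %d variants for samples %s", len(variants), panel.samples)

    matrix = ccf_mod.build_ccf_matrix(
        variants, segments, panel,
        min_depth=config.min_depth, ccf_cap=config.ccf_cap,
    )
    if matrix.empty:
        raise ClonevoError("no usable SNVs after CCF filtering")

    hp = clustering.DPHyperparams(
        sweeps=config.sweeps, burn_in=config.burn_in,
        grid_step=config.grid_step, min_cluster_size=config.min_cluster_size,
    )
    result = clustering.dp_cluster(matrix, variants, panel, hp,
                                   seed=config.seed)
    log.info("clustering found %d clusters: %s",
             len(result.centers), result.sizes)

    ploidy, per_sample_events = call_copy_number(segments, panel, config)
    partition = copynumber.compare_events_across_samples(per_sample_events) \
        if len(panel.samples) >= 2 else {"shared_all": [], "shared_subset": [],
                                         "private": []}

    root_id, centers, sizes = phylogeny.identify_mrca(
        result.centers, result.sizes, panel.samples,
        mrca_threshold=config.mrca_threshold,
    )
    # remap assignments of clusters merged into the root clone
    for vid, cid in list(result.assignments.items()):
        if cid not in centers:
            result.assignments[vid] = root_id
    result.centers = centers
    result.sizes = sizes

    tree = phylogeny.build_tree(
        centers, sizes, panel, event_partition=partition,
        mrca_threshold=config.mrca_threshold,
        presence_threshold=config.presence_threshold,
        epsilon=config.epsilon,
    )
    all_events = [ev for group in partition.values() for ev in group]
    timed = phylogeny.time_events(all_events, panel)

    paths = io_formats.write_results(
        matrix, result, tree, per_sample_events, out_dir,
        timed_events=timed, panel=panel,
    )
    bundle = ResultBundle(
        panel=panel, ccf_matrix=matrix, cluster_result=result,
        ploidy=ploidy, per_sample_events=per_sample_events,
        event_partition=partition, tree=tree, timed_events=timed,
        paths=paths,
    )
    (Path(out_dir) / "summary.txt").write_text(bundle.summary() + "\n")
    return bundle
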