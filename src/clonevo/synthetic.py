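"""Synthetic multi-sample tumor patients with known clonal structure.

The generator emits exactly the formats the pipeline consumes — a
multi-sample VCF of somatic SNVs (tumor samples plus one matched normal),
an ASCAT-style allele-specific segment TSV, a sample panel TSV — together
with a ``truth.json`` recording the clone tree, per-variant clone
assignments, per-sample ploidy/WGD status and event timing intervals.

Generative model, per SNV of clone k in sample s:

    expected VAF = phi_ks * rho_s * m / (rho_s * cn + (1 - rho_s) * ncn)
    depth ~ Poisson(mean_depth),  alt ~ Binomial(depth, expected VAF)

Copy-number events are clonal in the segment output: a sample's segment
file shows the event's integer state wherever any carrying clone is
present in that sample. SNVs acquired before a whole-genome doubling get
multiplicity n_major (both copies of the doubled haplotype mutated);
everything else has multiplicity 1. Random SNVs are placed outside CNA
intervals so those multiplicity semantics stay exact.

Three presets mirror the study designs this package targets:

- ``case1_like``: four dated samples (one ductal-morphology region),
  truncal WGD, a truncal 53-SNV clone carrying a PTEN SNV, a focal chrX
  AR amplification absent only from the earliest sample, a ductal branch
  with private arm events (1p LOH, 6q gain) and a 34-SNV clone private to
  the last sample;
- ``case2_like``: two synchronous regions (adenocarcinoma / NEPC) with a
  13q-LOH + RB1-loss trunk and a 3p-gain / 4p-LOH / 17p-LOH branch
  private to the NEPC region;
- ``null_single_clone``: one clone, no CNAs — a negative control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import copynumber
from .io_formats import default_arm_table, default_gene_table
from .phylogeny import TimedEvent, time_events
from .types import (
    ClonevoError,
    GenomicEvent,
    SamplePanel,
    Segment,
    normal_copy_number,
)

_BASES = "ACGT"
NORMAL_ID = "NORMAL"


@dataclass
class CloneSpec:
    name: str
    parent: str | None
    ccf: dict[str, float]  # sample -> CCF in [0, 1]
    n_snvs: int
    marker_genes: list[str] = field(default_factory=list)


@dataclass
class CNASpec:
    name: str
    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int
    clones: list[str]  # clones whose lineage carries the event


@dataclass
class SimConfig:
    samples: list[str]
    dates: dict[str, float]
    purity: dict[str, float]
    depth: float
    sex: str
    clones: list[CloneSpec]
    cnas: list[CNASpec]
    wgd_clone: str | None = None
    seed: int = 0

    def validate(self) -> None:
        by_name = {c.name: c for c in self.clones}
        roots = [c for c in self.clones if c.parent is None]
        if len(roots) != 1:
            raise ClonevoError("SimConfig: exactly one root clone required")
        if self.depth <= 0:
            raise ClonevoError("SimConfig: depth must be > 0")
        for c in self.clones:
            for s in self.samples:
                v = c.ccf.get(s)
                if v is None or not (0.0 <= v <= 1.0):
                    raise ClonevoError(
                        f"SimConfig: clone {c.name} CCF in {s} must be in [0,1]"
                    )
            if c.parent is not None:
                parent = by_name.get(c.parent)
                if parent is None:
                    raise ClonevoError(f"SimConfig: unknown parent {c.parent}")
                for s in self.samples:
                    if c.ccf[s] > 0 and parent.ccf[s] == 0:
                        raise ClonevoError(
                            f"SimConfig: subset rule violated for {c.name} in {s}"
                        )
        # exact sum rule
        for c in self.clones:
            kids = [k for k in self.clones if k.parent == c.name]
            for s in self.samples:
                if sum(k.ccf[s] for k in kids) > c.ccf[s] + 1e-9:
                    raise ClonevoError(
                        f"SimConfig: sum rule violated at {c.name} in {s}"
                    )
        if self.wgd_clone is not None and self.wgd_clone not in by_name:
            raise ClonevoError(f"SimConfig: unknown wgd_clone {self.wgd_clone}")
        for a in self.cnas:
            for b in self.cnas:
                if (
                    a is not b
                    and a.chrom == b.chrom
                    and a.start <= b.end
                    and b.start <= a.end
                ):
                    raise ClonevoError(
                        f"SimConfig: CNAs {a.name} and {b.name} overlap"
                    )


@dataclass
class SimTruth:
    variant_clone: dict[str, str]
    clone_ccf: dict[str, dict[str, float]]
    clone_parent: dict[str, str | None]
    clone_sizes: dict[str, int]
    ploidy: dict[str, float]
    wgd: dict[str, bool]
    event_presence: dict[str, dict[str, bool]]
    event_states: dict[str, tuple[int, int]]
    timing: dict[str, str]  # event/clone -> interval string

    def to_json(self) -> str:
        d = asdict(self)
        d["event_states"] = {k: list(v) for k, v in self.event_states.items()}
        return json.dumps(d, indent=2, sort_keys=True)


def _genome() -> dict[str, int]:
    lengths: dict[str, int] = {}
    for arm in default_arm_table():
        lengths[arm.chrom] = max(lengths.get(arm.chrom, 0), arm.end)
    return lengths


def _baseline_state(chrom: str, sex: str, doubled: bool) -> tuple[int, int]:
    ncn = normal_copy_number(chrom, sex)
    if ncn == 1:
        return (2, 0) if doubled else (1, 0)
    return (2, 2) if doubled else (1, 1)


def build_segments(config: SimConfig) -> dict[str, list[Segment]]:
    """Per-sample segment lists: baseline (optionally doubled) plus the
    integer state of every CNA carried by a clone present in the sample."""
    genome = _genome()
    by_name = {c.name: c for c in config.clones}
    out: dict[str, list[Segment]] = {}
    for s in config.samples:
        doubled = (
            config.wgd_clone is not None
            and by_name[config.wgd_clone].ccf[s] > 0
        )
        overrides: dict[str, list[CNASpec]] = {}
        for cna in config.cnas:
            if any(by_name[c].ccf[s] > 0 for c in cna.clones):
                overrides.setdefault(cna.chrom, []).append(cna)
        segs: list[Segment] = []
        for chrom in sorted(genome, key=_chrom_key):
            if chrom == "chrY":
                continue
            if chrom == "chrX" and config.sex == "female":
                pass
            base = _baseline_state(chrom, config.sex, doubled)
            pos = 1
            for cna in sorted(overrides.get(chrom, []), key=lambda c: c.start):
                if cna.start > pos:
                    segs.append(Segment(chrom, pos, cna.start - 1, *base))
                segs.append(
                    Segment(chrom, cna.start, cna.end, cna.n_major, cna.n_minor)
                )
                pos = cna.end + 1
            if pos <= genome[chrom]:
                segs.append(Segment(chrom, pos, genome[chrom], *base))
        out[s] = segs
    return out


def _chrom_key(chrom: str) -> tuple[int, str]:
    name = chrom.removeprefix("chr")
    return (0, f"{int(name):02d}") if name.isdigit() else (1, name)


def _locate(segs: list[Segment], chrom: str, pos: int) -> Segment:
    for s in segs:
        if s.chrom == chrom and s.start <= pos <= s.end:
            return s
    raise ClonevoError(f"position {chrom}:{pos} not covered")


def simulate_case(
    config: SimConfig, out_dir: str | Path
) -> tuple[dict[str, Path], SimTruth]:
    """Generate one synthetic patient; write VCF + segments + panel + truth.

    Returns ({"vcf":…, "segments":…, "panel":…, "truth":…}, SimTruth).
    Byte-identical outputs for identical (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = _genome()
    segments = build_segments(config)
    by_name = {c.name: c for c in config.clones}
    gene_coords = {g.name: g for g in default_gene_table()}

    # clones on the path from root down to (and including) the WGD clone
    # acquired their SNVs before the doubling
    pre_wgd: set[str] = set()
    if config.wgd_clone is not None:
        node: str | None = config.wgd_clone
        while node is not None:
            pre_wgd.add(node)
            node = by_name[node].parent

    blocked = [(c.chrom, c.start, c.end) for c in config.cnas]
    chroms = [c for c in sorted(genome, key=_chrom_key) if c != "chrY"]
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    positions: set[tuple[str, int]] = set()
    variants: list[dict] = []  # chrom,pos,ref,alt,gene,clone

    def place(clone: CloneSpec, chrom: str, pos: int, gene: str | None) -> None:
        ref = _BASES[rng.integers(4)]
        alt = rng.choice([b for b in _BASES if b != ref])
        variants.append(
            dict(chrom=chrom, pos=int(pos), ref=ref, alt=str(alt), gene=gene,
                 clone=clone.name)
        )

    for clone in config.clones:
        n_random = clone.n_snvs - len(clone.marker_genes)
        if n_random < 0:
            raise ClonevoError(f"clone {clone.name}: more markers than SNVs")
        for gname in clone.marker_genes:
            g = gene_coords[gname]
            pos = int(rng.integers(g.start, g.end + 1))
            place(clone, g.chrom, pos, gname)
            positions.add((g.chrom, pos))
        placed = 0
        while placed < n_random:
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            pos = int(rng.integers(1, genome[chrom] + 1))
            if (chrom, pos) in positions:
                continue
            if any(c == chrom and s <= pos <= e for c, s, e in blocked):
                continue
            positions.add((chrom, pos))
            place(clone, chrom, pos, None)
            placed += 1

    variants.sort(key=lambda v: (_chrom_key(v["chrom"]), v["pos"]))

    # draw read counts
    sample_cols = config.samples + [NORMAL_ID]
    for v in variants:
        clone = by_name[v["clone"]]
        v["counts"] = {}
        for s in config.samples:
            seg = _locate(segments[s], v["chrom"], v["pos"])
            ncn = normal_copy_number(v["chrom"], config.sex)
            m = seg.n_major if v["clone"] in pre_wgd else 1
            rho = config.purity[s]
            denom = rho * seg.total + (1 - rho) * ncn
            vaf = clone.ccf[s] * rho * m / denom
            depth = int(rng.poisson(config.depth))
            alt = int(rng.binomial(depth, min(vaf, 1.0))) if depth else 0
            v["counts"][s] = (depth - alt, alt)
        depth_n = int(rng.poisson(config.depth))
        v["counts"][NORMAL_ID] = (depth_n, 0)

    paths: dict[str, Path] = {}
    vcf_path = out / "sim.vcf"
    _write_vcf(vcf_path, variants, sample_cols, genome)
    paths["vcf"] = vcf_path

    seg_path = out / "segments.tsv"
    with open(seg_path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tnMajor\tnMinor\n")
        for s in config.samples:
            for seg in segments[s]:
                fh.write(
                    f"{s}\t{seg.chrom}\t{seg.start}\t{seg.end}"
                    f"\t{seg.n_major}\t{seg.n_minor}\n"
                )
    paths["segments"] = seg_path

    panel_path = out / "panel.tsv"
    with open(panel_path, "w") as fh:
        fh.write("sample\tpurity\tdate\tsex\n")
        for s in config.samples:
            fh.write(
                f"{s}\t{config.purity[s]:.4f}\t{config.dates[s]:g}\t{config.sex}\n"
            )
    paths["panel"] = panel_path

    truth = _build_truth(config, segments, variants)
    truth_path = out / "truth.json"
    truth_path.write_text(truth.to_json() + "\n")
    paths["truth"] = truth_path
    return paths, truth


def _write_vcf(
    path: Path, variants: list[dict], sample_cols: list[str],
    genome: dict[str, int]
) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=clonevo-simulator"]
    for chrom in sorted(genome, key=_chrom_key):
        lines.append(f"##contig=<ID={chrom},length={genome[chrom]}>")
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_cols),
    ]
    for v in variants:
        info = f"GENE={v['gene']}" if v["gene"] else "."
        cols = [
            v["chrom"], str(v["pos"]), ".", v["ref"], v["alt"], ".", "PASS",
            info, "GT:AD:DP",
        ]
        for s in sample_cols:
            ref_n, alt_n = v["counts"][s]
            gt = "0/1" if alt_n > 0 else "0/0"
            cols.append(f"{gt}:{ref_n},{alt_n}:{ref_n + alt_n}")
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


def _build_truth(
    config: SimConfig,
    segments: dict[str, list[Segment]],
    variants: list[dict],
) -> SimTruth:
    by_name = {c.name: c for c in config.clones}
    panel = SamplePanel(
        samples=config.samples,
        purity=config.purity,
        dates=config.dates,
        sex=config.sex,
    )
    ploidy = {}
    wgd = {}
    for s in config.samples:
        call = copynumber.compute_ploidy(segments[s])
        ploidy[s] = round(call.ploidy, 4)
        wgd[s] = call.wgd
    event_presence: dict[str, dict[str, bool]] = {}
    event_states: dict[str, tuple[int, int]] = {}
    timed_inputs: list[GenomicEvent] = []
    for cna in config.cnas:
        pres = {
            s: any(by_name[c].ccf[s] > 0 for c in cna.clones)
            for s in config.samples
        }
        event_presence[cna.name] = pres
        event_states[cna.name] = (cna.n_major, cna.n_minor)
        timed_inputs.append(
            GenomicEvent(kind="cna", scope="sim", target=cna.name,
                         sample_presence=pres)
        )
    for clone in config.clones:
        pres = {s: clone.ccf[s] > 0 for s in config.samples}
        timed_inputs.append(
            GenomicEvent(kind="clone", scope="sim", target=clone.name,
                         sample_presence=pres)
        )
    timing = {
        te.label: te.interval_str() for te in time_events(timed_inputs, panel)
    }
    variant_ids = {}
    for v in variants:
        vid = f"{v['chrom']}:{v['pos']}:{v['ref']}>{v['alt']}"
        variant_ids[vid] = v["clone"]
    return SimTruth(
        variant_clone=variant_ids,
        clone_ccf={c.name: dict(c.ccf) for c in config.clones},
        clone_parent={c.name: c.parent for c in config.clones},
        clone_sizes={c.name: c.n_snvs for c in config.clones},
        ploidy=ploidy,
        wgd=wgd,
        event_presence=event_presence,
        event_states=event_states,
        timing=timing,
    )


# ---------------------------------------------------------------------------
# presets

PRESETS = ("case1_like", "case2_like", "null_single_clone")


def preset(name: str, depth: float | None = None, seed: int = 0) -> SimConfig:
    """A documented SimConfig for one of the bundled study designs."""
    if name == "case1_like":
        samples = ["NE_2012", "NE_2015", "DUCTAL_2015", "NE_2017"]
        cfg = SimConfig(
            samples=samples,
            dates={"NE_2012": 2012, "NE_2015": 2015, "DUCTAL_2015": 2015,
                   "NE_2017": 2017},
            purity={s: 0.7 for s in samples},
            depth=depth if depth is not None else 100.0,
            sex="male",
            clones=[
                CloneSpec("trunk", None,
                          {s: 1.0 for s in samples}, 53,
                          marker_genes=["PTEN"]),
                CloneSpec("ne_branch", "trunk",
                          {"NE_2012": 0.0, "NE_2015": 0.65,
                           "DUCTAL_2015": 0.0, "NE_2017": 0.75}, 40),
                CloneSpec("ductal_branch", "trunk",
                          {"NE_2012": 0.0, "NE_2015": 0.0,
                           "DUCTAL_2015": 0.8, "NE_2017": 0.0}, 30),
                CloneSpec("ne_2017_private", "ne_branch",
                          {"NE_2012": 0.0, "NE_2015": 0.0,
                           "DUCTAL_2015": 0.0, "NE_2017": 0.5}, 34),
                CloneSpec("ne_2012_sub", "trunk",
                          {"NE_2012": 0.45, "NE_2015": 0.0,
                           "DUCTAL_2015": 0.0, "NE_2017": 0.0}, 25),
            ],
            cnas=[
                CNASpec("AR_amp", "chrX", 67_000_000, 68_000_000, 10, 0,
                        clones=["ne_branch", "ductal_branch"]),
                CNASpec("1p_LOH", "chr1", 1, 123_400_000, 2, 0,
                        clones=["ductal_branch"]),
                CNASpec("6q_gain", "chr6", 59_800_001, 170_805_979, 3, 2,
                        clones=["ductal_branch"]),
            ],
            wgd_clone="trunk",
            seed=seed,
        )
        return cfg
    if name == "case2_like":
        samples = ["ADENO", "TNEPC"]
        return SimConfig(
            samples=samples,
            # synchronous regions: ordinal pseudo-dates give the required
            # total order (region order, not calendar time)
            dates={"ADENO": 1.0, "TNEPC": 2.0},
            purity={s: 0.65 for s in samples},
            depth=depth if depth is not None else 100.0,
            sex="male",
            clones=[
                CloneSpec("trunk", None, {"ADENO": 1.0, "TNEPC": 1.0}, 45),
                CloneSpec("adeno_private", "trunk",
                          {"ADENO": 0.6, "TNEPC": 0.0}, 30),
                CloneSpec("tnepc_private", "trunk",
                          {"ADENO": 0.0, "TNEPC": 0.7}, 35),
            ],
            cnas=[
                CNASpec("13q_LOH", "chr13", 17_700_001, 114_364_328, 1, 0,
                        clones=["trunk"]),
                CNASpec("3p_gain", "chr3", 1, 90_900_000, 2, 1,
                        clones=["tnepc_private"]),
                CNASpec("4p_LOH", "chr4", 1, 50_000_000, 1, 0,
                        clones=["tnepc_private"]),
                CNASpec("17p_LOH", "chr17", 1, 25_100_000, 1, 0,
                        clones=["tnepc_private"]),
            ],
            wgd_clone=None,
            seed=seed,
        )
    if name == "null_single_clone":
        samples = ["S1", "S2"]
        return SimConfig(
            samples=samples,
            dates={"S1": 1.0, "S2": 2.0},
            purity={s: 0.7 for s in samples},
            depth=depth if depth is not None else 100.0,
            sex="male",
            clones=[CloneSpec("trunk", None, {"S1": 1.0, "S2": 1.0}, 60)],
            cnas=[],
            wgd_clone=None,
            seed=seed,
        )
    raise ClonevoError(
        f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
    )


def three_cluster_config(
    seed: int, n_per_cluster: int = 100, depth: float = 100.0,
    purity: float = 0.7,
) -> SimConfig:
    """Two-sample, three-clone benchmark with pairwise CCF-profile
    separation of at least 0.3 in one sample — the standard recovery
    scenario for the clustering stage."""
    samples = ["S1", "S2"]
    return SimConfig(
        samples=samples,
        dates={"S1": 1.0, "S2": 2.0},
        purity={s: purity for s in samples},
        depth=depth,
        sex="male",
        clones=[
            CloneSpec("trunk", None, {"S1": 1.0, "S2": 1.0}, n_per_cluster),
            CloneSpec("sub1", "trunk", {"S1": 0.6, "S2": 0.1}, n_per_cluster),
            CloneSpec("sub2", "trunk", {"S1": 0.1, "S2": 0.55}, n_per_cluster),
        ],
        cnas=[],
        seed=seed,
    )


def case1_family_config(index: int, seed: int, depth: float = 150.0) -> SimConfig:
    """Five-clone longitudinal scenarios in the case-1 mold.

    Even indices give the four-sample preset (with its ductal branch);
    odd indices a three-sample purely neuroendocrine variant whose fifth
    clone is a second subclone on the NE branch.
    """
    if index % 2 == 0:
        return preset("case1_like", depth=depth, seed=seed)
    samples = ["NE_2012", "NE_2015", "NE_2017"]
    return SimConfig(
        samples=samples,
        dates={"NE_2012": 2012, "NE_2015": 2015, "NE_2017": 2017},
        purity={s: 0.7 for s in samples},
        depth=depth,
        sex="male",
        clones=[
            CloneSpec("trunk", None, {s: 1.0 for s in samples}, 53,
                      marker_genes=["PTEN"]),
            CloneSpec("ne_branch", "trunk",
                      {"NE_2012": 0.0, "NE_2015": 0.65, "NE_2017": 0.75}, 40),
            CloneSpec("ne_2017_private", "ne_branch",
                      {"NE_2012": 0.0, "NE_2015": 0.0, "NE_2017": 0.5}, 34),
            CloneSpec("ne_2012_sub", "trunk",
                      {"NE_2012": 0.45, "NE_2015": 0.0, "NE_2017": 0.0}, 25),
            CloneSpec("ne_2015_sub", "ne_branch",
                      {"NE_2012": 0.0, "NE_2015": 0.3, "NE_2017": 0.0}, 20),
        ],
        cnas=[
            CNASpec("AR_amp", "chrX", 67_000_000, 68_000_000, 10, 0,
                    clones=["ne_branch"]),
        ],
        wgd_clone="trunk",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# truth-based evaluation helpers

def map_clusters_to_clones(
    assignments: dict[str, str], truth: SimTruth
) -> dict[str, str]:
    """Majority-vote mapping inferred cluster -> true clone."""
    votes: dict[str, dict[str, int]] = {}
    for vid, cid in assignments.items():
        clone = truth.variant_clone.get(vid)
        if clone is None:
            continue
        votes.setdefault(cid, {}).setdefault(clone, 0)
        votes[cid][clone] += 1
    return {
        cid: max(sorted(v), key=lambda c: v[c]) for cid, v in votes.items()
    }


def topology_matches(tree, assignments: dict[str, str], truth: SimTruth) -> bool:
    """True iff the inferred clone tree equals the simulated one.

    Requires a one-to-one cluster/clone correspondence (majority vote) and
    identical parent relations under that correspondence.
    """
    mapping = map_clusters_to_clones(assignments, truth)
    placed = [c for c in tree.nodes]
    mapped = {c: mapping.get(c) for c in placed}
    if len(set(mapped.values())) != len(placed):
        return False
    if set(mapped.values()) != set(truth.clone_parent):
        return False
    for cid in placed:
        parent = tree.nodes[cid].parent
        true_parent = truth.clone_parent[mapped[cid]]
        if parent is None:
            if true_parent is not None:
                return False
        elif mapped[parent] != true_parent:
            return False
    return True


def mrca_matches(tree, assignments: dict[str, str], truth: SimTruth) -> bool:
    """True iff the inferred root cluster corresponds to the true root clone."""
    mapping = map_clusters_to_clones(assignments, truth)
    true_root = next(
        c for c, p in truth.clone_parent.items() if p is None
    )
    return mapping.get(tree.root) == true_root
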