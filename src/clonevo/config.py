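"""Run configuration: every tunable threshold in one place, YAML-loadable."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .types import ClonevoError

_RANGES = {
    "mrca_threshold": (0.5, 1.0),
    "presence_threshold": (0.0, 0.5),
    "epsilon": (0.0, 0.5),
    "amp_factor": (1.0, 10.0),
    "arm_gain_margin": (0.1, 2.0),
    "arm_frac": (0.5, 1.0),
    "ccf_cap": (1.0, 2.0),
}


@dataclass
class RunConfig:
    """All pipeline thresholds with their documented defaults.

    mrca_threshold : minimum per-sample CCF for a cluster to qualify as
        the MRCA (truncal) clone.
    presence_threshold : CCF center above which a clone counts as present
        in a sample.
    epsilon : tolerance on the pigeonhole sum rule, absorbing CCF noise.
    amp_factor / focal_max_len : focal amplification is total copy number
        >= amp_factor x (ploidy-scaled baseline) on a segment at most
        focal_max_len bp long.
    arm_gain_margin / arm_frac : arm gain/loss margin (copies) and the
        minimum arm fraction with minor allele 0 for arm LOH.
    sweeps / burn_in / grid_step / min_cluster_size : Gibbs sampler
        controls (see clustering module).
    min_depth : variants below this depth in any sample are excluded.
    """

    mrca_threshold: float = 0.9
    presence_threshold: float = 0.10
    epsilon: float = 0.15
    amp_factor: float = 2.0
    focal_max_len: int = 10_000_000
    arm_gain_margin: float = 0.6
    arm_frac: float = 0.9
    ccf_cap: float = 1.2
    min_depth: int = 10
    sweeps: int = 2000
    burn_in: int = 500
    grid_step: float = 0.01
    min_cluster_size: int | None = None
    skip_nonpass: bool = True
    multiallelic: str = "skip"
    seed: int = 0

    def __post_init__(self) -> None:
        for key, (lo, hi) in _RANGES.items():
            v = getattr(self, key)
            if not (lo <= v <= hi):
                raise ClonevoError(
                    f"config {key}={v} outside documented range [{lo}, {hi}]"
                )
        if self.burn_in >= self.sweeps:
            raise ClonevoError("burn_in must be < sweeps")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ClonevoError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def echo(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def run_hash(self) -> str:
        return hashlib.sha1(self.echo().encode()).hexdigest()[:12]
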