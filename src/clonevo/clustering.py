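"""Dirichlet-process clustering of SNVs by their multi-sample CCF profiles.

Each variant's alt count in each sample is modeled as
Binomial(depth, phi_ks * c_is), where phi_ks is the CCF of cluster k in
sample s and c_is = purity * m / (purity * cn + (1 - purity) * normal_cn)
converts a CCF into an expected VAF given the variant's local copy number
and multiplicity. Cluster CCFs live on a grid over [0, 1]; cluster
membership follows a Chinese-restaurant-process prior whose concentration
is resampled each sweep under a Gamma(1, 1) hyperprior.

The final hard assignment is taken from the posterior co-clustering
matrix (average-linkage cut at 0.5), which damps Monte-Carlo noise
relative to reading off the last sweep.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from ._gibbs import run_gibbs
from .types import ClonevoError, SamplePanel, VariantRecord, normal_copy_number

log = logging.getLogger(__name__)


@dataclass
class DPHyperparams:
    sweeps: int = 2000
    burn_in: int = 500
    grid_step: float = 0.01
    alpha_init: float = 1.0
    alpha_prior_shape: float = 1.0
    alpha_prior_rate: float = 1.0
    thin: int = 5
    min_cluster_size: int | None = None  # None -> max(5, 2% of SNVs)
    cut_height: float = 0.5


@dataclass
class ClusterResult:
    assignments: dict[str, str]  # variant_id -> cluster_id
    centers: dict[str, dict[str, float]]  # cluster_id -> sample -> CCF
    sizes: dict[str, int]
    trace: pd.DataFrame  # sweep, n_clusters, alpha
    seed: int

    def center_vector(self, cluster_id: str, samples: list[str]) -> np.ndarray:
        return np.array([self.centers[cluster_id][s] for s in samples])


def _cluster_labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    return [letters[i] if i < 26 else f"C{i + 1}" for i in range(n)]


def _loglik_grid(
    alt: np.ndarray, ref: np.ndarray, conv: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """(N, S, G) binomial log-likelihood with the choose() constant dropped."""
    p = conv[:, :, None] * grid[None, None, :]
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return alt[:, :, None] * np.log(p) + ref[:, :, None] * np.log1p(-p)


def prepare_inputs(
    ccf_matrix: pd.DataFrame,
    variants: list[VariantRecord],
    panel: SamplePanel,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (variant_ids, alt, ref, conversion factor) arrays, N x S.

    Only variants present in the CCF matrix (i.e. not excluded upstream)
    enter clustering. The conversion factor c_is maps a cluster CCF to an
    expected VAF and uses each sample's own multiplicity and copy number.
    """
    by_id = {v.variant_id: v for v in variants}
    samples = panel.samples
    ids = sorted(ccf_matrix["variant_id"].unique())
    n, s_count = len(ids), len(samples)
    alt = np.zeros((n, s_count))
    ref = np.zeros((n, s_count))
    conv = np.zeros((n, s_count))
    sub = ccf_matrix.set_index(["variant_id", "sample"])
    for i, vid in enumerate(ids):
        v = by_id[vid]
        for j, smp in enumerate(samples):
            r, a = v.counts[smp]
            alt[i, j], ref[i, j] = a, r
            row = sub.loc[(vid, smp)]
            rho = panel.purity[smp]
            ncn = normal_copy_number(v.chrom, panel.sex)
            denom = rho * row["total_cn"] + (1.0 - rho) * ncn
            conv[i, j] = rho * row["multiplicity"] / denom
    return ids, alt, ref, conv


def dp_cluster(
    ccf_matrix: pd.DataFrame,
    variants: list[VariantRecord],
    panel: SamplePanel,
    hyperparams: DPHyperparams | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Cluster SNVs across samples; returns hard assignments and centers."""
    hp = hyperparams or DPHyperparams()
    ids, alt, ref, conv = prepare_inputs(ccf_matrix, variants, panel)
    n = len(ids)
    if n == 0:
        raise ClonevoError("dp_cluster: no variants to cluster")
    if np.all(alt + ref == 0):
        raise ClonevoError("dp_cluster: all depths are zero")
    grid = np.arange(0.0, 1.0 + hp.grid_step / 2, hp.grid_step)
    loglik = _loglik_grid(alt, ref, conv, grid)

    if n == 1:
        log.warning("dp_cluster: single variant, returning singleton cluster")
        center = _posterior_centers(loglik, [np.array([0])], grid)[0]
        return ClusterResult(
            assignments={ids[0]: "A"},
            centers={"A": dict(zip(panel.samples, center))},
            sizes={"A": 1},
            trace=pd.DataFrame({"sweep": [], "n_clusters": [], "alpha": []}),
            seed=seed,
        )

    cocluster, n_kept, k_trace, alpha_trace, _ = run_gibbs(
        loglik,
        hp.sweeps,
        hp.burn_in,
        hp.thin,
        seed,
        hp.alpha_init,
        hp.alpha_prior_shape,
        hp.alpha_prior_rate,
    )
    sim = (cocluster + cocluster.T) / n_kept
    np.fill_diagonal(sim, 1.0)
    dist = squareform(1.0 - sim, checks=False)
    link = sch.linkage(dist, method="average")
    labels = sch.fcluster(link, t=hp.cut_height, criterion="distance")

    min_size = hp.min_cluster_size
    if min_size is None:
        min_size = max(5, int(np.ceil(0.02 * n)))
    member_idx = [np.where(labels == c)[0] for c in np.unique(labels)]
    member_idx = _merge_small(member_idx, loglik, grid, min_size)
    centers = _posterior_centers(loglik, member_idx, grid)

    # canonical order: descending total CCF, then descending center tuple
    order = sorted(
        range(len(member_idx)),
        key=lambda k: (-centers[k].sum(), tuple(-centers[k])),
    )
    names = _cluster_labels(len(order))
    assignments: dict[str, str] = {}
    center_map: dict[str, dict[str, float]] = {}
    sizes: dict[str, int] = {}
    for name, k in zip(names, order):
        for i in member_idx[k]:
            assignments[ids[i]] = name
        center_map[name] = {
            s: float(centers[k][j]) for j, s in enumerate(panel.samples)
        }
        sizes[name] = int(len(member_idx[k]))

    trace = pd.DataFrame(
        {"sweep": np.arange(hp.sweeps), "n_clusters": k_trace, "alpha": alpha_trace}
    )
    return ClusterResult(
        assignments=assignments,
        centers=center_map,
        sizes=sizes,
        trace=trace,
        seed=seed,
    )


def _posterior_centers(
    loglik: np.ndarray, member_idx: list[np.ndarray], grid: np.ndarray
) -> list[np.ndarray]:
    """Posterior-mean CCF per cluster per sample given hard memberships."""
    centers = []
    for idx in member_idx:
        w = loglik[idx].sum(axis=0)  # (S, G)
        w = w - w.max(axis=1, keepdims=True)
        post = np.exp(w)
        post /= post.sum(axis=1, keepdims=True)
        centers.append(post @ grid)
    return centers


def _merge_small(
    member_idx: list[np.ndarray],
    loglik: np.ndarray,
    grid: np.ndarray,
    min_size: int,
) -> list[np.ndarray]:
    """Fold clusters below ``min_size`` into the nearest big cluster center."""
    while True:
        sizes = np.array([len(m) for m in member_idx])
        big = [k for k in range(len(member_idx)) if sizes[k] >= min_size]
        small = [k for k in range(len(member_idx)) if sizes[k] < min_size]
        if not small:
            return member_idx
        if not big:
            # nothing qualifies: merge everything into the largest
            k_star = int(np.argmax(sizes))
            merged = np.concatenate([m for m in member_idx])
            del k_star
            return [np.sort(merged)]
        centers = _posterior_centers(loglik, member_idx, grid)
        k = small[0]
        dists = [np.linalg.norm(centers[k] - centers[b]) for b in big]
        target = big[int(np.argmin(dists))]
        merged = np.sort(np.concatenate([member_idx[target], member_idx[k]]))
        member_idx = [
            m for j, m in enumerate(member_idx) if j not in (k, target)
        ] + [merged]


def summarize_clusters(
    result: ClusterResult,
    ccf_matrix: pd.DataFrame,
    panel: SamplePanel,
    presence_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-cluster table: size, center and empirical mean CCF per sample,
    and a presence vector (center > ``presence_threshold``)."""
    long = ccf_matrix.copy()
    long["cluster"] = long["variant_id"].map(result.assignments)
    emp = long.pivot_table(index="cluster", columns="sample", values="ccf",
                           aggfunc="mean")
    rows = []
    for cid in sorted(result.centers):
        row: dict[str, object] = {"cluster": cid, "size": result.sizes[cid]}
        for s in panel.samples:
            center = result.centers[cid][s]
            row[f"center_{s}"] = center
            row[f"mean_ccf_{s}"] = (
                float(emp.loc[cid, s]) if cid in emp.index else float("nan")
            )
            row[f"present_{s}"] = center > presence_threshold
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_members(result: ClusterResult) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {c: [] for c in result.centers}
    for vid, cid in sorted(result.assignments.items()):
        members[cid].append(vid)
    return members
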