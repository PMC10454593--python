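import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from clonevo import ccf, clustering, io_formats, synthetic
from clonevo.synthetic import CloneSpec, SimConfig
from clonevo.types import ClonevoError


def _two_sample_config(clones, depth=100, seed=0, purity=0.9):
    samples = ["S1", "S2"]
    return SimConfig(
        samples=samples,
        dates={"S1": 1.0, "S2": 2.0},
        purity={s: purity for s in samples},
        depth=depth,
        sex="male",
        clones=clones,
        cnas=[],
        seed=seed,
    )


def _cluster_inputs(config, tmp_path, hp=None, seed=0):
    paths, truth = synthetic.simulate_case(config, tmp_path)
    panel = io_formats.read_panel(paths["panel"])
    segs = io_formats.read_segments(paths["segments"])
    variants = io_formats.read_vcf(paths["vcf"], panel.samples)
    matrix = ccf.build_ccf_matrix(variants, segs, panel)
    result = clustering.dp_cluster(matrix, variants, panel, hp, seed=seed)
    return result, matrix, panel, truth


class TestDpCluster:
    def test_single_component_recovered(self, tmp_path):
        cfg = _two_sample_config(
            [CloneSpec("trunk", None, {"S1": 1.0, "S2": 1.0}, 60)]
        )
        result, _, _, _ = _cluster_inputs(cfg, tmp_path)
        assert len(result.centers) == 1
        center = result.centers["A"]
        assert center["S1"] == pytest.approx(1.0, abs=0.03)
        assert center["S2"] == pytest.approx(1.0, abs=0.03)

    def test_two_clusters_high_ari(self, tmp_path):
        cfg = _two_sample_config(
            [
                CloneSpec("trunk", None, {"S1": 1.0, "S2": 1.0}, 50),
                CloneSpec("sub", "trunk", {"S1": 0.55, "S2": 0.0}, 50),
            ],
            seed=1,
        )
        result, _, _, truth = _cluster_inputs(cfg, tmp_path, seed=1)
        pred, true = [], []
        for vid, cid in result.assignments.items():
            pred.append(cid)
            true.append(truth.variant_clone[vid])
        assert adjusted_rand_score(true, pred) >= 0.95

    def test_same_seed_identical_result(self, tmp_path):
        cfg = _two_sample_config(
            [
                CloneSpec("trunk", None, {"S1": 1.0, "S2": 1.0}, 30),
                CloneSpec("sub", "trunk", {"S1": 0.5, "S2": 0.0}, 30),
            ],
            seed=4,
        )
        r1, m, panel, _ = _cluster_inputs(cfg, tmp_path / "a", seed=9)
        paths, _ = synthetic.simulate_case(cfg, tmp_path / "b")
        variants = io_formats.read_vcf(paths["vcf"], panel.samples)
        r2 = clustering.dp_cluster(m, variants, panel, seed=9)
        assert r1.assignments == r2.assignments
        assert r1.centers == r2.centers
        assert r1.trace.equals(r2.trace)

    def test_different_seeds_allowed_to_differ_but_consistent_k(self, tmp_path):
        cfg = _two_sample_config(
            [
                CloneSpec("trunk", None, {"S1": 1.0, "S2": 1.0}, 40),
                CloneSpec("sub", "trunk", {"S1": 0.0, "S2": 0.6}, 40),
            ],
            seed=2,
        )
        r1, m, panel, _ = _cluster_inputs(cfg, tmp_path, seed=1)
        paths, _ = synthetic.simulate_case(cfg, tmp_path / "c")
        variants = io_formats.read_vcf(paths["vcf"], panel.samples)
        r2 = clustering.dp_cluster(m, variants, panel, seed=2)
        assert len(r1.centers) == len(r2.centers) == 2

    def test_occupied_cluster_trace_stabilizes(self, tmp_path):
        cfg = _two_sample_config(
            [
                CloneSpec("trunk", None, {"S1": 1.0, "S2": 1.0}, 50),
                CloneSpec("sub", "trunk", {"S1": 0.55, "S2": 0.0}, 50),
            ],
            seed=3,
        )
        result, _, _, _ = _cluster_inputs(cfg, tmp_path, seed=3)
        hp = clustering.DPHyperparams()
        post = result.trace[result.trace["sweep"] >= hp.burn_in]["n_clusters"]
        assert abs(post.mean() - 2) <= 1

    def test_all_zero_depth_is_error(self):
        from clonevo.types import SamplePanel, Segment, VariantRecord

        panel = SamplePanel(["S1"], {"S1": 0.9}, {"S1": 1.0})
        variants = [
            VariantRecord("chr1", i, "A", "T", {"S1": (0, 0)})
            for i in (100, 200)
        ]
        matrix = pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in variants],
                "sample": ["S1", "S1"],
                "vaf": [0.0, 0.0],
                "multiplicity": [1, 1],
                "total_cn": [2, 2],
                "normal_cn": [2, 2],
                "ccf_raw": [0.0, 0.0],
                "ccf": [0.0, 0.0],
                "flag": ["", ""],
            }
        )
        with pytest.raises(ClonevoError, match="zero"):
            clustering.dp_cluster(matrix, variants, panel)


class TestSummarize:
    def test_presence_from_centers(self, case1_run):
        bundle = case1_run["bundle"]
        table = clustering.summarize_clusters(
            bundle.cluster_result, bundle.ccf_matrix, bundle.panel
        )
        root_row = table[table["cluster"] == bundle.tree.root].iloc[0]
        for s in bundle.panel.samples:
            assert root_row[f"present_{s}"]

    def test_presence_monotone_in_threshold(self, case1_run):
        bundle = case1_run["bundle"]
        prev = None
        for thr in np.arange(0.05, 0.31, 0.05):
            table = clustering.summarize_clusters(
                bundle.cluster_result, bundle.ccf_matrix, bundle.panel,
                presence_threshold=thr,
            )
            count = int(
                table[[c for c in table.columns if c.startswith("present_")]]
                .sum()
                .sum()
            )
            if prev is not None:
                assert count <= prev
            prev = count

    def test_canonical_order_invariant_to_relabeling(self, case1_run):
        """Relabeling clusters leaves the canonically sorted summary identical."""
        bundle = case1_run["bundle"]
        result = bundle.cluster_result
        renames = {c: f"Z{i}" for i, c in enumerate(sorted(result.centers))}
        shuffled = clustering.ClusterResult(
            assignments={v: renames[c] for v, c in result.assignments.items()},
            centers={renames[c]: v for c, v in result.centers.items()},
            sizes={renames[c]: v for c, v in result.sizes.items()},
            trace=result.trace,
            seed=result.seed,
        )
        samples = bundle.panel.samples

        def canonical(res):
            return sorted(
                (tuple(round(res.centers[c][s], 6) for s in samples),
                 res.sizes[c])
                for c in res.centers
            )

        assert canonical(result) == canonical(shuffled)
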