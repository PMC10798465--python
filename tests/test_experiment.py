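"""Sweep orchestration: record bookkeeping, byte-level determinism,
coverage stopping rule with a coupon-collector-style oracle, and the CLI."""

import json
import random

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import walkrecon as wr
from walkrecon.cli import main as cli_main
from walkrecon.experiment import DEFAULT_WALK_LENGTHS, SweepConfig


@pytest.fixture()
def tiny_config(tmp_path):
    return SweepConfig(
        networks=[{"model": "er", "n": 60, "avg_degree": 5, "id": "er-tiny"}],
        dynamics=("rw",),
        walk_lengths=(20, 50, 100),
        repetitions=2,
        metrics=("degree", "clustering", "closeness", "betweenness", "eccentricity", "coreness"),
        seed=7,
        out_dir=str(tmp_path / "out"),
    )


class TestRunSweep:
    def test_record_count(self, tiny_config):
        # 1 network x 1 dynamics x 3 lengths x 2 reps x 6 metrics
        records = wr.run_sweep(tiny_config)
        cells = records[records.record_type == "cell"]
        aggregates = records[records.record_type == "aggregate"]
        assert len(cells) == 36
        assert len(aggregates) == 18  # one per (dynamics, w, metric)

    def test_byte_identical_rerun(self, tiny_config, tmp_path):
        wr.run_sweep(tiny_config)
        first = (tmp_path / "out" / "records_er-tiny.csv").read_bytes()
        wr.run_sweep(tiny_config)
        assert (tmp_path / "out" / "records_er-tiny.csv").read_bytes() == first

    def test_manifest_written(self, tiny_config, tmp_path):
        wr.run_sweep(tiny_config)
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["seed"] == 7
        assert manifest["walk_lengths"] == [20, 50, 100]

    def test_aggregate_is_mean_over_defined_cells(self, tiny_config):
        records = wr.run_sweep(tiny_config)
        cells = records[(records.record_type == "cell") & (records.metric == "degree")]
        agg = records[(records.record_type == "aggregate") & (records.metric == "degree")]
        for _, row in agg.iterrows():
            sub = cells[(cells.w == row.w)]
            assert row.pearson == pytest.approx(sub.pearson.mean())

    def test_long_walk_limit_recovers_degree(self):
        # near-full coverage drives the degree correlation to 1
        config = SweepConfig(
            networks=[{"model": "er", "n": 100, "avg_degree": 5, "id": "er-lim"}],
            dynamics=("rw",),
            walk_lengths=(20000,),
            repetitions=2,
            metrics=("degree",),
            seed=1,
        )
        records = wr.run_sweep(config)
        agg = records[records.record_type == "aggregate"]
        assert float(agg.pearson.iloc[0]) > 0.99

    def test_lfr_rows_carry_partition_scores(self):
        config = SweepConfig(
            networks=[{"model": "lfr", "n": 300, "mu": 0.05, "avg_degree": 8, "id": "lfr-tiny"}],
            dynamics=("tsaw-edge",),
            walk_lengths=(2000,),
            repetitions=1,
            metrics=("degree",),
            seed=3,
        )
        records = wr.run_sweep(config)
        cells = records[records.record_type == "cell"]
        assert cells.nmi.notna().all() and cells.ari.notna().all()
        assert (cells.nmi > 0).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SweepConfig(repetitions=0)
        with pytest.raises(ValueError):
            SweepConfig(dynamics=("teleport",))

    def test_config_from_yaml(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            "networks:\n- model: er\n  n: 50\n  avg_degree: 4\n"
            "dynamics: [rw, rwd]\nwalk_lengths: [10, 20]\nrepetitions: 1\nseed: 5\n"
        )
        cfg = SweepConfig.from_file(cfg_path)
        assert cfg.dynamics == ("rw", "rwd") and cfg.seed == 5


class TestCellSeed:
    def test_deterministic_and_bounded(self):
        s = wr.cell_seed(3, "net", "rw", 100, 0)
        assert s == wr.cell_seed(3, "net", "rw", 100, 0)
        assert 0 <= s < 2**31

    def test_distinct_cells_get_distinct_seeds(self):
        seeds = {
            wr.cell_seed(3, "net", d, w, r)
            for d in wr.DYNAMICS
            for w in DEFAULT_WALK_LENGTHS
            for r in range(20)
        }
        assert len(seeds) == len(wr.DYNAMICS) * len(DEFAULT_WALK_LENGTHS) * 20


class TestCoverage:
    def test_full_coverage_on_two_node_path(self):
        g = nx.path_graph(2)
        seq, w_reached, reached = wr.run_until_coverage(g, "rw", 1.0, seed=1)
        assert reached and w_reached == 2

    def test_first_crossing_property(self, small_connected_er):
        target = 0.5
        n = small_connected_er.number_of_nodes()
        seq, w_reached, reached = wr.run_until_coverage(
            small_connected_er, "rw", target, seed=9
        )
        assert reached
        assert wr.knowledge_fraction(seq, n) >= target
        assert wr.knowledge_fraction(seq.prefix(w_reached - 1), n) < target

    def test_cap_flags_unreached_target(self, small_connected_er):
        _, _, reached = wr.run_until_coverage(
            small_connected_er, "rw", 1.0, seed=2, max_steps=3
        )
        assert not reached

    def test_mean_cover_time_matches_independent_simulator(self):
        """Uniform walk on K_10: cover-time oracle by direct simulation.

        On the complete graph the walk is a sequence of uniform picks among
        the 9 other nodes, so an independent one-line simulator gives the
        distribution of the sequence length needed to see all 10 nodes.
        """
        rnd = random.Random(123)
        n_sim = 1500

        def simulate_once():
            current, seen, length = 0, {0}, 1
            while len(seen) < 10:
                nxt = rnd.choice([v for v in range(10) if v != current])
                seen.add(nxt)
                current = nxt
                length += 1
            return length

        oracle = np.array([simulate_once() for _ in range(n_sim)], dtype=float)

        g = nx.complete_graph(10)
        ours = np.array(
            [
                wr.run_until_coverage(g, "rw", 1.0, seed=s)[1]
                for s in range(n_sim)
            ],
            dtype=float,
        )
        se = np.sqrt(oracle.var() / n_sim + ours.var() / n_sim)
        assert abs(ours.mean() - oracle.mean()) <= 3 * se

    def test_coverage_sweep_prefix_mode(self):
        config = SweepConfig(
            networks=[{"model": "er", "n": 80, "avg_degree": 5, "id": "er-cov"}],
            dynamics=("rw",),
            walk_lengths=(50, 200, 800),
            repetitions=2,
            metrics=("degree",),
            seed=4,
        )
        records = wr.run_coverage_sweep(config)
        cells = records[records.record_type == "cell"]
        for rep, sub in cells.groupby("repetition"):
            ordered = sub.sort_values("w")
            assert ordered.knowledge.is_monotonic_increasing


class TestCLI:
    def test_generate_walk_reconstruct_chain(self, tmp_path):
        runner = CliRunner()
        net_path = tmp_path / "net.edgelist"
        res = runner.invoke(
            cli_main,
            ["generate", "--model", "er", "--n", "80", "--avg-degree", "5",
             "--seed", "1", "--out", str(net_path)],
        )
        assert res.exit_code == 0, res.output
        seq_path = tmp_path / "seq.txt"
        res = runner.invoke(
            cli_main,
            ["walk", "--edgelist", str(net_path), "--dynamics", "tsaw-edge",
             "--length", "200", "--seed", "2", "--out", str(seq_path)],
        )
        assert res.exit_code == 0, res.output
        recon_path = tmp_path / "recon.edgelist"
        res = runner.invoke(
            cli_main, ["reconstruct", "--sequence", str(seq_path), "--out", str(recon_path)]
        )
        assert res.exit_code == 0, res.output
        recon = wr.load_edgelist(recon_path)
        original = wr.load_edgelist(net_path)
        assert set(map(frozenset, recon.edges())) <= set(map(frozenset, original.edges()))

    def test_sweep_command_writes_records(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "out"
        res = runner.invoke(
            cli_main,
            ["sweep", "--model", "er", "--n", "60", "--avg-degree", "5",
             "--dynamics", "rw", "--walk-lengths", "20,50", "--reps", "1",
             "--metrics", "degree", "--seed", "3", "--out", str(out_dir)],
        )
        assert res.exit_code == 0, res.output
        csvs = list(out_dir.glob("records_*.csv"))
        assert len(csvs) == 1
        df = pd.read_csv(csvs[0])
        assert (df.record_type == "cell").sum() == 2
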