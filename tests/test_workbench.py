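"""Configuration round trips, file I/O, fixtures, and the CLI surface."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from netham.cli import main
from netham.config import ConfigError, from_dict, load_config, save_config, to_dict
from netham.fibril_assay import TEMPLATES, fibril_fraction
from netham.fixtures import make_fixture
from netham.io import (
    load_graph,
    read_edgelist,
    read_graphml,
    write_edgelist,
    write_ga_ledger,
    write_graphml,
)
from netham.netstats import Graph


@pytest.fixture
def runner():
    return CliRunner()


class TestConfig:
    def test_empty_ga_block_gets_typical_defaults(self):
        cfg = from_dict({"model": {"preset": "2-ribbon"}, "template": "2-ribbon", "ga": {}})
        ga = cfg.ga_config()
        assert ga.reps == 16
        assert ga.noiseVarInit == 1.0
        assert ga.topFraction == 0.25
        assert ga.maxSurvivors == 20
        assert ga.minLineDensity == 1.2
        assert ga.childMax == 100
        assert ga.fixEdge and ga.fixEdgeValue == 100.0
        assert ga.smartVar and ga.smartPts and ga.useLineDensity

    def test_out_of_range_top_fraction_rejected(self):
        with pytest.raises(ConfigError, match="topFraction"):
            from_dict({"ga": {"topFraction": 1.5}})

    def test_unknown_keys_rejected_by_name(self):
        with pytest.raises(ConfigError, match="unknown keys"):
            from_dict({"model": {"preset": "1-ribbon"}, "ga": {"mutationRate": 0.5}})
        with pytest.raises(ConfigError, match="unknown keys"):
            from_dict({"nodes": 48})

    def test_explicit_model_round_trips(self, tmp_path):
        data = {
            "model": {
                "statistics": ["edges", "twostar", "nsp1"],
                "phi": {"edges": -107.22, "twostar": 37.33, "nsp1": 1.35},
                "kBT": 1.0,
            },
            "n_nodes": 256,
            "template": "1-ribbon",
            "master_seed": 7,
            "sampler": {"burnin_proposals": 1000},
        }
        cfg = from_dict(data)
        path = tmp_path / "run.yaml"
        save_config(cfg, path)
        cfg2 = load_config(path)
        assert to_dict(cfg) == to_dict(cfg2)
        assert cfg2.model.phi["twostar"] == pytest.approx(37.33)
        assert cfg2.sampler.burnin_proposals == 1000

    def test_custom_template_round_trips(self, tmp_path):
        data = {
            "template": {
                "name": "my-ladder",
                "strands": 2,
                "edge_offsets": [[0, 1, 0], [0, 0, 1], [1, 1, 1]],
            }
        }
        cfg = from_dict(data)
        save_config(cfg, tmp_path / "t.yaml")
        cfg2 = load_config(tmp_path / "t.yaml")
        assert cfg2.template == cfg.template

    def test_bad_statistic_name_rejected(self):
        with pytest.raises(ConfigError, match="model.statistics"):
            from_dict({"model": {"statistics": ["edges", "fourstar"], "phi": {}}})


class TestGraphIO:
    def test_edgelist_round_trip_preserves_isolated_nodes(self, tmp_path):
        g = Graph(7, [(0, 1), (2, 5)])
        p = tmp_path / "g.edgelist"
        write_edgelist(g, p)
        assert read_edgelist(p) == g

    def test_graphml_round_trip(self, tmp_path):
        g = Graph(6, [(0, 3), (1, 2), (4, 5)])
        p = tmp_path / "g.graphml"
        write_graphml(g, p)
        assert read_graphml(p) == g
        assert load_graph(p) == g


class TestFixtures:
    def test_fig2_statistics(self):
        from netham.netstats import StatSpec, compute_stats

        g = make_fixture("fig2")
        spec = StatSpec(["edges", "nsp1", "esp0", "cycle3"])
        assert compute_stats(g, spec) == [4, 2, 1, 1]

    def test_perfect_cyclic_fixture_scores_one(self):
        g = make_fixture("perfect-1ribbon-48-cyclic")
        assert g.n_nodes == 48
        assert fibril_fraction(g, TEMPLATES["1-ribbon"]) == 1.0

    def test_damaged_fixture_reproducible(self):
        a = make_fixture("damaged-2ribbon-24u-k3", seed=5)
        b = make_fixture("damaged-2ribbon-24u-k3", seed=5)
        perfect = make_fixture("perfect-2ribbon-24u-cyclic")
        assert a == b
        assert a.n_edges == perfect.n_edges - 3

    def test_cloud_fixture(self):
        cloud = make_fixture("cloud-2-ribbon-25-r2.0", seed=3)
        assert len(cloud) == 25
        center = np.array([-102.28, 25.2, -0.44, -5.56])
        for ind in cloud:
            assert np.linalg.norm(ind.phi - center) <= 2.0 + 1e-9

    def test_unknown_fixture(self):
        with pytest.raises(KeyError):
            make_fixture("perfect-4ribbon-10")
        with pytest.raises(KeyError):
            make_fixture("nonsense")


class TestCLI:
    def test_stats_command(self, runner, tmp_path):
        write_edgelist(make_fixture("fig2"), tmp_path / "g.edgelist")
        res = runner.invoke(
            main, ["stats", str(tmp_path / "g.edgelist"), "-s", "edges,nsp1,cycle3"]
        )
        assert res.exit_code == 0
        assert res.output.split() == ["edges", "4", "nsp1", "2", "cycle3", "1"]

    def test_assay_command_batch_csv(self, runner, tmp_path):
        import pandas as pd

        for i, name in enumerate(["perfect-1ribbon-12-cyclic", "perfect-1ribbon-10"]):
            write_edgelist(make_fixture(name), tmp_path / f"g{i}.edgelist")
        out = tmp_path / "assay.csv"
        res = runner.invoke(
            main,
            ["assay", str(tmp_path / "g0.edgelist"), str(tmp_path / "g1.edgelist"),
             "-t", "1-ribbon", "-o", str(out)],
        )
        assert res.exit_code == 0
        df = pd.read_csv(out)
        assert df["fraction"].tolist() == pytest.approx([1.0, 0.8])

    def test_simulate_writes_draws_stats_and_metadata(self, runner, tmp_path):
        import pandas as pd

        out = tmp_path / "sim"
        res = runner.invoke(
            main,
            ["simulate", "--preset", "1-ribbon", "-n", "20", "--reps", "3",
             "--seed", "4", "--burnin", "2000", "-o", str(out)],
        )
        assert res.exit_code == 0, res.output
        assert len(list(out.glob("draw_*.edgelist"))) == 3
        df = pd.read_csv(out / "stats.csv")
        assert len(df) == 3
        meta = json.loads((out / "run.json").read_text())
        assert meta["master_seed"] == 4 and "config_hash" in meta
        # statistics table matches a recount of the written graphs
        from netham.netstats import StatSpec, compute_stats

        g0 = read_edgelist(out / "draw_000.edgelist")
        spec = StatSpec(["edges", "twostar", "nsp1"])
        assert compute_stats(g0, spec) == [int(df.loc[0, n]) for n in spec.names]

    def test_simulate_rerun_is_byte_identical(self, runner, tmp_path):
        args = ["simulate", "--preset", "1-ribbon", "-n", "16", "--reps", "2",
                "--seed", "9", "--burnin", "1500"]
        runner.invoke(main, args + ["-o", str(tmp_path / "a")])
        runner.invoke(main, args + ["-o", str(tmp_path / "b")])
        assert (tmp_path / "a/stats.csv").read_bytes() == (tmp_path / "b/stats.csv").read_bytes()
        assert (
            (tmp_path / "a/draw_000.edgelist").read_bytes()
            == (tmp_path / "b/draw_000.edgelist").read_bytes()
        )

    def test_evolve_command_writes_ledger_and_log(self, runner, tmp_path):
        cfg = {
            "model": {"preset": "2-ribbon"},
            "template": "2-ribbon",
            "n_nodes": 16,
            "master_seed": 3,
            "ga": {
                "reps": 2,
                "max_generations": 1,
                "childMax": 6,
                "maxSurvivors": 4,
                "max_retries_per_generation": 1,
                "seed_radius": 4.0,
                "seed_count": 6,
            },
        }
        path = tmp_path / "evolve.yaml"
        path.write_text(yaml.safe_dump(cfg))
        out = tmp_path / "run"
        res = runner.invoke(main, ["evolve", "-c", str(path), "-o", str(out)])
        assert res.exit_code == 0, res.output
        import pandas as pd

        ledger = pd.read_csv(out / "ledger.csv")
        assert (out / "run.log").exists() and (out / "best_phi.txt").exists()
        assert len(ledger) >= 6  # every evaluated individual has a row

    def test_ledger_accounting_identity(self, tmp_path):
        from netham.evolution import GAConfig, run_evolution
        from netham.netstats import StatSpec

        spec = StatSpec(["edges", "twostar", "nsp1", "nsp2"])
        cfg = GAConfig(spec=spec, template="2-ribbon", reps=1, max_generations=2)
        target = np.array([100.0, 1.0, 1.0, 1.0])

        def fit(phi, i, c):
            free = list(c.free_dims)
            return [float(np.exp(-np.sum((phi[free] - target[free]) ** 2)))]

        hist = run_evolution(
            cfg,
            initial=[[100.0, 3.0, 3.0, 3.0], [100.0, -1.0, -1.0, -1.0]],
            fitness=fit,
        )
        df = write_ga_ledger(hist, cfg, tmp_path / "ledger.csv")
        assert len(df) == len(hist.individuals)
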