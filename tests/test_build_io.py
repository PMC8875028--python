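"""System construction, trajectory/table I/O, sweep driver and CLI."""

import io as _io
import math

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from vesiflex import Conformation, ModelParams, Schedule
from vesiflex.build import init_polymer, init_vesicle
from vesiflex.cli import main
from vesiflex.io import (
    measurements_frame,
    read_manifest,
    read_trajectory,
    write_trajectory_frame,
)
from vesiflex.sweep import SweepPlan, sweep


class TestInitVesicle:
    def test_circumradius_closed_form(self):
        xy = init_vesicle(61, 0.7)
        r = np.hypot(*xy.T)
        assert np.allclose(r, 0.7 / (2 * math.sin(math.pi / 61)), atol=1e-12)
        assert r[0] == pytest.approx(6.798, abs=1e-3)

    def test_all_edges_including_closure(self):
        xy = init_vesicle(61, 0.7)
        d = np.roll(xy, -1, axis=0) - xy
        np.testing.assert_allclose(np.hypot(d[:, 0], d[:, 1]), 0.7, atol=1e-12)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            init_vesicle(2, 0.7)


class TestInitPolymer:
    def test_straight_tangent_geometry(self, params):
        ves = init_vesicle(params.n_beads, params.l0)
        pol = init_polymer(params.n_beads, params.l0, ves,
                           np.random.default_rng(0), params=params)
        bl = np.hypot(*np.diff(pol, axis=0).T)
        np.testing.assert_allclose(bl, params.l0, atol=1e-12)
        assert math.hypot(*(pol[-1] - pol[0])) == pytest.approx(42.0)

    def test_clearance_from_vesicle(self, params):
        ves = init_vesicle(params.n_beads, params.l0)
        pol = init_polymer(params.n_beads, params.l0, ves,
                           np.random.default_rng(1), params=params)
        d = np.hypot(*(ves[:, None, :] - pol[None, :, :]).transpose(2, 0, 1))
        assert d.min() >= params.lj_rm - 1e-9

    def test_rotation_differs_between_seeds(self, params):
        ves = init_vesicle(params.n_beads, params.l0)
        a = init_polymer(params.n_beads, params.l0, ves, np.random.default_rng(2),
                         params=params)
        b = init_polymer(params.n_beads, params.l0, ves, np.random.default_rng(3),
                         params=params)
        assert not np.allclose(a, b)

    def test_random_walk_mode_is_valid_and_clear(self, small_params):
        p = small_params
        ves = init_vesicle(p.n_beads, p.l0)
        pol = init_polymer(p.n_beads, p.l0, ves, np.random.default_rng(4),
                           mode="random-walk", params=p)
        conf = Conformation(ves, pol)
        assert conf.is_valid(p)
        d = np.hypot(*(ves[:, None, :] - pol[None, :, :]).transpose(2, 0, 1))
        assert d.min() >= p.lj_rm - 1e-9
        # non-bonded polymer pairs respect the excluded-volume clearance
        dd = np.hypot(*(pol[:, None, :] - pol[None, :, :]).transpose(2, 0, 1))
        iu, ju = np.triu_indices(p.n_beads, k=2)
        assert dd[iu, ju].min() >= 0.9 * p.morse_rmin - 1e-9

    def test_unknown_mode_rejected(self, small_params):
        ves = init_vesicle(small_params.n_beads, small_params.l0)
        with pytest.raises(ValueError):
            init_polymer(small_params.n_beads, small_params.l0, ves,
                         np.random.default_rng(0), mode="teleport")


class TestTrajectoryIO:
    def test_frame_format_and_round_trip(self, random_conformation):
        buf = _io.StringIO()
        write_trajectory_frame(random_conformation, 1234, buf)
        lines = buf.getvalue().splitlines()
        n = random_conformation.n_beads
        assert len(lines) == 2 * n + 2
        assert lines[0] == str(2 * n)
        assert lines[1] == "mcs=1234"
        tags = [ln.split()[0] for ln in lines[2:]]
        assert tags == ["V"] * n + ["P"] * n  # vesicle lines first, fixed order
        assert all(ln.split()[3] == "0.0" for ln in lines[2:])

    def test_round_trip_precision(self, tmp_path, random_conformation):
        path = tmp_path / "t.xyz"
        with open(path, "w") as sink:
            write_trajectory_frame(random_conformation, 5, sink)
            write_trajectory_frame(random_conformation, 10, sink)
        frames = list(read_trajectory(path))
        assert [m for m, _ in frames] == [5, 10]
        np.testing.assert_allclose(frames[0][1].vesicle_xy,
                                   random_conformation.vesicle_xy, atol=1e-9)
        np.testing.assert_allclose(frames[1][1].polymer_xy,
                                   random_conformation.polymer_xy, atol=1e-9)


def tiny_schedule(**kw):
    kw.setdefault("total_mcs", 300)
    kw.setdefault("equil_mcs", 100)
    kw.setdefault("measure_every", 20)
    kw.setdefault("n_measurements", 10)
    kw.setdefault("n_runs", 2)
    kw.setdefault("base_seed", 0)
    return Schedule(**kw)


class TestSweep:
    def test_grid_summary_and_manifest(self, tmp_path):
        plan = SweepPlan(kappa_grid=(5.0, 20.0), eps_grid=(0.0, 2.0),
                         schedule=tiny_schedule(), output_dir=tmp_path / "sw")
        table = sweep(plan, params=ModelParams(n_bonds=10))
        assert len(table) == 4
        # no vesicle-polymer interaction at eps_vp = 0
        assert (table.loc[table.eps_vp == 0.0, "u_vl_mean"] == 0.0).all()
        man = read_manifest(tmp_path / "sw" / "manifest.json")
        assert len(man["state_points"]) == 4
        assert all(v["complete"] for v in man["state_points"].values())
        point = tmp_path / "sw" / "k5_e2"
        assert (point / "measurements.tsv").exists()
        assert (point / "correlation.tsv").exists()

    def test_refuses_overwrite_without_force(self, tmp_path):
        plan = SweepPlan(kappa_grid=(5.0,), eps_grid=(2.0,),
                         schedule=tiny_schedule(), output_dir=tmp_path / "sw")
        sweep(plan, params=ModelParams(n_bonds=8))
        with pytest.raises(FileExistsError):
            sweep(plan, params=ModelParams(n_bonds=8))
        sweep(plan, params=ModelParams(n_bonds=8), force=True)

    def test_summary_bytes_are_deterministic(self, tmp_path):
        outs = []
        for name in ("a", "b"):
            plan = SweepPlan(kappa_grid=(5.0,), eps_grid=(2.0,),
                             schedule=tiny_schedule(), output_dir=tmp_path / name)
            sweep(plan, params=ModelParams(n_bonds=8))
            outs.append((tmp_path / name / "summary.tsv").read_bytes())
        assert outs[0] == outs[1]


class TestCli:
    def run_args(self, out, seed=1):
        return ["run", "--kappa", "5", "--eps-vp", "2", "--n-bonds", "8",
                "--total-mcs", "300", "--equil-mcs", "100", "--measure-every", "20",
                "--n-measurements", "10", "--runs", "2", "--seed", str(seed),
                "--out", str(out)]

    def test_run_is_deterministic(self, tmp_path):
        runner = CliRunner()
        outs = []
        for name in ("r1", "r2"):
            res = runner.invoke(main, self.run_args(tmp_path / name))
            assert res.exit_code == 0, res.output
            outs.append((tmp_path / name / "measurements.tsv").read_bytes())
        assert outs[0] == outs[1]

    def test_missing_kappa_is_usage_error(self):
        res = CliRunner().invoke(main, ["run"])
        assert res.exit_code != 0
        assert "--kappa" in res.output

    def test_analyze_recomputes_observables(self, tmp_path, random_conformation):
        traj = tmp_path / "t.xyz"
        with open(traj, "w") as sink:
            write_trajectory_frame(random_conformation, 100, sink)
        out = tmp_path / "m.tsv"
        res = CliRunner().invoke(main, ["analyze", str(traj), "--out", str(out)])
        assert res.exit_code == 0, res.output
        table = pd.read_csv(out, sep="\t")
        assert list(table.columns) == ["run", "seed", "mcs", "u_vl", "r_ee",
                                       "asphericity", "shape_label"]
        assert len(table) == 1

    def test_sweep_and_plot(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(main, [
            "sweep", "--kappa-grid", "5", "--eps-grid", "2", "--n-bonds", "8",
            "--total-mcs", "300", "--equil-mcs", "100", "--measure-every", "20",
            "--n-measurements", "10", "--runs", "2", "--seed", "3",
            "--out", str(tmp_path / "sw")])
        assert res.exit_code == 0, res.output
        res = runner.invoke(main, ["plot", str(tmp_path / "sw")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "sw" / "trends.png").exists()


class TestMeasurementTable:
    def test_columns_and_lengths(self, small_params, random_conformation):
        from vesiflex.observables import measure

        rec = [measure(random_conformation, small_params, mcs) for mcs in (1, 2)]
        df = measurements_frame(rec, run=3, seed=17)
        assert list(df.columns) == ["run", "seed", "mcs", "u_vl", "r_ee",
                                    "asphericity", "shape_label"]
        assert df.run.eq(3).all() and df.seed.eq(17).all()
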