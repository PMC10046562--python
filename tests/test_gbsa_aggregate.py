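import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_run_mean_table
from tubulinsel.errors import AssemblyError, WindowError
from tubulinsel.gbsa_aggregate import (
    SnapshotG,
    assemble_snapshot_g,
    assemble_table,
    binding_energy_per_snapshot,
    estimate_binding_energy,
    select_last_window,
)

finite = st.floats(-1e3, 1e3, allow_nan=False)


class TestSnapshotAssembly:
    def test_all_zero_components(self):
        comp = dict.fromkeys(
            ["e_elec", "e_vdw", "e_internal", "e_gb", "e_sasa", "ts_solute"], 0.0
        )
        assert assemble_snapshot_g(comp) == 0.0

    def test_direct_sum_example(self):
        comp = {"e_elec": -3.0, "e_vdw": -2.0, "e_internal": 1.0,
                "e_gb": 2.0, "e_sasa": -0.5, "ts_solute": 0.0}
        assert assemble_snapshot_g(comp) == -2.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(e=st.tuples(finite, finite, finite, finite, finite, finite))
    def test_matches_brute_force_sum(self, e):
        names = ["e_elec", "e_vdw", "e_internal", "e_gb", "e_sasa", "ts_solute"]
        comp = dict(zip(names, e))
        oracle = e[0] + e[1] + e[2] + e[3] + e[4] - e[5]
        assert assemble_snapshot_g(comp) == pytest.approx(oracle, abs=1e-12)

    def test_missing_component_rejected(self):
        with pytest.raises(AssemblyError, match="e_vdw"):
            assemble_snapshot_g({"e_elec": 1.0})

    def test_ts_solute_subtracted(self):
        comp = {"e_elec": 0.0, "e_vdw": 0.0, "e_internal": 0.0,
                "e_gb": 0.0, "e_sasa": 0.0, "ts_solute": 3.0}
        assert assemble_snapshot_g(comp) == -3.0


class TestBindingEnergyPerSnapshot:
    def test_null_binding(self):
        g = SnapshotG("c", 1, 0.0, g_complex=-95.0, g_receptor=-60.0, g_ligand=-35.0)
        assert binding_energy_per_snapshot(g) == 0.0

    def test_direct_example(self):
        g = SnapshotG("c", 1, 0.0, g_complex=-100.0, g_receptor=-60.0, g_ligand=-35.0)
        assert binding_energy_per_snapshot(g) == -5.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(gc=finite, gr=finite, gl=finite)
    def test_matches_oracle_subtraction(self, gc, gr, gl):
        g = SnapshotG("c", 1, 0.0, gc, gr, gl)
        assert binding_energy_per_snapshot(g) == gc - (gr + gl)


class TestWindowSelection:
    def test_last_nanosecond_of_two(self, tiny_energy_table):
        # runs span 20..200 ps here; check the analogous 100 ps window
        sel = select_last_window(tiny_energy_table, window_ps=100.0)
        assert sel["time_ps"].min() > 100.0
        assert sel["time_ps"].max() == 200.0
        n_runs = tiny_energy_table.groupby("complex_id")["run"].nunique().sum()
        assert len(sel) == n_runs * 5 * 3  # 5 snapshots x 3 species per run

    def test_full_length_window_keeps_all(self, tiny_energy_table):
        sel = select_last_window(tiny_energy_table, window_ps=200.0)
        assert len(sel) == len(tiny_energy_table)

    def test_oversized_window_clamped(self, tiny_energy_table):
        sel = select_last_window(tiny_energy_table, window_ps=10_000.0)
        assert len(sel) == len(tiny_energy_table)

    def test_nonpositive_window_rejected(self, tiny_energy_table):
        with pytest.raises(WindowError):
            select_last_window(tiny_energy_table, window_ps=0.0)


class TestEstimateBindingEnergy:
    def test_replicate_mean_and_sd_oracle(self):
        run_means = [-40.0, -44.0, -42.0, -46.0, -39.0]
        table = make_run_mean_table(run_means)
        est = estimate_binding_energy(table, window_ps=20.0)[0]
        assert est.dg_mean == pytest.approx(statistics.fmean(run_means), abs=1e-10)
        assert est.dg_mean == pytest.approx(-42.2, abs=1e-10)
        assert est.dg_sd == pytest.approx(statistics.stdev(run_means), abs=1e-10)
        assert est.dg_sd == pytest.approx(2.8635642, abs=1e-6)
        assert est.n_runs == 5

    def test_identical_run_means_zero_sd(self):
        est = estimate_binding_energy(make_run_mean_table([-5.0] * 4))[0]
        assert est.dg_sd == 0.0 and not est.degenerate

    def test_single_run_flagged_degenerate(self):
        est = estimate_binding_energy(make_run_mean_table([-5.0]))[0]
        assert est.dg_sd == 0.0 and est.degenerate

    def test_binding_energy_depends_only_on_differences(self, tiny_energy_table):
        """Balanced baseline shifts (complex shift = receptor + ligand shifts)
        leave every estimate unchanged; an unbalanced common shift c moves
        ΔG by exactly −c."""
        base = estimate_binding_energy(tiny_energy_table, window_ps=100.0)

        balanced = tiny_energy_table.copy()
        is_complex = balanced["species"] == "complex"
        balanced.loc[is_complex, "e_elec"] += 100.0
        balanced.loc[balanced["species"] == "receptor", "e_elec"] += 70.0
        balanced.loc[balanced["species"] == "ligand", "e_elec"] += 30.0
        for b, s in zip(base, estimate_binding_energy(balanced, window_ps=100.0)):
            assert s.dg_mean == pytest.approx(b.dg_mean, abs=1e-9)
            assert s.dg_sd == pytest.approx(b.dg_sd, abs=1e-9)

        common = tiny_energy_table.copy()
        common["e_elec"] = common["e_elec"] + 123.456  # all three species
        for b, s in zip(base, estimate_binding_energy(common, window_ps=100.0)):
            assert s.dg_mean == pytest.approx(b.dg_mean - 123.456, abs=1e-9)

    def test_equal_run_counts_mean_over_runs_equals_pooled_mean(self, tiny_energy_table):
        est = estimate_binding_energy(tiny_energy_table, window_ps=200.0)
        snap = assemble_table(tiny_energy_table)
        for e in est:
            pooled = snap[snap["complex_id"] == e.complex_id]["dg_bind"].mean()
            assert e.dg_mean == pytest.approx(pooled, abs=1e-12)

    def test_matches_naive_iteration_oracle(self, tiny_energy_table):
        """Recompute estimates by dict-based iteration over raw rows."""
        window = 100.0
        table = tiny_energy_table
        by_key = {}
        for row in table.to_dict("records"):
            g = (row["e_elec"] + row["e_vdw"] + row["e_internal"]
                 + row["e_gb"] + row["e_sasa"] - row["ts_solute"])
            by_key.setdefault(
                (row["complex_id"], row["run"], row["time_ps"]), {}
            )[row["species"]] = g
        run_dgs = {}
        tmax = {}
        for (cid, run, t), _ in by_key.items():
            tmax[(cid, run)] = max(tmax.get((cid, run), -1e30), t)
        for (cid, run, t), gs in by_key.items():
            if t > tmax[(cid, run)] - window:
                dg = gs["complex"] - (gs["receptor"] + gs["ligand"])
                run_dgs.setdefault(cid, {}).setdefault(run, []).append(dg)
        expected = {
            cid: statistics.fmean(
                statistics.fmean(v) for v in runs.values()
            )
            for cid, runs in run_dgs.items()
        }
        for est in estimate_binding_energy(table, window_ps=window):
            assert est.dg_mean == pytest.approx(expected[est.complex_id], abs=1e-10)
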