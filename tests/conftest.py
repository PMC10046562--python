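import pandas as pd
import pytest

from tubulinsel.synthetic_data import SimulationSpec, generate_energy_table


@pytest.fixture
def tiny_energy_table() -> pd.DataFrame:
    """Noise-free 2-complex table: 3 runs x 10 snapshots at 20 ps."""
    spec = SimulationSpec(
        true_dg={
            ("gatastatin", "gamma", "gamma", "gtp"): -27.1,
            ("gatastatin", "alpha_beta", "bIII", "colchicine_ab"): -35.0,
        },
        n_runs=3,
        run_length_ps=200.0,
        snapshot_interval_ps=20.0,
        seed=11,
    )
    return generate_energy_table(spec)


def make_run_mean_table(run_means, dg_per_snapshot=None) -> pd.DataFrame:
    """Energy table with one complex whose per-run snapshot ΔG is constant.

    Builds two snapshots per run so windowing and averaging are exercised;
    every snapshot of run i carries binding energy run_means[i-1].
    """
    rows = []
    for run, dg in enumerate(run_means, start=1):
        for t in (10.0, 20.0):
            for species, g in (
                ("receptor", -100.0),
                ("ligand", -10.0),
                ("complex", -110.0 + dg),
            ):
                rows.append({
                    "complex_id": "cpx", "ligand": "lig", "target": "gamma",
                    "isotype": "gamma", "site": "gtp", "run": run,
                    "time_ps": t, "species": species,
                    "e_elec": g, "e_vdw": 0.0, "e_internal": 0.0,
                    "e_gb": 0.0, "e_sasa": 0.0, "ts_solute": 0.0,
                })
    return pd.DataFrame(rows)
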