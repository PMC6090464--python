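"""Sweep orchestration: row bookkeeping, determinism, critical-point localization."""

import numpy as np
import pandas as pd
import pytest

from conncrit import (
    EnsembleSpec,
    SweepConfig,
    SweepResultTable,
    locate_critical_point,
    plot_curves,
    run_sweep,
    write_sweep_table,
)
from conncrit.errors import ConncritError, ParameterError
from conncrit.sweep import PLOT_KINDS

SMALL_GRID = tuple(np.round(np.arange(-1.0, 2.01, 0.5), 10))


@pytest.fixture(scope="module")
def small_table():
    config = SweepConfig(
        source=EnsembleSpec(n_regions=40, n_subjects=3, seed=21),
        n_grid=SMALL_GRID,
        p_values=(0.05,),
        n_trials=200,
        master_seed=21,
    )
    return run_sweep(config)


def test_row_counts(small_table):
    n_cells = len(SMALL_GRID)
    assert len(small_table.subject_rows) == 3 * n_cells
    assert len(small_table.ensemble_rows) == n_cells


def test_identical_subjects_average_to_themselves():
    config = SweepConfig(
        source=EnsembleSpec(n_regions=30, n_subjects=2, noise_sd=0.0, seed=3),
        n_grid=(0.0, 0.5, 1.0),
        p_values=(0.05,),
        n_trials=200,
        master_seed=3,
    )
    table = run_sweep(config)
    # topology columns are seed-independent, so subjects agree exactly
    for col in ("w_t", "lcc_fraction", "clustering", "ks_boundary_power"):
        merged = table.subject_rows.pivot_table(index="n", columns="subject_id", values=col)
        np.testing.assert_allclose(merged.iloc[:, 0], merged.iloc[:, 1], atol=1e-12)
        np.testing.assert_allclose(
            merged.mean(axis=1),
            table.ensemble_rows.sort_values("n")[col],
            atol=1e-12,
        )


def test_ensemble_rows_are_subject_means(small_table):
    recomputed = (
        small_table.subject_rows.groupby(["n", "p"])["m"].mean().reset_index()
    )
    merged = recomputed.merge(small_table.ensemble_rows, on=["n", "p"], suffixes=("_a", "_b"))
    np.testing.assert_allclose(merged["m_a"], merged["m_b"], atol=1e-14)


def test_sweep_is_byte_deterministic(tmp_path):
    config = SweepConfig(
        source=EnsembleSpec(n_regions=30, n_subjects=2, seed=8),
        n_grid=(0.0, 1.0),
        p_values=(0.02,),
        n_trials=100,
        master_seed=8,
    )
    paths = []
    for tag in ("a", "b"):
        table = run_sweep(config)
        paths.append(write_sweep_table(table.to_frame(), tmp_path / f"{tag}.csv"))
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_high_threshold_cells_go_missing_not_fatal(caplog):
    config = SweepConfig(
        source=EnsembleSpec(n_regions=30, n_subjects=1, seed=5),
        n_grid=(0.0, 8.0),  # n = 8 leaves almost no surviving weights
        p_values=(0.05,),
        n_trials=100,
        master_seed=5,
        models=("boundary_power",),
    )
    with caplog.at_level("INFO"):
        table = run_sweep(config)
    high = table.ensemble_rows[table.ensemble_rows["n"] == 8.0]
    assert np.isnan(high["ks_boundary_power"]).all()
    assert len(table.ensemble_rows) == 2


def test_empty_source_rejected():
    with pytest.raises(ConncritError):
        run_sweep(SweepConfig(source=[], n_grid=(0.0, 1.0)))


def test_invalid_grid_rejected():
    with pytest.raises(ParameterError):
        SweepConfig(n_grid=(1.0, 0.5))
    with pytest.raises(ParameterError):
        SweepConfig(p_values=(0.01, 0.01))


class TestLocateCriticalPoint:
    def test_monotone_curve_flagged_as_boundary_peak(self):
        rows = pd.DataFrame({
            "n": [0.0, 0.5, 1.0, 1.5],
            "p": 0.05,
            "w_t": [0.1, 0.2, 0.3, 0.4],
            "m": [0.4, 0.3, 0.2, 0.1],
            "lcc_fraction": [1.0, 0.9, 0.5, 0.2],
            "clustering": [0.5, 0.4, 0.3, 0.2],
            "delta_clustering": [0.1, 0.1, 0.1, np.nan],
            "ks_boundary_power": [0.3, 0.2, 0.1, 0.05],
        })
        table = SweepResultTable(subject_rows=rows, ensemble_rows=rows)
        summary = locate_critical_point(table, 0.05)
        assert summary.n_mi == 0.0
        assert not summary.mi_peak_interior
        assert summary.n_ks == 1.5

    def test_ties_break_toward_smaller_n(self):
        rows = pd.DataFrame({
            "n": [0.0, 0.5, 1.0],
            "p": 0.05,
            "w_t": [0.1, 0.2, 0.3],
            "m": [0.2, 0.2, 0.1],
            "lcc_fraction": [1.0, 1.0, 0.5],
            "clustering": [0.5, 0.5, 0.1],
            "delta_clustering": [0.0, 0.4, np.nan],
            "ks_boundary_power": [0.1, 0.1, 0.2],
        })
        table = SweepResultTable(subject_rows=rows, ensemble_rows=rows)
        summary = locate_critical_point(table, 0.05)
        assert summary.n_mi == 0.0
        assert summary.n_ks == 0.0
        assert summary.n_delta_c == 0.5

    def test_duplicated_rows_leave_summary_unchanged(self, small_table):
        doubled = SweepResultTable(
            subject_rows=small_table.subject_rows,
            ensemble_rows=pd.concat(
                [small_table.ensemble_rows, small_table.ensemble_rows]
            ),
        )
        a = locate_critical_point(small_table, 0.05)
        b = locate_critical_point(doubled, 0.05)
        assert (a.n_mi, a.n_delta_c, a.n_ks) == (b.n_mi, b.n_delta_c, b.n_ks)

    def test_missing_p_rejected(self, small_table):
        with pytest.raises(ParameterError):
            locate_critical_point(small_table, 0.3)


class TestPlots:
    def test_all_seven_kinds_render(self, small_table, tmp_path):
        files = [plot_curves(small_table, kind, tmp_path / f"{kind}.png")
                 for kind in PLOT_KINDS]
        assert len(files) == 7
        assert all(f.exists() and f.stat().st_size > 0 for f in files)

    def test_unknown_kind_rejected(self, small_table, tmp_path):
        with pytest.raises(ParameterError):
            plot_curves(small_table, "fig9", tmp_path / "x.png")

    def test_empty_table_rejected(self, tmp_path):
        empty = SweepResultTable(
            subject_rows=pd.DataFrame(), ensemble_rows=pd.DataFrame()
        )
        with pytest.raises(ConncritError):
            plot_curves(empty, "fig1", tmp_path / "x.png")


def test_lcc_curves_non_increasing_per_subject(small_table):
    for _, g in small_table.subject_rows.groupby("subject_id"):
        vals = g.drop_duplicates("n").sort_values("n")["lcc_fraction"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-15)
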