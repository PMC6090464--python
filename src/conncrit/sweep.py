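"""Threshold-sweep orchestration over a connectome ensemble.

For every subject matrix and every threshold multiplier ``n`` the sweep
computes the cut-off ``w_t``, the binarized network, its largest-
component fraction and transitivity, distribution fits of the surviving
``|w|`` values, and — for every activation density ``p`` — the Monte-
Carlo mutual-information score of the ternary transfer simulation.
Subject curves are averaged into ensemble curves, on which the critical
point is localized as the coincidence of the mutual-information peak,
the transitivity-drop (delta-C) peak, and the boundary-power KS-distance
minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import distfit
from .errors import ConncritError, InsufficientDataError, ParameterError
from .info import estimate_network_mi
from .io import ConnectivityMatrix, read_connectivity_matrix
from .network import binarize, clustering_coefficient, compute_threshold, largest_component_fraction
from .synthetic import EnsembleSpec, generate_ensemble

logger = logging.getLogger(__name__)

DEFAULT_N_GRID = tuple(np.round(np.arange(-2.0, 4.0 + 1e-9, 0.1), 10))
DEFAULT_P_VALUES = (0.001, 0.01, 0.1)

_FITTERS = {
    "boundary_power": distfit.fit_boundary_power,
    "truncated_power_law": distfit.fit_truncated_power_law,
}

#: spawn-key prefix of per-cell stimulus seeds
_KEY_MI = 100


@dataclass(frozen=True)
class SweepConfig:
    """Grid, trial count, seed, and input source of one sweep run."""

    source: EnsembleSpec | str | Path | Sequence[ConnectivityMatrix] = field(
        default_factory=EnsembleSpec
    )
    n_grid: tuple[float, ...] = DEFAULT_N_GRID
    p_values: tuple[float, ...] = DEFAULT_P_VALUES
    n_trials: int = 1000
    master_seed: int = 0
    models: tuple[str, ...] = ("boundary_power", "truncated_power_law")

    def __post_init__(self) -> None:
        ns = list(self.n_grid)
        if len(ns) < 1 or any(b <= a for a, b in zip(ns, ns[1:])):
            raise ParameterError("n_grid must be strictly increasing")
        if len(set(self.p_values)) != len(self.p_values):
            raise ParameterError("p_values must be distinct")
        unknown = set(self.models) - set(_FITTERS)
        if unknown:
            raise ParameterError(f"unknown distribution models: {sorted(unknown)}")


@dataclass(frozen=True)
class SweepResultTable:
    """Per-subject rows and ensemble-mean rows, keyed by (subject, n, p)."""

    subject_rows: pd.DataFrame
    ensemble_rows: pd.DataFrame
    config: SweepConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        mean_rows = self.ensemble_rows.copy()
        mean_rows.insert(0, "subject_id", "ensemble_mean")
        return pd.concat([self.subject_rows, mean_rows], ignore_index=True)


@dataclass(frozen=True)
class CriticalPointSummary:
    """Locations of the three transition markers on the n grid, plus diagnostics."""

    p: float
    n_mi: float
    n_delta_c: float
    n_ks: float
    w_t_mi: float
    lcc_at_mi: float
    grid_step: float
    steps_mi_delta_c: float
    steps_mi_ks: float
    mi_peak_value: float
    mi_peak_interior: bool


def _load_matrices(source) -> list[ConnectivityMatrix]:
    if isinstance(source, EnsembleSpec):
        return generate_ensemble(source)
    if isinstance(source, (str, Path)):
        paths = sorted(Path(source).glob("*"))
        matrices = [
            read_connectivity_matrix(p)
            for p in paths
            if p.is_file() and p.suffix in ("", ".txt", ".csv", ".tsv", ".dat")
        ]
        if not matrices:
            raise ConncritError(f"no matrix files found under {source}")
        return matrices
    matrices = list(source)
    if not matrices:
        raise ConncritError("empty input: no connectivity matrices")
    return matrices


def _cell_seed(master_seed: int, subject: int, n_idx: int, p_idx: int) -> int:
    ss = np.random.SeedSequence(
        master_seed, spawn_key=(_KEY_MI, subject, n_idx, p_idx)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(config: SweepConfig) -> SweepResultTable:
    """Run the full (subject, n, p) grid; deterministic given ``master_seed``.

    Per-cell failures (e.g. too few surviving weights for a distribution
    fit at high thresholds) are recorded as missing cells with a logged
    reason; they do not abort the sweep.
    """
    matrices = _load_matrices(config.source)
    rows = []
    for s_idx, matrix in enumerate(matrices):
        topo = []  # per-n topology and fits, shared across p
        for n_idx, n_mult in enumerate(config.n_grid):
            spec = compute_threshold(matrix, n_mult)
            w_t_eff = max(spec.w_t, 0.0)  # Eq.-style threshold clamped at 0
            net = binarize(matrix, w_t_eff)
            cell = {
                "n": float(n_mult),
                "w_t": spec.w_t,
                "lcc_fraction": largest_component_fraction(net),
                "clustering": clustering_coefficient(net),
                "_net": net,
            }
            surviving = matrix.offdiag_abs()
            surviving = surviving[surviving > w_t_eff]
            for model in config.models:
                try:
                    fit = _FITTERS[model](surviving, w_t_eff)
                    cell[f"ks_{model}"] = fit.ks_distance
                except (InsufficientDataError, ConncritError) as exc:
                    logger.info(
                        "subject %s n=%.2f: %s fit skipped (%s)",
                        matrix.subject_id, n_mult, model, exc,
                    )
                    cell[f"ks_{model}"] = np.nan
            topo.append(cell)
        # delta-C along the threshold sweep, indexed from the smallest n
        for i in range(len(topo)):
            topo[i]["delta_clustering"] = (
                topo[i]["clustering"] - topo[i + 1]["clustering"]
                if i + 1 < len(topo)
                else np.nan
            )
        for n_idx, cell in enumerate(topo):
            net = cell.pop("_net")
            for p_idx, p in enumerate(config.p_values):
                mi = estimate_network_mi(
                    net,
                    p,
                    n_trials=config.n_trials,
                    seed=_cell_seed(config.master_seed, s_idx, n_idx, p_idx),
                )
                row = {"subject_id": matrix.subject_id, "p": p, "m": mi.network_mean}
                row.update(cell)
                rows.append(row)
    subject_rows = pd.DataFrame(rows)
    value_cols = [
        c for c in subject_rows.columns if c not in ("subject_id", "n", "p")
    ]
    ensemble_rows = (
        subject_rows.groupby(["n", "p"], as_index=False)[value_cols]
        .mean()
        .sort_values(["n", "p"], kind="mergesort")
        .reset_index(drop=True)
    )
    return SweepResultTable(
        subject_rows=subject_rows, ensemble_rows=ensemble_rows, config=config
    )


def locate_critical_point(table: SweepResultTable, p: float) -> CriticalPointSummary:
    """Localize the three transition markers for one activation density.

    Returns the grid locations of the mutual-information argmax, the
    delta-C argmax, and the boundary-power KS argmin (ties broken toward
    smaller n), with their pairwise distances in grid steps.
    """
    df = table.ensemble_rows
    sub = df[np.isclose(df["p"], p)].sort_values("n", kind="mergesort")
    if len(sub) < 3:
        raise ParameterError(
            f"need >= 3 grid points for p={p}, found {len(sub)}"
        )

    def _arg(series: pd.Series, n: pd.Series, best):
        mask = series.notna()
        if not mask.any():
            raise ConncritError(f"all-missing column for p={p}")
        vals = series[mask].to_numpy()
        ns = n[mask].to_numpy()
        idx = int(best(vals))  # numpy arg* returns the first = smallest n
        return float(ns[idx]), idx, mask.sum()

    n_arr = sub["n"]
    n_mi, i_mi, k_mi = _arg(sub["m"], n_arr, np.argmax)
    n_dc, _, _ = _arg(sub["delta_clustering"], n_arr, np.argmax)
    n_ks, _, _ = _arg(sub["ks_boundary_power"], n_arr, np.argmin)
    grid = n_arr.to_numpy()
    distinct = np.unique(grid)
    step = float(np.median(np.diff(distinct))) if distinct.size > 1 else float("nan")
    at_mi = sub.iloc[int(np.flatnonzero(grid == n_mi)[0])]
    return CriticalPointSummary(
        p=float(p),
        n_mi=n_mi,
        n_delta_c=n_dc,
        n_ks=n_ks,
        w_t_mi=float(at_mi["w_t"]),
        lcc_at_mi=float(at_mi["lcc_fraction"]),
        grid_step=step,
        steps_mi_delta_c=abs(n_mi - n_dc) / step,
        steps_mi_ks=abs(n_mi - n_ks) / step,
        mi_peak_value=float(at_mi["m"]),
        mi_peak_interior=bool(0 < i_mi < k_mi - 1),
    )


# --------------------------------------------------------------------------
# figure analogues

PLOT_KINDS = ("fig1", "fig2", "fig3", "fig4a", "fig4b", "fig5", "fig6")


def plot_curves(table: SweepResultTable, kind: str, path: str | Path) -> Path:
    """Render one figure analogue of the sweep to an image file.

    Kinds: ``fig1`` m vs n per p; ``fig2`` LCC vs n; ``fig3`` m vs LCC
    per p; ``fig4a`` C vs n; ``fig4b`` delta-C vs LCC; ``fig5`` KS vs n
    per model; ``fig6`` KS vs LCC per model.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if kind not in PLOT_KINDS:
        raise ParameterError(f"unknown plot kind {kind!r}; choose from {PLOT_KINDS}")
    df = table.ensemble_rows
    if df.empty:
        raise ConncritError("empty sweep table: nothing to plot")
    needed = {
        "fig1": ["m", "n", "p"],
        "fig2": ["lcc_fraction", "n"],
        "fig3": ["m", "lcc_fraction", "p"],
        "fig4a": ["clustering", "n"],
        "fig4b": ["delta_clustering", "lcc_fraction"],
        "fig5": ["ks_boundary_power", "n"],
        "fig6": ["ks_boundary_power", "lcc_fraction"],
    }[kind]
    missing = [c for c in needed if c not in df.columns or df[c].isna().all()]
    if missing:
        raise ConncritError(f"sweep table is missing columns {missing} for {kind}")

    fig, ax = plt.subplots(figsize=(5.5, 4))
    ks_cols = sorted(c for c in df.columns if c.startswith("ks_"))
    if kind == "fig1":
        for p, g in df.groupby("p"):
            ax.plot(g["n"], g["m"], marker=".", label=f"p={p:g}")
        ax.set_xlabel("threshold multiplier n")
        ax.set_ylabel("mean mutual information m (nats)")
        ax.legend()
    elif kind == "fig2":
        g = df.drop_duplicates("n")
        ax.plot(g["n"], g["lcc_fraction"], marker=".")
        ax.set_xlabel("threshold multiplier n")
        ax.set_ylabel("largest component fraction")
    elif kind == "fig3":
        for p, g in df.groupby("p"):
            ax.plot(g["lcc_fraction"], g["m"], marker=".", ls="", label=f"p={p:g}")
        ax.set_xlabel("largest component fraction")
        ax.set_ylabel("mean mutual information m (nats)")
        ax.legend()
    elif kind == "fig4a":
        g = df.drop_duplicates("n")
        ax.plot(g["n"], g["clustering"], marker=".")
        ax.set_xlabel("threshold multiplier n")
        ax.set_ylabel("transitivity C")
    elif kind == "fig4b":
        g = df.drop_duplicates("n")
        ax.plot(g["lcc_fraction"], g["delta_clustering"], marker=".", ls="")
        ax.set_xlabel("largest component fraction")
        ax.set_ylabel("delta C")
    elif kind == "fig5":
        g = df.drop_duplicates("n")
        for c in ks_cols:
            ax.plot(g["n"], g[c], marker=".", label=c.removeprefix("ks_"))
        ax.set_xlabel("threshold multiplier n")
        ax.set_ylabel("KS distance D")
        ax.legend()
    else:  # fig6
        g = df.drop_duplicates("n")
        for c in ks_cols:
            ax.plot(g["lcc_fraction"], g[c], marker=".", ls="", label=c.removeprefix("ks_"))
        ax.set_xlabel("largest component fraction")
        ax.set_ylabel("KS distance D")
        ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
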