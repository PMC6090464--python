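"""Render the figure analogues of the sweep into results/figures/.

Reads results/sweep_table.csv and writes seven images: mutual information
vs threshold per density, largest-component fraction vs threshold, mutual
information vs component size, transitivity and its drop, and the KS
distances of both weight-distribution models.
"""

import importlib
from pathlib import Path

import conncrit as cc

RESULTS = Path(__file__).resolve().parent.parent / "results"

load_table = importlib.import_module("03_critical_points").load_table  # noqa: E402


def main() -> None:
    table = load_table(RESULTS / "sweep_table.csv")
    fig_dir = RESULTS / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    for kind in cc.sweep.PLOT_KINDS:
        path = cc.plot_curves(table, kind, fig_dir / f"{kind}.png")
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
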