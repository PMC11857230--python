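"""Predict the full grid, rank conditions both ways, select the consensus.

Refits the reduced model per analyte, interpolates all 225 conditions
(clamping negative predictions to zero), ranks by total predicted area and
by top-3 counts, and reports the consensus extraction condition.  Writes
results/ranking.csv.
"""

from pathlib import Path

from dllmeopt.design import ModelSpec
from dllmeopt.modeling import backward_eliminate, fit_model
from dllmeopt.optimization import (
    consensus_select,
    predict_grid,
    rank_top3_counts,
    rank_total_area,
    ranking_report,
)
from dllmeopt.pipeline import read_design_csv, read_responses_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    design = read_design_csv(OUT / "design.csv")
    tab = read_responses_csv(OUT / "responses.csv")
    models = []
    for analyte in tab["analyte"].unique():
        try:
            full = fit_model(tab, design, ModelSpec(), analyte=analyte)
        except ValueError:
            continue
        models.append(backward_eliminate(full, alpha=0.05))

    grid = predict_grid(models)
    n_clamped = int(grid.clamped.to_numpy().sum())
    print(f"predicted {len(grid.conditions)} conditions × {len(models)} analytes "
          f"({n_clamped} negative predictions clamped to 0)")

    by_total = rank_total_area(grid, k=10)
    by_counts = rank_top3_counts(grid, top_m=3, k=10)
    print("top 3 by total predicted area:")
    for c in by_total[:3]:
        print(f"  {c.x1} {c.x2:.0f} µL + {c.x3} {c.x4:.0f} µL")
    print("top 3 by number of analytes with top-3 efficiency:")
    for c, n in by_counts[:3]:
        print(f"  {c.x1} {c.x2:.0f} µL + {c.x3} {c.x4:.0f} µL  ({n} analytes)")

    consensus = consensus_select(by_total, by_counts)
    print(f"consensus optimum: {consensus.x1} {consensus.x2:.0f} µL + "
          f"{consensus.x3} {consensus.x4:.0f} µL")

    ranking_report(grid).to_csv(OUT / "ranking.csv", index=False)
    print(f"wrote {OUT / 'ranking.csv'}")


if __name__ == "__main__":
    main()
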