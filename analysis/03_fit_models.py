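"""Fit and reduce each analyte's response-surface model.

For every analyte with detected observations: OLS on the full model
(intercept, 4 main effects, 2 quadratics, 3 interactions → 25 columns),
then backward elimination of non-significant terms (α = 0.05, weak
heredity).  Writes results/models.csv and prints the retained-term summary.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from dllmeopt.design import ModelSpec
from dllmeopt.modeling import backward_eliminate, fit_model
from dllmeopt.pipeline import read_design_csv, read_responses_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    design = read_design_csv(OUT / "design.csv")
    tab = read_responses_csv(OUT / "responses.csv")
    spec = ModelSpec()
    rows = []
    term_counts: Counter[str] = Counter()
    excluded = []
    for analyte in tab["analyte"].unique():
        try:
            full = fit_model(tab, design, spec, analyte=analyte)
        except ValueError:
            excluded.append(analyte)
            continue
        m = backward_eliminate(full, alpha=0.05)
        retained = [t for t in m.spec.terms if t != "intercept"]
        term_counts.update(retained)
        rows.append((analyte, ";".join(retained), m.residual_sd, m.r_squared, m.n_obs))
    df = pd.DataFrame(rows, columns=["analyte", "retained_terms", "residual_sd",
                                     "r_squared", "n_obs"])
    df.to_csv(OUT / "models.csv", index=False)
    print(f"fitted {len(df)} analytes; excluded (all non-detect): {excluded}")
    print("term retention frequency across analytes:")
    for term, n in term_counts.most_common():
        print(f"  {term:14s} {n}/{len(df)}")
    eo = df[df["analyte"] == "ethyl octanoate"].iloc[0]
    print(f"ethyl octanoate retained: {eo.retained_terms} (r² = {eo.r_squared:.3f})")
    print(f"wrote {OUT / 'models.csv'}")


if __name__ == "__main__":
    main()
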