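"""Simulate triplicate GC-MS responses for the designed experiment.

Loads results/design.csv, draws the packaged 36-analyte ground-truth set
(the recovered ethyl octanoate surface verbatim plus 35 seeded randomized
surfaces; three analytes are never detected), and simulates replicate peak
areas at 5% CV.  Writes results/responses.csv.
"""

from pathlib import Path

from dllmeopt.pipeline import read_design_csv, stage_seeds, write_responses_csv
from dllmeopt.synthetic import SyntheticStudyConfig, generate_design_responses, make_random_truths

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    design = read_design_csv(OUT / "design.csv")
    seed = stage_seeds(SEED)["responses"]
    truths = make_random_truths(seed=seed, noise_cv=0.05)
    cfg = SyntheticStudyConfig(seed=seed, n_replicates=3)
    tab = generate_design_responses(design, truths, cfg)
    n_nd = int(tab["non_detect"].sum())
    print(f"simulated {len(tab)} rows ({design.n_runs} runs × 3 replicates × "
          f"{tab['analyte'].nunique()} analytes); {n_nd} non-detects")
    write_responses_csv(tab, OUT / "responses.csv")
    print(f"wrote {OUT / 'responses.csv'}")


if __name__ == "__main__":
    main()
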