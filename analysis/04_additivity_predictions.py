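"""Additive anchor rule: measured vs predicted partitioning free energies.

Using the measured single-anchor values (sC -0.4, sT +1.9 kBT), the
additive rule predicts each multi-anchor construct's free energy as the
sum of its anchors' contributions.  This script compares the predictions
against the measured populations quantified in 02: the double-cholesterol
duplex (dC = sC+sC) agrees with its prediction, while the chimeric sC+sT
construct sits below its additive sum (nonadditive stabilisation in Lo),
so its prediction overestimates the measured free energy.

Run from the repository root:  python analysis/04_additivity_predictions.py
"""

from pathlib import Path

from guvpart.io import read_records
from guvpart.pipeline import default_config, run_analyze

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    records = read_records(RESULTS / "records.csv")
    cfg = default_config()
    cfg["analyze"]["predictions"] = [
        {"name": "dC", "anchors": ["sC", "sC"]},
        {"name": "sC+sT", "anchors": ["sC", "sT"]},
    ]
    outputs = run_analyze(cfg, records, RESULTS)
    import pandas as pd

    preds = pd.read_csv(outputs["predictions"])
    for _, row in preds.iterrows():
        print(
            f"{row.design:6s} predicted {row.dG_pred:+.2f} kBT, "
            f"measured {row.dG_measured:+.2f} kBT, "
            f"nonadditivity {row.nonadditivity:+.2f} kBT"
        )
    print(f"figures: {outputs['box_scatter']}, {outputs['measured_vs_predicted']}")


if __name__ == "__main__":
    main()
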