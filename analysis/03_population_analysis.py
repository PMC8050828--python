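"""Population statistics: summaries, pairwise tests, radius independence.

From results/records.csv this computes per-construct summaries (mean, SD
and quartiles of f_p_Lo; per-vesicle free energies), Mann-Whitney
comparisons between constructs, and the radius-independence check
(Spearman rho of f against vesicle radius pooled over all constructs is
expected to be small: partitioning is a property of the anchors, not of
vesicle size).

Run from the repository root:  python analysis/03_population_analysis.py
"""

import dataclasses
from pathlib import Path

import pandas as pd

from guvpart.io import read_records
from guvpart.quantify import PartitionRecord
from guvpart.stats import compare_populations, radius_independence, summarize

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    records = read_records(RESULTS / "records.csv")
    labels = sorted(records.population_label.unique())

    summaries = []
    for label in labels:
        sub = records[records.population_label == label]
        s = summarize(list(sub.f_p_Lo), label)
        summaries.append(dataclasses.asdict(s))
        print(f"{label:6s} n={s.n:2d} f={s.mean_f:.3f}+/-{s.sd_f:.3f} "
              f"dG={s.mean_dG:+.2f}+/-{s.sd_dG:.2f} kBT")
    pd.DataFrame(summaries).drop(columns="flags").to_csv(
        RESULTS / "population_summary.csv", index=False
    )

    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            fa = records.loc[records.population_label == a, "f_p_Lo"]
            fb = records.loc[records.population_label == b, "f_p_Lo"]
            u, p = compare_populations(list(fa), list(fb))
            rows.append({"a": a, "b": b, "U": u, "p_two_sided": p})
            print(f"Mann-Whitney {a} vs {b}: U={u:.0f}, p={p:.2e}")
    pd.DataFrame(rows).to_csv(RESULTS / "comparisons.csv", index=False)

    recs = [
        PartitionRecord(i, r.I_Lo, r.I_Ld, r.f_p_Lo, r.radius_px, r.separation_score)
        for i, r in records[records.population_label == "sC"].iterrows()
    ]
    rho, p = radius_independence(recs)
    print(f"radius independence (sC): Spearman rho={rho:+.3f}, p={p:.2f}")
    pd.DataFrame([{"population": "sC", "spearman_rho": rho, "p": p}]).to_csv(
        RESULTS / "radius_independence.csv", index=False
    )


if __name__ == "__main__":
    main()
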