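"""Render synthetic GUV populations for the four duplex constructs.

One population per anchoring motif — single cholesterol (sC), double
cholesterol (dC), single tocopherol (sT) and the chimera (sC+sT) — each at
its measured partitioning free energy, imaged under the default conditions
(shot noise, 100-count background, 2 px PSF).  Images go to scratch/ (they
are regenerable); the ground-truth tables go to results/.

Run from the repository root:  python analysis/01_simulate_populations.py
"""

from pathlib import Path

from guvpart.pipeline import default_config, run_simulate

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "simulated"
RESULTS = ROOT / "results"

# measured single-construct free energies (kBT) on the ternary mixture
CONDITIONS = {"sC": -0.4, "dC": -0.8, "sT": 1.9, "sC+sT": 0.9}
SEED = 2026


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for i, (label, dg) in enumerate(CONDITIONS.items()):
        cfg = default_config()
        cfg["simulate"]["n_frames"] = 12
        cfg["simulate"]["vesicles_per_frame"] = 1
        cfg["simulate"]["population"]["dG_true"] = dg
        cfg["simulate"]["population"]["n_vesicles"] = 1
        cfg["simulate"]["imaging"]["frame_size"] = [192, 192]
        cfg["simulate"]["population_label"] = label
        out = SCRATCH / label.replace("+", "_")
        manifest = run_simulate(cfg, out, seed=SEED + i)
        print(f"{label:6s} dG_true={dg:+.1f} kBT -> {manifest.parent} "
              f"({cfg['simulate']['n_frames']} frames)")
    print(f"ground truth CSVs live beside the TIFFs under {SCRATCH}")


if __name__ == "__main__":
    main()
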