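"""Correspondence-analysis ordination of all genotyped individuals.

Projects individuals onto the first two chi-square-metric axes of the
allele-count matrix and checks the hybrid group's intermediacy between the
parental centroids on axis 1. Writes coordinates and a scatter plot.
"""

import sys
from pathlib import Path

import numpy as np

from hybridorigin import fca_of_table, read_genepop

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_genepop(ROOT / "data" / "genotypes.gen")
    out = ROOT / "ordination"
    out.mkdir(parents=True, exist_ok=True)
    res = fca_of_table(table, n_axes=2)
    df = res.coordinates.reset_index(names="individual")
    df.insert(1, "population", table.populations)
    df.to_csv(out / "fca_coordinates.tsv", sep="\t", index=False)

    frac = res.inertia_fraction
    print(f"axis 1 inertia: {100 * frac[0]:.1f}%, axis 2: {100 * frac[1]:.1f}% "
          f"(two axes: {100 * frac.sum():.1f}%)")
    pops = np.array(table.populations)
    ax1 = res.coordinates.axis1.to_numpy()
    cents = {p: ax1[pops == p].mean() for p in table.population_names}
    for p, c in cents.items():
        print(f"  {p}: axis-1 centroid = {c:+.3f}")
    lo, hi = sorted((cents["histrionica"], cents["lehmanni"]))
    print("hybrid group centroid is "
          + ("INTERMEDIATE" if lo < cents["pHYB"] < hi else "NOT intermediate")
          + " between the parental centroids on axis 1")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        for pop, marker in zip(table.population_names, "osD"):
            m = pops == pop
            ax.scatter(ax1[m], res.coordinates.axis2.to_numpy()[m],
                       label=pop, marker=marker, alpha=0.7)
        ax.set_xlabel(f"axis 1 ({100 * frac[0]:.1f}%)")
        ax.set_ylabel(f"axis 2 ({100 * frac[1]:.1f}%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "fca_scatter.png", dpi=150)
        print(f"scatter plot written to {out / 'fca_scatter.png'}")
    except ImportError:
        print("matplotlib not available; skipped the scatter plot")


if __name__ == "__main__":
    sys.exit(main())
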