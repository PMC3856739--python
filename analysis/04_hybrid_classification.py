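"""Genealogical-class posteriors for the putative-hybrid population.

Classifies every hybrid-group individual into pure-A / pure-B / F1 / F2 /
backcross categories using parental allele frequencies estimated from the
two parental samples, and summarizes the class composition.
"""

import sys
from pathlib import Path

from hybridorigin import classify, posterior_frame, read_genepop

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_genepop(ROOT / "data" / "genotypes.gen")
    out = ROOT / "hybrid_classification"
    out.mkdir(parents=True, exist_ok=True)
    post = classify(
        table.restrict_population("pHYB"),
        table.restrict_population("histrionica"),
        table.restrict_population("lehmanni"),
    )
    df = posterior_frame(post)
    df.to_csv(out / "posteriors.tsv", sep="\t", index=False)

    print(f"classified {len(df)} putative-hybrid individuals")
    print("modal class counts:")
    print(df.modal_class.value_counts().to_string())
    print(f"median F2 posterior: {df.F2.median():.3f}")
    print(f"median hybrid (F1+F2+BC) posterior: "
          f"{(df.F1 + df.F2 + df.BC_A + df.BC_B).median():.3f}")


if __name__ == "__main__":
    sys.exit(main())
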