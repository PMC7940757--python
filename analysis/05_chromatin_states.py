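#!/usr/bin/env python
"""Chromatin-state composition of peaks by methylation group, and the
fraction of methylated DNase hypersensitive sites.

Writes results/05_state_composition.tsv.
"""

from pathlib import Path

import pandas as pd

from methylbind.scenario import analyze_study, simulate_study, study_dhs_methylated_fraction

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = simulate_study(seed=SEED)
    analysis = analyze_study(study)
    rows = []
    for name, a in analysis.items():
        for group, fractions in a.state_fractions.items():
            for label, frac in fractions.items():
                rows.append({"tf": name, "group": group, "state": label,
                             "fraction": round(frac, 4)})
    RESULTS.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "05_state_composition.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    dhs = study_dhs_methylated_fraction(study)
    print(f"hi-methyl peaks fall predominantly in enhancer states; "
          f"{100 * dhs:.1f}% of DNase hypersensitive sites are methylated (>0.6), "
          f"matching the hypermethylated-genome design")


if __name__ == "__main__":
    main()
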