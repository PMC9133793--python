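"""Generate the default roving-oddball design and tabulate its arithmetic.

Emits the 600-train pseudo-randomized sequence (3,000 trials over stimuli
A-E) and verifies the published count structure: 600 deviants, 600/600/600/
400/200 standards at positions 2-6, all 20 ordered stimulus transitions at
near-equal frequency, and 120 trains headed by each stimulus.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from oddwave.design import DesignSpec, generate_design, position_counts, transition_counts

OUT = Path(__file__).resolve().parent.parent / "results" / "design"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = generate_design(DesignSpec(seed=2024))
    design.save(OUT / "design.tsv")

    pos = position_counts(design)
    pd.Series(pos, name="n_trials").rename_axis("position").to_csv(OUT / "position_counts.tsv", sep="\t")
    tc = transition_counts(design)
    rows = [{"from": a, "to": b, "count": n} for (a, b), n in sorted(tc.items())]
    pd.DataFrame(rows).to_csv(OUT / "transition_counts.tsv", sep="\t", index=False)

    heads = Counter(stim for stim, _ in design.trains)
    print(f"{design.n_trials} trials in {len(design.trains)} trains")
    print(f"position counts: {pos}")
    print(f"transition types: {len(tc)} (counts {min(tc.values())}-{max(tc.values())})")
    print(f"trains per stimulus: {dict(sorted(heads.items()))}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
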