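"""Packaged reference tables.

Currently a single table: the published group-level behavioral
characterization of the Control and Dyslexia cohorts (age-based standard
scores of reading, phonological and cognitive assessments; group means, SDs,
and the printed pooled-variance t and Cohen's d).  Used to regression-test
``pooled_t_and_d`` against every printed row and by the behavioral analysis
driver.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .inference import pooled_t_and_d

__all__ = ["behavioral_group_stats", "recompute_behavioral_contrasts"]


def behavioral_group_stats() -> pd.DataFrame:
    """Group means/SDs per assessment subtest, with the printed t and d."""
    with resources.files("oddwave.data").joinpath("behavioral_scores.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def recompute_behavioral_contrasts() -> pd.DataFrame:
    """Recompute pooled t, two-sided p, and Cohen's d for every subtest row."""
    table = behavioral_group_stats()
    out = []
    for _, row in table.iterrows():
        t, p, d = pooled_t_and_d(
            row.control_mean, row.control_sd, int(row.n_control),
            row.dyslexia_mean, row.dyslexia_sd, int(row.n_dyslexia),
        )
        out.append({**row, "t": t, "p": p, "d": d})
    return pd.DataFrame(out)
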