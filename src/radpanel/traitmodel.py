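"""Gene dosage to seed-oil phenotype: group comparisons and expected
trait directions.

Erucic acid (C22:1) is additive in functional FAE1 copy number, so
deletion lines drop and duplication lines gain erucic content (oleic
moves oppositely as its elongation substrate pool changes).  FAD2
desaturates oleic to linoleic acid, so loss of functional FAD2.A5 lowers
PUFA (linoleic) content and raises the monounsaturates (oleic, erucic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["DEFAULT_TIERS", "significance_label", "compare_groups",
           "predict_direction"]

#: adjusted-p thresholds and their labels, most stringent first
DEFAULT_TIERS = ((0.00005, "****"), (0.005, "**"))


def significance_label(p_adj: float, tiers=DEFAULT_TIERS) -> str:
    for threshold, label in sorted(tiers):
        if p_adj < threshold:
            return label
    return "ns"


def compare_groups(table: pd.DataFrame, analyte: str,
                   comparisons: list[tuple[str, str]],
                   tiers=DEFAULT_TIERS) -> pd.DataFrame:
    """Welch two-sample t tests with Benjamini-Hochberg adjustment.

    ``table`` needs columns ``group`` and the analyte (mol%);
    ``comparisons`` lists (group, control_group) pairs tested within one
    analysis (one BH family).  Returns group_a, group_b, mean_diff
    (group minus control), t, p, p_adj and the significance label.
    """
    if not comparisons:
        raise ValueError("at least one comparison is required")
    groups = {g: table.loc[table.group == g, analyte].to_numpy(dtype=float)
              for pair in comparisons for g in pair}
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    rows = []
    for a, b in comparisons:
        xa, xb = groups[a], groups[b]
        if np.allclose(xa.var(ddof=1), 0) and np.allclose(xb.var(ddof=1), 0) \
                and np.isclose(xa.mean(), xb.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append((a, b, float(xa.mean() - xb.mean()), float(t), float(p)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "t", "p"])
    out["p_adj"] = multipletests(out.p, method="fdr_bh")[1]
    out["label"] = [significance_label(p, tiers) for p in out.p_adj]
    return out


_DIRECTIONS = {
    "fae1_loss": {"erucic": -1, "oleic": +1},
    "fae1_gain": {"erucic": +1},
    "fad2a5_loss": {"linoleic": -1, "oleic": +1, "erucic": +1},
}


def predict_direction(genotype_change: str) -> dict[str, int]:
    """Expected sign of change per fatty acid for a genotype change.

    Accepted changes: ``fae1_loss``, ``fae1_gain``, ``fad2a5_loss``.
    Signs are +1 (increase) / -1 (decrease) relative to wild type.
    """
    key = genotype_change.strip().lower().replace(" ", "_").replace(".", "")
    aliases = {
        "fae1_copy_loss": "fae1_loss",
        "fae1_copy_gain": "fae1_gain",
        "fad2a5_loss": "fad2a5_loss",
        "fad2_a5_loss": "fad2a5_loss",
    }
    key = aliases.get(key, key)
    if key not in _DIRECTIONS:
        raise ValueError(f"unknown genotype change {genotype_change!r}; "
                         f"expected one of {sorted(_DIRECTIONS)}")
    return dict(_DIRECTIONS[key])
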