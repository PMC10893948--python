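"""Quantitative copy-number genotyping from inter-homoeologue polymorphisms.

At an IHP position the A- and C-genome homoeologues carry different bases;
after co-amplification of both copies, the capillary-sequencing peak
intensities of the two diagnostic bases measure the relative copy number
of the two subgenomes.  A genotype with ``a`` A copies and ``c`` C copies
is expected to show an A-base signal proportion of ``a / (a + c)`` —
e.g. 0.5 for the balanced AACC state and 2/3 for a homozygous A-segment
duplication (4 A : 2 C).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

__all__ = ["CopyClass", "DEFAULT_CLASSES", "proportion", "classify",
           "consensus", "call_samples"]


@dataclass(frozen=True)
class CopyClass:
    """A copy-state hypothesis: a_copies of the A allele, c_copies of the C."""

    a_copies: int
    c_copies: int

    def __post_init__(self) -> None:
        if self.a_copies < 0 or self.c_copies < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.a_copies + self.c_copies == 0:
            raise ValueError("a_copies + c_copies must be > 0")

    @property
    def expected_p(self) -> float:
        return self.a_copies / (self.a_copies + self.c_copies)

    def __str__(self) -> str:
        return f"{self.a_copies}A:{self.c_copies}C"


#: default copy-state hypotheses.  Expected proportions 0, 1/3, 1/2, 2/3, 1
#: are spaced at least 1/6 apart, which the 0.08 call margin keeps disjoint.
#: The 3A:2C state (p = 0.6) and 2A:1C (p = 2/3, indistinguishable from
#: 4A:2C by proportion alone) are deliberately not default hypotheses; pass
#: them explicitly when the segregating states of a line warrant it.
DEFAULT_CLASSES = tuple(CopyClass(a, c) for a, c in
                        [(0, 2), (1, 2), (2, 2), (4, 2), (2, 0)])

#: the full hypothesis list including the tight heterozygous-duplication
#: state and the single-C-loss state
EXTENDED_CLASSES = tuple(CopyClass(a, c) for a, c in
                         [(0, 2), (1, 2), (2, 2), (3, 2), (4, 2), (2, 1), (2, 0)])


def proportion(intensity_a: float, intensity_c: float) -> float:
    """A-base signal proportion ``p_A = I_A / (I_A + I_C)``.

    Scale-invariant in the overall signal strength.  Returns NaN (no-call)
    when both intensities are zero; negative intensities are invalid.
    """
    if intensity_a < 0 or intensity_c < 0:
        raise ValueError("peak intensities must be non-negative")
    total = intensity_a + intensity_c
    if total == 0:
        return math.nan
    return intensity_a / total


def classify(p_a: float, classes=DEFAULT_CLASSES,
             margin: float = 0.08) -> CopyClass | None:
    """Nearest-expectation copy-class call.

    Returns the class whose expected proportion is closest to ``p_a``, or
    None (no-call) if the residual exceeds ``margin`` or two classes tie.
    The default margin keeps adjacent default classes (spacing >= 1/6)
    from overlapping.
    """
    if not classes:
        raise ValueError("class set must be non-empty")
    if isinstance(p_a, float) and math.isnan(p_a):
        return None
    scored = sorted((abs(p_a - cl.expected_p), i) for i, cl in enumerate(classes))
    best_d, best_i = scored[0]
    if best_d > margin:
        return None
    if len(scored) > 1 and scored[1][0] - best_d < 1e-6:
        return None
    return tuple(classes)[best_i]


@dataclass(frozen=True)
class ConsensusCall:
    genotype: CopyClass | None
    agreed: bool  # all informative markers voted the same way
    votes: tuple[tuple[str, int], ...]  # (class label, count)


def consensus(marker_calls: list[CopyClass | None]) -> ConsensusCall:
    """Majority vote across markers of one amplicon for one sample.

    No-call markers abstain.  A strict majority wins (flagged when not
    unanimous); a tie or no informative markers yields a no-call with the
    per-marker vote detail retained.
    """
    if not marker_calls:
        raise ValueError("at least one marker call is required")
    votes = Counter(str(c) for c in marker_calls if c is not None)
    detail = tuple(sorted(votes.items(), key=lambda kv: (-kv[1], kv[0])))
    if not votes:
        return ConsensusCall(None, False, detail)
    ranked = votes.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return ConsensusCall(None, False, detail)
    winner = next(c for c in marker_calls if c is not None and str(c) == ranked[0][0])
    agreed = len(ranked) == 1
    return ConsensusCall(winner, agreed, detail)


def call_samples(signals: pd.DataFrame, classes=DEFAULT_CLASSES,
                 margin: float = 0.08) -> pd.DataFrame:
    """Genotype a table of IHP signals.

    ``signals`` columns: marker, sample_id, intensity_A, intensity_C.
    Returns one row per sample: sample_id, genotype (or NA), agreed,
    n_markers.
    """
    rows = []
    for sid, grp in signals.groupby("sample_id", sort=False):
        calls = [classify(proportion(r.intensity_A, r.intensity_C), classes, margin)
                 for r in grp.itertuples(index=False)]
        res = consensus(calls)
        rows.append((sid, str(res.genotype) if res.genotype else "NA",
                     res.agreed, len(calls)))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "agreed", "n_markers"])
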