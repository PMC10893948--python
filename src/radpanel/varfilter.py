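"""Small-variant filter chain for a mutagenesis panel, plus coding
consequence classification.

Pipeline order (as applied to the panel): per-sample quality filter
(QUAL > threshold, SNVs near retained InDels dropped), subtraction of the
merged control master set by position, removal of variants recurring in
more than ``max_occurrence`` samples (systematic artifacts: independent
radiation events should be line-specific), then region restriction and a
simplified coding-consequence classifier.  Every record keeps an
append-only ``filter_history`` naming each filter it met and whether it
survived, so survivors and rejects always partition the input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "VariantCall",
    "GeneModel",
    "Consequence",
    "calls_from_dataframe",
    "filter_quality",
    "subtract_controls",
    "filter_occurrence",
    "tier_by_vad",
    "classify_consequence",
    "run_filter_chain",
]


@dataclass
class VariantCall:
    """One variant observed in one sample (multi-allelic sites pre-split)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    sample_id: str
    vad: int  # variant-allele read depth
    gt: str = "0/1"
    filter_history: list[tuple[str, bool]] = field(default_factory=list)
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")
        if self.vad < 0:
            raise ValueError("variant-allele depth must be >= 0")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def record(self, name: str, passed: bool) -> None:
        self.filter_history.append((name, passed))


def calls_from_dataframe(df: pd.DataFrame) -> list[VariantCall]:
    """Build calls from a table with chrom, pos, ref, alt, qual, sample_id, vad."""
    return [VariantCall(r.chrom, int(r.pos), r.ref, r.alt, float(r.qual),
                        r.sample_id, int(r.vad),
                        getattr(r, "gt", "0/1"))
            for r in df.itertuples(index=False)]


def _check_sorted(calls: list[VariantCall]) -> None:
    """Positions must be non-decreasing within each chromosome and
    chromosomes must not interleave (any contig order is fine)."""
    done: set[str] = set()
    cur: str | None = None
    last_pos = 0
    for c in calls:
        if c.chrom != cur:
            if c.chrom in done:
                raise ValueError("records must be sorted by chrom, pos")
            if cur is not None:
                done.add(cur)
            cur, last_pos = c.chrom, 0
        if c.pos < last_pos:
            raise ValueError("records must be sorted by chrom, pos")
        last_pos = c.pos


def _split(calls, name, keep_fn):
    kept, rejected = [], []
    for c in calls:
        ok = keep_fn(c)
        c.record(name, ok)
        (kept if ok else rejected).append(c)
    return kept, rejected


def filter_quality(calls: list[VariantCall], qual_min: float = 20.0,
                   snp_gap: int = 3) -> tuple[list[VariantCall], list[VariantCall]]:
    """Quality filter: QUAL must exceed ``qual_min``; SNVs within
    ``snp_gap`` bases of a retained InDel on the same chromosome are
    dropped (InDels themselves are never removed by the gap rule).

    Input must be sorted by (chrom, pos).  Returns (kept, rejected).
    """
    _check_sorted(calls)
    kept_q, rej = _split(calls, "qual", lambda c: c.qual > qual_min)
    indel_pos: dict[str, list[int]] = {}
    for c in kept_q:
        if not c.is_snv:
            indel_pos.setdefault(c.chrom, []).append(c.pos)

    def far_from_indels(c: VariantCall) -> bool:
        if not c.is_snv:
            return True
        return all(abs(c.pos - p) > snp_gap for p in indel_pos.get(c.chrom, []))

    kept, rej2 = _split(kept_q, "snp_gap", far_from_indels)
    return kept, rej + rej2


def subtract_controls(calls: list[VariantCall], control_calls: list[VariantCall]
                      ) -> tuple[list[VariantCall], list[VariantCall]]:
    """Drop any mutant record whose (chrom, pos) appears in the merged
    control master set — position-level, regardless of allele."""
    master = {(c.chrom, c.pos) for c in control_calls}
    return _split(calls, "control_subtraction",
                  lambda c: (c.chrom, c.pos) not in master)


def filter_occurrence(calls: list[VariantCall], max_occurrence: int = 8
                      ) -> tuple[list[VariantCall], list[VariantCall]]:
    """Remove variants (same chrom, pos, ref, alt) present in more than
    ``max_occurrence`` samples — recurrent calls across independently
    mutagenized lines are systematic artifacts."""
    samples_per_variant: dict[tuple, set[str]] = {}
    for c in calls:
        samples_per_variant.setdefault(c.key, set()).add(c.sample_id)
    return _split(calls, "occurrence",
                  lambda c: len(samples_per_variant[c.key]) <= max_occurrence)


def tier_by_vad(calls: list[VariantCall],
                validated: dict | None = None) -> pd.DataFrame:
    """Validation tiers by variant-allele read depth.

    Tier "standard" for VAD > 2, "low" for VAD = 2, "reject" for VAD < 2.
    Given a validation truth map ``{(chrom,pos,ref,alt,sample_id): bool}``,
    reports per-tier validation percentages in both integer and
    one-decimal renderings; NA where nothing was tested.
    """
    tiers = {"standard": [], "low": [], "reject": []}
    for c in calls:
        t = "standard" if c.vad > 2 else ("low" if c.vad == 2 else "reject")
        tiers[t].append(c)
    rows = []
    for name in ("standard", "low", "reject"):
        group = tiers[name]
        tested = valid = 0
        if validated is not None:
            for c in group:
                k = c.key + (c.sample_id,)
                if k in validated:
                    tested += 1
                    valid += bool(validated[k])
        if tested:
            pct_int = int(np.round(100.0 * valid / tested))
            pct_1dp = np.round(100.0 * valid / tested, 1)
        else:
            pct_int = pct_1dp = np.nan
        rows.append((name, len(group), tested, valid, pct_int, pct_1dp))
    return pd.DataFrame(rows, columns=[
        "tier", "n_calls", "n_tested", "n_validated",
        "pct_validated", "pct_validated_1dp"])


# ---------------------------------------------------------------------------
# coding consequence

@dataclass(frozen=True)
class GeneModel:
    """A coding gene model: ordered CDS intervals and the coding sequence.

    ``cds_intervals`` are 1-based inclusive genomic intervals sorted in
    ascending genomic order; ``cds_seq`` is the spliced coding-strand
    sequence (length divisible by 3, equal to the summed interval length).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    cds_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ivs = self.cds_intervals
        total = 0
        for i, (s, e) in enumerate(ivs):
            if e < s:
                raise ValueError(f"interval {i} has end < start")
            if i and s <= ivs[i - 1][1]:
                raise ValueError("CDS intervals must be sorted and non-overlapping")
            total += e - s + 1
        if total != len(self.cds_seq):
            raise ValueError("cds_seq length does not match intervals")
        if total % 3:
            raise ValueError("coding length must be divisible by 3")

    def cds_index(self, pos: int) -> int | None:
        """0-based coding-sequence index of a genomic position, or None."""
        offset = 0
        fwd = None
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                fwd = offset + (pos - s)
                break
            offset += e - s + 1
        if fwd is None:
            return None
        if self.strand == "+":
            return fwd
        return len(self.cds_seq) - 1 - fwd

    def near_splice(self, pos: int, margin: int = 2) -> bool:
        """True for intronic/flanking positions within ``margin`` nt of a
        CDS/intron boundary."""
        for s, e in self.cds_intervals:
            if s - margin <= pos < s or e < pos <= e + margin:
                return True
        return False


@dataclass(frozen=True)
class Consequence:
    kind: str
    aa_change: int | None = None  # amino acids gained/lost for inframe indels


def classify_consequence(call: VariantCall, model: GeneModel) -> Consequence:
    """Simplified coding-consequence prediction (standard nuclear code).

    SNVs inside the CDS are classified by codon translation as
    synonymous / missense / stop_gained (or stop_lost); insertions and
    deletions of L nt are inframe (with L/3 amino acids changed) when
    L mod 3 == 0, else frameshift; variants landing within 2 nt of a
    CDS/intron boundary are splice_site; everything else is non_coding.
    Strand-aware.  The result is also stored on ``call.consequence``.
    """
    cons = _classify(call, model)
    call.consequence = cons.kind
    return cons


def _classify(call: VariantCall, model: GeneModel) -> Consequence:
    if call.chrom != model.chrom:
        return Consequence("non_coding")
    idx = model.cds_index(call.pos)
    if call.is_snv:
        if idx is None:
            return Consequence("splice_site") if model.near_splice(call.pos) \
                else Consequence("non_coding")
        seq = model.cds_seq
        alt = call.alt if model.strand == "+" else str(Seq(call.alt).reverse_complement())
        codon_i = idx // 3
        codon = seq[codon_i * 3: codon_i * 3 + 3]
        new_codon = codon[: idx % 3] + alt + codon[idx % 3 + 1:]
        aa_old = str(Seq(codon).translate())
        aa_new = str(Seq(new_codon).translate())
        if aa_new == aa_old:
            return Consequence("synonymous")
        if aa_new == "*":
            return Consequence("stop_gained")
        if aa_old == "*":
            return Consequence("stop_lost")
        return Consequence("missense")

    # indel: length change and anchor position within the CDS
    span = range(call.pos, call.pos + max(len(call.ref), 1))
    touches_cds = any(model.cds_index(p) is not None for p in span)
    if not touches_cds:
        return Consequence("splice_site") if any(
            model.near_splice(p) for p in span) else Consequence("non_coding")
    length = abs(len(call.ref) - len(call.alt))
    if length % 3 == 0 and length > 0:
        kind = "inframe_deletion" if len(call.ref) > len(call.alt) else "inframe_insertion"
        return Consequence(kind, aa_change=length // 3)
    return Consequence("frameshift")


# ---------------------------------------------------------------------------
# chain driver

def run_filter_chain(mutant_calls: list[VariantCall],
                     control_calls: list[VariantCall],
                     gene_models: list[GeneModel] | None = None,
                     qual_min: float = 20.0, snp_gap: int = 3,
                     max_occurrence: int = 8,
                     ) -> tuple[list[VariantCall], list[VariantCall]]:
    """Full chain: quality -> control subtraction -> occurrence ->
    (optional) region restriction + consequence.  Returns (survivors,
    rejects); every input call appears in exactly one of the two, with its
    filter_history naming the removing filter."""
    ctrl_kept, _ = filter_quality(control_calls, qual_min, snp_gap)
    kept, rej = filter_quality(mutant_calls, qual_min, snp_gap)
    kept, r2 = subtract_controls(kept, ctrl_kept)
    kept, r3 = filter_occurrence(kept, max_occurrence)
    rejects = rej + r2 + r3
    if gene_models:
        by_chrom: dict[str, list[GeneModel]] = {}
        for gm in gene_models:
            by_chrom.setdefault(gm.chrom, []).append(gm)
        in_region, out_region = [], []
        for c in kept:
            models = by_chrom.get(c.chrom, [])
            hit = None
            for gm in models:
                lo = gm.cds_intervals[0][0] - 2
                hi = gm.cds_intervals[-1][1] + 2
                if lo <= c.pos <= hi:
                    hit = gm
                    break
            c.record("region", hit is not None)
            if hit is None:
                out_region.append(c)
            else:
                classify_consequence(c, hit)
                in_region.append(c)
        kept = in_region
        rejects = rejects + out_region
    return kept, rejects


def occurrence_counts(calls: list[VariantCall]) -> Counter:
    """Distinct-sample occurrence count per variant key (diagnostics)."""
    seen = {(c.key, c.sample_id) for c in calls}
    return Counter(k for k, _ in seen)
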