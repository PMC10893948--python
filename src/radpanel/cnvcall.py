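"""Automated CNV calling from homoeologue dosage profiles.

Replaces visual inspection of display tile plots with a reproducible
caller: running-median smoothing of per-gene copy estimates along each
chromosome, threshold-run segmentation into deletions/duplications,
reclassification of near-complete runs as whole-chromosome events,
reciprocal merging of duplication/deletion pairs into homoeologous
exchanges, a single-gene CNV scan, sibling reciprocal-inheritance
matching, dose-response summarization and a saturation-size estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from radpanel.simpanel import (
    CHROMOSOME_GAIN,
    CHROMOSOME_LOSS,
    EVENT_COLUMNS,
    HOMOEOLOGOUS_EXCHANGE,
    SEGMENTAL_DELETION,
    SEGMENTAL_DUPLICATION,
)

__all__ = [
    "CallerParams",
    "smooth",
    "call_segments",
    "call_panel",
    "detect_homoeologous_exchange",
    "scan_gene_level",
    "match_sibling_events",
    "summarize_dose_response",
    "saturation_size",
    "recovery_metrics",
    "recovered_lesions",
    "round_half_up",
    "mean_visible_rate",
    "DOSE_RESPONSE_COLUMNS",
]

#: copy-state cut points: mean smoothed k in (-inf,0.5,1.5,2.5,3.5,inf) -> 0..4 copies
ZYGOSITY_CUTS = (0.5, 1.5, 2.5, 3.5)


@dataclass(frozen=True)
class CallerParams:
    """Segmentation parameters.

    Deletion/duplication thresholds default to 1.5 and 2.5 — midway
    between adjacent integer copy states, the maximal-margin choice under
    symmetric noise.  ``min_run`` operationalizes "visible" events: only
    runs of at least this many genes are called.  A candidate run must
    additionally depart from baseline by ``min_amplitude`` copies in its
    raw (unsmoothed) mean with a one-sample t statistic of at least
    ``min_t`` — a running median can drift past a threshold for a window
    length on autocorrelated noise alone, and the amplitude test is what
    separates such excursions from genuine half-copy shifts.
    """

    window: int = 15
    del_thresh: float = 1.5
    dup_thresh: float = 2.5
    min_run: int = 10
    whole_chrom_frac: float = 0.95
    he_overlap: float = 0.7
    sib_jaccard: float = 0.6
    min_amplitude: float = 0.5
    min_t: float = 4.0

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 1")
        if not (0 < self.del_thresh < 2 < self.dup_thresh):
            raise ValueError("need 0 < del_thresh < 2 < dup_thresh")
        for f in (self.whole_chrom_frac, self.he_overlap, self.sib_jaccard):
            if not 0 < f <= 1:
                raise ValueError("fractions must lie in (0, 1]")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "CallerParams":
        """Defaults per data mode: transcriptome dosage is noisier per
        gene, so it gets a wider running-median window (31 vs 15)."""
        if mode not in ("genome", "transcriptome"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "transcriptome":
            overrides.setdefault("window", 31)
        return cls(**overrides)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero (as printed tables use)."""
    scale = 10 ** ndigits
    return math.floor(abs(x) * scale + 0.5 + 1e-9) / scale * (1 if x >= 0 else -1)


def smooth(values, window: int) -> np.ndarray:
    """Running median along one chromosome; window truncated at the ends.

    Output length equals input length.  NaNs (masked genes) are ignored
    within each window.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot smooth an empty series")
    s = pd.Series(arr)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def _runs(state: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of identical non-zero state: (start, end, state)."""
    out = []
    n = len(state)
    i = 0
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j < n and state[j] == state[i]:
            j += 1
        out.append((i, j, int(state[i])))
        i = j
    return out


def _merge_runs(runs: list[tuple[int, int, int]], max_gap: int,
                ks: np.ndarray | None = None) -> list[tuple[int, int, int]]:
    """Bridge same-state runs across gaps visual inspection would span.

    Two same-state runs merge when the gap is shorter than ``max_gap``
    baseline genes, or when the gap's mean raw value never really returns
    to baseline (stays on the event side of 2 by more than 0.25 — a
    sub-threshold sag inside one lesion, not two lesions).  The gap is
    judged on raw values because a window-wide median straddling a short
    baseline gap between two real lesions is dragged to the lesion level.
    """
    merged: list[tuple[int, int, int]] = []
    for run in runs:
        if merged and merged[-1][2] == run[2]:
            gap_lo, gap_hi = merged[-1][1], run[0]
            bridge = gap_hi - gap_lo < max_gap
            if not bridge and ks is not None:
                gap_mean = float(np.nanmean(ks[gap_lo:gap_hi]))
                bridge = (gap_mean < 1.75) if run[2] < 0 else (gap_mean > 2.25)
            if bridge:
                merged[-1] = (merged[-1][0], run[1], run[2])
                continue
        merged.append(tuple(run))
    return merged


def _extend_runs(runs: list[tuple[int, int, int]], ks: np.ndarray,
                 max_extend: int) -> list[tuple[int, int, int]]:
    """Grow confirmed runs while the smoothed value stays beyond the
    midpoint between baseline and the event state (1.75 for deletions,
    2.25 for duplications), by at most ``max_extend`` genes per side.

    A w-gene running median erodes a lesion's shoulders by up to w/2
    genes, where the signal hovers between the calling threshold and
    baseline; extension recovers that smear.  The cap stops the boundary
    from wandering along autocorrelated baseline noise, and only runs
    that already passed the length filter are extended, so this refines
    boundaries without creating calls.
    """
    out = []
    n = len(ks)
    for i, (a, b, st) in enumerate(runs):
        lo_lim = max(runs[i - 1][1] if i > 0 else 0, a - max_extend)
        hi_lim = min(runs[i + 1][0] if i + 1 < len(runs) else n, b + max_extend)
        mid_ok = (lambda v: v < 1.75) if st < 0 else (lambda v: v > 2.25)
        while a > lo_lim and mid_ok(ks[a - 1]):
            a -= 1
        while b < hi_lim and mid_ok(ks[b]):
            b += 1
        out.append((a, b, st))
    return out


def _split_by_level(ks_run: np.ndarray, min_run: int,
                    state: int) -> list[tuple[int, int]]:
    """Split one threshold run at integer copy-state boundaries.

    Pieces are maximal stretches of constant digitized copy level
    (clamped to the run's side, so sub-threshold sags are not their own
    level); pieces shorter than ``min_run`` (threshold flicker) are
    merged into their longer neighbour, and a boundary survives only
    when the adjacent pieces' means differ by at least 0.75 — clearly
    different integer states, e.g. a homozygous deletion abutting a
    heterozygous one.  Duplication runs are never split: at 1.5x the
    baseline read depth the 3-versus-4-copy distinction is too noisy for
    reliable sub-segmentation.
    """
    if state > 0:
        return [(0, len(ks_run))]
    levels = np.digitize(ks_run, ZYGOSITY_CUTS)
    levels = np.minimum(levels, 1)
    pieces: list[list[int]] = []
    for i, lv in enumerate(levels):
        if pieces and pieces[-1][2] == lv:
            pieces[-1][1] = i + 1
        else:
            pieces.append([i, i + 1, lv])
    while len(pieces) > 1:
        shortest = min(range(len(pieces)), key=lambda j: pieces[j][1] - pieces[j][0])
        if pieces[shortest][1] - pieces[shortest][0] >= min_run:
            break
        j = shortest
        neighbours = [x for x in (j - 1, j + 1) if 0 <= x < len(pieces)]
        tgt = max(neighbours, key=lambda x: pieces[x][1] - pieces[x][0])
        lo, hi = min(j, tgt), max(j, tgt)
        pieces[lo] = [pieces[lo][0], pieces[hi][1], pieces[tgt][2]]
        del pieces[hi]
        # absorbing flicker can leave equal-level neighbours: coalesce
        m = 0
        while m < len(pieces) - 1:
            if pieces[m][2] == pieces[m + 1][2]:
                pieces[m][1] = pieces[m + 1][1]
                del pieces[m + 1]
            else:
                m += 1
    # keep only boundaries separating clearly different copy states
    m = 0
    while m < len(pieces) - 1:
        d = abs(float(np.mean(ks_run[pieces[m][0]:pieces[m][1]]))
                - float(np.mean(ks_run[pieces[m + 1][0]:pieces[m + 1][1]])))
        if d < 0.75:
            pieces[m] = [pieces[m][0], pieces[m + 1][1], pieces[m][2]]
            del pieces[m + 1]
        else:
            m += 1
    return [(p[0], p[1]) for p in pieces]


def call_segments(profile: pd.DataFrame, pair_map: pd.DataFrame,
                  params: CallerParams = CallerParams()) -> pd.DataFrame:
    """Call CNV segments for one sample's dosage profile.

    ``profile`` is the long-format pair profile of a single sample
    (columns sample_id, pair_id, k_A, k_C, masked).  Per subgenome and
    chromosome, smoothed copy estimates are segmented into maximal runs
    below ``del_thresh`` / above ``dup_thresh``; adjacent same-state runs
    separated by fewer than window/2 baseline genes are bridged; runs
    shorter than ``min_run`` usable genes are discarded.  Post-event copy
    number and zygosity come from the mean smoothed k of the run via the
    midpoints between integer copy states.  Runs spanning at least
    ``whole_chrom_frac`` of a chromosome's genes are reclassified as
    chromosome loss/gain.  Intervals are 0-based, half-open gene-order
    indices.
    """
    sample_ids = profile.sample_id.unique()
    if len(sample_ids) != 1:
        raise ValueError("call_segments expects the profile of exactly one sample")
    sample_id = sample_ids[0]
    prof = profile.set_index("pair_id")
    rows = []
    for sub in ("A", "C"):
        kcol = f"k_{sub}"
        for chrom, grp in pair_map.groupby(f"chrom_{sub}", sort=False):
            grp = grp.sort_values(f"idx_{sub}")
            k = prof.loc[grp.pair_id, kcol].to_numpy(dtype=float)
            idx = grp[f"idx_{sub}"].to_numpy()
            n_chrom = len(idx)
            usable = ~np.isnan(k)
            if usable.sum() == 0:
                continue
            ku = k[usable]
            iu = idx[usable]
            ks = smooth(ku, params.window)
            state = np.zeros(len(ks), dtype=int)
            state[ks < params.del_thresh] = -1
            state[ks > params.dup_thresh] = 1
            runs = _merge_runs(_runs(state), max_gap=max(1, params.window // 2),
                               ks=ku)
            runs = [r for r in runs if r[1] - r[0] >= params.min_run]
            runs = _extend_runs(runs, ks, max_extend=params.window // 2)
            for a, b, st in runs:
                # adjacent lesions of different copy state (e.g. a hom
                # deletion flanked by a het one) form one threshold run;
                # split it where the integer copy level changes
                for pa, pb in _split_by_level(ks[a:b], params.min_run, st):
                    raw = ku[a + pa:a + pb]
                    amp = float(np.mean(raw)) - 2.0
                    sd = max(float(np.std(raw, ddof=1)), 0.05)
                    t_stat = abs(amp) * np.sqrt(len(raw)) / sd
                    if abs(amp) < params.min_amplitude or t_stat < params.min_t:
                        continue
                    mean_k = float(np.mean(ks[a + pa:a + pb]))
                    copies = int(np.digitize(mean_k, ZYGOSITY_CUTS))
                    if st < 0:
                        copies = min(copies, 1)
                        klass = SEGMENTAL_DELETION
                    else:
                        copies = max(copies, 3)
                        klass = SEGMENTAL_DUPLICATION
                    copies = max(0, min(4, copies))
                    zyg = "hom" if copies in (0, 4) else "het"
                    start, end = int(iu[a + pa]), int(iu[a + pb - 1]) + 1
                    if (pb - pa) >= params.whole_chrom_frac * usable.sum():
                        klass = CHROMOSOME_LOSS if st < 0 else CHROMOSOME_GAIN
                        start, end = 0, n_chrom
                    rows.append((sample_id, sub, chrom, start, end, klass,
                                 copies, zyg))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def call_panel(profiles: pd.DataFrame, pair_map: pd.DataFrame,
               params: CallerParams = CallerParams()) -> pd.DataFrame:
    """call_segments applied per sample over a multi-sample profile table."""
    parts = [call_segments(grp, pair_map, params)
             for _, grp in profiles.groupby("sample_id", sort=False)]
    if not parts:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def _event_pairs(ev, pair_map: pd.DataFrame) -> set:
    sub = ev.subgenome
    grp = pair_map[pair_map[f"chrom_{sub}"] == ev.chrom]
    sel = (grp[f"idx_{sub}"] >= ev.start_idx) & (grp[f"idx_{sub}"] < ev.end_idx)
    return set(grp.pair_id[sel])


def detect_homoeologous_exchange(events: pd.DataFrame, pair_map: pd.DataFrame,
                                 he_overlap: float = 0.7
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge reciprocal duplication/deletion pairs into homoeologous exchanges.

    Within one sample, a duplication on one subgenome and a deletion on
    the homoeologous interval of the other (reciprocal overlap, in
    homoeologue-pair space, at least ``he_overlap`` of both intervals)
    are replaced by a single exchange call on the gaining subgenome with
    its direction recorded (e.g. ``A->C`` when A-genome sequence has
    replaced the corresponding C segment).  Returns ``(exchanges,
    remaining_events)``; constituent calls are consumed.
    """
    exchanges = []
    consumed: set[int] = set()
    ev = events.reset_index(drop=True)
    for sid, grp in ev.groupby("sample_id", sort=False):
        dups = grp[grp.event_class == SEGMENTAL_DUPLICATION]
        dels = grp[grp.event_class == SEGMENTAL_DELETION]
        for di, dup in dups.iterrows():
            if di in consumed:
                continue
            dup_pairs = _event_pairs(dup, pair_map)
            if not dup_pairs:
                continue
            for li, dele in dels.iterrows():
                if li in consumed or dele.subgenome == dup.subgenome:
                    continue
                del_pairs = _event_pairs(dele, pair_map)
                if not del_pairs:
                    continue
                inter = len(dup_pairs & del_pairs)
                if (inter / len(dup_pairs) >= he_overlap
                        and inter / len(del_pairs) >= he_overlap):
                    consumed.update((di, li))
                    exchanges.append((
                        sid, dup.subgenome, dup.chrom, dup.start_idx, dup.end_idx,
                        HOMOEOLOGOUS_EXCHANGE, dup.copies, dup.zygosity,
                        f"{dup.subgenome}->{dele.subgenome}"))
                    break
    exch = pd.DataFrame(exchanges, columns=EVENT_COLUMNS + ["direction"])
    remaining = ev.drop(index=sorted(consumed)).reset_index(drop=True)
    return exch, remaining


def scan_gene_level(k: pd.DataFrame, events: pd.DataFrame, pair_map: pd.DataFrame,
                    dup_ratio: float = 1.75, del_ratio: float = 0.25,
                    min_samples: int = 20) -> pd.DataFrame:
    """Single-gene CNV scan over population-normalized copy estimates.

    Per (gene, sample), ``r = k / median across samples`` flags candidate
    duplications (r >= dup_ratio) and homozygous deletions
    (r <= del_ratio), excluding genes already inside a called segment of
    that sample; candidates are ranked by |log2 r|.  Mirrors a manual
    scan of population-normalized read-depth spreadsheets.
    """
    if k.shape[1] < min_samples:
        raise ValueError(f"population scan needs >= {min_samples} samples")
    med = k.median(axis=1)
    degenerate = (med <= 0) | med.isna()
    if degenerate.any():
        warnings.warn(f"skipping {int(degenerate.sum())} genes with degenerate "
                      "population median", stacklevel=2)
    kk = k[~degenerate]
    r = kk.div(med[~degenerate], axis=0)

    gene_coord: dict[str, tuple[str, str, int]] = {}
    for sub in ("A", "C"):
        for g, c, i in zip(pair_map[f"gene_{sub}"], pair_map[f"chrom_{sub}"],
                           pair_map[f"idx_{sub}"]):
            gene_coord[g] = (sub, c, int(i))

    in_segment: set[tuple[str, str]] = set()
    for evr in events.itertuples(index=False):
        sub = evr.subgenome
        grp = pair_map[pair_map[f"chrom_{sub}"] == evr.chrom]
        sel = (grp[f"idx_{sub}"] >= evr.start_idx) & (grp[f"idx_{sub}"] < evr.end_idx)
        for g in grp[f"gene_{sub}"][sel]:
            in_segment.add((g, evr.sample_id))

    rows = []
    rv = r.to_numpy()
    genes = r.index.to_numpy()
    cols = r.columns.to_numpy()
    hit = np.argwhere((rv >= dup_ratio) | ((rv <= del_ratio) & ~np.isnan(rv)))
    for gi, si in hit:
        g, s = genes[gi], cols[si]
        if (g, s) in in_segment:
            continue
        ratio = rv[gi, si]
        kind = "duplication" if ratio >= dup_ratio else "hom_deletion"
        log2r = np.log2(ratio) if ratio > 0 else -np.inf
        rows.append((g, s, float(ratio), float(log2r), kind))
    out = pd.DataFrame(rows, columns=["gene", "sample_id", "ratio", "log2_ratio", "kind"])
    if len(out):
        out["abs_log2"] = out.log2_ratio.abs().replace(np.inf, 1e9)
        out = (out.sort_values("abs_log2", ascending=False)
                  .drop(columns="abs_log2").reset_index(drop=True))
    return out


def _jaccard(a0: int, a1: int, b0: int, b1: int) -> float:
    inter = max(0, min(a1, b1) - max(a0, b0))
    union = (a1 - a0) + (b1 - b0) - inter
    return inter / union if union else 0.0


def match_sibling_events(events: pd.DataFrame, samples: pd.DataFrame,
                         sib_jaccard: float = 0.6) -> pd.DataFrame:
    """Reciprocal inheritance: deletion in one M2 sib, duplication in another.

    For samples sharing an M1 family, a deletion interval in one sibling
    and a duplication interval in another on the same subgenome and
    chromosome with gene-index Jaccard >= ``sib_jaccard`` are reported as
    a reciprocal pair.  Symmetric in sibling order.
    """
    fam = samples.set_index("sample_id").m1_family.to_dict()
    ev = events[events.event_class.isin([SEGMENTAL_DELETION, SEGMENTAL_DUPLICATION])]
    ev = ev[[fam.get(s) not in (None, "NA") for s in ev.sample_id]]
    rows = []
    key = [fam[s] for s in ev.sample_id]
    for family, grp in ev.groupby(key, sort=False):
        dels = grp[grp.event_class == SEGMENTAL_DELETION]
        dups = grp[grp.event_class == SEGMENTAL_DUPLICATION]
        for d in dels.itertuples(index=False):
            for u in dups.itertuples(index=False):
                if (u.sample_id == d.sample_id or u.subgenome != d.subgenome
                        or u.chrom != d.chrom):
                    continue
                j = _jaccard(d.start_idx, d.end_idx, u.start_idx, u.end_idx)
                if j >= sib_jaccard:
                    rows.append((family, d.sample_id, u.sample_id, d.subgenome,
                                 d.chrom, d.start_idx, d.end_idx,
                                 u.start_idx, u.end_idx, j))
    return pd.DataFrame(rows, columns=[
        "m1_family", "deleted_in", "duplicated_in", "subgenome", "chrom",
        "del_start", "del_end", "dup_start", "dup_end", "jaccard"])


DOSE_RESPONSE_COLUMNS = [
    "radiation_type", "dose_Gy", "n_plants",
    "chrom_loss_A", "chrom_loss_C", "chrom_dup_A", "chrom_dup_C",
    "del_A", "del_C", "dup_A", "dup_C", "mean_del_dup",
]

_VISIBLE = ["del_A", "del_C", "dup_A", "dup_C"]


def mean_visible_rate(rates) -> float:
    """Mean of the four visible deletion/duplication per-plant rates, 2 dp."""
    rates = list(rates)
    if len(rates) != 4:
        raise ValueError("expected the four visible-event rates")
    return round_half_up(sum(rates) / 4.0, 2)


def summarize_dose_response(events: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-plant lesion rates per (radiation type, dose), 2-dp rounded.

    Columns follow the standard dose-response table layout: whole
    chromosome losses/duplications and visible segmental
    deletions/duplications per subgenome, then the unweighted mean of the
    four visible-event rates.  Homoeologous exchanges (pre-existing seed
    lot variation) are excluded.  Controls appear as a dose-0 row.
    """
    ev = events[events.event_class != HOMOEOLOGOUS_EXCHANGE]
    counts = {}
    for e in ev.itertuples(index=False):
        col = {
            CHROMOSOME_LOSS: f"chrom_loss_{e.subgenome}",
            CHROMOSOME_GAIN: f"chrom_dup_{e.subgenome}",
            SEGMENTAL_DELETION: f"del_{e.subgenome}",
            SEGMENTAL_DUPLICATION: f"dup_{e.subgenome}",
        }[e.event_class]
        counts.setdefault(e.sample_id, {}).setdefault(col, 0)
        counts[e.sample_id][col] += 1

    missing = set(ev.sample_id) - set(samples.sample_id)
    if missing:
        raise ValueError(f"events reference samples without dose metadata: "
                         f"{sorted(missing)[:3]}")
    rows = []
    groups = samples.groupby(["radiation_type", "dose_Gy"], sort=False)
    for (rtype, dose), grp in groups:
        n = len(grp)
        if n == 0:
            raise ValueError(f"dose group ({rtype}, {dose}) has zero plants")
        rates = {}
        for col in DOSE_RESPONSE_COLUMNS[3:-1]:
            total = sum(counts.get(s, {}).get(col, 0) for s in grp.sample_id)
            rates[col] = round_half_up(total / n, 2)
        mean = mean_visible_rate([rates[c] for c in _VISIBLE])
        rows.append([rtype, dose, n] + [rates[c] for c in DOSE_RESPONSE_COLUMNS[3:-1]]
                    + [mean])
    out = pd.DataFrame(rows, columns=DOSE_RESPONSE_COLUMNS)
    return out.sort_values(["radiation_type", "dose_Gy"]).reset_index(drop=True)


_DIRECTION = {SEGMENTAL_DELETION: -1, CHROMOSOME_LOSS: -1,
              SEGMENTAL_DUPLICATION: 1, CHROMOSOME_GAIN: 1}


def recovery_metrics(truth_events: pd.DataFrame, calls: pd.DataFrame,
                     min_genes: int = 30, min_jaccard: float = 0.5) -> dict:
    """Benchmark calls against simulated truth lesions.

    Sensitivity: fraction of truth lesions spanning >= ``min_genes``
    matched by a same-direction call with interval Jaccard >=
    ``min_jaccard`` on the same sample/subgenome/chromosome.  Precision:
    fraction of >= ``min_genes`` calls matching any truth lesion the same
    way (direction not enforced: calling a near-whole-chromosome deletion
    where a chromosome loss was simulated is not a false positive).
    Homoeologous exchanges are excluded from the truth side.
    """
    truth = truth_events[truth_events.event_class != HOMOEOLOGOUS_EXCHANGE]
    t_big = truth[(truth.end_idx - truth.start_idx) >= min_genes]
    c_big = calls[(calls.end_idx - calls.start_idx) >= min_genes]

    def _index(df):
        out: dict[tuple, list] = {}
        for e in df.itertuples(index=False):
            out.setdefault((e.sample_id, e.subgenome, e.chrom), []).append(e)
        return out

    call_idx, truth_idx = _index(calls), _index(truth)
    tp = sum(
        any(_DIRECTION.get(c.event_class) == _DIRECTION[e.event_class]
            and _jaccard(e.start_idx, e.end_idx, c.start_idx, c.end_idx)
            >= min_jaccard
            for c in call_idx.get((e.sample_id, e.subgenome, e.chrom), []))
        for e in t_big.itertuples(index=False))
    matched = sum(
        any(_jaccard(c.start_idx, c.end_idx, e.start_idx, e.end_idx)
            >= min_jaccard
            for e in truth_idx.get((c.sample_id, c.subgenome, c.chrom), []))
        for c in c_big.itertuples(index=False))
    return {
        "sensitivity": tp / len(t_big) if len(t_big) else float("nan"),
        "precision": matched / len(c_big) if len(c_big) else float("nan"),
        "n_truth": int(len(t_big)),
        "n_calls": int(len(c_big)),
    }


def recovered_lesions(truth_events: pd.DataFrame, calls: pd.DataFrame,
                      min_genes: int = 30, min_cover: float = 0.75) -> set:
    """Indices of truth lesions whose interval is covered to at least
    ``min_cover`` by same-direction calls (used to compare detection
    between genome and transcriptome modes, where boundary wobble should
    not count as disagreement)."""
    truth = truth_events[truth_events.event_class != HOMOEOLOGOUS_EXCHANGE]
    t_big = truth[(truth.end_idx - truth.start_idx) >= min_genes]
    out = set()
    for i, e in zip(t_big.index, t_big.itertuples(index=False)):
        sel = calls[(calls.sample_id == e.sample_id)
                    & (calls.subgenome == e.subgenome)
                    & (calls.chrom == e.chrom)]
        cov = np.zeros(e.end_idx - e.start_idx, dtype=bool)
        for c in sel.itertuples(index=False):
            if _DIRECTION.get(c.event_class) != _DIRECTION[e.event_class]:
                continue
            lo, hi = max(c.start_idx, e.start_idx), min(c.end_idx, e.end_idx)
            if hi > lo:
                cov[lo - e.start_idx:hi - e.start_idx] = True
        if cov.mean() >= min_cover:
            out.add(i)
    return out


def saturation_size(mean_del_per_plant: float, mean_frac_genome_per_del: float,
                    target_multiplicity: float = 5.0) -> int:
    """Population size for saturation of deletion coverage.

    A fixed genome point is hit by an expected ``rate x fraction`` deletions
    per plant, so reaching an average of ``target_multiplicity`` instances
    needs ``ceil(target / (rate x fraction))`` lines.
    """
    if target_multiplicity == 0:
        return 0
    if mean_del_per_plant <= 0 or mean_frac_genome_per_del <= 0:
        raise ValueError("per-plant rate and genome fraction must be positive")
    if target_multiplicity < 0:
        raise ValueError("target multiplicity must be non-negative")
    return math.ceil(target_multiplicity
                     / (mean_del_per_plant * mean_frac_genome_per_del) - 1e-9)
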