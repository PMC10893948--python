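"""Homoeologue dosage quantification.

Converts gene-level read counts to RPKM, estimates per-gene copy numbers
against a control-median baseline, and maps homoeologue-pair dosage to the
CMYK tile colours used by genome/transcriptome display tile plots: the
cyan channel encodes the A-genome homoeologue's abundance and the magenta
channel the C-genome homoeologue's, so a balanced AACC genotype renders a
mid blue, deletions render lighter and duplications darker.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DosageError",
    "rpkm_normalize",
    "control_baseline",
    "estimate_copies",
    "colour_map",
    "colour_key",
    "pair_profile",
    "DEFAULT_KEY_GENOTYPES",
]


class DosageError(ValueError):
    pass


DEFAULT_KEY_GENOTYPES = [
    (0, 2), (1, 2), (2, 2), (3, 2), (4, 2),
    (2, 0), (2, 1), (2, 3), (2, 4), (0, 0),
]


def rpkm_normalize(raw: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Reads per kb of gene model per million mapped reads.

    ``rpkm[g, s] = count[g, s] / ((len_g / 1e3) * (total_s / 1e6))`` where
    ``total_s`` is the per-sample sum of raw counts over all genes.
    """
    lengths = gene_lengths.reindex(raw.index)
    if lengths.isna().any():
        missing = raw.index[lengths.isna()][:3].tolist()
        raise DosageError(f"gene lengths missing for {missing}")
    if (lengths <= 0).any():
        bad = raw.index[(lengths <= 0).to_numpy()][:3].tolist()
        raise DosageError(f"non-positive gene length for {bad}")
    totals = raw.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DosageError(f"sample {zero.index[0]!r} has zero total mapped reads")
    return raw.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def control_baseline(rpkm: pd.DataFrame, control_samples: list[str],
                     tau_min: float = 0.5) -> pd.DataFrame:
    """Per-gene median control RPKM and a usability flag.

    Genes whose median control RPKM falls below ``tau_min`` carry too
    little signal for a stable dosage ratio and are masked downstream.
    Requires at least 3 control samples.
    """
    if len(control_samples) < 3:
        raise DosageError("control baseline requires >= 3 control samples")
    if tau_min <= 0:
        raise DosageError("tau_min must be > 0")
    missing = [s for s in control_samples if s not in rpkm.columns]
    if missing:
        raise DosageError(f"control samples absent from matrix: {missing}")
    med = rpkm[control_samples].median(axis=1)
    return pd.DataFrame({"median_rpkm": med, "usable": med >= tau_min})


def estimate_copies(rpkm: pd.DataFrame, baseline: pd.DataFrame,
                    recenter: bool = True) -> pd.DataFrame:
    """Per-gene copy-number estimates ``k = 2 * rpkm / control median``.

    Because RPKM shares a per-sample total, a sample carrying large
    duplications has all its ratios deflated (and deletions inflated);
    with ``recenter`` each sample is rescaled so its genome-wide median
    estimate is exactly 2 — valid as long as most of the genome is at
    baseline copy number.  Unusable genes (low control coverage) are NaN.
    Values are not clipped; callers decide how to treat extreme
    estimates.
    """
    missing = rpkm.index.difference(baseline.index)
    if len(missing):
        raise DosageError(f"baseline missing genes, e.g. {missing[:3].tolist()}")
    base = baseline.loc[rpkm.index]
    with np.errstate(divide="ignore", invalid="ignore"):
        k = 2.0 * rpkm.div(base.median_rpkm, axis=0)
    k[~base.usable] = np.nan
    if recenter:
        k = k.mul(2.0 / k.median(axis=0), axis=1)
    return k


def colour_map(k_a, k_c):
    """CMYK tile colour for one homoeologue pair.

    ``C = clamp(k_A / 4)``, ``M = clamp(k_C / 4)``, Y = K = 0: the
    balanced state (2, 2) is the (0.5, 0.5, 0, 0) mid blue; loss of an A
    segment leaves a magenta-dominated tile, amplification darkens the
    corresponding channel and saturates at 4 copies.  Accepts scalars or
    arrays (NaN passes through for masked pairs).
    """
    k_a = np.asarray(k_a, dtype=float)
    k_c = np.asarray(k_c, dtype=float)
    if np.nanmin(k_a, initial=0) < 0 or np.nanmin(k_c, initial=0) < 0:
        raise DosageError("copy numbers must be non-negative")
    c = np.clip(k_a / 4.0, 0.0, 1.0)
    m = np.clip(k_c / 4.0, 0.0, 1.0)
    y = np.zeros_like(c)
    k = np.zeros_like(c)
    if c.ndim == 0:
        return float(c), float(m), 0.0, 0.0
    return c, m, y, k


def colour_key(genotypes: list[tuple[int, int]] | None = None) -> pd.DataFrame:
    """In-silico genotype colour key for tile-plot legends.

    One row per (a_copies, c_copies) genotype with its CMYK channels;
    the default key spans single-subgenome losses and gains plus the
    double-null (white) state.
    """
    if genotypes is None:
        genotypes = DEFAULT_KEY_GENOTYPES
    seen = set()
    rows = []
    for a, c in genotypes:
        if not (0 <= a <= 4 and 0 <= c <= 4):
            raise DosageError(f"key genotype ({a}, {c}) outside [0, 4]")
        if (a, c) in seen:
            continue
        seen.add((a, c))
        cc, mm, _, _ = colour_map(float(a), float(c))
        rows.append((a, c, cc, mm, 0.0, 0.0))
    return pd.DataFrame(rows, columns=["a_copies", "c_copies", "C", "M", "Y", "K"])


def pair_profile(k: pd.DataFrame, pair_map: pd.DataFrame) -> pd.DataFrame:
    """Long-format dosage profile: one row per (sample, homoeologue pair).

    Columns: sample_id, pair_id, k_A, k_C, masked, C, M.  A pair is masked
    when either partner's copy estimate is unavailable; masked pairs carry
    no colour (NaN channels).
    """
    ka = k.reindex(pair_map.gene_A).to_numpy()
    kc = k.reindex(pair_map.gene_C).to_numpy()
    n_pairs, n_samples = ka.shape
    samples = np.repeat(k.columns.to_numpy(), n_pairs)
    pair_ids = np.tile(pair_map.pair_id.to_numpy(), n_samples)
    ka_f = ka.T.ravel()
    kc_f = kc.T.ravel()
    masked = np.isnan(ka_f) | np.isnan(kc_f)
    c, m, _, _ = colour_map(np.where(masked, np.nan, ka_f),
                            np.where(masked, np.nan, kc_f))
    return pd.DataFrame({
        "sample_id": samples,
        "pair_id": pair_ids,
        "k_A": ka_f,
        "k_C": kc_f,
        "masked": masked,
        "C": c,
        "M": m,
    })
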