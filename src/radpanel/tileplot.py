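"""Genome / Transcriptome Display Tile Plot rendering.

One coloured tile per homoeologue pair (cyan = A-genome dosage, magenta =
C-genome dosage), pairs in A-genome order with chromosome separators, one
row per sample grouped as controls first then treatments by ascending
dose, with an optional in-silico genotype colour key.  Also renders
gene-resolution depth tracks with called intervals marked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from radpanel.cnvcall import smooth  # noqa: E402
from radpanel.dosage import colour_key  # noqa: E402

__all__ = ["PlotSpec", "sample_plot_order", "gdtp_array", "render_gdtp",
           "render_depth_track"]

_MASK_RGB = (200, 200, 200)
_SEP_RGB = (0, 0, 0)


@dataclass(frozen=True)
class PlotSpec:
    """Rendering options for a tile plot."""

    tile_px: int = 4
    include_key: bool = False
    fmt: str = "PNG"

    def __post_init__(self) -> None:
        if self.tile_px < 1:
            raise ValueError("tile_px must be >= 1")
        if self.fmt not in ("PNG", "SVG"):
            raise ValueError("format must be PNG or SVG")


def _cmyk_to_rgb(c: np.ndarray, m: np.ndarray) -> np.ndarray:
    """CMYK (Y=K=0) to 8-bit RGB: R = 1-C, G = 1-M, B = 1."""
    rgb = np.empty(c.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = np.round(255 * (1.0 - c))
    rgb[..., 1] = np.round(255 * (1.0 - m))
    rgb[..., 2] = 255
    return rgb


def sample_plot_order(samples: pd.DataFrame) -> list[str]:
    """Controls first, then treated samples by radiation type and ascending dose."""
    s = samples.copy()
    s["_role"] = (s.role != "control").astype(int)
    s = s.sort_values(["_role", "radiation_type", "dose_Gy", "sample_id"],
                      kind="stable")
    return list(s.sample_id)


def gdtp_array(profiles: pd.DataFrame, pair_map: pd.DataFrame,
               samples: pd.DataFrame, spec: PlotSpec = PlotSpec()) -> np.ndarray:
    """Tile-plot RGB array (one pixel per tile, before tile_px scaling).

    Rows are samples in plot order; columns are homoeologue pairs in
    A-genome order with a black separator column between chromosomes.
    Masked pairs render as a neutral grey gap colour.
    """
    order = sample_plot_order(samples)
    pm = pair_map.sort_values(["chrom_A", "idx_A"],
                              key=lambda s: _chrom_sort_key(s) if s.name == "chrom_A" else s)
    pair_order = list(pm.pair_id)
    wide_c = profiles.pivot(index="sample_id", columns="pair_id", values="C")
    wide_m = profiles.pivot(index="sample_id", columns="pair_id", values="M")
    missing = [s for s in order if s not in wide_c.index]
    if missing:
        raise ValueError(f"sample {missing[0]!r} has no dosage profile")
    c = wide_c.loc[order, pair_order].to_numpy(dtype=float)
    m = wide_m.loc[order, pair_order].to_numpy(dtype=float)
    masked = np.isnan(c) | np.isnan(m)
    rgb = _cmyk_to_rgb(np.nan_to_num(c), np.nan_to_num(m))
    rgb[masked] = _MASK_RGB

    # insert separator columns at chromosome boundaries
    chrom_of = pm.chrom_A.to_numpy()
    cuts = np.flatnonzero(chrom_of[1:] != chrom_of[:-1]) + 1
    parts = []
    prev = 0
    sep = np.full((rgb.shape[0], 1, 3), _SEP_RGB, dtype=np.uint8)
    for cut in list(cuts) + [rgb.shape[1]]:
        parts.append(rgb[:, prev:cut])
        if cut != rgb.shape[1]:
            parts.append(sep)
        prev = cut
    img = np.concatenate(parts, axis=1)

    if spec.include_key:
        key = colour_key()
        krgb = _cmyk_to_rgb(key.C.to_numpy(), key.M.to_numpy())[None, :, :]
        row = np.full((1, img.shape[1], 3), 255, dtype=np.uint8)
        row[0, :krgb.shape[1]] = krgb[0]
        img = np.concatenate([img, np.full((1, img.shape[1], 3), 255, np.uint8), row],
                             axis=0)
    return img


def _chrom_sort_key(s: pd.Series) -> pd.Series:
    return s.str.extract(r"(\d+)", expand=False).astype(int)


def render_gdtp(profiles: pd.DataFrame, pair_map: pd.DataFrame,
                samples: pd.DataFrame, path: str,
                spec: PlotSpec = PlotSpec()) -> np.ndarray:
    """Render the tile plot to PNG (deterministic bytes for fixed inputs)."""
    arr = gdtp_array(profiles, pair_map, samples, spec)
    big = np.kron(arr, np.ones((spec.tile_px, spec.tile_px, 1), dtype=np.uint8))
    Image.fromarray(big, mode="RGB").save(path, format="PNG")
    return arr


def render_depth_track(k_values, calls: pd.DataFrame, chrom: str, path: str,
                       window: int = 15) -> None:
    """Gene-resolution dosage track for one sample and chromosome.

    Line plot of the smoothed copy estimate along gene order, with called
    duplication intervals shaded red and deletions blue (marker extents
    equal the call intervals exactly).
    """
    k = np.asarray(k_values, dtype=float)
    if k.size == 0:
        raise ValueError(f"chromosome {chrom!r} has no genes to plot")
    ks = smooth(k, window)
    fig, ax = plt.subplots(figsize=(8, 2.2), dpi=100)
    ax.plot(np.arange(len(ks)), ks, color="black", lw=0.8)
    for ev in calls.itertuples(index=False):
        if getattr(ev, "chrom", chrom) != chrom:
            continue
        colour = "red" if "dup" in ev.event_class or "gain" in ev.event_class else "blue"
        ax.axvspan(ev.start_idx, ev.end_idx, color=colour, alpha=0.3, lw=0)
    ax.axhline(2.0, color="grey", lw=0.5, ls="--")
    ax.set_xlabel(f"gene order along {chrom}")
    ax.set_ylabel("copy number")
    ax.set_ylim(-0.2, 4.5)
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": None})
    plt.close(fig)
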