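"""Synthetic irradiated-panel generator.

Emulates an AACC allotetraploid (A genome from *B. rapa*, C genome from
*B. oleracea*) re-sequencing panel: ~20k homoeologue gene pairs over
10 A + 9 C chromosomes; dose-dependent Poisson counts of segmental
deletions/duplications plus rare whole-chromosome events; M1-heterozygous
lesions segregating 1:2:1 in the selfed M2 generation; sibling reciprocal
inheritance of lost segments; homoeologous exchanges in untreated material;
negative-binomial read-count noise (tighter for genome re-sequencing,
looser for transcriptome); and SNV/InDel call sets with a false-positive
model stratified by variant-allele read depth.

Every generator is deterministic for a fixed :class:`PanelConfig`:
stage-specific random streams are spawned from ``config.seed`` so that,
for example, regenerating counts does not perturb the lesion draw.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "DoseGroup",
    "RateCoefficients",
    "NoiseModel",
    "TraitParams",
    "PanelConfig",
    "EVENT_COLUMNS",
    "make_pair_map",
    "build_sample_sheet",
    "simulate_lesions",
    "simulate_counts",
    "simulate_variants",
    "simulate_phenotypes",
]


class ConfigError(ValueError):
    """Raised when a panel configuration violates its invariants."""


CHROMS_A = tuple(f"A{i}" for i in range(1, 11))
CHROMS_C = tuple(f"C{i}" for i in range(1, 10))

EVENT_COLUMNS = [
    "sample_id",
    "subgenome",
    "chrom",
    "start_idx",
    "end_idx",
    "event_class",
    "copies",
    "zygosity",
]

SEGMENTAL_DELETION = "segmental_deletion"
SEGMENTAL_DUPLICATION = "segmental_duplication"
CHROMOSOME_LOSS = "chromosome_loss"
CHROMOSOME_GAIN = "chromosome_gain"
HOMOEOLOGOUS_EXCHANGE = "homoeologous_exchange"


@dataclass(frozen=True)
class DoseGroup:
    """One radiation treatment batch: M1 plants and their genotyped M2 sibs."""

    radiation_type: str  # "gamma" or "fnt"
    dose_gy: float
    n_m1: int = 8
    sibs_per_m1: int = 2

    def __post_init__(self) -> None:
        if self.radiation_type not in ("gamma", "fnt"):
            raise ConfigError(f"unknown radiation type {self.radiation_type!r}")
        if self.dose_gy < 0:
            raise ConfigError(f"dose must be non-negative, got {self.dose_gy}")
        if self.n_m1 < 1 or self.sibs_per_m1 < 1:
            raise ConfigError("n_m1 and sibs_per_m1 must be positive")


@dataclass(frozen=True)
class RateCoefficients:
    """Per-Gy Poisson rates of lesion classes in an M1 plant.

    Defaults are the observed per-plant event rates of the 2000 Gy gamma
    calibration batch divided by the dose, i.e. lesion counts scale
    linearly through the origin with absorbed dose.
    """

    del_a: float = 1.5 / 2000
    del_c: float = 2.38 / 2000
    dup_a: float = 0.63 / 2000
    dup_c: float = 0.31 / 2000
    chrom_loss: float = 0.06 / 2000
    chrom_gain: float = 0.06 / 2000

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"rate {f.name} must be finite and >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Read-count noise model.

    mean_depth is the expected read count per kb of gene model at the
    balanced copy number (2); with ~2 kb genes and 150 b reads the genome
    default corresponds to roughly 12-fold genome coverage.  The genome
    dispersion default follows from that depth: a ~160-read gene count
    has an 8% Poisson CV, and library/mappability effects add roughly
    10%, so the extra-Poisson CV is ~13% (r = 60).  Transcriptome mode
    adds a per-gene lognormal expression factor (coefficient of variation
    ``expression_cv``) and uses a much looser dispersion, since
    biological expression variation between plants dominates there.
    """

    mode: str = "genome"
    mean_depth: float = 80.0
    dispersion: float = 60.0
    expression_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("genome", "transcriptome"):
            raise ConfigError(f"unknown noise mode {self.mode!r}")
        if self.mean_depth <= 0 or self.dispersion <= 0 or self.expression_cv < 0:
            raise ConfigError("mean_depth, dispersion > 0 and expression_cv >= 0 required")

    @classmethod
    def transcriptome(cls, mean_depth: float = 60.0, dispersion: float = 25.0,
                      expression_cv: float = 0.4) -> "NoiseModel":
        """Transcriptome defaults: biological CV ~0.2 between plants
        (near-isogenic siblings under controlled conditions) plus a wide
        lognormal spread of per-gene expression levels."""
        return cls(mode="transcriptome", mean_depth=mean_depth,
                   dispersion=dispersion, expression_cv=expression_cv)


@dataclass(frozen=True)
class TraitParams:
    """Linear gene-dosage model of seed-oil fatty-acid composition (mol%).

    Anchors: a wild type (4 functional FAE1 copies, 2 functional FAD2.A5
    copies) sits at ~46% erucic / 15% oleic / 15% linoleic; a FAD2.A5 null
    at ~50% erucic / 19% oleic / 8% linoleic.  Erucic acid is additive in
    total functional FAE1 copies.
    """

    erucic_intercept: float = 10.0
    erucic_per_fae1_copy: float = 9.0
    erucic_per_fad2_loss: float = 2.0
    oleic_base: float = 15.0
    oleic_per_fae1_loss: float = 1.5
    oleic_per_fad2_loss: float = 2.0
    linoleic_base: float = 15.0
    linoleic_per_fad2_loss: float = 3.5
    resid_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.resid_sd < 0:
            raise ConfigError("residual SD must be non-negative")


def _default_doses() -> tuple[DoseGroup, ...]:
    # The calibration design: 8 M1 families x 2 sibs per gamma dose,
    # 8 M1 families x 1 plant per fast-neutron dose.
    gamma = tuple(DoseGroup("gamma", d, 8, 2) for d in (750, 1500, 1750, 2000))
    fnt = tuple(DoseGroup("fnt", d, 8, 1) for d in (40, 60, 80, 100))
    return gamma + fnt


@dataclass(frozen=True)
class PanelConfig:
    """Full configuration of a synthetic irradiated panel."""

    n_pairs_per_chrom: int = 200
    chrom_names_a: tuple[str, ...] = CHROMS_A
    chrom_names_c: tuple[str, ...] = CHROMS_C
    doses: tuple[DoseGroup, ...] = field(default_factory=_default_doses)
    n_controls: int = 16
    rates: RateCoefficients = field(default_factory=RateCoefficients)
    recip_prob: float = 0.3
    he_prob_control: float = 0.1
    min_seg_genes: int = 5
    p_valid_gt2: float = 0.38
    p_valid_eq2: float = 0.035
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs_per_chrom < 1:
            raise ConfigError("at least one homoeologue pair per chromosome is required")
        if not self.doses:
            raise ConfigError("doses must be non-empty")
        for p in (self.recip_prob, self.he_prob_control,
                  self.p_valid_gt2, self.p_valid_eq2):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.min_seg_genes < 1:
            raise ConfigError("min_seg_genes must be >= 1")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent random stream for one generator stage."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


# ---------------------------------------------------------------------------
# pair map

def make_pair_map(config: PanelConfig) -> pd.DataFrame:
    """Create an ordered homoeologue gene-pair map.

    One row per A/C pair, ordered by A-genome chromosome then gene-order
    index (the coordinate system of all dosage analysis).  C-genome
    partners are laid out contiguously over the 9 C chromosomes; C gene
    models are drawn slightly longer than their A partners, so the C
    genome is the larger of the two.

    Columns: pair_id, gene_A, chrom_A, idx_A, len_A_bp, gene_C, chrom_C,
    idx_C, len_C_bp.
    """
    rng = config.rng(0)
    n_a = len(config.chrom_names_a)
    n_total = n_a * config.n_pairs_per_chrom
    chrom_a = np.repeat(config.chrom_names_a, config.n_pairs_per_chrom)
    idx_a = np.tile(np.arange(config.n_pairs_per_chrom), n_a)

    # gene-model lengths: lognormal around ~2 kb, C ~10% longer on average
    len_a = np.clip(rng.lognormal(np.log(2000.0), 0.45, n_total), 300, 12000).astype(int)
    len_c = np.clip((len_a * rng.lognormal(np.log(1.1), 0.08, n_total)).astype(int),
                    300, 15000)

    # distribute pairs (in A order) contiguously over the C chromosomes
    n_c = len(config.chrom_names_c)
    bounds = np.linspace(0, n_total, n_c + 1).astype(int)
    chrom_c = np.empty(n_total, dtype=object)
    idx_c = np.empty(n_total, dtype=int)
    for i, name in enumerate(config.chrom_names_c):
        lo, hi = bounds[i], bounds[i + 1]
        chrom_c[lo:hi] = name
        idx_c[lo:hi] = np.arange(hi - lo)

    pm = pd.DataFrame({
        "pair_id": [f"pair{i:05d}" for i in range(n_total)],
        "gene_A": [f"{c}.g{j:04d}" for c, j in zip(chrom_a, idx_a)],
        "chrom_A": chrom_a,
        "idx_A": idx_a,
        "len_A_bp": len_a,
        "gene_C": [f"{c}.g{j:04d}" for c, j in zip(chrom_c, idx_c)],
        "chrom_C": chrom_c,
        "idx_C": idx_c,
        "len_C_bp": len_c,
    })
    return pm


def chrom_sizes(pair_map: pd.DataFrame, subgenome: str) -> dict[str, int]:
    """Number of gene models per chromosome of one subgenome."""
    col = f"chrom_{subgenome}"
    return pair_map.groupby(col, sort=False).size().to_dict()


# ---------------------------------------------------------------------------
# sample sheet

def build_sample_sheet(config: PanelConfig) -> pd.DataFrame:
    """Sample sheet: sample_id, role, radiation_type, dose_Gy, m1_family, sib_label."""
    rows = []
    for i in range(config.n_controls):
        rows.append((f"CTRL_{i + 1:02d}", "control", "none", 0.0, "NA", "NA"))
    for grp in config.doses:
        prefix = "G" if grp.radiation_type == "gamma" else "FNT"
        for fam in range(1, grp.n_m1 + 1):
            family = f"{prefix}{int(grp.dose_gy)}_{fam}"
            for s in range(grp.sibs_per_m1):
                sib = chr(ord("a") + s)
                rows.append((f"{family}{sib}", "treated", grp.radiation_type,
                             float(grp.dose_gy), family, sib))
    return pd.DataFrame(
        rows, columns=["sample_id", "role", "radiation_type", "dose_Gy",
                       "m1_family", "sib_label"])


# ---------------------------------------------------------------------------
# lesion simulation

def _draw_interval(rng: np.random.Generator, n_genes: int,
                   min_len: int) -> tuple[int, int]:
    """Log-uniform segment length between min_len and the chromosome size."""
    lo = min(min_len, n_genes)
    length = int(round(np.exp(rng.uniform(np.log(lo), np.log(n_genes)))))
    length = max(1, min(length, n_genes))
    start = int(rng.integers(0, n_genes - length + 1))
    return start, start + length


def _place_segment(rng: np.random.Generator, chrom_list: list[str],
                   sizes: dict[str, int], min_len: int,
                   occupied: dict, scope) -> tuple[str, int, int]:
    """Draw (chromosome, start, end), redrawing chromosome, length and
    start together until the segment avoids every interval already placed
    in this scope (an M1 family, or a single line for seed-lot
    exchanges).  Independent lesions stacking on the same genes would
    make the truth copy state ambiguous; with realistic event counts a
    non-overlapping placement is found almost immediately.
    """
    for _ in range(100):
        chrom = chrom_list[rng.integers(len(chrom_list))]
        occ = occupied.setdefault((scope, chrom), [])
        s, e = _draw_interval(rng, sizes[chrom], min_len)
        if all(e <= os or s >= oe for os, oe in occ):
            occ.append((s, e))
            return chrom, s, e
    occ.append((s, e))  # pathological saturation; accept the collision
    return chrom, s, e


def _segregate(rng: np.random.Generator) -> int:
    """M2 genotype of a lesion heterozygous in the selfed M1 parent.

    Returns the number of lesion-carrying haplotypes (0, 1 or 2) with
    probabilities 1/4 : 1/2 : 1/4.
    """
    return int(rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25]))


def simulate_lesions(config: PanelConfig, pair_map: pd.DataFrame,
                     samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Draw large-scale lesions for every panel sample.

    Rate coefficients are calibrated to the *observed* per-plant rates of
    the genotyped M2 generation.  A lesion heterozygous in the selfed M1
    parent is transmitted to (and visible in) 3/4 of its offspring, so
    per-family class counts are drawn Poisson with mean
    ``rate x dose x 4/3``; each lesion then segregates 1:2:1 among the
    genotyped sibs (homozygous absent : heterozygous : homozygous
    present), making the expected number of events per genotyped plant
    exactly ``rate x dose`` (when ``recip_prob`` is 0; the reciprocal
    pathway shifts a small share of deletions into duplications).  With
    probability ``recip_prob`` a deleted segment is instead captured by
    one sibling as an extra copy while another sibling carries the
    deletion (reciprocal inheritance).  Lesions of one family never
    overlap on a chromosome.  Every line, including untreated controls,
    may carry a pre-existing homoeologous exchange with probability
    ``he_prob_control``.

    Returns an event table with columns ``EVENT_COLUMNS`` (0-based,
    half-open gene-order index intervals).  Homoeologous-exchange rows
    record the *gaining* subgenome; the reciprocal loss on the partner
    subgenome is implied by the pair map.
    """
    rng = config.rng(1)
    if samples is None:
        samples = build_sample_sheet(config)
    sizes = {"A": chrom_sizes(pair_map, "A"), "C": chrom_sizes(pair_map, "C")}
    chrom_lists = {"A": list(sizes["A"]), "C": list(sizes["C"])}
    rows: list[tuple] = []

    def add(sample, sub, chrom, s, e, klass, copies, zyg):
        rows.append((sample, sub, chrom, int(s), int(e), klass, int(copies), zyg))

    treated = samples[samples.role == "treated"]
    occupied_all: dict[tuple, list[tuple[int, int]]] = {}
    for (family, dose), fam in treated.groupby(["m1_family", "dose_Gy"], sort=False):
        if dose < 0:
            raise ConfigError(f"negative dose for family {family}")
        sib_ids = list(fam.sample_id)
        r = config.rates
        # whole-chromosome events first: they occupy their chromosome, so
        # segmental lesions of the same family land elsewhere and the
        # truth copy state of every event stays unambiguous
        for klass, rate in ((CHROMOSOME_LOSS, r.chrom_loss),
                            (CHROMOSOME_GAIN, r.chrom_gain)):
            for _ in range(rng.poisson(rate * dose * 4.0 / 3.0)):
                sub = "A" if rng.random() < 0.5 else "C"
                chrom = chrom_lists[sub][rng.integers(len(chrom_lists[sub]))]
                n = sizes[sub][chrom]
                occ = occupied_all.setdefault(((family, sub), chrom), [])
                if occ:
                    continue  # chromosome already hit; drop this rare draw
                occ.append((0, n))
                for sid in sib_ids:
                    dose_hap = _segregate(rng)
                    if dose_hap == 0:
                        continue
                    copies = 2 - dose_hap if klass == CHROMOSOME_LOSS else 2 + dose_hap
                    zyg = "hom" if dose_hap == 2 else "het"
                    add(sid, sub, chrom, 0, n, klass, copies, zyg)
        class_plan = [
            (SEGMENTAL_DELETION, "A", r.del_a), (SEGMENTAL_DELETION, "C", r.del_c),
            (SEGMENTAL_DUPLICATION, "A", r.dup_a), (SEGMENTAL_DUPLICATION, "C", r.dup_c),
        ]
        for klass, sub, rate in class_plan:
            for _ in range(rng.poisson(rate * dose * 4.0 / 3.0)):
                chrom, s, e = _place_segment(
                    rng, chrom_lists[sub], sizes[sub], config.min_seg_genes,
                    occupied_all, (family, sub))
                is_del = klass == SEGMENTAL_DELETION
                if is_del and len(sib_ids) >= 2 and rng.random() < config.recip_prob:
                    # reciprocal capture: one sib loses the segment, another
                    # inherits it as an extra copy
                    a, b = rng.choice(len(sib_ids), size=2, replace=False)
                    add(sib_ids[a], sub, chrom, s, e, SEGMENTAL_DELETION, 1, "het")
                    add(sib_ids[b], sub, chrom, s, e, SEGMENTAL_DUPLICATION, 3, "het")
                    continue
                for sid in sib_ids:
                    dose_hap = _segregate(rng)
                    if dose_hap == 0:
                        continue
                    if is_del:
                        copies = 2 - dose_hap
                    else:
                        copies = 2 + dose_hap
                    zyg = "hom" if dose_hap == 2 else "het"
                    add(sid, sub, chrom, s, e, klass, copies, zyg)
    # pre-existing homoeologous exchanges, seen even in untreated material
    fam_of = samples.set_index("sample_id").m1_family.to_dict()
    for sid in samples.sample_id:
        if rng.random() < config.he_prob_control:
            gain = "A" if rng.random() < 0.5 else "C"
            scope = fam_of.get(sid, "NA")
            scope = sid if scope in (None, "NA") else scope
            chrom, s, e = _place_segment(
                rng, chrom_lists[gain], sizes[gain], config.min_seg_genes,
                occupied_all, (scope, gain))
            hom = rng.random() < 0.5
            add(sid, gain, chrom, s, e, HOMOEOLOGOUS_EXCHANGE,
                4 if hom else 3, "hom" if hom else "het")

    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# read-count simulation

def copy_number_matrix(pair_map: pd.DataFrame, events: pd.DataFrame,
                       samples: pd.DataFrame) -> pd.DataFrame:
    """Per-gene copy number (baseline 2) after overlaying events.

    Index: gene ids (all A genes then all C genes in pair order); columns:
    sample ids.  A homoeologous-exchange event on the gaining subgenome
    also sets the partner genes to ``4 - copies``.
    """
    genes = pd.Index(pd.concat([pair_map.gene_A, pair_map.gene_C]), name="gene")
    cn = pd.DataFrame(2.0, index=genes, columns=list(samples.sample_id))
    pos = {}  # (subgenome, chrom) -> (gene ids array, idx array, partner ids)
    for sub, other in (("A", "C"), ("C", "A")):
        for chrom, grp in pair_map.groupby(f"chrom_{sub}", sort=False):
            grp = grp.sort_values(f"idx_{sub}")
            pos[(sub, chrom)] = (
                grp[f"gene_{sub}"].to_numpy(),
                grp[f"idx_{sub}"].to_numpy(),
                grp[f"gene_{other}"].to_numpy(),
            )
    for ev in events.itertuples(index=False):
        key = (ev.subgenome, ev.chrom)
        if key not in pos:
            raise ConfigError(
                f"sample {ev.sample_id}: unknown chromosome {ev.chrom!r} "
                f"on subgenome {ev.subgenome}")
        gids, idx, partners = pos[key]
        inside = (idx >= ev.start_idx) & (idx < ev.end_idx)
        cn.loc[gids[inside], ev.sample_id] = ev.copies
        if ev.event_class == HOMOEOLOGOUS_EXCHANGE:
            cn.loc[partners[inside], ev.sample_id] = 4 - ev.copies
    return cn


def simulate_counts(pair_map: pd.DataFrame, events: pd.DataFrame,
                    samples: pd.DataFrame, noise: NoiseModel,
                    config: PanelConfig) -> pd.DataFrame:
    """Negative-binomial gene-level read counts for every sample.

    The expected count of gene g in sample s is
    ``mean_depth x (len_g / 1 kb) x (copies_{g,s} / 2)``, multiplied in
    transcriptome mode by a per-gene lognormal expression factor shared
    across samples.  Counts are NB-distributed with the model's dispersion
    (variance m + m^2/dispersion).
    """
    rng = config.rng(2 if noise.mode == "genome" else 3)
    cn = copy_number_matrix(pair_map, events, samples)
    lengths = pd.concat([
        pd.Series(pair_map.len_A_bp.values, index=pair_map.gene_A),
        pd.Series(pair_map.len_C_bp.values, index=pair_map.gene_C),
    ])
    base = noise.mean_depth * (lengths.loc[cn.index].to_numpy() / 1000.0)
    if noise.mode == "transcriptome" and noise.expression_cv > 0:
        sigma = np.sqrt(np.log1p(noise.expression_cv ** 2))
        expr = rng.lognormal(-sigma ** 2 / 2.0, sigma, size=len(base))
        base = base * expr
    mean = base[:, None] * (cn.to_numpy() / 2.0)
    r = noise.dispersion
    p = np.where(mean > 0, r / (r + mean), 1.0)
    counts = rng.negative_binomial(r, p)
    counts[mean == 0] = 0
    return pd.DataFrame(counts, index=cn.index, columns=cn.columns)


# ---------------------------------------------------------------------------
# small-variant simulation

_BASES = np.array(list("ACGT"))


def simulate_variants(config: PanelConfig, pair_map: pd.DataFrame,
                      samples: pd.DataFrame | None = None,
                      n_true_per_sample: float = 12.0,
                      n_fp_eq2_per_sample: float = 20.0,
                      n_fp_gt2_per_sample: float = 8.0,
                      n_artifacts: int = 30,
                      n_control_variants: int = 20,
                      n_lowqual_per_sample: float = 5.0,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a panel SNV/InDel call set with realistic failure modes.

    Emitted per-sample calls comprise: (i) true line-specific SNVs and
    InDels; (ii) false-positive calls whose validation probability depends
    on variant-allele read depth (``p_valid_gt2`` for VAD > 2,
    ``p_valid_eq2`` for VAD = 2 — at defaults 38% and 3.5% of emitted
    calls in those strata are real); (iii) systematic artifact calls
    shared across many samples including controls; (iv) pre-existing
    variation present in the control master set; (v) low-quality noise
    records (QUAL <= 20).

    Returns ``(calls, truth)``.  ``calls`` has one row per (variant,
    sample) with chrom, pos, ref, alt, qual, sample_id, vad, total_depth,
    gt; ``truth`` adds is_true and category.
    """
    if not (0 <= config.p_valid_gt2 <= 1 and 0 <= config.p_valid_eq2 <= 1):
        raise ConfigError("validation probabilities must lie in [0, 1]")
    rng = config.rng(4)
    if samples is None:
        samples = build_sample_sheet(config)
    sizes = {c: n * 2000 for c, n in chrom_sizes(pair_map, "A").items()}
    chroms = list(sizes)
    used: set[tuple[str, int]] = set()

    def new_site():
        while True:
            c = chroms[rng.integers(len(chroms))]
            p = int(rng.integers(100, sizes[c] - 100))
            if (c, p) not in used:
                used.add((c, p))
                return c, p

    def alleles(kind: str) -> tuple[str, str]:
        if kind == "snv":
            i = rng.integers(4)
            j = (i + 1 + rng.integers(3)) % 4
            return _BASES[i], _BASES[j]
        L = int(rng.integers(1, 25))
        seq = "".join(rng.choice(_BASES, L + 1))
        return (seq, seq[0]) if rng.random() < 0.5 else (seq[0], seq)

    rows, truth_rows = [], []

    def emit(sample_id, kind, vad, qual, is_true, category):
        chrom, pos = new_site()
        ref, alt = alleles(kind)
        total = vad + int(rng.integers(4, 14))
        gt = "0/1"
        rows.append((chrom, pos, ref, alt, qual, sample_id, vad, total, gt))
        truth_rows.append((chrom, pos, ref, alt, sample_id, vad, is_true, category))

    controls = samples[samples.role == "control"].sample_id.to_list()
    mutants = samples[samples.role == "treated"].sample_id.to_list()

    for sid in mutants:
        for _ in range(rng.poisson(n_true_per_sample)):
            kind = "snv" if rng.random() < 0.7 else "indel"
            vad = max(2, int(rng.poisson(6)))
            emit(sid, kind, vad, float(np.round(rng.uniform(40, 220), 1)),
                 True, "true_line_specific")
        for _ in range(rng.poisson(n_fp_eq2_per_sample)):
            is_true = bool(rng.random() < config.p_valid_eq2)
            emit(sid, "snv" if rng.random() < 0.7 else "indel", 2,
                 float(np.round(rng.uniform(21, 80), 1)), is_true, "vad2_stratum")
        for _ in range(rng.poisson(n_fp_gt2_per_sample)):
            is_true = bool(rng.random() < config.p_valid_gt2)
            emit(sid, "snv" if rng.random() < 0.7 else "indel",
                 int(rng.integers(3, 13)),
                 float(np.round(rng.uniform(21, 120), 1)), is_true, "vadgt2_stratum")
        for _ in range(rng.poisson(n_lowqual_per_sample)):
            emit(sid, "snv", int(rng.integers(2, 6)),
                 float(np.round(rng.uniform(3, 20), 1)), False, "low_quality")

    # systematic artifacts: same site called in many samples and controls
    for _ in range(n_artifacts):
        chrom, pos = new_site()
        ref, alt = alleles("snv")
        carriers = [s for s in mutants + controls if rng.random() < 0.6]
        while len(carriers) < 10:
            carriers = [s for s in mutants + controls if rng.random() < 0.6]
        for sid in carriers:
            vad = int(rng.integers(3, 12))
            rows.append((chrom, pos, ref, alt,
                         float(np.round(rng.uniform(30, 120), 1)),
                         sid, vad, vad + int(rng.integers(4, 14)), "0/1"))
            truth_rows.append((chrom, pos, ref, alt, sid, vad, False, "artifact"))

    # pre-existing variation: in controls, leaks into a few mutants
    for _ in range(n_control_variants):
        chrom, pos = new_site()
        ref, alt = alleles("snv")
        carriers = controls + [s for s in mutants if rng.random() < 0.15]
        for sid in carriers:
            vad = int(rng.integers(4, 12))
            rows.append((chrom, pos, ref, alt,
                         float(np.round(rng.uniform(30, 120), 1)),
                         sid, vad, vad + int(rng.integers(4, 14)), "0/1"))
            truth_rows.append((chrom, pos, ref, alt, sid, vad, False, "pre_existing"))

    cols = ["chrom", "pos", "ref", "alt", "qual", "sample_id", "vad", "total_depth", "gt"]
    calls = pd.DataFrame(rows, columns=cols)
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "sample_id", "vad", "is_true", "category"])
    order = np.lexsort((calls.pos.to_numpy(), calls.chrom.to_numpy()))
    return calls.iloc[order].reset_index(drop=True), truth.iloc[
        np.lexsort((truth.pos.to_numpy(), truth.chrom.to_numpy()))].reset_index(drop=True)


# ---------------------------------------------------------------------------
# phenotype simulation

def simulate_phenotypes(genotypes: pd.DataFrame,
                        params: TraitParams = TraitParams(),
                        seed: int = 0) -> pd.DataFrame:
    """Seed-oil fatty-acid composition from FAE1/FAD2 copy states.

    ``genotypes`` needs columns sample_id, fae1_a8_copies, fae1_c3_copies,
    fad2_a5_copies (functional copies; wild type 2/2/2) and optionally
    ``group``.  Erucic acid rises linearly with total functional FAE1
    copies; loss of functional FAD2.A5 lowers linoleic and raises oleic
    and erucic.  Gaussian residuals with SD ``params.resid_sd``.
    """
    if params.resid_sd < 0:
        raise ConfigError("residual SD must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    fae1 = genotypes.fae1_a8_copies.to_numpy(float) + genotypes.fae1_c3_copies.to_numpy(float)
    fad2_loss = 2.0 - genotypes.fad2_a5_copies.to_numpy(float)
    n = len(genotypes)
    erucic = (params.erucic_intercept + params.erucic_per_fae1_copy * fae1
              + params.erucic_per_fad2_loss * fad2_loss)
    oleic = (params.oleic_base + params.oleic_per_fae1_loss * (4.0 - fae1)
             + params.oleic_per_fad2_loss * fad2_loss)
    linoleic = params.linoleic_base - params.linoleic_per_fad2_loss * fad2_loss
    out = pd.DataFrame({
        "sample_id": genotypes.sample_id,
        "group": genotypes["group"] if "group" in genotypes else "NA",
        "erucic": np.maximum(0.0, erucic + rng.normal(0, params.resid_sd, n)),
        "oleic": np.maximum(0.0, oleic + rng.normal(0, params.resid_sd, n)),
        "linoleic": np.maximum(0.0, linoleic + rng.normal(0, params.resid_sd, n)),
    })
    return out
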