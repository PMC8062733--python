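"""Coupled genome / peak / ChIP-signal / expression simulator with ground truth.

The generator emulates the statistical structure of an interferon-β
stimulation study in epithelial cells:

* a motif-free background genome (any window matching a GAS or ISRE consensus
  is resampled), with GAS/ISRE/both consensus instances planted only inside
  designated peaks;
* two kinetic classes of inducible binding — an early class peaking at
  0.5–1 h (GAF-like, the GAS-motif peaks) and a late class peaking at 2–4 h
  (ISGF3-like, the ISRE/BOTH peaks) — with multiplicative lognormal tag
  noise;
* a dose gate: GAS-class peaks are not induced below the gating dose
  (low-dose IFN-β activates ISGF3 but not GAF);
* an expression experiment (unstimulated, low-dose β, low-dose γ, the
  mixture, high-dose β) with negative-binomial counts, ISGs induced by
  high-dose β, and supra-additive mixing (mean mixed RPKM = s·(RPKM_β +
  RPKM_γ)) planted on ISGs whose linked peak carries both motifs;
* a cell-mode toggle: genes linked to GAS-only peaks are never induced in
  "epithelial" mode and induced like the rest in "macrophage" mode.

Every random draw flows from a single integer seed through named
``numpy.random.SeedSequence`` streams, so outputs are byte-identical across
runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ifnsynergy.errors import GenerationError, ValidationError
from ifnsynergy.io import (
    FastaStore,
    GenomicInterval,
    condition_name,
    write_bed,
    write_fasta,
    write_matrix,
    write_tss_table,
)
from ifnsynergy.motifs import DEFAULT_MODELS, count_family_hits, scan_codes

CATEGORY_ORDER = ("GAS", "ISRE", "BOTH", "NO_MOTIF")

# printed category sizes at n = 723 peaks, as proportions
DEFAULT_PROPORTIONS = {
    "GAS": 280 / 723,
    "ISRE": 201 / 723,
    "BOTH": 155 / 723,
    "NO_MOTIF": 87 / 723,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class KineticClass:
    """A kinetic archetype: relative log2 amplitude per stimulated timepoint.

    The realized fold at timepoint i is 2**(amplitude * shape[i]) with the
    peak log2 amplitude drawn from ``log2_fold_range``.
    """

    shape: tuple[float, ...]
    log2_fold_range: tuple[float, float]


DEFAULT_KINETICS = {
    # early = GAF-like: maximal at 0.5 h, decaying by 4 h; weaker on average
    "early": KineticClass(shape=(1.0, 0.85, 0.5, 0.25), log2_fold_range=(3.0, 4.6)),
    # late = ISGF3-like: maximal at 4 h
    "late": KineticClass(shape=(0.2, 0.4, 0.9, 1.0), log2_fold_range=(3.6, 6.0)),
}


@dataclass
class SimulationParams:
    """All knobs of the simulator; defaults encode the study conditions."""

    n_chroms: int = 5
    chrom_length: int | None = None  # None = auto-sized from the layout
    gc_background: float = 0.42
    n_peaks: int = 723
    category_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    n_genes: int = 5000
    n_isgs: int = 179
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)
    doses: tuple[float, ...] = (1.0, 10.0)
    kinetic_params: Mapping[str, KineticClass] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS)
    )
    gas_dose_gate: float = 10.0
    synergy_factor: float = 2.0
    nb_dispersion: float = 0.02
    chip_noise_sigma: float = 0.2
    seed: int = 0
    # secondary structure
    frac_inducible: float = 0.9
    promoter_frac: float = 1 / 3
    n_chip_reps: int = 2
    n_rna_reps: int = 3
    cell_mode: str = "epithelial"
    linked_isg_rate: float = 0.45
    peak_width_range: tuple[int, int] = (200, 400)
    weak_fold_range: tuple[float, float] = (1.0, 1.5)
    basal_tag_scale: float = 30.0
    basal_tag_sigma: float = 0.5
    isg_fold_log2_range: tuple[float, float] = (3.0, 6.0)
    isg_single_rpkm_range: tuple[float, float] = (50.0, 200.0)
    rna_library_size: int = 8_000_000
    induction_fold: float = 2.0
    min_timepoints: int = 2
    target_spacing: int = 8000
    filler_spacing: int = 300

    def __post_init__(self) -> None:
        total = sum(self.category_proportions.get(c, 0.0) for c in CATEGORY_ORDER)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("category proportions must sum to 1")
        for name in ("n_chroms", "n_peaks", "n_genes", "n_isgs", "n_chip_reps", "n_rna_reps"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.synergy_factor <= 0:
            raise ValidationError("synergy_factor must be > 0")
        if not 0 <= self.gc_background <= 1:
            raise ValidationError("gc_background must be in [0, 1]")
        if self.n_genes <= self.n_peaks:
            raise ValidationError("need more genes than peaks (one linked gene per peak)")
        if self.timepoints[0] != 0:
            raise ValidationError("first timepoint must be the basal time 0")
        if self.cell_mode not in ("epithelial", "macrophage"):
            raise ValidationError("cell_mode must be 'epithelial' or 'macrophage'")
        for kc in self.kinetic_params.values():
            if len(kc.shape) != len(self.timepoints) - 1:
                raise ValidationError("kinetic shape must cover the stimulated timepoints")


@dataclass
class TruthTables:
    """Planted ground truth: one row per peak and per gene."""

    peaks: pd.DataFrame
    genes: pd.DataFrame
    peak_folds: pd.DataFrame | None = None  # peak x (dose, time) planted fold


@dataclass
class ExpressionSim:
    counts: pd.DataFrame
    lengths: pd.Series
    design: pd.DataFrame


@dataclass
class SyntheticDataset:
    genome: FastaStore
    peaks: list[GenomicInterval]
    signal: pd.DataFrame
    expression: ExpressionSim
    truth: TruthTables
    tss: pd.DataFrame


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def allocate_categories(n_peaks: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of peaks to categories.

    Reproduces the printed proportions exactly at their original total (e.g.
    280/155/201/87 at n = 723).  Remainder ties break in the fixed category
    order GAS, ISRE, BOTH, NO_MOTIF.
    """
    quotas = {c: n_peaks * proportions.get(c, 0.0) for c in CATEGORY_ORDER}
    counts = {c: int(math.floor(q + 1e-9)) for c, q in quotas.items()}
    short = n_peaks - sum(counts.values())
    remainders = sorted(
        CATEGORY_ORDER,
        key=lambda c: (-(quotas[c] - math.floor(quotas[c] + 1e-9)), CATEGORY_ORDER.index(c)),
    )
    for c in remainders[:short]:
        counts[c] += 1
    return counts


# ---------------------------------------------------------------------------
# Layout: deterministic placement of genes and peaks


@dataclass
class _Layout:
    chrom_names: list[str]
    chrom_length: int
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, linked_peak
    peaks: pd.DataFrame  # peak_id, chrom, start, end, category, kinetic_class,
    #                      assigned_inducible, linked_gene, promoter, signed_distance


_EDGE_MARGIN = 2000
_ZONE_GAP = 10_000


def _layout(params: SimulationParams) -> _Layout:
    rng = _rng(params.seed, 1)
    n_peaks, n_genes = params.n_peaks, params.n_genes
    n_fillers = n_genes - n_peaks
    chroms = [f"chr{i + 1}" for i in range(params.n_chroms)]

    counts = allocate_categories(n_peaks, params.category_proportions)
    categories = np.repeat(
        [c for c in CATEGORY_ORDER], [counts[c] for c in CATEGORY_ORDER]
    )
    categories = rng.permutation(categories)
    kinetic = np.where(
        categories == "GAS",
        "early",
        np.where(np.isin(categories, ["ISRE", "BOTH"]), "late", ""),
    ).astype(object)
    no_motif = categories == "NO_MOTIF"
    kinetic[no_motif] = rng.choice(["early", "late"], size=int(no_motif.sum()))
    assigned_inducible = rng.random(n_peaks) < params.frac_inducible

    widths = rng.integers(params.peak_width_range[0], params.peak_width_range[1] + 1, n_peaks)
    strands = rng.choice(np.array(["+", "-"]), size=n_genes)
    promoter = rng.random(n_peaks) < params.promoter_frac
    lo, hi = -800, 80  # inside the promoter window with margin
    d_prom = rng.integers(lo, hi + 1, n_peaks)
    d_dist = rng.integers(1500, 3001, n_peaks) * rng.choice([-1, 1], n_peaks)
    signed_d = np.where(promoter, d_prom, d_dist)

    nt_per_chrom = [len(range(c, n_peaks, params.n_chroms)) for c in range(params.n_chroms)]
    nf_per_chrom = [len(range(c, n_fillers, params.n_chroms)) for c in range(params.n_chroms)]
    needed = max(
        _EDGE_MARGIN
        + nt * params.target_spacing
        + _ZONE_GAP
        + nf * params.filler_spacing
        + _EDGE_MARGIN
        for nt, nf in zip(nt_per_chrom, nf_per_chrom)
    )
    if params.chrom_length is None:
        chrom_length = needed
    else:
        chrom_length = params.chrom_length
        if chrom_length < needed:
            raise GenerationError(
                f"chrom_length {chrom_length} too small: {n_peaks} peaks and "
                f"{n_genes} genes need >= {needed} bp per chromosome"
            )

    gene_rows = []
    peak_rows = []
    for i in range(n_peaks):
        c = i % params.n_chroms
        idx = i // params.n_chroms
        tss = _EDGE_MARGIN + idx * params.target_spacing + params.target_spacing // 2
        gid = f"gene_{i:05d}"
        pid = f"peak_{i:04d}"
        strand = strands[i]
        sd = int(signed_d[i])
        mid = tss + sd if strand == "+" else tss - sd
        w = int(widths[i])
        start = mid - w // 2
        end = start + w
        gene_rows.append(
            {"gene_id": gid, "chrom": chroms[c], "tss": tss, "strand": strand, "linked_peak": pid}
        )
        peak_rows.append(
            {
                "peak_id": pid,
                "chrom": chroms[c],
                "start": start,
                "end": end,
                "category": categories[i],
                "kinetic_class": kinetic[i],
                "assigned_inducible": bool(assigned_inducible[i]),
                "linked_gene": gid,
                "promoter": bool(promoter[i]),
                "signed_distance": sd,
            }
        )
    for j in range(n_fillers):
        c = j % params.n_chroms
        idx = j // params.n_chroms
        pos = (
            _EDGE_MARGIN
            + nt_per_chrom[c] * params.target_spacing
            + _ZONE_GAP
            + idx * params.filler_spacing
        )
        gene_rows.append(
            {
                "gene_id": f"gene_{n_peaks + j:05d}",
                "chrom": chroms[c],
                "tss": pos,
                "strand": strands[n_peaks + j],
                "linked_peak": pd.NA,
            }
        )
    genes = pd.DataFrame(gene_rows)
    peaks = pd.DataFrame(peak_rows)
    return _Layout(chrom_names=chroms, chrom_length=chrom_length, genes=genes, peaks=peaks)


# ---------------------------------------------------------------------------
# Genome


def _resample_positions(
    codes: np.ndarray, mask: np.ndarray, rng: np.random.Generator, probs: np.ndarray
) -> None:
    idx = np.nonzero(mask)[0]
    codes[idx] = rng.choice(_BASES, size=idx.size, p=probs)


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


_MAX_REJECTION_ROUNDS = 60


def simulate_genome(params: SimulationParams) -> FastaStore:
    """Generate a motif-free background genome.

    Background bases are drawn i.i.d. at the requested GC fraction; any
    window matching a GAS or ISRE consensus (either strand) is resampled
    until no matches remain, so a scan of the background yields exactly zero
    hits of either family.
    """
    layout = _layout(params)
    rng = _rng(params.seed, 0)
    probs = _base_probs(params.gc_background)
    seqs: dict[str, str] = {}
    for chrom in layout.chrom_names:
        codes = rng.choice(_BASES, size=layout.chrom_length, p=probs)
        for _round in range(_MAX_REJECTION_ROUNDS):
            mask = np.zeros(codes.size, dtype=bool)
            found = False
            for model in DEFAULT_MODELS:
                for off, _strand, length in scan_codes(codes, model):
                    mask[off : off + length] = True
                    found = True
            if not found:
                break
            _resample_positions(codes, mask, rng, probs)
        else:
            raise GenerationError(
                "motif-free background did not converge; lower gc_background "
                "or use shorter motifs"
            )
        seqs[chrom] = codes.tobytes().decode("ascii")
    return FastaStore(seqs)


# ---------------------------------------------------------------------------
# Peaks and ChIP signal


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _gas_instance(rng: np.random.Generator) -> str:
    spacer = int(rng.integers(2, 5))
    return "TTC" + _random_bases(rng, spacer) + "GAA"


def _isre_instance(rng: np.random.Generator) -> str:
    return "AGTTTC" + _random_bases(rng, 2) + "TTTC"


_PLANT_MARGIN = 5
_MAX_PLANT_ATTEMPTS = 80


def _plant_peak(
    chrom_codes: np.ndarray,
    start: int,
    end: int,
    category: str,
    rng: np.random.Generator,
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """Plant the motif instance(s) for one peak; verify the category scans back.

    Returns absolute (start, end) coordinates of the planted GAS and ISRE
    instances (None where the category plants none).
    """
    w = end - start
    original = chrom_codes[start:end].copy()
    for _attempt in range(_MAX_PLANT_ATTEMPTS):
        chrom_codes[start:end] = original
        gas_site = isre_site = None
        if category in ("GAS", "BOTH"):
            ins = _gas_instance(rng)
            if category == "BOTH":
                off = int(rng.integers(_PLANT_MARGIN, w // 2 - len(ins) + 1))
            else:
                off = int(rng.integers(_PLANT_MARGIN, w - len(ins) - _PLANT_MARGIN + 1))
            chrom_codes[start + off : start + off + len(ins)] = np.frombuffer(
                ins.encode(), dtype=np.uint8
            )
            gas_site = (start + off, start + off + len(ins))
        if category in ("ISRE", "BOTH"):
            ins = _isre_instance(rng)
            if category == "BOTH":
                off = int(rng.integers(w // 2, w - len(ins) - _PLANT_MARGIN + 1))
            else:
                off = int(rng.integers(_PLANT_MARGIN, w - len(ins) - _PLANT_MARGIN + 1))
            chrom_codes[start + off : start + off + len(ins)] = np.frombuffer(
                ins.encode(), dtype=np.uint8
            )
            isre_site = (start + off, start + off + len(ins))
        seq = chrom_codes[start:end].tobytes().decode("ascii")
        gas_hits, isre_hits = count_family_hits(seq)
        want_gas = category in ("GAS", "BOTH")
        want_isre = category in ("ISRE", "BOTH")
        if (gas_hits > 0) == want_gas and (isre_hits > 0) == want_isre:
            return gas_site, isre_site
    raise GenerationError(f"could not plant a clean {category} peak after retries")


def _condition_columns(params: SimulationParams) -> list[tuple[str, float, float, int]]:
    """(stimulus, dose, time, rep) for every ChIP signal column, basal first."""
    cols = [("unstim", 0.0, 0.0, r + 1) for r in range(params.n_chip_reps)]
    for dose in params.doses:
        for t in params.timepoints[1:]:
            for r in range(params.n_chip_reps):
                cols.append(("beta", float(dose), float(t), r + 1))
    return cols


def simulate_peaks_and_signal(
    params: SimulationParams, genome: FastaStore
) -> tuple[list[GenomicInterval], pd.DataFrame, TruthTables]:
    """Plant motif instances in peak windows and synthesize the signal matrix.

    Mutates ``genome`` in place (peak windows receive their planted
    consensus instances).  The signal value of peak p in column (dose, t,
    rep) is ``basal_p * fold_p(dose, t) * lognormal(0, sigma)``; the planted
    fold is 1 everywhere at time 0, 1 for GAS-class peaks below the dose
    gate, and follows the kinetic-class shape otherwise.  The truth
    ``inducible`` flag is True iff the planted fold reaches
    ``induction_fold`` in at least ``min_timepoints`` (dose, time) cells.
    """
    layout = _layout(params)
    plant_rng = _rng(params.seed, 5)
    signal_rng = _rng(params.seed, 2)

    codes_by_chrom = {
        chrom: np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8).copy()
        for chrom in layout.chrom_names
    }
    gas_sites: list[tuple[int, int] | None] = []
    isre_sites: list[tuple[int, int] | None] = []
    for row in layout.peaks.itertuples():
        gas_site, isre_site = _plant_peak(
            codes_by_chrom[row.chrom], row.start, row.end, row.category, plant_rng
        )
        gas_sites.append(gas_site)
        isre_sites.append(isre_site)
    for chrom, codes in codes_by_chrom.items():
        genome.replace(chrom, codes.tobytes().decode("ascii"))

    peaks = [
        GenomicInterval(row.chrom, row.start, row.end, name=row.peak_id)
        for row in layout.peaks.itertuples()
    ]

    # planted fold per peak x (dose, time)
    n_peaks = params.n_peaks
    stim_times = params.timepoints[1:]
    fold_cols: dict[tuple[float, float], np.ndarray] = {}
    amp = np.empty(n_peaks)
    weak = np.empty((n_peaks, len(stim_times)))
    for i, row in enumerate(layout.peaks.itertuples()):
        kc = params.kinetic_params[row.kinetic_class]
        amp[i] = signal_rng.uniform(*kc.log2_fold_range)
        weak[i] = signal_rng.uniform(*params.weak_fold_range, size=len(stim_times))
    shapes = np.stack(
        [params.kinetic_params[k].shape for k in layout.peaks["kinetic_class"]]
    )
    inducible_mask = layout.peaks["assigned_inducible"].to_numpy()
    gas_mask = (layout.peaks["category"] == "GAS").to_numpy()
    for dose in params.doses:
        folds = np.where(inducible_mask[:, None], 2.0 ** (amp[:, None] * shapes), weak)
        if dose < params.gas_dose_gate:
            folds = np.where(gas_mask[:, None], 1.0, folds)
        for j, t in enumerate(stim_times):
            fold_cols[(float(dose), float(t))] = folds[:, j]

    fold_matrix = np.column_stack([fold_cols[k] for k in sorted(fold_cols)])
    inducible_truth = (
        (fold_matrix >= params.induction_fold).sum(axis=1) >= params.min_timepoints
    )

    basal = signal_rng.lognormal(
        mean=math.log(params.basal_tag_scale), sigma=params.basal_tag_sigma, size=n_peaks
    )

    columns = _condition_columns(params)
    data = {}
    for stim, dose, t, rep in columns:
        fold = np.ones(n_peaks) if t == 0 else fold_cols[(dose, t)]
        noise = (
            signal_rng.lognormal(0.0, params.chip_noise_sigma, size=n_peaks)
            if params.chip_noise_sigma > 0
            else 1.0
        )
        data[condition_name(stim, dose, t, rep)] = basal * fold * noise
    signal = pd.DataFrame(data, index=layout.peaks["peak_id"])
    signal.index.name = "peak_id"

    truth_peaks = layout.peaks.copy()
    truth_peaks["inducible"] = inducible_truth
    truth_peaks["basal_scale"] = basal
    truth_peaks["gas_site_start"] = [s[0] if s else -1 for s in gas_sites]
    truth_peaks["gas_site_end"] = [s[1] if s else -1 for s in gas_sites]
    truth_peaks["isre_site_start"] = [s[0] if s else -1 for s in isre_sites]
    truth_peaks["isre_site_end"] = [s[1] if s else -1 for s in isre_sites]
    truth_peaks = truth_peaks.set_index("peak_id")

    peak_folds = pd.DataFrame(
        fold_matrix,
        index=truth_peaks.index,
        columns=[f"dose{d:g}_t{t:g}" for d, t in sorted(fold_cols)],
    )
    truth = TruthTables(
        peaks=truth_peaks, genes=layout.genes.set_index("gene_id"), peak_folds=peak_folds
    )
    return peaks, signal, truth


# ---------------------------------------------------------------------------
# Expression


RNA_CONDITIONS = (
    # (label, stimulus, dose, time)
    ("unstim", "unstim", 0.0, 0.0),
    ("beta_low", "beta", 1.0, 4.0),
    ("gamma_low", "gamma", 1.0, 4.0),
    ("mixed", "mixed", 1.0, 4.0),
    ("beta_high", "beta", 10.0, 4.0),
)


def simulate_expression(
    params: SimulationParams, truth: TruthTables
) -> ExpressionSim:
    """Synthesize the count matrix for the mixing experiment.

    Non-ISG genes have a constant negative-binomial mean across conditions.
    ISGs are induced by high-dose β; in the mixing arm their mixed-condition
    mean RPKM is ``s * (RPKM_β + RPKM_γ)`` with s = ``synergy_factor`` for
    genes linked to BOTH-motif peaks and s = 1 (additive) otherwise.  Genes
    linked to GAS-only peaks are never ISGs in epithelial mode.  Updates
    ``truth.genes`` in place with the planted per-gene expression truth.
    """
    rng_par = _rng(params.seed, 3)
    rng_cnt = _rng(params.seed, 4)
    genes = truth.genes
    n = len(genes)
    gene_ids = genes.index.to_numpy()

    lengths = pd.Series(
        rng_par.integers(500, 5001, size=n), index=genes.index, name="length"
    )
    linked = genes["linked_peak"].notna().to_numpy()
    basal = np.where(
        linked,
        np.maximum(rng_par.lognormal(math.log(20.0), 0.8, size=n), 5.0),
        rng_par.lognormal(math.log(10.0), 1.2, size=n),
    )

    peak_cat = pd.Series(pd.NA, index=genes.index, dtype="object")
    peak_inducible = pd.Series(False, index=genes.index)
    linked_rows = genes["linked_peak"].dropna()
    peak_cat.loc[linked_rows.index] = truth.peaks.loc[linked_rows.values, "category"].values
    peak_inducible.loc[linked_rows.index] = truth.peaks.loc[
        linked_rows.values, "inducible"
    ].values

    allowed = {"ISRE", "BOTH"} if params.cell_mode == "epithelial" else {"GAS", "ISRE", "BOTH"}
    eligible = genes.index[
        peak_cat.isin(allowed).to_numpy() & peak_inducible.to_numpy()
    ]
    n_linked_isg = min(int(round(params.linked_isg_rate * len(eligible))), params.n_isgs)
    chosen_linked = rng_par.choice(eligible.to_numpy(), size=n_linked_isg, replace=False)
    filler_pool = genes.index[~linked].to_numpy()
    n_fill = params.n_isgs - n_linked_isg
    if n_fill > len(filler_pool):
        raise ValidationError("not enough unlinked genes to reach n_isgs")
    chosen_fill = rng_par.choice(filler_pool, size=n_fill, replace=False)
    isg_ids = set(chosen_linked) | set(chosen_fill)
    is_isg = np.array([g in isg_ids for g in gene_ids])

    basal = np.where(
        is_isg, np.clip(rng_par.lognormal(math.log(4.0), 1.0, size=n), 1.0, 50.0), basal
    )
    f_high = 2.0 ** rng_par.uniform(*params.isg_fold_log2_range, size=n)
    r_beta = rng_par.uniform(*params.isg_single_rpkm_range, size=n)
    r_gamma = rng_par.uniform(*params.isg_single_rpkm_range, size=n)
    synergy = np.where(
        is_isg & (peak_cat == "BOTH").to_numpy(), params.synergy_factor, 1.0
    )

    mean_rpkm = {}
    mean_rpkm["unstim"] = basal
    mean_rpkm["beta_low"] = np.where(is_isg, r_beta, basal)
    mean_rpkm["gamma_low"] = np.where(is_isg, r_gamma, basal)
    mean_rpkm["mixed"] = np.where(is_isg, synergy * (r_beta + r_gamma), basal)
    mean_rpkm["beta_high"] = np.where(is_isg, basal * f_high, basal)

    lib = float(params.rna_library_size)
    len_kb = lengths.to_numpy() / 1000.0
    data = {}
    design_rows = []
    for label, stim, dose, t in RNA_CONDITIONS:
        mu = mean_rpkm[label] * len_kb * lib / 1e6
        for rep in range(1, params.n_rna_reps + 1):
            col = condition_name(stim, dose, t, rep)
            if params.nb_dispersion > 0:
                nb_n = 1.0 / params.nb_dispersion
                p = nb_n / (nb_n + mu)
                counts = rng_cnt.negative_binomial(nb_n, p)
            else:
                counts = np.rint(mu).astype(np.int64)
            data[col] = counts
            design_rows.append(
                {
                    "column": col,
                    "condition": label,
                    "stimulus": stim,
                    "dose": dose,
                    "time": t,
                    "replicate": rep,
                }
            )
    counts_df = pd.DataFrame(data, index=genes.index)
    counts_df.index.name = "gene_id"
    design = pd.DataFrame(design_rows)

    genes["length"] = lengths
    genes["is_isg"] = is_isg
    genes["synergy_factor"] = np.where(is_isg, synergy, np.nan)
    genes["peak_category"] = peak_cat
    genes["rpkm_basal"] = basal
    genes["rpkm_beta"] = mean_rpkm["beta_low"]
    genes["rpkm_gamma"] = mean_rpkm["gamma_low"]
    genes["rpkm_mixed"] = mean_rpkm["mixed"]
    genes["rpkm_high"] = mean_rpkm["beta_high"]
    genes["fold_high"] = np.where(is_isg, f_high, 1.0)
    return ExpressionSim(counts=counts_df, lengths=lengths, design=design)


# ---------------------------------------------------------------------------
# Convenience: full dataset and writers


def simulate_all(params: SimulationParams) -> SyntheticDataset:
    """Run the whole generator: genome, peaks, signal, expression, truth."""
    genome = simulate_genome(params)
    peaks, signal, truth = simulate_peaks_and_signal(params, genome)
    expression = simulate_expression(params, truth)
    tss = truth.genes.reset_index()[["gene_id", "chrom", "tss", "strand"]]
    return SyntheticDataset(
        genome=genome, peaks=peaks, signal=signal, expression=expression, truth=truth, tss=tss
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset to plain-text files; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "genome": outdir / "genome.fa",
        "peaks": outdir / "peaks.bed",
        "signal": outdir / "chip_signal.tsv",
        "counts": outdir / "counts.tsv",
        "lengths": outdir / "gene_lengths.tsv",
        "tss": outdir / "tss.tsv",
        "truth_peaks": outdir / "truth_peaks.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
    }
    write_fasta(ds.genome, files["genome"])
    write_bed(ds.peaks, files["peaks"])
    write_matrix(ds.signal, files["signal"])
    write_matrix(ds.expression.counts, files["counts"])
    ds.expression.lengths.to_frame().to_csv(files["lengths"], sep="\t")
    write_tss_table(ds.tss, files["tss"])
    write_matrix(ds.truth.peaks, files["truth_peaks"])
    write_matrix(ds.truth.genes, files["truth_genes"])
    return files
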