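"""Consensus motif models for GAS/ISRE elements and peak categorization.

The GAS (gamma-activated sequence) element bound by the STAT1 homodimer GAF
is the consensus ``TTC n{2-4} GAA``; the ISRE element bound by ISGF3 is
``AGTTTC nn TTTC``.  A variant GAS known from the Irf1 promoter
(``GATTTCCCCGAATG``) is included as a third GAS-family pattern.  Peaks are
scanned on both strands for all patterns; a peak with only GAS-family hits is
a GAS peak, only ISRE-family hits an ISRE peak, both families a BOTH peak and
neither a NO_MOTIF peak.

Consensus patterns use IUPAC letters plus ``N{min,max}`` variable spacers.
``N`` in the scanned sequence matches nothing (conservative presence calls).
Position-weight-matrix mode is supported for user-supplied matrices with a
log-odds threshold.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ifnsynergy.errors import ParseError, ValidationError
from ifnsynergy.io import FastaStore, GenomicInterval, reverse_complement

GAS_FAMILY = "GAS_family"
ISRE_FAMILY = "ISRE_family"

CATEGORIES = ("GAS", "ISRE", "BOTH", "NO_MOTIF")

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

# per-IUPAC-letter boolean lookup over byte codes; sequence letters outside
# {A,C,G,T} (including N) match no pattern position
_LUT: dict[str, np.ndarray] = {}
for letter, bases in IUPAC.items():
    table = np.zeros(256, dtype=bool)
    for b in bases:
        table[ord(b)] = True
    _LUT[letter] = table


@dataclass(frozen=True)
class MotifModel:
    """A consensus pattern with fixed IUPAC blocks and variable spacers.

    In ``pwm`` mode, ``pwm`` is a (4, L) column-stochastic matrix over
    A, C, G, T and ``threshold`` a log2-odds cutoff against a uniform
    background.
    """

    name: str
    family: str
    blocks: tuple[str, ...] = ()
    spacers: tuple[tuple[int, int], ...] = ()
    mode: str = "consensus"
    pwm: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.family not in (GAS_FAMILY, ISRE_FAMILY):
            raise ValidationError(f"unknown motif family {self.family!r}")
        if self.mode == "consensus":
            if not self.blocks:
                raise ValidationError("consensus motif requires >= 1 block")
            if len(self.spacers) != len(self.blocks) - 1:
                raise ValidationError("need exactly one spacer between consecutive blocks")
            for lo, hi in self.spacers:
                if lo > hi:
                    raise ValidationError(f"spacer min {lo} exceeds max {hi}")
                if lo < 0:
                    raise ValidationError("spacer lengths must be >= 0")
        elif self.mode == "pwm":
            if self.pwm is None or self.threshold is None:
                raise ValidationError("pwm mode requires a matrix and threshold")
            if self.pwm.shape[0] != 4:
                raise ValidationError("pwm must have 4 rows (A, C, G, T)")
            if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-6):
                raise ValidationError("pwm columns must sum to 1")
        else:
            raise ValidationError(f"unknown motif mode {self.mode!r}")

    @property
    def min_length(self) -> int:
        if self.mode == "pwm":
            return self.pwm.shape[1]
        return sum(len(b) for b in self.blocks) + sum(lo for lo, _ in self.spacers)

    @property
    def max_length(self) -> int:
        if self.mode == "pwm":
            return self.pwm.shape[1]
        return sum(len(b) for b in self.blocks) + sum(hi for _, hi in self.spacers)

    def expansions(self) -> list[tuple[str, tuple[int, ...]]]:
        """Concrete IUPAC strings for every spacer-length combination.

        Spacer positions are emitted as ``N`` (any base).  Ordered with the
        shortest spacers first.
        """
        if self.mode != "consensus":
            raise ValidationError("expansions are defined for consensus mode only")
        ranges = [range(lo, hi + 1) for lo, hi in self.spacers]
        out = []
        for combo in itertools.product(*ranges):
            parts = [self.blocks[0]]
            for gap, block in zip(combo, self.blocks[1:]):
                parts.append("N" * gap)
                parts.append(block)
            out.append(("".join(parts), combo))
        out.sort(key=lambda e: (len(e[0]), e[1]))
        return out


@dataclass(frozen=True)
class MotifMatch:
    """A single motif occurrence, in forward coordinates of the scanned sequence."""

    motif: str
    offset: int
    strand: str
    length: int
    peak_id: str | None = None


_SPACER_RE = re.compile(r"N\{(\d+)(?:,(\d+))?\}")


def compile_motif(spec: str, family: str, name: str | None = None) -> MotifModel:
    """Compile a pattern like ``"TTCN{2,4}GAA"`` into a :class:`MotifModel`.

    Plain IUPAC letters form fixed blocks; ``N{min,max}`` (or ``N{k}``) forms
    a variable spacer between blocks.  The pattern must start and end with a
    block.
    """
    spec = spec.strip().upper()
    if not spec:
        raise ParseError("empty motif pattern")
    blocks: list[str] = []
    spacers: list[tuple[int, int]] = []
    pos = 0
    pending_block = ""
    for m in _SPACER_RE.finditer(spec):
        pending_block += spec[pos : m.start()]
        if not pending_block:
            raise ParseError(f"pattern {spec!r}: spacer without a preceding block")
        blocks.append(pending_block)
        pending_block = ""
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if lo > hi:
            raise ParseError(f"pattern {spec!r}: spacer min {lo} > max {hi}")
        spacers.append((lo, hi))
        pos = m.end()
    pending_block += spec[pos:]
    if not pending_block:
        raise ParseError(f"pattern {spec!r}: pattern must end with a block")
    blocks.append(pending_block)
    for block in blocks:
        bad = set(block) - set(IUPAC)
        if bad:
            raise ParseError(f"pattern {spec!r}: invalid IUPAC letters {sorted(bad)}")
    return MotifModel(
        name=name or spec,
        family=family,
        blocks=tuple(blocks),
        spacers=tuple(spacers),
    )


# Published consensus definitions (GAS, the Irf1 promoter GAS variant, ISRE)
DEFAULT_GAS_MODELS = (
    compile_motif("TTCN{2,4}GAA", GAS_FAMILY, name="GAS"),
    compile_motif("GATTTCCCCGAATG", GAS_FAMILY, name="GAS_Irf1_variant"),
)
DEFAULT_ISRE_MODELS = (compile_motif("AGTTTCN{2}TTTC", ISRE_FAMILY, name="ISRE"),)
DEFAULT_MODELS = DEFAULT_GAS_MODELS + DEFAULT_ISRE_MODELS


def encode(seq: str) -> np.ndarray:
    """Byte-encode an uppercase nucleotide string for vectorized matching."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _pattern_hits(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Start offsets where the concrete IUPAC ``pattern`` matches ``codes``."""
    L = len(pattern)
    S = codes.size
    if S < L:
        return np.empty(0, dtype=np.int64)
    valid = _LUT[pattern[0]][codes[: S - L + 1]].copy()
    for j in range(1, L):
        if not valid.any():
            break
        valid &= _LUT[pattern[j]][codes[j : S - L + 1 + j]]
    return np.nonzero(valid)[0]


def _pwm_hits(codes: np.ndarray, model: MotifModel) -> np.ndarray:
    L = model.pwm.shape[1]
    S = codes.size
    if S < L:
        return np.empty(0, dtype=np.int64)
    # map base -> row index; anything else (incl. N) scores -inf
    idx = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        idx[ord(b)] = i
    with np.errstate(divide="ignore"):
        logodds = np.log2(np.maximum(model.pwm, 1e-12) / 0.25)
    score = np.zeros(S - L + 1)
    ok = np.ones(S - L + 1, dtype=bool)
    for j in range(L):
        rows = idx[codes[j : S - L + 1 + j]]
        ok &= rows >= 0
        score += np.where(rows >= 0, logodds[np.clip(rows, 0, 3), j], 0.0)
    return np.nonzero(ok & (score >= model.threshold))[0]


def scan_codes(codes: np.ndarray, model: MotifModel) -> list[tuple[int, str, int]]:
    """All matches of ``model`` on both strands of a byte-encoded sequence.

    Returns (forward offset, strand, length) tuples.  Reverse-strand matches
    are reported in forward coordinates.
    """
    S = codes.size
    hits: list[tuple[int, str, int]] = []
    rc_codes: np.ndarray | None = None
    if model.mode == "pwm":
        expansions = [(None, None)]
    else:
        expansions = model.expansions()
    for pattern, _ in expansions:
        if model.mode == "pwm":
            fwd = _pwm_hits(codes, model)
            L = model.pwm.shape[1]
        else:
            fwd = _pattern_hits(codes, pattern)
            L = len(pattern)
        hits.extend((int(o), "+", L) for o in fwd)
        if rc_codes is None:
            rc_codes = encode(reverse_complement(codes.tobytes().decode("ascii")))
        if model.mode == "pwm":
            rev = _pwm_hits(rc_codes, model)
        else:
            rev = _pattern_hits(rc_codes, pattern)
        hits.extend((S - (int(o) + L), "-", L) for o in rev)
    return hits


def scan_sequence(
    seq: str, motif: MotifModel, both_strands: bool = True, peak_id: str | None = None
) -> list[MotifMatch]:
    """All (possibly overlapping) matches of ``motif`` in ``seq``.

    Matches on the reverse complement are reported in forward coordinates.
    Deterministic order: position, then strand (+ before -), then shorter
    match first.
    """
    codes = encode(seq)
    raw = scan_codes(codes, motif)
    if not both_strands:
        raw = [h for h in raw if h[1] == "+"]
    raw.sort(key=lambda h: (h[0], h[1] != "+", h[2]))
    return [
        MotifMatch(motif=motif.name, offset=o, strand=s, length=L, peak_id=peak_id)
        for o, s, L in raw
    ]


def count_family_hits(
    seq: str,
    gas_models: Sequence[MotifModel] = DEFAULT_GAS_MODELS,
    isre_models: Sequence[MotifModel] = DEFAULT_ISRE_MODELS,
) -> tuple[int, int]:
    """(GAS-family, ISRE-family) match counts in ``seq`` on both strands."""
    gas = sum(len(scan_sequence(seq, m)) for m in gas_models)
    isre = sum(len(scan_sequence(seq, m)) for m in isre_models)
    return gas, isre


def categorize_peak(gas_hits: int, isre_hits: int) -> str:
    """Map motif-family hit counts to a peak category.

    At least one GAS-family hit and no ISRE-family hit -> GAS; the reverse ->
    ISRE; hits from both families -> BOTH; neither -> NO_MOTIF.
    """
    if gas_hits < 0 or isre_hits < 0:
        raise ValidationError("hit counts must be >= 0")
    if gas_hits > 0 and isre_hits > 0:
        return "BOTH"
    if gas_hits > 0:
        return "GAS"
    if isre_hits > 0:
        return "ISRE"
    return "NO_MOTIF"


def categorize_by_tf_presence(
    stat1_wt: bool, irf9_wt: bool, stat1_irf9ko: bool, stat2_irf9ko: bool
) -> str:
    """Categorize a binding location by cross-genotype TF presence.

    A STAT1 peak with no IRF9 peak is a GAF binding event; an IRF9 peak in
    wild-type cells with neither STAT1 nor STAT2 peaks in Irf9-null cells is
    an ISGF3 binding event; anything else is OTHER.
    """
    if stat1_wt and not irf9_wt:
        return "GAF"
    if irf9_wt and not stat1_irf9ko and not stat2_irf9ko:
        return "ISGF3"
    return "OTHER"


def classify_peaks(
    peaks: Sequence[GenomicInterval],
    genome: FastaStore,
    gas_models: Sequence[MotifModel] = DEFAULT_GAS_MODELS,
    isre_models: Sequence[MotifModel] = DEFAULT_ISRE_MODELS,
) -> pd.DataFrame:
    """Scan each peak's sequence and assign a motif category.

    Returns a DataFrame indexed by peak id with columns category, gas_hits,
    isre_hits.
    """
    rows = []
    for i, peak in enumerate(peaks):
        pid = peak.name or f"peak_{i}"
        seq = genome.subsequence(peak.chrom, peak.start, peak.end)
        gas, isre = count_family_hits(seq, gas_models, isre_models)
        rows.append(
            {"peak_id": pid, "category": categorize_peak(gas, isre), "gas_hits": gas, "isre_hits": isre}
        )
    return pd.DataFrame(rows).set_index("peak_id")


def read_motif_specs(path: str | Path) -> list[MotifModel]:
    """Read a motif spec file: one ``name family pattern`` per line."""
    models = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 'name family pattern'")
        name, family, pattern = parts
        models.append(compile_motif(pattern, family, name=name))
    return models
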