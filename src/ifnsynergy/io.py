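"""Readers/writers for the formats the pipeline touches, plus run configuration.

All genomic intervals are 0-based half-open throughout the package; the GTF
importer is the only place 1-based arithmetic appears.  Signal and expression
matrices are plain TSV with a header row; condition metadata is encoded in
column names using the convention ``stimulus_doseU_timeh_rN``
(e.g. ``beta_10U_2h_r1``) and parsed leniently — columns whose names do not
follow the convention are allowed but carry no metadata.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ifnsynergy.errors import ParseError, ValidationError

logger = logging.getLogger("ifnsynergy")

PROMOTER_WINDOW = (-1000, 100)
GC_WINDOW = (-300, 300)


def setup_logging(level: str = "INFO") -> None:
    """Configure timestamped logging for CLI runs."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally named.

    ``summit`` is an optional absolute position (e.g. from a peak caller) used
    as the reference point for distance calculations when present.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnalysisConfig:
    """Thresholds and windows used across the analysis.

    Defaults are the published operating points: two-fold induction in at
    least two timepoints for inducible peaks; ISGs at FDR < 0.05 and
    fold-change > 2; a 2 CPM expression filter; a promoter window of
    -1000..+100 bp around the TSS; GC content measured -300..+300 bp around
    the TSS; a 1 RPKM pseudocount for fold-changes and Enhancement scores.
    """

    induction_fold: float = 2.0
    min_timepoints: int = 2
    isg_fdr: float = 0.05
    isg_fold: float = 2.0
    cpm_filter: float = 2.0
    promoter_window: tuple[int, int] = PROMOTER_WINDOW
    gc_window: tuple[int, int] = GC_WINDOW
    rpkm_pseudocount: float = 1.0
    signal_pseudocount: float = 1.0
    kmeans_k: int = 2
    k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6)
    exclude_columns: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "induction_fold",
            "min_timepoints",
            "isg_fdr",
            "isg_fold",
            "cpm_filter",
            "rpkm_pseudocount",
            "signal_pseudocount",
            "kmeans_k",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config threshold {name} must be > 0")
        if self.cpm_filter is not None and self.cpm_filter < 0:
            raise ValidationError("cpm_filter must be >= 0")
        lo, hi = self.promoter_window
        if lo >= hi:
            raise ValidationError("promoter_window lower bound must be < upper bound")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a YAML file; every key is optional."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        for key in ("promoter_window", "gc_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "exclude_columns" in raw:
            raw["exclude_columns"] = tuple(raw["exclude_columns"])
        if "k_candidates" in raw:
            raw["k_candidates"] = tuple(raw["k_candidates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("promoter_window", "gc_window", "exclude_columns", "k_candidates"):
            d[key] = list(d[key])
        return d


@dataclass(frozen=True)
class ConditionMeta:
    """Metadata parsed from a matrix column name."""

    stimulus: str
    dose: float
    time: float
    replicate: int


_CONDITION_RE = re.compile(
    r"^(?P<stim>[A-Za-z][A-Za-z0-9.+-]*)_(?P<dose>\d+(?:\.\d+)?)U_"
    r"(?P<time>\d+(?:\.\d+)?)h_r(?P<rep>\d+)$"
)


def parse_condition(column: str) -> ConditionMeta | None:
    """Parse ``stimulus_doseU_timeh_rN`` column names; None if unparseable."""
    m = _CONDITION_RE.match(column)
    if m is None:
        return None
    return ConditionMeta(
        stimulus=m.group("stim"),
        dose=float(m.group("dose")),
        time=float(m.group("time")),
        replicate=int(m.group("rep")),
    )


def condition_metadata(columns: Iterable[str]) -> dict[str, ConditionMeta | None]:
    """Metadata for every column; unparseable names map to None."""
    return {c: parse_condition(c) for c in columns}


def condition_name(stimulus: str, dose: float, time: float, replicate: int) -> str:
    """Inverse of :func:`parse_condition`."""

    def num(x: float) -> str:
        return f"{x:g}"

    return f"{stimulus}_{num(dose)}U_{num(time)}h_r{replicate}"


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (>= 3 columns) as 0-based half-open intervals.

    Column 4, when present, is kept as the interval name (peak id).  Extra
    columns are ignored.  Malformed lines raise :class:`ParseError` naming the
    line number; ``end <= start`` raises :class:`ValidationError`.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else None
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                intervals.append(
                    GenomicInterval(chrom=chrom, start=start, end=end, name=name, strand=strand)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED4 (BED6 when a strand is set)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name or "."]
            if iv.strand != ".":
                fields += ["0", iv.strand]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


class FastaStore:
    """In-memory genome supporting strand-aware subsequence extraction."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._seqs[chrom]

    def replace(self, chrom: str, sequence: str) -> None:
        """Replace a chromosome sequence (used by the simulator)."""
        self._seqs[chrom] = sequence.upper()

    def subsequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Uppercase subsequence, reverse-complemented on the minus strand."""
        seq = self[chrom]
        if start < 0 or end > len(seq) or end <= start:
            raise IndexError(
                f"range [{start}, {end}) out of bounds for {chrom} (length {len(seq)})"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub


def read_fasta(path: str | Path) -> FastaStore:
    """Load a FASTA file into a :class:`FastaStore`."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return FastaStore(seqs)


def write_fasta(store: FastaStore, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(store[chrom]), id=chrom, description="") for chrom in store.chroms()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Matrices (signal, counts) and TSS annotations


def read_matrix(path: str | Path, index_name: str | None = None) -> pd.DataFrame:
    """Read a rectangular TSV keyed by its first column.

    Raises :class:`ParseError` on ragged rows and :class:`ValidationError` on
    duplicate row ids.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate row ids {dupes[:5]}")
    if index_name is not None:
        df.index.name = index_name
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read the 4-column TSS annotation TSV (gene_id, chrom, tss, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: TSS table requires columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids in TSS table")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError(f"{path}: TSS strand must be + or -")
    return df


def write_tss_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene_id", "chrom", "tss", "strand"]].to_csv(path, sep="\t", index=False)


_GTF_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def tss_from_gtf(path: str | Path) -> pd.DataFrame:
    """Extract one TSS per gene from a GTF file.

    The transcript start is strand-aware (GTF ``start`` on +, ``end`` on -)
    and converted to 0-based.  The transcript with the lexicographically
    smallest transcript_id wins for each gene.
    """
    chosen: dict[str, tuple[str, str, int, str]] = {}  # gene -> (tx, chrom, tss, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "transcript":
                continue
            chrom, start, end, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
            attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
            gene = attrs.get("gene_id")
            tx = attrs.get("transcript_id", "")
            if gene is None:
                raise ParseError(f"{path}:{lineno}: transcript without gene_id")
            tss = start - 1 if strand == "+" else end - 1  # 1-based inclusive -> 0-based
            if gene not in chosen or tx < chosen[gene][0]:
                chosen[gene] = (tx, chrom, tss, strand)
    rows = [
        {"gene_id": gene, "chrom": chrom, "tss": tss, "strand": strand}
        for gene, (_, chrom, tss, strand) in sorted(chosen.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
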