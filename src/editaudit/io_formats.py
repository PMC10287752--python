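"""Readers and writers for the formats the audit pipeline touches.

Supported formats: a VCF v4.2 subset (CHROM, POS, REF, ALT plus AD/DP/AF
from the first sample column), FASTA, BED-like 4-column interval TSVs,
rMATS junction-count (JC) tables, aligned-read tables, and genes x cells
expression matrices with cell metadata.

Coordinate conventions are never mixed: VCF positions are 1-based,
BED-like intervals are 0-based half-open.  The converters in this module
are the only crossing points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import ConfigError, FormatError, OrderingError

logger = logging.getLogger("editaudit")

_DNA = frozenset("ACGT")

REGION_CLASSES = ("exonic", "intronic", "UTR5", "UTR3")
EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")

#: sentinel meaning "no measurement" — distinct from an observed zero.
UNMEASURED = None


@dataclass
class VariantCall:
    """One ALT allele reported by one variant caller.

    ``ref_depth``/``alt_depth``/``allele_frequency`` are ``None`` when the
    caller did not report them ("unmeasured", which is distinct from 0).
    """

    caller_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_depth: int | None = None
    alt_depth: int | None = None
    allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or set(allele) - _DNA:
                raise ValueError(f"{name} allele {allele!r} is not plain DNA")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for d in (self.ref_depth, self.alt_depth):
            if d is not None and d < 0:
                raise ValueError("depths must be non-negative")
        af = self.allele_frequency
        if af is not None and not (0.0 <= af <= 1.0):
            raise ValueError(f"allele_frequency {af} outside [0, 1]")
        if (
            af is not None
            and self.ref_depth is not None
            and self.alt_depth is not None
            and self.ref_depth + self.alt_depth > 0
        ):
            expect = self.alt_depth / (self.ref_depth + self.alt_depth)
            if abs(af - expect) > 1e-6:
                raise ValueError(
                    f"allele_frequency {af} inconsistent with depths "
                    f"{self.alt_depth}/{self.ref_depth + self.alt_depth}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def _is_symbolic(allele: str | None) -> bool:
    if allele is None:
        return True
    return bool(set(allele.upper()) - _DNA)


def read_vcf(path: str | Path, caller_id: str) -> list[VariantCall]:
    """Read the supported VCF subset, one :class:`VariantCall` per ALT allele.

    Multi-allelic rows are split; depths come from the first sample's AD
    field when present; symbolic/breakend alleles are skipped with a
    logged warning.  A missing ``#CHROM`` header line is a format error.
    """
    path = Path(path)
    _require_vcf_header(path)
    calls: list[VariantCall] = []
    n_symbolic = 0
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:  # pragma: no cover - guarded above
        raise FormatError(f"{path}: not parseable as VCF: {exc}") from exc
    with vf:
        sample = vf.header.samples[0] if len(vf.header.samples) else None
        for rec in vf:
            alts = rec.alts or ()
            ad = _sample_field(rec, sample, "AD")
            af_field = _sample_field(rec, sample, "AF")
            if af_field is None:
                try:
                    af_field = rec.info.get("AF")
                except ValueError:  # AF not declared in the header
                    af_field = None
            for i, alt in enumerate(alts):
                if _is_symbolic(alt) or _is_symbolic(rec.ref):
                    n_symbolic += 1
                    continue
                ref_depth = alt_depth = None
                if ad is not None and len(ad) >= i + 2 and ad[0] is not None:
                    ref_depth = int(ad[0])
                    if ad[i + 1] is not None:
                        alt_depth = int(ad[i + 1])
                af = None
                if ref_depth is not None and alt_depth is not None:
                    total = ref_depth + alt_depth
                    af = alt_depth / total if total > 0 else None
                elif af_field is not None:
                    raw = af_field[i] if isinstance(af_field, tuple) else af_field
                    if raw is not None:
                        af = float(raw)
                calls.append(
                    VariantCall(
                        caller_id=caller_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        ref_depth=ref_depth,
                        alt_depth=alt_depth,
                        allele_frequency=af,
                    )
                )
    if n_symbolic:
        logger.warning("%s: skipped %d symbolic/non-ACGT alleles", path, n_symbolic)
    logger.info("%s: read %d calls for caller %s", path, len(calls), caller_id)
    return calls


def _require_vcf_header(path: Path) -> None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#CHROM"):
                return
            if not line.startswith("##"):
                break
    raise FormatError(f"{path}: no #CHROM header line; not a VCF")


def _sample_field(rec, sample, key):
    if sample is None:
        return None
    try:
        value = rec.samples[sample].get(key)
    except KeyError:
        return None
    if value is None or (isinstance(value, tuple) and all(v is None for v in value)):
        return None
    return value


def write_vcf(
    records: Sequence[VariantCall],
    path: str | Path,
    sample_name: str = "SAMPLE",
    sort: bool = False,
) -> None:
    """Write calls as a minimal VCF whose re-parse reproduces them.

    Records must be (chrom, pos)-sorted unless ``sort=True``.  Depths are
    emitted as the sample AD field, frequencies as a sample AF field when
    no depths are available.
    """
    records = list(records)
    keys = [(r.chrom, r.pos) for r in records]
    if sort:
        records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    elif keys != sorted(keys):
        raise OrderingError("records are not (chrom, pos)-sorted; pass sort=True")

    header = pysam.VariantHeader()
    max_pos: dict[str, int] = {}
    for r in records:
        end = r.pos + len(r.ref)
        max_pos[r.chrom] = max(max_pos.get(r.chrom, 0), end)
    for chrom, end in max_pos.items():
        header.contigs.add(chrom, length=end + 1000)
    header.add_meta(
        "FORMAT",
        items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
               ("Description", "Allelic depths (ref, alt)")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "AF"), ("Number", "A"), ("Type", "Float"),
               ("Description", "Allele frequency")],
    )
    header.add_sample(sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(contig=r.chrom, start=r.pos - 1,
                                 alleles=(r.ref, r.alt))
            if r.ref_depth is not None and r.alt_depth is not None:
                rec.samples[sample_name]["AD"] = (r.ref_depth, r.alt_depth)
            elif r.allele_frequency is not None:
                rec.samples[sample_name]["AF"] = r.allele_frequency
            out.write(rec)
    logger.info("%s: wrote %d records", path, len(records))


# ---------------------------------------------------------------------------
# region annotations (BED-like, 0-based half-open)
# ---------------------------------------------------------------------------

@dataclass
class RegionAnnotation:
    """Genomic intervals labelled exonic/intronic/UTR5/UTR3.

    Intervals are 0-based half-open.  When intervals overlap, class
    precedence for point queries is exonic > UTR5/UTR3 > intronic.
    """

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    _PRECEDENCE = {"exonic": 0, "UTR5": 1, "UTR3": 1, "intronic": 2}

    def __post_init__(self) -> None:
        for chrom, start, end, cls in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            if cls not in REGION_CLASSES:
                raise ValueError(f"unknown region class {cls!r}")

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionAnnotation":
        """Load a 4-column TSV: chrom, start, end, class (0-based half-open)."""
        intervals = []
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise FormatError(f"{path}:{line_no}: expected 4 columns")
                intervals.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
        return cls(intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, cls in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{cls}\n")

    def classify(self, chrom: str, pos: int) -> str | None:
        """Region class of a 1-based position, or None if in no interval."""
        hit: str | None = None
        best = math.inf
        zero_based = pos - 1
        for c, start, end, cls in self.intervals:
            if c == chrom and start <= zero_based < end:
                rank = self._PRECEDENCE[cls]
                if rank < best:
                    best, hit = rank, cls
        return hit


# ---------------------------------------------------------------------------
# rMATS junction-count tables
# ---------------------------------------------------------------------------

@dataclass
class SpliceTableRow:
    """One alternative-splicing event from an rMATS JC table.

    ``psi_group1``/``psi_group2`` hold per-replicate percent-spliced-in
    values with missing replicates as ``None``.
    """

    event_id: str
    gene: str
    event_type: str
    psi_group1: list[float | None]
    psi_group2: list[float | None]
    fdr: float

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        for grp in (self.psi_group1, self.psi_group2):
            if all(v is None for v in grp):
                raise ValueError(f"event {self.event_id}: all-missing PSI group")
            for v in grp:
                if v is not None and not (0.0 <= v <= 1.0):
                    raise ValueError(f"PSI {v} outside [0, 1]")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"FDR {self.fdr} outside [0, 1]")

    def mean_psi(self, group: int) -> float:
        vals = [v for v in (self.psi_group1 if group == 1 else self.psi_group2)
                if v is not None]
        return sum(vals) / len(vals)


def _parse_inclevel(text: str) -> list[float | None]:
    return [None if t.strip() in ("NA", "", ".") else float(t)
            for t in str(text).split(",")]


def read_rmats_jc(path: str | Path, event_type: str | None = None) -> list[SpliceTableRow]:
    """Read an rMATS junction-count (JC) results table.

    Requires ID, IncLevel1, IncLevel2 and FDR columns; the event type is
    taken from an ``eventType`` column, from ``event_type``, or from the
    file name (e.g. ``SE.MATS.JC.txt``).  Rows whose PSI values are all
    missing in a group are rejected with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"ID", "IncLevel1", "IncLevel2", "FDR"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: missing columns {needed - set(df.columns)}")
    if event_type is None and "eventType" not in df.columns:
        stem = Path(path).name.split(".")[0]
        if stem in EVENT_TYPES:
            event_type = stem
        else:
            raise FormatError(f"{path}: event type not given and not inferable")
    gene_col = next((c for c in ("geneSymbol", "GeneID", "gene") if c in df.columns), None)
    rows: list[SpliceTableRow] = []
    n_rejected = 0
    for _, raw in df.iterrows():
        g1 = _parse_inclevel(raw["IncLevel1"])
        g2 = _parse_inclevel(raw["IncLevel2"])
        if all(v is None for v in g1) or all(v is None for v in g2):
            n_rejected += 1
            continue
        rows.append(
            SpliceTableRow(
                event_id=str(raw["ID"]),
                gene=str(raw[gene_col]) if gene_col else "",
                event_type=raw.get("eventType", event_type),
                psi_group1=g1,
                psi_group2=g2,
                fdr=float(raw["FDR"]),
            )
        )
    if n_rejected:
        logger.warning("%s: rejected %d rows with an all-missing PSI group",
                       path, n_rejected)
    logger.info("%s: read %d splice events", path, len(rows))
    return rows


def write_rmats_jc(rows: Sequence[SpliceTableRow], path: str | Path) -> None:
    """Write rows in the rMATS-JC column layout this package reads back."""

    def fmt(grp: Iterable[float | None]) -> str:
        return ",".join("NA" if v is None else f"{v:.6g}" for v in grp)

    df = pd.DataFrame(
        {
            "ID": [r.event_id for r in rows],
            "geneSymbol": [r.gene for r in rows],
            "eventType": [r.event_type for r in rows],
            "IncLevel1": [fmt(r.psi_group1) for r in rows],
            "IncLevel2": [fmt(r.psi_group2) for r in rows],
            "FDR": [f"{r.fdr:.6g}" for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / read tables / known-variant sets / expression matrices
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_reads_table(path: str | Path) -> list[str]:
    """Aligned amplicon reads: FASTA or one sequence per line."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def write_reads_table(reads: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(read + "\n")


def read_known_sites(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Known-variant exclusion set from a VCF or a chrom/pos/ref/alt TSV."""
    path = Path(path)
    try:
        _require_vcf_header(path)
        return {c.key for c in read_vcf(path, caller_id="known")}
    except FormatError:
        pass
    keys = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            keys.add((chrom, int(pos), ref.upper(), alt.upper()))
    return keys


def write_known_sites(keys: Iterable[tuple[str, int, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(keys):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x cells TSV with gene identifiers in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate gene or cell identifiers")
    return df


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Cell metadata TSV with cell_id, condition and cluster columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"cell_id", "condition", "cluster"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: missing columns {needed - set(df.columns)}")
    return df.set_index("cell_id")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


__all__ = [
    "VariantCall", "RegionAnnotation", "SpliceTableRow", "UNMEASURED",
    "REGION_CLASSES", "EVENT_TYPES",
    "read_vcf", "write_vcf", "read_rmats_jc", "write_rmats_jc",
    "read_fasta", "write_fasta", "read_reads_table", "write_reads_table",
    "read_known_sites", "write_known_sites",
    "read_expression_matrix", "read_cell_metadata", "load_config",
]
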