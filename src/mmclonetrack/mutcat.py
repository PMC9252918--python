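"""SBS-96 mutation catalogs: records, trinucleotide channels, strand counts.

Single-base substitutions are classified into the standard 96 channels:
6 pyrimidine-normalized substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
times 16 flanking-base combinations.  Channel order is the de-facto standard
signature-matrix layout: substitution classes in the order above, flanks
lexicographic within each class, so external reference matrices load without
permutation.

Coordinate conventions: mutation positions are 1-based (VCF/TSV native);
transcript intervals are BED-style 0-based half-open.  Conversion happens at
the file boundary, never inside the data model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Fixed 96-channel order: 6 substitution blocks x 16 lexicographic flank pairs.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

TX_STRANDS = ("transcribed", "untranscribed", "intergenic")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed under its declared format."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def channel_of(ref: str, alt: str, context: str) -> str:
    """SBS-96 channel label for a substitution in its trinucleotide context.

    ``context`` is the 3-mer on the forward reference strand with the mutated
    base in the middle.  Purine references are reverse-complemented so the
    mutated base is reported as C or T ("pyrimidine normalization").
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3:
        raise ValueError(f"context must be a 3-mer, got {context!r}")
    for b in (ref, alt, *context):
        if b not in BASES:
            raise ValueError(f"non-ACGT symbol in ({ref}, {alt}, {context})")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} != ref {ref!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref in "AG":
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def channel_context(channel: str) -> str:
    """Pyrimidine-strand trinucleotide context of a channel, e.g. A[C>T]G -> ACG."""
    return channel[0] + channel[2] + channel[6]


@dataclass
class MutationRecord:
    """One somatic single-base substitution with read support.

    Optional fields carry downstream annotation: the forward-strand
    trinucleotide ``context``, transcriptional strand, gene symbol and RNA
    alt-read support used for expressed-mutation calls.
    """

    patient_id: str
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_reads: int
    total_reads: int
    vaf: Optional[float] = None
    context: Optional[str] = None
    tx_strand: Optional[str] = None
    gene: Optional[str] = None
    rna_alt_reads: Optional[int] = None
    unclassifiable: bool = False
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single ACGT bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"positions are 1-based, got {self.pos}")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.alt_reads < 0 or self.alt_reads > self.total_reads:
            raise ValueError("alt_reads must be in [0, total_reads]")
        if self.vaf is None:
            self.vaf = self.alt_reads / self.total_reads
        elif abs(self.vaf - self.alt_reads / self.total_reads) > 1e-9:
            raise ValueError(
                f"vaf {self.vaf} inconsistent with {self.alt_reads}/{self.total_reads}"
            )
        if self.context is not None:
            self.context = self.context.upper()
            if len(self.context) != 3 or self.context[1] != self.ref:
                raise ValueError(f"context {self.context!r} incompatible with ref {self.ref}")
        if self.tx_strand is not None and self.tx_strand not in TX_STRANDS:
            raise ValueError(f"tx_strand must be one of {TX_STRANDS}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def channel(self) -> Optional[str]:
        if self.unclassifiable or self.context is None:
            return None
        if any(b not in BASES for b in self.context):
            return None
        return channel_of(self.ref, self.alt, self.context)


@dataclass
class TrinucleotideCatalog:
    """96-channel nonnegative count vector in the fixed channel order."""

    sample_id: str
    counts: np.ndarray
    n_unclassifiable: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError(f"catalog must have exactly 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name=self.sample_id)

    @classmethod
    def from_series(cls, s: pd.Series, sample_id: Optional[str] = None) -> "TrinucleotideCatalog":
        if list(s.index) != list(CHANNELS):
            s = s.reindex(list(CHANNELS))
            if s.isna().any():
                raise ValueError("series does not cover the 96 channels in canonical order")
        return cls(sample_id or str(s.name), s.to_numpy())


@dataclass
class StrandedContextCounts:
    """Counts per (channel, transcriptional strand), genic mutations only."""

    sample_id: str
    counts: dict  # (channel, strand) -> int

    def strand_totals(
        self, contexts: Optional[Iterable[str]] = None, substitution: Optional[str] = None
    ) -> tuple[int, int]:
        """(transcribed, untranscribed) totals, optionally restricted to
        pyrimidine-strand contexts and/or one substitution class."""
        ctx = set(c.upper() for c in contexts) if contexts is not None else None
        t = u = 0
        for (channel, strand), n in self.counts.items():
            if substitution is not None and channel[2:5] != substitution:
                continue
            if ctx is not None and channel_context(channel) not in ctx:
                continue
            if strand == "transcribed":
                t += n
            elif strand == "untranscribed":
                u += n
        return t, u

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"channel": ch, "tx_strand": st, "count": n}
            for (ch, st), n in sorted(self.counts.items(), key=lambda kv: (CHANNEL_INDEX[kv[0][0]], kv[0][1]))
        ]
        return pd.DataFrame(rows, columns=["channel", "tx_strand", "count"])


# ---------------------------------------------------------------------------
# Readers

_TSV_REQUIRED = ("chrom", "pos", "ref", "alt", "alt_reads", "total_reads")


def read_mutations(path, sample_id: str, patient_id: Optional[str] = None) -> list[MutationRecord]:
    """Read somatic SNVs from a VCF (.vcf/.vcf.gz) or TSV mutation table.

    Non-SNV records (indels, MNVs) are skipped with a logged count.  VAF is
    computed from AD-style depths when no explicit column is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, sample_id, patient_id or sample_id)
    return _read_tsv(path, sample_id, patient_id or sample_id)


def _read_vcf(path: Path, sample_id: str, patient_id: str) -> list[MutationRecord]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare Exceptions on bad input
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    records: list[MutationRecord] = []
    n_skipped = 0
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        alt_reads, total_reads = _vcf_depths(v)
        records.append(
            MutationRecord(
                patient_id=patient_id,
                sample_id=sample_id,
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                alt_reads=alt_reads,
                total_reads=total_reads,
            )
        )
    if n_skipped:
        logger.info("%s: skipped %d non-SNV records", path.name, n_skipped)
    return records


def _vcf_depths(v) -> tuple[int, int]:
    ad = v.format("AD")
    if ad is not None:
        ref_d, alt_d = int(ad[0][0]), int(ad[0][1])
        return alt_d, max(ref_d + alt_d, 1)
    dp = v.INFO.get("DP")
    af = v.INFO.get("AF")
    if dp is not None and af is not None:
        dp = int(dp)
        return int(round(float(af) * dp)), max(dp, 1)
    raise FormatError(f"no AD format or DP/AF info at {v.CHROM}:{v.POS}")


def _read_tsv(path: Path, sample_id: str, patient_id: str) -> list[MutationRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:
        raise FormatError(f"cannot parse mutation TSV {path}: {exc}") from exc
    missing = [c for c in _TSV_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if "sample_id" in df.columns:
        df = df[df["sample_id"] == sample_id]
    records: list[MutationRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            n_skipped += 1
            continue
        records.append(
            MutationRecord(
                patient_id=getattr(row, "patient_id", patient_id) or patient_id,
                sample_id=sample_id,
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=ref,
                alt=alt,
                alt_reads=int(row.alt_reads),
                total_reads=int(row.total_reads),
                vaf=_opt_float(getattr(row, "vaf", None)),
                context=_opt_str(getattr(row, "context", None)),
                tx_strand=_opt_str(getattr(row, "tx_strand", None)),
                gene=_opt_str(getattr(row, "gene", None)),
                rna_alt_reads=_opt_int(getattr(row, "rna_alt_reads", None)),
            )
        )
    if n_skipped:
        logger.info("%s: skipped %d non-SNV rows", path.name, n_skipped)
    return records


def _opt_float(x):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)


def _opt_int(x):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else int(x)


def _opt_str(x):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    return str(x)


# ---------------------------------------------------------------------------
# Annotation and catalogs


def annotate_context(muts: Sequence[MutationRecord], reference) -> list[MutationRecord]:
    """Attach forward-strand trinucleotide contexts from a FASTA reference.

    Records that already carry a context are returned unchanged.  Positions at
    contig edges are flagged unclassifiable rather than erroring; a missing
    contig is an error naming it.
    """
    from pyfaidx import Fasta

    fasta = reference if not isinstance(reference, (str, Path)) else Fasta(str(reference))
    out: list[MutationRecord] = []
    for m in muts:
        if m.context is not None or m.unclassifiable:
            out.append(m)
            continue
        if m.chrom not in fasta:
            raise KeyError(f"contig {m.chrom!r} not found in reference")
        contig = fasta[m.chrom]
        if m.pos < 2 or m.pos > len(contig) - 1:
            out.append(replace(m, unclassifiable=True, flags=m.flags + ["contig_edge"]))
            continue
        ctx = str(contig[m.pos - 2 : m.pos + 1]).upper()
        if ctx[1] != m.ref:
            out.append(replace(m, unclassifiable=True, flags=m.flags + ["ref_mismatch"]))
            continue
        if any(b not in BASES for b in ctx):
            out.append(replace(m, unclassifiable=True, flags=m.flags + ["ambiguous_base"]))
            continue
        out.append(replace(m, context=ctx))
    return out


def build_catalog(muts: Sequence[MutationRecord], sample_id: Optional[str] = None) -> TrinucleotideCatalog:
    """Histogram context-annotated records into a 96-channel catalog.

    Records without a usable context (missing, N-containing, or flagged)
    count as unclassifiable; classifiable + unclassifiable == input size.
    """
    counts = np.zeros(96, dtype=np.int64)
    n_uncls = 0
    sid = sample_id
    for m in muts:
        if sid is None:
            sid = m.sample_id
        ch = m.channel()
        if ch is None:
            n_uncls += 1
        else:
            counts[CHANNEL_INDEX[ch]] += 1
    return TrinucleotideCatalog(sample_id=sid or "", counts=counts, n_unclassifiable=n_uncls)


def read_transcript_intervals(path) -> list[tuple[str, int, int, str]]:
    """Read BED-like stranded transcript intervals: chrom, start (0-based),
    end (half-open), strand in column 6 (BED6) or column 4."""
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                strand = parts[5] if len(parts) >= 6 else parts[3]
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{i}: malformed interval line") from exc
            if strand not in "+-":
                raise FormatError(f"{path}:{i}: strand must be + or -, got {strand!r}")
            if end <= start:
                raise FormatError(f"{path}:{i}: empty or inverted interval")
            rows.append((chrom, start, end, strand))
    return rows


def stranded_counts(
    muts: Sequence[MutationRecord],
    tx_intervals,
    sample_id: Optional[str] = None,
) -> StrandedContextCounts:
    """Per-(channel, transcriptional strand) counts for genic mutations.

    A pyrimidine-channel mutation is "untranscribed" when the pyrimidine of
    the mutated pair lies on the gene's coding (sense) strand and
    "transcribed" when it lies on the template strand.  Intergenic mutations
    are excluded; mutations overlapping genes on both strands are ambiguous
    and excluded as well.  Records already carrying ``tx_strand`` keep it.
    """
    from intervaltree import IntervalTree

    if isinstance(tx_intervals, (str, Path)):
        tx_intervals = read_transcript_intervals(tx_intervals)
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, strand in tx_intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, strand)

    counts: dict[tuple[str, str], int] = {}
    sid = sample_id
    for m in muts:
        if sid is None:
            sid = m.sample_id
        ch = m.channel()
        if ch is None:
            continue
        strand = m.tx_strand
        if strand is None:
            strand = _tx_strand_of(m, trees)
        if strand in ("transcribed", "untranscribed"):
            counts[(ch, strand)] = counts.get((ch, strand), 0) + 1
    return StrandedContextCounts(sample_id=sid or "", counts=counts)


def _tx_strand_of(m: MutationRecord, trees) -> Optional[str]:
    tree = trees.get(m.chrom)
    if tree is None:
        return None
    hits = tree[m.pos - 1]  # 1-based position -> 0-based point query
    strands = {iv.data for iv in hits}
    if not strands:
        return None  # intergenic
    if len(strands) > 1:
        return None  # genes on both strands: ambiguous, excluded
    gene_strand = strands.pop()
    pyr_strand = "+" if m.ref in "CT" else "-"
    return "untranscribed" if pyr_strand == gene_strand else "transcribed"


def write_catalog_tsv(catalogs: Sequence[TrinucleotideCatalog], path) -> None:
    """Catalog TSV: fixed-order channel column + one count column per sample."""
    df = pd.DataFrame({c.sample_id: c.counts for c in catalogs}, index=list(CHANNELS))
    df.index.name = "channel"
    df.to_csv(path, sep="\t")


def read_catalog_tsv(path) -> list[TrinucleotideCatalog]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CHANNELS):
        raise FormatError(f"{path}: channel column must list the 96 channels in canonical order")
    return [TrinucleotideCatalog(sample_id=col, counts=df[col].to_numpy()) for col in df.columns]
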