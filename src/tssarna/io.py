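"""Genomic I/O and strand-aware 5'-start profiles.

Internal coordinates are 0-based half-open throughout the package.  GFF3
(1-based inclusive) and SAM (1-based POS) are converted on ingest; BED6 is
taken as-is.  On the minus strand a read's 5' end is its highest genomic
coordinate (``end - 1``).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated CDS.

    ``cds_start``/``cds_end`` are 0-based half-open.  The translation-start
    anchor is ``cds_start`` on '+' and ``cds_end - 1`` on '-'.
    """

    gene_id: str
    replicon: str
    strand: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise AnnotationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.cds_start < self.cds_end:
            raise AnnotationError(
                f"{self.gene_id}: cds_start must be < cds_end "
                f"({self.cds_start} >= {self.cds_end})"
            )

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def start_codon(self) -> int:
        """Genomic coordinate of the translation start (strand-aware)."""
        return self.cds_start if self.strand == "+" else self.cds_end - 1


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read, 0-based half-open, with a strand-aware 5' end."""

    replicon: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"zero/negative-length read: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class StartProfile:
    """Per-(replicon, strand) tallies of read 5'-end positions and coverage.

    ``starts[(replicon, strand)]`` maps coordinate -> number of reads whose
    5' end is there; ``coverage`` maps coordinate -> number of reads
    overlapping it.  Sum of starts equals the read count and sum of coverage
    equals total aligned bases, per (replicon, strand).
    """

    starts: dict[tuple[str, str], Counter] = field(default_factory=dict)
    coverage: dict[tuple[str, str], Counter] = field(default_factory=dict)
    n_reads: Counter = field(default_factory=Counter)

    def start_count(self, replicon: str, strand: str, coord: int) -> int:
        return self.starts.get((replicon, strand), Counter())[coord]

    def starts_in(self, replicon: str, strand: str, lo: int, hi: int) -> dict[int, int]:
        """Start counts restricted to the half-open window [lo, hi)."""
        tab = self.starts.get((replicon, strand))
        if not tab:
            return {}
        return {c: n for c, n in tab.items() if lo <= c < hi}


def compute_start_profile(reads: Iterable[AlignedRead]) -> StartProfile:
    """Tally 5'-start counts and depth of coverage per (replicon, strand)."""
    prof = StartProfile()
    for r in reads:
        key = (r.replicon, r.strand)
        if key not in prof.starts:
            prof.starts[key] = Counter()
            prof.coverage[key] = Counter()
        prof.starts[key][r.five_prime] += 1
        cov = prof.coverage[key]
        for c in range(r.start, r.end):
            cov[c] += 1
        prof.n_reads[key] += 1
    return prof


# ---------------------------------------------------------------------------
# annotation


def load_annotation(path: str | Path) -> list[GeneRecord]:
    """Load CDS records from GFF3 or a tab-delimited CDS table.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    A tab-delimited table must carry columns gene_id, replicon, strand,
    start, end with 0-based half-open coordinates.  gene_id must be unique.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text_head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                text_head = line
                break
    if not text_head:
        return []
    records = (
        _load_gff3(path) if len(text_head.rstrip("\n").split("\t")) == 9 else _load_table(path)
    )
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
    return records


def _load_gff3(path: Path) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error", from_string=False,
    )
    records = []
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        # GFF3 is 1-based inclusive: [start, end] -> [start-1, end)
        records.append(
            GeneRecord(
                gene_id=gene_id,
                replicon=feat.seqid,
                strand=feat.strand,
                cds_start=feat.start - 1,
                cds_end=feat.end,
            )
        )
    return records


def _load_table(path: Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "replicon", "strand", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"CDS table missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                GeneRecord(
                    gene_id=str(row["gene_id"]),
                    replicon=str(row["replicon"]),
                    strand=str(row["strand"]),
                    cds_start=int(row["start"]),
                    cds_end=int(row["end"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"{path} line {i + 2}: {exc}") from exc
    return out


def write_annotation_gff3(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write records as GFF3 CDS features (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(
                f"{rec.replicon}\tsynthetic\tCDS\t{rec.cds_start + 1}\t{rec.cds_end}\t."
                f"\t{rec.strand}\t0\tID={rec.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# reads

BED6_COLUMNS = ["replicon", "start", "end", "name", "score", "strand"]


def load_reads(path: str | Path) -> list[AlignedRead]:
    """Load aligned reads from BED6 or SAM/BAM (dispatch on suffix).

    Records without a strand are skipped; the number skipped is logged.
    """
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam", ".cram"):
        return _load_sam(path)
    return _load_bed(path)


def _load_bed(path: Path) -> list[AlignedRead]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED6 requires 6 columns, found {df.shape[1]}")
    df = df.iloc[:, :6]
    df.columns = BED6_COLUMNS
    reads, skipped = [], 0
    for row in df.itertuples(index=False):
        if row.strand not in STRANDS:
            skipped += 1
            continue
        reads.append(AlignedRead(str(row.replicon), int(row.start), int(row.end), row.strand))
    if skipped:
        logger.warning("%s: skipped %d records without a valid strand", path, skipped)
    return reads


def _load_sam(path: Path) -> list[AlignedRead]:
    import pysam

    reads, skipped = [], 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                skipped += 1
                continue
            strand = "-" if aln.is_reverse else "+"
            # pysam exposes 0-based half-open coordinates already
            reads.append(
                AlignedRead(aln.reference_name, aln.reference_start, aln.reference_end, strand)
            )
    if skipped:
        logger.warning("%s: skipped %d unmapped records", path, skipped)
    return reads


def write_reads_bed(reads: Iterable[AlignedRead], path: str | Path) -> None:
    rows = [
        (r.replicon, r.start, r.end, f"read{i}", 0, r.strand) for i, r in enumerate(reads)
    ]
    pd.DataFrame(rows, columns=BED6_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


def mirror_reads(reads: Iterable[AlignedRead], replicon_length: Mapping[str, int]) -> list[AlignedRead]:
    """Reverse-complement image of a read set: coordinates reflected about the
    replicon, strands flipped.  Used by strand-symmetry checks."""
    out = []
    for r in reads:
        n = replicon_length[r.replicon]
        out.append(
            AlignedRead(r.replicon, n - r.end, n - r.start, "-" if r.strand == "+" else "+")
        )
    return out
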