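"""TSSaRNA detection from strand-specific read 5'-start profiles.

A TSSaRNA is a small RNA whose 5' end coincides with the transcription start
site (TSS) of an annotated gene.  Because small-RNA libraries are built from
non-fragmented molecules, two read populations share a TSS coordinate:
identical full-length reads from the TSSaRNA itself, and reads from the
cognate gene's transcript truncated at the sequencer's read-length limit or
before.  Detection therefore proceeds in two stages per gene:

1. find the most frequent read 5'-start coordinate in a strand-aware window
   around the start codon (50 bp upstream to 20% of the CDS length inside),
   requiring more than ``min_tss_count`` reads to trust the TSS;
2. at that coordinate, group reads by their exact (5', 3') extent; the most
   abundant species shorter than the read-length limit is the TSSaRNA
   full-length sequence, retained when it has at least ``min_tssarna_count``
   copies.  All other reads starting there belong to the cognate gene.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import AlignedRead, GeneRecord, StartProfile, compute_start_profile


@dataclass(frozen=True)
class DetectionParams:
    upstream_window: int = 50
    cds_fraction: float = 0.20
    min_tss_count: int = 20       # strict: the TSS needs more than this many reads
    max_read_len: int = 151       # species must be shorter than this
    min_tssarna_count: int = 10   # inclusive: at least this many identical copies

    def __post_init__(self) -> None:
        if not (0 < self.cds_fraction <= 1):
            raise ValueError("cds_fraction must be in (0, 1]")
        for name in ("upstream_window", "min_tss_count", "max_read_len", "min_tssarna_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TssaRnaCall:
    """A detected TSSaRNA.

    ``tss`` is the shared 5' coordinate (0-based); ``tssarna_end`` the
    genomic coordinate of the TSSaRNA's 3'-terminal base (inclusive, so on
    the minus strand it is below ``tss``).  ``distance_to_start_codon`` is
    signed in transcription direction; negative means upstream.
    """

    gene_id: str
    replicon: str
    strand: str
    tss: int
    tssarna_end: int
    tssarna_length: int
    tssarna_count: int
    tss_total_count: int
    distance_to_start_codon: int

    @property
    def cognate_count(self) -> int:
        return self.tss_total_count - self.tssarna_count

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open genomic interval covered by the TSSaRNA."""
        lo, hi = sorted((self.tss, self.tssarna_end))
        return lo, hi + 1


def search_window(gene: GeneRecord, params: DetectionParams = DetectionParams()) -> tuple[int, int]:
    """Strand-aware half-open interval searched for the TSS.

    Covers 50 bp upstream of the start codon through floor(cds_fraction x
    length) bases into the CDS; mirrored about the gene's 5' end on '-'.
    """
    into = int(params.cds_fraction * gene.length)
    if gene.strand == "+":
        return gene.cds_start - params.upstream_window, gene.cds_start + into
    return gene.cds_end - into, gene.cds_end + params.upstream_window


def find_tss(
    gene: GeneRecord,
    profile: StartProfile,
    params: DetectionParams = DetectionParams(),
) -> Optional[int]:
    """Most frequent read 5'-start in the gene's search window.

    Returns the coordinate only when its start count strictly exceeds
    ``min_tss_count``.  Ties break to the coordinate closest to the start
    codon, then to the more upstream one.
    """
    lo, hi = search_window(gene, params)
    counts = profile.starts_in(gene.replicon, gene.strand, lo, hi)
    if not counts:
        return None
    anchor = gene.start_codon
    upstream_sign = -1 if gene.strand == "+" else 1

    def rank(coord: int):
        # maximize count; then minimize distance to anchor; then prefer upstream
        return (-counts[coord], abs(coord - anchor), -upstream_sign * coord)

    best = min(counts, key=rank)
    if counts[best] <= params.min_tss_count:
        return None
    return best


def call_tssarna(
    gene: GeneRecord,
    tss: int,
    reads_at_tss: Sequence[AlignedRead],
    params: DetectionParams = DetectionParams(),
) -> Optional[TssaRnaCall]:
    """Split the reads sharing ``tss`` into TSSaRNA and cognate populations.

    Species (identical 5' and 3' extents) shorter than ``max_read_len``
    compete; the most abundant wins, ties going to the shorter species.
    Returns None when no short species reaches ``min_tssarna_count``.
    """
    for r in reads_at_tss:
        if r.five_prime != tss or r.strand != gene.strand:
            raise ValueError("reads_at_tss must all share the TSS 5' coordinate and strand")
    species = Counter(r.length for r in reads_at_tss)
    short = {ln: n for ln, n in species.items() if ln < params.max_read_len}
    if not short:
        return None
    best_len = min(short, key=lambda ln: (-short[ln], ln))
    if short[best_len] < params.min_tssarna_count:
        return None
    tss_total = len(reads_at_tss)
    end = tss + best_len - 1 if gene.strand == "+" else tss - best_len + 1
    anchor = gene.start_codon
    distance = tss - anchor if gene.strand == "+" else anchor - tss
    return TssaRnaCall(
        gene_id=gene.gene_id,
        replicon=gene.replicon,
        strand=gene.strand,
        tss=tss,
        tssarna_end=end,
        tssarna_length=best_len,
        tssarna_count=short[best_len],
        tss_total_count=tss_total,
        distance_to_start_codon=distance,
    )


# audit reasons, one per rejected gene
NO_WINDOW_SIGNAL = "no-window-signal"
BELOW_TSS_THRESHOLD = "below-tss-threshold"
NO_SHORT_SPECIES = "no-short-species"
BELOW_TSSARNA_THRESHOLD = "below-tssarna-threshold"
CALLED = "called"
MULTI_ASSIGNED = "multi-assigned"


@dataclass
class DetectionResult:
    calls: list[TssaRnaCall]
    audit: pd.DataFrame = field(repr=False)


def detect_all(
    annotation: Iterable[GeneRecord],
    reads: Sequence[AlignedRead],
    params: DetectionParams = DetectionParams(),
) -> DetectionResult:
    """Run the full detection procedure over every annotated gene.

    Output is ordered by (replicon, tss).  The audit table records one row
    per gene with the stage at which it was rejected, or 'called'; a TSS
    claimed by more than one gene is additionally flagged 'multi-assigned'
    and every claim is kept.
    """
    profile = compute_start_profile(reads)
    by_tss: dict[tuple[str, str, int], list[AlignedRead]] = {}
    for r in reads:
        by_tss.setdefault((r.replicon, r.strand, r.five_prime), []).append(r)

    calls: list[TssaRnaCall] = []
    audit_rows = []
    tss_claims: Counter = Counter()
    for gene in annotation:
        tss = find_tss(gene, profile, params)
        if tss is None:
            lo, hi = search_window(gene, params)
            reason = (
                NO_WINDOW_SIGNAL
                if not profile.starts_in(gene.replicon, gene.strand, lo, hi)
                else BELOW_TSS_THRESHOLD
            )
            audit_rows.append((gene.gene_id, reason, None))
            continue
        at_tss = by_tss.get((gene.replicon, gene.strand, tss), [])
        call = call_tssarna(gene, tss, at_tss, params)
        if call is None:
            species = Counter(r.length for r in at_tss)
            reason = (
                NO_SHORT_SPECIES
                if not any(ln < params.max_read_len for ln in species)
                else BELOW_TSSARNA_THRESHOLD
            )
            audit_rows.append((gene.gene_id, reason, tss))
            continue
        calls.append(call)
        tss_claims[(gene.replicon, gene.strand, tss)] += 1
        audit_rows.append((gene.gene_id, CALLED, tss))

    audit = pd.DataFrame(audit_rows, columns=["gene_id", "status", "tss"])
    multi = {k for k, n in tss_claims.items() if n > 1}
    if multi:
        flagged = audit["gene_id"].isin(
            c.gene_id for c in calls if (c.replicon, c.strand, c.tss) in multi
        )
        audit.loc[flagged & (audit["status"] == CALLED), "status"] = MULTI_ASSIGNED
    calls.sort(key=lambda c: (c.replicon, c.tss))
    return DetectionResult(calls=calls, audit=audit)


def calls_to_frame(calls: Iterable[TssaRnaCall]) -> pd.DataFrame:
    """Tabulate calls; tss and tssarna_end are reported 1-based for output."""
    rows = [
        {
            "gene_id": c.gene_id,
            "replicon": c.replicon,
            "strand": c.strand,
            "tss": c.tss + 1,
            "tssarna_end": c.tssarna_end + 1,
            "length": c.tssarna_length,
            "tssarna_count": c.tssarna_count,
            "tss_total_count": c.tss_total_count,
            "cognate_count": c.cognate_count,
            "distance_to_start_codon": c.distance_to_start_codon,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "replicon", "strand", "tss", "tssarna_end", "length",
            "tssarna_count", "tss_total_count", "cognate_count",
            "distance_to_start_codon",
        ],
    )


def calls_from_frame(df: pd.DataFrame) -> list[TssaRnaCall]:
    """Inverse of :func:`calls_to_frame` (coordinates back to 0-based)."""
    return [
        TssaRnaCall(
            gene_id=row.gene_id,
            replicon=row.replicon,
            strand=row.strand,
            tss=int(row.tss) - 1,
            tssarna_end=int(row.tssarna_end) - 1,
            tssarna_length=int(row.length),
            tssarna_count=int(row.tssarna_count),
            tss_total_count=int(row.tss_total_count),
            distance_to_start_codon=int(row.distance_to_start_codon),
        )
        for row in df.itertuples(index=False)
    ]
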