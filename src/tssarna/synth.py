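"""Synthetic fixtures with the statistical structure the pipeline assumes.

Generates a toy genome and annotation, planted TSSaRNA read populations
(one abundant identical full-length species plus cognate-gene reads sharing
its 5' start), TEX+/TEX- dRNA-seq pairs with controllable enrichment, and
tiling-probe matrices over a growth curve — each with a machine-readable
truth table so detection, classification and differential expression can be
tested by exact recovery.  Every generator is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detect import TssaRnaCall
from .diffexp import ProbeSeries, upstream_window
from .io import AlignedRead, GeneRecord

MAX_READ_LEN = 151


class GenerationError(ValueError):
    """Requested fixture cannot be constructed."""


# ---------------------------------------------------------------------------
# genome


def make_genome(
    n_genes: int = 20,
    replicon_length: int = 50_000,
    seed: int = 0,
    replicon: str = "synrep",
    gene_len_range: tuple[int, int] = (300, 1500),
    min_gap: int = 600,
) -> tuple[list[GeneRecord], str]:
    """Non-overlapping CDSs on both strands plus a random sequence.

    ``min_gap`` keeps intergenic space large enough for the upstream
    control regions the differential-expression procedure needs.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    pos = min_gap
    for i in range(n_genes):
        length = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        if pos + length + min_gap > replicon_length:
            raise GenerationError(
                f"cannot pack {n_genes} genes of {gene_len_range} bp into "
                f"{replicon_length} bp with {min_gap} bp gaps"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"syn{i:04d}", replicon, strand, pos, pos + length))
        pos += length + min_gap + int(rng.integers(0, min_gap))
    seq = "".join(rng.choice(list("ACGT"), size=replicon_length))
    return genes, seq


def write_fasta(sequence: str, replicon: str, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(sequence), id=replicon, description="")], str(path), "fasta")


# ---------------------------------------------------------------------------
# planted reads


@dataclass(frozen=True)
class PlantSpec:
    """One planted TSSaRNA.

    ``tss_offset`` is signed along the transcription direction (negative =
    upstream of the start codon); defaults mirror a leaderless archaeal
    transcriptome where TSSs sit at or just upstream of start codons.
    """

    gene_id: str
    tss_offset: int = 0
    tssarna_length: int = 27
    tssarna_count: int = 40
    cognate_read_count: int = 15
    is_primary: bool = True
    is_DE: bool = False
    de_fold: float = 16.0
    de_direction: str = "up"

    def __post_init__(self) -> None:
        if not (0 < self.tssarna_length < MAX_READ_LEN):
            raise GenerationError("tssarna_length must be in (0, 151)")
        if self.tssarna_count < 0 or self.cognate_read_count < 0:
            raise GenerationError("counts must be >= 0")


def sample_tssarna_length(rng: np.random.Generator) -> int:
    """Study-like length: triangular on [16, 146] with mode 27."""
    return int(round(rng.triangular(16, 27, 146)))


def default_plants(
    annotation: Sequence[GeneRecord],
    seed: int = 0,
    n_primary: Optional[int] = None,
    n_de: int = 0,
    min_len_de: int = 40,
) -> list[PlantSpec]:
    """A study-like plant per gene: lengths from the triangular default,
    counts comfortably above the detection thresholds, the first
    ``n_primary`` genes primary and the first ``n_de`` differentially
    expressed (with lengths >= ``min_len_de`` so a tiling probe fits)."""
    rng = np.random.default_rng(seed)
    if n_primary is None:
        n_primary = len(annotation)
    plants = []
    for i, gene in enumerate(annotation):
        is_de = i < n_de
        length = max(min_len_de, sample_tssarna_length(rng)) if is_de else sample_tssarna_length(rng)
        length = min(length, max(16, gene.length - 1))
        plants.append(
            PlantSpec(
                gene_id=gene.gene_id,
                tss_offset=int(rng.integers(-10, 3)),
                tssarna_length=length,
                tssarna_count=int(rng.integers(40, 120)),
                cognate_read_count=int(rng.integers(10, 40)),
                is_primary=i < n_primary,
                is_DE=is_de,
                de_direction="up" if i % 2 == 0 else "down",
            )
        )
    return plants


def _plant_geometry(gene: GeneRecord, plant: PlantSpec) -> tuple[int, int]:
    """(tss, tssarna_end) in genomic coordinates (both inclusive ends)."""
    if gene.strand == "+":
        tss = gene.start_codon + plant.tss_offset
        return tss, tss + plant.tssarna_length - 1
    tss = gene.start_codon - plant.tss_offset
    return tss, tss - plant.tssarna_length + 1


def _read_from_five_prime(replicon: str, strand: str, five: int, length: int) -> AlignedRead:
    if strand == "+":
        return AlignedRead(replicon, five, five + length, strand)
    return AlignedRead(replicon, five - length + 1, five + 1, strand)


def emit_reads(
    annotation: Sequence[GeneRecord],
    plants: Sequence[PlantSpec],
    noise_rate: float = 0.0,
    seed: int = 0,
    replicon_length: int = 50_000,
    max_read_len: int = MAX_READ_LEN,
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Planted read populations plus a truth table.

    At each planted TSS: ``tssarna_count`` identical reads of the planted
    length and ``cognate_read_count`` reads of assorted longer lengths (up
    to ``max_read_len``) sharing the 5' start.  Cognate lengths are redrawn
    if any single length would rival the TSSaRNA species, so the planted
    species is always the most abundant.  Background noise reads are
    uniform at ``noise_rate`` per kb per strand.
    """
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in annotation}
    reads: list[AlignedRead] = []
    rows = []
    for plant in plants:
        if plant.gene_id not in by_id:
            raise GenerationError(f"plant references unknown gene {plant.gene_id!r}")
        gene = by_id[plant.gene_id]
        tss, tss_end = _plant_geometry(gene, plant)
        for _ in range(plant.tssarna_count):
            reads.append(
                _read_from_five_prime(gene.replicon, gene.strand, tss, plant.tssarna_length)
            )
        lo, hi = plant.tssarna_length + 1, max_read_len
        if plant.cognate_read_count and lo > hi:
            raise GenerationError(
                f"{plant.gene_id}: no room for cognate lengths above {plant.tssarna_length}"
            )
        for _attempt in range(100):
            lengths = rng.integers(lo, hi + 1, size=plant.cognate_read_count)
            counts = np.bincount(lengths) if len(lengths) else np.array([0])
            if counts.max(initial=0) < max(plant.tssarna_count, 1):
                break
        else:
            raise GenerationError(f"{plant.gene_id}: cognate species rival the TSSaRNA")
        for ln in lengths:
            reads.append(_read_from_five_prime(gene.replicon, gene.strand, tss, int(ln)))
        rows.append(
            {
                "gene_id": gene.gene_id,
                "replicon": gene.replicon,
                "strand": gene.strand,
                "tss": tss,
                "tssarna_end": tss_end,
                "tssarna_length": plant.tssarna_length,
                "tssarna_count": plant.tssarna_count,
                "cognate_count": plant.cognate_read_count,
                "tss_total_count": plant.tssarna_count + plant.cognate_read_count,
                "is_primary": plant.is_primary,
                "is_DE": plant.is_DE,
                "de_fold": plant.de_fold,
                "de_direction": plant.de_direction,
            }
        )
    n_noise = int(round(noise_rate * replicon_length / 1000)) * 2  # per strand
    replicons = sorted({g.replicon for g in annotation}) or ["synrep"]
    for _ in range(n_noise):
        length = int(rng.integers(16, max_read_len + 1))
        start = int(rng.integers(0, replicon_length - length))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(AlignedRead(str(rng.choice(replicons)), start, start + length, strand))
    return reads, pd.DataFrame(rows)


def truth_to_calls(truth: pd.DataFrame) -> list[TssaRnaCall]:
    """Re-express the truth table as calls (for feeding downstream stages
    without running detection)."""
    calls = []
    for row in truth.itertuples(index=False):
        calls.append(
            TssaRnaCall(
                gene_id=row.gene_id,
                replicon=row.replicon,
                strand=row.strand,
                tss=int(row.tss),
                tssarna_end=int(row.tssarna_end),
                tssarna_length=int(row.tssarna_length),
                tssarna_count=int(row.tssarna_count),
                tss_total_count=int(row.tss_total_count),
                distance_to_start_codon=0,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# TEX pair


def emit_tex_pair(
    annotation: Sequence[GeneRecord],
    truth: pd.DataFrame,
    depletion_factor: float = 100.0,
    seed: int = 0,
    max_read_len: int = MAX_READ_LEN,
    background: int = 2000,
    replicon_length: int = 50_000,
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """TEX+ / TEX- read sets over the planted TSSs.

    Primary plants keep their full count in TEX+ and are depleted
    ``depletion_factor``-fold in TEX-; processed plants appear with equal
    counts in both libraries, so their normalized TEX+ share stays well
    below the 0.95 primary threshold.  ``background`` reads at uniform
    positions away from the planted TSSs are added to each library,
    emulating the processed-RNA background a real TEX- library retains —
    without it, depth normalization of a mostly-primary truth set would
    cancel the depletion."""
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in annotation}
    planted_tss = {
        (row.replicon, row.strand, int(row.tss)) for row in truth.itertuples(index=False)
    }
    plus: list[AlignedRead] = []
    minus: list[AlignedRead] = []
    for row in truth.itertuples(index=False):
        gene = by_id[row.gene_id]
        n = int(row.tss_total_count)
        n_minus = max(1, round(n / depletion_factor)) if row.is_primary else n
        for target, count in ((plus, n), (minus, n_minus)):
            for _ in range(count):
                ln = min(int(rng.integers(16, max_read_len)), int(row.tssarna_length) + 30)
                target.append(
                    _read_from_five_prime(gene.replicon, gene.strand, int(row.tss), ln)
                )
    replicons = sorted({g.replicon for g in annotation}) or ["synrep"]
    for target in (plus, minus):
        added = 0
        while added < background:
            length = int(rng.integers(16, max_read_len + 1))
            start = int(rng.integers(0, replicon_length - length))
            strand = "+" if rng.random() < 0.5 else "-"
            read = AlignedRead(str(rng.choice(replicons)), start, start + length, strand)
            if (read.replicon, read.strand, read.five_prime) in planted_tss:
                continue
            target.append(read)
            added += 1
    return plus, minus


# ---------------------------------------------------------------------------
# probe matrix


def emit_probe_matrix(
    annotation: Sequence[GeneRecord],
    truth: pd.DataFrame,
    probe_len: int = 20,
    probe_step: int = 12,
    n_timepoints: int = 13,
    seed: int = 0,
    replicon_length: int = 50_000,
    noise_sigma: float = 0.05,
    n_de_points: int = 3,
    baseline: float = 1000.0,
) -> list[ProbeSeries]:
    """Tiling probes over both strands with planted intensity dynamics.

    Probes wholly inside a planted TSSaRNA follow that plant's profile: flat
    for co-varying (non-DE) plants, and ``de_fold``-fold up or down at
    ``n_de_points`` seeded time points for DE plants.  Cognate-CDS and
    upstream-control probes stay flat, so DE plants differ from both
    references at >= 2 time points while non-DE plants differ from neither.
    Multiplicative log-normal noise (sigma on the log10 scale) is applied to
    every non-reference intensity.  Raises when a DE plant admits no
    wholly-contained probe.
    """
    rng = np.random.default_rng(seed)
    plants = list(truth.itertuples(index=False))
    profiles = {}
    for row in plants:
        fold = np.ones(n_timepoints)
        if row.is_DE:
            pts = rng.choice(n_timepoints, size=n_de_points, replace=False)
            f = row.de_fold if row.de_direction == "up" else 1.0 / row.de_fold
            fold[pts] = f
        profiles[row.gene_id] = fold

    probes: list[ProbeSeries] = []
    covered_de = {row.gene_id: False for row in plants if row.is_DE}
    replicons = sorted({g.replicon for g in annotation}) or ["synrep"]
    idx = 0
    for replicon in replicons:
        for strand in ("+", "-"):
            for start in range(0, replicon_length - probe_len + 1, probe_step):
                end = start + probe_len
                fold = np.ones(n_timepoints)
                for row in plants:
                    if row.replicon != replicon or row.strand != strand:
                        continue
                    lo, hi = sorted((int(row.tss), int(row.tssarna_end)))
                    if start >= lo and end <= hi + 1:
                        fold = profiles[row.gene_id]
                        if row.is_DE:
                            covered_de[row.gene_id] = True
                        break
                base = baseline * float(10 ** rng.normal(0, noise_sigma))
                noise = 10 ** rng.normal(0, noise_sigma, size=n_timepoints)
                probes.append(
                    ProbeSeries(
                        probe_id=f"p{idx:06d}",
                        replicon=replicon,
                        strand=strand,
                        start=start,
                        end=end,
                        intensity=base * fold * noise,
                        ref_intensity=base,
                    )
                )
                idx += 1
    missing = [g for g, ok in covered_de.items() if not ok]
    if missing:
        raise GenerationError(
            f"no wholly-contained probe for DE plants {missing}; "
            f"shorten probe_len or lengthen the planted TSSaRNAs"
        )
    return probes
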