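"""Primary-transcript classification from a TEX+/TEX- dRNA-seq library pair.

Terminator 5'-phosphate-dependent exonuclease (TEX) degrades processed RNAs
(5'-monophosphate) but spares primary transcripts (5'-triphosphate), so a
TEX-treated library is enriched for true transcription starts.  A TSSaRNA is
classified primary when at least 95% of the depth-normalized signal at its
TSS survives TEX treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .detect import TssaRnaCall
from .io import AlignedRead

DEFAULT_THRESHOLD = 0.95


@dataclass(frozen=True)
class TexPair:
    """Counts at one TSS in the TEX+ and TEX- libraries, plus library sizes."""

    tex_plus_count: int
    tex_minus_count: int
    lib_size_plus: int = 1
    lib_size_minus: int = 1

    def __post_init__(self) -> None:
        if self.tex_plus_count < 0 or self.tex_minus_count < 0:
            raise ValueError("counts must be non-negative")
        if self.lib_size_plus <= 0 or self.lib_size_minus <= 0:
            raise ValueError("library sizes must be positive")


@dataclass(frozen=True)
class PrimaryCall:
    gene_id: str
    enrichment: float
    is_primary: bool


def enrichment_score(pair: TexPair, normalize: bool = True) -> float:
    """TEX+ share of the (optionally depth-normalized) signal at a TSS.

    With normalized counts n+- = count+- / lib_size+-, returns
    n+ / (n+ + n-); 0 when both counts are zero (no evidence, not primary).
    """
    if normalize:
        n_plus = pair.tex_plus_count / pair.lib_size_plus
        n_minus = pair.tex_minus_count / pair.lib_size_minus
    else:
        n_plus, n_minus = float(pair.tex_plus_count), float(pair.tex_minus_count)
    total = n_plus + n_minus
    if total == 0:
        return 0.0
    return n_plus / total


def count_at_tss(
    reads: Sequence[AlignedRead], call: TssaRnaCall, fuzz: int = 0
) -> int:
    """Reads whose 5' end falls within ``fuzz`` bp of the call's TSS, same
    replicon and strand.  fuzz=0 demands single-base agreement."""
    return sum(
        1
        for r in reads
        if r.replicon == call.replicon
        and r.strand == call.strand
        and abs(r.five_prime - call.tss) <= fuzz
    )


def classify_primary(
    calls: Iterable[TssaRnaCall],
    tex_plus_reads: Sequence[AlignedRead],
    tex_minus_reads: Sequence[AlignedRead],
    threshold: float = DEFAULT_THRESHOLD,
    normalize: bool = True,
    fuzz: int = 0,
) -> list[PrimaryCall]:
    """Classify every call as primary (enrichment >= threshold) or processed."""
    lib_plus = max(len(tex_plus_reads), 1)
    lib_minus = max(len(tex_minus_reads), 1)
    out = []
    for call in calls:
        pair = TexPair(
            tex_plus_count=count_at_tss(tex_plus_reads, call, fuzz),
            tex_minus_count=count_at_tss(tex_minus_reads, call, fuzz),
            lib_size_plus=lib_plus,
            lib_size_minus=lib_minus,
        )
        score = enrichment_score(pair, normalize=normalize)
        out.append(PrimaryCall(call.gene_id, score, score >= threshold))
    return out


def primary_to_frame(calls: Iterable[PrimaryCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.enrichment, c.is_primary) for c in calls],
        columns=["gene_id", "enrichment", "is_primary"],
    )
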