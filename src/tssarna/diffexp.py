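"""Tiling-array differential expression of TSSaRNAs versus their cognate genes.

The procedure works on probe intensities over a growth curve (13 time points
in the original compendium) expressed relative to a reference condition,
M = log10(I_t / I_ref).  For each TSSaRNA a single representative probe is
chosen: the probe covering the most TSSaRNA bases while not extending past
the TSSaRNA 3' end.  The differential signal against the cognate gene is

    V(t) = M_probe(t) - M_cognate(t),

with M_cognate the per-time-point median over cognate-gene probes starting
beyond the TSSaRNA 3' end.  A TSSaRNA is differentially expressed when
|V| >= 1 (10-fold) at the time point with the *second* largest |V| — so a
single-time-point spike never qualifies — and when the analogous statistic
against an upstream control region reaches 2-fold at its own second-ranked
time point, ruling out mere continuity with an adjacent transcript.  The
upstream control is a 300-bp region 120 bp upstream of the TSS, replaced by
the adjacent CDS when an annotated gene lies closer than 200 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .detect import TssaRnaCall
from .io import GeneRecord


@dataclass(frozen=True)
class ProbeSeries:
    """A tiling probe: interval plus intensities across the growth curve."""

    probe_id: str
    replicon: str
    strand: str
    start: int
    end: int
    intensity: np.ndarray          # one value per growth-curve time point
    ref_intensity: float           # reference-condition intensity

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.probe_id}: start must be < end")
        if self.ref_intensity <= 0 or np.any(np.asarray(self.intensity) <= 0):
            raise ValueError(f"{self.probe_id}: intensities must be positive")

    @property
    def m(self) -> np.ndarray:
        """Relative intensity M(t) = log10(I_t / I_ref)."""
        return np.log10(np.asarray(self.intensity, dtype=float) / self.ref_intensity)

    def overlap(self, lo: int, hi: int) -> int:
        return max(0, min(self.end, hi) - max(self.start, lo))


@dataclass(frozen=True)
class DEParams:
    fold_gene: float = 1.0                  # log10: 10-fold vs cognate gene
    fold_upstream: float = math.log10(2.0)  # log10: 2-fold vs upstream control
    upstream_len: int = 300
    upstream_gap: int = 120
    adjacent_gene_dist: int = 200
    rank_select: int = 2                    # use the 2nd most different |V|

    def __post_init__(self) -> None:
        if self.rank_select < 1:
            raise ValueError("rank_select must be >= 1")
        for name in ("fold_gene", "fold_upstream", "upstream_len", "upstream_gap",
                     "adjacent_gene_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# unevaluable reasons
NO_PROBE = "no-admissible-probe"
NO_COGNATE_PROBE = "no-cognate-probe"
NO_UPSTREAM_PROBE = "no-upstream-probe"
OK = "ok"


@dataclass
class DECall:
    gene_id: str
    status: str
    selected_probe: Optional[str] = None
    V_gene: Optional[np.ndarray] = None
    V_upstream: Optional[np.ndarray] = None
    t_selected: Optional[int] = None
    t_selected_upstream: Optional[int] = None
    is_DE: bool = False
    direction: Optional[str] = None


def relative_intensity(i_t: float, i_ref: float) -> float:
    """M = log10(I_t / I_ref)."""
    if i_t <= 0 or i_ref <= 0:
        raise ValueError("intensities must be positive")
    return math.log10(i_t / i_ref)


def select_probe(
    call: TssaRnaCall, probes: Iterable[ProbeSeries]
) -> Optional[ProbeSeries]:
    """Representative probe: maximal TSSaRNA coverage without extending past
    the TSSaRNA 3' end.  Ties break to the most 5' probe."""
    lo, hi = call.interval
    admissible = []
    for p in probes:
        if p.replicon != call.replicon or p.strand != call.strand:
            continue
        ov = p.overlap(lo, hi)
        if ov == 0:
            continue
        beyond = p.end > hi if call.strand == "+" else p.start < lo
        if beyond:
            continue
        admissible.append((p, ov))
    if not admissible:
        return None
    if call.strand == "+":
        return min(admissible, key=lambda t: (-t[1], t[0].start))[0]
    return min(admissible, key=lambda t: (-t[1], -t[0].end))[0]


def cognate_reference(
    call: TssaRnaCall,
    probes: Iterable[ProbeSeries],
    gene: Optional[GeneRecord] = None,
) -> Optional[np.ndarray]:
    """Per-time-point median M over cognate-gene probes starting beyond the
    TSSaRNA 3' end.  When ``gene`` is given, probes must also overlap its
    CDS.  None when no probe qualifies."""
    lo, hi = call.interval
    rows = []
    for p in probes:
        if p.replicon != call.replicon or p.strand != call.strand:
            continue
        five = p.start if call.strand == "+" else p.end - 1
        beyond = five >= hi if call.strand == "+" else five < lo
        if not beyond:
            continue
        if gene is not None and p.overlap(gene.cds_start, gene.cds_end) == 0:
            continue
        rows.append(p.m)
    if not rows:
        return None
    return np.median(np.vstack(rows), axis=0)


def upstream_window(call: TssaRnaCall, params: DEParams = DEParams()) -> tuple[int, int]:
    """Strand-aware control window upstream of the TSS (0-based half-open)."""
    if call.strand == "+":
        return call.tss - params.upstream_gap - params.upstream_len, call.tss - params.upstream_gap
    return call.tss + params.upstream_gap + 1, call.tss + params.upstream_gap + params.upstream_len + 1


def _nearest_upstream_gene(
    call: TssaRnaCall, annotation: Sequence[GeneRecord]
) -> tuple[Optional[GeneRecord], Optional[int]]:
    best, best_d = None, None
    for g in annotation:
        if g.replicon != call.replicon or g.gene_id == call.gene_id:
            continue
        if call.strand == "+":
            if g.cds_end > call.tss:
                continue
            d = call.tss - g.cds_end
        else:
            if g.cds_start <= call.tss:
                continue
            d = g.cds_start - call.tss - 1
        if best_d is None or d < best_d:
            best, best_d = g, d
    return best, best_d


def upstream_reference(
    call: TssaRnaCall,
    probes: Iterable[ProbeSeries],
    annotation: Sequence[GeneRecord],
    params: DEParams = DEParams(),
) -> Optional[np.ndarray]:
    """Per-time-point median M over the upstream control region.

    Uses the fixed window from :func:`upstream_window` unless an annotated
    gene lies closer than ``adjacent_gene_dist`` to the TSS, in which case
    all probes over that adjacent CDS are used instead."""
    gene, dist = _nearest_upstream_gene(call, annotation)
    if gene is not None and dist is not None and dist < params.adjacent_gene_dist:
        lo, hi = gene.cds_start, gene.cds_end
    else:
        lo, hi = upstream_window(call, params)
    rows = [
        p.m
        for p in probes
        if p.replicon == call.replicon and p.strand == call.strand and p.overlap(lo, hi) > 0
    ]
    if not rows:
        return None
    return np.median(np.vstack(rows), axis=0)


def rank_timepoint(v: np.ndarray, rank_select: int) -> int:
    """Index of the ``rank_select``-th largest |v| (1-based rank); ties break
    to the earlier time point."""
    if rank_select > len(v):
        raise ValueError(f"need at least {rank_select} time points, got {len(v)}")
    order = sorted(range(len(v)), key=lambda t: (-abs(v[t]), t))
    return order[rank_select - 1]


def de_call(
    call: TssaRnaCall,
    probes: Sequence[ProbeSeries],
    annotation: Sequence[GeneRecord],
    params: DEParams = DEParams(),
) -> DECall:
    """Full differential-expression decision for one TSSaRNA call."""
    probe = select_probe(call, probes)
    if probe is None:
        return DECall(call.gene_id, NO_PROBE)
    gene = next((g for g in annotation if g.gene_id == call.gene_id), None)
    m_cog = cognate_reference(call, probes, gene)
    if m_cog is None:
        return DECall(call.gene_id, NO_COGNATE_PROBE, selected_probe=probe.probe_id)
    m_up = upstream_reference(call, probes, annotation, params)
    if m_up is None:
        return DECall(call.gene_id, NO_UPSTREAM_PROBE, selected_probe=probe.probe_id)
    v_gene = probe.m - m_cog
    v_up = probe.m - m_up
    t_sel = rank_timepoint(v_gene, params.rank_select)
    t_sel_up = rank_timepoint(v_up, params.rank_select)
    gene_ok = abs(v_gene[t_sel]) >= params.fold_gene
    upstream_ok = abs(v_up[t_sel_up]) >= params.fold_upstream
    is_de = bool(gene_ok and upstream_ok)
    direction = "up" if v_gene[t_sel] > 0 else "down"
    return DECall(
        gene_id=call.gene_id,
        status=OK,
        selected_probe=probe.probe_id,
        V_gene=v_gene,
        V_upstream=v_up,
        t_selected=t_sel,
        t_selected_upstream=t_sel_up,
        is_DE=is_de,
        direction=direction,
    )


def de_all(
    calls: Iterable[TssaRnaCall],
    probes: Sequence[ProbeSeries],
    annotation: Sequence[GeneRecord],
    params: DEParams = DEParams(),
) -> pd.DataFrame:
    rows = []
    for call in calls:
        d = de_call(call, probes, annotation, params)
        rows.append(
            {
                "gene_id": d.gene_id,
                "status": d.status,
                "selected_probe": d.selected_probe,
                "t_selected": d.t_selected,
                "V_at_t": None if d.V_gene is None else float(d.V_gene[d.t_selected]),
                "V_upstream_at_t": None
                if d.V_upstream is None
                else float(d.V_upstream[d.t_selected_upstream]),
                "is_DE": d.is_DE,
                "direction": d.direction,
            }
        )
    return pd.DataFrame(rows)


def load_probes(path, ref_column: str = "ref") -> list[ProbeSeries]:
    """Read a probe table: probe_id, replicon, strand, start, end, the
    reference-intensity column, then one column per time point (in order)."""
    df = pd.read_csv(path, sep="\t")
    core = ["probe_id", "replicon", "strand", "start", "end"]
    missing = set(core + [ref_column]) - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    time_cols = [c for c in df.columns if c not in core + [ref_column]]
    return [
        ProbeSeries(
            probe_id=str(r["probe_id"]),
            replicon=str(r["replicon"]),
            strand=str(r["strand"]),
            start=int(r["start"]),
            end=int(r["end"]),
            intensity=r[time_cols].to_numpy(dtype=float),
            ref_intensity=float(r[ref_column]),
        )
        for _, r in df.iterrows()
    ]


def write_probes(probes: Sequence[ProbeSeries], path, ref_column: str = "ref") -> None:
    n_t = len(probes[0].intensity) if probes else 0
    rows = []
    for p in probes:
        row = {
            "probe_id": p.probe_id, "replicon": p.replicon, "strand": p.strand,
            "start": p.start, "end": p.end, ref_column: p.ref_intensity,
        }
        row.update({f"t{i}": p.intensity[i] for i in range(n_t)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
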