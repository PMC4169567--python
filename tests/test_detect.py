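import pytest

from tssarna import (
    DetectionParams,
    GeneRecord,
    call_tssarna,
    compute_start_profile,
    detect_all,
    find_tss,
    search_window,
)
from tssarna.detect import (
    BELOW_TSS_THRESHOLD,
    BELOW_TSSARNA_THRESHOLD,
    CALLED,
    NO_SHORT_SPECIES,
)
from tssarna.io import AlignedRead, mirror_reads

PARAMS = DetectionParams()


def reads_at(tss, lengths, strand="+", replicon="chr"):
    """Reads sharing a 5' coordinate, one per entry of ``lengths``."""
    out = []
    for ln in lengths:
        if strand == "+":
            out.append(AlignedRead(replicon, tss, tss + ln, strand))
        else:
            out.append(AlignedRead(replicon, tss - ln + 1, tss + 1, strand))
    return out


class TestSearchWindow:
    @pytest.mark.parametrize(
        "strand,cds,expected",
        [
            ("+", (1000, 1600), (950, 1120)),   # 50 bp upstream + 20% of 600
            ("-", (1000, 1600), (1480, 1650)),  # mirrored about the 5' anchor
            ("+", (1000, 1004), (950, 1000)),   # degenerate: floor(0.2*4)=0
        ],
    )
    def test_window_geometry(self, strand, cds, expected):
        gene = GeneRecord("g", "chr", strand, *cds)
        assert search_window(gene, PARAMS) == expected


class TestFindTss:
    gene = GeneRecord("g", "chr", "+", 1000, 1600)

    def _profile(self, counts):
        reads = []
        for coord, n in counts.items():
            reads += [AlignedRead("chr", coord, coord + 30, "+")] * n
        return compute_start_profile(reads)

    def test_argmax_within_window(self):
        assert find_tss(self.gene, self._profile({995: 30, 1005: 12}), PARAMS) == 995

    def test_threshold_is_strictly_more_than(self):
        assert find_tss(self.gene, self._profile({995: 20}), PARAMS) is None
        assert find_tss(self.gene, self._profile({995: 21}), PARAMS) == 995

    def test_empty_window_absent(self):
        assert find_tss(self.gene, self._profile({5000: 100}), PARAMS) is None

    def test_signal_outside_window_ignored(self):
        # 1120 is the first coordinate beyond the window
        assert find_tss(self.gene, self._profile({1120: 99, 995: 25}), PARAMS) == 995

    def test_tie_breaks_to_coordinate_nearest_start_codon(self):
        assert find_tss(self.gene, self._profile({960: 30, 995: 30}), PARAMS) == 995

    def test_remaining_tie_breaks_upstream(self):
        # equidistant from the start codon at 1000
        assert find_tss(self.gene, self._profile({995: 30, 1005: 30}), PARAMS) == 995


class TestCallTssarna:
    gene = GeneRecord("g", "chr", "+", 1000, 1600)

    def test_two_population_split(self):
        reads = reads_at(995, [27] * 40 + [60, 80, 100, 120, 140] * 3)
        call = call_tssarna(self.gene, 995, reads, PARAMS)
        assert call.tssarna_length == 27
        assert call.tssarna_count == 40
        assert call.tss_total_count == 55
        assert call.cognate_count == 15
        assert call.tssarna_end == 995 + 26
        assert call.distance_to_start_codon == -5

    def test_no_species_shorter_than_limit(self):
        assert call_tssarna(self.gene, 995, reads_at(995, [151] * 50), PARAMS) is None

    def test_species_threshold_is_at_least(self):
        reads = reads_at(995, [27] * 9 + list(range(60, 90)))  # best species: 9 copies
        assert call_tssarna(self.gene, 995, reads, PARAMS) is None
        reads = reads_at(995, [27] * 10 + [70] * 9 + [80] * 9)
        assert call_tssarna(self.gene, 995, reads, PARAMS).tssarna_count == 10

    def test_tie_between_species_goes_to_shorter(self):
        reads = reads_at(995, [27] * 15 + [40] * 15)
        assert call_tssarna(self.gene, 995, reads, PARAMS).tssarna_length == 27

    def test_minus_strand_end_below_tss(self):
        gene = GeneRecord("g", "chr", "-", 1000, 1600)
        call = call_tssarna(gene, 1610, reads_at(1610, [27] * 30, strand="-"), PARAMS)
        assert call.tssarna_end == 1610 - 26
        assert call.distance_to_start_codon == -11


class TestDetectAll:
    def test_exact_truth_recovery_at_zero_noise(self, detected):
        _, truth, result = detected
        assert len(result.calls) == len(truth) == 20
        t = truth.set_index("gene_id")
        for c in result.calls:
            row = t.loc[c.gene_id]
            assert c.tss == row.tss
            assert c.tssarna_length == row.tssarna_length
            assert c.tssarna_count == row.tssarna_count
            assert c.tss_total_count == row.tss_total_count
            assert c.tssarna_count + c.cognate_count == c.tss_total_count

    def test_output_ordered_by_replicon_then_tss(self, detected):
        _, _, result = detected
        keys = [(c.replicon, c.tss) for c in result.calls]
        assert keys == sorted(keys)

    def test_opposite_strand_reads_yield_no_calls(self):
        gene = GeneRecord("g", "chr", "-", 1000, 1600)
        reads = reads_at(1599, [27] * 50, strand="+")
        assert detect_all([gene], reads).calls == []

    def test_boundary_composition(self):
        """total=21 with species=10 passes both stated thresholds; total=20
        fails the TSS threshold; species=9 fails the species threshold."""
        gene = GeneRecord("g", "chr", "+", 1000, 1600)
        ok = reads_at(1000, [27] * 10 + list(range(40, 51)))        # total 21
        (call,) = detect_all([gene], ok).calls
        assert (call.tss_total_count, call.tssarna_count) == (21, 10)
        at_thresh = reads_at(1000, [27] * 10 + list(range(40, 50)))  # total 20
        result = detect_all([gene], at_thresh)
        assert result.calls == []
        assert result.audit.status.tolist() == [BELOW_TSS_THRESHOLD]
        few = reads_at(1000, [27] * 9 + list(range(40, 56)))         # species 9
        result = detect_all([gene], few)
        assert result.calls == []
        assert result.audit.status.tolist() == [BELOW_TSSARNA_THRESHOLD]

    def test_audit_no_short_species(self):
        gene = GeneRecord("g", "chr", "+", 1000, 1600)
        result = detect_all([gene], reads_at(1000, [151] * 30))
        assert result.audit.status.tolist() == [NO_SHORT_SPECIES]

    def test_threshold_monotonicity(self, planted):
        genes, _, reads, _ = planted
        base = {c.gene_id for c in detect_all(genes, reads).calls}
        for p in [
            DetectionParams(min_tss_count=60),
            DetectionParams(min_tssarna_count=60),
            DetectionParams(min_tss_count=60, min_tssarna_count=60),
        ]:
            assert {c.gene_id for c in detect_all(genes, reads, p).calls} <= base

    def test_strand_equivariance(self, planted):
        genes, _, reads, _ = planted
        n = 50_000
        flipped_genes = [
            GeneRecord(
                g.gene_id, g.replicon, "-" if g.strand == "+" else "+",
                n - g.cds_end, n - g.cds_start,
            )
            for g in genes
        ]
        flipped = detect_all(flipped_genes, mirror_reads(reads, {"synrep": n}))
        orig = detect_all(genes, reads)
        assert len(flipped.calls) == len(orig.calls)
        mapping = {c.gene_id: c for c in flipped.calls}
        for c in orig.calls:
            m = mapping[c.gene_id]
            assert m.tss == n - 1 - c.tss
            assert m.tssarna_length == c.tssarna_length
            assert m.tssarna_count == c.tssarna_count
            assert m.distance_to_start_codon == c.distance_to_start_codon

    def test_called_genes_flagged_in_audit(self, detected):
        _, _, result = detected
        assert (result.audit.status == CALLED).sum() == len(result.calls)
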