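"""Counting engine, normalized frequencies, Ts/Tv and delta-nu."""

import numpy as np
import pytest

from vipmut import _encoding as enc
from vipmut.frequencies import (
    MotifSpec,
    RegionMotifCounts,
    SBSMotifCounts,
    count_region_motifs,
    count_sbs_motifs,
    delta_nu,
    normalized_frequency,
    per_substitution_delta_nu,
    ts_tv,
)
from vipmut.gene_context import (
    GeneModel,
    GenomeSequence,
    SBSRecord,
    SiteContext,
    SUPPORTED_PATTERNS,
)
from vipmut.vip_tables import builtin_base_vips


def utr_model_over(seq_len: int, extra: int = 4) -> tuple[GeneModel, str]:
    """A + strand model whose 5'UTR covers [0, seq_len); CDS is a tail stub.

    Lets tests count motifs over an arbitrary sequence region whose
    flanks can still run off into an appended N pad.
    """
    total = seq_len + 1 + 3  # N spacer + 3-base CDS
    model = GeneModel(
        id="u", chrom="c", strand="+",
        exons=[(0, total)], cds_start=seq_len + 1, cds_end=total,
    )
    return model, "utr5"


def brute_force_counts(seq: str, pattern: str, positions, strand: str = "+"):
    """Independent window-scan oracle: pure string slicing."""
    x = pattern.index("X")
    k = len(pattern)
    counts = {}
    sense = seq if strand == "+" else enc.revcomp(seq)
    for pos in positions:
        p = pos if strand == "+" else len(seq) - 1 - pos
        start = p - x
        end = start + k
        if start < 0 or end > len(sense):
            continue
        motif = sense[start:end]
        if "N" in motif:
            continue
        counts[motif] = counts.get(motif, 0) + 1
    return counts


class TestCountRegionMotifs:
    def _counts(self, seq: str, pattern: str):
        model, region = utr_model_over(len(seq))
        genome = GenomeSequence({"c": seq + "N" + "ATG"})
        return count_region_motifs(genome, [model], region, MotifSpec(pattern))

    def test_hand_enumeration_doublets(self):
        rc = self._counts("ACGTACGT", "XN")
        assert rc.as_dict() == {"AC": 2, "CG": 2, "GT": 2, "TA": 1}
        assert rc.total == 7

    def test_hand_enumeration_triplets(self):
        rc = self._counts("ACGTACGT", "NXN")
        assert rc.as_dict() == {"ACG": 2, "CGT": 2, "GTA": 1, "TAC": 1}
        assert rc.total == 6

    def test_homopolymer(self):
        rc = self._counts("A" * 30, "XN")
        assert rc.as_dict() == {"AA": 29}

    def test_empty_region_rejected(self, toy_genome):
        model = GeneModel(id="e", chrom="c1", strand="+",
                          exons=[(0, 9)], cds_start=0, cds_end=9)
        with pytest.raises(ValueError):
            count_region_motifs(toy_genome, [model], "intron", MotifSpec("XN"))

    @pytest.mark.parametrize("pattern", SUPPORTED_PATTERNS)
    @pytest.mark.parametrize("strand", "+-")
    def test_oracle_equivalence_small(self, pattern, strand):
        """Engine counts equal the brute-force scan, both strands, with Ns."""
        rng = np.random.default_rng(hash((pattern, strand)) % 2**31)
        seq = "".join("ACGTN"[i] for i in rng.choice(5, size=300, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        L = len(seq)
        model = GeneModel(id="m", chrom="c", strand=strand,
                          exons=[(0, L + 3)], cds_start=L, cds_end=L + 3)
        genome = GenomeSequence({"c": seq + "NNN"})
        region = "utr5" if strand == "+" else "utr3"
        rc = count_region_motifs(genome, [model], region, MotifSpec(pattern))
        assert rc.as_dict() == brute_force_counts(seq, pattern, range(L), strand)


def _rec(motif: str, clinical="vus", region="intron", alt=None):
    """An SBSRecord/SiteContext pair whose NXN (or XN/X) motif is `motif`."""
    x = len(motif) // 2 if len(motif) == 3 else 0
    ref = motif[x]
    alt = alt or ("A" if ref != "A" else "G")
    rec = SBSRecord("c", 50, ref, alt, region, "noncoding", clinical, "t")
    ctx = SiteContext("c", 50, ref, region,
                      up_flank="ACGTA" + motif[:x], down_flank=motif[x + 1 :] + "ACGTA")
    return rec, ctx


class TestCountSbsMotifs:
    def test_counting_and_filters(self):
        pairs = [_rec("ACG")] * 0
        pairs = [_rec("CGT") for _ in range(3)] + [_rec("ACG")]
        # wild-type base of CGT is G; of ACG is C
        recs = [r for r, _ in pairs]
        ctxs = [c for _, c in pairs]
        spec = MotifSpec("NXN")
        all_counts = count_sbs_motifs(recs, ctxs, "intron", spec)
        assert all_counts.as_dict() == {"CGT": 3, "ACG": 1}
        assert all_counts.total == 4
        g_only = count_sbs_motifs(recs, ctxs, "intron", spec, wild_type="G")
        assert g_only.as_dict() == {"CGT": 3}

    def test_clinical_filter_on_unlabelled_is_empty(self):
        pairs = [_rec("CGT"), _rec("ACG")]
        counts = count_sbs_motifs([r for r, _ in pairs], [c for _, c in pairs],
                                  "intron", MotifSpec("NXN"), clinical_group="pathogenic")
        assert counts.total == 0

    def test_short_flank_skipped_and_counted(self):
        rec = SBSRecord("c", 0, "A", "G", "intron", "noncoding", "vus", "t")
        ctx = SiteContext("c", 0, "A", "intron", up_flank="", down_flank="CCCCC")
        counts = count_sbs_motifs([rec], [ctx], "intron", MotifSpec("NXN"))
        assert counts.total == 0
        assert counts.n_skipped == 1


class TestNormalizedFrequency:
    def _region_counts(self):
        model, region = utr_model_over(8)
        genome = GenomeSequence({"c": "ACGTACGT" + "N" + "ATG"})
        return count_region_motifs(genome, [model], region, MotifSpec("XN"))

    def _sbs(self, counts: dict, region="utr5"):
        arr = np.zeros(16, dtype=np.int64)
        for m, n in counts.items():
            arr[enc.motif_to_code(m)] = n
        return SBSMotifCounts(region=region, spec=MotifSpec("XN"), counts_by_code=arr)

    def test_hand_ratio(self):
        table = normalized_frequency(self._sbs({"CG": 2, "AC": 1}), self._region_counts())
        assert table.ratios["CG"] == pytest.approx((2 / 3) / (2 / 7), abs=1e-12)

    def test_proportional_gives_all_ones(self):
        rc = self._region_counts()
        table = normalized_frequency(
            self._sbs({m: 3 * c for m, c in rc.as_dict().items()}), rc
        )
        assert all(v == pytest.approx(1.0, abs=1e-12) for v in table.ratios.values())

    def test_absent_motif_ratio_zero(self):
        table = normalized_frequency(self._sbs({"CG": 2}), self._region_counts())
        assert table.ratios["TA"] == 0.0

    def test_weighted_mean_identity(self, small_study):
        """Region-frequency-weighted mean of ratios is exactly 1."""
        from vipmut.frequencies import count_region_motifs as crm

        s = small_study
        for pattern in ("XN", "NXN"):
            spec = MotifSpec(pattern)
            rc = crm(s.genome, s.models, "exon", spec)
            sc = count_sbs_motifs(s.records, s.contexts, "exon", spec)
            table = normalized_frequency(sc, rc)
            assert table.weighted_mean(rc) == pytest.approx(1.0, abs=1e-9)

    def test_empty_numerator_rejected(self):
        with pytest.raises(ValueError):
            normalized_frequency(self._sbs({}), self._region_counts())


class TestTsTv:
    def test_hand_ratio(self):
        recs = [
            SBSRecord("c", i, r, a, "intron", "noncoding", "vus", "t")
            for i, (r, a) in enumerate([("C", "T"), ("T", "C"), ("A", "G"), ("A", "T")])
        ]
        res = ts_tv(recs)
        assert (res.n_transitions, res.n_transversions) == (3, 1)
        assert res.ratio == 3.0

    def test_zero_transversions_undefined(self):
        recs = [SBSRecord("c", 0, "A", "G", "intron", "noncoding", "vus", "t")]
        with pytest.raises(ZeroDivisionError):
            ts_tv(recs).ratio

    def test_zero_transitions(self):
        recs = [
            SBSRecord("c", i, "A", a, "intron", "noncoding", "vus", "t")
            for i, a in enumerate("CT")
        ]
        assert ts_tv(recs).ratio == 0.0


def _region_counts_from(counts: dict, pattern: str, region="intron"):
    k = len(pattern)
    arr = np.zeros(4**k, dtype=np.int64)
    for m, n in counts.items():
        arr[enc.motif_to_code(m)] = n
    return RegionMotifCounts(region=region, spec=MotifSpec(pattern), counts_by_code=arr)


class TestDeltaNu:
    def _pairs(self, path_counts, benign_counts):
        pairs = []
        for m, n in path_counts.items():
            pairs += [_rec(m, clinical="pathogenic") for _ in range(n)]
        for m, n in benign_counts.items():
            pairs += [_rec(m, clinical="likely_benign") for _ in range(n)]
        return [r for r, _ in pairs], [c for _, c in pairs]

    def test_hand_value(self):
        # region frequencies CG=0.4, AC=0.6 via counts 2 and 3
        rc = _region_counts_from({"CG": 2, "AC": 3}, "XN")
        recs, ctxs = self._pairs({"CG": 3, "AC": 1}, {"CG": 1, "AC": 3})
        table = delta_nu(recs, ctxs, rc, MotifSpec("XN"))
        assert table.values["CG"] == pytest.approx((0.75 - 0.25) / 0.4, abs=1e-12)

    def test_identical_groups_zero(self):
        rc = _region_counts_from({"CG": 2, "AC": 3}, "XN")
        recs, ctxs = self._pairs({"CG": 2, "AC": 2}, {"CG": 2, "AC": 2})
        table = delta_nu(recs, ctxs, rc, MotifSpec("XN"))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in table.values.values())

    def test_swapped_labels_negate(self):
        rc = _region_counts_from({"CG": 2, "AC": 3}, "XN")
        recs, ctxs = self._pairs({"CG": 3, "AC": 1}, {"CG": 1, "AC": 3})
        fwd = delta_nu(recs, ctxs, rc, MotifSpec("XN"))
        recs2, ctxs2 = self._pairs({"CG": 1, "AC": 3}, {"CG": 3, "AC": 1})
        rev = delta_nu(recs2, ctxs2, rc, MotifSpec("XN"))
        for m in fwd.values:
            assert fwd.values[m] == pytest.approx(-rev.values[m], abs=1e-12)

    def test_empty_group_rejected(self):
        rc = _region_counts_from({"CG": 2, "AC": 3}, "XN")
        recs, ctxs = self._pairs({"CG": 3}, {})
        with pytest.raises(ValueError, match="benign=0"):
            delta_nu(recs, ctxs, rc, MotifSpec("XN"))


class TestPerSubstitutionDeltaNu:
    def _base_counts(self, freqs, region="intron"):
        return _region_counts_from(freqs, "X", region)

    def test_equal_frequency_gives_zero(self):
        rc = self._base_counts({"C": 1, "A": 1})
        recs = [
            SBSRecord("c", 0, "C", "T", "intron", "noncoding", "pathogenic", "t"),
            SBSRecord("c", 1, "C", "T", "intron", "noncoding", "benign", "t"),
        ]
        df = per_substitution_delta_nu(recs, rc, builtin_base_vips())
        row = df[(df.ref == "C") & (df.alt == "T")].iloc[0]
        assert row.delta_nu == pytest.approx(0.0, abs=1e-12)

    def test_hand_values_and_cardinality(self):
        rc = self._base_counts({"C": 1, "A": 1})
        recs = [
            SBSRecord("c", 0, "C", "T", "intron", "noncoding", "pathogenic", "t"),
            SBSRecord("c", 1, "A", "G", "intron", "noncoding", "benign", "t"),
        ]
        df = per_substitution_delta_nu(recs, rc, builtin_base_vips())
        assert len(df) == 12
        assert df.set_index(["ref", "alt"]).loc[("C", "T"), "delta_nu"] == pytest.approx(2.0)
        assert df.set_index(["ref", "alt"]).loc[("A", "G"), "delta_nu"] == pytest.approx(-2.0)
        assert df.set_index(["ref", "alt"]).loc[("C", "T"), "abs_delta_vip"] == pytest.approx(0.25)


def test_group_frequencies_sum_to_one(small_study):
    """Within each clinical group, motif shares sum to 1."""
    s = small_study
    spec = MotifSpec("NXN")
    for group in ("pathogenic", "benign"):
        sc = count_sbs_motifs(s.records, s.contexts, "exon", spec, clinical_group=group)
        shares = sc.counts_by_code / sc.total
        assert shares.sum() == pytest.approx(1.0, abs=1e-12)
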