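"""Template annotation: codon risk enumeration, region partitioning, q."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shmstop.template import (
    BASES,
    STOP_CODONS,
    DEFAULT_REGION_WEIGHTS,
    RegionPartition,
    Region,
    VGeneTemplate,
    codon_stop_risk,
    find_hotspot_motifs,
    merge_intervals,
    partition_regions,
    position_stop_risk,
    risk_profile,
    template_stop_probability_per_mutation,
)

ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
NON_STOP = [c for c in ALL_CODONS if c not in STOP_CODONS]


def brute_force_risk(codon):
    """Independent enumeration over the 9 single-nucleotide variants."""
    n = 0
    for pos in range(3):
        for base in BASES:
            if base != codon[pos]:
                variant = codon[:pos] + base + codon[pos + 1:]
                if variant in ("TAA", "TAG", "TGA"):
                    n += 1
    return n


class TestCodonRisk:
    @pytest.mark.parametrize("codon,expected", [
        ("CAA", 1),   # only C->T gives TAA
        ("TAT", 2),   # T->A gives TAA, T->G gives TAG
        ("GGG", 0),   # no single change reaches a stop
        ("TGG", 2),   # tryptophan: G->A at either G -> TAG or TGA
    ])
    def test_known_codons(self, codon, expected):
        count, prob = codon_stop_risk(codon)
        assert count == expected
        assert prob == pytest.approx(expected / 9)

    def test_all_codons_match_enumeration(self):
        """Formulaic risk equals independent brute force for all 64 codons."""
        for codon in ALL_CODONS:
            if codon in STOP_CODONS:
                with pytest.raises(ValueError):
                    codon_stop_risk(codon)
            else:
                assert codon_stop_risk(codon)[0] == brute_force_risk(codon)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            codon_stop_risk("TAA")

    def test_invalid_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_stop_risk("ANN")

    def test_position_risk_sums_to_codon_risk(self):
        for codon in NON_STOP:
            total = sum(position_stop_risk(codon, i) for i in range(3))
            assert total * 3 == pytest.approx(codon_stop_risk(codon)[0])


class TestTemplateValidation:
    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop codon"):
            VGeneTemplate("bad", "CAATAAGGG")

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            VGeneTemplate("bad", "CAAT")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            VGeneTemplate("bad", "CANTATGGG")

    def test_overlapping_cdrs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            VGeneTemplate("bad", "CAATATGGGCAA", cdr_intervals=((0, 6), (3, 9)))

    def test_cdr_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            VGeneTemplate("bad", "CAATATGGG", cdr_intervals=((0, 12),))


class TestHotspotMotifs:
    def test_absent_pattern(self):
        t = VGeneTemplate("t", "AAAAAA")
        assert find_hotspot_motifs(t, ["RGYW"]) == []

    def test_literal_match_at_offset_zero(self):
        t = VGeneTemplate("t", "AGCTCACAA")
        assert find_hotspot_motifs(t, ["AGCT"]) == [(0, 4)]

    def test_degenerate_scan_matches_window_oracle(self, synthetic_template):
        """RGYW hits equal an independent brute-force window scan."""
        seq = synthetic_template.seq
        expected = []
        for i in range(len(seq) - 3):
            win = seq[i:i + 4]
            if (win[0] in "AG" and win[1] == "G" and win[2] in "CT"
                    and win[3] in "AT"):
                expected.append((i, i + 4))
        assert find_hotspot_motifs(synthetic_template, ["RGYW"]) == \
            merge_intervals(expected)

    def test_overlapping_matches_merge(self):
        t = VGeneTemplate("t", "CAGCTAGCTAGC")  # CAG CTA GCT AGC: no stops
        # AGCT matches at 1 and 5; the touching intervals merge
        assert find_hotspot_motifs(t, ["AGCT"]) == [(1, 9)]
        assert find_hotspot_motifs(t, ["GCTA"]) == [(2, 10)]
        # overlapping matches of two patterns collapse to one interval
        assert find_hotspot_motifs(t, ["AGCT", "GCTA"]) == [(1, 10)]

    def test_invalid_iupac_symbol(self):
        t = VGeneTemplate("t", "AAAAAA")
        with pytest.raises(ValueError, match="IUPAC"):
            find_hotspot_motifs(t, ["RGYX"])


class TestPartition:
    def test_no_annotations_single_region(self):
        t = VGeneTemplate("t", "CAATATGGG")
        part = partition_regions(t)
        assert len(part.regions) == 1
        r = part.regions[0]
        assert (r.start, r.end, r.region_class, r.weight) == (0, 9, "FR_plain", 1.0)

    def test_cdr_motif_intersection(self):
        # CDR [3,9), motif [6,12), L=15 -> five regions by set intersection
        t = VGeneTemplate("t", "CAACAACAACAACAA", cdr_intervals=((3, 9),))
        part = partition_regions(t, [(6, 12)])
        got = [(r.start, r.end, r.region_class) for r in part.regions]
        assert got == [
            (0, 3, "FR_plain"),
            (3, 6, "CDR_plain"),
            (6, 9, "CDR_motif"),
            (9, 12, "FR_motif"),
            (12, 15, "FR_plain"),
        ]
        weights = {r.region_class: r.weight for r in part.regions}
        assert weights == {"FR_plain": 1.0, "CDR_plain": 5.0,
                           "CDR_motif": 10.0, "FR_motif": 2.0}

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 29), st.integers(1, 6)), max_size=4),
           st.lists(st.tuples(st.integers(0, 29), st.integers(1, 6)), max_size=4))
    def test_tiling_conservation(self, cdr_raw, motif_raw):
        """Regions always tile [0, L) exactly, whatever the annotations."""
        L = 30
        cdrs = merge_intervals([(s, min(L, s + w)) for s, w in cdr_raw])
        motifs = merge_intervals([(s, min(L, s + w)) for s, w in motif_raw])
        t = VGeneTemplate("t", "CAA" * 10, cdr_intervals=tuple(cdrs))
        part = partition_regions(t, motifs)
        assert sum(r.size for r in part.regions) == L
        assert part.regions[0].start == 0 and part.regions[-1].end == L

    def test_out_of_range_motif_rejected(self):
        t = VGeneTemplate("t", "CAATATGGG")
        with pytest.raises(ValueError):
            partition_regions(t, [(3, 12)])


class TestTemplateQ:
    def test_zero_risk_template(self):
        t = VGeneTemplate("t", "GGG" * 4)
        assert template_stop_probability_per_mutation(t) == 0.0

    def test_toy_unweighted(self, toy_template):
        # brute force over all 27 single-nucleotide substitutions: 1+2+0 stops
        assert template_stop_probability_per_mutation(toy_template) == \
            pytest.approx(3 / 27)

    def test_toy_weighted_matches_enumeration(self, toy_template):
        """Weighted q equals an exhaustive position-weighted enumeration."""
        part = RegionPartition((
            Region(0, 3, "FR_plain", 1.0),
            Region(3, 6, "CDR_plain", 5.0),
            Region(6, 9, "FR_plain", 1.0),
        ), 9)
        # enumeration oracle: each position i has weight w_i; each of its 3
        # substitutions probability w_i / (3 * sum w)
        seq = toy_template.seq
        w = part.position_weights()
        num = 0.0
        for i, wi in enumerate(w):
            for base in BASES:
                if base == seq[i]:
                    continue
                cs = 3 * (i // 3)
                codon = seq[cs:cs + 3]
                mutated = codon[:i - cs] + base + codon[i - cs + 1:]
                if mutated in STOP_CODONS:
                    num += wi / 3
        expected = num / sum(w)
        assert template_stop_probability_per_mutation(toy_template, part) == \
            pytest.approx(expected)

    def test_uniform_weights_reduce_to_mean_codon_risk(self, synthetic_template):
        q = template_stop_probability_per_mutation(synthetic_template)
        counts = [codon_stop_risk(synthetic_template.codon(i))[0]
                  for i in range(synthetic_template.n_codons)]
        mean_risk = np.mean([c / 9 for c in counts])
        assert q == pytest.approx(mean_risk)

    def test_resplitting_invariance(self, toy_template):
        """q is unchanged when a region splits into equal-weight parts."""
        one = RegionPartition((Region(0, 9, "CDR_plain", 5.0),), 9)
        split = RegionPartition((
            Region(0, 3, "CDR_plain", 5.0),
            Region(3, 9, "CDR_plain", 5.0),
        ), 9)
        assert template_stop_probability_per_mutation(toy_template, one) == \
            pytest.approx(template_stop_probability_per_mutation(toy_template, split))

    def test_monte_carlo_agreement(self, synthetic_template, synthetic_partition, rng):
        """Formula q matches sampling positions ~ weights + uniform base."""
        t, part = synthetic_template, synthetic_partition
        q = template_stop_probability_per_mutation(t, part)
        w = np.asarray(part.position_weights(), float)
        w = w / w.sum()
        n = 100_000
        positions = rng.choice(t.length, size=n, p=w)
        hits = 0
        seq = t.seq
        for i in positions:
            alts = [b for b in BASES if b != seq[i]]
            base = alts[rng.integers(0, 3)]
            cs = 3 * (i // 3)
            codon = seq[cs:cs + 3]
            if codon[:i - cs] + base + codon[i - cs + 1:] in STOP_CODONS:
                hits += 1
        est = hits / n
        se = np.sqrt(q * (1 - q) / n)
        assert abs(est - q) < 3 * se


class TestRiskProfile:
    def test_profile_consistency(self, synthetic_template, synthetic_partition):
        prof = risk_profile(synthetic_template, synthetic_partition)
        assert len(prof.codons) == synthetic_template.n_codons
        for c in prof.codons:
            assert c.risk_count == brute_force_risk(c.codon)
            assert c.risk_probability == pytest.approx(c.risk_count / 9)
        recs = prof.to_records()
        assert recs[0]["codon_index"] == 1  # 1-based in reports
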