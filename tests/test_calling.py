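"""Mutation-calling filters: flags, quality/end rules, SNP masking, SAM."""

import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tlkinetics import (CallStats, MutationEvent, ReadRecord, SimConfig,
                        SnpMask, count_mutations, filter_mutations,
                        identify_snp_sites, read_records_with_artifacts,
                        select_proper_pairs, simulate_experiment)


def _read(events, gene="g1", read_id="r1"):
    return ReadRecord(sample_id="s1", gene_id=gene, read_id=read_id,
                      events=events, n_t_sites=25)


class TestProperPairs:
    def test_allowed_and_disallowed_flag_pairs(self):
        recs = [ReadRecord("s", "g", "a", mate_flags=(99, 147)),
                ReadRecord("s", "g", "b", mate_flags=(163, 83)),
                ReadRecord("s", "g", "c", mate_flags=(77, 141)),
                ReadRecord("s", "g", "d", mate_flags=(99, 83))]
        stats = CallStats()
        kept = [r.read_id for r in select_proper_pairs(recs, stats)]
        assert kept == ["a", "b"]
        assert stats.pairs_dropped_flags == 2

    def test_mixed_stream_counts(self):
        allowed = [(83, 163), (99, 147)]
        rng = np.random.default_rng(3)
        flags = [allowed[i % 2] for i in range(4)] + \
                [(int(rng.integers(0, 60)), 141) for _ in range(6)]
        recs = [ReadRecord("s", "g", str(i), mate_flags=f)
                for i, f in enumerate(flags)]
        assert len(list(select_proper_pairs(recs))) == 4

    def test_malformed_flags_skipped_with_count(self):
        recs = [ReadRecord("s", "g", "a", mate_flags=("x", None))]
        stats = CallStats()
        assert list(select_proper_pairs(recs, stats)) == []
        assert stats.records_malformed == 1


class TestFilterMutations:
    def test_hand_enumerated_example(self):
        # q41/off10 kept; q41/off1 dropped (end); q39/off10 dropped (quality)
        read = _read([
            MutationEvent(100, 41, 10, 89),
            MutationEvent(120, 41, 1, 98),
            MutationEvent(140, 39, 10, 89),
        ])
        assert filter_mutations(read) == 1

    def test_quality_threshold_is_strict(self):
        assert filter_mutations(_read([MutationEvent(5, 39, 10, 50)])) == 0
        assert filter_mutations(_read([MutationEvent(5, 40, 10, 50)])) == 1

    def test_end_exclusion_applies_to_both_ends(self):
        # offset 2 from the 3' end is within the excluded 3-nt window
        assert filter_mutations(_read([MutationEvent(5, 41, 50, 2)])) == 0
        assert filter_mutations(_read([MutationEvent(5, 41, 3, 50)])) == 1

    def test_snp_site_masked(self):
        mask = SnpMask([("g1", 100)])
        read = _read([MutationEvent(100, 41, 10, 89),
                      MutationEvent(101, 41, 10, 89)])
        assert filter_mutations(read, snp_mask=mask) == 1

    def test_non_tc_events_never_counted(self):
        ev = MutationEvent(5, 41, 10, 50, ref_base="G", alt_base="A")
        assert filter_mutations(_read([ev])) == 0

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            filter_mutations(_read([MutationEvent(5, 41, -1, 50)]))

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 45), st.integers(0, 20),
                              st.integers(0, 20)), max_size=12),
           st.integers(30, 45), st.integers(0, 6))
    def test_tightening_thresholds_is_monotone(self, raw, q, end):
        events = [MutationEvent(i, a, b, c)
                  for i, (a, b, c) in enumerate(raw)]
        read = _read(events)
        base = filter_mutations(read, min_quality=q, end_exclusion_nt=end)
        assert filter_mutations(read, min_quality=q + 2,
                                end_exclusion_nt=end) <= base
        assert filter_mutations(read, min_quality=q,
                                end_exclusion_nt=end + 2) <= base


class TestSnpDetection:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "ref_pos",
                                           "mutations", "coverage"])

    def test_obvious_het_site_masked(self):
        mask = identify_snp_sites(
            self._sites([("g1", 10, 25, 50)]), background_rate=0.001)
        assert ("g1", 10) in mask

    def test_clean_site_not_masked(self):
        mask = identify_snp_sites(
            self._sites([("g1", 10, 0, 50)]), background_rate=0.001)
        assert ("g1", 10) not in mask

    def test_marginal_site_exact_binomial(self):
        # P(X >= 1 | n=10, p=0.1) = 1 - 0.9^10 = 0.651 > 0.05
        mask = identify_snp_sites(
            self._sites([("g1", 10, 1, 10)]), background_rate=0.1)
        assert len(mask) == 0
        assert mask.site_table["p_value"].iloc[0] == pytest.approx(
            1 - 0.9 ** 10, abs=1e-12)

    def test_alpha_extremes(self):
        sites = self._sites([("g1", 1, 2, 50), ("g1", 2, 0, 50)])
        assert len(identify_snp_sites(sites, background_rate=0.01,
                                      alpha=0.0)) == 0
        masked = identify_snp_sites(sites, background_rate=0.01, alpha=1.0)
        assert ("g1", 1) in masked and ("g1", 2) not in masked

    def test_background_rate_validation(self):
        with pytest.raises(ValueError):
            identify_snp_sites(self._sites([("g", 0, 0, 10)]),
                               background_rate=1.5)
        with pytest.raises(ValueError):
            identify_snp_sites(self._sites([("g", 0, 0, 0)]))

    def test_detects_injected_snps_in_simulated_controls(self):
        cfg = SimConfig(n_genes=80, reads_per_gene=150, snp_fraction=0.02,
                        seed=12)
        ds = simulate_experiment(cfg)
        sites = ds.site_counts[ds.site_counts["coverage"] >= 50]
        mask = identify_snp_sites(
            sites[["gene_id", "ref_pos", "mutations", "coverage"]])
        truth = set(map(tuple, ds.truth.snp_sites.to_numpy()))
        truth &= set(zip(sites["gene_id"], sites["ref_pos"]))
        found = sum(1 for s in truth if s in mask)
        assert found / max(len(truth), 1) >= 0.95
        # false-positive side: clean sites rarely masked
        clean = sites[~sites["is_snp"]]
        fp = sum(1 for s in zip(clean["gene_id"], clean["ref_pos"])
                 if s in mask)
        assert fp / max(len(clean), 1) <= 0.06

    def test_blacklist_merge(self):
        mask = SnpMask([("g1", 5)])
        mask.merge_blacklist([("g2", 7)])
        assert ("g2", 7) in mask and len(mask) == 2


class TestCountMutations:
    META = {"s1": ("WT", 1)}

    def test_empty_stream_keeps_headers(self):
        table = count_mutations([], None, self.META)
        assert list(table.columns) == ["sample_id", "condition", "s4u",
                                       "gene_id", "read_id", "tc"]
        assert len(table) == 0

    def test_reads_without_surviving_events_stay_as_zero_rows(self):
        recs = [_read([MutationEvent(1, 10, 10, 50)], read_id=f"r{i}")
                for i in range(5)]
        table = count_mutations(recs, None, self.META)
        assert len(table) == 5
        assert (table["tc"] == 0).all()

    def test_unknown_gene_dropped_with_count(self):
        recs = [_read([], gene="gX")]
        stats = CallStats()
        table = count_mutations(recs, None, self.META, genes={"g1"},
                                stats=stats)
        assert len(table) == 0 and stats.reads_no_gene == 1

    def test_artifact_decorated_reads_recover_truth_exactly(self):
        cfg = SimConfig(n_genes=12, reads_per_gene=40,
                        replicates_per_condition=1, snp_fraction=0.05,
                        seed=21)
        ds = simulate_experiment(cfg)
        records, mask_sites = read_records_with_artifacts(ds, seed=22)
        meta = {r.sample_id: (r.condition, int(r.s4u))
                for r in ds.truth.samples.itertuples(index=False)}
        table = count_mutations(records, SnpMask(mask_sites), meta)
        merged = table.merge(ds.reads[["read_id", "tc"]], on="read_id",
                             suffixes=("", "_truth"))
        assert len(merged) == len(ds.reads)
        assert (merged["tc"] == merged["tc_truth"]).all()


SAM_TEMPLATE = """\
@HD\tVN:1.6\tSO:coordinate
@SQ\tSN:chr1\tLN:10000
{body}
"""


def _write_sam(tmp_path, body):
    p = tmp_path / "toy.sam"
    p.write_text(SAM_TEMPLATE.format(body=textwrap.dedent(body).strip()))
    return p


def _annotation():
    return pd.DataFrame({
        "chrom": ["chr1", "chr1"], "start": [1000, 2000],
        "end": [1500, 2500], "gene_id": ["plusG", "minusG"],
        "strand": ["+", "-"]})


class TestParseSam:
    def test_clean_read_has_no_events(self, tmp_path):
        from tlkinetics import parse_sam
        seq = "A" * 50
        body = (f"r1\t0\tchr1\t1101\t60\t50M\t*\t0\t0\t{seq}\t{'J'*50}"
                f"\tMD:Z:50\tNM:i:0")
        recs = list(parse_sam(_write_sam(tmp_path, body), _annotation()))
        assert len(recs) == 1
        assert recs[0].gene_id == "plusG"
        assert recs[0].events == []

    def test_forward_t_to_c_event_coordinates(self, tmp_path):
        from tlkinetics import parse_sam
        # reference T at offset 20 read as C, q=41 ('J')
        seq = "A" * 20 + "C" + "A" * 29
        body = (f"r1\t0\tchr1\t1101\t60\t50M\t*\t0\t0\t{seq}\t{'J'*50}"
                f"\tMD:Z:20T29\tNM:i:1")
        recs = list(parse_sam(_write_sam(tmp_path, body), _annotation()))
        (ev,) = recs[0].events
        assert ev.ref_pos == 1120  # 0-based: (1101-1) + 20
        assert ev.base_quality == 41
        assert ev.offset_from_5p == 20 and ev.offset_from_3p == 29
        assert (ev.ref_base, ev.alt_base) == ("T", "C")

    def test_minus_strand_a_to_g_is_t_to_c(self, tmp_path):
        from tlkinetics import parse_sam
        # gene on the minus strand: genomic A>G == transcript T>C; the read
        # maps reversed, so 5' offset counts from the read's other end
        seq = "C" * 10 + "G" + "C" * 39
        body = (f"r1\t16\tchr1\t2101\t60\t50M\t*\t0\t0\t{seq}\t{'J'*50}"
                f"\tMD:Z:10A39\tNM:i:1")
        recs = list(parse_sam(_write_sam(tmp_path, body), _annotation()))
        (ev,) = recs[0].events
        assert (ev.ref_base, ev.alt_base) == ("T", "C")
        assert ev.offset_from_5p == 39 and ev.offset_from_3p == 10
        assert recs[0].n_t_sites == 1  # single reference A in the window

    def test_read_outside_annotation_dropped(self, tmp_path):
        from tlkinetics import parse_sam
        stats = CallStats()
        body = (f"r1\t0\tchr1\t5001\t60\t10M\t*\t0\t0\t{'A'*10}\t{'J'*10}"
                f"\tMD:Z:10\tNM:i:0")
        recs = list(parse_sam(_write_sam(tmp_path, body), _annotation(),
                              stats=stats))
        assert recs == [] and stats.reads_no_gene == 1

    def test_missing_md_counted(self, tmp_path):
        from tlkinetics import parse_sam
        stats = CallStats()
        body = f"r1\t0\tchr1\t1101\t60\t10M\t*\t0\t0\t{'A'*10}\t{'J'*10}"
        recs = list(parse_sam(_write_sam(tmp_path, body), _annotation(),
                              stats=stats))
        assert recs == [] and stats.reads_missing_md == 1

    def test_mate_flags_joined_by_name(self, tmp_path):
        from tlkinetics import parse_sam
        seq10 = "A" * 10
        body = (
            f"r1\t99\tchr1\t1101\t60\t10M\t=\t1201\t110\t{seq10}\t{'J'*10}\tMD:Z:10\tNM:i:0\n"
            f"r1\t147\tchr1\t1201\t60\t10M\t=\t1101\t-110\t{seq10}\t{'J'*10}\tMD:Z:10\tNM:i:0"
        )
        recs = list(parse_sam(_write_sam(tmp_path, body), _annotation()))
        assert sorted(r.mate_flags for r in recs) == [(99, 147), (147, 99)]
        assert len(list(select_proper_pairs(recs))) == 2
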