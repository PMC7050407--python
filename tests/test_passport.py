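"""Tests for the reporter-assay pipeline: design, demux, UMIs, tests."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from asekit.passport import (
    AlleleIndex,
    OligoConstruct,
    _directional_clusters,
    assign_allele,
    call_consistent_hits,
    count_pipeline,
    dedup_count,
    demultiplex,
    design_library,
    detection_summary,
    extract_umi,
    run_cell_line,
)
from asekit.passport import test_snp_activity as snp_activity_test
from asekit.simulate import PassportDesign, generate_passport_reads

from test_simulate import small_manifest


class TestDesignLibrary:
    def test_two_constructs_per_snp_differing_at_center(self, rng):
        manifest = small_manifest(rng, 1, flank=15)
        lib, table = design_library(manifest, flank_len=15)
        assert len(lib) == 2
        a, b = lib[0].sequence, lib[1].sequence
        diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        assert diffs == [15]  # the centered variant base

    def test_insufficient_flank_names_the_snp(self, rng):
        manifest = small_manifest(rng, 2, flank=10)
        with pytest.raises(ValueError, match="rs0|rs1"):
            design_library(manifest, flank_len=25)

    def test_duplicate_inserts_rejected(self, rng):
        manifest = small_manifest(rng, 1, flank=12)
        dup = pd.concat(
            [manifest, manifest.assign(snp_id="rs_dup")], ignore_index=True
        )
        with pytest.raises(ValueError, match="duplicate insert"):
            design_library(dup, flank_len=12)


class TestDemultiplex:
    BC = {"AAAAAAAA": ("SH", 1, "DNA"), "CCCCCCCC": ("SH", 1, "RNA")}

    def test_exact_match_assigned(self):
        reads = [("r1", "AAAAAAAA" + "T" * 20)]
        by_cond, un = demultiplex(reads, self.BC)
        assert len(by_cond[("SH", 1, "DNA")]) == 1
        assert un == 0

    def test_two_mismatches_unassigned_at_zero_tolerance(self):
        reads = [("r1", "AATTAAAA" + "T" * 20)]
        by_cond, un = demultiplex(reads, self.BC, max_mismatch=0)
        assert un == 1

    def test_equidistant_tie_is_unassigned(self):
        bc = {"AAAAAAAA": ("SH", 1, "DNA"), "AAAAAAAT": ("SH", 1, "RNA")}
        reads = [("r1", "AAAAAAAG" + "T" * 20)]  # 1 mismatch from both
        by_cond, un = demultiplex(reads, bc, max_mismatch=1)
        assert un == 1

    def test_one_mismatch_assigned_within_tolerance(self):
        reads = [("r1", "AAAAAAAT" + "G" * 20)]
        bc = {"AAAAAAAA": ("SH", 1, "DNA"), "CCCCCCCC": ("SH", 1, "RNA")}
        by_cond, un = demultiplex(reads, bc, max_mismatch=1)
        assert len(by_cond[("SH", 1, "DNA")]) == 1

    def test_counts_conserved(self, rng):
        bases = np.array(list("ACGT"))
        reads = [
            (f"r{i}", "".join(bases[rng.integers(0, 4, 30)])) for i in range(200)
        ]
        by_cond, un = demultiplex(reads, self.BC)
        assert sum(len(v) for v in by_cond.values()) + un == 200


class TestExtractUmi:
    def test_umi_split_lengths(self):
        out, disc = extract_umi([("r", "A" * 10 + "C" * 65)], umi_len=10)
        (name, umi, insert), = out
        assert umi == "A" * 10 and len(insert) == 65
        assert disc == 0

    def test_read_no_longer_than_umi_discarded(self):
        out, disc = extract_umi([("r", "A" * 10)], umi_len=10)
        assert out == [] and disc == 1

    def test_n_containing_umi_retained(self):
        out, _ = extract_umi([("r", "ANANANANAN" + "C" * 20)], umi_len=10)
        assert out[0][1] == "ANANANANAN"


class TestAssignAllele:
    def make_library(self):
        return [
            OligoConstruct("rs1", "ref", "AAAA" + "C" + "GGGG", 4),
            OligoConstruct("rs1", "alt", "AAAA" + "T" + "GGGG", 4),
        ]

    def test_full_insert_assigned(self):
        idx = AlleleIndex(self.make_library())
        assigned, amb, unm = assign_allele([("r", "UMI", "AAAACGGGG")], idx)
        assert assigned == [("rs1", "ref", "UMI")]

    def test_flank_only_read_is_ambiguous(self):
        idx = AlleleIndex(self.make_library())
        assigned, amb, unm = assign_allele([("r", "UMI", "AAAA")], idx)
        assert (assigned, amb, unm) == ([], 1, 0)

    def test_variant_base_substitution_matches_other_allele(self):
        idx = AlleleIndex(self.make_library())
        assigned, *_ = assign_allele([("r", "UMI", "AAAATGGGG")], idx)
        assert assigned == [("rs1", "alt", "UMI")]

    def test_unrelated_read_unmapped(self):
        idx = AlleleIndex(self.make_library())
        assigned, amb, unm = assign_allele([("r", "UMI", "TTTTTTTTTTTT")], idx)
        assert (assigned, amb, unm) == ([], 0, 1)


def brute_force_directional(umis):
    """Reference implementation of the directional collapse over a multiset."""
    counts = Counter(umis)
    uniq = sorted(counts, key=lambda u: (-counts[u], u))
    parent = {u: u for u in uniq}

    def find(u):
        while parent[u] != u:
            u = parent[u]
        return u

    # repeatedly absorb any B into A when hamming==1 and count rule holds,
    # processing high-count UMIs first (same rule, independent traversal)
    absorbed = set()
    for a in uniq:
        if a in absorbed:
            continue
        frontier = [a]
        while frontier:
            cur = frontier.pop()
            for b in uniq:
                if b in absorbed or b == a or b == cur:
                    continue
                d = sum(x != y for x, y in zip(cur, b))
                if d == 1 and counts[cur] >= 2 * counts[b] - 1:
                    absorbed.add(b)
                    frontier.append(b)
    return len([u for u in uniq if u not in absorbed])


class TestDedup:
    def group(self, umis):
        return {
            ("SH", 1, "RNA"): [("rs1", "ref", u) for u in umis]
        }

    def test_unique_counts_distinct_strings(self):
        df = dedup_count(self.group(["AAA", "AAA", "AAT"]), method="unique")
        assert df["umi_count"].iloc[0] == 2
        assert df["read_count"].iloc[0] == 3

    def test_directional_collapses_error_neighbour(self):
        df = dedup_count(self.group(["AAA", "AAA", "AAT"]), method="directional")
        assert df["umi_count"].iloc[0] == 1

    def test_empty_group_absent(self):
        df = dedup_count({("SH", 1, "RNA"): []})
        assert df.empty

    def test_directional_matches_brute_force_on_random_multisets(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            n = int(rng.integers(1, 30))
            umis = [
                "".join(bases[rng.integers(0, 4, 3)]) for _ in range(n)
            ]
            got = _directional_clusters(Counter(umis))
            assert got == brute_force_directional(umis)

    def test_unique_matches_brute_force(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            umis = [
                "".join(bases[rng.integers(0, 4, 4)])
                for _ in range(int(rng.integers(0, 40)))
            ]
            df = dedup_count(self.group(umis), method="unique")
            expect = len(set(umis))
            got = 0 if df.empty else int(df["umi_count"].iloc[0])
            assert got == expect


def deterministic_counts(ratio_rna_alt=2.0, n_reps=6, base=100):
    rows = []
    for rep in range(1, n_reps + 1):
        for source in ("DNA", "RNA"):
            for allele in ("ref", "alt"):
                v = base
                if allele == "alt":
                    v = base if source == "DNA" else int(base * ratio_rna_alt)
                rows.append(
                    {
                        "snp_id": "rs1",
                        "allele": allele,
                        "cell_line": "SH",
                        "replicate": rep,
                        "source": source,
                        "umi_count": v,
                        "read_count": v,
                    }
                )
    return pd.DataFrame(rows)


class TestActivityTest:
    def test_identical_ratios_give_null_result(self):
        counts = deterministic_counts(ratio_rna_alt=1.0)
        res = snp_activity_test(counts, "rs1", "SH")
        assert abs(res.beta12) < 1e-6
        assert res.p_value > 0.5

    def test_exact_twofold_rna_shift_recovers_ln2(self):
        # noise-free counts: the saturated cell means force beta12 = ln 2
        counts = deterministic_counts(ratio_rna_alt=2.0)
        res = snp_activity_test(counts, "rs1", "SH")
        assert res.beta12 == pytest.approx(np.log(2.0), abs=1e-4)
        assert res.adj_log2_fc == pytest.approx(1.0, abs=2e-4)

    def test_undetected_snp_reports_no_test(self):
        counts = deterministic_counts()
        counts.loc[
            (counts["allele"] == "alt") & (counts["source"] == "RNA"), "umi_count"
        ] = 0
        res = snp_activity_test(counts, "rs1", "SH")
        assert not res.detected
        assert np.isnan(res.p_value)


class TestConsistency:
    def make_results(self, entries):
        # entries: snp -> (q_SH, beta_SH, q_SK, beta_SK)
        rows_sh, rows_sk = [], []
        for snp, (q1, b1, q2, b2) in entries.items():
            rows_sh.append(
                {"snp_id": snp, "cell_line": "SH", "beta12": b1, "q_value": q1}
            )
            rows_sk.append(
                {"snp_id": snp, "cell_line": "SK", "beta12": b2, "q_value": q2}
            )
        return {"SH": pd.DataFrame(rows_sh), "SK": pd.DataFrame(rows_sk)}

    def test_same_sign_hit_is_consistent(self):
        res = call_consistent_hits(
            self.make_results({"rs1": (0.01, 1.0, 0.02, 0.5)})
        )
        assert len(res) == 1 and bool(res["consistent"].iloc[0])

    def test_opposite_sign_hit_in_hits_but_inconsistent(self):
        res = call_consistent_hits(
            self.make_results({"rs1": (0.01, 1.0, 0.02, -0.5)})
        )
        assert len(res) == 1 and not bool(res["consistent"].iloc[0])

    def test_fixture_counts_four_hits_three_consistent(self):
        entries = {
            "rs1": (0.01, 1.0, 0.01, 1.0),
            "rs2": (0.01, -1.0, 0.01, -2.0),
            "rs3": (0.01, 1.0, 0.04, 0.3),
            "rs4": (0.02, 1.0, 0.04, -0.3),
            "rs5": (0.01, 1.0, 0.50, 1.0),   # not significant in SK
            "rs6": (0.80, 1.0, 0.01, 1.0),   # not significant in SH
        }
        res = call_consistent_hits(self.make_results(entries))
        assert len(res) == 4
        assert int(res["consistent"].sum()) == 3


class TestDetectionSummary:
    def counts_with(self, detected_snps, all_snps):
        rows = []
        for snp in all_snps:
            for cl in ("SH", "SK"):
                for allele in ("ref", "alt"):
                    v = 5 if snp in detected_snps else 0
                    if snp not in detected_snps and allele == "ref":
                        v = 5  # ref seen, alt missing -> undetected
                    rows.append(
                        {
                            "snp_id": snp,
                            "allele": allele,
                            "cell_line": cl,
                            "replicate": 1,
                            "source": "RNA",
                            "umi_count": v,
                            "read_count": v,
                        }
                    )
        return pd.DataFrame(rows)

    def test_none_detected_is_zero_percent(self):
        snps = [f"rs{i}" for i in range(4)]
        s = detection_summary(self.counts_with(set(), snps), snps)
        assert s["detection_rate_pct"] == 0.0

    def test_all_detected_is_hundred_percent(self):
        snps = [f"rs{i}" for i in range(4)]
        s = detection_summary(self.counts_with(set(snps), snps), snps)
        assert s["detection_rate_pct"] == 100.0


class TestEndToEnd:
    def test_round_trip_with_duplicates_recovers_truth_exactly(self, rng, tmp_path):
        manifest = small_manifest(rng, 4, flank=20)
        lib, _ = design_library(manifest, flank_len=20)
        design = PassportDesign(
            n_replicates=2, mean_molecules=40.0, duplication_rate=0.5
        )
        fq = tmp_path / "reads.fastq"
        barcode_map, truth = generate_passport_reads(
            lib, design, {}, seed=17, fastq_path=fq
        )
        counts, qc = count_pipeline(fq, barcode_map, lib, umi_len=10)
        merged = truth.merge(
            counts,
            on=["snp_id", "allele", "cell_line", "replicate", "source"],
            how="left",
        )
        merged["umi_count"] = merged["umi_count"].fillna(0).astype(int)
        assert (merged["umi_count"] == merged["n_molecules"]).all()
        assert (merged["read_count"].fillna(0) == merged["n_reads"]).all()
        # stage conservation
        assert (
            qc["n_assigned"]
            + qc["n_unassigned_barcode"]
            + qc["n_too_short"]
            + qc["n_ambiguous"]
            + qc["n_unmapped"]
            == qc["n_reads"]
        )


class TestMismatchTolerantAssignment:
    def make_library(self):
        return [
            OligoConstruct("rs1", "ref", "AAAA" + "C" + "GGGG", 4),
            OligoConstruct("rs1", "alt", "AAAA" + "T" + "GGGG", 4),
        ]

    def test_one_flank_error_recovered(self):
        idx = AlleleIndex(self.make_library(), max_mismatch=1)
        assigned, amb, unm = assign_allele([("r", "U", "TAAACGGGG")], idx)
        assert assigned == [("rs1", "ref", "U")]

    def test_variant_base_never_treated_as_error(self):
        # a mismatch at the variant base is a different allele, not an
        # error to forgive: "AAAAGGGGG" differs from both alleles there
        idx = AlleleIndex(self.make_library(), max_mismatch=1)
        assigned, amb, unm = assign_allele([("r", "U", "AAAAGGGGG")], idx)
        assert (assigned, amb, unm) == ([], 0, 1)

    def test_sequencing_errors_recovered_end_to_end(self, rng, tmp_path):
        manifest = small_manifest(rng, 3, flank=20)
        lib, _ = design_library(manifest, flank_len=20)
        design = PassportDesign(n_replicates=2, mean_molecules=30.0)
        fq = tmp_path / "noisy.fastq"
        barcode_map, truth = generate_passport_reads(
            lib, design, {}, seed=5, fastq_path=fq, error_rate=0.002
        )
        counts, qc = count_pipeline(
            fq, barcode_map, lib, umi_len=10, assign_mismatch=1
        )
        # nearly all reads recovered despite substitutions
        assert qc["n_assigned"] / qc["n_reads"] > 0.95
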