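"""Profile analytics: normalization, filters, R-squared, missing transcripts."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htsupersage import (
    BFAI,
    DPNII,
    NLAIII,
    TagCountProfile,
    Transcript,
    build_virtual_tag_index,
    filter_by_reference,
    filter_homopolymer,
    gene_expression_table,
    missing_transcript_analysis,
    normalize_tpm,
    pairwise_r2,
    profile_summary,
)
from htsupersage.profiles import longest_homopolymer_run

EXAMPLE_TAG = "CATGACAAGTTTTTGTTAATAATAAT"


def make_profile(counts, enzyme=NLAIII, sample="s"):
    return TagCountProfile(sample_id=sample, enzyme=enzyme, counts=dict(counts))


def random_tags(rng, n):
    return ["CATG" + "".join(rng.choice(list("ACGT"), size=22)) for _ in range(n)]


class TestProfileSummary:
    def test_counts(self):
        p = make_profile({"A" * 26: 1, "C" * 26: 5, "G" * 26: 1})
        assert profile_summary(p) == (7, 3, 1)

    def test_empty(self):
        assert profile_summary(make_profile({})) == (0, 0, 0)

    def test_against_recount_oracle(self):
        rng = np.random.default_rng(7)
        counts = {t: int(rng.integers(1, 50)) for t in random_tags(rng, 200)}
        total, unique, nonsingleton = profile_summary(make_profile(counts))
        assert total == sum(counts.values())
        assert unique == len(counts)
        assert nonsingleton == len([c for c in counts.values() if c > 1])


class TestNormalizeTpm:
    def test_single_tag_gets_full_scale(self):
        p = normalize_tpm(make_profile({EXAMPLE_TAG: 10}))
        assert p.normalized == {EXAMPLE_TAG: 1_000_000.0}

    def test_proportions(self):
        p = normalize_tpm(make_profile({"A" * 26: 1, "C" * 26: 3}))
        assert p.normalized == {"A" * 26: 250_000.0, "C" * 26: 750_000.0}

    def test_formula_and_sum_invariant(self):
        rng = np.random.default_rng(11)
        counts = {t: int(rng.integers(1, 100)) for t in random_tags(rng, 300)}
        p = normalize_tpm(make_profile(counts))
        total = sum(counts.values())
        for tag, c in counts.items():
            assert p.normalized[tag] == pytest.approx(c * 1e6 / total)
        assert sum(p.normalized.values()) == pytest.approx(1e6, rel=1e-6)
        # relative order conserved
        order = sorted(counts, key=counts.get)
        tpms = [p.normalized[t] for t in order]
        assert tpms == sorted(tpms)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            normalize_tpm(make_profile({}))


class TestHomopolymerFilter:
    def test_run_of_five_retained(self):
        p = make_profile({EXAMPLE_TAG: 3})
        retained, removed = filter_homopolymer(p, max_run=5)
        assert EXAMPLE_TAG in retained.counts
        assert removed == []

    def test_run_of_six_removed(self):
        bad = "CATGAAAAAACCCCCCCCCCCCCCCC"
        retained, removed = filter_homopolymer(make_profile({bad: 1, EXAMPLE_TAG: 1}))
        assert removed == [bad]
        assert set(retained.counts) == {EXAMPLE_TAG}

    def test_partition_matches_regex_oracle(self):
        rng = np.random.default_rng(3)
        tags = random_tags(rng, 300) + ["CATG" + "T" * 22, "CATG" + "AC" * 11]
        p = make_profile({t: 1 for t in tags})
        retained, removed = filter_homopolymer(p, max_run=5)
        oracle_removed = {
            t
            for t in p.counts
            if max(len(m.group(0)) for m in re.finditer(r"(.)\1*", t)) > 5
        }
        assert set(removed) == oracle_removed
        assert set(retained.counts) | set(removed) == set(p.counts)
        assert not set(retained.counts) & set(removed)

    def test_longest_run_helper(self):
        assert longest_homopolymer_run("") == 0
        assert longest_homopolymer_run("ACGT") == 1
        assert longest_homopolymer_run("AATTTTG") == 4


class TestReferenceFilter:
    def test_virtual_tag_retained_both_modes(self):
        tr = Transcript("g1", "GGG" + EXAMPLE_TAG + "A" * 10)
        index = build_virtual_tag_index([tr], NLAIII)
        p = make_profile({EXAMPLE_TAG: 5})
        for ref, mode in [([tr], "substring"), (index, "virtual_index")]:
            retained, removed = filter_by_reference(p, ref, mode=mode)
            assert EXAMPLE_TAG in retained.counts and removed == []

    def test_reverse_strand_substring_match(self):
        from htsupersage import reverse_complement

        tr = Transcript("g1", reverse_complement(EXAMPLE_TAG) + "GGG")
        retained, _ = filter_by_reference(
            make_profile({EXAMPLE_TAG: 1}), [tr], mode="substring"
        )
        assert EXAMPLE_TAG in retained.counts

    def test_foreign_tag_removed(self):
        rng = np.random.default_rng(5)
        trs = [
            Transcript(f"g{i}", "".join(rng.choice(list("ACGT"), size=120)))
            for i in range(10)
        ]
        foreign = "CATG" + "".join(rng.choice(list("ACGT"), size=22))
        _, removed = filter_by_reference(
            make_profile({foreign: 1}), trs, mode="substring"
        )
        assert removed == [foreign]

    def test_error_free_library_fully_retained(self, toy_transcriptome):
        from htsupersage import LibrarySpec, demultiplex_fastq, load_barcode_table, simulate_library

        transcripts, _, weights = toy_transcriptome
        spec = LibrarySpec("s", "GCCC", NLAIII, n_reads=2000, seed=9)
        reads, _ = simulate_library(spec, transcripts, weights)
        table = load_barcode_table([("s", "GCCC", "NlaIII")])
        profiles, _ = demultiplex_fastq(reads, table)
        retained, removed = filter_by_reference(
            profiles["s"], transcripts, mode="substring"
        )
        assert removed == []
        assert retained.counts == profiles["s"].counts


class TestPairwiseR2:
    def test_self_comparison(self):
        p = make_profile({"A" * 26: 1, "C" * 26: 5, "G" * 26: 2})
        assert pairwise_r2(p, p).r2 == pytest.approx(1.0)

    def test_scaling_invariance(self):
        p = make_profile({"A" * 26: 1, "C" * 26: 5, "G" * 26: 2})
        q = make_profile({t: 2 * c for t, c in p.counts.items()})
        res = pairwise_r2(p, q)
        assert res.r2 == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)

    def test_anticorrelation_reported_with_sign(self):
        a = make_profile({"A" * 26: 1, "C" * 26: 2, "G" * 26: 3})
        b = make_profile({"A" * 26: 3, "C" * 26: 2, "G" * 26: 1})
        res = pairwise_r2(a, b)
        assert res.r2 == pytest.approx(1.0)
        assert res.r == pytest.approx(-1.0)

    def test_union_with_zero_fill_hand_check(self):
        a = make_profile({"A" * 26: 4, "C" * 26: 2})
        b = make_profile({"A" * 26: 4, "G" * 26: 6})
        res = pairwise_r2(a, b)
        x, y = np.array([4.0, 2.0, 0.0]), np.array([4.0, 0.0, 6.0])
        r_hand = np.corrcoef(x, y)[0, 1]
        assert res.r == pytest.approx(r_hand)
        assert res.n_tags == 3

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        tags = random_tags(rng, 50)
        a = make_profile({t: int(rng.integers(0, 20)) + 1 for t in tags[:40]})
        b = make_profile({t: int(rng.integers(0, 20)) + 1 for t in tags[10:]})
        assert pairwise_r2(a, b).r2 == pytest.approx(pairwise_r2(b, a).r2)

    def test_log_scale(self):
        a = make_profile({"A" * 26: 9, "C" * 26: 99, "G" * 26: 999})
        b = make_profile({"A" * 26: 99, "C" * 26: 999, "G" * 26: 9999})
        assert pairwise_r2(a, b, scale="log10p1").r2 == pytest.approx(1.0, abs=1e-3)

    def test_zero_variance_rejected(self):
        a = make_profile({"A" * 26: 1, "C" * 26: 1})
        b = make_profile({"A" * 26: 1, "C" * 26: 2})
        with pytest.raises(ValueError, match="zero-variance"):
            pairwise_r2(a, b)


def _three_enzyme_fixture():
    """Three genes: g1 has all sites, g2 lacks DpnII, g3 lacks BfaI."""
    rng = np.random.default_rng(23)
    fill = lambda n: "".join(rng.choice(list("AC"), size=n))
    g1 = Transcript("g1", "GATC" + fill(30) + "CTAG" + fill(30) + "CATG" + fill(30))
    g2 = Transcript("g2", "CTAG" + fill(30) + "CATG" + fill(30))
    g3 = Transcript("g3", "GATC" + fill(30) + "CATG" + fill(30))
    trs = [g1, g2, g3]
    indexes = [build_virtual_tag_index(trs, e) for e in (NLAIII, DPNII, BFAI)]
    return trs, indexes


class TestGeneExpressionTable:
    def test_tpm_mapped_and_absent_site_zero(self):
        trs, indexes = _three_enzyme_fixture()
        profiles = []
        for enz, ix in zip((NLAIII, DPNII, BFAI), indexes):
            counts = {tag: 10 for tag in ix.entries}
            profiles.append(
                normalize_tpm(
                    TagCountProfile(f"s_{enz.name}", enz, counts)
                )
            )
        table = gene_expression_table(profiles, indexes)
        df = table.table
        assert df.loc["g2", "DpnII"] == 0.0
        assert df.loc["g2", "NlaIII"] > 0
        # abundance is the arithmetic mean with zeros included
        for g in df.index:
            assert df.loc[g, "abundance"] == pytest.approx(
                np.mean([df.loc[g, e] for e in table.enzymes])
            )

    def test_enzyme_mismatch_rejected(self):
        trs, indexes = _three_enzyme_fixture()
        p = normalize_tpm(
            TagCountProfile("s", NLAIII, {t: 1 for t in indexes[0].entries})
        )
        with pytest.raises(ValueError, match="does not match"):
            gene_expression_table([p], [indexes[1]])

    def test_unnormalized_profile_rejected(self):
        trs, indexes = _three_enzyme_fixture()
        p = TagCountProfile("s", NLAIII, {t: 1 for t in indexes[0].entries})
        with pytest.raises(ValueError, match="not normalized"):
            gene_expression_table([p], [indexes[0]])


def _table_from_tpm(rows):
    """Build a GeneEnzymeTable directly from {gene: (nla, dpn, bfa)} TPMs."""
    from htsupersage.profiles import GeneEnzymeTable

    enzymes = ["NlaIII", "DpnII", "BfaI"]
    df = pd.DataFrame(
        {e: [rows[g][i] for g in sorted(rows)] for i, e in enumerate(enzymes)},
        index=pd.Index(sorted(rows), name="gene_id"),
        dtype=float,
    )
    df["abundance"] = df[enzymes].mean(axis=1)
    return GeneEnzymeTable(table=df, enzymes=enzymes)


class TestMissingTranscriptAnalysis:
    def test_single_enzyme_dropout(self):
        table = _table_from_tpm({"g1": (90, 90, 0), "g2": (50, 50, 50)})
        report = missing_transcript_analysis(table, top_n=2, threshold=0.1)
        assert report.missing_counts == {"NlaIII": 0, "DpnII": 0, "BfaI": 1}
        assert bool(report.flags.loc["g1", "BfaI"])

    def test_balanced_gene_never_missing(self):
        table = _table_from_tpm({"g1": (40, 40, 40)})
        report = missing_transcript_analysis(table, top_n=1)
        assert sum(report.missing_counts.values()) == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(31)
        rows = {
            f"g{i}": tuple(rng.integers(0, 200, size=3)) for i in range(100)
        }
        table = _table_from_tpm(rows)
        previous = None
        for threshold in (0.02, 0.1, 0.3, 0.8):
            counts = missing_transcript_analysis(
                table, top_n=50, threshold=threshold
            ).missing_counts
            if previous is not None:
                assert all(counts[e] >= previous[e] for e in counts)
            previous = counts

    def test_top_n_exceeding_genes_rejected(self):
        table = _table_from_tpm({"g1": (1, 1, 1)})
        with pytest.raises(ValueError):
            missing_transcript_analysis(table, top_n=5)

    def test_zero_abundance_excluded_and_ties_deterministic(self):
        table = _table_from_tpm(
            {"g1": (0, 0, 0), "g2": (10, 10, 10), "g3": (10, 10, 10), "g4": (5, 5, 5)}
        )
        report = missing_transcript_analysis(table, top_n=3)
        assert list(report.flags.index) == ["g2", "g3", "g4"]
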