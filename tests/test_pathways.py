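import itertools

import numpy as np
import pandas as pd
import pytest

from oxiseq import ValidationError, hypergeometric_ora, make_report_fixture, tabulate_membership
from oxiseq.io import GeneSet, GeneSetCollection


def collection(**sets) -> GeneSetCollection:
    return GeneSetCollection(
        {name: GeneSet(name, "", frozenset(members)) for name, members in sets.items()}
    )


def results_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_symbol", "enrichment", "de_log2fc", "de_padj"],
    )


class TestMembership:
    def test_one_row_per_pathway_transcript_pair(self):
        res = results_frame(
            [
                ("tx1", "KAT5", 4.4, 6.7, 0.0048),
                ("tx2", "BRCA1", 7.8, 4.4, 0.1271),
                ("tx3", "XYZ", 1.0, 0.1, 0.9),
            ]
        )
        gsc = collection(A={"KAT5", "BRCA1"}, B={"KAT5"})
        out = tabulate_membership(res, gsc)
        # tx1 in both pathways -> 2 rows; tx2 in A; tx3 nowhere
        assert len(out) == 3
        assert (out[out.transcript_id == "tx1"]["pathway"].tolist()) == ["A", "B"]
        assert out.loc[out.transcript_id == "tx1", "de_significant"].all()
        assert not out.loc[out.transcript_id == "tx2", "de_significant"].any()

    def test_no_row_loss_across_pathways(self):
        rng = np.random.default_rng(0)
        symbols = [f"G{i}" for i in range(30)]
        res = results_frame(
            [(f"tx{i}", s, rng.normal(), rng.normal(), rng.uniform()) for i, s in enumerate(symbols)]
        )
        gsc = collection(A=set(symbols[:10]), B=set(symbols[5:20]), C=set(symbols[25:]))
        out = tabulate_membership(res, gsc)
        expected_pairs = sum(
            s in gsc[name].members for name in gsc.names() for s in symbols
        )
        assert len(out) == expected_pairs

    def test_empty_collection_rejected(self):
        with pytest.raises(ValidationError):
            tabulate_membership(results_frame([("t", "G", 1, 1, 0.5)]), GeneSetCollection({}))

    def test_missing_columns_rejected(self):
        df = pd.DataFrame({"transcript_id": ["t"], "gene_symbol": ["G"]})
        with pytest.raises(ValidationError, match="missing columns"):
            tabulate_membership(df, collection(A={"G"}))


class TestPackagedReportTable:
    """Worked examples against the packaged two-pathway report fixture."""

    @pytest.fixture(scope="class")
    @staticmethod
    def fixture():
        return make_report_fixture()

    def test_table_has_two_sections_of_21_and_10_rows(self, fixture):
        counts = fixture["table"]["pathway"].value_counts()
        assert counts["Chromatin modifying enzymes"] == 21
        assert counts["DNA damage response, signal transduction by p53 class mediator"] == 10

    def test_chromatin_membership_rows_and_significance(self, fixture):
        out = tabulate_membership(fixture["results"], fixture["genesets"], alpha_de=0.05)
        chrom = out[out.pathway == "Chromatin modifying enzymes"]
        assert len(chrom) == 21
        assert int(chrom["de_significant"].sum()) == 13

    def test_dna_damage_significant_rows(self, fixture):
        out = tabulate_membership(fixture["results"], fixture["genesets"], alpha_de=0.05)
        dna = out[out.pathway != "Chromatin modifying enzymes"]
        assert len(dna) == 10
        assert int(dna["de_significant"].sum()) == 4

    def test_exactly_one_transcript_in_both_pathways(self, fixture):
        out = tabulate_membership(fixture["results"], fixture["genesets"])
        per_tx = out.groupby("transcript_id")["pathway"].nunique()
        both = per_tx[per_tx == 2]
        assert len(both) == 1
        assert both.index[0] == "ENST00000534650"  # the shared KAT5 transcript

    def test_censored_padj_parsed_to_printed_bound(self, fixture):
        table = fixture["table"]
        censored = table[table["de_padj_printed"].str.startswith("<")]
        assert len(censored) == 3
        assert (censored["de_padj"] == 1e-4).all()


class TestOra:
    def test_set_equal_to_universe_has_p_one(self):
        out = hypergeometric_ora({"a"}, collection(S={"a", "b", "c"}), {"a", "b", "c"})
        assert out.loc["S", "p"] == pytest.approx(1.0)

    def test_hand_counted_tail(self):
        # universe 10, set 5, hits 3, overlap 3: C(5,3)/C(10,3) = 10/120
        universe = {f"g{i}" for i in range(10)}
        members = {f"g{i}" for i in range(5)}
        hits = {"g0", "g1", "g2"}
        out = hypergeometric_ora(hits, collection(S=members), universe)
        assert out.loc["S", "p"] == pytest.approx(10 / 120)

    def test_zero_overlap_has_p_one(self):
        out = hypergeometric_ora({"x"}, collection(S={"a", "b"}), {"a", "b", "x"})
        assert out.loc["S", "p"] == pytest.approx(1.0)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            hypergeometric_ora({"zz"}, collection(S={"a"}), {"a"})

    def test_relabeling_invariance(self):
        universe = {f"g{i}" for i in range(8)}
        members = {"g0", "g1", "g2"}
        hits = {"g1", "g2", "g5"}
        p1 = hypergeometric_ora(hits, collection(S=members), universe).loc["S", "p"]
        relabel = {f"g{i}": f"h{7 - i}" for i in range(8)}
        p2 = hypergeometric_ora(
            {relabel[h] for h in hits},
            collection(S={relabel[m] for m in members}),
            {relabel[u] for u in universe},
        ).loc["S", "p"]
        assert p1 == pytest.approx(p2)

    def test_padj_bh_across_sets(self):
        universe = {f"g{i}" for i in range(12)}
        gsc = collection(A={"g0", "g1"}, B={"g0", "g1", "g2", "g3"}, C={"g9"})
        out = hypergeometric_ora({"g0", "g1", "g2"}, gsc, universe)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        assert (out["p_adj"] <= 1.0 + 1e-12).all()


def enumeration_tail(m: int, k_set: int, n_hits: int, overlap: int) -> float:
    """Oracle: P(|draw ∩ set| >= overlap) by enumerating all C(m, n) draws."""
    members = set(range(k_set))
    total = 0
    ge = 0
    for draw in itertools.combinations(range(m), n_hits):
        total += 1
        if len(members.intersection(draw)) >= overlap:
            ge += 1
    return ge / total if total else 1.0


def test_ora_matches_exhaustive_enumeration_on_small_universes():
    """Oracle sweep over every (universe, set, hits, overlap) config, m <= 8."""
    for m in range(1, 9):
        universe = {f"u{i}" for i in range(m)}
        for n_hits in range(0, m + 1):
            for k_set in range(1, m + 1):
                lo = max(0, n_hits - (m - k_set))
                hi = min(k_set, n_hits)
                sets = {}
                expected = {}
                for ov in range(lo, hi + 1):
                    # build a set realizing exactly this overlap with the hits
                    name = f"K{k_set}ov{ov}"
                    members = {f"u{i}" for i in range(ov)} | {
                        f"u{m - 1 - i}" for i in range(k_set - ov)
                    }
                    assert len(members) == k_set
                    sets[name] = members
                    expected[name] = enumeration_tail(m, k_set, n_hits, ov)
                if not sets:
                    continue
                hits = {f"u{i}" for i in range(n_hits)}
                out = hypergeometric_ora(hits, collection(**sets), universe)
                for name, exp in expected.items():
                    assert out.loc[name, "p"] == pytest.approx(exp, abs=1e-12), (
                        m,
                        k_set,
                        n_hits,
                        name,
                    )
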