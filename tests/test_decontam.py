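"""Contaminant rule, taxon removal, Z gate and cross-contamination review."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aerocore as ac
from aerocore.decontam import _wells_adjacent
from aerocore.tables import make_taxa_frame


def tiny_table(neg_counts: dict[str, list[int]], air_counts=None):
    """Build a table from per-taxon negative (and optional air) count lists."""
    taxids = sorted(neg_counts)
    n_neg = len(next(iter(neg_counts.values())))
    n_air = len(next(iter(air_counts.values()))) if air_counts else 0
    samples = [f"NEG{i}" for i in range(n_neg)] + [f"AIR{i}" for i in range(n_air)]
    rows = []
    for i in range(n_neg):
        rows.append([neg_counts[t][i] for t in taxids])
    for i in range(n_air):
        rows.append([air_counts[t][i] for t in taxids])
    taxa = make_taxa_frame([(t, f"sp{t}", "species", "Bacteria") for t in taxids])
    return (
        ac.TaxonCountTable(pd.DataFrame(rows, index=samples, columns=taxids), taxa),
        [f"NEG{i}" for i in range(n_neg)],
    )


class TestIdentifyContaminants:
    def test_rule_boundaries(self):
        # (6000, 5000, 0): 2 negatives, total 11000 -> contaminant
        # (10000, 0, 0): 1 negative -> no; (5000, 5000, 0): total == 10000 -> no
        table, neg = tiny_table(
            {1: [6000, 5000, 0], 2: [10000, 0, 0], 3: [5000, 5000, 0]}
        )
        ev = ac.identify_contaminants(table, neg)
        assert ev.loc[1, "is_contaminant"]
        assert not ev.loc[2, "is_contaminant"]
        assert not ev.loc[3, "is_contaminant"]
        assert ev.loc[1, "n_negatives_present"] == 2
        assert ev.loc[1, "total_negative_reads"] == 11000

    def test_fewer_than_two_negatives_is_an_error(self):
        table, neg = tiny_table({1: [5, 5]})
        with pytest.raises(ac.TableError, match="negative"):
            ac.identify_contaminants(table, neg[:1])

    def test_matches_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 9000, size=(6, 50))
        taxids = list(range(1, 51))
        taxa = make_taxa_frame([(t, f"sp{t}", "species", "Bacteria") for t in taxids])
        table = ac.TaxonCountTable(
            pd.DataFrame(counts, index=[f"N{i}" for i in range(6)], columns=taxids),
            taxa,
        )
        ev = ac.identify_contaminants(table, table.sample_ids)
        for t in taxids:
            col = counts[:, t - 1]
            expect = (col > 0).sum() >= 2 and col.sum() > 10_000
            assert ev.loc[t, "is_contaminant"] == expect


class TestRemoveTaxa:
    def test_empty_set_is_identity(self, small_survey):
        table, _, _ = small_survey
        cleaned, summary = ac.remove_taxa(table, set())
        assert cleaned == table
        assert (summary["removed_fraction"] == 0).all()

    def test_remove_all_gives_fraction_one(self, small_survey):
        table, _, _ = small_survey
        cleaned, summary = ac.remove_taxa(table, set(table.taxids))
        assert cleaned.n_taxa == 0
        assert (summary["removed_fraction"] == 1.0).all()

    def test_read_conservation_exact(self, small_pipeline):
        p = small_pipeline
        before = p.filtered.sample_totals()
        after = p.cleaned.sample_totals()
        assert ((after + p.removal_summary["removed_reads"]) == before).all()

    def test_reported_fraction_matches_truth_tally(self, pipeline):
        # contaminant read fraction per air sample equals the truth-label tally
        p = pipeline
        _, raw_summary = ac.remove_taxa(p.table, p.truth.contaminant_taxids)
        for sid in p.air_ids[:20]:
            assert raw_summary.at[sid, "removed_fraction"] == pytest.approx(
                p.truth.contaminant_fraction[sid]
            )

    def test_kingdom_split_sums_to_total_fraction(self, small_pipeline):
        p = small_pipeline
        _, summary = ac.remove_taxa(p.table, p.contaminants)
        split = sum(
            summary[f"removed_frac_{k.lower()}"] for k in ("archaea", "bacteria", "fungi", "virus", "other")
        )
        assert np.allclose(split, summary["removed_fraction"])


class TestPrevalenceZTest:
    def test_hand_computed_example(self):
        # p1=0.9, p2=0.5, pooled=5/6: z = 0.4 / sqrt(5/6*1/6*(1/100+1/20))
        res = ac.prevalence_z_test(90, 100, 10, 20)
        assert res.pooled_p == pytest.approx(0.83333, abs=1e-4)
        assert res.z == pytest.approx(4.3818, abs=1e-4)
        assert res.passes

    def test_equal_proportions_degenerate(self):
        res = ac.prevalence_z_test(5, 10, 5, 10)
        assert res.z == 0.0 and not res.passes and res.flag == "degenerate"

    def test_wrong_direction_fails(self):
        res = ac.prevalence_z_test(5, 100, 18, 20)
        assert res.z < 0 and not res.passes

    def test_absent_from_negatives_trivially_greater(self):
        res = ac.prevalence_z_test(100, 100, 0, 20)
        assert res.passes and res.flag == "trivially_greater"
        weak = ac.prevalence_z_test(3, 100, 0, 20)
        assert weak.passes and weak.flag == "trivially_greater"

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.proportion import proportions_ztest

        cases = [(90, 100, 10, 20), (40, 80, 5, 19), (7, 30, 2, 21)]
        for x1, n1, x2, n2 in cases:
            res = ac.prevalence_z_test(x1, n1, x2, n2)
            z, p = proportions_ztest([x1, x2], [n1, n2], alternative="larger")
            assert res.z == pytest.approx(z, abs=1e-12)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    @given(
        n1=st.integers(2, 60),
        n2=st.integers(2, 60),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_antisymmetric_under_group_swap(self, n1, n2, data):
        x1 = data.draw(st.integers(0, n1))
        x2 = data.draw(st.integers(0, n2))
        a = ac.prevalence_z_test(x1, n1, x2, n2)
        b = ac.prevalence_z_test(x2, n2, x1, n1)
        assert a.z == pytest.approx(-b.z, abs=1e-12)

    def test_closed_form_formula_to_1e12(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n1, n2 = rng.integers(2, 200, size=2)
            x1, x2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            res = ac.prevalence_z_test(int(x1), int(n1), int(x2), int(n2))
            p1, p2 = x1 / n1, x2 / n2
            pooled = (x1 + x2) / (n1 + n2)
            if pooled in (0.0, 1.0) or p1 == p2:
                continue
            expect = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            assert res.z == pytest.approx(expect, abs=1e-12)


class TestCrossContamination:
    def _embedding_and_meta(self, foreign_dna_bd, foreign_adjacent):
        rng = np.random.default_rng(2)
        coords, rows = [], []
        for i in range(12):  # tight Oslo cluster
            coords.append([rng.normal(0, 0.1), rng.normal(0, 0.1)])
            rows.append(("O%d" % i, "Oslo", f"P1:A{i % 12 + 1}"))
        for i in range(12):  # tight Bergen cluster
            coords.append([rng.normal(10, 0.1), rng.normal(0, 0.1)])
            rows.append(("B%d" % i, "Bergen", f"P1:C{i % 12 + 1}"))
        # suspect: labelled Oslo but embedded inside Bergen
        coords.append([10.05, 0.0])
        rows.append(("SUSPECT", "Oslo", "P1:B3" if foreign_adjacent else "P2:H12"))
        records = [
            ac.SampleRecord(
                sample_id=sid,
                city=city,
                year=2018,
                sample_type="air",
                dna_conc=None if (sid == "SUSPECT" and foreign_dna_bd) else 0.5,
                dna_below_detection=sid == "SUSPECT" and foreign_dna_bd,
                plate_position=well,
            )
            for sid, city, well in rows
        ]
        embedding = pd.DataFrame(
            coords, index=[r.sample_id for r in records], columns=["x", "y"]
        )
        return embedding, records

    def test_sample_within_own_city_not_flagged(self):
        embedding, records = self._embedding_and_meta(False, False)
        flags = ac.flag_cross_contamination(embedding.drop("SUSPECT"), records, k=5)
        assert flags == []

    def test_candidate_with_measurable_dna_is_retained(self):
        embedding, records = self._embedding_and_meta(False, True)
        [flag] = ac.flag_cross_contamination(embedding, records, k=5)
        assert flag.sample_id == "SUSPECT"
        assert flag.embedded_neighbor_city == "Bergen"
        assert flag.verdict == "retain"

    def test_both_metadata_confirmations_exclude(self):
        embedding, records = self._embedding_and_meta(True, True)
        [flag] = ac.flag_cross_contamination(embedding, records, k=5)
        assert flag.dna_below_detection and flag.plate_adjacent_to_neighbor_city
        assert flag.verdict == "exclude"

    def test_well_adjacency_is_chebyshev_one_on_same_plate(self):
        assert _wells_adjacent("P1:B3", "P1:B4")
        assert _wells_adjacent("P1:B3", "P1:C4")
        assert not _wells_adjacent("P1:B3", "P1:B5")
        assert not _wells_adjacent("P1:B3", "P2:B4")
        assert not _wells_adjacent("P1:B3", "P1:B3")
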