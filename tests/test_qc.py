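import math

import numpy as np
import pytest

from conftest import make_record
from voxelprot import qc
from voxelprot.catalog import METHYL_SHIFT
from voxelprot.digest import CleavageRule
from voxelprot.errors import InvalidArgumentError, UndefinedRatioError
from voxelprot.synthetic import ModChannel, SimulationConfig, generate_peptide_table


def binom_3sigma(p, n):
    return 3 * math.sqrt(p * (1 - p) / n)


class TestSemiTryptic:
    def test_two_semi_of_eighty(self):
        recs = [
            make_record(f"AEPTID{a}{b}R", prev="K", nxt="A")
            for a in "ACDEFGHILM"
            for b in "ACDEFGHILM"
        ][:78]
        recs += [
            make_record("TIDESAK", prev="W", nxt="A"),  # N-term non-conforming
            make_record("ATIDEW", prev="K", nxt="L"),  # C-term non-conforming
        ]
        assert qc.semi_tryptic_fraction(recs, per_voxel=False) == pytest.approx(2 / 80)

    def test_no_semi_gives_zero(self):
        recs = [make_record("AEPTIDEK", prev="K", nxt="A")]
        assert qc.semi_tryptic_fraction(recs, per_voxel=False) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            qc.semi_tryptic_fraction([])

    def test_recovery_from_generator(self, proteome):
        cfg = SimulationConfig(seed=11, p_semi=0.02)
        records, _ = generate_peptide_table(cfg, proteome)
        est = qc.semi_tryptic_fraction(records, per_voxel=False)
        assert abs(est - 0.02) < binom_3sigma(0.02, cfg.n_peptides)


class TestMiscleavage:
    def test_one_of_four(self):
        recs = [
            make_record("IAVAQYSDDVKVESR", prev="K", nxt="A"),  # internal K
            make_record("PEPTIDER", prev="K", nxt="A"),
            make_record("AEDTIDEK", prev="R", nxt="A"),
            make_record("WEDTIDER", prev="R", nxt="A"),
        ]
        assert qc.miscleavage_fraction(recs, per_voxel=False) == pytest.approx(0.25)

    def test_internal_k_before_p_not_a_site(self):
        recs = [make_record("IAVAQYSDDVKPESR", prev="K", nxt="A")]
        assert qc.miscleavage_fraction(recs, per_voxel=False) == 0.0

    def test_recovery_from_generator(self, proteome):
        cfg = SimulationConfig(seed=3, p_misclv=0.12, p_methyl_K=0.0)
        records, _ = generate_peptide_table(cfg, proteome)
        est = qc.miscleavage_fraction(records, per_voxel=False)
        assert abs(est - 0.12) < binom_3sigma(0.12, cfg.n_peptides)


class TestKRRatio:
    def test_c_term_counting(self):
        seqs = ["AAK", "CCK", "DDR", "EER", "FFR", "GGR"]
        prevs = ["K", "R", "K", "R", "K", "R"]
        recs = [make_record(s, prev=p, nxt="A") for s, p in zip(seqs, prevs)]
        c, up = qc.kr_cleavage_ratio(recs)
        assert c == pytest.approx(0.5)  # arginine cleavage twice preferred
        assert up == pytest.approx(1.0)

    def test_symmetric_input_gives_one(self):
        recs = [
            make_record("AAK", prev="K", nxt="A"),
            make_record("CCR", prev="R", nxt="A"),
        ]
        c, up = qc.kr_cleavage_ratio(recs)
        assert c == 1.0 and up == 1.0

    def test_undefined_upstream(self):
        recs = [make_record("AAK", prev="-", nxt="A"), make_record("CCR", prev="-", nxt="A")]
        with pytest.raises(UndefinedRatioError) as exc:
            qc.kr_cleavage_ratio(recs)
        assert "upstream" in str(exc.value)

    def test_protein_terminal_peptides_excluded(self):
        recs = [
            make_record("AAK", prev="K", nxt="-"),  # protein C-term: not counted at C
            make_record("CCK", prev="K", nxt="A"),
            make_record("DDR", prev="R", nxt="A"),
        ]
        c, _ = qc.kr_cleavage_ratio(recs)
        assert c == 1.0


class TestMassShiftTable:
    def test_six_percent_oxidation(self):
        recs = [make_record(f"A{a}{b}PDEK", prev="K", nxt="A") for a in "ACDEFGHILM" for b in "ACDEFGHILM"]
        recs = recs[:94] + [
            make_record(f"AM{b}PDEK", prev="R", nxt="A", mods=[(4, 15.9949)]) for b in "ACDEFG"
        ]
        table = qc.mass_shift_table(recs)
        assert len(recs) == 100
        row = table[table["name"] == "oxidation/hydroxylation"].iloc[0]
        assert row["percent"] == pytest.approx(6.0)

    def test_all_excluded_gives_empty(self):
        recs = [make_record("PEPTIDEK", mods=[(1, 57.0215)])]
        table = qc.mass_shift_table(recs)
        assert table.empty

    def test_peptide_counts_once_per_distinct_shift(self):
        recs = [make_record("PMPTIDEK", mods=[(1, 15.9949), (3, 15.9950)])]
        table = qc.mass_shift_table(recs)
        assert table["percent"].tolist() == [100.0]

    def test_frequency_recovery(self, proteome):
        channels = (
            ModChannel(14.015650, 0.03, (("K", 1.0),)),
            ModChannel(15.994915, 0.06, (("P", 3.0), ("M", 1.0))),
        )
        cfg = SimulationConfig(seed=5, mod_channels=channels, p_methyl_K=0.0)
        records, _ = generate_peptide_table(cfg, proteome)
        table = qc.mass_shift_table(records).set_index("name")["percent"]
        n = cfg.n_peptides
        assert abs(table["methylation"] / 100 - 0.03) < binom_3sigma(0.03, n)
        assert abs(table["oxidation/hydroxylation"] / 100 - 0.06) < binom_3sigma(0.06, n)


class TestResidueDistribution:
    def test_all_on_lysine(self):
        recs = [make_record("PEPTIDEK", mods=[(8, 14.0157)]) for _ in range(3)]
        dist = qc.residue_distribution(recs, 14.0157)
        assert dist.to_dict() == {"K": 100.0}

    def test_even_split(self):
        recs = [
            make_record("PEPTIDEK", mods=[(1, 15.9949)]),
            make_record("AEPTIDEK", voxel=2, mods=[(8, 15.9949)]),
        ]
        dist = qc.residue_distribution(recs, 15.9949)
        assert dist.to_dict() == {"K": 50.0, "P": 50.0}

    def test_absent_shift_warns_empty(self):
        recs = [make_record("PEPTIDEK")]
        with pytest.warns(UserWarning):
            dist = qc.residue_distribution(recs, 14.0157)
        assert dist.empty

    def test_preference_recovery_three_to_one(self, proteome):
        channels = (ModChannel(15.994915, 0.5, (("P", 3.0), ("M", 1.0))),)
        cfg = SimulationConfig(seed=9, mod_channels=channels, p_methyl_K=0.0)
        records, _ = generate_peptide_table(cfg, proteome)
        dist = qc.residue_distribution(records, 15.9949)
        n_carrying = round(0.5 * cfg.n_peptides)
        assert abs(dist["P"] / 100 - 0.75) < binom_3sigma(0.75, n_carrying)


class TestStratification:
    def test_worked_counts(self):
        recs = (
            [make_record(f"PEPT{a}DEK", prev="K", nxt="A") for a in "ACDEFGH"]  # 7 tryptic unmod
            + [make_record("PEPTIWEK", mods=[(1, 15.9949)])]
            + [make_record("PEKTIDER", prev="K", nxt="A")]  # miscleaved unmod
            + [make_record("PEKTIDEW", prev="K", nxt="A", mods=[(3, METHYL_SHIFT)])]
        )
        strata, cond = qc.miscleavage_modification_stratification(recs)
        assert strata.tolist() == pytest.approx([0.7, 0.1, 0.1, 0.1, 0.0])
        assert cond.to_dict() == {
            "miscleaved_methylK": 1.0,
            "miscleaved_other_modified": 0.0,
        }

    def test_no_miscleaved_modified_empty_conditional(self):
        recs = [make_record("PEPTIDEK")]
        _, cond = qc.miscleavage_modification_stratification(recs)
        assert cond.empty

    def test_fractions_sum_to_one(self, default_peptides):
        _, records, _ = default_peptides
        strata, cond = qc.miscleavage_modification_stratification(records)
        assert strata.sum() == pytest.approx(1.0, abs=1e-12)
        assert cond.sum() == pytest.approx(1.0, abs=1e-12)

    def test_full_coupling_matches_ground_truth(self, proteome):
        cfg = SimulationConfig(seed=2, methyl_misclv_coupling=1.0, p_methyl_K=0.1)
        records, truth = generate_peptide_table(cfg, proteome)
        for rec, (mis, methyl) in zip(
            records, zip(truth.peptide_truth["miscleaved"], truth.peptide_truth["has_methyl_K"])
        ):
            internal_methyl = any(
                rec.sequence[p - 1] == "K" and p < len(rec.sequence)
                and abs(s - METHYL_SHIFT) < 1e-6
                for p, s in rec.modifications
            )
            if internal_methyl:
                assert mis  # a methylated internal lysine is always miscleaved


class TestOverlapAndLocalization:
    def test_two_set_overlap(self):
        counts = qc.identification_overlap({"s1": {"a", "b", "c"}, "s2": {"b", "c", "d"}})
        assert counts[frozenset({"s1"})] == 1
        assert counts[frozenset({"s2"})] == 1
        assert counts[frozenset({"s1", "s2"})] == 2

    def test_identical_sets(self):
        counts = qc.identification_overlap({"x": {1, 2}, "y": {1, 2}})
        assert counts[frozenset({"x", "y"})] == 2
        assert counts[frozenset({"x"})] == 0

    def test_counts_equal_bruteforce_enumeration(self, rng):
        sets = {f"s{i}": set(rng.integers(0, 300, size=100).tolist()) for i in range(3)}
        counts = qc.identification_overlap(sets)
        union = set().union(*sets.values())
        assert sum(counts.values()) == len(union)
        for elem in union:
            pattern = frozenset(k for k, v in sets.items() if elem in v)
            assert counts[pattern] >= 1

    def test_single_set_rejected(self):
        with pytest.raises(InvalidArgumentError):
            qc.identification_overlap({"only": {1}})

    def test_subcellular_basic(self):
        dist = qc.subcellular_distribution(
            {"a", "b", "c", "d"},
            {"a": {"cytoplasm"}, "b": {"cytoplasm"}, "c": {"nucleus"}},
            ["cytoplasm", "nucleus"],
        )
        assert dist.to_dict() == {"cytoplasm": 50.0, "nucleus": 25.0, "not_annotated": 25.0}

    def test_multi_label_counted_in_both(self):
        dist = qc.subcellular_distribution(
            {"a"}, {"a": {"cytoplasm", "nucleus"}}, ["cytoplasm", "nucleus"]
        )
        assert dist["cytoplasm"] == 100.0 and dist["nucleus"] == 100.0

    def test_empty_annotation_all_unannotated(self):
        dist = qc.subcellular_distribution({"a", "b"}, {}, ["cytoplasm"])
        assert dist["not_annotated"] == 100.0
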