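import numpy as np
import pytest

from gutmr import estimators
from gutmr.exceptions import ConfigurationError
from gutmr.instruments import (
    LDInfo,
    clump,
    exclude_confounder_associated,
    exclude_outcome_associated,
    f_filter,
    harmonize,
    select_significant,
)

from conftest import make_table


class TestSelectSignificant:
    def test_strict_inequality_at_threshold(self):
        table = make_table(
            [
                {"rsid": "rs1", "pval": 2e-6},
                {"rsid": "rs2", "pval": 5e-5},
                {"rsid": "rs3", "pval": 1e-5},  # exactly at threshold: excluded
            ]
        )
        kept = select_significant(table, 1e-5)
        assert kept.records["rsid"].tolist() == ["rs1"]

    def test_empty_input_empty_output(self):
        table = make_table([{"rsid": "rs1"}]).subset([False])
        assert len(select_significant(table)) == 0


class TestClump:
    def _ld(self):
        return LDInfo(
            positions={"rs1": ("1", 1_000_000), "rs2": ("1", 6_000_000), "rs3": ("2", 1_000_000)}
        )

    def test_correlated_neighbour_removed(self):
        ld = self._ld()
        ld.set_r2("rs1", "rs2", 0.5)
        table = make_table(
            [{"rsid": "rs1", "pval": 1e-8}, {"rsid": "rs2", "pos": 6_000_000, "pval": 1e-6}]
        )
        kept = clump(table, ld)
        assert kept.records["rsid"].tolist() == ["rs1"]

    def test_below_r2_threshold_both_kept(self):
        ld = self._ld()
        ld.set_r2("rs1", "rs2", 0.0005)
        table = make_table(
            [{"rsid": "rs1", "pval": 1e-8}, {"rsid": "rs2", "pos": 6_000_000, "pval": 1e-6}]
        )
        assert len(clump(table, ld)) == 2

    def test_different_chromosomes_both_kept(self):
        ld = self._ld()
        table = make_table(
            [{"rsid": "rs1", "pval": 1e-8}, {"rsid": "rs3", "chrom": "2", "pval": 1e-6}]
        )
        assert len(clump(table, ld)) == 2

    def test_outside_window_both_kept(self):
        ld = LDInfo(positions={"rs1": ("1", 1_000_000), "rs2": ("1", 20_000_000)})
        ld.set_r2("rs1", "rs2", 0.9)
        table = make_table(
            [{"rsid": "rs1", "pval": 1e-8}, {"rsid": "rs2", "pos": 20_000_000, "pval": 1e-6}]
        )
        assert len(clump(table, ld)) == 2

    def test_missing_rsid_raises_naming_it(self):
        table = make_table([{"rsid": "rsX", "pval": 1e-8}])
        with pytest.raises(ConfigurationError, match="rsX"):
            clump(table, LDInfo())

    def test_retained_pairs_are_independent(self, rng):
        # property: no kept same-chromosome pair within the window has r2 >= cutoff
        n = 20
        ld = LDInfo(
            positions={f"rs{i}": ("1", 1_000_000 + i * 500_000) for i in range(n)}
        )
        for i in range(n):
            for k in range(i + 1, n):
                if rng.random() < 0.3:
                    ld.set_r2(f"rs{i}", f"rs{k}", float(rng.random()))
        table = make_table(
            [
                {"rsid": f"rs{i}", "pos": 1_000_000 + i * 500_000,
                 "pval": float(rng.uniform(1e-9, 1e-6))}
                for i in range(n)
            ]
        )
        kept = clump(table, ld).records["rsid"].tolist()
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                pa, pb = ld.positions[a][1], ld.positions[b][1]
                if abs(pa - pb) <= 10_000_000:
                    assert ld.get_r2(a, b) < 0.001


class TestFFilter:
    @pytest.mark.parametrize(
        "beta,se,kept",
        [
            (0.05, 0.01, True),   # F = 25
            (0.03, 0.01, False),  # F = 9
            (0.0411, 0.01, True),  # F ~ 16.89, typical strength for these instruments
        ],
    )
    def test_threshold(self, beta, se, kept):
        table = make_table([{"rsid": "rs1", "beta": beta, "se": se}])
        assert (len(f_filter(table)) == 1) is kept


class TestOutcomeExclusion:
    def test_outcome_significant_removed(self):
        cand = make_table([{"rsid": "rs1"}, {"rsid": "rs2", "pos": 2000}])
        outcome = make_table(
            [{"rsid": "rs1", "pval": 1e-7}, {"rsid": "rs2", "pos": 2000, "pval": 0.5}],
            trait_kind="outcome", taxon_level=None,
        )
        kept = exclude_outcome_associated(cand, outcome)
        assert kept.records["rsid"].tolist() == ["rs2"]

    def test_known_outcome_associated_panel(self):
        # the four variants dropped for outcome association in the reference workflow
        flagged = ["rs11597285", "rs62240188", "rs62028349", "rs12925026"]
        others = ["rs111", "rs222"]
        cand = make_table(
            [{"rsid": r, "pos": 1000 * (i + 1)} for i, r in enumerate(flagged + others)]
        )
        outcome = make_table(
            [{"rsid": r, "pos": 1000 * (i + 1),
              "pval": 1e-7 if r in flagged else 0.2}
             for i, r in enumerate(flagged + others)],
            trait_kind="outcome", taxon_level=None,
        )
        kept = exclude_outcome_associated(cand, outcome)
        assert kept.records["rsid"].tolist() == others

    def test_absent_from_outcome_retained(self):
        cand = make_table([{"rsid": "rs1"}])
        outcome = make_table([{"rsid": "rs9", "pval": 1e-9}], trait_kind="outcome",
                             taxon_level=None)
        assert len(exclude_outcome_associated(cand, outcome)) == 1


class TestConfounderExclusion:
    def test_annotated_confounder_removed(self):
        cand = make_table([{"rsid": "rs4506202"}, {"rsid": "rs2", "pos": 2000}])
        kept = exclude_confounder_associated(
            cand, {"rs4506202": {"smoking"}}, {"smoking", "occupational exposure"}
        )
        assert kept.records["rsid"].tolist() == ["rs2"]

    def test_empty_annotations_no_change(self):
        cand = make_table([{"rsid": "rs1"}])
        assert len(exclude_confounder_associated(cand, {}, {"smoking"})) == 1

    def test_unlisted_trait_retained(self):
        cand = make_table([{"rsid": "rs1"}])
        kept = exclude_confounder_associated(cand, {"rs1": {"height"}}, {"smoking"})
        assert len(kept) == 1


class TestHarmonize:
    def _outcome(self, rows):
        return make_table(rows, trait_name="out", trait_kind="outcome", taxon_level=None)

    def test_swapped_alleles_flip_sign(self):
        exposure = make_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "G",
                                "beta": 0.1}])
        outcome = self._outcome([{"rsid": "rs1", "effect_allele": "G", "other_allele": "A",
                                  "beta": -0.05}])
        inst = harmonize(exposure, outcome)
        assert inst.j == 1
        assert inst.instruments[0].Gamma_out == pytest.approx(0.05)

    def test_palindromic_dropped_unconditionally(self):
        exposure = make_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "T",
                                "beta": 0.1, "eaf": 0.1}])
        outcome = self._outcome([{"rsid": "rs1", "effect_allele": "A", "other_allele": "T",
                                  "beta": 0.05, "eaf": 0.1}])
        inst = harmonize(exposure, outcome)
        assert inst.j == 0
        assert inst.provenance["harmonize_dropped_palindromic"] == 1

    def test_irreconcilable_dropped(self):
        exposure = make_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "G"}])
        outcome = self._outcome([{"rsid": "rs1", "effect_allele": "A", "other_allele": "C"}])
        inst = harmonize(exposure, outcome)
        assert inst.j == 0
        assert inst.provenance["harmonize_dropped_irreconcilable"] == 1

    def test_absent_from_outcome_dropped(self):
        exposure = make_table([{"rsid": "rs1"}])
        outcome = self._outcome([{"rsid": "rs2", "pos": 2000}])
        inst = harmonize(exposure, outcome)
        assert inst.j == 0
        assert inst.provenance["harmonize_dropped_absent_from_outcome"] == 1

    def test_orientation_invariance_downstream(self):
        """Recoding any input record (swap alleles, negate beta, eaf -> 1-eaf)
        must leave harmonized effects and every estimate unchanged."""
        rows_exp, rows_out = [], []
        rng = np.random.default_rng(5)
        for i in range(5):
            beta = float(rng.normal(0.1, 0.02))
            rows_exp.append({"rsid": f"rs{i}", "pos": 1000 * (i + 1), "beta": beta,
                             "effect_allele": "A", "other_allele": "G", "eaf": 0.3})
            rows_out.append({"rsid": f"rs{i}", "pos": 1000 * (i + 1),
                             "beta": float(rng.normal(0.03, 0.01)), "se": 0.01,
                             "effect_allele": "A", "other_allele": "G", "eaf": 0.3})
        exposure = make_table(rows_exp)
        outcome = self._outcome(rows_out)

        flipped = [dict(r) for r in rows_out]
        for r in flipped[::2]:  # flip the coding of every other outcome record
            r["effect_allele"], r["other_allele"] = r["other_allele"], r["effect_allele"]
            r["beta"] = -r["beta"]
            r["eaf"] = 1 - r["eaf"]
        outcome_flipped = self._outcome(flipped)

        a = harmonize(exposure, outcome)
        b = harmonize(exposure, outcome_flipped)
        assert a.arrays()[2].tolist() == b.arrays()[2].tolist()
        assert estimators.ivw(a).beta == estimators.ivw(b).beta

    def test_provenance_counts_conserve(self):
        exposure = make_table(
            [
                {"rsid": "rs1", "effect_allele": "A", "other_allele": "G"},
                {"rsid": "rs2", "pos": 2000, "effect_allele": "A", "other_allele": "T"},
                {"rsid": "rs3", "pos": 3000, "effect_allele": "C", "other_allele": "T"},
            ]
        )
        outcome = self._outcome(
            [
                {"rsid": "rs1", "effect_allele": "A", "other_allele": "G"},
                {"rsid": "rs2", "pos": 2000, "effect_allele": "A", "other_allele": "T"},
            ]
        )
        inst = harmonize(exposure, outcome)
        assert inst.j + sum(inst.provenance.values()) == len(exposure)
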