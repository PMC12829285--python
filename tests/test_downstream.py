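import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methmark import (
    BetaMatrix,
    annotate_cpgs,
    assign_specificity,
    catalogue_overlap,
    direction_call,
    spearman_screen,
    substream,
)
from methmark.downstream import SpecificityRecord
from methmark.selection import ConsensusSet


def _matrix_from_columns(cols: dict):
    ids = list(cols)
    vals = np.array([cols[g] for g in ids], dtype=float).T
    return BetaMatrix([f"s{i}" for i in range(vals.shape[0])], ids, vals)


class TestSpearmanScreen:
    def test_perfect_monotone_correlation(self):
        m = _matrix_from_columns({"cg1": [0.1, 0.2, 0.3, 0.4, 0.5]})
        traits = pd.DataFrame(
            {"bmi": [2, 4, 6, 8, 10]}, index=[f"s{i}" for i in range(5)]
        )
        records, counts = spearman_screen(m, traits)
        assert records["rho"].iloc[0] == pytest.approx(1.0)
        assert records["p_value"].iloc[0] == 0.0
        assert counts["bmi"] == 1

    def test_hand_computed_rank_correlation(self):
        # ranks (1,2,3,4) vs (4,1,2,3): sum d^2 = 12,
        # rho = 1 - 6*12/(4*15) = -0.2
        m = _matrix_from_columns({"cg1": [0.1, 0.2, 0.3, 0.4]})
        traits = pd.DataFrame(
            {"t": [4.0, 1.0, 2.0, 3.0]}, index=["s0", "s1", "s2", "s3"]
        )
        records, _ = spearman_screen(m, traits)
        assert records["rho"].iloc[0] == pytest.approx(-0.2)

    def test_fewer_than_four_observations_flagged(self):
        m = _matrix_from_columns({"cg1": [0.1, 0.2, 0.3]})
        traits = pd.DataFrame({"t": [3.0, 1.0, 2.0]}, index=["s0", "s1", "s2"])
        records, counts = spearman_screen(m, traits)
        assert bool(records["flagged"].iloc[0])
        assert counts.get("t", 0) == 0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.uniform(0.2, 0.8, 30), 1)  # ties by rounding
        y = rng.normal(size=30)
        m = _matrix_from_columns({"cg1": x})
        traits = pd.DataFrame({"t": y}, index=[f"s{i}" for i in range(30)])
        records, _ = spearman_screen(m, traits)
        rho_ref, p_ref = stats.spearmanr(x, y)
        assert records["rho"].iloc[0] == pytest.approx(rho_ref, abs=1e-12)
        assert records["p_value"].iloc[0] == pytest.approx(p_ref, rel=1e-9)

    def test_constant_cpg_flagged_and_excluded(self):
        m = _matrix_from_columns({"flat": [0.5] * 6, "ok": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]})
        traits = pd.DataFrame(
            {"t": [1.0, 2, 3, 4, 5, 6]}, index=[f"s{i}" for i in range(6)]
        )
        records, counts = spearman_screen(m, traits)
        flat = records[records.cpg_id == "flat"].iloc[0]
        assert flat["flagged"] and not flat["significant"]
        assert counts["t"] == 1

    def test_null_significant_fraction_near_alpha(self, small_pair):
        """With traits independent of methylation, ~5% of screens hit p<0.05."""
        _, disc, _, _, _ = small_pair
        sub = disc.select_cpgs(list(disc.cpg_ids[:150]))
        rng = substream(123, "null-traits")
        traits = pd.DataFrame(
            {f"t{i}": rng.normal(size=sub.n_samples) for i in range(4)},
            index=list(sub.sample_ids),
        )
        records, counts = spearman_screen(sub, traits)
        frac = counts.sum() / len(records)
        # binomial 99.9% envelope around 0.05 for 600 tests
        assert 0.02 < frac < 0.09


class TestSpecificity:
    def _consensus(self, freqs):
        per_class = {c: {} for c in (2, 3, 5, 6)}
        for g, by_c in freqs.items():
            for c, f in by_c.items():
                per_class[c][g] = f
        overall = {g: max(by_c.values()) for g, by_c in freqs.items()}
        return ConsensusSet(overall, per_class, frozenset(freqs), len(freqs))

    def test_singleton_membership_is_specific(self):
        cons = self._consensus({"g1": {2: 0.6, 3: 0.05, 5: 0.02, 6: 0.0}})
        records, venn = assign_specificity(cons)
        assert records[0].specific_to == 2
        assert venn == {frozenset([2]): 1}

    def test_mixed_membership(self):
        cons = self._consensus({"g1": {2: 0.01, 3: 0.4, 5: 0.3, 6: 0.05}})
        records, _ = assign_specificity(cons)
        assert records[0].class_sets == frozenset([3, 5])
        assert records[0].specific_to is None

    def test_center_of_venn(self):
        cons = self._consensus({"g1": {2: 0.2, 3: 0.2, 5: 0.2, 6: 0.2}})
        records, venn = assign_specificity(cons)
        assert records[0].class_sets == frozenset([2, 3, 5, 6])

    def test_weak_cpg_falls_back_to_argmax(self):
        cons = self._consensus({"g1": {2: 0.04, 3: 0.08, 5: 0.02, 6: 0.01}})
        records, _ = assign_specificity(cons)
        assert records[0].specific_to == 3 and records[0].weak

    def test_venn_counts_sum_to_retained(self):
        rng = np.random.default_rng(0)
        freqs = {
            f"g{i}": {c: float(rng.uniform(0, 0.4)) for c in (2, 3, 5, 6)}
            for i in range(40)
        }
        cons = self._consensus(freqs)
        _, venn = assign_specificity(cons)
        assert sum(venn.values()) == len(cons.retained)


class TestDirectionCall:
    def _data(self):
        vals = {"cg1": [0.8] * 3 + [0.4] * 6, "cg2": [0.2] * 3 + [0.5] * 6}
        m = _matrix_from_columns(vals)
        labels = np.array([5] * 3 + [3] * 3 + [6] * 3)
        return m, labels

    def test_hyper_and_hypo(self):
        m, labels = self._data()
        assert direction_call(m, labels, SpecificityRecord("cg1", frozenset([5]), 5)) == "hyper"
        assert direction_call(m, labels, SpecificityRecord("cg2", frozenset([5]), 5)) == "hypo"

    def test_tie_is_indeterminate(self):
        m = _matrix_from_columns({"cg1": [0.5, 0.5, 0.5, 0.5]})
        labels = np.array([5, 5, 3, 3])
        rec = SpecificityRecord("cg1", frozenset([5]), 5)
        assert direction_call(m, labels, rec) == "indeterminate"

    def test_non_specific_record_rejected(self):
        m, labels = self._data()
        rec = SpecificityRecord("cg1", frozenset([3, 5]), None)
        with pytest.raises(ValueError, match="not cluster-specific"):
            direction_call(m, labels, rec)

    def test_planted_directions_recovered(self, small_pair, small_labels):
        """At generator strength, nearly all truth directions are reproduced."""
        _, disc, _, _, truth = small_pair
        hits = total = 0
        for g in sorted(truth.informative_cpgs):
            rec = SpecificityRecord(g, frozenset([truth.target_cluster[g]]), truth.target_cluster[g])
            call = direction_call(disc, small_labels, rec)
            total += 1
            hits += call == truth.direction[g]
        assert hits / total >= 0.95


class TestAnnotation:
    def _genes(self):
        return pd.DataFrame(
            {
                "gene": ["GENE1", "GENE2"],
                "chrom": ["chr1", "chr1"],
                "tss": [10_000, 50_000],
                "first_exon_start": [10_000, 50_000],
                "last_exon_end": [20_000, 58_000],
            }
        )

    def test_promoter_within_2kb_upstream(self):
        pos = pd.DataFrame({"cpg_id": ["c1"], "chrom": ["chr1"], "pos": [8_500]})
        ann = annotate_cpgs(pos, self._genes())
        assert ann.loc[0, "region"] == "promoter"
        assert ann.loc[0, "gene"] == "GENE1"

    def test_gene_body_past_promoter_window(self):
        pos = pd.DataFrame({"cpg_id": ["c1"], "chrom": ["chr1"], "pos": [15_000]})
        ann = annotate_cpgs(pos, self._genes())
        assert ann.loc[0, "region"] == "gene_body"
        assert ann.loc[0, "gene"] == "GENE1"

    def test_intergenic_far_from_genes(self):
        pos = pd.DataFrame({"cpg_id": ["c1"], "chrom": ["chr1"], "pos": [35_000]})
        ann = annotate_cpgs(pos, self._genes())
        assert ann.loc[0, "region"] == "intergenic"
        assert ann.loc[0, "gene"] is None

    def test_unknown_chromosome_flagged(self):
        pos = pd.DataFrame({"cpg_id": ["c1"], "chrom": ["chrX"], "pos": [100]})
        ann = annotate_cpgs(pos, self._genes())
        assert ann.loc[0, "region"] == "unmapped"

    def test_every_cpg_gets_exactly_one_region(self):
        rng = np.random.default_rng(8)
        pos = pd.DataFrame(
            {
                "cpg_id": [f"c{i}" for i in range(200)],
                "chrom": "chr1",
                "pos": rng.integers(0, 70_000, 200),
            }
        )
        ann = annotate_cpgs(pos, self._genes())
        assert len(ann) == 200
        assert ann["region"].isin(["promoter", "gene_body", "intergenic"]).all()


class TestCatalogueOverlap:
    def _catalogue(self):
        return pd.DataFrame(
            {
                "cpg_id": ["b", "c", "b"],
                "trait_category": ["T2D", "CRP", "CRP"],
            }
        )

    def test_counts_per_trait(self):
        out = catalogue_overlap({"a", "b"}, self._catalogue())
        counts = dict(zip(out.trait_category, out.n_overlap))
        assert counts == {"T2D": 1, "CRP": 1}

    def test_multi_trait_cpg_counted_in_each(self):
        out = catalogue_overlap({"b"}, self._catalogue())
        assert out["n_overlap"].tolist() == [1, 1]

    def test_empty_set_all_zero(self):
        out = catalogue_overlap(set(), self._catalogue())
        assert (out["n_overlap"] == 0).all()

    def test_cluster_breakdown(self):
        spec = [
            SpecificityRecord("b", frozenset([5]), 5),
            SpecificityRecord("c", frozenset([3, 5]), None),
        ]
        out = catalogue_overlap({"b", "c"}, self._catalogue(), specificity=spec)
        crp = out[out.trait_category == "CRP"].iloc[0]
        assert crp["n_overlap_5"] == 1 and crp["n_overlap_mixed"] == 1
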