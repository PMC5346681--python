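"""MAF parsing, mutation frequencies, and the rank-sum group comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ppibench import (
    GeneSet,
    SyntheticConfig,
    compare_rank_groups,
    generate_maf_frame,
    load_maf,
    mutation_frequency,
)

MAF_HEADER = "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n"


def write_maf_text(tmp_path, rows, header=MAF_HEADER, name="x.maf"):
    p = tmp_path / name
    p.write_text(header + "".join(rows), encoding="utf-8")
    return p


def _table(freq_frame, cancer, n_samples):
    from ppibench.mutation import MutationTable

    return MutationTable(
        freq=freq_frame,
        counts=freq_frame * n_samples,
        samples_per_cancer={cancer: n_samples},
    )


class TestLoadMaf:
    def test_basic_records(self, tmp_path):
        p = write_maf_text(
            tmp_path,
            ["TP53\tS1\tMissense_Mutation\n", "TP53\tS2\tNonsense_Mutation\n",
             "KRAS\tS1\tMissense_Mutation\n"],
        )
        rec = load_maf(p, cancer_type="BRCA")
        assert len(rec) == 3
        assert rec["sample"].nunique() == 2
        assert set(rec["cancer_type"]) == {"BRCA"}

    def test_header_only(self, tmp_path):
        assert len(load_maf(write_maf_text(tmp_path, []))) == 0

    def test_exclude_silent(self, tmp_path):
        p = write_maf_text(
            tmp_path, ["A\tS1\tSilent\n", "A\tS2\tMissense_Mutation\n"]
        )
        assert len(load_maf(p)) == 2
        assert len(load_maf(p, exclude_silent=True)) == 1

    def test_missing_column_named_in_error(self, tmp_path):
        p = write_maf_text(
            tmp_path, ["A\tS1\n"], header="Hugo_Symbol\tTumor_Sample_Barcode\n"
        )
        with pytest.raises(ValueError, match="Variant_Classification"):
            load_maf(p)

    def test_entrez_id_accepted_as_gene_column(self, tmp_path):
        p = write_maf_text(
            tmp_path,
            ["7157\tS1\tMissense_Mutation\n"],
            header="Entrez_Gene_Id\tTumor_Sample_Barcode\tVariant_Classification\n",
        )
        assert load_maf(p)["gene"].tolist() == ["7157"]


class TestMutationFrequency:
    def records(self, triples):
        return pd.DataFrame(
            [
                {"gene": g, "sample": s, "cancer_type": c, "variant_class": "M"}
                for g, s, c in triples
            ]
        )

    def test_three_of_twenty_samples(self):
        rec = self.records([("A", f"S{i}", "C") for i in range(3)])
        t = mutation_frequency(rec, total_samples={"C": 20})
        assert t.frequency("A", "C") == pytest.approx(0.15)

    def test_repeat_records_in_one_sample_count_once(self):
        rec = self.records([("A", "S1", "C")] * 5)
        t = mutation_frequency(rec, total_samples={"C": 10})
        assert t.frequency("A", "C") == pytest.approx(0.1)

    def test_duplication_invariance(self):
        rec = self.records([("A", "S1", "C"), ("A", "S2", "C"), ("B", "S1", "C")])
        doubled = pd.concat([rec, rec], ignore_index=True)
        a = mutation_frequency(rec, total_samples={"C": 5})
        b = mutation_frequency(doubled, total_samples={"C": 5})
        assert a.freq.equals(b.freq)

    def test_totals_inferred_from_distinct_samples(self):
        rec = self.records([("A", "S1", "C"), ("B", "S2", "C")])
        t = mutation_frequency(rec)
        assert t.samples_per_cancer["C"] == 2
        assert t.frequency("A", "C") == pytest.approx(0.5)

    def test_understated_totals_rejected(self):
        rec = self.records([("A", f"S{i}", "C") for i in range(5)])
        with pytest.raises(ValueError, match="smaller"):
            mutation_frequency(rec, total_samples={"C": 3})

    def test_absent_gene_frequency_zero_unknown_cancer_raises(self):
        t = mutation_frequency(self.records([("A", "S1", "C")]))
        assert t.frequency("NOT_THERE", "C") == 0.0
        with pytest.raises(KeyError):
            t.frequency("A", "D")

    def test_generator_frequencies_match_planted_rate(self):
        cfg = SyntheticConfig(
            n_genes=20, n_positives=5, n_samples=500,
            baseline_rate=0.02, planted_rate=0.3, cancer_labels=("C1",), seed=5,
        )
        genes = [f"G{i:04d}" for i in range(20)]
        pos = GeneSet(ids=frozenset(genes[:5]), label="p")
        frame, totals = generate_maf_frame(genes, pos, cfg, seed=6)
        t = mutation_frequency(load_like(frame), total_samples=totals)
        # binomial 99% interval around the planted rate at n=500
        half = 2.576 * np.sqrt(0.3 * 0.7 / 500)
        for g in pos.ids:
            assert abs(t.frequency(g, "C1") - 0.3) < half + 1e-9


def load_like(frame: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": frame["Hugo_Symbol"],
            "sample": frame["Tumor_Sample_Barcode"],
            "cancer_type": frame["Cancer_Type"],
            "variant_class": frame["Variant_Classification"],
        }
    )


class TestRankSum:
    def test_exact_p_for_clean_separation(self):
        # all C(6,3)=20 rank assignments; only one gives complete separation
        t = _table(
            pd.DataFrame({"C": [0.4, 0.5, 0.6, 0.1, 0.2, 0.3]},
                         index=["T1", "T2", "T3", "B1", "B2", "B3"]),
            "C", 10,
        )
        res = compare_rank_groups(t, ["T1", "T2", "T3"], ["B1", "B2", "B3"], "C")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 20)

    def test_exact_p_by_full_enumeration_oracle(self):
        # oracle: enumerate all assignments of ranks to the top group
        freqs = [0.05, 0.12, 0.33, 0.47, 0.51, 0.62, 0.70, 0.81]
        top_idx = (1, 4, 6, 7)
        names = [f"g{i}" for i in range(8)]
        t = _table(pd.DataFrame({"C": freqs}, index=names), "C", 100)
        top = [names[i] for i in top_idx]
        bottom = [names[i] for i in range(8) if i not in top_idx]
        obs_ranksum = sum(sorted(range(8))[i] + 1 for i in top_idx)
        count = sum(
            1
            for comb in itertools.combinations(range(1, 9), 4)
            if sum(comb) >= obs_ranksum
        )
        expected_p = count / 70  # C(8,4)
        res = compare_rank_groups(t, top, bottom, "C")
        assert res.p_value == pytest.approx(expected_p)

    def test_label_swap_flips_tail(self):
        t = _table(
            pd.DataFrame({"C": [0.4, 0.5, 0.6, 0.1, 0.2, 0.3]},
                         index=["T1", "T2", "T3", "B1", "B2", "B3"]),
            "C", 10,
        )
        fwd = compare_rank_groups(t, ["T1", "T2", "T3"], ["B1", "B2", "B3"], "C")
        rev = compare_rank_groups(t, ["B1", "B2", "B3"], ["T1", "T2", "T3"], "C")
        assert rev.p_value == pytest.approx(1.0)  # P(U >= 0) over 20 assignments
        assert fwd.p_value < rev.p_value

    def test_identical_groups_not_significant(self):
        t = _table(
            pd.DataFrame({"C": [0.1, 0.2, 0.3] * 2},
                         index=["T1", "T2", "T3", "B1", "B2", "B3"]),
            "C", 10,
        )
        res = compare_rank_groups(t, ["T1", "T2", "T3"], ["B1", "B2", "B3"], "C")
        assert res.p_value >= 0.5

    def test_degenerate_all_identical(self):
        t = _table(pd.DataFrame({"C": [0.1] * 6},
                                index=["T1", "T2", "T3", "B1", "B2", "B3"]), "C", 10)
        res = compare_rank_groups(t, ["T1", "T2", "T3"], ["B1", "B2", "B3"], "C")
        assert res.p_value == 1.0
        assert res.note

    def test_empty_group_rejected(self):
        t = _table(pd.DataFrame({"C": [0.1]}, index=["A"]), "C", 10)
        with pytest.raises(ValueError, match="nonempty"):
            compare_rank_groups(t, [], ["A"], "C")

    def test_power_monotone_in_effect_size(self):
        # planted-vs-baseline separation should grow with the planted rate
        rng_master = np.random.default_rng(77)
        genes = [f"G{i:03d}" for i in range(40)]
        top, bottom = genes[:20], genes[20:]
        power = []
        for planted in (0.10, 0.12, 0.14):
            rej = 0
            reps = 150
            rng = np.random.default_rng(rng_master.integers(2**31))
            for _ in range(reps):
                counts = np.concatenate(
                    [rng.binomial(100, planted, 20), rng.binomial(100, 0.10, 20)]
                )
                t = _table(pd.DataFrame({"C": counts / 100}, index=genes), "C", 100)
                rej += compare_rank_groups(t, top, bottom, "C").p_value < 0.05
            power.append(rej / reps)
        assert power[0] < power[1] < power[2]
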