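"""Minor-allele recoding, composite labels and factor encoding."""

import numpy as np
import pandas as pd
import pytest

import genosets as g
from genosets.composite import RARE_LEVEL


def _matrix(cols: dict) -> pd.DataFrame:
    n = len(next(iter(cols.values())))
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cols.items()},
                        index=[f"a{i}" for i in range(n)])


class TestMinorAlleleRecoding:
    def test_high_frequency_column_is_complemented(self):
        # alt frequency 0.7 -> ref is minor; a 2-alt-copy call recodes to 0
        m = _matrix({"s1": [2, 2, 2, 1, 1, 1, 1, 0, 2, 2]})  # freq 0.7
        rec, ann = g.determine_minor_alleles(m)
        assert rec["s1"].tolist() == [0, 0, 0, 1, 1, 1, 1, 2, 0, 0]
        assert bool(ann["recoded"][0])
        assert ann["maf"][0] == pytest.approx(0.3)

    def test_tie_at_half_keeps_alt_as_minor(self):
        m = _matrix({"s1": [0, 2, 0, 2]})  # frequency exactly 0.5
        rec, ann = g.determine_minor_alleles(m)
        assert not ann["recoded"][0]
        pd.testing.assert_frame_equal(rec, m)

    def test_recoding_is_involutive_and_matches_direct_tally(self):
        rng = np.random.default_rng(0)
        m = _matrix({f"s{j}": rng.binomial(2, f, 200)
                     for j, f in enumerate([0.1, 0.5, 0.8, 0.95])})
        rec, ann = g.determine_minor_alleles(m)
        rec2, ann2 = g.determine_minor_alleles(rec)
        pd.testing.assert_frame_equal(rec, rec2)  # idempotent
        assert not ann2["recoded"].any()
        for j, col in enumerate(m.columns):
            f = m[col].sum() / (2 * len(m))  # direct allele tally
            assert ann["maf"][j] == pytest.approx(min(f, 1 - f))
            assert rec[col].mean() / 2 == pytest.approx(min(f, 1 - f))

    def test_monomorphic_flagged_and_zeroed(self):
        m = _matrix({"s1": [2, 2, 2, 2]})
        rec, ann = g.determine_minor_alleles(m)
        assert bool(ann["monomorphic"][0])
        assert (rec["s1"] == 0).all()

    def test_minor_allele_label_from_snp_map(self):
        m = _matrix({"s1": [2, 2, 2, 0], "s2": [0, 0, 0, 2]})
        snp_map = pd.DataFrame({"snp_id": ["s1", "s2"], "chrom": "chr1",
                                "pos": [1, 2], "ref": ["A", "C"],
                                "alt": ["G", "T"]})
        _, ann = g.determine_minor_alleles(m, snp_map)
        assert ann["minor_allele"].tolist() == ["A", "T"]


class TestCompositeLabels:
    def test_worked_three_snp_encoding(self):
        # counts [0, 2, 1] concatenate to the label "0-2-1"
        m = _matrix({"s1": [0, 1], "s2": [2, 1], "s3": [1, 1]})
        gs = g.GeneSnpSet("G", ("s1", "s2", "s3"))
        comp = g.build_composite(m, gs)
        assert comp.labels.iloc[0] == "0-2-1"
        assert comp.labels.iloc[1] == "1-1-1"

    def test_single_snp_label(self):
        m = _matrix({"s1": [2]})
        comp = g.build_composite(m, g.GeneSnpSet("G", ("s1",)))
        assert comp.labels.iloc[0] == "2"

    def test_parse_inverts_build_on_random_instance(self):
        rng = np.random.default_rng(3)
        m = _matrix({f"s{j}": rng.integers(0, 3, 100) for j in range(4)})
        gs = g.GeneSnpSet("G", tuple(m.columns))
        comp = g.build_composite(m, gs)
        for animal, label in comp.labels.items():
            assert g.parse_composite_label(label) == tuple(
                int(v) for v in m.loc[animal])

    def test_label_tokens_are_permutation_covariant(self):
        rng = np.random.default_rng(4)
        m = _matrix({f"s{j}": rng.integers(0, 3, 50) for j in range(3)})
        fwd = g.build_composite(m, g.GeneSnpSet("G", ("s0", "s1", "s2")))
        rev = g.build_composite(m, g.GeneSnpSet("G", ("s2", "s1", "s0")))
        for a in m.index:
            assert fwd.labels[a].split("-") == rev.labels[a].split("-")[::-1]

    def test_missing_policies(self):
        m = _matrix({"s1": [0, 0, 0, 1, np.nan], "s2": [1, 1, 2, 2, 2]})
        gs = g.GeneSnpSet("G", ("s1", "s2"))
        imp = g.build_composite(m, gs, missing_policy="impute")
        assert imp.labels.iloc[4] == "0-2"  # modal count of s1 is 0
        assert imp.imputed.tolist() == [False] * 4 + [True]
        drop = g.build_composite(m, gs, missing_policy="drop")
        assert drop.labels.iloc[4] is None

    def test_empty_gene_set_raises(self):
        m = _matrix({"s1": [0]})
        with pytest.raises(ValueError, match="empty"):
            g.build_composite(m, g.GeneSnpSet("G", ()))


class TestFactorEncoding:
    def _encoding_from_labels(self, labels, min_count=5):
        comp = g.CompositeGenotype(
            gene="G", snp_ids=("s",),
            labels=pd.Series(labels), imputed=pd.Series([False] * len(labels)))
        return g.encode_factor(comp, min_count)

    def test_tied_top_levels_reference_is_lexicographic(self):
        enc = self._encoding_from_labels(["1"] * 50 + ["0"] * 50)
        assert enc.levels == ("0", "1")
        assert enc.reference == "0"

    def test_rare_pooling_arithmetic(self):
        enc = self._encoding_from_labels(["0"] * 96 + ["1"] * 3 + ["2"] * 1)
        assert set(enc.levels) == {"0", RARE_LEVEL}
        assert dict(zip(enc.levels, enc.counts))[RARE_LEVEL] == 4
        assert enc.pooled_labels == ("1", "2")

    def test_pooling_conserves_observations_and_never_adds_levels(self):
        rng = np.random.default_rng(5)
        labels = [f"{a}-{b}" for a, b in rng.integers(0, 3, size=(300, 2))]
        unpooled = self._encoding_from_labels(labels, min_count=1)
        pooled = self._encoding_from_labels(labels, min_count=10)
        assert sum(pooled.counts) == sum(unpooled.counts) == 300
        assert pooled.n_levels <= unpooled.n_levels

    def test_level_count_matches_brute_force_tally(self):
        rng = np.random.default_rng(6)
        m = _matrix({f"s{j}": rng.binomial(2, 0.3, 1546) for j in range(3)})
        comp = g.build_composite(m, g.GeneSnpSet("G", tuple(m.columns)))
        enc = g.encode_factor(comp, min_level_count=1)
        assert enc.n_levels == len(set(comp.labels))  # label multiset tally

    def test_single_level_is_non_informative(self):
        enc = self._encoding_from_labels(["0"] * 20)
        assert not enc.informative
        enc2 = self._encoding_from_labels(["0"] * 3 + ["1"] * 2, min_count=5)
        assert not enc2.informative  # everything pooled into one RARE level


def test_fast_path_matches_label_based_encoding(small_panel):
    recoded, _ = g.determine_minor_alleles(small_panel["genotypes"])
    fast = g.encode_gene_sets(recoded, small_panel["gene_sets"], 5)
    for gs, fenc in zip([s for s in small_panel["gene_sets"] if not s.empty],
                        fast):
        slow = g.encode_factor(g.build_composite(recoded, gs), 5)
        assert fenc.levels == slow.levels
        assert fenc.counts == slow.counts
        np.testing.assert_array_equal(fenc.codes, slow.codes)
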