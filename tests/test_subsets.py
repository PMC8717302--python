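"""Locus ranking and subset construction."""

import numpy as np
import pytest

from mscdelim.io import LocusAlignment
from mscdelim.subsets import SubsetSpec, make_subsets, site_counts


def loc_from_cols(lid, cols):
    """Build a locus from a list of column strings (one char per row)."""
    n_rows = len(cols[0])
    rows = {}
    for i in range(n_rows):
        rows[f"r{i}"] = "".join(c[i] for c in cols)
    return LocusAlignment(lid, rows)


class TestSiteCounts:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            # column 2 has A,A,C,C -> variable and informative
            ({"a": "AAT", "b": "AAT", "c": "ACT", "d": "ACT"}, (1, 1)),
            # singleton column: variable, not informative
            ({"a": "AAT", "b": "AAT", "c": "AAT", "d": "ACT"}, (1, 0)),
            ({"a": "AAT", "b": "AAT", "c": "AAT", "d": "AAT"}, (0, 0)),
            # missing symbols excluded from state counts
            ({"a": "AN", "b": "AN", "c": "A-", "d": "CN"}, (1, 0)),
        ],
    )
    def test_hand_counted_examples(self, rows, expected):
        assert site_counts(LocusAlignment("x", rows)) == expected

    def test_single_sequence_warns_zero(self):
        loc = LocusAlignment("x", {"a": "ACGT", "b": "NNNN"})
        with pytest.warns(UserWarning):
            assert site_counts(loc) == (0, 0)

    def test_row_order_invariant(self):
        rows = {"a": "ACT", "b": "AAT", "c": "ACT", "d": "AAG"}
        rev = dict(reversed(list(rows.items())))
        assert site_counts(LocusAlignment("x", rows)) == site_counts(
            LocusAlignment("x", rev)
        )


def synthetic_ranked_loci():
    """Six loci with informative counts {6, 5, 4, 2, 1, 0}."""
    out = []
    for k, n_inf in enumerate((6, 5, 4, 2, 1, 0)):
        cols = ["AACC"] * n_inf + ["AAAA"] * (8 - n_inf)
        out.append(loc_from_cols(f"L{k + 1}", cols))
    return out


class TestMakeSubsets:
    def test_min_informative_threshold(self):
        loci = synthetic_ranked_loci()
        subs = make_subsets(loci, SubsetSpec("min_informative", min_count=4))
        assert subs[0].locus_ids == ["L1", "L2", "L3"]

    def test_informative_range_inclusive(self):
        # mirrors the between-10-and-20 band rule on counts {25,15,12,9}
        counts = {"L1": (25, 25), "L2": (15, 15), "L3": (12, 12), "L4": (9, 9)}
        loci = synthetic_ranked_loci()[:4]
        subs = make_subsets(
            loci, SubsetSpec("informative_range", bounds=(10, 20)), counts=counts
        )
        assert sorted(subs[0].locus_ids) == ["L2", "L3"]

    def test_k_most_variable_total_order(self):
        loci = synthetic_ranked_loci()
        a = make_subsets(loci, SubsetSpec("k_most_variable", k=3))
        b = make_subsets(loci, SubsetSpec("k_most_variable", k=3))
        assert a[0].locus_ids == b[0].locus_ids == ["L1", "L2", "L3"]

    def test_k_too_large_names_both_numbers(self):
        loci = synthetic_ranked_loci()
        with pytest.raises(ValueError, match="99.*6"):
            make_subsets(loci, SubsetSpec("k_most_variable", k=99))

    def test_random_replicates_deterministic_and_subsets(self):
        loci = synthetic_ranked_loci()
        spec = SubsetSpec("random", n_loci=3, replicates=3, seed=5)
        subs = make_subsets(loci, spec)
        again = make_subsets(loci, spec)
        variable = {"L1", "L2", "L3", "L4", "L5"}  # L6 invariant
        for s, s2 in zip(subs, again):
            assert s.locus_ids == s2.locus_ids
            assert len(set(s.locus_ids)) == len(s.locus_ids) == 3
            assert set(s.locus_ids) <= variable

    def test_random_excludes_invariant_loci(self):
        loci = synthetic_ranked_loci()
        subs = make_subsets(loci, SubsetSpec("random", n_loci=5, replicates=4, seed=1))
        for s in subs:
            assert "L6" not in s.locus_ids

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SubsetSpec("k_most_variable")
        with pytest.raises(ValueError):
            SubsetSpec("bogus", k=1)
        with pytest.raises(ValueError):
            SubsetSpec("random", n_loci=5, replicates=0)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            make_subsets([], SubsetSpec("k_most_variable", k=1))
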