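"""Sequence classification, strand symmetry, culling, filters."""
from collections import Counter
from io import StringIO

import numpy as np
import pytest

from helixmech.curation import (
    END_SENTINEL,
    EnsembleTable,
    InvalidBaseError,
    StepRecord,
    StructureMeta,
    UNIQUE_DIMERS,
    classify_dimer,
    classify_tetramer,
    complement_step,
    cull_3sd,
    filter_by,
    redundancy_filter,
    reverse_complement,
    symmetrize_self_complementary,
)
from helixmech.geometry import StepParameters

ALL_DIMERS = [a + b for a in "ACGT" for b in "ACGT"]


def record(dimer="AA", params=(0, 0, 34, 0, 0, 3.4), context=("A", "A"),
           resolution=2.0, year=2010, structure_id="S1", **flags):
    return StepRecord(
        structure_id=structure_id,
        resolution=resolution,
        year=year,
        dimer=dimer,
        context=context,
        params=StepParameters(*params),
        **flags,
    )


class TestClassifyDimer:
    def test_complementary_pair_shares_group(self):
        assert classify_dimer("CT") == ("AG", True)
        assert classify_dimer("AG") == ("AG", False)

    def test_self_complementary(self):
        assert classify_dimer("TA") == ("TA", False)

    def test_exhaustive_partition(self):
        labels = [classify_dimer(d)[0] for d in ALL_DIMERS]
        sizes = Counter(Counter(labels).values())
        assert len(set(labels)) == 10
        # 6 classes of two dimers, 4 self-complementary singletons
        assert sizes == {2: 6, 1: 4}
        selfc = [d for d in ALL_DIMERS if reverse_complement(d) == d]
        assert sorted(selfc) == ["AT", "CG", "GC", "TA"]

    def test_invalid_base(self):
        with pytest.raises(InvalidBaseError):
            classify_dimer("AX")


class TestClassifyTetramer:
    def test_exhaustive_count(self):
        labels = {
            classify_tetramer(p, a + b, f)
            for p in "ACGT" for a in "ACGT" for b in "ACGT" for f in "ACGT"
        }
        assert len(labels) == 136

    def test_partition_by_central_dimer(self):
        """16 contexts per non-self-complementary dimer, 10 per
        self-complementary one: 136 = 16 x 6 + 10 x 4."""
        by_central = Counter()
        seen = set()
        for p in "ACGT":
            for d in ALL_DIMERS:
                for f in "ACGT":
                    lab = classify_tetramer(p, d, f)
                    if lab not in seen:
                        seen.add(lab)
                        by_central[classify_dimer(lab[1:3])[0]] += 1
        assert sum(by_central.values()) == 136
        for d in UNIQUE_DIMERS:
            expected = 10 if reverse_complement(d) == d else 16
            assert by_central[d] == expected

    def test_reverse_complement_same_label(self):
        assert classify_tetramer("G", "AT", "G") == classify_tetramer("C", "AT", "C")
        assert classify_tetramer("G", "AT", "G") == "CATC"  # min(GATG, CATC)

    def test_class_sizes_one_or_two(self):
        members = Counter(
            classify_tetramer(t[0], t[1:3], t[3])
            for t in ("".join(x) for x in __import__("itertools").product("ACGT", repeat=4))
        )
        assert set(members.values()) <= {1, 2}


class TestComplementStep:
    def test_sign_rule(self):
        r = record("CT", (2, 1.0, 34, 0.5, -0.3, 3.3), context=("G", "A"))
        c = complement_step(r)
        assert c.dimer == "AG"
        assert c.context == ("T", "C")
        assert np.allclose(
            c.params.as_array(), [-2, 1.0, 34, -0.5, -0.3, 3.3]
        )

    def test_involution(self):
        r = record("CT", (2, 1, 34, 0.5, -0.3, 3.3), context=("G", END_SENTINEL))
        assert complement_step(complement_step(r)) == r

    def test_self_complementary_context_mirrored(self):
        r = record("AT", (1.2, 0, 34, -0.3, 0, 3.4), context=("G", "C"))
        c = complement_step(r)
        assert c.dimer == "AT"
        assert c.context == ("G", "C")  # GATC is palindromic
        assert c.params.tilt == -1.2 and c.params.shift == 0.3


class TestSymmetrize:
    def test_both_readings_and_null_means(self):
        recs = [record("TA", (1.2, 2.0, 35, -0.3, 0.1, 3.3)),
                record("TA", (0.4, -1.0, 33, 0.2, 0.0, 3.5))]
        out = symmetrize_self_complementary(recs)
        arr = np.array([r.params.as_array() for r in out])
        assert len(out) == 4
        assert arr[:, 0].mean() == 0.0 and arr[:, 3].mean() == 0.0
        # strand-invariant parameters keep their means
        src = np.array([r.params.as_array() for r in recs])
        assert np.allclose(arr[:, [1, 2, 4, 5]].mean(0), src[:, [1, 2, 4, 5]].mean(0))

    def test_empty_group(self):
        assert symmetrize_self_complementary([]) == []

    def test_rejects_non_self_complementary(self):
        with pytest.raises(ValueError):
            symmetrize_self_complementary([record("AG")])


class TestCull3SD:
    def test_gross_outlier_removed_first_round(self, rng):
        inliers = [record("AA", (0, 0, 34 + x, 0, 0, 3.4))
                   for x in rng.normal(0, 1, 100)]
        outlier = record("AA", (0, 0, 34 + 10.0, 0, 0, 3.4), structure_id="OUT")
        kept, rounds = cull_3sd(inliers + [outlier])
        assert all(r.structure_id != "OUT" for r in kept)

    def test_idempotent_on_clean_set(self, rng):
        recs = [record("AA", (0, 0, 34 + x, 0, 0, 3.4))
                for x in rng.normal(0, 1, 200)]
        kept, _ = cull_3sd(recs)
        kept2, rounds2 = cull_3sd(kept)
        assert len(kept2) == len(kept) and rounds2 == 1

    def test_postcondition_no_z_above_threshold(self, rng):
        draws = rng.normal(0, 1, size=(300, 6)) * [3, 4, 4, 0.4, 0.5, 0.2]
        draws[:20] *= 6  # contaminated tail
        recs = [record("AA", tuple(np.array([0, 0, 34, 0, 0, 3.4]) + d))
                for d in draws]
        kept, rounds = cull_3sd(recs)
        arr = np.array([r.params.as_array() for r in kept])
        sd = arr.std(0)
        z = np.abs(arr - arr.mean(0)) / np.where(sd > 0, sd, 1.0)
        assert z.max() <= 3.0 + 1e-12
        assert len(kept) <= len(recs)

    def test_small_group_returned_unculled(self):
        recs = [record("AA") for _ in range(5)]
        with pytest.warns(UserWarning, match="too small"):
            kept, rounds = cull_3sd(recs)
        assert kept == recs and rounds == 0


class TestRedundancyFilter:
    def meta(self, sid, res, seqs, domains):
        return StructureMeta(sid, res, tuple(seqs), tuple(domains))

    def test_better_resolution_wins(self):
        a = self.meta("A", 1.9, ["ACGTACGTACGTACGTACGT"], ["F1", "H1"])
        b = self.meta("B", 2.5, ["ACGTACGTACGTACGTACGT"], ["F1", "H1"])
        kept = redundancy_filter([a, b])
        assert [m.structure_id for m in kept] == ["A"]

    def test_different_domains_both_kept(self):
        a = self.meta("A", 1.9, ["ACGTACGTACGTACGTACGT"], ["F1"])
        b = self.meta("B", 2.5, ["ACGTACGTACGTACGTACGT"], ["F1", "F1"])
        assert len(redundancy_filter([a, b])) == 2

    def test_below_70_percent_both_kept(self):
        # 14 identical bp, longer length 30: 14/30 < 0.7
        common = "ACGTACGTACGTAC"
        a = self.meta("A", 1.9, [common + "GGGGGG"], ["F1"])
        b = self.meta("B", 2.5, ["TTTTTTTT" + common + "CCCCCCCC"], ["F1"])
        assert len(redundancy_filter([a, b])) == 2

    def test_order_independent(self, rng):
        metas = [
            self.meta("A", 1.9, ["ACGTACGTACGTACGTACGT"], ["F1"]),
            self.meta("B", 2.5, ["ACGTACGTACGTACGTACGT"], ["F1"]),
            self.meta("C", 2.2, ["AAAAAAAACCCCCCCCGGGG"], ["F1"]),
            self.meta("D", 3.0, ["AAAAAAAACCCCCCCCGGGG"], ["F2"]),
        ]
        base = {m.structure_id for m in redundancy_filter(metas)}
        for _ in range(5):
            perm = list(rng.permutation(len(metas)))
            got = {m.structure_id for m in redundancy_filter([metas[i] for i in perm])}
            assert got == base


class TestFilterBy:
    def table(self):
        return EnsembleTable([
            record("AA", resolution=1.8, year=2000),
            record("AA", resolution=2.9, year=2010),
            record("AA", resolution=3.4, year=2020),
        ])

    def test_resolution_limit(self):
        assert len(filter_by(self.table(), max_resolution=3.0)) == 2

    def test_year_before_all_records_is_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            out = filter_by(self.table(), max_year=1990)
        assert len(out) == 0

    def test_combined_is_intersection(self):
        t = self.table()
        both = filter_by(t, max_resolution=3.0, max_year=2005)
        res_only = {id(r) for r in filter_by(t, max_resolution=3.0).records}
        year_only = {id(r) for r in filter_by(t, max_year=2005).records}
        assert {id(r) for r in both.records} == res_only & year_only

    def test_provenance_logged(self):
        out = filter_by(self.table(), max_resolution=3.0)
        assert any("filter_by" in ev for ev in out.provenance)


def test_table_tsv_round_trip(small_ensemble):
    buf = StringIO()
    small_ensemble.to_tsv(buf)
    buf.seek(0)
    back = EnsembleTable.from_tsv(buf)
    assert len(back) == len(small_ensemble)
    r0, s0 = back.records[0], small_ensemble.records[0]
    assert (r0.structure_id, r0.dimer, r0.context, r0.year) == (
        s0.structure_id, s0.dimer, s0.context, s0.year
    )
    # text serialization keeps 12+ significant digits
    assert np.allclose(back.params_array(), small_ensemble.params_array(),
                       rtol=0, atol=1e-9)
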