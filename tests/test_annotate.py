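"""isomiR taxonomy, star-arm prediction, and read-cluster classification."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import reverse_complement

from srnapipe.align import TagAlignment
from srnapipe.annotate import (
    call_clusters,
    classify_isomir,
    max_pairing_fold,
    predict_star_interval,
)
from srnapipe.reference import HairpinRecord, MatureAnnotation, extend_hairpins

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def _brute_force_max_pairs(seq: str) -> int:
    """Enumerate all non-crossing pairings with min loop 3 (oracle, n <= 14)."""

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < 4:
            return 0
        out = best(i + 1, j)
        for k in range(i + 4, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                out = max(out, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, len(seq) - 1)


class TestMaxPairingFold:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 15))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        pairs = max_pairing_fold(seq)
        n_pairs = sum(1 for p in pairs if p is not None) // 2
        assert n_pairs == _brute_force_max_pairs(seq)
        for i, j in enumerate(pairs):  # structural sanity of the traceback
            if j is not None:
                assert pairs[j] == i and abs(j - i) >= 4
                lo, hi = min(i, j), max(i, j)
                assert (seq[lo], seq[hi]) in _PAIRS

    def test_pairing_is_non_crossing(self):
        rng = np.random.default_rng(40)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        pairs = max_pairing_fold(seq)
        opened = []
        for i, j in enumerate(pairs):
            if j is None:
                continue
            if j > i:
                opened.append(j)
            else:
                assert opened.pop() == i


def _perfect_hairpin(arm: str, loop: str) -> HairpinRecord:
    seq = arm + loop + reverse_complement(arm)
    return HairpinRecord(
        hairpin_id="hp1",
        sequence=seq,
        contig="chr1",
        start=1,
        end=len(seq),
        strand="+",
    )


class TestPredictStarInterval:
    def test_perfect_inverted_repeat_gives_mirrored_interval_with_overhang(self):
        """On a perfect duplex, the star of mature [s, e) is the mirrored
        interval [H - e + 2, H - s + 2): same length, 2-nt 3' overhangs on
        both ends (manual pair-mapping oracle)."""
        rng = np.random.default_rng(13)
        arm = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        hp = _perfect_hairpin(arm, "TTTTTTTTTT")
        H = len(hp.sequence)
        mature = MatureAnnotation("m", "5p", (2, 24), hp.sequence[2:24])
        star = predict_star_interval(hp, mature)
        assert star == (H - 24 + 2, H - 2 + 2)

    def test_mature_spanning_whole_hairpin_has_no_star(self):
        rng = np.random.default_rng(14)
        arm = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        hp = _perfect_hairpin(arm, "TTTT")
        mature = MatureAnnotation("m", "5p", (0, len(hp.sequence)), hp.sequence)
        assert predict_star_interval(hp, mature) is None

    def test_sequence_without_self_complementarity_has_no_star(self):
        seq = "ACACACACACACACACACACACACACACAC"  # A/C only: no AU, CG or GU pairs
        hp = HairpinRecord("hp1", seq, "chr1", 1, len(seq), "+")
        mature = MatureAnnotation("m", "5p", (0, 15), seq[:15])
        assert predict_star_interval(hp, mature) is None


def _aln(tag: str, pos: int, mm: int = 0, mmpos=()) -> TagAlignment:
    return TagAlignment(tag, "hp1", pos, "+", mm, tuple(mmpos))


class TestClassifyIsomir:
    MATURE_SEQ = "ACGTACGTACGTACGTACGTAC"  # 22-mer
    MATURE = MatureAnnotation("miR-x", "5p", (10, 32), MATURE_SEQ)
    INTERVAL = (40, 62)  # extended-local

    def test_exact_match(self):
        rec = classify_isomir(_aln(self.MATURE_SEQ, 40), self.MATURE, self.INTERVAL)
        assert (rec.category, rec.region, rec.delta5, rec.delta3) == ("exact", "none", 0, 0)

    def test_two_longer_at_three_prime(self):
        rec = classify_isomir(
            _aln(self.MATURE_SEQ + "GG", 40), self.MATURE, self.INTERVAL
        )
        assert (rec.category, rec.region, rec.delta3) == ("shorter_longer", "3p_end", 2)

    def test_shorter_at_five_prime(self):
        rec = classify_isomir(_aln(self.MATURE_SEQ[1:], 41), self.MATURE, self.INTERVAL)
        assert (rec.category, rec.region, rec.delta5) == ("shorter_longer", "5p_end", 1)

    def test_mismatches_in_both_halves(self):
        """Substitutions at tag positions 3 and 20 of a 22-mer: the midpoint
        rule places one in each half -> region 'both'."""
        rec = classify_isomir(
            _aln(self.MATURE_SEQ, 40, mm=2, mmpos=(3, 20)), self.MATURE, self.INTERVAL
        )
        assert (rec.category, rec.region) == ("mismatch2", "both")

    def test_single_mismatch_in_five_prime_half(self):
        rec = classify_isomir(
            _aln(self.MATURE_SEQ, 40, mm=1, mmpos=(4,)), self.MATURE, self.INTERVAL
        )
        assert (rec.category, rec.region) == ("mismatch1", "5p_end")

    def test_offset_beyond_two_is_not_isomir(self):
        assert classify_isomir(_aln(self.MATURE_SEQ, 43), self.MATURE, self.INTERVAL) is None

    def test_no_overlap_is_not_isomir(self):
        assert classify_isomir(_aln(self.MATURE_SEQ, 80), self.MATURE, self.INTERVAL) is None


def _toy_extended(two_arms: bool = True):
    rng = np.random.default_rng(23)
    arm = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
    loop = "".join("ACGT"[i] for i in rng.integers(0, 4, 12))
    seq = arm + loop + reverse_complement(arm)
    H = len(seq)
    m5 = (2, 24)
    m3 = (H - 24 + 2, H - 2 + 2)
    matures = [MatureAnnotation("miR-t-5p", "5p", m5, seq[m5[0] : m5[1]])]
    if two_arms:
        matures.append(MatureAnnotation("miR-t-3p", "3p", m3, seq[m3[0] : m3[1]]))
    genome_seq = (
        "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        + seq
        + "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
    )
    hp = HairpinRecord("mir-t", seq, "chr1", 101, 100 + H, "+", matures)
    (ext,) = extend_hairpins([hp], {"chr1": genome_seq}, flank=30)
    return ext


class TestCallClusters:
    def test_upstream_cluster_becomes_five_prime_mor(self):
        ext = _toy_extended()
        m5_ext = 2 + 30
        tag = ext.sequence[m5_ext - 21 : m5_ext]
        totals = pd.Series({tag: 50})
        feats, unassigned = call_clusters(
            ext, [(tag, m5_ext - 21, m5_ext)], totals, None, None
        )
        assert len(feats) == 1 and not unassigned
        assert feats[0].klass == "moRNA"
        assert feats[0].feature_id == "moR-t-5p"
        assert feats[0].arm == "5p"

    def test_clusters_on_both_flanks_give_two_mornas(self):
        ext = _toy_extended()
        m5_ext = 2 + 30
        m3_end_ext = ext.mature_intervals_extended()["miR-t-3p"][1]
        up = ext.sequence[m5_ext - 21 : m5_ext]
        down = ext.sequence[m3_end_ext : m3_end_ext + 21]
        totals = pd.Series({up: 40, down: 30})
        feats, _ = call_clusters(
            ext,
            [(up, m5_ext - 21, m5_ext), (down, m3_end_ext, m3_end_ext + 21)],
            totals,
            None,
            None,
        )
        assert sorted(f.feature_id for f in feats) == ["moR-t-3p", "moR-t-5p"]
        assert {f.arm for f in feats} == {"5p", "3p"}

    def test_cluster_at_star_interval_named_after_mature(self):
        ext = _toy_extended(two_arms=False)
        star_local = predict_star_interval(ext.hairpin, ext.hairpin.matures[0])
        star = (star_local[0] + ext.offset, star_local[1] + ext.offset)
        tag = ext.sequence[star[0] : star[1]]
        totals = pd.Series({tag: 60})
        feats, _ = call_clusters(
            ext, [(tag, star[0], star[1])], totals, star, "miR-t-5p"
        )
        assert len(feats) == 1
        assert feats[0].klass == "new_miRNA"
        assert feats[0].feature_id == "miR-t-5p*"

    def test_cluster_below_count_floor_unassigned(self):
        ext = _toy_extended()
        m5_ext = 2 + 30
        tag = ext.sequence[m5_ext - 21 : m5_ext]
        totals = pd.Series({tag: 9})
        feats, unassigned = call_clusters(
            ext, [(tag, m5_ext - 21, m5_ext)], totals, None, None
        )
        assert not feats and unassigned == {tag: "cluster_below_count_floor"}


class TestCataloguePartition:
    def test_every_kept_tag_assigned_once_or_unassigned_with_reason(self, small_study):
        cat = small_study.catalogue
        assigned: dict[str, int] = {}
        for feat in cat.features:
            for tag in feat.tags:
                assigned[tag] = assigned.get(tag, 0) + 1
        assert all(n == 1 for n in assigned.values())
        kept = {t for t, v in small_study.verdicts.items() if v.status == "kept"}
        # every kept tag is in exactly one feature or unassigned-with-reason;
        # discarded/unaligned tags appear in the unassigned map with their status
        assert kept <= set(assigned) | set(cat.unassigned)
        assert set(assigned) <= kept
        assert set(assigned).isdisjoint(cat.unassigned)
        for tag, verdict in small_study.verdicts.items():
            if verdict.status != "kept":
                assert cat.unassigned[tag] == verdict.status

    def test_classification_invariant_to_tag_order(self, small_study):
        from srnapipe.annotate import annotate

        tags_rev = small_study.tags.iloc[::-1]
        verdicts_rev = dict(reversed(list(small_study.verdicts.items())))
        cat2 = annotate(small_study.index, verdicts_rev, tags_rev)
        key = lambda f: (f.feature_id, f.klass, f.interval, tuple(sorted(f.tags)))
        assert sorted(map(key, cat2.features)) == sorted(
            map(key, small_study.catalogue.features)
        )

    def test_mismatch_isomirs_never_in_region_none(self, small_study):
        for rec in small_study.catalogue.isomirs:
            if rec.category.startswith("mismatch"):
                assert rec.region != "none"
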