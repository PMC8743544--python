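"""Structural stage: ORF calling, origin-spanning merge, sORFs, filtering."""

import random

import pytest

from prokannot import structural
from prokannot.fixtures import STOPPER, make_replicon
from prokannot.model import FeatureClass, reverse_complement, translate
from prokannot.refdb import compute_digest
from prokannot.structural import (
    SpuriousFilterError,
    extract_sorfs,
    filter_spurious,
    ingest_cds,
    merge_edge_cds,
    naive_orf_call,
)
from prokannot.model import Genome


# ---------------------------------------------------------------------------
# Independent brute-force six-frame ORF oracle (index arithmetic with
# explicit wrapping; no shared code with the implementation's scanner).
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_STARTS = {"ATG", "GTG", "TTG"}


def _codon_at(seq, pos, circular):
    L = len(seq)
    if not circular and pos + 3 > L:
        return None
    return "".join(seq[(pos + k) % L] for k in range(3))


def oracle_orfs(seq, circular, min_aa, max_aa_exclusive=None,
                longest_per_stop=False):
    """All (start, unwrapped stop, strand) ORFs by per-position walking."""
    L = len(seq)
    found = []
    for strand in ("+", "-"):
        s_seq = seq if strand == "+" else reverse_complement(seq)
        for s in range(L):
            if _codon_at(s_seq, s, circular) not in _STARTS:
                continue
            k = 1
            while 3 * (k + 1) <= L:
                codon = _codon_at(s_seq, s + 3 * k, circular)
                if codon is None:
                    break
                if codon in _STOPS:
                    if k >= min_aa and (max_aa_exclusive is None
                                        or k < max_aa_exclusive):
                        found.append((s, s + 3 * k + 3, strand))
                    break
                k += 1
    if longest_per_stop:
        best = {}
        for s, e, strand in found:
            key = (e % L, strand)
            if key not in best or (e - s) > (best[key][1] - best[key][0]):
                best[key] = (s, e, strand)
        found = list(best.values())
    # map to forward coordinates as (start, stop, strand)
    out = set()
    for s, e, strand in found:
        if strand == "+":
            out.add((s, e, "+"))
        else:
            start = (L - e) % L
            out.add((start, start + (e - s), "-"))
    return out


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestNaiveOrfCall:
    def test_planted_orf(self):
        rep = make_replicon(STOPPER + "ATGGGTAAATAA" + STOPPER)
        orfs = naive_orf_call(rep, min_aa=2)
        assert [(f.aa, f.strand) for f in orfs] == [("MGK", "+")]

    def test_all_n_sequence(self):
        rep = make_replicon("N" * 300)
        assert naive_orf_call(rep, min_aa=1) == []

    @pytest.mark.parametrize("circular", [False, True])
    def test_matches_brute_force_oracle(self, circular):
        rng = random.Random(31 if circular else 13)
        for _ in range(15):
            rep = make_replicon(random_seq(rng, 3000), circular=circular)
            got = {(f.start, f.stop, f.strand)
                   for f in naive_orf_call(rep, min_aa=20)}
            expected = oracle_orfs(rep.seq, circular, 20,
                                   longest_per_stop=True)
            assert got == expected

    def test_proteins_translate_cleanly(self):
        rng = random.Random(8)
        rep = make_replicon(random_seq(rng, 5000), circular=True)
        for f in naive_orf_call(rep, min_aa=10):
            assert f.aa == translate(f.nt)
            assert len(f.nt) == f.stop - f.start


class TestExtractSorfs:
    def _planted(self, n_codons):
        body = "ATG" + "GGT" * (n_codons - 1) + "TAA"
        return make_replicon(STOPPER + body + STOPPER)

    def test_29_aa_included_30_excluded(self):
        found29 = extract_sorfs(self._planted(29))
        assert any(len(f.aa) == 29 for f in found29)
        found30 = extract_sorfs(self._planted(30))
        assert not any(len(f.aa) == 30 for f in found30)

    def test_feature_class_is_sorf(self):
        for f in extract_sorfs(self._planted(20)):
            assert f.feature_class is FeatureClass.SORF
            assert len(f.aa) < 30

    @pytest.mark.parametrize("circular", [False, True])
    def test_matches_brute_force_oracle(self, circular):
        rng = random.Random(77 if circular else 71)
        for _ in range(15):
            rep = make_replicon(random_seq(rng, 3000), circular=circular)
            got = {(f.start, f.stop, f.strand) for f in extract_sorfs(rep)}
            expected = oracle_orfs(rep.seq, circular, 7, 30)
            assert got == expected

    def test_rotation_invariance(self):
        rng = random.Random(3)
        seq = random_seq(rng, 2001)
        rep = make_replicon(seq, circular=True)
        proteins = sorted(f.aa for f in extract_sorfs(rep))
        for shift in (1, 500, 1999):
            rotated = make_replicon(seq[shift:] + seq[:shift], circular=True)
            assert sorted(f.aa for f in extract_sorfs(rotated)) == proteins


class TestMergeEdgeCds:
    def _edge_fixture(self, circular=True):
        rng = random.Random(17)
        aa = "M" + "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(81))
        from prokannot.fixtures import _reverse_translate

        nt = _reverse_translate(rng, aa)  # 249 nt: 82 aa + stop
        filler = (STOPPER * 225)[: 3000 - 249]
        seq = nt[99:] + filler + nt[:99]  # head 150 bp | ... | tail 99 bp
        rep = make_replicon(seq, circular=circular, replicon_id="c1")
        L = rep.length
        from prokannot.model import CdsFeature

        tail = CdsFeature(id="tail", replicon_id="c1", start=L - 99, stop=L,
                          strand="+", partial3=True, nt=nt[:99],
                          aa=translate(nt[:99]))
        head = CdsFeature(id="head", replicon_id="c1", start=0, stop=150,
                          strand="+", partial5=True, nt=nt[99:],
                          aa=translate(nt[99:], partial5=True))
        return rep, tail, head, nt

    def test_merge_recovers_planted_gene(self):
        rep, tail, head, nt = self._edge_fixture()
        merged = merge_edge_cds([tail, head], rep)
        assert len(merged) == 1
        feat = merged[0]
        assert feat.edge
        assert feat.start == rep.length - 99
        assert feat.stop == rep.length + 150
        assert feat.nt == nt
        assert len(feat.aa) == 82  # 249/3 - 1
        assert len(feat.nt) == len(tail.nt) + len(head.nt)

    def test_linear_replicon_unchanged(self):
        rep, tail, head, _ = self._edge_fixture(circular=False)
        merged = merge_edge_cds([tail, head], rep)
        assert sorted(f.id for f in merged) == ["head", "tail"]

    def test_opposite_strands_not_merged(self):
        rep, tail, head, _ = self._edge_fixture()
        head.strand = "-"
        head.nt = reverse_complement(head.nt)
        merged = merge_edge_cds([tail, head], rep)
        assert sorted(f.id for f in merged) == ["head", "tail"]

    def test_unclean_merge_abandoned(self):
        rep, tail, head, _ = self._edge_fixture()
        tail.nt = tail.nt[:-1]  # break the frame
        log = []
        merged = merge_edge_cds([tail, head], rep, log=log)
        assert sorted(f.id for f in merged) == ["head", "tail"]
        assert any("abandoned" in line for line in log)


class TestIngest:
    def _genome(self):
        seq = STOPPER + "ATGGGTAAATAA" + STOPPER * 2
        return Genome(replicons=[make_replicon(seq, replicon_id="r1")])

    def _write(self, tmp_path, lines):
        path = tmp_path / "in.gff3"
        path.write_text("##gff-version 3\n" + "".join(
            line + "\n" for line in lines))
        return path

    def test_coordinate_conversion_and_translation(self, tmp_path):
        genome = self._genome()
        path = self._write(tmp_path, [
            "r1\tsrc\tCDS\t13\t24\t.\t+\t0\tID=g1"])
        feats, rejects = ingest_cds(path, genome)
        assert rejects == []
        assert (feats[0].start, feats[0].stop) == (12, 24)
        assert feats[0].aa == "MGK"

    def test_minus_strand_reverse_complement(self, tmp_path):
        genome = self._genome()
        path = self._write(tmp_path, [
            "r1\tsrc\tCDS\t13\t24\t.\t-\t0\tID=g1"])
        feats, _ = ingest_cds(path, genome)
        rep = genome.replicons[0]
        assert feats[0].nt == reverse_complement(rep.seq[12:24])

    def test_internal_stop_rejected_with_report(self, tmp_path):
        genome = self._genome()
        # 13..27 reads ATGGGTAAATAA + TTA: internal TAA stop
        path = self._write(tmp_path, [
            "r1\tsrc\tCDS\t13\t27\t.\t+\t0\tID=bad"])
        feats, rejects = ingest_cds(path, genome)
        assert feats == []
        assert rejects[0][0] == "bad"
        assert "stop" in rejects[0][1]

    def test_unknown_replicon_raises(self, tmp_path):
        genome = self._genome()
        path = self._write(tmp_path, [
            "nope\tsrc\tCDS\t13\t24\t.\t+\t0\tID=g1"])
        with pytest.raises((ValueError, KeyError)):
            ingest_cds(path, genome)


class TestFilterSpurious:
    def _features(self):
        rep = make_replicon(STOPPER + "ATGGGTAAATAA" + "ATGTGGTAA" + STOPPER)
        return naive_orf_call(rep, min_aa=2)

    def test_blocklist_backend(self, tmp_path, ref_manifest, ref_db):
        from prokannot.structural import blocklist_backend

        feats = self._features()
        backend = blocklist_backend(ref_db)
        assert filter_spurious(feats, backend) == feats  # none blocked

        spurious_aa = ref_manifest["spurious"][0]
        assert backend(spurious_aa) is not None

    def test_stub_backend_removes_exactly_flagged(self):
        feats = self._features()
        log = []
        kept = filter_spurious(
            feats, lambda aa: "has W" if "W" in aa else None, log=log)
        assert all("W" not in f.aa for f in kept)
        assert len(kept) + len(log) == len(feats)
        assert len(log) == sum(1 for f in feats if "W" in f.aa) > 0

    def test_empty_backend_is_identity(self):
        feats = self._features()
        assert filter_spurious(feats, lambda aa: None) == feats

    def test_backend_failure_aborts(self):
        def broken(aa):
            raise RuntimeError("backend down")

        with pytest.raises(SpuriousFilterError, match="backend"):
            filter_spurious(self._features(), broken)
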