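"""Cloverleaf folding, identity assignment and rescue of absent tRNAs."""

import numpy as np
import pytest

import mitoglyph as mg
from mitoglyph.trna import VALID_PAIRS

from conftest import mutate_seq

# ---------------------------------------------------------------------------
# Independent brute-force oracle over the same placement grid: plain nested
# loops, no shared code with the implementation.

ACC = (6, 7)
SP1 = (1, 2, 3)
DSTEM = (3, 4)
DLOOP = range(3, 11)
SP2 = (0, 1, 2)
CSTEM = (4, 5)
VAR = range(3, 10)
TSTEM = (3, 4, 5)
TLOOP = range(3, 10)


def _oracle_fold(seq):
    """Best passing placement by exhaustive enumeration, or None."""
    n = len(seq)

    def stem_valid(i5, j3, k):
        # 5' side starts at i5, 3' side *ends* at j3 (exclusive), k pairs
        return sum(seq[i5 + x] + seq[j3 - 1 - x] in VALID_PAIRS
                   for x in range(k))

    best = None
    dhu_choices = [None] + [(d, dl) for d in DSTEM for dl in DLOOP]
    for a in ACC:
        for s1 in SP1:
            for dhu in dhu_choices:
                dlen = 0 if dhu is None else 2 * dhu[0] + dhu[1]
                for s2 in SP2:
                    for c in CSTEM:
                        for t in TSTEM:
                            for tl in TLOOP:
                                v = n - (2 * a + s1 + dlen + s2
                                         + 2 * c + 7 + 2 * t + tl)
                                if not 3 <= v <= 9:
                                    continue
                                valid = stem_valid(0, n, a)
                                pairs = a + c + t
                                pos = a + s1
                                if dhu is not None:
                                    valid += stem_valid(pos, pos + dlen,
                                                        dhu[0])
                                    pairs += dhu[0]
                                    pos += dlen
                                pos += s2
                                valid += stem_valid(pos, pos + 2 * c + 7, c)
                                tpos = pos + 2 * c + 7 + v
                                valid += stem_valid(tpos, tpos + 2 * t + tl,
                                                    t)
                                if valid < (18 if dhu else 14):
                                    continue
                                mism = pairs - valid
                                score = valid - mism - (0 if dhu else 2)
                                anticodon = seq[pos + c + 2:pos + c + 5]
                                key = (score, valid, -mism, dhu is not None)
                                if best is None or key > best[0]:
                                    best = (key, anticodon)
    return best


@pytest.fixture(scope="module")
def perfect_trna():
    """A generated 4-arm tRNA with fully Watson-Crick stems."""
    g = mg.generate(mg.GenomeSpec.camelliae_like(seed=7))
    return g.truth["trna_templates"]["trnM"]["sequence"]


class TestFold:
    def test_perfect_cloverleaf_has_no_mismatches(self, perfect_trna):
        st = mg.fold_trna(perfect_trna)
        assert st is not None
        assert st.mismatch_count == 0
        assert st.score == st.valid_pairs
        assert st.has_DHU
        assert len(st.arms) == 4

    def test_dhu_less_template_folds_three_armed(self, synthetic_genome):
        seq = synthetic_genome.truth["trna_templates"]["trnS2"]["sequence"]
        assert len(seq) == 56
        st = mg.fold_trna(seq)
        assert st is not None
        assert not st.has_DHU
        assert len(st.arms) == 3

    def test_non_acgt_rejected_without_flag(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            mg.fold_trna("ACGTN" * 14)
        # with the flag the scan proceeds (ambiguous pairs just mismatch)
        mg.fold_trna("ACGTN" * 14, allow_ambiguity=True)

    def test_matches_exhaustive_oracle_on_random_and_mutated(self):
        """fold_trna equals brute-force enumeration over the same grid.

        100 random 60-75-mers plus 100 planted tRNAs carrying 0-6 point
        mutations, fixed seed.
        """
        rng = np.random.default_rng(42)
        genome = mg.generate(mg.GenomeSpec.camelliae_like(seed=13))
        templates = [t["sequence"]
                     for t in genome.truth["trna_templates"].values()]
        cases = []
        for _ in range(100):
            n = int(rng.integers(60, 76))
            cases.append("".join(rng.choice(list("ACGT"), size=n)))
        for k in range(100):
            seq = list(templates[k % len(templates)])
            for _ in range(int(rng.integers(0, 7))):
                i = int(rng.integers(0, len(seq)))
                seq[i] = str(rng.choice(list("ACGT")))
            cases.append("".join(seq))
        n_folded = 0
        for seq in cases:
            got = mg.fold_trna(seq)
            want = _oracle_fold(seq)
            if want is None:
                assert got is None
            else:
                (score, valid, neg_mism, has_dhu), anticodon = want
                assert got is not None
                assert (got.score, got.valid_pairs, -got.mismatch_count,
                        got.has_DHU) == (score, valid, neg_mism, has_dhu)
                n_folded += 1
        assert n_folded >= 80, "mutated templates should mostly still fold"


class TestIdentity:
    @pytest.mark.parametrize("anticodon, gene", [
        ("CAT", "trnM"), ("TCA", "trnW"), ("TGA", "trnS2"), ("TCT", "trnS1"),
        ("TAG", "trnL1"), ("TAA", "trnL2"), ("GAT", "trnI"), ("GTG", "trnH"),
    ])
    def test_anticodon_to_gene(self, anticodon, gene):
        from mitoglyph.vocab import identity_from_anticodon
        assert identity_from_anticodon(anticodon) == gene

    def test_stop_decoding_anticodon_is_unknown(self):
        from mitoglyph.vocab import identity_from_anticodon
        assert identity_from_anticodon("TTA") == "unknown"   # codon TAA

    def test_assign_identity_on_folded_structure(self, perfect_trna):
        st = mg.fold_trna(perfect_trna)
        ident = mg.assign_identity(st)
        assert ident.gene == "trnM"
        assert ident.anticodon == "CAT"
        assert set(ident.codon_family) == {"ATA", "ATG"}


class TestMismatchCensus:
    def test_additivity(self, perfect_trna):
        st = mg.fold_trna(perfect_trna)
        assert mg.mismatch_census([st, st]) == 2 * st.mismatch_count

    def test_all_perfect_set_is_zero(self, synthetic_genome):
        ann = synthetic_genome.annotation
        structures = [mg.fold_trna(mg.extract_region(ann, r))
                      for r in ann.by_class("tRNA")]
        assert all(s is not None for s in structures)
        assert mg.mismatch_census(structures) == 0


class TestRescue:
    def test_empty_targets_empty_result(self, synthetic_genome):
        assert mg.rescue_scan(synthetic_genome.annotation, set()) == []

    def test_planted_trnI_recovered_at_locus(self):
        """An unannotated trnI in a gap is rescued within 2 bp."""
        spec = mg.GenomeSpec.camelliae_like(seed=31)
        i = next(k for k, p in enumerate(spec.genes) if p.name == "trnM")
        spec.genes.insert(i, mg.PlannedGene("trnI", 66, 20))
        spec.deletions = [mg.Deletion("trnI", "unannotated")]
        genome = mg.generate(spec)
        rng = np.random.default_rng(31)
        refs = {"trnI": mutate_seq(
            genome.truth["trna_templates"]["trnI"]["sequence"], rng)}
        cands = mg.rescue_scan(genome.annotation, {"trnI"}, refs=refs)
        assert len(cands) == 1
        truth = next(t for t in genome.truth["genes"] if t["name"] == "trnI")
        assert abs(cands[0].record.start - truth["start"]) <= 2
        assert abs(cands[0].record.end - truth["end"]) <= 2
        assert cands[0].record.anticodon == "GAT"

    def test_planted_trnN_in_gap_recovered_with_anticodon(self):
        """trnN unannotated behind its 47-bp gap is recovered as ATT."""
        spec = mg.GenomeSpec.camelliae_like(seed=33)
        spec.deletions = [mg.Deletion("trnN", "unannotated")]
        genome = mg.generate(spec)
        rng = np.random.default_rng(33)
        refs = {"trnN": mutate_seq(
            genome.truth["trna_templates"]["trnN"]["sequence"], rng)}
        cands = mg.rescue_scan(genome.annotation, {"trnN"}, refs=refs)
        assert len(cands) == 1
        assert cands[0].record.anticodon == "ATT"
        truth = next(t for t in genome.truth["genes"] if t["name"] == "trnN")
        assert abs(cands[0].record.start - truth["start"]) <= 2

    def test_minus_strand_gene_recovered_on_its_strand(self):
        """Scanning both strands finds a reverse-strand tRNA with the same
        identity its forward fold would give."""
        spec = mg.GenomeSpec.camelliae_like(seed=37)
        spec.deletions = [mg.Deletion("trnH", "unannotated")]
        genome = mg.generate(spec)
        cands = mg.rescue_scan(genome.annotation, {"trnH"})
        best = max(cands, key=lambda c: c.score)
        assert best.record.strand == "-"
        assert best.record.name == "trnH"

    def test_sequence_required(self, camelliae):
        with pytest.raises(ValueError, match="sequence required"):
            mg.rescue_scan(camelliae, {"trnI"})
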