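import itertools

import pytest
from hypothesis import given, strategies as st

from mitoprofile.annotation import (breakpoint_count, classify_codons,
                                    count_pair_types, gene_order,
                                    gene_order_string, junctions,
                                    read_structure_file, validate_orf)
from mitoprofile.model import GenomeRecord, make_feature
from mitoprofile.vocab import ANCESTRAL_INSECT_ORDER, Strand


def linear_record(seq, feats):
    return GenomeRecord("toy", seq, is_circular=False, is_complete=False,
                        features=feats)


class TestGeneOrder:
    def test_synthetic_matches_ancestral(self, sim_record):
        assert gene_order(sim_record) == ANCESTRAL_INSECT_ORDER

    def test_rotation_invariance(self, sim_record):
        rotated = sim_record.rotated(5000)
        assert gene_order(rotated) == ANCESTRAL_INSECT_ORDER

    def test_signed_string(self, sim_record):
        s = gene_order_string(sim_record)
        assert s.startswith("trnI -trnQ trnM ND2")

    def test_swap_gives_breakpoints(self):
        order = tuple(ANCESTRAL_INSECT_ORDER)
        swapped = list(order)
        swapped[3], swapped[4] = swapped[4], swapped[3]  # ND2 <-> trnW
        swapped = tuple(swapped)
        assert swapped != order

        # independent oracle: brute-force adjacency comparison
        def adjacency_pairs(o):
            names = [n for n, _ in o]
            return {frozenset((names[i], names[(i + 1) % len(names)]))
                    for i in range(len(names))}

        expected = len(adjacency_pairs(swapped) - adjacency_pairs(order))
        assert expected == 2
        assert breakpoint_count(swapped, order) == expected

    def test_identical_orders_zero_breakpoints(self):
        assert breakpoint_count(ANCESTRAL_INSECT_ORDER,
                                ANCESTRAL_INSECT_ORDER) == 0


class TestJunctions:
    def test_abutting(self):
        rec = linear_record("A" * 20, [make_feature("trnI", "J", 0, 10),
                                       make_feature("trnM", "J", 10, 20)])
        rep = junctions(rec)
        assert len(rep.entries) == 1
        assert rep.entries[0].relation == "abutting"
        assert rep.entries[0].length == 0

    def test_overlap_and_spacer(self):
        rec = linear_record("A" * 40, [make_feature("trnI", "J", 0, 12),
                                       make_feature("trnM", "J", 9, 21),
                                       make_feature("trnW", "J", 26, 38)])
        rep = junctions(rec)
        assert [(e.relation, e.length) for e in rep.entries] == [
            ("overlap", 3), ("spacer", 5)]
        assert rep.extent("overlap") == (3, 3)

    def test_linear_count_is_n_minus_1(self, default_sim):
        from mitoprofile.simulate import degrade
        rec, man = default_sim
        degraded, _ = degrade(rec, man, "drop_cr")
        rep = junctions(degraded, include_cr=True)
        assert len(rep.entries) == len(degraded.features) - 1

    def test_circular_count_is_n(self, sim_record):
        rep = junctions(sim_record, include_cr=True)
        assert len(rep.entries) == len(sim_record.features)

    def test_cr_junctions_excluded_by_default(self, sim_record):
        rep = junctions(sim_record)
        names = {e.upstream for e in rep.entries} | {
            e.downstream for e in rep.entries}
        assert "CR" not in names
        assert len(rep.entries) == len(sim_record.features) - 2

    def test_nested_feature_warns(self):
        rec = linear_record("A" * 40, [make_feature("trnI", "J", 0, 30),
                                       make_feature("trnM", "J", 5, 15),
                                       make_feature("trnW", "J", 30, 40)])
        with pytest.warns(UserWarning, match="nested"):
            rep = junctions(rec)
        nested = rep.entries[0]
        assert nested.relation == "overlap"
        assert nested.length == 10  # the shorter feature's full length

    def test_conservation_identity(self, sim_record):
        rep = junctions(sim_record, include_cr=True)
        total = (sum(len(f) for f in sim_record.features)
                 - sum(e.length for e in rep.overlaps)
                 + sum(e.length for e in rep.spacers))
        assert total == len(sim_record.sequence)

    def test_orientation_antisymmetry(self, sim_record):
        """Reversing the record preserves junction lengths and relations."""
        from mitoprofile.model import reverse_complement
        L = len(sim_record.sequence)
        flipped_feats = []
        for f in sim_record.features:
            start, end = L - f.end, L - f.start
            if start < 0:  # unwrapped feature: shift into range
                start, end = start + L, end + L
            strand = Strand.N if f.strand == Strand.J else Strand.J
            flipped_feats.append(make_feature(f.name, strand, start, end))
        flipped = GenomeRecord("flipped",
                               reverse_complement(sim_record.sequence),
                               is_circular=True, is_complete=True,
                               features=flipped_feats)
        fwd = junctions(sim_record, include_cr=True)
        rev = junctions(flipped, include_cr=True)
        fwd_set = sorted((tuple(sorted((e.upstream, e.downstream))),
                          e.relation, e.length) for e in fwd.entries)
        rev_set = sorted((tuple(sorted((e.upstream, e.downstream))),
                          e.relation, e.length) for e in rev.entries)
        assert fwd_set == rev_set


class TestClassifyCodons:
    def test_canonical_toy(self):
        rec = linear_record("ATGAAATAA", [make_feature("ATP8", "J", 0, 9)])
        (call,) = classify_codons(rec)
        assert call.start_codon == "ATG"
        assert call.start_class == "canonical_ATN"
        assert call.stop_codon == "TAA"
        assert call.stop_class == "complete"

    def test_partial_t(self):
        rec = linear_record("ATGAAAT", [make_feature("COX2", "J", 0, 7)])
        (call,) = classify_codons(rec)
        assert call.stop_codon == "T" and call.stop_class == "partial"

    def test_partial_ta(self):
        rec = linear_record("ATGAAATA", [make_feature("COX2", "J", 0, 8)])
        (call,) = classify_codons(rec)
        assert call.stop_codon == "TA" and call.stop_class == "partial"

    def test_noncanonical_start(self):
        rec = linear_record("TCGAAATAA", [make_feature("COX1", "J", 0, 9)])
        (call,) = classify_codons(rec)
        assert call.start_class == "noncanonical"

    def test_anomalous_terminus_warns_not_raises(self):
        rec = linear_record("ATGAAAA", [make_feature("ATP8", "J", 0, 7)])
        with pytest.warns(UserWarning, match="anomalous"):
            (call,) = classify_codons(rec)
        assert call.stop_class == "anomalous"
        assert call.stop_codon is None

    def test_frame_offset_respected(self):
        rec = linear_record("CCATGAAATAA",
                            [make_feature("ATP8", "J", 0, 11, frame_offset=2)])
        (call,) = classify_codons(rec)
        assert call.start_codon == "ATG"
        assert call.stop_codon == "TAA"

    def test_short_pcg_errors(self):
        rec = linear_record("ATGAA", [make_feature("ATP8", "J", 0, 5)])
        with pytest.raises(ValueError, match="shorter"):
            classify_codons(rec)

    def test_n_strand_gene(self):
        # sense ATGAAATAA on N strand -> J-strand carries its revcomp
        rec = linear_record("TTATTTCAT", [make_feature("ND1", "N", 0, 9)])
        (call,) = classify_codons(rec)
        assert call.start_codon == "ATG" and call.stop_codon == "TAA"

    def test_rotation_invariance(self, sim_record):
        base = classify_codons(sim_record)
        rotated = classify_codons(sim_record.rotated(7777))
        key = lambda c: c.gene
        assert sorted(base, key=key) == sorted(rotated, key=key)

    def test_matches_manifest(self, default_sim):
        record, manifest = default_sim
        assert classify_codons(record) == manifest.codon_calls


class TestValidateOrf:
    def test_clean(self):
        rec = linear_record("ATGAAATAA", [make_feature("ATP8", "J", 0, 9)])
        assert validate_orf(rec, "ATP8") == 0

    def test_internal_stop(self):
        rec = linear_record("ATGTAAAAATAA", [make_feature("ATP8", "J", 0, 12)])
        assert validate_orf(rec, "ATP8") == 1

    def test_non_pcg_rejected(self, sim_record):
        with pytest.raises(ValueError, match="not a protein-coding"):
            validate_orf(sim_record, "trnI")

    def test_all_simulated_pcgs_clean(self, sim_record):
        from mitoprofile.vocab import GeneClass
        for f in sim_record.genes(GeneClass.PCG):
            assert validate_orf(sim_record, f.name) == 0


def oracle_pairs(structure):
    """Independent bracket matcher: repeatedly collapse innermost pairs."""
    pairs = []
    chars = list(structure)
    changed = True
    while changed:
        changed = False
        depth_open = None
        for i, ch in enumerate(chars):
            if ch == "(":
                depth_open = i
            elif ch == ")":
                if depth_open is None:
                    raise ValueError("unbalanced")
                pairs.append((depth_open, i))
                chars[depth_open] = chars[i] = "."
                depth_open = None
                changed = True
                break
    if "(" in chars or ")" in chars:
        raise ValueError("unbalanced")
    return sorted(pairs)


def balanced_structures(length):
    for combo in itertools.product("().", repeat=length):
        s = "".join(combo)
        depth = 0
        ok = True
        for ch in s:
            depth += 1 if ch == "(" else (-1 if ch == ")" else 0)
            if depth < 0:
                ok = False
                break
        if ok and depth == 0 and "(" in s:
            yield s


class TestPairTypes:
    def test_all_wc(self):
        counts = count_pair_types("GGGAAACCC", "(((...)))")
        assert counts.watson_crick == {"C-G": 3}
        assert counts.wobble == 0
        assert counts.mismatch_count() == 0
        assert counts.total == 3

    def test_uu_mismatches(self):
        # five U-U pairs by construction
        seq = "TTTTT" + "AAA" + "TTTTT"
        struct = "(((((...)))))"
        counts = count_pair_types(seq, struct)
        assert counts.mismatch_count("U-U") == 5
        assert counts.total == 5

    def test_wobble(self):
        counts = count_pair_types("GT", "()")
        assert counts.wobble == 1

    def test_t_read_as_u(self):
        counts = count_pair_types("AT", "()")
        assert counts.watson_crick == {"A-U": 1}

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="length"):
            count_pair_types("AAA", "(.")

    def test_unbalanced_error(self):
        with pytest.raises(ValueError, match="unbalanced"):
            count_pair_types("AAA", "(..")
        with pytest.raises(ValueError, match="unbalanced"):
            count_pair_types("AAA", ").(")

    def test_matches_oracle_up_to_length_6(self):
        # exhaustive: every balanced structure up to length 6, fixed sequence
        seq12 = "AUGCUAGGCAUC"
        for L in range(2, 7):
            for struct in balanced_structures(L):
                counts = count_pair_types(seq12[:L], struct)
                assert counts.total == len(oracle_pairs(struct))

    @given(st.integers(0, 2**30))
    def test_random_structures_sum_to_pair_count(self, seed):
        import random
        rng = random.Random(seed)
        n_pairs = rng.randint(1, 6)
        inner = "." * rng.randint(0, 3)
        struct = "(" * n_pairs + inner + ")" * n_pairs
        seq = "".join(rng.choice("ACGU") for _ in struct)
        counts = count_pair_types(seq, struct)
        assert counts.total == n_pairs == len(oracle_pairs(struct))


def test_read_structure_file(tmp_path):
    path = tmp_path / "structs.tsv"
    path.write_text("# comment\ntrnI\tGGGAAACCC\t(((...)))\n")
    records = read_structure_file(path)
    assert records == [("trnI", "GGGAAACCC", "(((...)))")]
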