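"""Primer-site finding and amplicon extraction."""

import numpy as np
import pytest

from peroxscan.insilico_pcr import Amplicon, PrimerPair, amplify, find_sites
from peroxscan.sequence_core import (
    DegeneratePrimer,
    NucRecord,
    bases_compatible,
    expand_degenerate,
    reverse_complement,
)


def concretize(expansion: str, rng) -> str:
    """Replace wildcard Ns of an expansion with concrete bases."""
    return "".join(rng.choice(list("ACGT")) if c == "N" else c for c in expansion)


@pytest.fixture()
def peroxiF2():
    return DegeneratePrimer("peroxiF2", "GGYGGIGGIGCBGAYGGYTC")


class TestFindSites:
    def test_exact_expansion_found_plus_strand(self, peroxiF2, rng):
        exp = concretize(sorted(expand_degenerate(peroxiF2))[0], rng)
        template = NucRecord(id="t", seq="TTTT" + exp + "AAAA")
        sites = find_sites(template, peroxiF2, max_mismatch=0)
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1 and plus[0].position == 4 and plus[0].mismatches == 0

    def test_reverse_strand_site(self, peroxiF2, rng):
        exp = concretize(sorted(expand_degenerate(peroxiF2))[0], rng)
        template = NucRecord(id="t", seq="TTTT" + reverse_complement(exp) + "AAAA")
        sites = find_sites(template, peroxiF2, max_mismatch=0)
        minus = [s for s in sites if s.strand == "-"]
        assert len(minus) == 1 and minus[0].position == 4

    def test_no_compatible_window_empty(self, peroxiF2):
        template = NucRecord(id="t", seq="AT" * 50)
        assert find_sites(template, peroxiF2, max_mismatch=0) == []

    def test_single_internal_substitution_needs_tolerance(self, peroxiF2, rng):
        # oracle: a single-base edit of an expansion at a concretely
        # determined position is exactly one disjoint-base-set mismatch
        exp = concretize(sorted(expand_degenerate(peroxiF2))[0], rng)
        pos = 0  # position 0 is G in every expansion (concrete code)
        edited = ("A" if exp[pos] != "A" else "C") + exp[1:]
        template = NucRecord(id="t", seq="TT" + edited + "TT")
        assert [s for s in find_sites(template, peroxiF2, 0) if s.strand == "+"] == []
        hits = [s for s in find_sites(template, peroxiF2, 1) if s.strand == "+"]
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_three_prime_anchor_must_match(self, peroxiF2, rng):
        # a mismatch in the 3'-terminal 2 positions kills the site even
        # with a generous tolerance
        exp = concretize(sorted(expand_degenerate(peroxiF2))[0], rng)
        edited = exp[:-1] + ("A" if exp[-1] != "A" else "G")
        template = NucRecord(id="t", seq="TT" + edited + "TT")
        assert [s for s in find_sites(template, peroxiF2, 5) if s.strand == "+"] == []

    def test_inosine_matches_anything(self):
        primer = DegeneratePrimer("p", "AAAAIAAAAA")
        for base in "ACGT":
            template = NucRecord(id="t", seq="AAAA" + base + "AAAAA")
            assert any(s.strand == "+" for s in find_sites(template, primer, 0))


def make_upo_template(rng, insert_len=173):
    """Forward APO_65F expansion + insert + reverse-complemented APO_130R expansion."""
    fwd = DegeneratePrimer("APO_65F", "AAYGCIATGGCNAAYCAYGG")
    rev = DegeneratePrimer("APO_130R", "GCRTCRTGYTCIATNCC")
    f = concretize(sorted(expand_degenerate(fwd))[0], rng)
    r = concretize(sorted(expand_degenerate(rev))[0], rng)
    insert = "".join(rng.choice(list("ACGT"), size=insert_len))
    return f + insert + reverse_complement(r), fwd, rev


class TestAmplify:
    def test_upo_construction_yields_one_210bp_amplicon(self, rng, primer_pairs):
        seq, _, _ = make_upo_template(rng)
        template = NucRecord(id="t", seq=seq)
        products = amplify(template, primer_pairs["UPO"], max_mismatch=0)
        assert len(products) == 1
        assert len(products[0]) == 210
        assert products[0].strand == "+"

    def test_size_window_filters(self, rng):
        seq, fwd, rev = make_upo_template(rng)
        pair = PrimerPair(forward=fwd, reverse=rev, family="UPO", size_window=(300, 500))
        assert amplify(NucRecord(id="t", seq=seq), pair) == []

    def test_two_forward_sites_two_amplicons(self, rng, primer_pairs):
        # exhaustive-pairing oracle: 2 forward x 1 reverse convergent
        # in-window combinations -> 2 products
        pair = primer_pairs["UPO"]
        f = concretize(sorted(expand_degenerate(pair.forward))[0], rng)
        r = concretize(sorted(expand_degenerate(pair.reverse))[0], rng)
        fill1 = "".join(rng.choice(list("ACGT"), size=30))
        fill2 = "".join(rng.choice(list("ACGT"), size=120))
        seq = f + fill1 + f + fill2 + reverse_complement(r)
        products = amplify(NucRecord(id="t", seq=seq), pair)
        assert len(products) == 2
        # product lengths: 20+120+17 from the inner site, 20+30+20+120+17 from the outer
        assert sorted(len(p) for p in products) == [157, 207]

    def test_reverse_complement_invariance(self, rng, primer_pairs):
        seq, _, _ = make_upo_template(rng)
        fwd_products = amplify(NucRecord(id="t", seq=seq), primer_pairs["UPO"])
        rc_products = amplify(NucRecord(id="t", seq=reverse_complement(seq)), primer_pairs["UPO"])
        assert len(fwd_products) == len(rc_products) == 1
        assert fwd_products[0].seq == rc_products[0].seq  # reported on the forward-primer strand
        assert fwd_products[0].strand == "+" and rc_products[0].strand == "-"

    def test_amplicon_ends_compatible_with_primers(self, small_sim, primer_pairs):
        site = sorted(small_sim.pools)[0]
        for family, pair in primer_pairs.items():
            for tmpl in small_sim.pools[site]:
                for amp in amplify(tmpl, pair):
                    head = amp.seq[: len(pair.forward)]
                    tail = amp.seq[-len(pair.reverse):]
                    assert all(bases_compatible(p, b) for p, b in zip(pair.forward.seq, head))
                    rc_rev = reverse_complement(pair.reverse.seq)
                    assert all(bases_compatible(p, b) for p, b in zip(rc_rev, tail))

    def test_window_invariant_on_pair(self):
        fwd = DegeneratePrimer("f", "ACGTACGTAC")
        rev = DegeneratePrimer("r", "ACGTACGTAC")
        with pytest.raises(ValueError):
            PrimerPair(forward=fwd, reverse=rev, family="UPO", size_window=(10, 100))
        with pytest.raises(ValueError):
            PrimerPair(forward=fwd, reverse=rev, family="UPO", size_window=(200, 100))


class TestSyntheticRecovery:
    def test_zero_noise_pool_recovers_every_target(self, clean_sim, primer_pairs):
        truth = clean_sim.truth
        n_targets = len(truth)
        n_amplicons = 0
        for site, templates in clean_sim.pools.items():
            for tmpl in templates:
                fam = (tmpl.meta or {}).get("family")
                for pair in primer_pairs.values():
                    products = amplify(tmpl, pair)
                    n_amplicons += len(products)
                    if fam == "DECOY":
                        assert products == []
        assert n_amplicons == n_targets
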