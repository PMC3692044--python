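import shutil
import subprocess

import numpy as np
import pytest

from mirtarget import MiRNA, NucSequence, reverse_complement
from mirtarget.site_scanner import SiteType, TargetSite
from mirtarget import thermodynamics as th

RNG = np.random.default_rng(2024)


def random_rna(length, rng=RNG):
    return "".join("ACGU"[i] for i in rng.integers(4, size=length))


#: perfect Watson-Crick duplexes whose energy is a hand-summable chain of
#: identical or alternating stacks
DESIGNED_DUPLEXES = [
    ("GGGGGG", "CCCCCC"),
    ("CCCCC", "GGGGG"),
    ("GCGCGC", "GCGCGC"),
    ("AAAAAA", "UUUUUU"),
    ("GGGAAA", "UUUCCC"),
]


def hand_duplex_energy(a, b, table):
    """Independent nearest-neighbor sum for a full-length perfect duplex:
    initiation + stack terms along the helix + terminal AU/GU penalties."""
    pairs = [(x, y) for x, y in zip(a, b[::-1])]
    total = table.duplex_init
    total += table.end_penalty(pairs[0]) + table.end_penalty(pairs[-1])
    for p1, p2 in zip(pairs, pairs[1:]):
        total += table.stack(p1, p2)
    return min(0.0, total)


class TestDgDuplex:
    @pytest.mark.parametrize("a,b", DESIGNED_DUPLEXES)
    def test_perfect_duplex_equals_hand_summed_nearest_neighbors(
        self, a, b, backend, nn_table
    ):
        assert th.dg_duplex(a, b, backend) == pytest.approx(
            hand_duplex_energy(a, b, nn_table), abs=1e-9
        )

    def test_no_legal_pairs_gives_zero(self, backend):
        assert th.dg_duplex("AAAA", "AAAA", backend) == 0.0
        assert th.dg_duplex("NNNN", "NNNN", backend) == 0.0

    def test_reverse_symmetry(self, backend):
        for _ in range(20):
            a, b = random_rna(10), random_rna(12)
            assert th.dg_duplex(a, b, backend) == pytest.approx(
                th.dg_duplex(b, a, backend), abs=1e-9
            )

    def test_empty_sequence_rejected(self, backend):
        with pytest.raises(Exception):
            th.dg_duplex("", "ACGU", backend)


class TestDgBinding:
    def test_single_pair_closed_form(self, backend, nn_table):
        # one G:C pair: Z = 1 + exp(-init/RT); no stacks, no end penalty
        z = 1.0 + np.exp(-nn_table.duplex_init / th.RT_37C)
        expect = -th.RT_37C * np.log(z)
        assert th.dg_binding("G", "C", backend) == pytest.approx(expect, abs=1e-12)

    def test_no_legal_pairs_gives_zero(self, backend):
        assert th.dg_binding("AAA", "GGG", backend) == 0.0

    def test_ensemble_below_mfe(self, backend):
        for _ in range(30):
            a, b = random_rna(9), random_rna(14)
            assert th.dg_binding(a, b, backend) <= th.dg_duplex(a, b, backend) + 1e-12


class TestSeedEnergies:
    def test_8mer_seed_duplex_is_the_8nt_subproblem(self, mirna, backend):
        site_seq = reverse_complement(mirna.residues[:8])
        utr = NucSequence("u", "CC" + site_seq + "CC")
        site = TargetSite("u", mirna.name, 2, 10, SiteType.EIGHT_MER)
        assert th.dg_seed_duplex(mirna, utr, site, backend) == pytest.approx(
            th.dg_duplex(mirna.residues[:8], site_seq, backend), abs=1e-12
        )

    def test_seed_binding_below_seed_duplex(self, mirna, backend):
        rng = np.random.default_rng(5)
        for _ in range(10):
            utr = NucSequence("u", random_rna(40, rng))
            site = TargetSite("u", mirna.name, 10, 16, SiteType.SIX_MER)
            assert th.dg_seed_binding(mirna, utr, site, backend) <= (
                th.dg_seed_duplex(mirna, utr, site, backend) + 1e-12
            )


class TestDgOpen:
    def site(self, start, end):
        return TargetSite("u", "m", start, end, SiteType.SIX_MER)

    def test_unstructured_window_costs_nothing(self, backend):
        utr = NucSequence("u", "A" * 60)
        assert th.dg_open(utr, self.site(20, 26), flank=20, backend=backend) == 0.0

    def test_site_sequestered_in_designed_stem_costs_energy(self, backend):
        # upstream flank is the exact complement of the site: the MFE fold
        # pairs the site; forcing it open must cost energy
        site_seq = "CAUUCC"
        utr = NucSequence(
            "u", "AAAA" + reverse_complement(site_seq) + "AAAA" + site_seq + "AAAA"
        )
        start = utr.residues.index(site_seq, 8)
        cost = th.dg_open(
            utr, self.site(start, start + 6), flank=30, backend=backend
        )
        assert cost > 1.0

    def test_whole_utr_site_with_no_structure(self, backend):
        utr = NucSequence("u", "ACAACA")
        assert th.dg_open(utr, self.site(0, 6), flank=0, backend=backend) == 0.0

    def test_nonnegative_on_random_windows(self, backend):
        rng = np.random.default_rng(11)
        for _ in range(25):
            utr = NucSequence("u", random_rna(50, rng))
            cost = th.dg_open(utr, self.site(20, 26), flank=15, backend=backend)
            assert cost >= 0.0


class TestDgTotal:
    def test_sum_identity(self):
        e = th.SiteEnergies(
            dg_duplex=-8.1, dg_binding=-8.5, dg_seed_duplex=-5.0,
            dg_seed_binding=-5.2, dg_open=3.0,
        )
        assert th.dg_total(e) == pytest.approx(-5.1)
        assert e.dg_total == pytest.approx(-5.1)

    def test_zero_open_reduces_to_duplex(self):
        e = th.SiteEnergies(-7.0, -7.2, -4.0, -4.1, 0.0)
        assert th.dg_total(e) == e.dg_duplex


@pytest.mark.skipif(shutil.which("RNAduplex") is None, reason="RNAduplex not on PATH")
def test_sign_and_rank_agreement_with_external_engine(backend):
    """Independent cross-check: an established folding engine agrees on
    the sign of strong duplexes and ranks a well-separated panel the
    same way."""
    panel = [
        ("GGGGGGGGG", "CCCCCCCCC"),
        ("GCGCGC", "GCGCGC"),
        ("AUAUAU", "AUAUAU"),
    ]
    external = []
    internal = []
    for a, b in panel:
        out = subprocess.run(
            ["RNAduplex"], input=f"{a}\n{b}\n", capture_output=True, text=True,
            check=True,
        ).stdout
        energy = float(out.split("(")[-1].split(")")[0])
        external.append(energy)
        internal.append(th.dg_duplex(a, b, backend))
    assert all(e < 0 for e in external)
    assert all(i < 0 for i in internal)
    assert np.argsort(external).tolist() == np.argsort(internal).tolist()
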