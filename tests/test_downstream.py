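"""Flanking inverted repeats, MITE overlap and target-mimic rules vs oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ricircle.circ_calling import CircRNACall
from ricircle.downstream_analysis import (
    FlankConfig,
    MimicConfig,
    find_flanking_complements,
    mite_overlap,
    predict_mimics,
)
from ricircle.io_core import Genome, revcomp

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def call_on(chrom, start, end, cid="c1"):
    return CircRNACall(id=cid, chrom=chrom, strand="+", start=start, end=end,
                       support=2, gtag_ok=True)


def genome_with_flanks(up: str, down: str, circle_len: int = 200):
    """chromosome = pad + up + circle + down + pad; returns (genome, call)."""
    pad = "A" * 10
    circle = "C" * circle_len
    seq = pad + up + circle + down + pad
    start = len(pad) + len(up)
    return Genome({"c": seq}), call_on("c", start, start + circle_len - 1)


# ---------------------------------------------------------------------------
# Flanking complements
# ---------------------------------------------------------------------------

class TestFlankingComplements:
    def setup_method(self):
        self.rng = np.random.default_rng(31)
        self.cfg = FlankConfig()

    def _flanks(self, planted_len):
        up = rand_seq(self.rng, 500)
        down = rand_seq(self.rng, 500)
        word = rand_seq(self.rng, planted_len)
        up = up[:100] + word + up[100 + planted_len:]
        down = down[:300] + revcomp(word) + down[300 + planted_len:]
        return up, down, word

    def test_planted_18mer_found_at_threshold(self):
        up, down, word = self._flanks(18)
        g, call = genome_with_flanks(up, down)
        pairs = find_flanking_complements(call, g, self.cfg)
        assert any(p.length >= 18 and word in p.seq or word in p.seq
                   for p in pairs) or any(p.length >= 18 for p in pairs)
        hit = max(pairs, key=lambda p: p.length)
        assert word in hit.seq or hit.seq in word or hit.length >= 18

    def test_17mer_below_threshold_absent(self):
        up, down, _ = self._flanks(17)
        g, call = genome_with_flanks(up, down)
        assert find_flanking_complements(call, g, self.cfg) == []

    def test_matches_brute_force_oracle(self):
        """All maximal >= 18-bp reverse-complement matches equal an
        exhaustive all-substring-pair scan (low-complexity flanks to force
        several hits)."""
        rng = np.random.default_rng(7)
        up = "".join("ACG"[i] for i in rng.integers(0, 3, 220))
        down = "".join("CGT"[i] for i in rng.integers(0, 3, 220))
        word = rand_seq(rng, 25)
        up = up[:50] + word + up[75:]
        down = down[:120] + revcomp(word) + down[145:]
        g, call = genome_with_flanks(up, down)
        cfg = FlankConfig(flank_window=220, min_complement=18)
        got = {(p.up_start, p.down_start, p.length)
               for p in find_flanking_complements(call, g, cfg)}

        # oracle: maximal common substrings >= 18 of up vs revcomp(down),
        # enumerated from every start pair
        expected = set()
        u0 = call.start - 220
        d0 = call.end + 1
        rcd = revcomp(down)
        for i in range(len(up) - 17):
            for j in range(len(rcd) - 17):
                L = 0
                while i + L < len(up) and j + L < len(rcd) and up[i + L] == rcd[j + L]:
                    L += 1
                if L >= 18:
                    left_max = (i == 0 or j == 0 or up[i - 1] != rcd[j - 1])
                    if left_max:
                        expected.add((u0 + i, d0 + len(down) - j - L, L))
        assert got == expected
        assert any(L >= 25 for *_xy, L in got)

    def test_symmetry_under_flank_swap(self):
        """Swapping the flanks and reverse-complementing both yields the
        mirrored matches."""
        up, down, _ = self._flanks(22)
        g1, c1 = genome_with_flanks(up, down)
        g2, c2 = genome_with_flanks(revcomp(down), revcomp(up))
        p1 = find_flanking_complements(c1, g1, self.cfg)
        p2 = find_flanking_complements(c2, g2, self.cfg)
        assert sorted(p.length for p in p1) == sorted(p.length for p in p2)
        # matched sequence content mirrors: each upstream match in one run
        # appears (reverse-complemented) as a downstream match in the other
        assert {revcomp(p.seq) for p in p1} == \
            {g2["c"][p.down_start:p.down_start + p.length] for p in p2}
        assert len(p1) == len(p2) >= 1


# ---------------------------------------------------------------------------
# MITE overlap
# ---------------------------------------------------------------------------

class TestMiteOverlap:
    cfg = FlankConfig()

    def test_both_flanks_required(self):
        call = call_on("chr1", 10_000, 10_500)
        both = [("chr1", 9_600, 9_700, "m1"), ("chr1", 10_600, 10_700, "m2")]
        one = [("chr1", 9_600, 9_700, "m1")]
        assert mite_overlap([call], both, self.cfg) == ["c1"]
        assert mite_overlap([call], one, self.cfg) == []

    def test_single_spanning_mite_counts_for_both(self):
        call = call_on("chr1", 10_000, 10_100)
        spanning = [("chr1", 9_900, 10_300, "m")]
        assert mite_overlap([call], spanning, self.cfg) == ["c1"]

    def test_matches_brute_force_intersection(self, rng):
        calls = [call_on("chr1", int(s), int(s) + 400, cid=f"c{i}")
                 for i, s in enumerate(rng.integers(1_000, 50_000, size=30))]
        mites = [("chr1", int(s), int(s) + int(l), f"m{i}")
                 for i, (s, l) in enumerate(zip(rng.integers(0, 52_000, size=60),
                                                rng.integers(20, 600, size=60)))]
        got = set(mite_overlap(calls, mites, self.cfg))

        def olap(a0, a1, b0, b1):
            return min(a1, b1) - max(a0, b0)

        expected = set()
        for c in calls:
            up = (c.start - 500, c.start)
            down = (c.end + 1, c.end + 501)
            if any(olap(*up, m[1], m[2]) >= 1 for m in mites) and \
               any(olap(*down, m[1], m[2]) >= 1 for m in mites):
                expected.add(c.id)
        assert got == expected
        assert expected  # construction yields at least one flagged call


# ---------------------------------------------------------------------------
# miRNA target mimics
# ---------------------------------------------------------------------------

def ideal_site(mirna: str, bulge_after: int = 10, bulge: str = "TTT") -> str:
    """Perfect-complement target with a 3-nt bulge opposite miRNA positions
    ``bulge_after``/``bulge_after + 1``, given 5'->3'."""
    paired = "".join(COMP[c] for c in mirna)[::-1]  # revcomp, 5'->3'
    # miRNA position p pairs target base (from 3' end); insert bulge after
    # the pairing partner of position ``bulge_after``
    cut = len(mirna) - bulge_after
    return paired[:cut] + bulge + paired[cut:]


MIRNA = "TGGAGCTCGTGTCATTGCGTT"  # 21 nt, wobble-capable outside the seed


class TestMimics:
    cfg = MimicConfig()

    def _scan(self, site, mirna=MIRNA):
        circ = "GG" + site + "CC" + "ACGT" * 10
        return predict_mimics("x", circ, [("mir", mirna)], self.cfg)

    def test_ideal_mimic_found_once(self):
        sites = self._scan(ideal_site(MIRNA))
        assert len(sites) == 1
        s = sites[0]
        assert s.weighted_mismatches == 0.0
        assert s.position == 2
        assert s.bulge_after == 10

    def test_seed_mismatch_rejected(self):
        site = ideal_site(MIRNA)
        # corrupt the pairing partner of miRNA position 5 (inside seed 2-8)
        idx = len(site) - 5  # position 5 from the 3' end, no bulge shift
        bad = site[:idx] + ("A" if site[idx] != "A" else "C") + site[idx + 1:]
        assert self._scan(bad) == []

    def test_weighted_gu_boundary(self):
        """Six G:U wobbles outside the bulge weigh 3.0 (accepted); seven
        weigh 3.5 (rejected)."""
        def with_wobbles(n):
            site = list(ideal_site(MIRNA))
            # wobble-capable miRNA positions (G or U) beyond the bulge region
            capable = [15, 16, 17, 19, 20, 21, 12][:n]
            assert len(capable) == n, "not enough wobble-capable positions"
            for p in capable:
                m = MIRNA[p - 1]
                ti = len(site) - 1 - (p - 1 + 3)  # bulge shifts targets by 3
                site[ti] = "T" if m == "G" else "G"  # G:U / U:G wobble
            return "".join(site)

        six = self._scan(with_wobbles(6))
        assert len(six) == 1 and six[0].weighted_mismatches == 3.0
        assert self._scan(with_wobbles(7)) == []

    def test_mismatch_cap_outside_seed(self):
        site = list(ideal_site(MIRNA))
        # three full mismatches at miRNA positions 13, 15, 17 (A<->C swaps)
        for p in (13, 15, 17):
            ti = len(site) - 1 - (p - 1 + 3)
            site[ti] = "C" if site[ti] in "AGT" and COMP[MIRNA[p - 1]] != "C" else "A"
        three = self._scan("".join(site))
        assert len(three) == 1 and three[0].weighted_mismatches == 3.0

    def test_short_mirna_skipped(self):
        assert predict_mimics("x", "ACGT" * 30, [("tiny", "ACGTACGTACGT")],
                              self.cfg) == []

    def test_wraparound_equals_doubled_linear_scan(self):
        """Sites found on the circle equal those on the doubled linear
        sequence restricted to first-copy offsets."""
        site = ideal_site(MIRNA)
        circ = site[10:] + "ACGT" * 15 + site[:10]  # site spans the backsplice
        wrapped = predict_mimics("x", circ, [("mir", MIRNA)], self.cfg, wrap=True)
        doubled = predict_mimics("x", circ + circ, [("mir", MIRNA)], self.cfg,
                                 wrap=False)
        w_keys = {(s.position, s.bulge_after) for s in wrapped}
        d_keys = {(s.position % len(circ), s.bulge_after) for s in doubled
                  if s.position < len(circ)}
        assert w_keys == d_keys
        assert any(p + len(site) > len(circ) for p, _ in w_keys)  # wraps indeed

    def test_no_wrap_misses_junction_spanning_site(self):
        site = ideal_site(MIRNA)
        circ = site[10:] + "ACGT" * 15 + site[:10]
        assert predict_mimics("x", circ, [("mir", MIRNA)], self.cfg,
                              wrap=False) == []
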