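"""Shared fixtures: a planted-truth detection fixture and small helpers.

The detection fixture builds 50 candidate sites programmatically: planted
true editing events (plus- and minus-strand) interleaved with every decoy
class the caller must reject — knockout-shared signals, low coverage, weak
edit support, multiple transitions, sub-threshold angle or magnitude, SNP
and repeat overlaps, and splice-junction proximity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from editvar.detect import BaseCountVector, ExclusionTracks


@dataclass
class DetectionFixture:
    wt: list[BaseCountVector]
    ko: list[BaseCountVector]
    tracks: ExclusionTracks
    truth: set[tuple[str, int]]  # (chrom, pos) of planted true calls
    snp_intervals: list[tuple[str, int, int]]
    repeat_intervals: list[tuple[str, int, int]]
    splice_positions: list[tuple[str, int]]


def _vec(chrom, pos, strand, ref, a=0, t=0, g=0, c=0):
    return BaseCountVector(chrom=chrom, pos=pos, strand=strand, ref_base=ref,
                           a=a, t=t, g=g, c=c)


@pytest.fixture(scope="session")
def planted_sites() -> DetectionFixture:
    chrom = "chr1"
    wt, ko, truth = [], [], set()
    snp_iv, rep_iv, splice_pos = [], [], []
    pos = 1000

    def nxt(step=1000):
        nonlocal pos
        pos += step
        return pos

    # --- 15 planted true positives (coverage >= 20, edited fraction >= 10%)
    plus_truths = [(18, 2), (17, 3), (25, 5), (2, 18), (10, 10), (27, 3),
                   (40, 8), (16, 4), (30, 10), (90, 10)]
    for cref, ted in plus_truths:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
        ko.append(_vec(chrom, p, "+", "C", c=cref + ted))
        truth.add((chrom, p))
    minus_truths = [(18, 2), (20, 6), (5, 15), (33, 7)]
    for gref, aed in minus_truths:
        p = nxt()
        wt.append(_vec(chrom, p, "-", "G", g=gref, a=aed))
        ko.append(_vec(chrom, p, "-", "G", g=gref + aed))
        truth.add((chrom, p))
    # true site exactly 5 bp from a splice junction (outside the 4 bp zone)
    p = nxt()
    wt.append(_vec(chrom, p, "+", "C", c=20, t=5))
    ko.append(_vec(chrom, p, "+", "C", c=25))
    splice_pos.append((chrom, p + 5))
    truth.add((chrom, p))

    # --- decoys ---------------------------------------------------------
    # knockout shares the edit signal (not enzyme-dependent)
    for cref, ted in [(18, 2), (25, 6), (40, 10)]:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
        ko.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
    # wild-type coverage below 5 reads
    for cref, ted in [(2, 2), (1, 3)]:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
        ko.append(_vec(chrom, p, "+", "C", c=20))
    # fewer than 2 edit-supporting reads
    for cref, ted in [(19, 1), (30, 1), (40, 0)]:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
        ko.append(_vec(chrom, p, "+", "C", c=cref + 1))
    # a second transition is also supported (messy site)
    for cref, ted, gsec in [(14, 3, 3), (20, 5, 2)]:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted, g=gsec))
        ko.append(_vec(chrom, p, "+", "C", c=cref + ted + gsec))
    # magnitude below 15 reads (passes QC)
    for cref, ted in [(8, 2), (10, 3), (12, 2)]:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
        ko.append(_vec(chrom, p, "+", "C", c=cref + ted))
    # angle below 0.11 radians (well-covered but weakly edited)
    for cref, ted in [(95, 5), (60, 3), (97, 3)]:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
        ko.append(_vec(chrom, p, "+", "C", c=cref + ted))
    # known SNP positions
    for cref, ted in [(18, 6), (22, 8)]:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
        ko.append(_vec(chrom, p, "+", "C", c=cref + ted))
        snp_iv.append((chrom, p - 1, p))  # BED-style 0-based half-open
    # inside repeats
    for cref, ted in [(18, 6), (25, 10)]:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
        ko.append(_vec(chrom, p, "+", "C", c=cref + ted))
        rep_iv.append((chrom, p - 10, p + 10))
    # within 4 bp of a splice junction (at 1 and 3 bp)
    for off, (cref, ted) in [(1, (18, 6)), (3, (20, 5))]:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
        ko.append(_vec(chrom, p, "+", "C", c=cref + ted))
        splice_pos.append((chrom, p + off))
    # reference base is not an editing candidate
    for _ in range(2):
        p = nxt()
        wt.append(_vec(chrom, p, "+", "A", a=20, g=5))
        ko.append(_vec(chrom, p, "+", "A", a=25))
    # knockout has zero coverage: cannot be assessed
    p = nxt()
    wt.append(_vec(chrom, p, "+", "C", c=18, t=6))
    ko.append(_vec(chrom, p, "+", "C"))
    # site absent from the knockout table entirely
    p = nxt()
    wt.append(_vec(chrom, p, "+", "C", c=18, t=6))
    # minus-strand decoy: knockout shares the G->A signal
    p = nxt()
    wt.append(_vec(chrom, p, "-", "G", g=18, a=6))
    ko.append(_vec(chrom, p, "-", "G", g=18, a=6))
    # low-coverage minus-strand decoy
    p = nxt()
    wt.append(_vec(chrom, p, "-", "G", g=2, a=2))
    ko.append(_vec(chrom, p, "-", "G", g=20))
    # further knockout-shared signals
    for cref, ted in [(30, 4), (50, 12)]:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
        ko.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
    # further sub-threshold angles (weakly edited, well covered)
    for cref, ted in [(80, 4), (120, 6)]:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
        ko.append(_vec(chrom, p, "+", "C", c=cref + ted))
    # further single-read edit support
    for cref, ted in [(25, 1), (60, 1)]:
        p = nxt()
        wt.append(_vec(chrom, p, "+", "C", c=cref, t=ted))
        ko.append(_vec(chrom, p, "+", "C", c=cref + 1))
    # unedited clean site (no signal at all)
    p = nxt()
    wt.append(_vec(chrom, p, "+", "C", c=40))
    ko.append(_vec(chrom, p, "+", "C", c=40))

    assert len(wt) == 50, f"fixture should contain 50 sites, has {len(wt)}"
    tracks = ExclusionTracks(snp_iv, splice_pos, rep_iv)
    return DetectionFixture(wt=wt, ko=ko, tracks=tracks, truth=truth,
                            snp_intervals=snp_iv, repeat_intervals=rep_iv,
                            splice_positions=splice_pos)
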