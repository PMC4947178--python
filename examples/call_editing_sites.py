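"""Call C-to-U editing sites from wild-type vs knockout base counts.

Builds a small in-memory pileup table for four candidate sites and runs the
vector-angle caller: a genuine edit shows a C->T signal in the wild type
that is absent from the enzyme knockout, with the angle between the two
A/T/G/C count vectors quantifying the shift.
"""

from editvar import BaseCountVector, DetectionThresholds, call_edits, vector_angle


def site(pos, strand="+", ref="C", **counts):
    return BaseCountVector(chrom="chr1", pos=pos, strand=strand, ref_base=ref,
                           a=counts.get("a", 0), t=counts.get("t", 0),
                           g=counts.get("g", 0), c=counts.get("c", 0))


wt = [
    site(1000, c=18, t=2),                      # 10% edited at coverage 20
    site(2000, c=19, t=1),                      # only one supporting read
    site(3000, c=30, t=12),                     # strongly edited
    site(4000, strand="-", ref="G", g=25, a=6), # minus strand: G->A on genome
]
ko = [
    site(1000, c=20),
    site(2000, c=20),
    site(3000, c=42, t=12),                     # knockout shares the signal
    site(4000, strand="-", ref="G", g=31),
]

calls = call_edits(wt, ko, DetectionThresholds(),
                   transcripts={("chr1", 1000): "GeneA", ("chr1", 4000): "GeneB"})
print(f"{len(calls)} of {len(wt)} candidate sites called:\n")
for c in calls:
    print(f"  {c.chrom}:{c.pos}({c.strand}) rate={c.editing_rate:.3f} "
          f"angle={c.angle:.4f} rad  coverage={int(c.wt_norm)}  "
          f"transcript={c.transcript_id} ({c.classification})")

borderline = vector_angle(site(1000, c=18, t=2), site(1000, c=20))
print(f"\nThe 10%-edited site sits just above the 0.11 rad threshold "
      f"(angle {borderline:.4f}).")
print("Site 2000 fails the 2-read support minimum; site 3000 is rejected "
      "because\nthe knockout shows the same C->T signal (not enzyme-dependent).")
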