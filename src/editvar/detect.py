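"""Bulk C-to-U editing-site caller: wild-type vs knockout base-count vectors.

Each candidate genomic coordinate is summarized, per sample, as the vector
of A/T/G/C read counts from a pileup.  Genuine APOBEC1-dependent editing
shows up as a C-to-T signal (on the transcript strand) present in the
wild-type but absent in the enzyme knockout, so the caller compares the two
vectors directly: a site is retained when it passes per-site QC, the
wild-type vector is large enough (magnitude >= 15 reads), and the angle
between the wild-type and knockout vectors is at least 0.11 radians —
jointly approximately equivalent to requiring 20 reads of coverage with 10%
of them edited.  Annotation-based exclusions (known SNPs, repeats, splice
junction proximity) remove the usual false-positive classes.

The magnitude threshold is applied to the total read count of the wild-type
vector (its L1 norm).  Under the Euclidean norm a strongly edited site
(e.g. 10 edited of 20 reads, norm 14.1) would fail the cut-off while weakly
edited sites pass, inverting the intent of a coverage floor; the total-count
reading keeps the admissible edited-read counts at coverage 20 exactly
{2..20} and matches the stated coverage equivalence.

Coordinates: site tables are 1-based; BED exclusion tracks are 0-based
half-open, converted centrally here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

BASES = ("A", "T", "G", "C")

# edited (alternate) base implied by C-to-U editing, per genomic strand:
# plus-strand transcripts show C->T on the genome, minus-strand ones G->A.
_EDIT_AXIS = {"+": ("C", "T"), "-": ("G", "A")}


@dataclass(frozen=True)
class BaseCountVector:
    """Per-site A/T/G/C read counts for one sample (genomic bases)."""

    chrom: str
    pos: int  # 1-based
    strand: str
    ref_base: str
    a: int
    t: int
    g: int
    c: int

    def __post_init__(self) -> None:
        if self.ref_base not in BASES:
            raise ValueError(f"ref_base must be one of {BASES}, got {self.ref_base!r}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if min(self.a, self.t, self.g, self.c) < 0:
            raise ValueError("base counts must be nonnegative")

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.a, self.t, self.g, self.c], dtype=float)

    @property
    def coverage(self) -> int:
        return self.a + self.t + self.g + self.c

    def count(self, base: str) -> int:
        return {"A": self.a, "T": self.t, "G": self.g, "C": self.c}[base]


@dataclass(frozen=True)
class DetectionThresholds:
    min_coverage: int = 5
    min_edited: int = 2
    min_wt_norm: float = 15.0
    min_angle: float = 0.11  # radians
    splice_distance: int = 4  # bp

    def __post_init__(self) -> None:
        if min(
            self.min_coverage, self.min_edited, self.min_wt_norm,
            self.min_angle, self.splice_distance,
        ) < 0:
            raise ValueError("all detection thresholds must be nonnegative")


@dataclass(frozen=True)
class EditingSiteCall:
    chrom: str
    pos: int
    strand: str
    ref_base: str
    edited_reads: int
    total_reads: int  # edited + reference reads at the site (wild type)
    editing_rate: float
    angle: float
    wt_norm: float
    transcript_id: str | None = None
    classification: str | None = None


@dataclass(frozen=True)
class ReadObs:
    """Minimal aligned-read abstraction for the read-level filter."""

    length: int
    has_indel: bool = False
    edit_positions: tuple[int, ...] = ()  # 1-based offsets within the read


def vector_angle(wt: BaseCountVector, ko: BaseCountVector) -> float:
    """Angle (radians) between the two 4-component count vectors.

    arccos of the normalized dot product; lies in [0, pi/2] for nonnegative
    counts and is invariant under positive scaling of either vector.
    """
    u, w = wt.counts, ko.counts
    nu, nw = float(np.linalg.norm(u)), float(np.linalg.norm(w))
    if nu == 0.0 or nw == 0.0:
        raise ValueError(
            f"angle undefined for a zero base-count vector at {wt.chrom}:{wt.pos}"
        )
    # atan2 form: stable for near-parallel vectors and exactly 0 for equal ones
    uh, wh = u / nu, w / nw
    return 2.0 * math.atan2(float(np.linalg.norm(uh - wh)), float(np.linalg.norm(uh + wh)))


def vector_magnitude(vec: BaseCountVector) -> float:
    """Magnitude of a base-count vector: its total read count."""
    return float(vec.coverage)


def filter_read(read: ReadObs, end_trim: int = 2) -> bool:
    """Read-level QC: keep unless the read has an indel or supports an edit
    within the first or last ``end_trim`` base pairs (where chemistry and
    alignment artefacts concentrate)."""
    if read.has_indel:
        return False
    for pos in read.edit_positions:
        if pos <= end_trim or pos > read.length - end_trim:
            return False
    return True


def edit_counts(vec: BaseCountVector) -> tuple[int, int]:
    """(edited, reference) read counts on the site's transcript strand.

    C-to-U editing reads as C->T on plus-strand transcripts and G->A on the
    genome for minus-strand ones; the strand handling is centralized here so
    the caller logic is strand-agnostic.
    """
    ref, alt = _EDIT_AXIS[vec.strand]
    if vec.ref_base != ref:
        raise ValueError(
            f"{vec.chrom}:{vec.pos}({vec.strand}) ref {vec.ref_base} is not a "
            f"C-to-U candidate (expected {ref})"
        )
    return vec.count(alt), vec.count(ref)


def is_candidate(vec: BaseCountVector) -> bool:
    return vec.ref_base == _EDIT_AXIS[vec.strand][0]


def site_qc(
    wt: BaseCountVector,
    ko: BaseCountVector,
    th: DetectionThresholds = DetectionThresholds(),
) -> tuple[bool, list[str]]:
    """Per-site QC; returns (passed, reason codes), reporting every failure.

    Codes: ``coverage`` (wild-type depth below minimum), ``min_edited``
    (too few edit-supporting reads), ``multiple_transitions`` (a second
    non-reference base is also supported by >= min_edited reads, i.e. the
    site looks like noise or a mapping artefact rather than one clean
    transition), ``ko_signal`` (the knockout also shows the edited base, so
    the change is not enzyme-dependent).
    """
    if wt.ref_base != ko.ref_base:
        raise ValueError(
            f"{wt.chrom}:{wt.pos}: wild-type and knockout disagree on the "
            f"reference base ({wt.ref_base} vs {ko.ref_base})"
        )
    reasons: list[str] = []
    if not is_candidate(wt):
        return False, ["not_candidate"]
    edited, _ = edit_counts(wt)
    alt_base = _EDIT_AXIS[wt.strand][1]
    if wt.coverage < th.min_coverage:
        reasons.append("coverage")
    if edited < th.min_edited:
        reasons.append("min_edited")
    second_alts = [
        b for b in BASES
        if b not in (wt.ref_base, alt_base) and wt.count(b) >= th.min_edited
    ]
    if second_alts:
        reasons.append("multiple_transitions")
    ko_edited, _ = edit_counts(ko)
    if ko_edited > 0:
        reasons.append("ko_signal")
    return not reasons, reasons


class ExclusionTracks:
    """Genomic exclusion annotation: SNPs, splice junctions, repeats.

    Interval tracks (SNPs, repeats) are held 0-based half-open as in BED;
    lookups take 1-based site positions.  Splice junctions are a position
    set: each BED record contributes both of its boundary coordinates.
    """

    def __init__(
        self,
        snp_intervals: Iterable[tuple[str, int, int]] = (),
        splice_positions: Iterable[tuple[str, int]] = (),
        repeat_intervals: Iterable[tuple[str, int, int]] = (),
    ) -> None:
        from intervaltree import IntervalTree

        def build(intervals):
            trees: dict[str, IntervalTree] = {}
            for chrom, start, end in intervals:
                if start >= end:
                    raise ValueError(f"malformed interval {chrom}:{start}-{end}")
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
            return trees

        self._snp = build(snp_intervals)
        self._repeat = build(repeat_intervals)
        self._splice: dict[str, np.ndarray] = {}
        tmp: dict[str, set[int]] = {}
        for chrom, pos in splice_positions:
            tmp.setdefault(chrom, set()).add(pos)
        for chrom, positions in tmp.items():
            self._splice[chrom] = np.array(sorted(positions))

    @classmethod
    def from_bed_files(
        cls,
        snps: str | None = None,
        splices: str | None = None,
        repeats: str | None = None,
    ) -> "ExclusionTracks":
        from .io import read_bed

        snp_iv = read_bed(snps) if snps else ()
        rep_iv = read_bed(repeats) if repeats else ()
        splice_pos: list[tuple[str, int]] = []
        if splices:
            for chrom, start, end in read_bed(splices):
                # both boundaries of a junction interval, as 1-based positions
                splice_pos.extend([(chrom, start + 1), (chrom, end)])
        return cls(snp_iv, splice_pos, rep_iv)

    def in_snp(self, chrom: str, pos: int) -> bool:
        tree = self._snp.get(chrom)
        return bool(tree is not None and tree.overlaps(pos - 1))

    def in_repeat(self, chrom: str, pos: int) -> bool:
        tree = self._repeat.get(chrom)
        return bool(tree is not None and tree.overlaps(pos - 1))

    def near_splice(self, chrom: str, pos: int, distance: int) -> bool:
        junctions = self._splice.get(chrom)
        if junctions is None or junctions.size == 0:
            return False
        i = int(np.searchsorted(junctions, pos))
        nearest = min(
            abs(pos - int(junctions[j])) for j in (max(i - 1, 0), min(i, junctions.size - 1))
        )
        return nearest <= distance


def call_edits(
    wt_table: Iterable[BaseCountVector],
    ko_table: Iterable[BaseCountVector],
    th: DetectionThresholds = DetectionThresholds(),
    excl: ExclusionTracks | None = None,
    transcripts: Mapping[tuple[str, int], str] | None = None,
) -> list[EditingSiteCall]:
    """Call C-to-U editing sites from paired wild-type / knockout tables.

    A site is retained when it passes :func:`site_qc`, the wild-type vector
    magnitude is >= ``min_wt_norm``, the wild-type/knockout angle is
    >= ``min_angle`` radians, the position is not a known SNP or inside a
    repeat, and it lies more than ``splice_distance`` bp from every splice
    junction.  Sites missing from the knockout table cannot be assessed and
    are skipped.  Output is sorted by (chrom, pos); when a transcript map is
    supplied, calls carry transcript ids and site-specific/hyperedited
    classifications.
    """
    if excl is None:
        excl = ExclusionTracks()
    ko_by_site = {(v.chrom, v.pos, v.strand): v for v in ko_table}
    calls: list[EditingSiteCall] = []
    for wt in wt_table:
        if not is_candidate(wt):
            continue
        ko = ko_by_site.get((wt.chrom, wt.pos, wt.strand))
        if ko is None:
            continue
        passed, _ = site_qc(wt, ko, th)
        if not passed:
            continue
        if vector_magnitude(wt) < th.min_wt_norm:
            continue
        if ko.coverage == 0:
            continue
        angle = vector_angle(wt, ko)
        if angle < th.min_angle:
            continue
        if excl.in_snp(wt.chrom, wt.pos) or excl.in_repeat(wt.chrom, wt.pos):
            continue
        if excl.near_splice(wt.chrom, wt.pos, th.splice_distance):
            continue
        edited, ref_reads = edit_counts(wt)
        calls.append(
            EditingSiteCall(
                chrom=wt.chrom,
                pos=wt.pos,
                strand=wt.strand,
                ref_base=wt.ref_base,
                edited_reads=edited,
                total_reads=edited + ref_reads,
                editing_rate=edited / (edited + ref_reads),
                angle=angle,
                wt_norm=vector_magnitude(wt),
                transcript_id=(
                    transcripts.get((wt.chrom, wt.pos)) if transcripts else None
                ),
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    if transcripts:
        classes = classify_transcripts(calls)
        calls = [
            replace(c, classification=classes.get(c.transcript_id)) for c in calls
        ]
    return calls


def classify_transcripts(
    calls: Iterable[EditingSiteCall],
    all_transcripts: Iterable[str] | None = None,
) -> dict[str, str]:
    """Classify transcripts by their number of called sites.

    Exactly one called site -> ``site-specific``; two or more distinct sites
    -> ``hyperedited``; transcripts from ``all_transcripts`` with no call ->
    ``none``.
    """
    per_transcript: dict[str, set[tuple[str, int]]] = {}
    for call in calls:
        if call.transcript_id is None:
            continue
        per_transcript.setdefault(call.transcript_id, set()).add((call.chrom, call.pos))
    out = {
        tid: ("site-specific" if len(sites) == 1 else "hyperedited")
        for tid, sites in per_transcript.items()
    }
    if all_transcripts is not None:
        for tid in all_transcripts:
            out.setdefault(tid, "none")
    return out


# ---------------------------------------------------------------------------
# optional alignment adapter


def base_counts_from_alignment(
    path: str,
    strand_of: Mapping[tuple[str, int], str] | None = None,
    end_trim: int = 2,
    drop_duplicates: bool = False,
) -> list[BaseCountVector]:
    """Build per-site base-count vectors from a coordinate-sorted alignment.

    Convenience adapter over pysam so the caller can start from SAM/BAM
    rather than precomputed pileup tables; the core statistic never depends
    on it.  Reads must carry MD tags (reference bases are reconstructed from
    them).  Reads with indels, or with any mismatch within ``end_trim`` bp
    of either read end, are dropped, mirroring :func:`filter_read`.  With
    ``drop_duplicates`` reads sharing (start, CIGAR) are collapsed to one
    (deduplication is normally done upstream).  ``strand_of`` assigns site
    strands (default '+').
    """
    import pysam

    counts: dict[tuple[str, int], dict[str, int]] = {}
    refs: dict[tuple[str, int], str] = {}
    seen: set[tuple[str, int, str]] = set()
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.query_sequence is None:
                continue
            if any(op in (1, 2) for op, _ in (read.cigartuples or ())):
                continue  # indel
            if drop_duplicates:
                key = (read.reference_name, read.reference_start, read.cigarstring)
                if key in seen:
                    continue
                seen.add(key)
            pairs = read.get_aligned_pairs(matches_only=True, with_seq=True)
            qlen = read.query_length
            mismatch_qpos = [
                qpos for qpos, _, ref in pairs
                if ref is not None and read.query_sequence[qpos].upper() != ref.upper()
            ]
            if any(q < end_trim or q >= qlen - end_trim for q in mismatch_qpos):
                continue
            for qpos, rpos, ref in pairs:
                base = read.query_sequence[qpos].upper()
                if base not in BASES or ref is None:
                    continue
                site = (read.reference_name, rpos + 1)
                counts.setdefault(site, {b: 0 for b in BASES})[base] += 1
                refs[site] = ref.upper()
    out = []
    for (chrom, pos), tally in sorted(counts.items()):
        strand = strand_of.get((chrom, pos), "+") if strand_of else "+"
        out.append(
            BaseCountVector(
                chrom=chrom, pos=pos, strand=strand, ref_base=refs[(chrom, pos)],
                a=tally["A"], t=tally["T"], g=tally["G"], c=tally["C"],
            )
        )
    return out
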