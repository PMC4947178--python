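"""Tab-separated file formats and run metadata.

All tables are plain TSV with a comment header (lines starting with ``#``)
recording the tool version, the seed and a hash of the configuration, so a
rerun with identical inputs is byte-identical and every output is
self-describing.  Parsers validate eagerly and report the offending line
number; nothing is silently coerced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .detect import BASES, BaseCountVector, EditingSiteCall
from .inference import PosteriorSamples, excludes_zero, hpd_interval, kde_mode, marginal_rate_draws
from .model import BulkSiteCounts, CellSiteCounts, GenomicSite, SiteDataset

CELL_COLUMNS = ("site_id", "chrom", "pos", "strand", "cell_id", "edited_reads", "total_reads")
BULK_COLUMNS = ("site_id", "edited_reads", "total_reads")
COUNT_TABLE_COLUMNS = ("chrom", "pos", "strand", "ref", "A", "T", "G", "C")
SUMMARY_COLUMNS = (
    "site_id", "J", "bulk_rate", "v_mean", "v_mode", "hpd_lo", "hpd_hi",
    "excludes_zero", "acceptance_rate", "seed",
)
CALL_COLUMNS = (
    "chrom", "pos", "strand", "ref", "edited_reads", "total_reads",
    "editing_rate", "angle", "wt_norm", "transcript_id", "class",
)


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed: int | None, config: dict | None) -> list[str]:
    lines = [f"# editvar v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config={config_hash(config)}")
    return lines


def _fmt(x) -> str:
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, float):
        return f"{x:.6g}"
    return "" if x is None else str(x)


def _write_table(path, columns: Sequence[str], rows: Iterable[Sequence], seed, config) -> None:
    out = _header_lines(seed, config)
    out.append("\t".join(columns))
    for row in rows:
        out.append("\t".join(_fmt(x) for x in row))
    Path(path).write_text("\n".join(out) + "\n")


def _read_rows(path, columns: Sequence[str]):
    """Yield (line_number, field dict) for a TSV with the given columns."""
    path = Path(path)
    header = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in columns if c not in header]
                if missing:
                    raise ParseError(
                        f"{path}:{lineno}: missing column(s) {', '.join(missing)}"
                    )
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            yield lineno, dict(zip(header, fields))
    if header is None:
        raise ParseError(f"{path}: empty file, no header found")


def _int_field(path, lineno, rec, key) -> int:
    try:
        return int(rec[key])
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: column {key!r} must be an integer, got {rec[key]!r}"
        ) from None


# ---------------------------------------------------------------------------
# single-cell count tables (simulate <-> infer)


def load_single_cell_counts(cells_path, bulk_path) -> list[SiteDataset]:
    """Read the per-cell counts table and its companion bulk table.

    Cells TSV columns: site_id, chrom, pos, strand, cell_id, edited_reads,
    total_reads.  Bulk TSV columns: site_id, edited_reads, total_reads.
    Returns one SiteDataset per site_id, cells in file order.
    """
    bulk: dict[str, BulkSiteCounts] = {}
    for lineno, rec in _read_rows(bulk_path, BULK_COLUMNS):
        x = _int_field(bulk_path, lineno, rec, "edited_reads")
        n = _int_field(bulk_path, lineno, rec, "total_reads")
        try:
            bulk[rec["site_id"]] = BulkSiteCounts(edited=x, total=n)
        except ValueError as exc:
            raise ParseError(f"{bulk_path}:{lineno}: {exc}") from None

    sites: dict[str, GenomicSite] = {}
    cells: dict[str, list[CellSiteCounts]] = {}
    for lineno, rec in _read_rows(cells_path, CELL_COLUMNS):
        sid = rec["site_id"]
        try:
            site = GenomicSite(
                chrom=rec["chrom"],
                pos=_int_field(cells_path, lineno, rec, "pos"),
                strand=rec["strand"],
            )
            cell = CellSiteCounts(
                cell_id=rec["cell_id"],
                edited=_int_field(cells_path, lineno, rec, "edited_reads"),
                total=_int_field(cells_path, lineno, rec, "total_reads"),
            )
        except ValueError as exc:
            raise ParseError(f"{cells_path}:{lineno}: {exc}") from None
        prev = sites.setdefault(sid, site)
        if prev != site:
            raise ParseError(
                f"{cells_path}:{lineno}: site_id {sid!r} maps to conflicting coordinates"
            )
        cells.setdefault(sid, []).append(cell)

    datasets = []
    for sid, cell_list in cells.items():
        if sid not in bulk:
            raise ParseError(
                f"{bulk_path}: bulk counts missing for site_id {sid!r}"
            )
        datasets.append(
            SiteDataset(site=sites[sid], cells=tuple(cell_list), bulk=bulk[sid], site_id=sid)
        )
    return datasets


def write_single_cell_counts(
    datasets: Iterable[SiteDataset], cells_path, bulk_path,
    seed: int | None = None, config: dict | None = None,
) -> None:
    datasets = list(datasets)
    _write_table(
        cells_path, CELL_COLUMNS,
        (
            (d.label, d.site.chrom, d.site.pos, d.site.strand, c.cell_id, c.edited, c.total)
            for d in datasets for c in d.cells
        ),
        seed, config,
    )
    _write_table(
        bulk_path, BULK_COLUMNS,
        ((d.label, d.bulk.edited, d.bulk.total) for d in datasets),
        seed, config,
    )


# ---------------------------------------------------------------------------
# posterior summaries and raw draws


@dataclass(frozen=True)
class SiteSummary:
    site_id: str
    n_cells: int
    bulk_rate: float
    v_mean: float
    v_mode: float
    hpd_lo: float
    hpd_hi: float
    excludes_zero: bool
    acceptance_rate: float
    seed: int


def summarize_site(site_id: str, post: PosteriorSamples, mass: float = 0.95) -> SiteSummary:
    """Condense a posterior into the one-row summary used in reports."""
    interval = hpd_interval(post.v, mass)
    return SiteSummary(
        site_id=site_id,
        n_cells=len(post.cell_ids),
        bulk_rate=post.bulk_rate,
        v_mean=float(post.v.mean()),
        v_mode=kde_mode(post.v, support=(0.0, post.v_max)),
        hpd_lo=interval.lo,
        hpd_hi=interval.hi,
        excludes_zero=excludes_zero(interval, post.settings.excludes_zero_delta),
        acceptance_rate=post.acceptance_rate,
        seed=post.settings.seed,
    )


def write_posterior_summary(
    summaries: Iterable[SiteSummary], path, seed: int | None = None,
    config: dict | None = None,
) -> None:
    _write_table(
        path, SUMMARY_COLUMNS,
        (
            (s.site_id, s.n_cells, s.bulk_rate, s.v_mean, s.v_mode, s.hpd_lo,
             s.hpd_hi, s.excludes_zero, s.acceptance_rate, s.seed)
            for s in summaries
        ),
        seed, config,
    )


def write_draws(post: PosteriorSamples, path) -> None:
    """Raw retained draws as plain CSV: v, the posterior-predictive marginal
    rate, and one column per cell's rate."""
    marginal = marginal_rate_draws(post)
    cols = ["v", "p_marginal"] + [f"p_{cid}" for cid in post.cell_ids]
    lines = _header_lines(post.settings.seed, None)
    lines.append(",".join(cols))
    for i in range(post.n_draws):
        row = [post.v[i], marginal[i], *post.p[i]]
        lines.append(",".join(f"{x:.6g}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# detection tables


def read_base_count_table(path) -> list[BaseCountVector]:
    """Read a per-site base-count TSV (chrom, pos, strand, ref, A, T, G, C)."""
    out = []
    for lineno, rec in _read_rows(path, COUNT_TABLE_COLUMNS):
        try:
            out.append(
                BaseCountVector(
                    chrom=rec["chrom"],
                    pos=_int_field(path, lineno, rec, "pos"),
                    strand=rec["strand"],
                    ref_base=rec["ref"],
                    a=_int_field(path, lineno, rec, "A"),
                    t=_int_field(path, lineno, rec, "T"),
                    g=_int_field(path, lineno, rec, "G"),
                    c=_int_field(path, lineno, rec, "C"),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_base_count_table(
    vectors: Iterable[BaseCountVector], path, seed: int | None = None,
) -> None:
    _write_table(
        path, COUNT_TABLE_COLUMNS,
        ((v.chrom, v.pos, v.strand, v.ref_base, v.a, v.t, v.g, v.c) for v in vectors),
        seed, None,
    )


def write_calls(
    calls: Iterable[EditingSiteCall], path, seed: int | None = None,
    config: dict | None = None,
) -> None:
    _write_table(
        path, CALL_COLUMNS,
        (
            (c.chrom, c.pos, c.strand, c.ref_base, c.edited_reads, c.total_reads,
             c.editing_rate, c.angle, c.wt_norm, c.transcript_id, c.classification)
            for c in calls
        ),
        seed, config,
    )


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED (3+ column) file into (chrom, start, end) tuples,
    0-based half-open."""
    path = Path(path)
    out = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs at least 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: BED start/end must be integers"
                ) from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: BED interval start >= end")
            out.append((fields[0], start, end))
    return out


def read_transcript_map(path) -> dict[tuple[str, int], str]:
    """TSV (chrom, pos, transcript_id) mapping sites to transcripts."""
    out = {}
    for lineno, rec in _read_rows(path, ("chrom", "pos", "transcript_id")):
        out[(rec["chrom"], _int_field(path, lineno, rec, "pos"))] = rec["transcript_id"]
    return out
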