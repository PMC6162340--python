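"""Alignment-based premature stop-codon calling and abundance filtering.

Reads (Sanger per-cell sequences or assembled NGS amplicon reads) are
globally aligned to the V-gene template, translated in the template-anchored
forward frame, and scanned for premature stop codons; indels whose net
length is not a multiple of 3 are frameshifts and count as stop-causing.

For bulk NGS samples of n sorted cells, a unique sequence present in one
cell should account for roughly (100/n)% of reads, so unique sequences are
kept only when their read share is strictly greater than (100/n)% — this
removes sequencing-error singletons while retaining anything carried by one
or more real cells.  The per-sample stop frequency is computed over reads
passing that threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .template import STOP_CODONS, VGeneTemplate

__all__ = [
    "AlignmentResult",
    "StopCall",
    "StopCallResult",
    "SampleReads",
    "make_aligner",
    "align_to_template",
    "call_stops",
    "call_sequence",
    "collapse_reads",
    "abundance_filter",
    "sample_stop_frequency",
    "sanger_call_cells",
    "process_ngs_sample",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.5


def make_aligner(match: float = 5.0, mismatch: float = -4.0,
                 gap_open: float = 10.0, gap_extend: float = 0.5) -> Align.PairwiseAligner:
    """Global affine-gap aligner with EMBOSS-needle-style default scores
    (match 5, mismatch -4, gap open 10, gap extend 0.5)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # EMBOSS convention: a gap of length L costs gap_open + L * gap_extend;
    # PairwiseAligner charges open on the first position and extend after,
    # so fold one extension into the opening score
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """A read/template global alignment, template row first."""

    aligned_template: str
    aligned_read: str
    score: float
    identity: float
    n_mismatches: int
    n_gap_blocks: int
    net_indel: int          # template length minus read length (deletions > 0)
    reverse_complemented: bool
    aligned: bool           # False when identity fell below the floor


@dataclass(frozen=True)
class StopCall:
    template_codon: int     # 1-based template codon index
    call_type: str          # "substitution_stop" | "frameshift"


@dataclass(frozen=True)
class StopCallResult:
    sequence_id: str
    aligned: bool
    calls: tuple[StopCall, ...] = ()
    n_mutations: int = 0
    read_count: int = 1
    read_fraction: float = float("nan")
    passes_threshold: bool = True

    @property
    def has_premature_stop(self) -> bool:
        return len(self.calls) > 0


@dataclass
class SampleReads:
    """Reads for one sorted sample.

    In ``"sanger"`` mode each read is one cell (read ids are cell ids); in
    ``"ngs"`` mode reads are bulk amplicon reads from ``n_cells_sorted``
    cells.
    """

    sample_id: str
    n_cells_sorted: int
    reads: list[tuple[str, str]]
    mode: str = "ngs"

    def __post_init__(self):
        if self.n_cells_sorted <= 0:
            raise ValueError("n_cells_sorted must be positive")
        if self.mode not in ("sanger", "ngs"):
            raise ValueError("mode must be 'sanger' or 'ngs'")
        if self.mode == "sanger":
            ids = [rid for rid, _ in self.reads]
            if len(ids) != len(set(ids)):
                raise ValueError("sanger mode requires exactly one sequence per cell id")


def _pairwise_stats(a_template: str, a_read: str) -> tuple[int, int, int]:
    """(matches, mismatches, gap blocks in either row) over alignment columns."""
    matches = mismatches = gap_blocks = 0
    in_gap = False
    for t, r in zip(a_template, a_read):
        if t == "-" or r == "-":
            if not in_gap:
                gap_blocks += 1
                in_gap = True
        else:
            in_gap = False
            if t == r:
                matches += 1
            else:
                mismatches += 1
    return matches, mismatches, gap_blocks


def _result_from_alignment(alignment, read_len: int, template_len: int,
                           revcomp: bool, min_identity: float) -> AlignmentResult:
    a_template, a_read = str(alignment[0]), str(alignment[1])
    matches, mismatches, gap_blocks = _pairwise_stats(a_template, a_read)
    identity = matches / max(1, len(a_template))
    return AlignmentResult(
        aligned_template=a_template, aligned_read=a_read,
        score=float(alignment.score), identity=identity,
        n_mismatches=mismatches, n_gap_blocks=gap_blocks,
        net_indel=template_len - read_len,
        reverse_complemented=revcomp,
        aligned=identity >= min_identity,
    )


def align_to_template(read: str, template: VGeneTemplate,
                      aligner: Align.PairwiseAligner | None = None,
                      min_identity: float = DEFAULT_MIN_IDENTITY,
                      try_reverse_complement: bool = True) -> AlignmentResult:
    """Globally align a read to the template, auto-reorienting reverse-
    complement reads.  Reads below the identity floor come back with
    ``aligned=False`` and are excluded upstream with a logged warning."""
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    if aligner is None:
        aligner = make_aligner()

    # Identical and equal-length near-identical reads dominate real samples;
    # a direct comparison short-circuits the dynamic program for them.
    if len(read) == template.length:
        mismatches = sum(1 for a, b in zip(template.seq, read) if a != b)
        if mismatches / template.length <= 0.2:
            identity = 1.0 - mismatches / template.length
            return AlignmentResult(template.seq, read, float("nan"), identity,
                                   mismatches, 0, 0, False, identity >= min_identity)

    fwd = next(iter(aligner.align(template.seq, read)))
    best = _result_from_alignment(fwd, len(read), template.length, False, min_identity)
    if try_reverse_complement:
        rc = str(Seq(read).reverse_complement())
        rev = next(iter(aligner.align(template.seq, rc)))
        if rev.score > fwd.score:
            best = _result_from_alignment(rev, len(read), template.length, True, min_identity)
    if not best.aligned:
        logger.warning("read excluded: identity %.2f below floor %.2f",
                       best.identity, min_identity)
    return best


def _first_frameshift_block(alignment: AlignmentResult) -> tuple[int, int]:
    """(1-based template codon, 0-based ungapped-read position) of the first
    gap block that breaks the reading frame (its own length, or the
    cumulative indel offset, not a multiple of 3)."""
    tpos = rpos = 0
    offset = 0
    block_len = 0
    block_start = (0, 0)  # (tpos, rpos)
    prev_gap = None  # "read" | "template" | None

    def breaks(prev_gap, block_len, offset):
        delta = block_len if prev_gap == "read" else -block_len
        return (offset + delta) % 3 != 0 or delta % 3 != 0, offset + delta

    for t, r in zip(alignment.aligned_template, alignment.aligned_read):
        gap = "read" if r == "-" else ("template" if t == "-" else None)
        if gap != prev_gap:
            if prev_gap is not None:
                broke, offset = breaks(prev_gap, block_len, offset)
                if broke:
                    return block_start[0] // 3 + 1, block_start[1]
            block_len = 0
            block_start = (tpos, rpos)
            prev_gap = gap
        if gap is not None:
            block_len += 1
        if t != "-":
            tpos += 1
        if r != "-":
            rpos += 1
    if prev_gap is not None:
        broke, offset = breaks(prev_gap, block_len, offset)
        if broke:
            return block_start[0] // 3 + 1, block_start[1]
    return max(1, tpos // 3), rpos  # net frameshift with no single breaking block


def _read_to_template_codon(alignment: AlignmentResult, read_pos: int) -> int:
    """1-based template codon containing the template column matched to
    ``read_pos`` (0-based position in the ungapped read)."""
    rpos = tpos = 0
    last_tpos = 0
    for t, r in zip(alignment.aligned_template, alignment.aligned_read):
        if t != "-":
            last_tpos = tpos
        if r != "-":
            if rpos == read_pos:
                return last_tpos // 3 + 1
            rpos += 1
        if t != "-":
            tpos += 1
    return last_tpos // 3 + 1


def call_stops(alignment: AlignmentResult, template: VGeneTemplate,
               sequence_id: str = "", count_frameshifts: bool = True,
               ) -> StopCallResult:
    """Call premature stops on one aligned read.

    A net frameshift yields one ``frameshift`` call at the first frame-
    breaking gap's template codon.  The read is then translated in the
    template-anchored forward frame and any stop codon strictly before its
    final complete codon yields a ``substitution_stop`` call at the
    corresponding template codon.
    """
    if not alignment.aligned:
        return StopCallResult(sequence_id, aligned=False)
    read = alignment.aligned_read.replace("-", "")
    calls: list[StopCall] = []
    net = alignment.net_indel
    scan_codons = len(read) // 3 - 1  # the read's final codon is the template's end
    if net % 3 != 0:
        codon, break_rpos = _first_frameshift_block(alignment)
        if count_frameshifts:
            calls.append(StopCall(codon, "frameshift"))
        # downstream of the frame break the naive translation is out of
        # frame; only the in-frame prefix is scanned for substitution stops
        scan_codons = min(scan_codons, break_rpos // 3)
    for j in range(max(0, scan_codons)):
        if read[3 * j:3 * j + 3] in STOP_CODONS:
            calls.append(StopCall(_read_to_template_codon(alignment, 3 * j),
                                  "substitution_stop"))
    n_mut = alignment.n_mismatches + alignment.n_gap_blocks
    return StopCallResult(sequence_id, aligned=True, calls=tuple(calls),
                          n_mutations=n_mut)


def call_sequence(read: str, template: VGeneTemplate,
                  sequence_id: str = "",
                  aligner: Align.PairwiseAligner | None = None,
                  min_identity: float = DEFAULT_MIN_IDENTITY) -> StopCallResult:
    """Convenience: align then call one sequence."""
    aln = align_to_template(read, template, aligner, min_identity)
    return call_stops(aln, template, sequence_id)


def collapse_reads(sample: SampleReads) -> pd.DataFrame:
    """Group identical NGS read sequences.

    Returns a DataFrame with columns ``sequence``, ``read_count``,
    ``read_fraction`` and ``first_read_id``, sorted by descending count then
    sequence (deterministic).  Fractions sum to 1.
    """
    if sample.mode != "ngs":
        raise ValueError("collapse_reads applies to ngs samples")
    if not sample.reads:
        raise ValueError(f"sample {sample.sample_id} has no reads")
    df = pd.DataFrame(sample.reads, columns=["read_id", "sequence"])
    grouped = (df.groupby("sequence", sort=False)
                 .agg(read_count=("read_id", "size"), first_read_id=("read_id", "first"))
                 .reset_index())
    grouped["read_fraction"] = grouped["read_count"] / grouped["read_count"].sum()
    return (grouped.sort_values(["read_count", "sequence"], ascending=[False, True])
                   .reset_index(drop=True))


def abundance_filter(collapsed: pd.DataFrame, n_cells_sorted: int) -> pd.DataFrame:
    """Mark unique sequences passing the (100/n)% read-share threshold.

    A sequence passes only when its read share, in percent, is *strictly*
    greater than 100/n_cells_sorted.
    """
    if n_cells_sorted <= 0:
        raise ValueError("n_cells_sorted must be positive")
    out = collapsed.copy()
    threshold = 100.0 / n_cells_sorted
    out["passes_threshold"] = out["read_fraction"] * 100.0 > threshold
    return out


def sample_stop_frequency(calls: pd.DataFrame) -> float:
    """Percent of threshold-passing reads whose sequence carries >= 1 stop
    call.  Requires columns ``read_count``, ``passes_threshold``,
    ``has_premature_stop``.  Returns NaN (with a warning) if nothing passes."""
    passing = calls[calls["passes_threshold"]]
    total = passing["read_count"].sum()
    if total == 0:
        warnings.warn("no reads pass the abundance threshold; frequency undefined")
        return float("nan")
    stop_reads = passing.loc[passing["has_premature_stop"], "read_count"].sum()
    return 100.0 * stop_reads / total


def sanger_call_cells(sample: SampleReads, template: VGeneTemplate,
                      aligner: Align.PairwiseAligner | None = None,
                      min_identity: float = DEFAULT_MIN_IDENTITY) -> pd.DataFrame:
    """Per-cell stop calls for a Sanger sample (no abundance filtering).

    Unalignable cells are reported with ``aligned=False`` and a null stop
    status, never as stop-positive.
    """
    if sample.mode != "sanger":
        raise ValueError("sanger_call_cells applies to sanger samples")
    if aligner is None:
        aligner = make_aligner()
    rows = []
    for cell_id, seq in sample.reads:
        res = call_sequence(seq, template, cell_id, aligner, min_identity)
        rows.append({
            "sample_id": sample.sample_id,
            "cell_id": cell_id,
            "aligned": res.aligned,
            "has_premature_stop": res.has_premature_stop if res.aligned else None,
            "n_calls": len(res.calls),
            "call_positions": ";".join(str(c.template_codon) for c in res.calls),
            "call_types": ";".join(c.call_type for c in res.calls),
            "n_mutations": res.n_mutations,
        })
    return pd.DataFrame(rows)


def process_ngs_sample(sample: SampleReads, template: VGeneTemplate,
                       aligner: Align.PairwiseAligner | None = None,
                       min_identity: float = DEFAULT_MIN_IDENTITY,
                       ) -> tuple[pd.DataFrame, float]:
    """Collapse, filter and call one NGS sample.

    Returns the per-unique-sequence call table and the sample stop
    frequency (percent, over threshold-passing reads).
    """
    if aligner is None:
        aligner = make_aligner()
    table = abundance_filter(collapse_reads(sample), sample.n_cells_sorted)
    results = []
    for _, row in table.iterrows():
        res = call_sequence(row["sequence"], template, row["first_read_id"],
                            aligner, min_identity)
        results.append(res)
    table = table.assign(
        aligned=[r.aligned for r in results],
        has_premature_stop=[r.aligned and r.has_premature_stop for r in results],
        n_calls=[len(r.calls) for r in results],
        call_positions=[";".join(str(c.template_codon) for c in r.calls) for r in results],
        call_types=[";".join(c.call_type for c in r.calls) for r in results],
        n_mutations=[r.n_mutations for r in results],
        sample_id=sample.sample_id,
    )
    # unalignable sequences are excluded from the frequency denominator
    table.loc[~table["aligned"], "passes_threshold"] = False
    freq = sample_stop_frequency(table)
    return table, freq
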