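"""Reference-based Hi-C pair QC from name-grouped alignments.

Implements the classic cut-site classification of Hi-C read pairs (valid
pairs separated by at least two intervening cut sites; dangling ends,
self-circles and religation products otherwise), separation statistics
(trans fraction, >1 kb and >10 kb fractions, log-binned histogram),
read-through detection (alignments clipped at a cut site), and a
sigma-clipped estimate of the conventional-fragment insert length, which
feeds the unobserved-fraction correction of the read-through rate.

Orientation semantics follow field convention: mates on one restriction
fragment pointing toward each other are dangling ends (an unligated
biotinylated fragment sequences inward), pointing away from each other are
self-circles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pysam

from .digest import Enzyme, JunctionSet, find_cut_sites
from .kmer_mode import alpha_fragment

__all__ = [
    "CutSiteIndex",
    "PairClass",
    "MateInfo",
    "BamStats",
    "build_cut_index",
    "classify_pair",
    "separation",
    "detect_read_through",
    "sigma_clip_insert",
    "unobs_and_adjust",
    "bam_report",
]

DEFAULT_MIN_MAPQ = 10
SHORT_RANGE_BP = 1000
LONG_RANGE_BP = 10_000
CUT_SITE_TOLERANCE = 1  # bp slack when matching a clip boundary to a cut


class PairClass(str, Enum):
    VALID_FF = "valid_ff"
    VALID_FR = "valid_fr"
    VALID_RF = "valid_rf"
    VALID_TRANS = "valid_trans"
    DANGLING_END = "dangling_end"
    SELF_CIRCLE = "self_circle"
    RELIGATION = "religation"
    INVALID_OTHER = "invalid_other"


VALID_CLASSES = frozenset(
    {PairClass.VALID_FF, PairClass.VALID_FR, PairClass.VALID_RF, PairClass.VALID_TRANS}
)


@dataclass
class CutSiteIndex:
    """Per-contig ascending cut positions (0-based) and contig lengths."""

    cuts: dict[str, np.ndarray]
    contig_lengths: dict[str, int]

    def n_between(self, contig: str, lo: int, hi: int) -> int:
        """Number of cut sites strictly between positions lo and hi."""
        if lo > hi:
            lo, hi = hi, lo
        c = self.cuts[contig]
        return int(np.searchsorted(c, hi, "left") - np.searchsorted(c, lo, "right"))

    def nearest_distance(self, contig: str, pos: int) -> int:
        c = self.cuts[contig]
        if c.size == 0:
            return 1 << 30
        i = int(np.searchsorted(c, pos))
        best = 1 << 30
        for j in (i - 1, i):
            if 0 <= j < c.size:
                best = min(best, abs(int(c[j]) - pos))
        return best


def build_cut_index(
    reference: str | Path | dict[str, str], enzymes: list[Enzyme]
) -> CutSiteIndex:
    """Scan a FASTA reference (or {name: seq} dict) for cut positions."""
    if isinstance(reference, dict):
        contigs = reference
    else:
        contigs = {}
        with pysam.FastxFile(str(reference)) as fx:
            for rec in fx:
                contigs[rec.name] = rec.sequence
    if not contigs:
        raise ValueError("empty reference")
    cuts: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for name, seq in contigs.items():
        pos: set[int] = set()
        for enz in enzymes:
            pos.update(find_cut_sites(seq, enz))
        cuts[name] = np.array(sorted(pos), dtype=np.int64)
        lengths[name] = len(seq)
    return CutSiteIndex(cuts=cuts, contig_lengths=lengths)


@dataclass(frozen=True)
class MateInfo:
    """Minimal alignment facts for one mate of a pair."""

    contig: str
    start: int  # leftmost aligned reference position, 0-based
    end: int  # one past the rightmost aligned reference position
    reverse: bool
    read_length: int
    mapq: int = 60
    clip_3p: int = 0  # soft/hard clipped bases at the 3' (sequencing) end

    @property
    def pos5(self) -> int:
        """5' mapping coordinate: start for forward, end-1 for reverse."""
        return self.end - 1 if self.reverse else self.start

    @property
    def end3(self) -> int:
        """Reference coordinate of the 3' alignment boundary."""
        return self.start if self.reverse else self.end


def mate_from_alignment(aln: pysam.AlignedSegment) -> MateInfo:
    cig = aln.cigartuples or []
    # ops 4 (S) and 5 (H) at the 3' sequencing end: last for forward reads,
    # first for reverse reads
    if aln.is_reverse:
        clip = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
    else:
        clip = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
    return MateInfo(
        contig=aln.reference_name,
        start=aln.reference_start,
        end=aln.reference_end,
        reverse=aln.is_reverse,
        read_length=aln.infer_read_length() or aln.query_length,
        mapq=aln.mapping_quality,
        clip_3p=clip,
    )


def classify_pair(a: MateInfo, b: MateInfo, index: CutSiteIndex) -> PairClass:
    """Cut-site classification of one mapped pair.

    Different contigs are valid trans pairs.  On one contig, cut sites
    strictly between the mates' 5' coordinates decide: >= 2 intervening
    sites are valid (labelled by orientation), 0 sites mean one fragment
    (dangling end when the mates point toward each other, self-circle when
    away), and 1 intervening site with inward-facing mates is a religation
    at the shared cut.
    """
    if a.contig != b.contig:
        return PairClass.VALID_TRANS
    left, right = (a, b) if a.pos5 <= b.pos5 else (b, a)
    n_int = index.n_between(a.contig, left.pos5, right.pos5)
    inward = (not left.reverse) and right.reverse
    outward = left.reverse and (not right.reverse)
    if n_int >= 2:
        if inward:
            return PairClass.VALID_FR
        if outward:
            return PairClass.VALID_RF
        return PairClass.VALID_FF
    if n_int == 0:
        if inward:
            return PairClass.DANGLING_END
        if outward:
            return PairClass.SELF_CIRCLE
        return PairClass.INVALID_OTHER
    # exactly one intervening cut: inward mates facing the shared site
    return PairClass.RELIGATION if inward else PairClass.INVALID_OTHER


def separation(a: MateInfo, b: MateInfo) -> int | None:
    """Outermost-coordinate span for cis pairs; None for trans."""
    if a.contig != b.contig:
        return None
    return max(a.end, b.end) - min(a.start, b.start)


def detect_read_through(
    mate: MateInfo,
    index: CutSiteIndex,
    junctions: JunctionSet,
    tolerance: int = CUT_SITE_TOLERANCE,
) -> bool:
    """True when an alignment ends early at a cut site with a clipped tail.

    A read sequencing across a proximity-ligation junction stops aligning
    at the junction; its 3' boundary falls on a cut site (within
    ``tolerance`` bp) and at least ceil(l_LA/2) bases are soft/hard clipped
    (unaligned or carried as a supplementary alignment).
    """
    min_clip = math.ceil(junctions.l_la_max / 2)
    if mate.clip_3p < min_clip:
        return False
    return index.nearest_distance(mate.contig, mate.end3) <= tolerance


def sigma_clip_insert(
    separations, n_sigma: float = 3.0, max_iter: int = 10, gate: int = SHORT_RANGE_BP
) -> float:
    """Sigma-clipped mean of sub-``gate`` cis separations.

    The short-range peak of a Hi-C separation distribution is dominated by
    conventional (non-proximity-ligation) fragments, so its robust mean
    estimates the library insert length.
    """
    x = np.asarray(list(separations), dtype=float)
    x = x[x < gate]
    if x.size < 100:
        raise ValueError(
            f"only {x.size} cis separations below {gate} bp; at least 100 "
            "are needed for a stable insert estimate (supply more pairs)"
        )
    for _ in range(max_iter):
        mu, sd = x.mean(), x.std()
        keep = np.abs(x - mu) <= n_sigma * sd
        if keep.all():
            break
        x = x[keep]
    return float(x.mean())


def unobs_and_adjust(
    mean_insert: float,
    read_lengths: tuple[float, float],
    read_through_frac: float,
    l_la: int,
) -> tuple[float, float]:
    """Unobserved fraction from the pair coverage mask, and the adjusted
    read-through fraction observed / (1 - alpha)."""
    alpha = alpha_fragment(
        [int(read_lengths[0]), int(read_lengths[1])], l_la, mean_insert
    )
    denom = 1.0 - alpha
    return alpha, (read_through_frac / denom if denom > 0 else 1.0)


@dataclass
class BamStats:
    """Aggregate reference-based QC statistics over N analyzed pairs."""

    n_pairs_seen: int
    n_analyzed: int
    n_filtered: int
    class_counts: dict[str, int]
    trans_frac: float
    long_range_frac_1kb: float
    long_range_frac_10kb: float
    read_through_count: int
    read_through_frac: float
    adj_read_through_frac: float
    mean_insert: float | None
    unobs_frac: float | None
    histogram: dict[str, list[float]] = field(default_factory=dict)

    @property
    def valid_frac(self) -> float:
        v = sum(c for k, v_ in self.class_counts.items()
                for c in [v_] if PairClass(k) in VALID_CLASSES)
        return v / self.n_analyzed if self.n_analyzed else 0.0


def _iter_name_groups(bam: pysam.AlignmentFile):
    group: list[pysam.AlignedSegment] = []
    name = None
    for aln in bam:
        if name is not None and aln.query_name != name:
            yield group
            group = []
        name = aln.query_name
        group.append(aln)
    if group:
        yield group


def bam_report(
    bam_path: str | Path,
    reference: str | Path | dict[str, str],
    enzymes: list[Enzyme],
    junctions: JunctionSet,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> BamStats:
    """Stream a name-grouped BAM/SAM once and compute all QC statistics."""
    index = build_cut_index(reference, enzymes)
    mode = "r" if str(bam_path).endswith(".sam") else "rb"
    bam = pysam.AlignmentFile(str(bam_path), mode)
    so = (bam.header.get("HD") or {}).get("SO", "")
    if so == "coordinate":
        bam.close()
        raise ValueError(
            "coordinate-sorted input: BAM must be grouped by read name "
            "(sort -n or collate) so mates are adjacent"
        )
    for contig in bam.references:
        if contig not in index.cuts:
            bam.close()
            raise ValueError(f"contig {contig!r} in BAM header missing from reference")

    class_counts = {c.value: 0 for c in PairClass}
    seps: list[int] = []
    n_pairs_seen = n_analyzed = n_filtered = 0
    n_trans = n_gt1k = n_gt10k = 0
    rt_count = 0
    n_reads_analyzed = 0
    read_len_sum = 0.0

    for group in _iter_name_groups(bam):
        primaries = [a for a in group if not (a.is_secondary or a.is_supplementary)]
        mates1 = [a for a in primaries if a.is_read1 or not a.is_read2]
        mates2 = [a for a in primaries if a.is_read2]
        if not mates1 or not mates2:
            continue  # unpaired record, not a pair
        a_aln, b_aln = mates1[0], mates2[0]
        n_pairs_seen += 1
        if (
            a_aln.is_unmapped
            or b_aln.is_unmapped
            or a_aln.is_duplicate
            or b_aln.is_duplicate
            or a_aln.mapping_quality < min_mapq
            or b_aln.mapping_quality < min_mapq
        ):
            n_filtered += 1
            continue
        a, b = mate_from_alignment(a_aln), mate_from_alignment(b_aln)
        n_analyzed += 1
        cls = classify_pair(a, b, index)
        class_counts[cls.value] += 1
        sep = separation(a, b)
        if sep is None:
            n_trans += 1
        else:
            seps.append(sep)
            if sep > SHORT_RANGE_BP:
                n_gt1k += 1
            if sep > LONG_RANGE_BP:
                n_gt10k += 1
        for m in (a, b):
            n_reads_analyzed += 1
            read_len_sum += m.read_length
            if detect_read_through(m, index, junctions):
                rt_count += 1
    bam.close()
    if n_pairs_seen == 0:
        raise ValueError("no pairs found in input")
    if n_analyzed == 0:
        raise ValueError("no pairs passed filters")

    rt_frac = rt_count / n_reads_analyzed if n_reads_analyzed else 0.0
    mean_insert = None
    unobs = None
    adj_rt = rt_frac
    try:
        mean_insert = sigma_clip_insert(seps)
    except ValueError:
        pass
    if mean_insert is not None:
        mean_rl = read_len_sum / n_reads_analyzed
        unobs, adj_rt = unobs_and_adjust(
            mean_insert, (mean_rl, mean_rl), rt_frac, junctions.l_la_max
        )

    if seps:
        log_edges = np.logspace(1, 8, 36)
        hist, edges = np.histogram(seps, bins=log_edges)
        histogram = {"bin_edges_bp": edges.tolist(), "count": hist.tolist()}
    else:
        histogram = {"bin_edges_bp": [], "count": []}

    return BamStats(
        n_pairs_seen=n_pairs_seen,
        n_analyzed=n_analyzed,
        n_filtered=n_filtered,
        class_counts=class_counts,
        trans_frac=n_trans / n_analyzed,
        long_range_frac_1kb=n_gt1k / n_analyzed,
        long_range_frac_10kb=n_gt10k / n_analyzed,
        read_through_count=rt_count,
        read_through_frac=rt_frac,
        adj_read_through_frac=adj_rt,
        mean_insert=mean_insert,
        unobs_frac=unobs,
        histogram=histogram,
    )
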