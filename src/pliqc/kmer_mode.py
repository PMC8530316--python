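"""Reference-free estimation of the proximity-ligation (Hi-C) fraction.

The estimator scans a sample of read pairs (or pre-merged reads) for the
digest's ligation-junction motif.  For every fragment it records a relative
local k-mer frequency phi — the ratio of geometric means of three k-mers
spanning the candidate site (inner set) to six k-mers flanking it (outer
set) — together with a binary indicator lambda for junction presence.
Junction sites created by proximity ligation are chimeric and therefore
carry k-mers that are rare relative to their flanks (phi << 1), whereas a
junction motif that occurs natively in the genome has phi ~ 1.

Empirical rank p-values computed from the lambda=0 (null) observations are
assigned to the lambda=1 observations; each junction observation then
contributes its probability of *not* being explainable as a native-frequency
site, yielding the observed proximity-ligation fraction rho_obs.  Bootstrap
resampling of the observation table provides 95% confidence intervals.
Finally rho_obs is corrected by the expected fraction of insert extent on
which a junction could never have been detected (unobserved fraction
alpha), giving the library-wide estimate rho_lib = rho_obs / (1 - alpha).

Two unobserved-fraction masks are provided.  The plain mask counts only the
unsequenced insert middle and the (l_LA - 1)-base blind spot at each read's
3' end; it is what the reference-based mode reports.  The estimator itself
uses a window-aware mask that additionally excludes the k-sized flanks a
junction needs on both sides for its frequency inspection — without this
the correction does not match what the detector can actually see, and
rho_lib is biased low by roughly 2k/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .digest import JunctionSet
from .kmer_index import KmerDatabase, build_db

__all__ = [
    "LibraryParams",
    "ObservationTable",
    "EmpiricalPvalueTable",
    "BootstrapResult",
    "feasible_window",
    "find_junction",
    "flanking_kmers",
    "relative_frequency",
    "alpha_fragment",
    "collect_observations",
    "empirical_pvalue_table",
    "lookup_pvalue",
    "bootstrap",
    "estimate_library",
    "iter_fragments",
]

OUTER_COVERAGE_DIVISOR = 2.5  # reject when GM(outer) < f_bar / 2.5

K_DEFAULT = 24
K_ACCEPTED = (16, 32)
K_RECOMMENDED = (24, 32)


@dataclass
class LibraryParams:
    """Run parameters for the reference-free estimator.

    mean_insert
        User-supplied mean library insert length L-bar in bases; drives the
        unobserved-fraction correction for unmerged pairs.
    k
        Flanking k-mer size.  Must exceed the longest junction motif.
    n_boot
        Number of bootstrap resamples of the observation table.
    max_observations
        Stop after this many accepted observation rows.  The default of
        20000 gives a standard error on rho_obs of roughly 0.3 percentage
        points, ample for a QC verdict.
    """

    mean_insert: float
    junctions: JunctionSet
    k: int = K_DEFAULT
    n_boot: int = 100
    max_observations: int | None = 20_000
    seed: int = 1
    literal_sum: bool = False  # sum p-hat instead of (1 - p-hat); see docs

    def __post_init__(self) -> None:
        if self.mean_insert <= 0:
            raise ValueError("mean insert length must be positive")
        if self.k <= self.junctions.l_la_max:
            raise ValueError(
                f"k={self.k} must exceed the longest junction motif "
                f"({self.junctions.l_la_max} bp)"
            )
        if not K_ACCEPTED[0] <= self.k <= K_ACCEPTED[1]:
            raise ValueError(f"k={self.k} outside accepted range {K_ACCEPTED}")


# -- geometry -------------------------------------------------------------


def feasible_window(l_read: int, k: int, l_la: int) -> tuple[int, int]:
    """Inclusive 0-based range of junction starts usable within a read.

    All nine k-mers (three inner, six outer) must fit inside the read:
    the left outer set begins at x-(k+1) and the right outer set ends at
    x+l_la+k, so lo = k+1 and hi = l_read - l_la - k - 1.
    """
    lo, hi = k + 1, l_read - l_la - k - 1
    if hi < lo:
        raise ValueError(
            f"read unusable: length {l_read} < {2 * k + l_la + 2} "
            f"(2k + l_LA + 2 for k={k}, l_LA={l_la})"
        )
    return lo, hi


def find_junction(
    read: str, junctions: JunctionSet, window: tuple[int, int]
) -> tuple[int, str] | str | None:
    """Leftmost in-window junction occurrence in ``read``.

    Returns ``(x, motif)`` for a hit whose start lies in the inclusive
    ``window``; the string ``"outside"`` when occurrences exist only outside
    the window; ``None`` for a motif-free read.
    """
    lo, hi = window
    best: tuple[int, str] | None = None
    any_hit = False
    for motif in junctions.concrete:
        start = read.find(motif)
        while start != -1:
            any_hit = True
            if start >= lo:
                if start <= hi and (best is None or start < best[0]):
                    best = (start, motif)
                break  # later occurrences of this motif cannot be better
            start = read.find(motif, start + 1)
    if best is not None:
        return best
    return "outside" if any_hit else None


def flanking_kmers(
    read: str, x: int, k: int, l_la: int
) -> tuple[list[str], list[str]]:
    """(inner, outer) k-mers around a junction/sample start ``x``.

    Inner starts {x-1, x, x+1}; outer starts {x-(k+1), x-k, x-(k-1)} on the
    left and {x+l_la-1, x+l_la, x+l_la+1} on the right.  ``x`` must lie in
    the feasible window so every substring fits.
    """
    inner = [read[s : s + k] for s in (x - 1, x, x + 1)]
    outer_starts = (
        x - (k + 1), x - k, x - (k - 1),
        x + l_la - 1, x + l_la, x + l_la + 1,
    )
    outer = [read[s : s + k] for s in outer_starts]
    return inner, outer


def relative_frequency(
    inner_counts: Sequence[int | None],
    outer_counts: Sequence[int | None],
    f_bar: float,
) -> tuple[float | None, str | None]:
    """phi = GM(inner)/GM(outer), or (None, reason) when rejected.

    Any missing k-mer abandons the calculation.  Outer coverage below
    f_bar/2.5 is rejected; the inner set is deliberately unconstrained
    (an introduced junction is *expected* to have low inner coverage).
    """
    if any(c is None for c in inner_counts) or any(c is None for c in outer_counts):
        return None, "missing k-mer"
    gm_outer = math.exp(sum(math.log(c) for c in outer_counts) / len(outer_counts))
    if gm_outer < f_bar / OUTER_COVERAGE_DIVISOR:
        return None, "low outer coverage"
    gm_inner = math.exp(sum(math.log(c) for c in inner_counts) / len(inner_counts))
    return gm_inner / gm_outer, None


# -- unobserved fraction --------------------------------------------------


def _interval_union(intervals: list[tuple[float, float]]) -> float:
    total, hi_prev = 0.0, -math.inf
    for lo, hi in sorted(intervals):
        if hi <= lo:
            continue
        if lo > hi_prev:
            total += hi - lo
            hi_prev = hi
        elif hi > hi_prev:
            total += hi - hi_prev
            hi_prev = hi
    return total


def alpha_fragment(
    lengths: Sequence[int],
    l_la: int,
    mean_insert: float | None = None,
    k: int | None = None,
    account_flanks: bool = False,
) -> float:
    """Unobserved fraction alpha_i for one fragment.

    ``lengths`` holds one read length (merged fragment, insert fully
    sequenced) or two (unmerged pair against the supplied mean insert
    L-bar).  With ``account_flanks=False`` (the plain mask) only the
    junction-match blind spot of l_LA - 1 bases at each read's 3' end and
    the unsequenced insert middle count as unobserved:

      merged:  alpha = 1 - (l - l_LA) / l
      paired:  read 1 observes [0, l1 - (l_LA - 1)), read 2 observes
               [L - l2 + (l_LA - 1), L); alpha = 1 - |union| / L

    With ``account_flanks=True`` the mask instead marks junction-start
    positions detectable by the k-mer inspection (feasible window per
    read), normalised by the L - l_LA + 1 possible junction starts.  This
    is the mask the reference-free estimator uses.
    """
    if any(l <= 0 for l in lengths):
        raise ValueError("read lengths must be positive")
    if account_flanks:
        if k is None:
            raise ValueError("k required for the window-aware mask")
        if len(lengths) == 1:
            (l,) = lengths
            denom = l - l_la + 1
            if denom <= 0:
                return 1.0
            lo, hi = k + 1, l - l_la - k - 1
            obs = max(0, hi - lo + 1)
            return min(1.0, max(0.0, 1.0 - obs / denom))
        l1, l2 = lengths
        lbar = float(mean_insert)
        denom = lbar - l_la + 1
        if denom <= 0:
            return 1.0
        iv = [
            (k + 1, min(l1 - l_la - k, lbar - l_la + 1)),
            (max(0, lbar - l2 + k + 1), lbar - l_la - k),
        ]
        iv = [(max(0.0, lo), max(0.0, hi)) for lo, hi in iv]
        obs = _interval_union(iv)
        return min(1.0, max(0.0, 1.0 - obs / denom))
    if len(lengths) == 1:
        (l,) = lengths
        return min(1.0, max(0.0, 1.0 - (l - l_la) / l))
    l1, l2 = lengths
    if mean_insert is None:
        raise ValueError("mean insert length required for unmerged pairs")
    lbar = float(mean_insert)
    iv = [
        (0.0, min(l1 - (l_la - 1), lbar)),
        (max(0.0, lbar - l2 + (l_la - 1)), lbar),
    ]
    obs = _interval_union(iv)
    return min(1.0, max(0.0, 1.0 - obs / lbar))


# -- observation collection ----------------------------------------------


@dataclass
class ObservationTable:
    """Rows (phi_i, lambda_i, alpha_i) plus rejection bookkeeping."""

    phi: np.ndarray
    lam: np.ndarray  # uint8, 1 = junction present
    alpha: np.ndarray
    k: int
    junctions: JunctionSet
    rejections: dict[str, int] = field(default_factory=dict)
    n_attempted: int = 0

    def __len__(self) -> int:
        return int(self.phi.size)

    @property
    def n_junction(self) -> int:
        return int(self.lam.sum())


def iter_fragments(
    r1: str | Path | None = None,
    r2: str | Path | None = None,
    merged: str | Path | None = None,
) -> Iterator[tuple[str, ...]]:
    """Yield fragments from FASTQ inputs: 2-tuples for pairs, 1-tuples merged."""
    if (r1 is None) != (r2 is None):
        raise ValueError("paired input requires both R1 and R2")
    if r1 is not None:
        with pysam.FastxFile(str(r1)) as f1, pysam.FastxFile(str(r2)) as f2:
            for a, b in zip(f1, f2):
                yield a.sequence, b.sequence
    if merged is not None:
        with pysam.FastxFile(str(merged)) as fm:
            for rec in fm:
                yield (rec.sequence,)


def collect_observations(
    fragments: Iterable[tuple[str, ...]],
    db: KmerDatabase,
    params: LibraryParams,
    rng: np.random.Generator,
) -> ObservationTable:
    """Scan fragments into an observation table.

    Per fragment: reads are searched for a junction (read 1 first; the
    first in-window hit wins and sets lambda=1).  Otherwise one read is
    chosen uniformly and a null position x is drawn uniformly from its
    feasible window (lambda=0).  A junction found only outside the feasible
    window is tallied and the fragment falls through to the null draw — the
    window-aware unobserved-fraction mask accounts for exactly those
    positions, keeping the corrected estimate consistent.  A failed phi
    computation discards the whole fragment observation.
    """
    l_la = params.junctions.l_la_max
    k = params.k
    if db.k != k:
        raise ValueError(f"database k={db.k} != params.k={k}")
    f_bar = db.f_bar
    gate = f_bar / OUTER_COVERAGE_DIVISOR
    max_rows = params.max_observations or np.inf

    rej = {
        "read_too_short": 0,
        "junction_outside_window": 0,
        "missing_kmer": 0,
        "low_outer_coverage": 0,
    }
    phis: list[np.ndarray] = []
    lams: list[np.ndarray] = []
    alphas: list[np.ndarray] = []
    n_attempted = 0
    n_rows = 0

    # cache window-aware alpha per length signature (usually one signature)
    alpha_cache: dict[tuple[int, ...], float] = {}

    def frag_alpha(lengths: tuple[int, ...]) -> float:
        a = alpha_cache.get(lengths)
        if a is None:
            a = alpha_fragment(
                lengths, l_la, params.mean_insert, k=k, account_flanks=True
            )
            alpha_cache[lengths] = a
        return a

    chunk_reads: list[str] = []
    chunk_x: list[int] = []
    chunk_lam: list[int] = []
    chunk_alpha: list[float] = []

    def flush_chunk() -> None:
        nonlocal n_rows
        if not chunk_reads:
            return
        m = len(chunk_reads)
        seqs: list[str] = []
        for read, x in zip(chunk_reads, chunk_x):
            inner, outer = flanking_kmers(read, x, k, l_la)
            seqs.extend(inner)
            seqs.extend(outer)
        counts = db.query_codes(db.canonical_codes(seqs)).reshape(m, 9).astype(float)
        missing = (counts < 0).any(axis=1)
        safe = np.where(counts <= 0, 1.0, counts)
        logc = np.log(safe)
        gm_inner = np.exp(logc[:, :3].mean(axis=1))
        gm_outer = np.exp(logc[:, 3:].mean(axis=1))
        low = (~missing) & (gm_outer < gate)
        ok = ~(missing | low)
        rej["missing_kmer"] += int(missing.sum())
        rej["low_outer_coverage"] += int(low.sum())
        phis.append((gm_inner / gm_outer)[ok])
        lams.append(np.asarray(chunk_lam, dtype=np.uint8)[ok])
        alphas.append(np.asarray(chunk_alpha, dtype=float)[ok])
        n_rows += int(ok.sum())
        chunk_reads.clear()
        chunk_x.clear()
        chunk_lam.clear()
        chunk_alpha.clear()

    for frag in fragments:
        if n_rows >= max_rows:
            break
        n_attempted += 1
        windows: list[tuple[int, int] | None] = []
        usable = []
        for read in frag:
            try:
                w = feasible_window(len(read), k, l_la)
            except ValueError:
                w = None
            windows.append(w)
            if w is not None:
                usable.append(read)
        if not usable:
            rej["read_too_short"] += 1
            continue
        hit: tuple[str, int] | None = None
        saw_outside = False
        for read, w in zip(frag, windows):
            if w is None:
                continue
            res = find_junction(read, params.junctions, w)
            if isinstance(res, tuple):
                hit = (read, res[0])
                break
            if res == "outside":
                saw_outside = True
        if hit is not None:
            read, x = hit
            lam = 1
        else:
            if saw_outside:
                rej["junction_outside_window"] += 1
            read = usable[int(rng.integers(len(usable)))] if len(usable) > 1 else usable[0]
            lo, hi = feasible_window(len(read), k, l_la)
            x = int(rng.integers(lo, hi + 1))
            lam = 0
        chunk_reads.append(read)
        chunk_x.append(x)
        chunk_lam.append(lam)
        chunk_alpha.append(frag_alpha(tuple(len(r) for r in frag)))
        if len(chunk_reads) >= 8192:
            flush_chunk()
    flush_chunk()

    if n_attempted == 0:
        raise ValueError("no input fragments")
    if n_rows == 0:
        raise ValueError("zero accepted observations")
    phi = np.concatenate(phis)[: int(max_rows) if max_rows != np.inf else None]
    lam_a = np.concatenate(lams)[: phi.size]
    alpha_a = np.concatenate(alphas)[: phi.size]
    return ObservationTable(
        phi=phi,
        lam=lam_a,
        alpha=alpha_a,
        k=k,
        junctions=params.junctions,
        rejections=rej,
        n_attempted=n_attempted,
    )


# -- empirical p-values ---------------------------------------------------


@dataclass
class EmpiricalPvalueTable:
    """Rank-order empirical p-values over unique null phi values.

    p-hat(phi) = (r(phi) + 1) / (n + 1) with r(phi) the count of unique
    null values <= phi and n the number of unique null values.
    """

    unique_phis: np.ndarray
    pvals: np.ndarray
    n: int


def empirical_pvalue_table(phis_lambda0: Sequence[float]) -> EmpiricalPvalueTable:
    u = np.unique(np.asarray(phis_lambda0, dtype=float))
    n = u.size
    if n < 2:
        raise ValueError("insufficient null observations (< 2 unique values)")
    p = (np.arange(1, n + 1) + 1) / (n + 1)
    return EmpiricalPvalueTable(unique_phis=u, pvals=p, n=n)


def lookup_pvalue(table: EmpiricalPvalueTable, phi: float | np.ndarray) -> np.ndarray:
    """p-hat of the nearest-not-greater unique phi; floor 1/(n+1) below all."""
    r = np.searchsorted(table.unique_phis, np.asarray(phi, dtype=float), side="right")
    return (r + 1) / (table.n + 1)


# -- bootstrap ------------------------------------------------------------


@dataclass
class Interval:
    point: float
    ci_low: float
    ci_high: float

    def as_dict(self) -> dict[str, float]:
        return {"point": self.point, "ci_low": self.ci_low, "ci_high": self.ci_high}


@dataclass
class BootstrapResult:
    rho_obs: Interval
    alpha_lib: Interval
    rho_lib: Interval
    n_boot: int
    rho_samples: np.ndarray
    alpha_samples: np.ndarray
    rho_lib_samples: np.ndarray
    seed: int
    no_junctions: bool = False


def _summary(samples: np.ndarray) -> Interval:
    lo = float(np.quantile(samples, 0.025))
    hi = float(np.quantile(samples, 0.975))
    # float summation can put the mean an ulp outside a degenerate interval
    point = min(max(float(samples.mean()), lo), hi)
    return Interval(point=point, ci_low=lo, ci_high=hi)


def bootstrap(
    table: ObservationTable, params: LibraryParams, rng: np.random.Generator
) -> BootstrapResult:
    """Bootstrap rho_obs, alpha_lib and rho_lib over resamples of the table.

    Each resample rebuilds the null p-value table, assigns p-values to the
    junction rows and computes rho_n = sum_{lambda=1}(1 - p-hat)/|t_n| and
    alpha_n = mean alpha_i; rho_lib is computed per resample as
    rho_n / (1 - alpha_n) (clamped to [0, 1]) so the correlation between
    the two is propagated into its interval.
    """
    n = len(table)
    if table.n_junction == 0:
        zero = Interval(0.0, 0.0, 0.0)
        a = _summary(
            np.array([table.alpha.mean()] * params.n_boot)
            if n
            else np.zeros(params.n_boot)
        )
        return BootstrapResult(
            rho_obs=zero,
            alpha_lib=a,
            rho_lib=zero,
            n_boot=params.n_boot,
            rho_samples=np.zeros(params.n_boot),
            alpha_samples=np.full(params.n_boot, table.alpha.mean() if n else 0.0),
            rho_lib_samples=np.zeros(params.n_boot),
            seed=params.seed,
            no_junctions=True,
        )
    phi, lam, alpha = table.phi, table.lam.astype(bool), table.alpha
    if np.unique(phi[~lam]).size < 2:
        raise ValueError("insufficient null observations (< 2 unique phi)")
    rho_s = np.empty(params.n_boot)
    alpha_s = np.empty(params.n_boot)
    rho_lib_s = np.empty(params.n_boot)
    for b in range(params.n_boot):
        idx = rng.integers(0, n, n)
        lam_b = lam[idx]
        phi_b = phi[idx]
        null_phi = phi_b[~lam_b]
        u = np.unique(null_phi)
        if u.size < 2 or lam_b.sum() == 0:
            rho_s[b] = 0.0
            alpha_s[b] = alpha[idx].mean()
            rho_lib_s[b] = 0.0
            continue
        tab = EmpiricalPvalueTable(u, (np.arange(1, u.size + 1) + 1) / (u.size + 1), u.size)
        p = lookup_pvalue(tab, phi_b[lam_b])
        contrib = p if params.literal_sum else (1.0 - p)
        rho_s[b] = contrib.sum() / n
        alpha_s[b] = alpha[idx].mean()
        denom = 1.0 - alpha_s[b]
        rho_lib_s[b] = min(1.0, rho_s[b] / denom) if denom > 0 else 1.0
    return BootstrapResult(
        rho_obs=_summary(rho_s),
        alpha_lib=_summary(alpha_s),
        rho_lib=_summary(rho_lib_s),
        n_boot=params.n_boot,
        rho_samples=rho_s,
        alpha_samples=alpha_s,
        rho_lib_samples=rho_lib_s,
        seed=params.seed,
        no_junctions=False,
    )


# -- orchestration --------------------------------------------------------


def estimate_library(
    params: LibraryParams,
    db: KmerDatabase | None = None,
    r1: str | Path | None = None,
    r2: str | Path | None = None,
    merged: str | Path | None = None,
    fragments: Iterable[tuple[str, ...]] | None = None,
) -> dict:
    """Full reference-free QC run: collect observations, bootstrap, report.

    Inputs may be FASTQ paths (R1/R2 and/or a merged file) or an in-memory
    fragment iterable.  When no database is supplied, one is built from the
    same FASTQ inputs (the standard single-pass workflow).  The returned
    dict is the kmer-mode results block of the QC report and is fully
    reproducible for a fixed seed.
    """
    if fragments is None and r1 is None and merged is None:
        raise ValueError("no input reads")
    if db is None:
        paths = [p for p in (r1, r2, merged) if p is not None]
        if not paths:
            raise ValueError("cannot build a k-mer database from in-memory input")
        db = build_db(paths, params.k)
    rng = np.random.default_rng(params.seed)
    if fragments is None:
        fragments = iter_fragments(r1, r2, merged)
    table = collect_observations(fragments, db, params, rng)
    result = bootstrap(table, params, rng)
    flags = ["no junctions observed"] if result.no_junctions else []
    return {
        "mode": "kmer",
        "k": params.k,
        "enzymes": [e.name for e in params.junctions.enzymes],
        "junctions": {m.sequence: m.l_la for m in params.junctions.motifs},
        "mean_insert": params.mean_insert,
        "f_bar": db.f_bar,
        "n_distinct_kmers": db.n_distinct,
        "n_fragments": table.n_attempted,
        "n_accepted": len(table),
        "n_junction": table.n_junction,
        "rejections": dict(table.rejections),
        "n_boot": params.n_boot,
        "seed": params.seed,
        "rho_obs": result.rho_obs.as_dict(),
        "alpha_lib": result.alpha_lib.as_dict(),
        "rho_lib": result.rho_lib.as_dict(),
        "flags": flags,
    }
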