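"""Canonical k-mer frequency database built from FASTQ reads.

Counts are keyed by canonical k-mer (the lexicographic minimum of a k-mer
and its reverse complement) so that frequencies are strand independent.
Bases below a Phred quality threshold break a read into segments; windows
spanning a masked or non-ACGT base are not counted.

The counter is an in-memory numpy implementation: bases are 2-bit encoded
and k-mer codes are accumulated with a rolling Horner scheme, so k is
limited to 31 code-wise (the practical range for junction flanking queries
is 16-32).  Databases round-trip through a small versioned text format that
doubles as an import path for external counter dumps (``KMER<TAB>COUNT``).
"""

from __future__ import annotations

import gzip
import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

__all__ = ["KmerDatabase", "build_db", "count_sequences", "load_db", "KmerFormatError"]

K_MIN, K_MAX = 4, 31

_MAGIC = "#pliqc-kmerdb"
_VERSION = 1

# byte -> 2-bit code; 255 marks invalid (non-ACGT or quality-masked)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


class KmerFormatError(ValueError):
    """Raised when a database file cannot be parsed or is incompatible."""


def _encode_bytes(buf: bytes) -> np.ndarray:
    return _ENCODE[np.frombuffer(buf, dtype=np.uint8)]


def _window_codes_numpy(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement codes of every k-window, plus validity.

    Returns (canonical_codes, valid) where invalid windows (containing a
    255 base) are flagged False.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    c = codes.astype(np.int64)
    bad = (c >= 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    c = np.where(c >= 4, 0, c)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for j in range(k):
        fwd += c[j : j + n] << (2 * (k - 1 - j))
        rev += (3 - c[j : j + n]) << (2 * j)
    canon = np.minimum(fwd, rev).astype(np.uint64)
    return canon, valid


try:  # rolling-hash kernel; the numpy path is the reference fallback
    from numba import njit

    @njit(cache=True)
    def _window_codes_jit(codes, k):  # pragma: no cover - exercised via wrapper
        n = codes.size - k + 1
        out = np.zeros(n, dtype=np.uint64)
        valid = np.zeros(n, dtype=np.bool_)
        mask = np.uint64((1 << (2 * k)) - 1)
        top = np.uint64(2 * (k - 1))
        fwd = np.uint64(0)
        rev = np.uint64(0)
        run = 0
        for i in range(codes.size):
            b = codes[i]
            if b >= 4:
                run = 0
                fwd = np.uint64(0)
                rev = np.uint64(0)
            else:
                run += 1
                fwd = ((fwd << np.uint64(2)) | np.uint64(b)) & mask
                rev = (rev >> np.uint64(2)) | (np.uint64(3 - b) << top)
            j = i - k + 1
            if j >= 0 and run >= k:
                out[j] = fwd if fwd < rev else rev
                valid[j] = True
        return out, valid

    def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        n = codes.size - k + 1
        if n <= 0:
            return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
        return _window_codes_jit(codes, k)

except ImportError:  # pragma: no cover
    _window_codes = _window_codes_numpy


def _canonical_codes_of(seqs: Sequence[str], k: int) -> np.ndarray:
    """Canonical codes of exact-length-k sequences; invalid -> sentinel max."""
    if len(seqs) == 0:
        return np.empty(0, dtype=np.uint64)
    buf = "".join(seqs).encode()
    if len(buf) != k * len(seqs):
        raise ValueError(f"all sequences must have length k={k}")
    c = _encode_bytes(buf).astype(np.int64).reshape(len(seqs), k)
    bad = (c >= 4).any(axis=1)
    c = np.where(c >= 4, 0, c)
    fwd = np.zeros(len(seqs), dtype=np.int64)
    rev = np.zeros(len(seqs), dtype=np.int64)
    for j in range(k):
        fwd += c[:, j] << (2 * (k - 1 - j))
        rev += (3 - c[:, j]) << (2 * j)
    canon = np.minimum(fwd, rev).astype(np.uint64)
    canon[bad] = np.iinfo(np.uint64).max
    return canon


def _decode_code(code: int, k: int) -> str:
    out = bytearray(k)
    for j in range(k - 1, -1, -1):
        out[j] = _DECODE[code & 3]
        code >>= 2
    return out.decode()


@dataclass
class KmerDatabase:
    """Sorted-array map from canonical k-mer code to count."""

    k: int
    codes: np.ndarray  # uint64, sorted ascending, distinct
    counts: np.ndarray  # int64, aligned with codes
    min_quality: int = 0
    source: str = ""

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def f_bar(self) -> float:
        """Mean frequency over distinct stored k-mers (singletons included)."""
        if self.codes.size == 0:
            raise ValueError("empty database has no mean frequency")
        return float(self.counts.mean())

    def query(self, seq: str) -> int | None:
        """Count of one k-mer, or None when the k-mer is absent ("missing")."""
        if len(seq) != self.k:
            raise ValueError(f"query length {len(seq)} != k={self.k}")
        code = _canonical_codes_of([seq], self.k)
        if code[0] == np.iinfo(np.uint64).max:
            return None  # non-ACGT symbols can never have been stored
        c = self.query_codes(code)[0]
        return None if c < 0 else int(c)

    def query_codes(self, canon: np.ndarray) -> np.ndarray:
        """Vectorised lookup of canonical codes; missing entries are -1."""
        idx = np.searchsorted(self.codes, canon)
        idx_c = np.minimum(idx, self.codes.size - 1) if self.codes.size else idx
        hit = (
            (self.codes.size > 0)
            & (idx < self.codes.size)
            & (self.codes[idx_c] == canon)
        )
        out = np.full(canon.size, -1, dtype=np.int64)
        out[hit] = self.counts[idx_c[hit]]
        return out

    def canonical_codes(self, seqs: Sequence[str]) -> np.ndarray:
        return _canonical_codes_of(seqs, self.k)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            fh.write(f"{_MAGIC} v{_VERSION}\n")
            fh.write(f"#k={self.k}\tmin_quality={self.min_quality}\n")
            fh.write(f"#n_distinct={self.n_distinct}\tf_bar={self.f_bar!r}\n")
            for code, count in zip(self.codes.tolist(), self.counts.tolist()):
                fh.write(f"{_decode_code(code, self.k)}\t{count}\n")


def load_db(path: str | Path) -> KmerDatabase:
    """Load a saved database, or import a bare ``KMER<TAB>COUNT`` dump."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.readline()
        if first.startswith("#"):
            if not first.startswith(_MAGIC):
                raise KmerFormatError(f"{path}: unrecognised header {first!r}")
            header = fh.readline()
            try:
                fields = dict(
                    kv.split("=") for kv in header.lstrip("#").split()
                )
                k = int(fields["k"])
                min_quality = int(fields["min_quality"])
            except (ValueError, KeyError) as exc:
                raise KmerFormatError(f"{path}: bad header line") from exc
            line3 = fh.readline()
            if not line3.startswith("#"):
                fh = _chain_line(line3, fh)
        else:
            # bare text import: infer k from the first record
            k = len(first.split("\t")[0])
            min_quality = 0
            fh = _chain_line(first, fh)
        kmers: list[str] = []
        counts: list[int] = []
        for line in fh:
            if not line.strip():
                continue
            km, cnt = line.split("\t")
            if len(km) != k:
                raise KmerFormatError(f"{path}: record length != k={k}")
            kmers.append(km)
            counts.append(int(cnt))
    if not kmers:
        raise KmerFormatError(f"{path}: no k-mer records")
    return _from_pairs(kmers, np.asarray(counts, dtype=np.int64), k, min_quality)


def _chain_line(line: str, fh: io.TextIOBase):
    yield line
    yield from fh


def _from_pairs(
    kmers: Sequence[str], counts: np.ndarray, k: int, min_quality: int
) -> KmerDatabase:
    canon = _canonical_codes_of(kmers, k)
    order = np.argsort(canon, kind="stable")
    canon, counts = canon[order], counts[order]
    uniq, start = np.unique(canon, return_index=True)
    if uniq.size != canon.size:  # merge records that canonicalise together
        summed = np.add.reduceat(counts, start)
        canon, counts = uniq, summed
    return KmerDatabase(k=k, codes=canon, counts=counts, min_quality=min_quality)


# -- construction ---------------------------------------------------------


def count_sequences(
    seqs: Iterable[str],
    k: int,
    quals: Iterable[Sequence[int]] | None = None,
    min_quality: int = 0,
) -> KmerDatabase:
    """Count canonical k-mers of in-memory sequences.

    ``quals`` (Phred scores per base) is consulted only when
    ``min_quality > 0``: low-quality bases are masked and windows spanning
    them are dropped.
    """
    if not K_MIN <= k <= K_MAX:
        raise ValueError(f"k={k} outside supported range [{K_MIN}, {K_MAX}]")
    chunks: list[np.ndarray] = []
    qual_iter = iter(quals) if quals is not None else None
    mask_quals = qual_iter is not None and min_quality > 0

    # reads are joined with an invalid separator byte so windows never
    # span a read boundary; one encode pass per multi-megabase batch
    buf: list[str] = []
    qbuf: list[np.ndarray] = []
    buf_len = 0

    def flush() -> None:
        nonlocal buf, qbuf, buf_len
        if not buf:
            return
        codes = _encode_bytes("\n".join(buf).encode())
        if mask_quals:
            q = np.concatenate(qbuf)
            codes[q < min_quality] = 255
        canon, valid = _window_codes(codes, k)
        chunks.append(canon[valid])
        buf, qbuf, buf_len = [], [], 0

    qsep = np.array([127], dtype=np.int64)
    for seq in seqs:
        buf.append(seq)
        if mask_quals:
            q = np.asarray(next(qual_iter), dtype=np.int64)
            if q.size != len(seq):
                raise ValueError("quality array length != read length")
            qbuf.append(q)
            qbuf.append(qsep)
        buf_len += len(seq) + 1
        if buf_len >= 8_000_000:
            if mask_quals:
                qbuf.pop()  # no separator after the final read of a batch
            flush()
    if mask_quals and qbuf:
        qbuf.pop()
    flush()
    if chunks:
        allc = np.concatenate(chunks)
        codes_u, counts = np.unique(allc, return_counts=True)
    else:
        codes_u = np.empty(0, dtype=np.uint64)
        counts = np.empty(0, dtype=np.int64)
    return KmerDatabase(
        k=k, codes=codes_u, counts=counts.astype(np.int64), min_quality=min_quality
    )


def build_db(
    reads: Sequence[str | Path],
    k: int,
    min_quality: int = 0,
    limit: int | None = None,
) -> KmerDatabase:
    """Build a canonical k-mer database from FASTQ files (plain or gzip)."""
    paths = [Path(p) for p in reads]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)

    def seq_iter():
        n = 0
        for p in paths:
            with pysam.FastxFile(str(p)) as fx:
                for rec in fx:
                    yield rec.sequence, rec.get_quality_array()
                    n += 1
                    if limit is not None and n >= limit:
                        return

    seqs = []
    quals = []
    for s, q in seq_iter():
        seqs.append(s)
        quals.append(q if q is not None else [93] * len(s))
    db = count_sequences(
        seqs, k, quals=quals if min_quality > 0 else None, min_quality=min_quality
    )
    h = hashlib.sha256()
    for p in paths:
        h.update(p.name.encode())
    db.source = ",".join(p.name for p in paths) + ":" + h.hexdigest()[:12]
    return db
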