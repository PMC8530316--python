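"""Seeded synthetic Hi-C library generator with a truth table.

Emulates the minimum of the Hi-C protocol the estimator cares about: a
random genome, restriction digestion, chimeric proximity-ligation (PL)
inserts whose junction motif sits uniformly along the insert, a controlled
PL fraction, Gaussian insert lengths and fixed-length paired reads with
i.i.d. substitution errors.  Every pair is recorded in a truth table so
parameter recovery can be scored exactly.

A PL insert joins the end-filled blunt ends of two independently chosen
restriction cut sites: the upstream part is genomic sequence ending at a
cut-derived end (whose terminal bases are the enzyme's end-fill
contribution) and the downstream part starts at another cut-derived end,
so the concatenation contains the exact junction motif at the drawn offset
u ~ U(0, L - l_LA).  Non-PL (noise) pairs are plain shotgun substrings.
There is no distance decay or 3D structure: the estimator under test
ignores pair separation, so uniform cut choice introduces no model
mismatch.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .digest import Enzyme, JunctionSet, find_cut_sites, junction_set, parse_enzyme

__all__ = ["SimConfig", "SimResult", "random_genome", "make_pl_insert",
           "make_shotgun_insert", "simulate"]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Synthetic library conditions (defaults mirror the validation regime:
    150 bp reads, DpnII digest, 300 +/- 50 bp inserts)."""

    genome_length: int = 500_000
    gc: float = 0.5
    enzymes: tuple[str, ...] = ("DpnII",)
    n_pairs: int = 100_000
    hic_fraction: float = 0.5
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    read_length: int = 150
    substitution_error: float = 0.001
    seed: int = 1

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome length must be positive")
        if not 0.0 <= self.hic_fraction <= 1.0:
            raise ValueError("hic_fraction must be in [0, 1]")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")
        if not 0.0 <= self.substitution_error < 1.0:
            raise ValueError("substitution_error must be in [0, 1)")


@dataclass
class SimResult:
    """In-memory library: reads, truth table, genome and the digest used."""

    config: SimConfig
    genome: str
    r1: list[str]
    r2: list[str]
    truth: pd.DataFrame
    junctions: JunctionSet
    contig: str = "sim_contig"
    qual_char: str = "I"  # Q40 written for every base

    def fragments(self):
        """Read pairs as the estimator consumes them."""
        return zip(self.r1, self.r2)

    # -- file output ------------------------------------------------------

    def write(self, outdir: str | Path, gzip_fastq: bool = True) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = ".fastq.gz" if gzip_fastq else ".fastq"
        paths = {
            "genome": outdir / "genome.fasta",
            "r1": outdir / f"reads_R1{ext}",
            "r2": outdir / f"reads_R2{ext}",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["genome"], "w") as fh:
            fh.write(f">{self.contig}\n")
            for i in range(0, len(self.genome), 80):
                fh.write(self.genome[i : i + 80] + "\n")
        for key, reads, mate in (("r1", self.r1, 1), ("r2", self.r2, 2)):
            opener = gzip.open if gzip_fastq else open
            with opener(paths[key], "wt") as fh:
                for i, seq in enumerate(reads):
                    fh.write(f"@pair_{i}/{mate}\n{seq}\n+\n{self.qual_char * len(seq)}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def random_genome(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. random genome at the requested GC content."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return bases.tobytes().decode()


def _end_partition(junctions: JunctionSet):
    """Per-enzyme end-fill contributions for insert construction."""
    return [(e, e.end_fill_left, e.end_fill_right) for e in junctions.enzymes]


def make_pl_insert(
    genome: str,
    cuts_by_enzyme: dict[str, list[int]],
    length: int,
    junctions: JunctionSet,
    rng: np.random.Generator,
) -> tuple[str, int, tuple[int, int]]:
    """One chimeric PL insert: returns (sequence, junction offset u, loci).

    Draws two cut occurrences (independent enzymes for dual digests),
    places the junction uniformly (u ~ U(0, L - l_LA)) and pastes genomic
    sequence around the two end-filled termini.  Draws are retried when a
    chosen cut is too close to a genome edge to supply flanking sequence.
    """
    ends = _end_partition(junctions)
    enz_a, left_a, _ = ends[int(rng.integers(len(ends)))]
    enz_b, _, right_b = ends[int(rng.integers(len(ends)))]
    l_la = len(left_a) + len(right_b)
    if length < l_la + 2:
        raise ValueError(f"insert length {length} < l_LA + 2 = {l_la + 2}")
    cuts_a = cuts_by_enzyme[enz_a.name]
    cuts_b = cuts_by_enzyme[enz_b.name]
    if len(cuts_a) < 2 or len(cuts_b) < 2:
        raise ValueError("genome has too few cut sites for proximity ligation")
    u = int(rng.integers(0, length - l_la + 1))
    left_need = u + len(left_a)
    right_need = length - left_need
    for _ in range(64):
        ca = int(cuts_a[int(rng.integers(len(cuts_a)))])
        cb = int(cuts_b[int(rng.integers(len(cuts_b)))])
        # end-filled upstream terminus extends len(overhang) past the cut;
        # the downstream terminus starts exactly at the cut position
        a_end = ca + len(enz_a.overhang)
        b_start = cb
        if a_end - left_need < 0 or b_start + right_need > len(genome):
            continue
        left = genome[a_end - left_need : a_end]
        right = genome[b_start : b_start + right_need]
        return left + right, u, (a_end, b_start)
    raise ValueError("could not place a PL insert within the genome")


def make_shotgun_insert(
    genome: str, length: int, rng: np.random.Generator
) -> tuple[str, int]:
    """One conventional shotgun insert: contiguous substring, uniform start."""
    if length > len(genome):
        raise ValueError("insert longer than genome")
    start = int(rng.integers(0, len(genome) - length + 1))
    return genome[start : start + length], start


def _apply_errors(reads: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    if rate <= 0 or not reads:
        return reads
    buf = bytearray("".join(reads).encode())
    arr = np.frombuffer(buf, dtype=np.uint8)
    n_err = rng.binomial(arr.size, rate)
    if n_err:
        pos = rng.choice(arr.size, size=n_err, replace=False)
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        code = np.zeros(256, dtype=np.uint8)
        code[np.frombuffer(b"ACGT", dtype=np.uint8)] = np.arange(4)
        new = (code[arr[pos]] + shift) % 4
        arr[pos] = np.frombuffer(b"ACGT", dtype=np.uint8)[new]
    flat = bytes(buf).decode()
    out, off = [], 0
    for r in reads:
        out.append(flat[off : off + len(r)])
        off += len(r)
    return out


def simulate(config: SimConfig) -> SimResult:
    """Generate a full synthetic library (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    genome = random_genome(config.genome_length, config.gc, rng)
    enzymes = [parse_enzyme(e) for e in config.enzymes]
    juncs = junction_set(*enzymes) if len(enzymes) > 1 else junction_set(enzymes[0])
    cuts = {e.name: find_cut_sites(genome, e) for e in enzymes}
    for e in enzymes:
        if len(cuts[e.name]) < 2:
            raise ValueError(f"genome has < 2 cut sites for {e.name}")

    lengths = rng.normal(config.insert_mean, config.insert_sd, config.n_pairs)
    lengths = np.maximum(np.rint(lengths), config.read_length).astype(int)
    is_pl = rng.random(config.n_pairs) < config.hic_fraction

    r1: list[str] = []
    r2: list[str] = []
    rows = []
    rl = config.read_length
    for i in range(config.n_pairs):
        L = int(lengths[i])
        if is_pl[i]:
            insert, u, loci = make_pl_insert(genome, cuts, L, juncs, rng)
        else:
            insert, start = make_shotgun_insert(genome, L, rng)
            u, loci = -1, (start, start)
        r1.append(insert[:rl])
        r2.append(_revcomp(insert[-rl:]))
        rows.append(
            (f"pair_{i}", bool(is_pl[i]), u, L, loci[0], loci[1])
        )
    r1 = _apply_errors(r1, config.substitution_error, rng)
    r2 = _apply_errors(r2, config.substitution_error, rng)
    truth = pd.DataFrame(
        rows, columns=["pair_id", "is_PL", "u", "insert_len", "locus_a", "locus_b"]
    )
    return SimResult(config=config, genome=genome, r1=r1, r2=r2, truth=truth,
                     junctions=juncs)
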