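"""Reference-based pair QC on a small constructed alignment set.

Builds a toy contig with four DpnII cut sites and a name-grouped SAM of
four read pairs, one per classical Hi-C pair class, then runs the
reference-based report.  Class counts follow the cut-site rules: a pair is
valid only when at least two cut sites lie between the mates.
"""

import tempfile
from pathlib import Path

import numpy as np
import pysam

from pliqc import bam_report, junction_set, parse_enzyme

rng = np.random.default_rng(40)
genome = "".join(rng.choice(list("ACGT"), 4500)).replace("GATC", "ACCA")
for pos in (1000, 2000, 3000, 4000):
    genome = genome[:pos] + "GATC" + genome[pos + 4:]

pairs = [
    ("dangling", (1100, False), (1900, True)),   # one fragment, inward
    ("self_circle", (1100, True), (1850, False)),  # one fragment, outward
    ("religation", (1900, False), (2100, True)),   # adjacent fragments
    ("valid", (1100, False), (3500, True)),        # two intervening cuts
]

with tempfile.TemporaryDirectory() as tmp:
    sam = Path(tmp) / "toy.sam"
    header = {"HD": {"VN": "1.6", "SO": "queryname"},
              "SQ": [{"SN": "toy", "LN": 4500}]}
    with pysam.AlignmentFile(str(sam), "w", header=header) as out:
        for name, m1, m2 in pairs:
            for i, (pos5, reverse) in enumerate((m1, m2)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = name
                a.query_sequence = "A" * 100
                a.reference_id = 0
                a.mapping_quality = 60
                a.cigarstring = "100M"
                a.is_paired = True
                a.is_read1 = i == 0
                a.is_read2 = i == 1
                a.is_reverse = reverse
                a.reference_start = pos5 - 99 if reverse else pos5
                out.write(a)

    dpnii = parse_enzyme("DpnII")
    stats = bam_report(sam, {"toy": genome}, [dpnii], junction_set(dpnii))

print(f"analyzed {stats.n_analyzed} pairs")
for cls, count in stats.class_counts.items():
    if count:
        print(f"  {cls:14s} {count}")
print(f"fraction separated > 1 kb: {stats.long_range_frac_1kb:.2f} "
      "(only the valid pair spans that far)")
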