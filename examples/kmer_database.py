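"""Build, persist and query a canonical k-mer frequency database.

Counts are canonical (strand independent); querying a k-mer absent from
the input returns None ("missing"), which the estimator treats differently
from a low count.
"""

import tempfile
from pathlib import Path

from pliqc import count_sequences, load_db

reads = ["ACGTACGTGG", "CCACGTACGT"]  # the second is the reverse complement
db = count_sequences(reads, k=6)
print(f"k={db.k}, {db.n_distinct} distinct canonical 6-mers, "
      f"f_bar={db.f_bar:.2f}")

for q in ("ACGTAC", "GTACGT", "AAAAAA"):
    print(f"  query {q}: {db.query(q)}")  # GTACGT canonicalises to ACGTAC

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "library.kdb"
    db.save(path)
    back = load_db(path)
    print(f"round-trip: k={back.k}, f_bar={back.f_bar:.2f}, "
          f"identical={back.n_distinct == db.n_distinct}")
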